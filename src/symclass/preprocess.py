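"""Leakage-safe modality preprocessing chains.

Each step estimates its parameters on the training fold only (optionally on
a reference group within it, typically the healthy controls) and applies the
frozen transform to any data. Chains compose steps in a fixed order and
serialize to plain dicts/JSON.

Per-modality default chains:

* neurocognition: covariate regression (age, sex) -> z-score -> winsorize
* fALFF slow-5 / slow-4, functional connectivity, GMV: site mean-offset
  correction (HC reference) -> covariate regression (age, sex, FD; HC
  reference) -> reliability mask -> PCA by retained variance energy ->
  median-based z-score -> winsorize
* polygenic scores: covariate regression (age, sex, 10 ancestry components)
  -> z-score -> winsorize

Winsorization clips standardized values at +/-4 SD (clipping applied after
scaling so the bound is well-defined).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "Step",
    "CovariateRegress",
    "SiteOffsetCorrect",
    "ReliabilityMask",
    "PCAEnergy",
    "ScaleWinsorize",
    "PreprocessChain",
    "build_chain",
    "MODALITIES",
]

MODALITIES = ("neurocognition", "falff5", "falff4", "fc", "gmv", "prs")

ANCESTRY_COLS = [f"pc{j + 1}" for j in range(10)]


class NotFittedError(RuntimeError):
    pass


class Step:
    """Base preprocessing step with fit/apply separation."""

    name = "step"
    uses_covariates: tuple[str, ...] = ()

    def __init__(self):
        self.fitted = False

    def fit(self, X: np.ndarray, meta: pd.DataFrame, reference: np.ndarray) -> None:
        raise NotImplementedError

    def apply(self, X: np.ndarray, meta: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def backproject(self, w: np.ndarray) -> np.ndarray:
        """Map a weight vector from this step's output space to its input
        space. Linear maps only where meaningful; default is identity."""
        return w

    def params(self) -> dict:
        return {}


def _design(meta: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    names = []
    for c in covariates:
        if c == "ancestry":
            for a in ANCESTRY_COLS:
                cols.append(meta[a].values.astype(float))
                names.append(a)
        else:
            cols.append(meta[c].values.astype(float))
            names.append(c)
    C = np.column_stack([np.ones(len(meta))] + cols) if cols else np.ones((len(meta), 1))
    return C, ["intercept"] + names


class CovariateRegress(Step):
    """Remove linear covariate effects estimated by per-feature OLS on the
    reference subset of the training fold (intercept included, so reference
    residual means are ~0)."""

    name = "covariate_regress"

    def __init__(self, covariates=("age", "sex")):
        super().__init__()
        self.covariates = tuple(covariates)
        self.betas: np.ndarray | None = None

    def fit(self, X, meta, reference):
        C, names = _design(meta.loc[reference], self.covariates)
        rank = np.linalg.matrix_rank(C)
        if rank < C.shape[1]:
            # identify the offending columns for the error message
            bad = []
            for j in range(1, C.shape[1]):
                sub = np.delete(C, j, axis=1)
                if np.linalg.matrix_rank(sub) == rank:
                    bad.append(names[j])
            raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
        self.betas, *_ = np.linalg.lstsq(C, X[reference], rcond=None)
        self.fitted = True

    def apply(self, X, meta):
        C, _ = _design(meta, self.covariates)
        return X - C @ self.betas

    def params(self):
        return {"covariates": list(self.covariates), "betas": self.betas.tolist()}


class SiteOffsetCorrect(Step):
    """Subtract per-site per-feature mean offsets estimated on the reference
    subset (site mean minus grand mean). Sites unseen at fit time, or with
    no reference subjects, fall back to the global offset (zero) with a
    warning."""

    name = "site_offset_correct"

    def __init__(self, site_col: str = "site"):
        super().__init__()
        self.site_col = site_col
        self.offsets: dict = {}
        self.grand_mean: np.ndarray | None = None

    def fit(self, X, meta, reference):
        sites_all = pd.unique(meta[self.site_col])
        ref_sites = meta.loc[reference, self.site_col].values
        Xr = X[reference]
        self.grand_mean = Xr.mean(axis=0)
        self.offsets = {}
        for s in sites_all:
            rows = Xr[ref_sites == s]
            if len(rows) == 0:
                warnings.warn(
                    f"site {s!r} has no reference subjects in the training fold; "
                    "falling back to global offset",
                    RuntimeWarning,
                    stacklevel=2,
                )
                self.offsets[s] = np.zeros(X.shape[1])
            else:
                self.offsets[s] = rows.mean(axis=0) - self.grand_mean
        self.fitted = True

    def apply(self, X, meta):
        out = X.copy()
        sites = meta[self.site_col].values
        for s in pd.unique(sites):
            if s not in self.offsets:
                warnings.warn(
                    f"site {s!r} unseen at fit time; applying global offset",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            out[sites == s] -= self.offsets[s]
        return out

    def params(self):
        return {
            "offsets": {str(s): o.tolist() for s, o in self.offsets.items()},
            "grand_mean": self.grand_mean.tolist(),
        }


class ReliabilityMask(Step):
    """Drop features where a binary reliability mask is zero. The mask is an
    externally supplied input (e.g. an inter-site reliability map thresholded
    upstream); an all-ones mask is the identity."""

    name = "reliability_mask"

    def __init__(self, mask: np.ndarray | None = None):
        super().__init__()
        self.mask = None if mask is None else np.asarray(mask).astype(bool)

    def fit(self, X, meta, reference):
        if self.mask is None:
            self.mask = np.ones(X.shape[1], dtype=bool)
        if len(self.mask) != X.shape[1]:
            raise ValueError(
                f"mask length {len(self.mask)} != feature count {X.shape[1]}"
            )
        self.fitted = True

    def apply(self, X, meta):
        if X.shape[1] != len(self.mask):
            raise ValueError("feature count mismatch with fitted mask")
        return X[:, self.mask]

    def backproject(self, w):
        out = np.zeros(len(self.mask))
        out[self.mask] = w
        return out

    def params(self):
        return {"mask": self.mask.astype(int).tolist()}


class PCAEnergy(Step):
    """Project onto the leading principal components covering at least the
    requested share of total variance ('energy'). Centered internally; the
    center and basis are stored at fit time."""

    name = "pca_energy"

    def __init__(self, energy: float = 0.8):
        super().__init__()
        if not (0.0 < energy <= 1.0):
            raise ValueError("energy must be in (0, 1]")
        self.energy = energy
        self.center: np.ndarray | None = None
        self.basis: np.ndarray | None = None  # features x n_components
        self.n_components: int | None = None

    def fit(self, X, meta, reference):
        self.center = X.mean(axis=0)
        Xc = X - self.center
        # economical SVD; eigenvalue share = squared singular value share
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2
        total = var.sum()
        if total <= 0:
            raise ValueError("training data has zero total variance")
        share = np.cumsum(var) / total
        ncomp = int(np.searchsorted(share, self.energy - 1e-12) + 1)
        ncomp = min(ncomp, np.sum(var > total * 1e-12))
        self.n_components = max(1, ncomp)
        self.basis = Vt[: self.n_components].T
        self.fitted = True

    def apply(self, X, meta):
        return (X - self.center) @ self.basis

    def backproject(self, w):
        return self.basis @ w

    def params(self):
        return {
            "energy": self.energy,
            "n_components": self.n_components,
            "center": self.center.tolist(),
            "basis": self.basis.tolist(),
        }


class ScaleWinsorize(Step):
    """Standardize with training-fold center/scale (mean or median center,
    SD scale) and clip at +/- ``limit`` afterwards. Zero-scale features are
    dropped with a warning and recorded."""

    name = "scale_winsorize"

    def __init__(self, center: str = "mean", limit: float = 4.0):
        if center not in ("mean", "median"):
            raise ValueError("center must be 'mean' or 'median'")
        super().__init__()
        self.center_kind = center
        self.limit = limit
        self.center: np.ndarray | None = None
        self.scale: np.ndarray | None = None
        self.kept: np.ndarray | None = None
        self.dropped: list[int] = []

    def fit(self, X, meta, reference):
        c = np.median(X, axis=0) if self.center_kind == "median" else X.mean(axis=0)
        s = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        self.kept = s > 0
        self.dropped = list(np.flatnonzero(~self.kept))
        if self.dropped:
            warnings.warn(
                f"dropping {len(self.dropped)} zero-scale feature(s)",
                RuntimeWarning,
                stacklevel=2,
            )
        self.center = c[self.kept]
        self.scale = s[self.kept]
        self.fitted = True

    def apply(self, X, meta):
        Z = (X[:, self.kept] - self.center) / self.scale
        return np.clip(Z, -self.limit, self.limit)

    def backproject(self, w):
        out = np.zeros(len(self.kept))
        out[self.kept] = w  # scale left in standardized units
        return out

    def params(self):
        return {
            "center_kind": self.center_kind,
            "limit": self.limit,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "dropped": self.dropped,
        }


_STEP_TYPES = {
    cls.name: cls
    for cls in (CovariateRegress, SiteOffsetCorrect, ReliabilityMask, PCAEnergy, ScaleWinsorize)
}


class PreprocessChain:
    """Ordered, leakage-safe composition of preprocessing steps.

    ``reference_group`` restricts parameter estimation of every step to that
    label within the training fold ('all' uses everyone). ``fit`` must
    precede ``apply``; applying to the training data reproduces the fit-time
    transform exactly (parameters are frozen, never re-estimated).
    """

    def __init__(self, steps: list[Step], reference_group: str = "all"):
        self.steps = steps
        self.reference_group = reference_group
        self.fitted = False

    def fit(self, X: np.ndarray, meta: pd.DataFrame, labels: pd.Series | np.ndarray):
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        if self.reference_group == "all":
            reference = np.ones(len(labels), dtype=bool)
        else:
            reference = labels == self.reference_group
            if reference.sum() == 0:
                raise ValueError(
                    f"no subjects of reference group {self.reference_group!r} in fold"
                )
        for step in self.steps:
            step.fit(X, meta, reference)
            X = step.apply(X, meta)
        self.fitted = True
        return self

    def apply(self, X: np.ndarray, meta: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("chain must be fitted before apply()")
        X = np.asarray(X, dtype=float)
        for step in self.steps:
            X = step.apply(X, meta)
        return X

    def fit_apply(self, X, meta, labels) -> np.ndarray:
        self.fit(X, meta, labels)
        return self.apply(X, meta)

    def backproject(self, w: np.ndarray) -> np.ndarray:
        """Map a model weight vector from the chain's output space back to
        input-feature space through the linear steps (PCA basis, masks)."""
        for step in reversed(self.steps):
            w = step.backproject(w)
        return w

    @property
    def step_names(self) -> list[str]:
        return [s.name for s in self.steps]

    def to_dict(self) -> dict:
        return {
            "reference_group": self.reference_group,
            "steps": [
                {"name": s.name, "fitted": s.fitted, "params": s.params() if s.fitted else {}}
                for s in self.steps
            ],
        }


def build_chain(modality: str, config: dict | None = None) -> PreprocessChain:
    """Default preprocessing chain for a modality.

    ``config`` keys (all optional): ``pca_energy`` (float), ``mask`` (binary
    vector for imaging modalities), ``reference_group`` (default 'HC' for
    imaging, 'all' otherwise), ``winsor_limit``; ``preset: 'generic'``
    selects a plain standardize+winsorize chain for arbitrary feature tables
    (``preset: 'generic_pca'`` additionally inserts a PCA step).
    """
    config = dict(config or {})
    limit = float(config.get("winsor_limit", 4.0))
    energy = float(config.get("pca_energy", 0.8))
    mask = config.get("mask")

    preset = config.get("preset")
    if preset in ("generic", "generic_pca"):
        ref = config.get("reference_group", "all")
        steps = [ScaleWinsorize(center="mean", limit=limit)]
        if preset == "generic_pca":
            steps.insert(0, PCAEnergy(energy))
        return PreprocessChain(steps, reference_group=ref)

    if modality == "neurocognition":
        ref = config.get("reference_group", "all")
        steps = [
            CovariateRegress(("age", "sex")),
            ScaleWinsorize(center="mean", limit=limit),
        ]
    elif modality in ("falff5", "falff4", "fc", "gmv"):
        ref = config.get("reference_group", "HC")
        steps = [
            SiteOffsetCorrect(),
            CovariateRegress(("age", "sex", "fd")),
            ReliabilityMask(mask),
            PCAEnergy(energy),
            ScaleWinsorize(center="median", limit=limit),
        ]
    elif modality == "prs":
        ref = config.get("reference_group", "all")
        steps = [
            CovariateRegress(("age", "sex", "ancestry")),
            ScaleWinsorize(center="mean", limit=limit),
        ]
    else:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    return PreprocessChain(steps, reference_group=ref)
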