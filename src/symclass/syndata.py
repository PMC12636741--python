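"""Synthetic cohort generator for the subtyping-and-classification pipeline.

Emulates a multi-site early-psychosis study at the level the downstream
analysis consumes: 30 ordinal symptom items (1-7, floor-heavy like clinical
rating scales) generated from a correlated 4-factor model, patient subgroups
defined by each subject's dominant symptom dimension, and per-modality
numeric feature tables (neurocognition, fALFF slow-5/slow-4, functional
connectivity, gray-matter volume, polygenic scores) carrying planted group
effects, additive site offsets and linear age/sex/motion confounds.

Every generated cohort carries a ``truth`` record (true subgroup, affected
feature indices) so recovery and calibration tests have a ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorSpec",
    "ModalityEffect",
    "EffectSpec",
    "Cohort",
    "default_factor_spec",
    "default_effect_spec",
    "generate_symptoms",
    "items_from_scores",
    "generate_cohort",
    "generate_followup",
    "make_default_cohort",
    "dominant_labels",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_N_HC",
    "DEFAULT_N_SITES",
]

# Cohort layout mirroring the study the pipeline targets: four patient
# subgroups plus healthy controls recruited across 7 sites.
DEFAULT_GROUP_SIZES = (92, 92, 82, 96)
DEFAULT_N_HC = 338
DEFAULT_N_SITES = 7

# PANSS item codes: 7 positive, 7 negative, 16 general psychopathology.
PANSS_ITEMS = (
    [f"P{i}" for i in range(1, 8)]
    + [f"N{i}" for i in range(1, 8)]
    + [f"G{i}" for i in range(1, 17)]
)

FACTOR_NAMES = ("MOTCOG", "POS", "SOCWD", "AFF")

# Item blocks per factor, highest-loading item first. Content loosely follows
# the usual motor/cognitive, positive, social-withdrawal and affective
# groupings of the 30 items.
_FACTOR_ITEMS = {
    "MOTCOG": ["N6", "N1", "N3", "G7", "N5", "G11", "G10", "N7"],
    "POS": ["G12", "G9", "P4", "P1", "P3", "P2", "P6", "P5"],
    "SOCWD": ["N4", "G16", "N2", "G13", "G15", "P7", "G5"],
    "AFF": ["G2", "G4", "G6", "G3", "G1", "G14", "G8"],
}
# Primary loading levels per factor; items within a block span base +/- 0.12.
_FACTOR_BASE_LOADING = {"MOTCOG": 0.70, "POS": 0.58, "SOCWD": 0.57, "AFF": 0.55}

# Moderate oblique factor correlations (0.25-0.40).
_DEFAULT_PHI = np.array(
    [
        [1.00, 0.30, 0.35, 0.25],
        [0.30, 1.00, 0.28, 0.32],
        [0.35, 0.28, 1.00, 0.30],
        [0.25, 0.32, 0.30, 1.00],
    ]
)

# Floor-heavy category probabilities for the 7-point ordinal scale; most
# subjects score low on most symptom items.
_CATEGORY_PROBS = np.array([0.35, 0.25, 0.16, 0.10, 0.07, 0.045, 0.025])


@dataclass
class FactorSpec:
    """Ground-truth factor model: loadings, factor correlations, thresholds."""

    loadings: np.ndarray  # items x k, pattern loadings
    factor_corr: np.ndarray  # k x k
    thresholds: np.ndarray  # items x 6, strictly increasing cutpoints
    item_names: list[str]
    factor_names: list[str]
    seed: int = 0

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def uniquenesses(self) -> np.ndarray:
        """Per-item unique variance; communality + uniqueness = 1."""
        return 1.0 - self.communalities

    @property
    def communalities(self) -> np.ndarray:
        return np.diag(self.loadings @ self.factor_corr @ self.loadings.T)

    def implied_correlation(self) -> np.ndarray:
        """Model-implied item correlation matrix L Phi L' + Psi."""
        return self.loadings @ self.factor_corr @ self.loadings.T + np.diag(
            self.uniquenesses
        )

    def variance_profile(self) -> np.ndarray:
        """Per-factor common-variance shares, sorted descending.

        Share_j = sum_i pattern_ij * structure_ij / n_items; the cumulative
        sum ends at the mean communality.
        """
        S = self.loadings @ self.factor_corr
        v = np.sum(self.loadings * S, axis=0) / self.n_items
        return np.sort(v)[::-1]

    def validate(self) -> None:
        k = self.n_factors
        Phi = self.factor_corr
        if Phi.shape != (k, k) or not np.allclose(Phi, Phi.T):
            raise ValueError("factor_corr must be symmetric k x k")
        if not np.allclose(np.diag(Phi), 1.0, atol=1e-9):
            raise ValueError("factor_corr must have unit diagonal")
        if np.linalg.eigvalsh(Phi).min() <= 0:
            raise ValueError("factor_corr is not positive definite")
        if np.any(self.uniquenesses <= 0) or np.any(self.uniquenesses > 1):
            raise ValueError("implied uniquenesses must lie in (0, 1]")
        if self.thresholds.shape != (self.n_items, 6):
            raise ValueError("thresholds must be items x 6")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing")


@dataclass
class ModalityEffect:
    """Planted structure of one feature table.

    ``effect_size`` is the standardized mean difference each affected feature
    shows between a patient group and HC (sign pattern drawn per group);
    ``covar_betas`` maps covariate name -> per-feature slope (scalar
    broadcasts).
    """

    n_features: int
    affected_fraction: float = 0.1
    effect_size: float = 0.5
    noise_sd: float = 1.0
    site_sd: float = 0.0
    site_offsets: np.ndarray | None = None  # n_sites x n_features, overrides site_sd
    covar_betas: dict[str, float | np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise ValueError("affected_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")


@dataclass
class EffectSpec:
    modalities: dict[str, ModalityEffect]
    n_sites: int = DEFAULT_N_SITES

    def validate(self) -> None:
        for eff in self.modalities.values():
            eff.validate()


@dataclass
class Cohort:
    """Row-aligned multimodal tables + covariates + labels for one timepoint."""

    modalities: dict[str, pd.DataFrame]
    covariates: pd.DataFrame
    labels: pd.Series  # 'HC' or a subgroup name
    timepoint: str = "T0"
    truth: dict | None = None

    @property
    def subjects(self) -> pd.Index:
        return self.covariates.index

    def validate(self) -> None:
        idx = self.covariates.index
        if not self.labels.index.equals(idx):
            raise ValueError("labels not aligned with covariates")
        for name, tab in self.modalities.items():
            if not tab.index.equals(idx):
                raise ValueError(f"modality {name!r} not row-aligned")
            if tab.shape[1] == 0:
                raise ValueError(f"modality {name!r} has no features")
            if tab.isna().any().any():
                raise ValueError(f"modality {name!r} contains missing values")

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, tab in self.modalities.items():
            tab.to_csv(d / f"modality_{name}.csv", index_label="subject_id")
        self.covariates.to_csv(d / "covariates.csv", index_label="subject_id")
        self.labels.rename("label").to_frame().to_csv(
            d / "labels.csv", index_label="subject_id"
        )
        manifest = {
            "timepoint": self.timepoint,
            "modalities": sorted(self.modalities),
            "truth": _jsonify(self.truth) if self.truth is not None else None,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "Cohort":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        modalities = {
            name: pd.read_csv(d / f"modality_{name}.csv", index_col="subject_id")
            for name in manifest["modalities"]
        }
        covariates = pd.read_csv(d / "covariates.csv", index_col="subject_id")
        labels = pd.read_csv(d / "labels.csv", index_col="subject_id")["label"]
        return cls(
            modalities=modalities,
            covariates=covariates,
            labels=labels,
            timepoint=manifest["timepoint"],
            truth=manifest.get("truth"),
        )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def default_factor_spec(seed: int = 0) -> FactorSpec:
    """30-item, 4-factor simple-structure spec.

    Primary loadings span roughly 0.43-0.82 in blocks of 8/8/7/7 items with
    moderately correlated factors; the implied common-variance profile
    accumulates to ~13/22/30/37% across the four factors.
    """
    k = len(FACTOR_NAMES)
    p = len(PANSS_ITEMS)
    L = np.zeros((p, k))
    item_pos = {name: i for i, name in enumerate(PANSS_ITEMS)}
    for j, fname in enumerate(FACTOR_NAMES):
        items = _FACTOR_ITEMS[fname]
        base = _FACTOR_BASE_LOADING[fname]
        lam = np.linspace(base + 0.12, base - 0.12, len(items))
        for item, lo in zip(items, lam):
            L[item_pos[item], j] = lo
    cut = stats.norm.ppf(np.cumsum(_CATEGORY_PROBS)[:-1])
    thresholds = np.tile(cut, (p, 1))
    spec = FactorSpec(
        loadings=L,
        factor_corr=_DEFAULT_PHI.copy(),
        thresholds=thresholds,
        item_names=list(PANSS_ITEMS),
        factor_names=list(FACTOR_NAMES),
        seed=seed,
    )
    spec.validate()
    return spec


def _draw_scores(spec: FactorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    Phi = spec.factor_corr
    eigmin = np.linalg.eigvalsh(Phi).min()
    if eigmin <= 0:
        raise ValueError("factor_corr is not positive definite")
    C = np.linalg.cholesky(Phi)
    return rng.standard_normal((n, spec.n_factors)) @ C.T


def _enforce_dominance(
    scores: np.ndarray,
    dominant: np.ndarray,
    margin: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raise each subject's designated factor above the others by
    ``margin`` plus a small exponential gap (scale 0.25), keeping dominance
    strict even at margin 0."""
    out = scores.copy()
    n, k = scores.shape
    gap = rng.exponential(0.25, n)
    for i in range(n):
        d = dominant[i]
        others = np.delete(out[i], d)
        out[i, d] = others.max() + margin + gap[i]
    return out


def items_from_scores(
    spec: FactorSpec,
    scores: np.ndarray,
    rng: np.random.Generator,
    *,
    return_latent: bool = False,
):
    """Discretize latent item responses implied by factor scores into 1-7."""
    n = scores.shape[0]
    latent = scores @ spec.loadings.T + rng.standard_normal(
        (n, spec.n_items)
    ) * np.sqrt(spec.uniquenesses)
    items = 1 + np.sum(latent[:, :, None] > spec.thresholds[None, :, :], axis=2)
    df = pd.DataFrame(items.astype(int), columns=spec.item_names)
    if return_latent:
        return df, latent
    return df


def generate_symptoms(
    spec: FactorSpec,
    n_subjects: int,
    seed: int,
    *,
    dominant: np.ndarray | None = None,
    margin: float = 0.0,
    return_latent: bool = False,
):
    """Generate an ordinal symptom table plus the generating factor scores.

    Factor scores are drawn from N(0, Phi); latent item responses are formed
    through the loadings with Gaussian uniqueness noise and cut at the
    per-item thresholds. With ``dominant`` given (per-subject factor index),
    each subject's designated factor is raised above the others by at least
    ``margin`` SD, defining ground-truth subgroups. With ``return_latent``
    the pre-discretization item responses are returned as a third element
    (useful for checking implied moments without ordinal attenuation).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    spec.validate()
    rng = np.random.default_rng(seed)
    scores = _draw_scores(spec, n_subjects, rng)
    if dominant is not None:
        dominant = np.asarray(dominant, dtype=int)
        if dominant.shape != (n_subjects,):
            raise ValueError("dominant must have one factor index per subject")
        scores = _enforce_dominance(scores, dominant, margin, rng)
    idx = pd.Index([f"S{i:04d}" for i in range(n_subjects)], name="subject_id")
    if return_latent:
        X, latent = items_from_scores(spec, scores, rng, return_latent=True)
        X.index = idx
        return X, scores, latent
    X = items_from_scores(spec, scores, rng)
    X.index = idx
    return X, scores


def dominant_labels(group_sizes, seed: int) -> np.ndarray:
    """Shuffled per-subject dominant-factor indices with the given counts."""
    rng = np.random.default_rng(seed)
    lab = np.repeat(np.arange(len(group_sizes)), group_sizes)
    rng.shuffle(lab)
    return lab


def default_effect_spec(
    *,
    effect_size: float = 0.5,
    affected_fraction: float = 0.1,
    site_sd: float = 0.3,
    full_scale_fc: bool = False,
) -> EffectSpec:
    """Desk-scale modality layout.

    Feature counts: neurocognition 7 (six MATRICS-like domains + composite),
    fALFF slow-5/slow-4 500 components each, functional connectivity 190
    (20-ROI lower triangle; 15,400 edges for the full 176-ROI atlas via
    ``full_scale_fc``), GMV 1000, PRS 12. Imaging modalities carry motion
    (FD) confounds, PRS carries ancestry confounds.
    """
    n_fc = 15400 if full_scale_fc else 190
    imaging_betas = {"age": 0.02, "sex": 0.2, "fd": 0.5}
    mods = {
        "neurocognition": ModalityEffect(
            7, affected_fraction=0.3, effect_size=effect_size,
            covar_betas={"age": -0.02, "sex": 0.15},
        ),
        "falff5": ModalityEffect(
            500, affected_fraction=affected_fraction, effect_size=effect_size,
            site_sd=site_sd, covar_betas=dict(imaging_betas),
        ),
        "falff4": ModalityEffect(
            500, affected_fraction=affected_fraction, effect_size=effect_size,
            site_sd=site_sd, covar_betas=dict(imaging_betas),
        ),
        "fc": ModalityEffect(
            n_fc, affected_fraction=affected_fraction, effect_size=effect_size,
            site_sd=site_sd, covar_betas=dict(imaging_betas),
        ),
        "gmv": ModalityEffect(
            1000, affected_fraction=affected_fraction, effect_size=effect_size,
            site_sd=site_sd, covar_betas={"age": -0.03, "sex": 0.3, "fd": 0.2},
        ),
        "prs": ModalityEffect(
            12, affected_fraction=0.25, effect_size=effect_size * 0.6,
            covar_betas={"ancestry": 0.2},
        ),
    }
    return EffectSpec(modalities=mods)


def _covariates(n: int, n_sites: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(25.0, 6.0, n), 16, 45)
    sex = rng.binomial(1, 0.35, n)
    site = rng.integers(0, n_sites, n)
    fd = np.exp(rng.normal(np.log(0.15), 0.4, n))  # mm, right-skewed
    pcs = rng.standard_normal((n, 10)) * 0.01
    cov = pd.DataFrame({"age": age, "sex": sex, "site": site, "fd": fd})
    for j in range(10):
        cov[f"pc{j + 1}"] = pcs[:, j]
    return cov


def generate_cohort(
    assignments,
    effects: EffectSpec,
    n_hc: int,
    seed: int,
) -> Cohort:
    """Build a multimodal cohort with planted group effects.

    ``assignments`` gives patients' true subgroup labels (strings or factor
    indices). Per modality, a seeded subset of features (``affected_fraction``)
    receives group-specific mean shifts of ``effect_size`` standardized units
    with a per-group random sign pattern; site offsets and covariate effects
    are added to every subject (HC included); HC carry no group effect.
    """
    effects.validate()
    assignments = np.asarray(assignments)
    groups = list(pd.unique(assignments))
    if len(groups) < 2:
        raise ValueError("need at least 2 patient groups")
    counts = pd.Series(assignments).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"groups with <2 members: {list(small.index)}")

    rng = np.random.default_rng(seed)
    n_pat = len(assignments)
    n = n_pat + n_hc
    labels = pd.Series(
        [str(a) for a in assignments] + ["HC"] * n_hc,
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id"),
        name="label",
    )
    cov = _covariates(n, effects.n_sites, rng)
    cov.index = labels.index

    modalities: dict[str, pd.DataFrame] = {}
    truth: dict = {
        "groups": [str(g) for g in groups],
        "subgroup": labels.tolist(),
        "affected": {},
        "group_shift": {},
    }
    for name, eff in effects.modalities.items():
        f = eff.n_features
        X = rng.standard_normal((n, f)) * eff.noise_sd
        n_aff = int(round(eff.affected_fraction * f))
        affected = np.sort(rng.choice(f, size=n_aff, replace=False))
        shifts = {}
        for g in groups:
            signs = rng.choice([-1.0, 1.0], size=n_aff)
            shift = eff.effect_size * eff.noise_sd * signs
            rows = np.flatnonzero(labels.values == str(g))
            X[np.ix_(rows, affected)] += shift
            shifts[str(g)] = shift
        if eff.site_offsets is not None:
            offs = np.asarray(eff.site_offsets, dtype=float)
            if offs.shape != (effects.n_sites, f):
                raise ValueError(f"site_offsets for {name!r} must be n_sites x n_features")
        elif eff.site_sd > 0:
            offs = rng.normal(0.0, eff.site_sd, (effects.n_sites, f))
        else:
            offs = np.zeros((effects.n_sites, f))
        X += offs[cov["site"].values]
        for cname, beta in eff.covar_betas.items():
            if cname == "ancestry":
                pcs = cov[[f"pc{j + 1}" for j in range(10)]].values
                B = rng.normal(0.0, float(beta), (10, f))
                X += pcs @ B
                continue
            c = cov[cname].values.astype(float)
            c = c - c.mean()
            b = np.broadcast_to(np.asarray(beta, dtype=float), (f,))
            X += np.outer(c, b)
        modalities[name] = pd.DataFrame(
            X, index=labels.index, columns=[f"{name}_{j}" for j in range(f)]
        )
        truth["affected"][name] = affected.tolist()
        truth["group_shift"][name] = {g: s.tolist() for g, s in shifts.items()}

    cohort = Cohort(
        modalities=modalities, covariates=cov, labels=labels, timepoint="T0",
        truth=truth,
    )
    cohort.validate()
    return cohort


def generate_followup(
    spec: FactorSpec,
    true_scores_t0: np.ndarray,
    persistence,
    seed: int,
    *,
    n_timepoints: int = 1,
) -> list[tuple[pd.DataFrame, np.ndarray]]:
    """Follow-up symptom tables with partial persistence of the dominant
    dimension.

    Per subject and timepoint: with probability ``persistence`` (scalar or
    per-group array indexed by the T0 dominant factor) the dominant factor
    stays dominant; otherwise dominance moves to a uniformly chosen other
    factor by swapping the two score values. Items are regenerated from the
    perturbed scores. Returns ``[(symptoms, scores), ...]`` per timepoint.
    """
    rng = np.random.default_rng(seed)
    scores0 = np.asarray(true_scores_t0, dtype=float)
    n, k = scores0.shape
    dom0 = np.argmax(scores0, axis=1)
    pers = np.broadcast_to(np.asarray(persistence, dtype=float), (k,))
    if np.any(pers < 0) or np.any(pers > 1):
        raise ValueError("persistence must be in [0, 1]")
    out = []
    for _ in range(n_timepoints):
        scores = scores0.copy()
        stay = rng.random(n) < pers[dom0]
        for i in np.flatnonzero(~stay):
            d = dom0[i]
            choices = [j for j in range(k) if j != d]
            new = choices[rng.integers(0, k - 1)]
            scores[i, [d, new]] = scores[i, [new, d]]
        X = items_from_scores(spec, scores, rng)
        X.index = pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id")
        out.append((X, scores))
    return out


def make_default_cohort(
    seed: int,
    *,
    margin: float = 1.0,
    effects: EffectSpec | None = None,
    group_sizes=DEFAULT_GROUP_SIZES,
    n_hc: int = DEFAULT_N_HC,
) -> tuple[Cohort, pd.DataFrame, np.ndarray]:
    """Symptoms + multimodal cohort at the default study layout.

    Returns ``(cohort, symptoms, true_scores)`` for the patients; subgroup
    truth labels are the designated dominant factors.
    """
    spec = default_factor_spec()
    dom = dominant_labels(group_sizes, seed)
    X, scores = generate_symptoms(
        spec, int(np.sum(group_sizes)), seed, dominant=dom, margin=margin
    )
    if effects is None:
        effects = default_effect_spec()
    names = [spec.factor_names[d] for d in dom]
    cohort = generate_cohort(names, effects, n_hc=n_hc, seed=seed + 1)
    return cohort, X, scores
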