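"""Significance and stability inference for trained classifier ensembles.

* Permutation test of balanced accuracy: group labels are shuffled once per
  iteration, the full (deterministic) pipeline is re-run, and the one-sided
  p-value uses the add-one rule p = (1 + #{null >= observed}) / (1 + n_perm),
  which can never reach zero.
* Cross-validation ratio (CVR): per-feature mean / standard error of all
  archived SVM weight vectors pooled across the CV ensemble — a t-like
  stability score of the predictive pattern.
* Sign-based consistency: the share of the ensemble in which a feature's
  weight keeps its majority sign, rescaled to [0, 1] (0 = even split,
  1 = unanimous), with a z-score and one-sided normal p-value under the
  fair-coin Binomial(M, 1/2) null.
* Benjamini-Hochberg FDR masking of the consistency p-values.
* Decision-score correlations: Pearson r between out-of-fold decision
  scores of classifiers trained on different modalities, per contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "permutation_test",
    "cvr",
    "sign_consistency",
    "fdr_bh",
    "stability_report",
    "score_correlations",
]


@dataclass
class PermutationResult:
    observed_bac: float
    null_bacs: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_bac": self.observed_bac,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_mean": float(np.mean(self.null_bacs)),
            "null_q95": float(np.quantile(self.null_bacs, 0.95)),
        }


def permutation_test(
    runner,
    labels,
    *,
    n_perm: int = 1000,
    seed: int = 0,
    contrast: tuple | None = None,
) -> PermutationResult:
    """Permutation test of out-of-fold BAC against label exchangeability.

    ``runner(labels) -> BAC`` re-runs the full pipeline (it must be
    deterministic). Labels are shuffled once per iteration before the entire
    nested CV; with ``contrast`` given, shuffling is restricted to subjects
    of those two classes (others keep their labels).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    observed = float(runner(labels))
    if contrast is not None:
        pool = np.flatnonzero((labels == contrast[0]) | (labels == contrast[1]))
    else:
        pool = np.arange(len(labels))
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = labels.copy()
        shuffled[pool] = shuffled[rng.permutation(pool)]
        null[i] = runner(shuffled)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        observed_bac=observed, null_bacs=null, p_value=float(p),
        n_perm=n_perm, seed=seed,
    )


def cvr(weight_archive: np.ndarray) -> np.ndarray:
    """Cross-validation ratio per feature: mean / SE over the M archived
    weight vectors (rows). SE == 0 with nonzero mean yields a signed +/-inf
    sentinel; SE == mean == 0 yields 0."""
    W = np.asarray(weight_archive, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need a (M >= 2) x features weight archive")
    M = W.shape[0]
    mean = W.mean(axis=0)
    se = W.std(axis=0, ddof=1) / np.sqrt(M)
    out = np.empty(W.shape[1])
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out[~degenerate] = mean[~degenerate] / se[~degenerate]
    out[degenerate & (mean > 0)] = np.inf
    out[degenerate & (mean < 0)] = -np.inf
    out[degenerate & (mean == 0)] = 0.0
    return out


def sign_consistency(weight_archive: np.ndarray):
    """Sign-based consistency of each feature's weight across the ensemble.

    Over the nonzero weights of a feature, f = max(#positive, #negative)/M;
    consistency c = 2f - 1 (0 at an even split, 1 at unanimity);
    z = (f - 0.5) / sqrt(0.25 / M) under the Binomial(M, 1/2) null; p is the
    one-sided upper-tail normal probability. Features with zero weight in
    every model are returned as NaN.

    Returns a DataFrame with columns consistency, z, p, n_models.
    """
    W = np.asarray(weight_archive, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need a (M >= 2) x features weight archive")
    n_feat = W.shape[1]
    cons = np.full(n_feat, np.nan)
    z = np.full(n_feat, np.nan)
    p = np.full(n_feat, np.nan)
    M_eff = np.zeros(n_feat, dtype=int)
    for j in range(n_feat):
        w = W[:, j]
        nz = w != 0
        M = int(nz.sum())
        M_eff[j] = M
        if M < 2:
            continue
        npos = int(np.sum(w[nz] > 0))
        f = max(npos, M - npos) / M
        cons[j] = 2.0 * f - 1.0
        z[j] = (f - 0.5) / np.sqrt(0.25 / M)
        p[j] = sps.norm.sf(z[j])
    return pd.DataFrame(
        {"consistency": cons, "z": z, "p": p, "n_models": M_eff}
    )


def fdr_bh(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask (NaN p -> not significant)."""
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return mask
    order = np.argsort(pv)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = pv[order] <= thresh
    if passed.any():
        kmax = np.max(np.flatnonzero(passed))
        sig = np.zeros(m, dtype=bool)
        sig[order[: kmax + 1]] = True
        mask[np.flatnonzero(ok)] = sig
    return mask


def stability_report(
    weight_archive: np.ndarray, *, alpha: float = 0.05, feature_names=None
) -> pd.DataFrame:
    """Per-feature stability table for one binary contrast: CVR,
    sign-consistency, z, p, and the BH-FDR significance mask."""
    rep = sign_consistency(weight_archive)
    rep.insert(0, "cvr", cvr(weight_archive))
    rep["fdr_significant"] = fdr_bh(rep["p"].values, alpha=alpha)
    if feature_names is not None:
        rep.index = pd.Index(feature_names, name="feature")
    return rep


def score_correlations(oof_scores: dict, contrasts=None) -> pd.DataFrame:
    """Pearson correlations between modalities' OOF decision scores.

    ``oof_scores`` maps modality name -> DataFrame (subjects x contrast
    columns). Returns a long-format table (contrast, modality_a, modality_b,
    r, p, n).
    """
    names = sorted(oof_scores)
    if len(names) < 2:
        raise ValueError("need >= 2 modalities")
    if contrasts is None:
        contrasts = list(oof_scores[names[0]].columns)
    rows = []
    for contrast in contrasts:
        for a, b in combinations(names, 2):
            sa = oof_scores[a][contrast]
            sb = oof_scores[b][contrast]
            shared = sa.index.intersection(sb.index)
            if len(shared) < 3:
                raise ValueError(
                    f"fewer than 3 shared subjects between {a!r} and {b!r}"
                )
            r, p = sps.pearsonr(sa.loc[shared], sb.loc[shared])
            rows.append(
                {
                    "contrast": contrast,
                    "modality_a": a,
                    "modality_b": b,
                    "r": float(r),
                    "p": float(p),
                    "n": len(shared),
                }
            )
    return pd.DataFrame(rows)
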