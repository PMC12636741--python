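"""Symptom factor modelling: jackknife model selection, subtyping, stability.

The workflow mirrors common clinical-subtyping practice on ordinal symptom
scales: fit maximum-likelihood EFA with promax rotation on the item Pearson
correlations for a range of candidate factor counts, pick the count with the
lowest mean BIC over leave-one-out jackknife replicates, assign each patient
to the subgroup of their maximum factor score by majority vote across the
jackknife replicates (the vote share is the assignment certainty), and
quantify longitudinal stability of the solution by loading correlations,
a dice coefficient over item-to-factor assignments, subgroup transition
tables and factor-score correlations across timepoints.

BIC convention: ``chi^2 - df * ln(N)`` (the EFA convention of the R *psych*
package), which can be negative for well-fitting models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .efa import (
    EFAConvergenceError,
    bartlett_chisq,
    congruence_matrix,
    efa_dof,
    match_factors,
    ml_efa_corr,
    promax,
)

__all__ = [
    "FactorModel",
    "JackknifeSelection",
    "StabilityResult",
    "fit_efa",
    "jackknife_select",
    "score_factors",
    "assign_subgroups",
    "standardized_alpha",
    "alpha_from_mean_r",
    "item_assignment_for_factor",
    "longitudinal_stability",
]


@dataclass
class FactorModel:
    """Fitted, promax-rotated factor model plus everything needed to score
    new data with it (fit-sample item means/SDs and correlation matrix)."""

    loadings: pd.DataFrame  # items x k pattern matrix
    factor_corr: np.ndarray  # k x k promax Phi
    uniquenesses: pd.Series
    chisq: float
    df: int
    n_obs: int
    bic: float
    cum_variance: np.ndarray  # length-k nondecreasing proportions
    item_means: pd.Series
    item_sds: pd.Series
    item_corr: np.ndarray  # fit-sample Pearson correlations
    heywood: bool = False
    promax_power: int = 4

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def items(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def structure(self) -> pd.DataFrame:
        """Structure loadings S = pattern @ Phi (item-factor correlations)."""
        return pd.DataFrame(
            self.loadings.values @ self.factor_corr,
            index=self.loadings.index,
            columns=self.loadings.columns,
        )

    @property
    def communalities(self) -> pd.Series:
        return 1.0 - self.uniquenesses

    def scoring_weights(self) -> np.ndarray:
        """Thurstone regression weights W = R^-1 (L Phi)."""
        return linalg.solve(self.item_corr, self.structure.values, assume_a="pos")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "items": self.items,
            "factors": list(self.loadings.columns),
            "loadings": self.loadings.values.tolist(),
            "factor_corr": self.factor_corr.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "chisq": self.chisq,
            "df": self.df,
            "n_obs": self.n_obs,
            "bic": self.bic,
            "cum_variance": self.cum_variance.tolist(),
            "item_means": self.item_means.tolist(),
            "item_sds": self.item_sds.tolist(),
            "item_corr": self.item_corr.tolist(),
            "heywood": self.heywood,
            "promax_power": self.promax_power,
        }
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FactorModel":
        obj = json.loads(Path(path).read_text())
        items = obj["items"]
        factors = obj["factors"]
        return cls(
            loadings=pd.DataFrame(obj["loadings"], index=items, columns=factors),
            factor_corr=np.array(obj["factor_corr"]),
            uniquenesses=pd.Series(obj["uniquenesses"], index=items),
            chisq=obj["chisq"],
            df=obj["df"],
            n_obs=obj["n_obs"],
            bic=obj["bic"],
            cum_variance=np.array(obj["cum_variance"]),
            item_means=pd.Series(obj["item_means"], index=items),
            item_sds=pd.Series(obj["item_sds"], index=items),
            item_corr=np.array(obj["item_corr"]),
            heywood=obj["heywood"],
            promax_power=obj["promax_power"],
        )


@dataclass
class JackknifeSelection:
    k_range: list[int]
    bic: pd.DataFrame  # replicates x k (columns = k), NaN = non-convergent
    mean_bic: pd.Series
    ci95_low: pd.Series
    ci95_high: pd.Series
    selected_k: int
    pairwise_tests: pd.DataFrame  # (k1, k2, t_p, mwu_p)


@dataclass
class StabilityResult:
    loading_correlations: dict  # timepoint -> per-factor Pearson r
    dice: dict  # timepoint -> proportion of items keeping their factor
    transition_tables: dict  # timepoint -> k x k DataFrame of counts
    persistence: dict  # timepoint -> per-group % staying in their T0 group
    score_correlations: dict  # timepoint -> per-factor cross-timepoint r


def _validate_symptoms(X: pd.DataFrame) -> np.ndarray:
    V = X.values.astype(float)
    if np.isnan(V).any():
        raise ValueError("symptom matrix contains missing values")
    sd = V.std(axis=0, ddof=1)
    dead = [c for c, s in zip(X.columns, sd) if s <= 0]
    if dead:
        raise ValueError(f"zero-variance items: {dead}")
    return V


def _rotate(raw: np.ndarray, power: int):
    if raw.shape[1] == 1:
        return raw.copy(), np.eye(1)
    return promax(raw, power=power)[:2]


def _order_factors(pattern: np.ndarray, phi: np.ndarray):
    """Deterministic output convention: factors ordered by explained common
    variance (descending), column signs chosen so loading sums are >= 0."""
    shares = np.sum(pattern * (pattern @ phi), axis=0)
    order = np.argsort(-shares)
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.where(pattern.sum(axis=0) < 0, -1.0, 1.0)
    pattern = pattern * signs[None, :]
    phi = phi * np.outer(signs, signs)
    return pattern, phi


def fit_efa(X: pd.DataFrame, k: int, *, promax_power: int = 4) -> FactorModel:
    """ML EFA on the Pearson item correlations with promax rotation.

    Heywood cases (uniqueness at the 0.005 bound) are clipped, warned about
    and flagged on the returned model. Raises on non-convergence.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than items ({p})")
    V = _validate_symptoms(X)
    R = np.corrcoef(V, rowvar=False)
    fit = ml_efa_corr(R, k)
    if fit.heywood:
        warnings.warn(
            "Heywood case: uniqueness clipped at 0.005", RuntimeWarning, stacklevel=2
        )
    pattern, phi = _rotate(fit.loadings, promax_power)
    pattern, phi = _order_factors(pattern, phi)
    chisq = bartlett_chisq(fit.objective, p, k, n)
    df = efa_dof(p, k)
    bic = chisq - df * np.log(n)
    shares = np.sum(pattern * (pattern @ phi), axis=0) / p
    factors = [f"F{j + 1}" for j in range(k)]
    return FactorModel(
        loadings=pd.DataFrame(pattern, index=X.columns, columns=factors),
        factor_corr=phi,
        uniquenesses=pd.Series(fit.uniquenesses, index=X.columns),
        chisq=chisq,
        df=df,
        n_obs=n,
        bic=bic,
        cum_variance=np.cumsum(np.sort(shares)[::-1]),
        item_means=pd.Series(V.mean(axis=0), index=X.columns),
        item_sds=pd.Series(V.std(axis=0, ddof=1), index=X.columns),
        item_corr=R,
        heywood=fit.heywood,
        promax_power=promax_power,
    )


def score_factors(model: FactorModel, X: pd.DataFrame) -> pd.DataFrame:
    """Thurstone regression factor scores of ``X`` under a fitted model.

    Items are standardized with the scoring reference (fit-sample) means/SDs,
    then multiplied by W = R^-1 (L Phi). Scoring the fit-sample mean row
    therefore gives exactly zero on every factor.
    """
    unknown = [c for c in X.columns if c not in model.items]
    if unknown:
        raise ValueError(f"unknown items: {unknown}")
    missing = [c for c in model.items if c not in X.columns]
    if missing:
        raise ValueError(f"missing items: {missing}")
    V = X[model.items].values.astype(float)
    Z = (V - model.item_means.values) / model.item_sds.values
    scores = Z @ model.scoring_weights()
    return pd.DataFrame(scores, index=X.index, columns=model.loadings.columns)


def _loo_moments(V: np.ndarray):
    """Leave-one-out means, SDs and correlation matrices via rank-one
    downdates of the full-sample sums (O(p^2) per replicate)."""
    n, p = V.shape
    S1 = V.sum(axis=0)
    S2 = V.T @ V
    for i in range(n):
        s1 = S1 - V[i]
        s2 = S2 - np.outer(V[i], V[i])
        m = s1 / (n - 1)
        cov = (s2 - np.outer(s1, s1) / (n - 1)) / (n - 2)
        sd = np.sqrt(np.diag(cov))
        R = cov / np.outer(sd, sd)
        np.fill_diagonal(R, 1.0)
        yield i, m, sd, R


def jackknife_select(
    X: pd.DataFrame, k_range, *, min_convergent: float = 0.9
) -> JackknifeSelection:
    """Select the factor count by lowest mean BIC over leave-one-out
    replicates; also reports percentile 95% CIs and pairwise paired-t /
    Mann-Whitney tests between the BIC distributions."""
    k_range = sorted(int(k) for k in k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    n, p = X.shape
    if n < 30:
        raise ValueError("need n >= 30 for jackknife selection")
    V = _validate_symptoms(X)

    # full-sample fits provide warm starts for every replicate
    R_full = np.corrcoef(V, rowvar=False)
    starts = {}
    for k in k_range:
        if efa_dof(p, k) <= 0:
            raise ValueError(f"k={k} leaves df <= 0 for p={p} items")
        starts[k] = ml_efa_corr(R_full, k).uniquenesses

    bic = np.full((n, len(k_range)), np.nan)
    corr = (n - 1) - 1 - (2 * p + 5) / 6.0
    logn1 = np.log(n - 1)
    for i, _, _, R in _loo_moments(V):
        for jk, k in enumerate(k_range):
            try:
                fit = ml_efa_corr(R, k, start=starts[k])
            except EFAConvergenceError:
                continue
            chisq = max(fit.objective, 0.0) * (corr - (2 * k) / 3.0)
            bic[i, jk] = chisq - efa_dof(p, k) * logn1

    bic_df = pd.DataFrame(bic, columns=k_range)
    conv = bic_df.notna().mean()
    bad = conv[conv < min_convergent]
    if len(bad):
        raise RuntimeError(
            f"too many non-convergent jackknife replicates for k={list(bad.index)}"
        )
    mean_bic = bic_df.mean()
    ci_low = bic_df.quantile(0.025)
    ci_high = bic_df.quantile(0.975)
    selected_k = int(mean_bic.idxmin())

    rows = []
    for k1, k2 in combinations(k_range, 2):
        a = bic_df[k1]
        b = bic_df[k2]
        ok = a.notna() & b.notna()
        if ok.sum() < 3 or np.allclose(a[ok], b[ok]):
            tp, up = np.nan, np.nan
        else:
            tp = stats.ttest_rel(a[ok], b[ok]).pvalue
            up = stats.mannwhitneyu(a[ok], b[ok]).pvalue
        rows.append({"k1": k1, "k2": k2, "t_p": tp, "mwu_p": up})
    return JackknifeSelection(
        k_range=k_range,
        bic=bic_df,
        mean_bic=mean_bic,
        ci95_low=ci_low,
        ci95_high=ci_high,
        selected_k=selected_k,
        pairwise_tests=pd.DataFrame(rows),
    )


def _align_to_reference(ref_pattern, pattern, phi):
    """Match, sign-align and reorder a replicate solution to the reference."""
    perm, signs, ambiguous = match_factors(ref_pattern, pattern)
    pat = pattern[:, perm] * signs[None, :]
    ph = phi[np.ix_(perm, perm)] * np.outer(signs, signs)
    return pat, ph, ambiguous


def assign_subgroups(
    X: pd.DataFrame,
    k: int,
    *,
    promax_power: int = 4,
    reference_model: FactorModel | None = None,
):
    """Jackknife majority-vote subgroup assignment.

    Each leave-one-out replicate refits the k-factor model, aligns its
    factors to the full-sample reference by maximal absolute Tucker
    congruence, scores ALL subjects (including the held-out one) with the
    replicate model, and records each subject's argmax factor. The final
    label is the modal vote; certainty is the modal vote share in percent.
    Argmax and vote ties break to the lowest factor index and are flagged.

    Returns ``(assignments, model)`` where ``assignments`` has one row per
    subject (label 1..k, certainty, vote counts, full-model factor scores)
    and ``model`` is the full-sample reference model.
    """
    if reference_model is None:
        reference_model = fit_efa(X, k, promax_power=promax_power)
    if reference_model.k != k:
        raise ValueError("reference model has a different k")
    ref_pattern = reference_model.loadings.values
    V = _validate_symptoms(X)
    n, p = V.shape
    start = ml_efa_corr(reference_model.item_corr, k).uniquenesses

    votes = np.zeros((n, k), dtype=int)
    tie_votes = np.zeros(n, dtype=bool)
    n_ambiguous = 0
    for i, m, sd, R in _loo_moments(V):
        fit = ml_efa_corr(R, k, start=start)
        pattern, phi = _rotate(fit.loadings, promax_power)
        pattern, phi, ambiguous = _align_to_reference(ref_pattern, pattern, phi)
        n_ambiguous += ambiguous
        S = pattern @ phi
        W = linalg.solve(R, S, assume_a="pos")
        Z = (V - m) / sd
        scores = Z @ W
        # argmax with ties to the lowest factor index (np.argmax convention)
        amax = np.argmax(scores, axis=1)
        votes[np.arange(n), amax] += 1

    label = np.argmax(votes, axis=1)
    top = votes[np.arange(n), label]
    # flag vote ties (modal count shared by 2+ factors)
    for i in range(n):
        if np.sum(votes[i] == top[i]) > 1:
            tie_votes[i] = True
    certainty = 100.0 * top / votes.sum(axis=1)
    full_scores = score_factors(reference_model, X)

    out = pd.DataFrame(index=X.index)
    out["label"] = label + 1
    out["certainty"] = certainty
    out["vote_tie"] = tie_votes
    for j in range(k):
        out[f"votes_{j + 1}"] = votes[:, j]
    for j, c in enumerate(full_scores.columns):
        out[f"score_{j + 1}"] = full_scores[c].values
    out.attrs["n_replicates"] = n
    out.attrs["n_ambiguous_replicates"] = int(n_ambiguous)
    return out, reference_model


def alpha_from_mean_r(m: int, rbar: float) -> float:
    """Standardized Cronbach's alpha from set size and mean inter-item r."""
    return m * rbar / (1.0 + (m - 1) * rbar)


def standardized_alpha(X: pd.DataFrame, item_sets: dict) -> pd.Series:
    """Standardized alpha per named item set: m*rbar / (1 + (m-1)*rbar)."""
    out = {}
    for name, items in item_sets.items():
        items = list(items)
        if len(items) < 2:
            raise ValueError(f"item set {name!r} needs >= 2 items")
        V = X[items].values.astype(float)
        if np.any(V.std(axis=0, ddof=1) <= 0):
            raise ValueError(f"zero-variance item in set {name!r}")
        R = np.corrcoef(V, rowvar=False)
        m = len(items)
        rbar = (R.sum() - m) / (m * (m - 1))
        out[name] = alpha_from_mean_r(m, rbar)
    return pd.Series(out)


def item_assignment_for_factor(model: FactorModel):
    """Assign each item to its argmax-|pattern-loading| factor.

    Returns ``(sets, flags)``: per-factor item lists sorted by descending
    absolute loading, and the list of items whose top loadings were tied
    (assigned to the lower factor index).
    """
    L = model.loadings
    A = L.abs().values
    best = np.argmax(A, axis=1)
    flags = []
    for i, item in enumerate(L.index):
        top = A[i, best[i]]
        if np.sum(np.isclose(A[i], top)) > 1:
            flags.append(item)
    sets = {}
    for j, f in enumerate(L.columns):
        items = [item for i, item in enumerate(L.index) if best[i] == j]
        items.sort(key=lambda it: -abs(L.loc[it, f]))
        sets[f] = items
    return sets, flags


def _dice_same_argmax(best0: np.ndarray, best1: np.ndarray) -> float:
    same = int(np.sum(best0 == best1))
    return 2.0 * same / (len(best0) + len(best1))


def longitudinal_stability(
    model_t0: FactorModel,
    X_t0: pd.DataFrame,
    X_t1: pd.DataFrame,
    X_t2: pd.DataFrame | None = None,
    *,
    promax_power: int | None = None,
) -> StabilityResult:
    """Stability of the baseline factor solution at follow-up timepoints.

    Per follow-up: (a) refit EFA and correlate matched loading columns with
    baseline; (b) dice coefficient over items keeping their argmax factor;
    (c) subgroup persistence by scoring the follow-up data with the baseline
    model and cross-tabulating argmax labels; (d) per-factor Pearson r of
    factor scores across timepoints (overlapping subjects).
    """
    if promax_power is None:
        promax_power = model_t0.promax_power
    followups = {"T1": X_t1}
    if X_t2 is not None:
        followups["T2"] = X_t2

    scores0 = score_factors(model_t0, X_t0)
    labels0 = pd.Series(
        np.argmax(scores0.values, axis=1), index=scores0.index, name="label"
    )
    best0 = np.argmax(model_t0.loadings.abs().values, axis=1)
    k = model_t0.k
    factors = list(model_t0.loadings.columns)

    loading_corr, dice, transitions, persistence, score_corr = {}, {}, {}, {}, {}
    for tp, X_fu in followups.items():
        shared = X_t0.index.intersection(X_fu.index)
        if len(shared) == 0:
            raise ValueError(f"no overlapping subjects between T0 and {tp}")
        model_fu = fit_efa(X_fu[model_t0.items], k, promax_power=promax_power)
        pat, phi, _ = _align_to_reference(
            model_t0.loadings.values, model_fu.loadings.values, model_fu.factor_corr
        )
        loading_corr[tp] = pd.Series(
            [stats.pearsonr(model_t0.loadings.values[:, j], pat[:, j])[0] for j in range(k)],
            index=factors,
        )
        dice[tp] = _dice_same_argmax(best0, np.argmax(np.abs(pat), axis=1))

        scores_fu = score_factors(model_t0, X_fu.loc[shared])
        labels_fu = np.argmax(scores_fu.values, axis=1)
        lab0 = labels0.loc[shared].values
        tab = np.zeros((k, k), dtype=int)
        for a, b in zip(lab0, labels_fu):
            tab[a, b] += 1
        transitions[tp] = pd.DataFrame(tab, index=factors, columns=factors)
        with np.errstate(invalid="ignore"):
            pers = 100.0 * np.diag(tab) / np.maximum(tab.sum(axis=1), 1)
        persistence[tp] = pd.Series(pers, index=factors)
        score_corr[tp] = pd.Series(
            [
                stats.pearsonr(scores0.loc[shared].values[:, j], scores_fu.values[:, j])[0]
                for j in range(k)
            ],
            index=factors,
        )
    return StabilityResult(
        loading_correlations=loading_corr,
        dice=dice,
        transition_tables=transitions,
        persistence=persistence,
        score_correlations=score_corr,
    )
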