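"""Repeated nested cross-validated multi-class linear SVM classification.

The estimation protocol: a stratified outer CV (default 10 folds x 5
permutations) measures out-of-fold (OOF) generalization; within each outer
training set an inner CV of the same shape selects the SVM slack parameter
(geometric grid 2^-6 .. 2^4) and, for modalities with PCA, the retained
variance energy. Multi-class problems are decomposed one-vs-one into
k(k-1)/2 L2-regularized linear SVMs with inverse-frequency class weighting
and decoded with error-correcting output codes (ECOC) by Hamming distance
between the predicted sign pattern and each class's reference code — which
for one-vs-one codes coincides with majority voting on non-tied patterns.

Unimodal models can be fused by stacked generalization: the meta-learner
(same ECOC linear-SVM machinery) is trained on each subject's inner-CV
out-of-fold decision scores from every modality, and evaluated on scores
produced by modality models trained on the full outer training set.

Modality preprocessing is embedded inside the CV structure: chains are
fitted on (reference subjects of) the training fold only and applied frozen
to held-out data. Every binary learner's weight vector is archived in
input-feature space (back-projected through PCA/masking) for downstream
stability statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .preprocess import PreprocessChain, ScaleWinsorize, build_chain
from .syndata import Cohort

__all__ = [
    "CVStructure",
    "make_cv",
    "DEFAULT_C_GRID",
    "ENERGY_GRID",
    "train_binary_svm",
    "BinaryModel",
    "EcocModel",
    "ovo_pairs",
    "ovo_code_matrix",
    "ecoc_decode",
    "optimize_slack",
    "nested_cv_run",
    "stack",
    "one_vs_rest_summary",
    "ModalityRun",
    "PerformanceMetrics",
]

# slack grid: geometric progression, ratio 2, from 2^-6 to 2^4 (11 values)
DEFAULT_C_GRID = tuple(2.0**e for e in range(-6, 5))
# PCA retained-variance grid for imaging modalities
ENERGY_GRID = (0.4, 0.6, 0.8)


# --------------------------------------------------------------------------
# cross-validation structure
# --------------------------------------------------------------------------


@dataclass
class CVStructure:
    """Stratified repeated K-fold partitions, outer and inner."""

    outer: list  # [perm][fold] -> (train_idx, test_idx), absolute indices
    outer_folds: int
    outer_perms: int
    inner_folds: int
    inner_perms: int
    seed: int
    n: int

    def inner_splits(self, train_idx: np.ndarray, labels: np.ndarray, key: int):
        """Inner stratified folds of one outer training set, deterministic
        given (seed, key). Yields (perm, fold, train_abs, val_abs)."""
        y = labels[train_idx]
        folds = _effective_folds(y, self.inner_folds)
        for q in range(self.inner_perms):
            skf = StratifiedKFold(
                n_splits=folds, shuffle=True,
                random_state=(self.seed * 1_000_003 + key * 101 + q) % (2**31 - 1),
            )
            for f, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
                yield q, f, train_idx[tr], train_idx[va]


def _effective_folds(y, folds: int) -> int:
    counts = pd.Series(y).value_counts()
    mc = int(counts.min())
    if mc < folds:
        warnings.warn(
            f"smallest class has {mc} members; reducing fold count from "
            f"{folds} to {mc}",
            RuntimeWarning,
            stacklevel=3,
        )
        return max(2, mc)
    return folds


def make_cv(labels, outer=(10, 5), inner=(10, 5), seed: int = 0) -> CVStructure:
    """Build the repeated stratified nested CV structure.

    ``outer``/``inner`` are (folds, permutations). Classes smaller than the
    fold count trigger a warned fold-count reduction.
    """
    y = np.asarray(labels)
    n = len(y)
    ofolds = _effective_folds(y, outer[0])
    perms = []
    for p in range(outer[1]):
        skf = StratifiedKFold(
            n_splits=ofolds, shuffle=True,
            random_state=(seed * 9_176 + p) % (2**31 - 1),
        )
        perms.append([(tr, te) for tr, te in skf.split(np.zeros(n), y)])
    return CVStructure(
        outer=perms,
        outer_folds=ofolds,
        outer_perms=outer[1],
        inner_folds=inner[0],
        inner_perms=inner[1],
        seed=seed,
        n=n,
    )


# --------------------------------------------------------------------------
# binary SVM and ECOC decoding
# --------------------------------------------------------------------------


@dataclass
class BinaryModel:
    """Linear SVM for one class pair; positive decision score => class a."""

    class_pair: tuple
    weights: np.ndarray
    bias: float
    C: float
    class_weights: dict

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias


def train_binary_svm(X, y, class_a, class_b, C: float) -> BinaryModel:
    """L2-regularized hinge-loss linear SVM with inverse-frequency class
    weighting (per-class penalty C_c = C * n_total / (2 * n_c))."""
    y = np.asarray(y)
    present = set(np.unique(y))
    if class_a not in present or class_b not in present:
        raise ValueError(f"both classes must be present; got {sorted(map(str, present))}")
    ybin = (y == class_a).astype(int)  # 1 => class a, sklearn's positive class
    n = len(y)
    n_a = int(ybin.sum())
    n_b = n - n_a
    cw = {1: n / (2.0 * n_a), 0: n / (2.0 * n_b)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # dual coordinate descent; tolerance/iteration cap chosen for
        # deterministic, fast fits — hinge dual oscillates on heavily
        # overlapping classes and extra iterations do not change predictions
        clf = LinearSVC(
            C=C, loss="hinge", class_weight=cw, max_iter=2000, tol=1e-3,
            random_state=0,
        )
        clf.fit(X, ybin)
    return BinaryModel(
        class_pair=(class_a, class_b),
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        C=C,
        class_weights=cw,
    )


def ovo_pairs(classes) -> list[tuple]:
    return list(combinations(classes, 2))


def ovo_code_matrix(classes) -> np.ndarray:
    """One-vs-one ECOC code matrix: one column per class pair, +1 for the
    first class of the pair, -1 for the second, 0 elsewhere."""
    classes = list(classes)
    pairs = ovo_pairs(classes)
    code = np.zeros((len(classes), len(pairs)), dtype=int)
    for m, (a, b) in enumerate(pairs):
        code[classes.index(a), m] = 1
        code[classes.index(b), m] = -1
    return code


def ecoc_decode(scores: np.ndarray, code: np.ndarray):
    """Decode decision scores against class codes by Hamming distance.

    Only nonzero code entries count; a zero-margin learner contributes half
    a mismatch to both classes of its pair. Distance ties go to the class
    with the larger summed |margin| over its nonzero entries, then to the
    lower class index. Returns (labels, tie_flags).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n, m = scores.shape
    k = code.shape[0]
    sgn = np.sign(scores)
    nz = code != 0  # k x m
    # mismatch per (class, learner): 1 if signs oppose, 0.5 if margin is 0
    dist = np.empty((n, k))
    strength = np.abs(scores) @ nz.T.astype(float)
    for c in range(k):
        prod = sgn[:, nz[c]] * code[c, nz[c]][None, :]
        dist[:, c] = np.sum(prod < 0, axis=1) + 0.5 * np.sum(prod == 0, axis=1)
    labels = np.empty(n, dtype=int)
    ties = np.zeros(n, dtype=bool)
    for i in range(n):
        d = dist[i]
        cand = np.flatnonzero(np.isclose(d, d.min()))
        if len(cand) > 1:
            ties[i] = True
            s = strength[i, cand]
            cand = cand[np.isclose(s, s.max())]
        labels[i] = cand[0]
    return labels, ties


@dataclass
class EcocModel:
    classes: list
    code_matrix: np.ndarray
    learners: list[BinaryModel]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.decision(X) for m in self.learners])

    def predict(self, X: np.ndarray):
        labels, ties = ecoc_decode(self.decision_scores(X), self.code_matrix)
        return np.asarray(self.classes, dtype=object)[labels], ties


def _fit_ecoc(X, y, classes, C) -> EcocModel:
    learners = [train_binary_svm(X, y, a, b, C) for a, b in ovo_pairs(classes)]
    return EcocModel(
        classes=list(classes), code_matrix=ovo_code_matrix(classes), learners=learners
    )


def _balanced_accuracy(y_true, y_pred, classes) -> float:
    recalls = []
    for c in classes:
        mask = y_true == c
        if mask.sum() == 0:
            continue
        recalls.append(np.mean(y_pred[mask] == c))
    return float(np.mean(recalls))


# --------------------------------------------------------------------------
# nested CV
# --------------------------------------------------------------------------


@dataclass
class PerformanceMetrics:
    """Per-contrast and multi-class OOF performance (percent scales)."""

    contrasts: pd.DataFrame  # rows per contrast: bac, sensitivity, specificity
    misclassification: pd.DataFrame  # k x k, rows = true class, sums to 1
    multiclass_bac: float

    def to_dict(self) -> dict:
        return {
            "contrasts": {
                f"{a}_vs_{b}": {
                    "bac": row["bac"],
                    "sensitivity": row["sensitivity"],
                    "specificity": row["specificity"],
                }
                for (a, b), row in self.contrasts.iterrows()
            },
            "multiclass_bac": self.multiclass_bac,
            "misclassification": {
                str(i): {str(j): float(v) for j, v in row.items()}
                for i, row in self.misclassification.iterrows()
            },
        }


@dataclass
class ModalityRun:
    """Everything a nested CV run produces for one modality."""

    modality: str
    classes: list
    pairs: list[tuple]
    cv: CVStructure
    oof_scores: pd.DataFrame  # subjects x contrasts, mean over permutations
    oof_pred: pd.Series
    metrics: PerformanceMetrics
    weights: dict  # contrast name -> (M x features) array in input space
    folds: list = field(default_factory=list)  # per-(perm,fold) records


def _ordered_classes(labels) -> list:
    u = sorted(map(str, pd.unique(np.asarray(labels, dtype=object))))
    if "HC" in u:
        u.remove("HC")
        u = ["HC"] + u
    return u


def _contrast_name(a, b) -> str:
    return f"{a}_vs_{b}"


def optimize_slack(scores_by_c: dict, *, grid=DEFAULT_C_GRID) -> float:
    """Pick C maximizing mean inner-CV BAC; ties break to the smallest C
    (strongest regularization). ``scores_by_c`` maps C -> mean BAC."""
    best_bac = -np.inf
    best_c = None
    for C in sorted(grid):
        bac = scores_by_c[C]
        if bac > best_bac + 1e-12:
            best_bac = bac
            best_c = C
    return best_c


def _make_chain(modality, config, energy) -> PreprocessChain:
    cfg = dict(config or {})
    if energy is not None:
        cfg["pca_energy"] = energy
    return build_chain(modality, cfg)


def nested_cv_run(
    cohort: Cohort,
    modality: str,
    *,
    labels=None,
    cv: CVStructure | None = None,
    config: dict | None = None,
    c_grid=DEFAULT_C_GRID,
    energy_grid=None,
    outer=(10, 5),
    inner=(10, 5),
    seed: int = 0,
    collect_train_scores: bool = True,
    store_chains: bool = False,
) -> ModalityRun:
    """Run the full nested CV pipeline for one modality.

    Per outer fold: the preprocessing chain is fitted on the outer training
    set (respecting reference-group rules), (C, energy) are selected on the
    inner CV by mean multi-class BAC (ties to smallest C, then smallest
    energy), all one-vs-one learners are trained on the outer training set
    and the outer test set is scored. OOF decision scores are averaged over
    the outer permutations; metrics come from the aggregated scores. Weight
    vectors are archived in input-feature space.

    ``labels`` overrides the cohort labels (used by permutation testing).
    """
    if modality not in cohort.modalities:
        raise ValueError(f"cohort has no modality {modality!r}")
    X_all = cohort.modalities[modality].values.astype(float)
    meta = cohort.covariates
    y_all = np.asarray(labels if labels is not None else cohort.labels.values, dtype=object)
    y_all = np.array([str(v) for v in y_all], dtype=object)
    if len(y_all) != len(X_all):
        raise ValueError("labels not aligned with modality table")
    classes = _ordered_classes(y_all)
    pairs = ovo_pairs(classes)
    code = ovo_code_matrix(classes)
    if cv is None:
        cv = make_cv(y_all, outer=outer, inner=inner, seed=seed)
    if energy_grid is None:
        probe = _make_chain(modality, config, None)
        has_pca = any(s.name == "pca_energy" for s in probe.steps)
        energy_grid = list(ENERGY_GRID) if has_pca else [None]

    n = len(y_all)
    m = len(pairs)
    score_sum = np.zeros((n, m))
    score_cnt = np.zeros(n)
    weights: dict[str, list] = {_contrast_name(a, b): [] for a, b in pairs}
    folds_out = []

    for p, perm in enumerate(cv.outer):
        for f, (tr, te) in enumerate(perm):
            key = p * 1000 + f
            # ---- inner CV: hyperparameter selection -------------------
            bac_acc = {(e, C): [] for e in energy_grid for C in c_grid}
            val_scores = {(e, C): {} for e in energy_grid for C in c_grid}
            for q, g, itr, iva in cv.inner_splits(tr, y_all, key):
                for e in energy_grid:
                    chain = _make_chain(modality, config, e)
                    chain.fit(X_all[itr], meta.iloc[itr], y_all[itr])
                    Xtr = chain.apply(X_all[itr], meta.iloc[itr])
                    Xva = chain.apply(X_all[iva], meta.iloc[iva])
                    for C in c_grid:
                        model = _fit_ecoc(Xtr, y_all[itr], classes, C)
                        sc = model.decision_scores(Xva)
                        lab, _ = ecoc_decode(sc, code)
                        pred = np.asarray(classes, dtype=object)[lab]
                        bac_acc[(e, C)].append(
                            _balanced_accuracy(y_all[iva], pred, classes)
                        )
                        if collect_train_scores:
                            for row, idx in zip(sc, iva):
                                val_scores[(e, C)].setdefault(idx, []).append(row)
            mean_bac = {k_: float(np.mean(v)) for k_, v in bac_acc.items()}
            # ties -> smaller C, then smaller energy (grid iterated ascending)
            best = None
            for e in sorted(energy_grid, key=lambda x: (x is not None, x)):
                for C in sorted(c_grid):
                    b = mean_bac[(e, C)]
                    if best is None or b > best[0] + 1e-12:
                        best = (b, C, e)
            _, C_star, e_star = best

            # ---- outer-train model -----------------------------------
            chain = _make_chain(modality, config, e_star)
            chain.fit(X_all[tr], meta.iloc[tr], y_all[tr])
            Xtr = chain.apply(X_all[tr], meta.iloc[tr])
            Xte = chain.apply(X_all[te], meta.iloc[te])
            model = _fit_ecoc(Xtr, y_all[tr], classes, C_star)
            te_scores = model.decision_scores(Xte)
            score_sum[te] += te_scores
            score_cnt[te] += 1
            for learner, (a, b) in zip(model.learners, pairs):
                weights[_contrast_name(a, b)].append(chain.backproject(learner.weights))

            train_scores = None
            if collect_train_scores:
                vs = val_scores[(e_star, C_star)]
                train_scores = np.full((len(tr), m), np.nan)
                pos = {idx: i for i, idx in enumerate(tr)}
                for idx, rows in vs.items():
                    train_scores[pos[idx]] = np.mean(rows, axis=0)
            folds_out.append(
                {
                    "perm": p,
                    "fold": f,
                    "train_idx": tr,
                    "test_idx": te,
                    "C": C_star,
                    "energy": e_star,
                    "inner_bac": mean_bac[(e_star, C_star)],
                    "test_scores": te_scores,
                    "train_scores": train_scores,
                    "chain_params": chain.to_dict() if store_chains else None,
                }
            )

    oof = score_sum / score_cnt[:, None]
    subjects = cohort.subjects
    oof_df = pd.DataFrame(
        oof, index=subjects, columns=[_contrast_name(a, b) for a, b in pairs]
    )
    lab_idx, _ = ecoc_decode(oof, code)
    oof_pred = pd.Series(
        np.asarray(classes, dtype=object)[lab_idx], index=subjects, name="pred"
    )
    metrics = _compute_metrics(y_all, oof, oof_pred.values, classes, pairs)
    return ModalityRun(
        modality=modality,
        classes=classes,
        pairs=pairs,
        cv=cv,
        oof_scores=oof_df,
        oof_pred=oof_pred,
        metrics=metrics,
        weights={k_: np.array(v) for k_, v in weights.items()},
        folds=folds_out,
    )


def _compute_metrics(y, oof_scores, oof_pred, classes, pairs) -> PerformanceMetrics:
    rows = {}
    for j, (a, b) in enumerate(pairs):
        mask = (y == a) | (y == b)
        s = oof_scores[mask, j]
        truth = y[mask]
        pred = np.where(s > 0, a, b)  # zero margin counts against class a
        sens = 100.0 * np.mean(pred[truth == a] == a)
        spec = 100.0 * np.mean(pred[truth == b] == b)
        rows[(a, b)] = {
            "sensitivity": sens,
            "specificity": spec,
            "bac": (sens + spec) / 2.0,
        }
    contrasts = pd.DataFrame.from_dict(rows, orient="index")
    k = len(classes)
    M = np.zeros((k, k))
    for i, c in enumerate(classes):
        mask = y == c
        for j, d in enumerate(classes):
            M[i, j] = np.mean(oof_pred[mask] == d) if mask.sum() else 0.0
    mis = pd.DataFrame(M, index=classes, columns=classes)
    mbac = 100.0 * _balanced_accuracy(y, np.asarray(oof_pred, dtype=object), classes)
    return PerformanceMetrics(
        contrasts=contrasts, misclassification=mis, multiclass_bac=mbac
    )


def one_vs_rest_summary(run: ModalityRun, labels=None):
    """Per-class summaries derived from the one-vs-one models.

    For each class c: average the binary OOF metrics (BAC and the recall of
    c = sensitivity from c's side) over the k-1 contrasts involving c.
    Returns (per_class DataFrame, misclassification matrix).
    """
    contrasts = run.metrics.contrasts
    rows = {}
    for c in run.classes:
        bacs, sens, specs = [], [], []
        for (a, b), row in contrasts.iterrows():
            if c == a:
                bacs.append(row["bac"])
                sens.append(row["sensitivity"])
                specs.append(row["specificity"])
            elif c == b:
                bacs.append(row["bac"])
                sens.append(row["specificity"])  # recall of c on c's side
                specs.append(row["sensitivity"])
        rows[c] = {
            "bac": float(np.mean(bacs)),
            "sensitivity": float(np.mean(sens)),
            "specificity": float(np.mean(specs)),
        }
    return pd.DataFrame.from_dict(rows, orient="index"), run.metrics.misclassification


def stack(
    runs: dict,
    cohort: Cohort,
    *,
    labels=None,
    c_grid=DEFAULT_C_GRID,
    winsor_limit: float = 4.0,
) -> ModalityRun:
    """Stacked multimodal model over >= 2 unimodal runs sharing a CV
    structure.

    Meta-features for an outer-train subject are its inner-CV out-of-fold
    decision scores from every modality (computed within the outer training
    set at that modality's selected hyperparameters); meta-features for
    outer-test subjects come from the modality models trained on the full
    outer training set. The meta-learner is the same ECOC linear-SVM
    machinery with C optimized on the inner CV.
    """
    names = sorted(runs)
    if len(names) < 2:
        raise ValueError("stacking needs >= 2 unimodal runs")
    base = runs[names[0]]
    cv = base.cv
    for nm in names[1:]:
        r = runs[nm]
        if r.cv is not cv and (
            r.cv.seed != cv.seed
            or r.cv.n != cv.n
            or r.cv.outer_folds != cv.outer_folds
            or r.cv.outer_perms != cv.outer_perms
        ):
            raise ValueError("unimodal runs use different CV structures")
        if r.classes != base.classes:
            raise ValueError("unimodal runs disagree on classes")
        for fr, fb in zip(r.folds, base.folds):
            if fr["train_scores"] is None:
                raise ValueError(
                    f"run {nm!r} lacks inner-CV train scores; rerun with "
                    "collect_train_scores=True"
                )

    y_all = np.asarray(
        labels if labels is not None else cohort.labels.values, dtype=object
    )
    y_all = np.array([str(v) for v in y_all], dtype=object)
    classes = base.classes
    pairs = base.pairs
    code = ovo_code_matrix(classes)
    n = cv.n
    m = len(pairs)
    score_sum = np.zeros((n, m))
    score_cnt = np.zeros(n)
    weights: dict[str, list] = {_contrast_name(a, b): [] for a, b in pairs}
    folds_out = []

    fold_index = {(fr["perm"], fr["fold"]): i for i, fr in enumerate(base.folds)}
    for (p, f), i in sorted(fold_index.items()):
        tr = base.folds[i]["train_idx"]
        te = base.folds[i]["test_idx"]
        meta_tr = np.hstack([runs[nm].folds[i]["train_scores"] for nm in names])
        meta_te = np.hstack([runs[nm].folds[i]["test_scores"] for nm in names])
        # inner CV on the meta-features for the slack parameter
        key = p * 1000 + f
        bac_acc = {C: [] for C in c_grid}
        pos = {idx: j for j, idx in enumerate(tr)}
        for q, g, itr, iva in cv.inner_splits(tr, y_all, key):
            rtr = np.array([pos[i_] for i_ in itr])
            rva = np.array([pos[i_] for i_ in iva])
            sc = ScaleWinsorize(center="mean", limit=winsor_limit)
            sc.fit(meta_tr[rtr], None, np.ones(len(rtr), dtype=bool))
            Xtr = sc.apply(meta_tr[rtr], None)
            Xva = sc.apply(meta_tr[rva], None)
            for C in c_grid:
                model = _fit_ecoc(Xtr, y_all[itr], classes, C)
                lab, _ = ecoc_decode(model.decision_scores(Xva), code)
                pred = np.asarray(classes, dtype=object)[lab]
                bac_acc[C].append(_balanced_accuracy(y_all[iva], pred, classes))
        C_star = optimize_slack({C: float(np.mean(v)) for C, v in bac_acc.items()}, grid=c_grid)

        sc = ScaleWinsorize(center="mean", limit=winsor_limit)
        sc.fit(meta_tr, None, np.ones(len(tr), dtype=bool))
        model = _fit_ecoc(sc.apply(meta_tr, None), y_all[tr], classes, C_star)
        te_scores = model.decision_scores(sc.apply(meta_te, None))
        score_sum[te] += te_scores
        score_cnt[te] += 1
        for learner, (a, b) in zip(model.learners, pairs):
            weights[_contrast_name(a, b)].append(learner.weights.copy())
        folds_out.append(
            {
                "perm": p,
                "fold": f,
                "train_idx": tr,
                "test_idx": te,
                "C": C_star,
                "energy": None,
                "test_scores": te_scores,
                "train_scores": None,
                "chain_params": None,
            }
        )

    oof = score_sum / score_cnt[:, None]
    subjects = cohort.subjects
    oof_df = pd.DataFrame(
        oof, index=subjects, columns=[_contrast_name(a, b) for a, b in pairs]
    )
    lab_idx, _ = ecoc_decode(oof, code)
    oof_pred = pd.Series(
        np.asarray(classes, dtype=object)[lab_idx], index=subjects, name="pred"
    )
    metrics = _compute_metrics(y_all, oof, oof_pred.values, classes, pairs)
    return ModalityRun(
        modality="stacked[" + "+".join(names) + "]",
        classes=classes,
        pairs=pairs,
        cv=cv,
        oof_scores=oof_df,
        oof_pred=oof_pred,
        metrics=metrics,
        weights={k_: np.array(v) for k_, v in weights.items()},
        folds=folds_out,
    )
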