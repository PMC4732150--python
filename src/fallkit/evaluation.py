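"""Evaluation protocol for fall detectors.

Covers the full study machinery: ROC curves and AUC, the geometric-mean
operating point, stratified 10-fold cross-validation, nested grid search on
90/10 inner splits, the personalized-vs-generic comparison per subject,
two-sided Wilcoxon signed-rank tests, and the table summaries used to
report results (per-algorithm means, per-subject tables, paired
differences, win counts, and the false-alarm reduction factor).

Detectors are referred to by short names: ``nn``, ``lof``, ``ocsvm``,
``svm``.  Novelty detectors (nn/lof/ocsvm) are always fitted on the ADL
portion of whatever training set they are handed; the supervised SVM uses
both classes.  Reporting uses the conventional variant labels PNN/GNN/
PSVM/GSVM for personalized/generic NN and SVM.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .records import ADL, FALL, Dataset, Record
from .novelty import ExemplarSet, median_pairwise_distance
from .svm import (
    TrainedModel,
    anomaly_scores,
    train_lof,
    train_nn,
    train_oneclass,
    train_svm,
)

ALGORITHMS = ("nn", "lof", "ocsvm", "svm")
CONDITIONS = ("personalized", "generic")

_SEED_CAP = 2**31 - 1


# ---------------------------------------------------------------------------
# ROC / AUC / operating point


@dataclass
class ROCCurve:
    """ROC curve: thresholds descending, SE (=TPR) and FPR non-decreasing."""

    thresholds: np.ndarray
    se: np.ndarray
    fpr: np.ndarray

    @property
    def sp(self) -> np.ndarray:
        return 1.0 - self.fpr


def roc_and_auc(
    fall_scores: Sequence[float], adl_scores: Sequence[float]
) -> tuple[ROCCurve, float]:
    """ROC curve and trapezoid AUC from fall/ADL anomaly scores.

    The AUC equals the rank statistic P(fall > adl) + 0.5 P(tie).
    """
    fall_scores = np.asarray(fall_scores, dtype=float)
    adl_scores = np.asarray(adl_scores, dtype=float)
    if fall_scores.size == 0 or adl_scores.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(fall_scores.size), np.zeros(adl_scores.size)])
    s = np.concatenate([fall_scores, adl_scores])
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(thr, tpr, fpr), float(_trapezoid_auc(fpr, tpr))


def best_operating_point(curve: ROCCurve) -> tuple[float, float]:
    """(SE, SP) at the threshold maximizing sqrt(SE * SP).

    Ties (within 1e-12) are broken toward higher SE; among equal SE the
    higher SP dominates.
    """
    g = np.sqrt(np.clip(curve.se * curve.sp, 0.0, None))
    best = g.max()
    cand = np.flatnonzero(g >= best - 1e-12)
    pick = max(cand, key=lambda i: (curve.se[i], curve.sp[i]))
    return float(curve.se[pick]), float(curve.sp[pick])


def false_alarm_factor(sp_generic: float, sp_personalized: float) -> float:
    """Fold reduction in false alarms, (1 - SP_gen) / (1 - SP_pers)."""
    if sp_personalized >= 1.0:
        raise ValueError(
            "personalized SP = 1 implies an infinite false-alarm factor"
        )
    if sp_generic >= 1.0:
        raise ValueError("generic SP must be < 1")
    return (1.0 - sp_generic) / (1.0 - sp_personalized)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded.  The null distribution is exact
    (dynamic programming over all sign assignments, tie-averaged ranks)
    for n <= 25 remaining pairs, and a normal approximation with
    continuity and tie corrections above.  All-zero differences give 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size == 0:
        raise ValueError("need at least one pair")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        return _exact_wilcoxon_p(ranks, w_pos)
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (abs(w_pos - mu) - 0.5) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * norm.sf(z)))


def _exact_wilcoxon_p(ranks: np.ndarray, w_pos: float) -> float:
    # doubled ranks are integers even with tie-averaged (half-integer) ranks
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    w2 = int(round(2 * w_pos))
    denom = counts.sum()
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# Splits and grids


def kfold_split(
    labels: Sequence[str] | Dataset,
    folds: int = 10,
    seed: int = 0,
    stratify_by_label: bool = True,
) -> np.ndarray:
    """Fold id (0..folds-1) per record; stratified by label by default."""
    if isinstance(labels, Dataset):
        labels = labels.labels()
    labels = np.asarray(labels)
    n = labels.size
    if stratify_by_label:
        _, class_counts = np.unique(labels, return_counts=True)
        if class_counts.min() < folds:
            raise ValueError(
                f"stratified {folds}-fold split needs >= {folds} records "
                f"per class; got class counts {class_counts.tolist()}"
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed)
        split = splitter.split(np.zeros(n), labels)
    else:
        if n < folds:
            raise ValueError(f"need >= {folds} records, got {n}")
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    assignment = np.empty(n, dtype=int)
    for fold_id, (_, val_idx) in enumerate(split):
        assignment[val_idx] = fold_id
    return assignment


def stratified_holdout(
    labels: Sequence[str], test_size: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(train_idx, val_idx) with per-class proportional sampling.

    Every class contributes at least one record to the validation side and
    keeps at least one on the training side, so AUC is always defined on
    the holdout even for small minority classes.
    """
    labels = np.asarray(labels)
    val_parts = []
    for cls in np.unique(labels):
        cls_idx = np.flatnonzero(labels == cls)
        if cls_idx.size < 2:
            raise ValueError(
                f"class {cls!r} needs >= 2 records for a stratified holdout"
            )
        n_val = int(np.clip(round(test_size * cls_idx.size), 1,
                            cls_idx.size - 1))
        val_parts.append(rng.choice(cls_idx, n_val, replace=False))
    val = np.sort(np.concatenate(val_parts))
    train = np.setdiff1d(np.arange(labels.size), val)
    return train, val


@dataclass
class GridSpec:
    """Candidate parameter lists per detector parameter."""

    params: dict[str, list]

    def __post_init__(self) -> None:
        for key, values in self.params.items():
            if not values:
                raise ValueError(f"empty candidate list for {key!r}")

    def points(self) -> list[dict]:
        keys = list(self.params)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.params[k] for k in keys))
        ]


def default_grid(
    algorithm: str,
    train_records: Sequence[Record],
    kernel_form: str = "distance",
) -> GridSpec:
    """Standard log-spaced grids scaled to the training ADL geometry.

    gamma candidates are powers of four from 2^-8 to 2^2 divided by the
    median pairwise ADL distance (or its square for the squared kernel
    form); C spans 2^-2..2^8 by powers of four; nu and k use short fixed
    lists.  NN has no free parameters and gets an empty grid.
    """
    if algorithm == "nn":
        return GridSpec({})
    adl = [r for r in train_records if r.label == ADL]
    if algorithm == "lof":
        n = len(adl)
        ks = [k for k in (3, 5, 10, 20, 35) if k < max(n, 2)]
        return GridSpec({"k": ks or [1]})
    med = median_pairwise_distance(adl) if adl else 1.0
    scale = med if kernel_form == "distance" else med * med
    gammas = [float(2.0**e) / scale for e in (-8, -6, -4, -2, 0, 2)]
    if algorithm == "ocsvm":
        return GridSpec({"nu": [0.01, 0.05, 0.1, 0.2, 0.3], "gamma": gammas})
    if algorithm == "svm":
        cs = [float(2.0**e) for e in (-2, 0, 2, 4, 6, 8)]
        return GridSpec({"c_penalty": cs, "gamma": gammas})
    raise ValueError(f"unknown algorithm {algorithm!r}")


def fit_detector(
    algorithm: str,
    records: Sequence[Record],
    params: Mapping | None = None,
    kernel_form: str = "distance",
    lof_variant: str = "breunig",
) -> TrainedModel:
    """Train any of the four detector families on a labeled record set.

    Novelty detectors use only the ADL records; the SVM needs both labels.
    """
    params = dict(params or {})
    adl = [r for r in records if r.label == ADL]
    if algorithm == "nn":
        return train_nn(adl)
    if algorithm == "lof":
        return train_lof(adl, k=int(params["k"]), variant=lof_variant)
    if algorithm == "ocsvm":
        return train_oneclass(
            adl, nu=float(params["nu"]), gamma=float(params["gamma"]),
            kernel_form=kernel_form,
        )
    if algorithm == "svm":
        return train_svm(
            list(records), c_penalty=float(params["c_penalty"]),
            gamma=float(params["gamma"]), kernel_form=kernel_form,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _score_split(
    model: TrainedModel, val_records: Sequence[Record]
) -> tuple[np.ndarray, np.ndarray]:
    falls = [r for r in val_records if r.label == FALL]
    adls = [r for r in val_records if r.label == ADL]
    if not falls or not adls:
        raise ValueError("validation set must contain both ADL and FALL")
    return anomaly_scores(model, falls), anomaly_scores(model, adls)


def grid_search(
    train_records: Sequence[Record],
    algorithm: str,
    grid: GridSpec | None = None,
    seed: int = 0,
    n_splits: int = 10,
    test_size: float = 0.1,
    kernel_form: str = "distance",
    lof_variant: str = "breunig",
) -> dict:
    """Pick detector parameters by mean AUC over inner 90/10 splits.

    Each inner split trains on 90% (S1) and scores the held-out 10% (S2);
    the grid point with the best average AUC wins, first-in-grid-order on
    ties.  NN returns an empty parameter set immediately.  Grid points
    whose training fails are skipped with a warning.
    """
    if algorithm == "nn":
        return {}
    train_records = list(train_records)
    if grid is None:
        grid = default_grid(algorithm, train_records, kernel_form)
    points = grid.points()
    if not points:
        return {}
    if len(points) == 1:
        return points[0]
    labels = np.array([r.label for r in train_records])
    rng = np.random.default_rng(seed)
    splits = [stratified_holdout(labels, test_size, rng)
              for _ in range(n_splits)]
    best_params: dict | None = None
    best_auc = -np.inf
    for point in points:
        aucs = []
        try:
            for s1_idx, s2_idx in splits:
                s1 = [train_records[i] for i in s1_idx]
                s2 = [train_records[i] for i in s2_idx]
                model = fit_detector(algorithm, s1, point, kernel_form,
                                     lof_variant)
                fall_s, adl_s = _score_split(model, s2)
                _, auc_val = roc_and_auc(fall_s, adl_s)
                aucs.append(auc_val)
        except Exception as exc:
            warnings.warn(
                f"grid point {point} skipped for {algorithm}: {exc}",
                stacklevel=2,
            )
            continue
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc = mean_auc
            best_params = point
    if best_params is None:
        raise RuntimeError(f"all grid points failed for {algorithm}")
    return best_params


# ---------------------------------------------------------------------------
# Cross-validation experiments


@dataclass
class FoldResult:
    """AUC and the geometric-mean operating point for one validation fold."""

    fold: int
    auc: float
    se: float
    sp: float
    params: dict = field(default_factory=dict)

    @property
    def gmean(self) -> float:
        return float(np.sqrt(self.se * self.sp))


@dataclass
class SubjectResult:
    """All folds of one subject under one condition and algorithm."""

    subject_id: str
    algorithm: str
    condition: str
    folds: list[FoldResult]

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    @property
    def std_auc(self) -> float:
        return float(np.std([f.auc for f in self.folds], ddof=1))

    @property
    def mean_se(self) -> float:
        return float(np.mean([f.se for f in self.folds]))

    @property
    def mean_sp(self) -> float:
        return float(np.mean([f.sp for f in self.folds]))


def _evaluate_fold(
    algorithm: str,
    train: Sequence[Record],
    val: Sequence[Record],
    fold_id: int,
    grid: GridSpec | None,
    seed: int,
    kernel_form: str,
    lof_variant: str,
) -> FoldResult:
    params = grid_search(train, algorithm, grid, seed=seed,
                         kernel_form=kernel_form, lof_variant=lof_variant)
    model = fit_detector(algorithm, train, params, kernel_form, lof_variant)
    fall_s, adl_s = _score_split(model, val)
    curve, auc_val = roc_and_auc(fall_s, adl_s)
    se, sp = best_operating_point(curve)
    return FoldResult(fold_id, auc_val, se, sp, params)


def run_pooled_cv(
    dataset: Dataset,
    algorithm: str,
    folds: int = 10,
    seed: int = 0,
    grid: GridSpec | None = None,
    kernel_form: str = "distance",
    lof_variant: str = "breunig",
) -> list[FoldResult]:
    """Conventional stratified k-fold CV over the pooled dataset.

    Per fold, parameters come from a nested grid search on the training
    folds; novelty detectors then train on the training-fold ADL, the SVM
    on ADL+falls; the held-out fold is scored for AUC and the SE/SP
    operating point.
    """
    assignment = kfold_split(dataset, folds=folds, seed=seed)
    rng = np.random.default_rng(seed)
    inner_seeds = rng.integers(0, _SEED_CAP, size=folds)
    results = []
    for f in range(folds):
        train = [r for r, a in zip(dataset.records, assignment) if a != f]
        val = [r for r, a in zip(dataset.records, assignment) if a == f]
        results.append(
            _evaluate_fold(algorithm, train, val, f, grid,
                           int(inner_seeds[f]), kernel_form, lof_variant)
        )
    return results


def _sample_without_replacement(
    pool: list[Record], size: int, rng: np.random.Generator, what: str
) -> list[Record]:
    if size > len(pool):
        raise ValueError(
            f"need {size} {what} from other subjects but only "
            f"{len(pool)} available"
        )
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in sorted(idx)]


def personalization_experiment(
    dataset: Dataset,
    subject_id: str,
    algorithm: str,
    seed: int = 0,
    runs: int = 10,
    test_size: float = 0.1,
    grid: GridSpec | None = None,
    personal_falls: str = "own",
    kernel_form: str = "distance",
    lof_variant: str = "breunig",
) -> tuple[SubjectResult, SubjectResult]:
    """Personalized vs generic detectors for one subject.

    Each of ``runs`` repetitions holds out a stratified 10% of the
    subject's records for validation.  The personalized detector trains on
    the remaining 90% of that subject's data (novelty detectors use only
    its ADL; the SVM also uses the subject's own falls, or other-subject
    falls when ``personal_falls="generic"``).  The generic detector trains
    on an equal-count uniform sample, without replacement, of the other
    subjects' ADL (and falls).  Both conditions are scored on the
    identical validation slice; parameters are re-chosen by grid search
    inside each training set.
    """
    if personal_falls not in ("own", "generic"):
        raise ValueError("personal_falls must be 'own' or 'generic'")
    own = dataset.select(subject_id=subject_id)
    if len(own) == 0:
        raise ValueError(f"no records for subject {subject_id!r}")
    counts = own.counts()
    if counts[ADL] == 0 or counts[FALL] == 0:
        raise ValueError(f"subject {subject_id!r} needs both ADL and falls")
    others_adl = dataset.select(label=ADL, exclude_subject=subject_id).records
    others_fall = dataset.select(label=FALL,
                                 exclude_subject=subject_id).records
    if not others_adl:
        raise ValueError("no other-subject ADL available for the generic pool")

    labels = own.labels()
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, _SEED_CAP, size=(runs, 3))
    split_rng = np.random.default_rng(rng.integers(0, _SEED_CAP))

    personal_folds: list[FoldResult] = []
    generic_folds: list[FoldResult] = []
    for run_id in range(runs):
        train_idx, val_idx = stratified_holdout(labels, test_size, split_rng)
        val = [own.records[i] for i in val_idx]
        personal_train = [own.records[i] for i in train_idx]
        n_adl = sum(1 for r in personal_train if r.label == ADL)
        n_fall = len(personal_train) - n_adl
        sample_rng = np.random.default_rng(int(run_seeds[run_id, 0]))

        if personal_falls == "generic":
            p_adl = [r for r in personal_train if r.label == ADL]
            p_falls = _sample_without_replacement(
                others_fall, n_fall, sample_rng, "falls")
            personal_train = p_adl + p_falls

        g_adl = _sample_without_replacement(
            others_adl, n_adl, sample_rng, "ADL")
        g_falls = _sample_without_replacement(
            others_fall, n_fall, sample_rng, "falls")
        generic_train = g_adl + g_falls

        personal_folds.append(
            _evaluate_fold(algorithm, personal_train, val, run_id, grid,
                           int(run_seeds[run_id, 1]), kernel_form,
                           lof_variant)
        )
        generic_folds.append(
            _evaluate_fold(algorithm, generic_train, val, run_id, grid,
                           int(run_seeds[run_id, 2]), kernel_form,
                           lof_variant)
        )
    return (
        SubjectResult(subject_id, algorithm, "personalized", personal_folds),
        SubjectResult(subject_id, algorithm, "generic", generic_folds),
    )


# ---------------------------------------------------------------------------
# Tidy results and reporting


def variant_name(algorithm: str, condition: str | None = None) -> str:
    """Conventional short label, e.g. ('nn', 'personalized') -> 'PNN'."""
    base = {"nn": "NN", "lof": "LOF", "ocsvm": "OneClass-SVM",
            "svm": "SVM"}[algorithm]
    if condition is None:
        return base
    return {"personalized": "P", "generic": "G"}[condition] + base


def results_frame(
    results: Iterable[SubjectResult | tuple[str, str, str, FoldResult]],
) -> pd.DataFrame:
    """Tidy per-fold results: one row per (subject, algorithm, condition,
    fold) with auc/se/sp and the chosen parameters as JSON."""
    rows = []
    for item in results:
        if isinstance(item, SubjectResult):
            for fr in item.folds:
                rows.append(
                    (item.subject_id, item.algorithm, item.condition,
                     fr.fold, fr.auc, fr.se, fr.sp, json.dumps(fr.params))
                )
        else:
            subject_id, algorithm, condition, fr = item
            rows.append(
                (subject_id, algorithm, condition, fr.fold, fr.auc,
                 fr.se, fr.sp, json.dumps(fr.params))
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "algorithm", "condition", "fold", "auc",
                 "se", "sp", "params_json"],
    )


def pooled_results_frame(
    fold_results: Mapping[str, list[FoldResult]]
) -> pd.DataFrame:
    """Tidy frame for pooled CV: subject_id is 'all', condition 'pooled'."""
    items = [
        ("all", algorithm, "pooled", fr)
        for algorithm, frs in fold_results.items()
        for fr in frs
    ]
    return results_frame(items)


def algorithm_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and std of AUC/SE/SP/gmean per (algorithm, condition) over all
    folds — the shape of the pooled-comparison tables."""
    work = df.copy()
    work["gmean"] = np.sqrt(work["se"] * work["sp"])
    grouped = work.groupby(["algorithm", "condition"])[
        ["auc", "se", "sp", "gmean"]
    ].agg(["mean", "std"])
    grouped.columns = [f"{m}_{s}" for m, s in grouped.columns]
    return grouped.reset_index()


def subject_table(df: pd.DataFrame, metric: str = "auc") -> pd.DataFrame:
    """Per-subject mean of a metric, one column per detector variant."""
    work = df.copy()
    work["variant"] = [
        variant_name(a, c if c in CONDITIONS else None)
        for a, c in zip(work["algorithm"], work["condition"])
    ]
    table = work.pivot_table(index="subject_id", columns="variant",
                             values=metric, aggfunc="mean")
    table.columns.name = None
    return table


def win_count(a: Sequence[float], b: Sequence[float]) -> tuple[int, int]:
    """(#rows where a > b, #rows where b > a); exact ties count for neither."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("win_count needs equal-length columns")
    return int((a > b).sum()), int((b > a).sum())


def cell_fraction(table: pd.DataFrame, threshold: float) -> float:
    """Fraction of numeric cells strictly above a threshold."""
    values = table.to_numpy(dtype=float).ravel()
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("table has no numeric cells")
    return float((values > threshold).mean())


def paired_difference_summary(
    df: pd.DataFrame,
    variant_a: str,
    variant_b: str,
    metric: str = "auc",
    alpha: float = 0.05,
) -> dict:
    """Per-subject paired comparison of two detector variants.

    For every subject the per-fold metric values of the two variants are
    paired by fold: the summary holds the per-subject mean difference and
    its per-fold std, a Wilcoxon p-value per subject, a significance flag
    at ``alpha``, win counts over subjects, and the mean difference
    aggregated both over subjects and over all pooled folds.
    """
    work = df.copy()
    work["variant"] = [
        variant_name(a, c if c in CONDITIONS else None)
        for a, c in zip(work["algorithm"], work["condition"])
    ]
    per_subject = {}
    all_a: list[float] = []
    all_b: list[float] = []
    subjects = sorted(work["subject_id"].unique())
    for subject in subjects:
        sub = work[work["subject_id"] == subject]
        a = sub[sub["variant"] == variant_a].sort_values("fold")[metric]
        b = sub[sub["variant"] == variant_b].sort_values("fold")[metric]
        if len(a) == 0 or len(b) == 0 or len(a) != len(b):
            raise ValueError(
                f"subject {subject!r}: missing or unbalanced folds for "
                f"{variant_a} ({len(a)}) vs {variant_b} ({len(b)})"
            )
        a = a.to_numpy()
        b = b.to_numpy()
        diffs = a - b
        p = wilcoxon_signed_rank(a, b)
        per_subject[subject] = {
            "mean_diff": float(diffs.mean()),
            "std_diff": float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0,
            "p_value": p,
            "significant": bool(p < alpha),
        }
        all_a.extend(a)
        all_b.extend(b)
    subject_diffs = np.array(
        [per_subject[s]["mean_diff"] for s in subjects]
    )
    pooled = np.array(all_a) - np.array(all_b)
    wins_a, wins_b = win_count(subject_diffs, np.zeros_like(subject_diffs))
    return {
        "pair": (variant_a, variant_b),
        "metric": metric,
        "per_subject": per_subject,
        "mean_diff_subjects": float(subject_diffs.mean()),
        "std_diff_subjects": float(subject_diffs.std(ddof=1))
        if subject_diffs.size > 1 else 0.0,
        "sem_diff_subjects": float(
            subject_diffs.std(ddof=1) / np.sqrt(subject_diffs.size)
        ) if subject_diffs.size > 1 else 0.0,
        "mean_diff_folds": float(pooled.mean()),
        "std_diff_folds": float(pooled.std(ddof=1))
        if pooled.size > 1 else 0.0,
        "p_value_subjects": wilcoxon_signed_rank(
            subject_diffs, np.zeros_like(subject_diffs)
        ),
        "n_better": wins_a,
        "n_worse": wins_b,
    }


def summarize_tables(
    df: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> dict:
    """All report blocks from a tidy results frame, JSON-serializable.

    Emits per-algorithm mean/std, per-subject AUC and SE/SP/gmean tables,
    paired-difference blocks with Wilcoxon p-values for each requested
    variant pair, win counts per metric, and cell fractions above 0.90
    and 0.95.
    """
    work = df.copy()
    work["variant"] = [
        variant_name(a, c if c in CONDITIONS else None)
        for a, c in zip(work["algorithm"], work["condition"])
    ]
    variants = sorted(work["variant"].unique())
    if pairs is None:
        pairs = [
            (a, b) for i, a in enumerate(variants) for b in variants[i + 1:]
        ]
    out: dict = {
        "algorithms": json.loads(
            algorithm_summary(df).to_json(orient="records")
        ),
    }
    auc_table = subject_table(df, "auc")
    out["subject_auc"] = json.loads(auc_table.to_json())
    op_tables = {m: subject_table(df, m) for m in ("se", "sp")}
    gmean = np.sqrt(op_tables["se"] * op_tables["sp"])
    out["subject_operating_points"] = {
        "se": json.loads(op_tables["se"].to_json()),
        "sp": json.loads(op_tables["sp"].to_json()),
        "gmean": json.loads(gmean.to_json()),
    }
    multi_subject = auc_table.shape[0] > 1
    comparisons = {}
    win_counts: dict = {}
    for a, b in pairs:
        if a not in auc_table.columns or b not in auc_table.columns:
            continue
        key = f"{a}_vs_{b}"
        if multi_subject:
            comparisons[key] = paired_difference_summary(df, a, b, alpha=alpha)
        win_counts[key] = {}
        for metric, table in (("auc", auc_table), ("se", op_tables["se"]),
                              ("sp", op_tables["sp"]), ("gmean", gmean)):
            wa, wb = win_count(table[a], table[b])
            win_counts[key][metric] = {a: wa, b: wb}
    if comparisons:
        out["comparisons"] = comparisons
    out["win_counts"] = win_counts
    out["cell_fractions"] = {
        "auc_gt_0.90": cell_fraction(auc_table, 0.90),
        "auc_gt_0.95": cell_fraction(auc_table, 0.95),
    }
    return out
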