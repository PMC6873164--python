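"""Feature selection, nested LOOCV classification, and group statistics.

Implements the evaluation protocol for the multi-modal connectivity
features: each subject's asymmetric K x K network is flattened to a
K(K-1)-dimensional edge vector; inside every leave-one-out fold a
two-sample-t filter keeps the top 20% of edges, a linear SVM-RFE ranks the
survivors under a dimension-dependent step schedule, the SVM cost C is
tuned by an inner stratified 5-fold search over powers of two, and the
held-out subject is predicted at an increasing fraction of the top-ranked
features (10%, 15%, ..., 100%).  All selection statistics are computed from
the n-1 training subjects only.

Also provides edge-wise two-sample t tests with Benjamini-Hochberg FDR
control, and the small cohort-table statistics (2x2 chi-square without
continuity correction; pooled two-sample t from summary statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .mmc_network import ConnectivityNetwork
from .regional_io import InputError

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "pMCI"


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class EdgeFeatureTable:
    """n_subjects x K(K-1) matrix of edge weights plus the edge index map.

    Column order: target region k outer (row of the network), regressor j
    inner, skipping j = k; ``edge_index[c] = (k, j)`` in region ids.
    """

    matrix: np.ndarray
    edge_index: list[tuple[int, int]]
    labels: np.ndarray
    region_ids: tuple[int, ...]

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SelectionConfig:
    filter_keep_frac: float = 0.20
    fraction_grid: tuple[float, ...] = tuple(np.round(np.arange(0.10, 1.0001, 0.05), 2))
    c_betas: tuple[int, ...] = tuple(range(-8, 9))
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.filter_keep_frac <= 1.0):
            raise InputError("filter_keep_frac must lie in (0, 1]")
        if any(not (0.0 < f <= 1.0) for f in self.fraction_grid):
            raise InputError("fractions must lie in (0, 1]")

    @property
    def c_grid(self) -> tuple[float, ...]:
        return tuple(2.0**b for b in self.c_betas)


@dataclass
class CVReport:
    """Leave-one-out results across the feature-fraction grid.

    ``grid_metrics`` maps fraction -> dict(accuracy, sensitivity,
    specificity, auc); the peak row is the argmax-accuracy grid point and is
    optimistically biased (the fraction is selected on the evaluation
    metric itself).
    """

    fractions: tuple[float, ...]
    grid_metrics: dict[float, dict[str, float]]
    peak_fraction: float
    peak: dict[str, float]
    fold_predictions: pd.DataFrame
    chosen_C: list[float]
    selected_features: list[np.ndarray]
    positive_label: str
    #: unbiased alternative: per-fold fraction chosen by inner CV, not on the
    #: evaluation metric; populated when honest_fraction=True
    honest: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"fraction": f, **m} for f, m in self.grid_metrics.items()]
        )


@dataclass
class EdgeStats:
    """Per-edge two-sample t with BH-adjusted q values."""

    table: pd.DataFrame  # columns: target_region, regressor_region, t, p, q, significant, sign

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


# ---------------------------------------------------------------------------
# Edge vectorization
# ---------------------------------------------------------------------------


def edge_index_map(K: int, region_ids: Sequence[int] | None = None) -> list[tuple[int, int]]:
    ids = list(region_ids) if region_ids is not None else list(range(1, K + 1))
    return [(ids[k], ids[j]) for k in range(K) for j in range(K) if j != k]


def vectorize_networks(
    networks: Sequence[ConnectivityNetwork], labels: Sequence[str]
) -> EdgeFeatureTable:
    """Flatten K x K networks to K(K-1) off-diagonal edge features."""
    Ks = {n.K for n in networks}
    if len(Ks) != 1:
        raise InputError(f"networks have mixed K: {sorted(Ks)}")
    K = Ks.pop()
    mask = ~np.eye(K, dtype=bool)
    matrix = np.vstack([n.weights[mask] for n in networks])
    return EdgeFeatureTable(
        matrix=matrix,
        edge_index=edge_index_map(K, networks[0].region_ids),
        labels=np.asarray(list(labels)),
        region_ids=networks[0].region_ids,
    )


def devectorize(row: np.ndarray, K: int) -> np.ndarray:
    """Inverse of vectorization: rebuild the K x K matrix (zero diagonal)."""
    out = np.zeros((K, K))
    out[~np.eye(K, dtype=bool)] = row
    return out


# ---------------------------------------------------------------------------
# Two-step feature selection
# ---------------------------------------------------------------------------


def pooled_t(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Columnwise pooled-variance (Student) two-sample t; 0 where variance is 0."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(denom)
    ok = denom > 0
    t[ok] = (m1[ok] - m2[ok]) / denom[ok]
    return t


def ttest_filter(
    X: np.ndarray, labels: np.ndarray, keep_frac: float = 0.20
) -> np.ndarray:
    """Rank columns by |pooled t| descending; keep the top fraction.

    Returns the kept column indices ranked by decreasing |t| (ties broken
    by column index).  Zero-variance columns get t = 0 and rank last.
    """
    classes = np.unique(labels)
    if classes.size != 2:
        raise InputError(f"need exactly two classes, got {classes.tolist()}")
    t = pooled_t(X[labels == classes[0]], X[labels == classes[1]])
    order = np.lexsort((np.arange(t.size), -np.abs(t)))
    n_keep = max(1, _round_half_up(keep_frac * t.size))
    return order[:n_keep]


def _rfe_step(dim: int) -> int:
    """Step schedule on the current surviving dimension."""
    if dim > 10000:
        return 500
    if dim > 1000:
        return 50
    if dim > 100:
        return 5
    return 1


def rfe_step_trace(start_dim: int) -> list[tuple[int, int]]:
    """(dimension, step) sequence the elimination will follow, down to 1."""
    trace = []
    d = start_dim
    while d > 1:
        s = min(_rfe_step(d), d - 1)
        trace.append((d, s))
        d -= s
    return trace


def svm_rfe(
    X: np.ndarray, labels: np.ndarray, C: float, step_schedule=None
) -> np.ndarray:
    """Linear SVM recursive feature elimination.

    Iteratively fits a linear SVM at fixed C, ranks surviving columns by the
    squared weights w_j^2 of the primal hyperplane (w = sum_k alpha_k y_k
    x_k), and removes the schedule's step-size lowest.  Returns all column
    indices ranked best-first (elimination order reversed; within one
    removal batch, lower w^2 ranks worse).
    """
    if X.shape[1] < 2:
        raise InputError("RFE needs at least 2 columns")
    step_fn = step_schedule or _rfe_step
    surviving = np.arange(X.shape[1])
    eliminated: list[np.ndarray] = []
    while surviving.size > 1:
        try:
            clf = SVC(kernel="linear", C=C).fit(X[:, surviving], labels)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"SVM fit failed at dimension {surviving.size}"
            ) from exc
        w2 = (clf.coef_.ravel()) ** 2
        step = min(step_fn(surviving.size), surviving.size - 1)
        # remove the `step` lowest-w^2 features; ties by column index
        order = np.lexsort((surviving, w2))
        drop = order[:step]
        # eliminated batch recorded worst-first within the batch
        eliminated.append(surviving[drop])
        surviving = np.delete(surviving, drop)
    ranking = [surviving]
    for batch in reversed(eliminated):
        ranking.append(batch[::-1])
    return np.concatenate(ranking)


def nested_c_search(
    X: np.ndarray,
    labels: np.ndarray,
    c_betas: Sequence[int],
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the SVM cost C = 2^beta with the best stratified k-fold accuracy.

    Ties resolve to the smallest beta.  Fold assignment is deterministic in
    the seed.
    """
    labels = np.asarray(labels)
    y01 = (labels == np.unique(labels)[1]).astype(int)
    for attempt in range(2):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        try:
            splits = list(skf.split(X, y01))
        except ValueError as exc:
            if attempt == 1:
                raise InputError("cannot stratify inner folds") from exc
            continue
        if all((len(np.unique(y01[tr])) == 2) for tr, _ in splits):
            break
    else:  # pragma: no cover
        raise InputError("inner fold missing a class after re-stratification")
    best_beta, best_acc = None, -1.0
    for beta in sorted(c_betas):
        C = 2.0**beta
        correct = 0
        for tr, te in splits:
            clf = SVC(kernel="linear", C=C).fit(X[tr], labels[tr])
            correct += int(np.sum(clf.predict(X[te]) == labels[te]))
        acc = correct / len(labels)
        if acc > best_acc:
            best_acc, best_beta = acc, beta
    return 2.0**best_beta


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_metrics(
    predictions: np.ndarray,
    decision_values: np.ndarray | None,
    labels: np.ndarray,
    positive_label: str = POSITIVE_LABEL,
) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and (rank-statistic) AUC.

    Sensitivity = TP/(TP+FN) with the positive class being disease
    progression (pMCI); AUC is computed from the decision values with the
    Mann-Whitney tie correction.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    pos = labels == positive_label
    if pos.all() or not pos.any():
        raise InputError("both classes must be present to compute sensitivity/specificity")
    tp = int(np.sum(pos & (predictions == positive_label)))
    fn = int(np.sum(pos & (predictions != positive_label)))
    tn = int(np.sum(~pos & (predictions != positive_label)))
    fp = int(np.sum(~pos & (predictions == positive_label)))
    out = {
        "accuracy": (tp + tn) / labels.size,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }
    if decision_values is not None:
        dv = np.asarray(decision_values, dtype=np.float64)
        ranks = stats.rankdata(dv)
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        out["auc"] = float(auc)
    return out


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Aggregate metrics directly from confusion counts."""
    n = tp + fn + tn + fp
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    }


# ---------------------------------------------------------------------------
# Leave-one-out cross-validated classification
# ---------------------------------------------------------------------------


def _positive_decision(clf: SVC, x: np.ndarray, positive_label: str) -> float:
    """Signed distance oriented so larger means more positive-class."""
    d = float(clf.decision_function(x.reshape(1, -1))[0])
    return d if clf.classes_[1] == positive_label else -d


def loocv_classify(
    X: np.ndarray,
    labels: np.ndarray,
    config: SelectionConfig,
    positive_label: str = POSITIVE_LABEL,
    audit_leakage: bool = False,
    honest_fraction: bool = False,
) -> CVReport:
    """Leave-one-out evaluation with nested two-step feature selection.

    Per fold: t-filter (top ``filter_keep_frac``) -> inner stratified k-fold
    C search on the filtered set -> SVM-RFE ranking at that C -> train/
    predict at every feature fraction of the grid.  Every statistic is a
    pure function of the n-1 training rows; ``audit_leakage=True``
    additionally re-runs the selection of each fold with the held-out row
    poisoned and hard-fails if any selection changes.

    The reported peak grid point selects the fraction on the evaluation
    metric itself and is optimistically biased.  With
    ``honest_fraction=True`` an unbiased variant is reported alongside:
    each fold picks its fraction by inner stratified k-fold accuracy on the
    training rows only.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise InputError("need at least 3 subjects for LOOCV")
    if np.unique(labels).size != 2:
        raise InputError("need exactly two classes")

    fractions = config.fraction_grid
    preds = {f: np.empty(n, dtype=object) for f in fractions}
    decs = {f: np.empty(n) for f in fractions}
    chosen_C: list[float] = []
    selected: list[np.ndarray] = []
    honest_preds = np.empty(n, dtype=object)
    honest_decs = np.empty(n)

    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        Xtr, ytr = X[tr], labels[tr]

        def run_selection(Xt, yt):
            filt = ttest_filter(Xt, yt, config.filter_keep_frac)
            C = nested_c_search(
                Xt[:, filt], yt, config.c_betas, config.inner_folds, config.seed
            )
            rank = svm_rfe(Xt[:, filt], yt, C)
            return filt, C, filt[rank]

        filt, C, ranked_cols = run_selection(Xtr, ytr)
        if audit_leakage:
            Xp = X.copy()
            Xp[i] = 1e6 * (1.0 + np.arange(X.shape[1]))
            f2, C2, r2 = run_selection(Xp[tr], ytr)
            if not (np.array_equal(filt, f2) and C == C2 and np.array_equal(ranked_cols, r2)):
                raise RuntimeError("leakage audit failed: selection depends on held-out row")
        chosen_C.append(C)
        selected.append(ranked_cols)

        for f in fractions:
            n_feat = max(1, _round_half_up(f * ranked_cols.size))
            cols = ranked_cols[:n_feat]
            clf = SVC(kernel="linear", C=C).fit(Xtr[:, cols], ytr)
            preds[f][i] = clf.predict(X[i, cols].reshape(1, -1))[0]
            decs[f][i] = _positive_decision(clf, X[i, cols], positive_label)

        if honest_fraction:
            f_best = _inner_fraction_choice(
                Xtr, ytr, ranked_cols, C, fractions, config.inner_folds, config.seed
            )
            n_feat = max(1, _round_half_up(f_best * ranked_cols.size))
            cols = ranked_cols[:n_feat]
            clf = SVC(kernel="linear", C=C).fit(Xtr[:, cols], ytr)
            honest_preds[i] = clf.predict(X[i, cols].reshape(1, -1))[0]
            honest_decs[i] = _positive_decision(clf, X[i, cols], positive_label)

    grid_metrics = {
        float(f): compute_metrics(preds[f].astype(str), decs[f], labels, positive_label)
        for f in fractions
    }
    peak_fraction = max(
        grid_metrics, key=lambda f: (grid_metrics[f]["accuracy"], -f)
    )
    fold_df = pd.DataFrame(
        {
            "label": labels,
            **{f"pred@{f:.2f}": preds[f].astype(str) for f in fractions},
            **{f"dec@{f:.2f}": decs[f] for f in fractions},
        }
    )
    honest = (
        compute_metrics(honest_preds.astype(str), honest_decs, labels, positive_label)
        if honest_fraction
        else None
    )
    return CVReport(
        fractions=tuple(float(f) for f in fractions),
        grid_metrics=grid_metrics,
        peak_fraction=float(peak_fraction),
        peak=grid_metrics[peak_fraction],
        fold_predictions=fold_df,
        chosen_C=chosen_C,
        selected_features=selected,
        positive_label=positive_label,
        honest=honest,
    )


def _inner_fraction_choice(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    ranked_cols: np.ndarray,
    C: float,
    fractions,
    folds: int,
    seed: int,
) -> float:
    """Pick the feature fraction by inner stratified k-fold accuracy."""
    y01 = (ytr == np.unique(ytr)[1]).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xtr, y01))
    best_f, best_acc = fractions[0], -1.0
    for f in fractions:
        n_feat = max(1, _round_half_up(f * ranked_cols.size))
        cols = ranked_cols[:n_feat]
        correct = 0
        for tr, te in splits:
            clf = SVC(kernel="linear", C=C).fit(Xtr[np.ix_(tr, cols)], ytr[tr])
            correct += int(np.sum(clf.predict(Xtr[np.ix_(te, cols)]) == ytr[te]))
        acc = correct / len(ytr)
        if acc > best_acc:
            best_acc, best_f = acc, float(f)
    return best_f


# ---------------------------------------------------------------------------
# Edge-wise group difference and cohort statistics
# ---------------------------------------------------------------------------


def edge_group_difference(
    table1: np.ndarray,
    table2: np.ndarray,
    edge_index: Sequence[tuple[int, int]] | None = None,
    q_threshold: float = 0.05,
) -> EdgeStats:
    """Edge-wise pooled two-sample t with Benjamini-Hochberg FDR control.

    Sign is reported as the group2 - group1 mean difference; edges with zero
    variance in both groups record p = 1.
    """
    if table1.shape[0] < 2 or table2.shape[0] < 2:
        raise InputError("need at least 2 subjects per group")
    t = pooled_t(table1, table2)
    df = table1.shape[0] + table2.shape[0] - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    flat = (table1.var(axis=0) == 0) & (table2.var(axis=0) == 0)
    p[flat] = 1.0
    reject, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    diff = table2.mean(axis=0) - table1.mean(axis=0)
    idx = list(edge_index) if edge_index is not None else [(-1, -1)] * t.size
    table = pd.DataFrame(
        {
            "target_region": [a for a, _ in idx],
            "regressor_region": [b for _, b in idx],
            "t": t,
            "p": p,
            "q": q,
            "significant": reject & (q < q_threshold),
            "sign": np.sign(diff).astype(int),
        }
    )
    return EdgeStats(table)


def chi_square_2x2(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise InputError("expected a nonnegative 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise InputError("zero margin in the 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), float(p)


def two_sample_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, df, p) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise InputError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise InputError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)
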