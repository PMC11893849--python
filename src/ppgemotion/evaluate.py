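"""Statistical screening and classifier evaluation protocol.

Feature screening uses a two-sided Mann-Whitney U test per feature
(exact null distribution for small samples, tie-corrected normal
approximation otherwise).  Classification follows a repeated-split
protocol: 100 independent stratified 70/30 splits of the epoch table, an
RBF-kernel SVM at library-default regularization per split, the median
held-out AUC as the headline metric, and confusion-matrix metrics taken
from the split realizing that median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

__all__ = [
    "GroupComparison",
    "EvalResult",
    "utest",
    "screen_features",
    "svm_protocol",
    "roc_metrics",
    "correlation_matrix",
]


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group rank comparison."""

    feature: str
    u_stat: float
    p_value: float
    n_a: int
    n_b: int
    method: str

    @property
    def stars(self) -> str:
        p = self.p_value
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank arrangements per U value for group sizes (n, m).

    Classic recursion ``f(U; n, m) = f(U - m; n - 1, m) + f(U; n, m - 1)``
    over the count of arrangements; valid in the absence of ties.
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)
    b = _u_counts(n, m - 1)
    size = n * m + 1
    out = [0] * size
    for u in range(size):
        if u - m >= 0 and u - m < len(a):
            out[u] += a[u - m]
        if u < len(b):
            out[u] += b[u]
    return tuple(out)


def _ranks_with_ties(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of the pooled sample and the tie-group sizes."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    ties = []
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        ties.append(j - i + 1)
        i = j + 1
    return ranks, np.asarray(ties, dtype=float)


def utest(group_a, group_b, feature: str = "", exact_limit: int = 400) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    The exact enumeration of the U null distribution is used when
    ``n_a * n_b <= exact_limit`` and the pooled sample is tie-free;
    otherwise the normal approximation with tie correction and continuity
    correction.  ``U`` reported is the statistic of the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks, tie_sizes = _ranks_with_ties(pooled)
    has_ties = np.any(tie_sizes > 1)
    u_a = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    if n * m <= exact_limit and not has_ties:
        counts = np.asarray(_u_counts(n, m), dtype=float)
        total = counts.sum()
        u_int = int(round(u_a))
        cdf = counts[: u_int + 1].sum() / total
        sf = counts[u_int:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "exact"
    else:
        mu = n * m / 2.0
        nt = n + m
        tie_term = tie_sizes**3 - tie_sizes
        var = n * m / 12.0 * ((nt + 1) - tie_term.sum() / (nt * (nt - 1)))
        if var == 0:
            p = 1.0
        else:
            z = (abs(u_a - mu) - 0.5) / np.sqrt(var)
            from scipy.stats import norm
            p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
        method = "normal"
    return GroupComparison(feature=feature, u_stat=u_a, p_value=p,
                           n_a=n, n_b=m, method=method)


def screen_features(
    table: pd.DataFrame,
    dimension: str,
    feature_cols: list[str],
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[list[str], list[GroupComparison]]:
    """Mann-Whitney screening of features along one emotion dimension.

    ``dimension`` is ``"arousal"`` or ``"valence"``; the table must carry a
    ``label_<dimension>`` column with both ``"low"`` and ``"high"``
    present.  Returns the features with two-sided ``p < alpha`` plus the
    full comparison list (reported regardless of retention).  Raw
    p-values are used by default; ``correction="bh"`` applies the
    Benjamini-Hochberg adjustment before thresholding (the reported
    comparisons keep their raw p-values either way).
    """
    col = f"label_{dimension}"
    levels = set(table[col].dropna().unique())
    if not {"low", "high"} <= levels:
        raise ValueError(f"both classes required in {col}, found {sorted(levels)}")
    comparisons = []
    for feat in feature_cols:
        sub = table[[col, feat]].dropna()
        cmp_ = utest(sub.loc[sub[col] == "low", feat],
                     sub.loc[sub[col] == "high", feat], feature=feat)
        comparisons.append(cmp_)
    pvals = np.array([c.p_value for c in comparisons])
    if correction == "bh":
        from scipy.stats import false_discovery_control
        pvals = false_discovery_control(pvals)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    retained = [c.feature for c, p in zip(comparisons, pvals) if p < alpha]
    return retained, comparisons


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalResult:
    """Classifier performance summary."""

    accuracy: float
    auc: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    roc_fpr: np.ndarray = field(default=None, repr=False)
    roc_tpr: np.ndarray = field(default=None, repr=False)
    iteration_aucs: np.ndarray = field(default=None, repr=False)
    n_iterations: int = 1

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy, "auc": self.auc,
            "precision": self.precision, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1,
        }


def _roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC by descending-threshold sweep, merging tied scores."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(y)[distinct].astype(float)
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / y.sum()]
    fpr = np.r_[0.0, fps / (y.size - y.sum())]
    return fpr, tpr


def roc_metrics(scores, labels, threshold: float = 0.0) -> EvalResult:
    """ROC curve, trapezoidal AUC, and point metrics at a decision threshold.

    ``labels`` are binary (positive = 1).  The trapezoid over tied-score
    blocks gives half credit to ties, so the AUC equals the normalized
    Mann-Whitney U of scores by class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    fpr, tpr = _roc_curve(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity else 0.0)
    return EvalResult(
        accuracy=(tp + tn) / labels.size, auc=auc, precision=precision,
        sensitivity=sensitivity, specificity=specificity, f1=f1,
        roc_fpr=fpr, roc_tpr=tpr,
    )


# ---------------------------------------------------------------------------
# repeated-split SVM protocol
# ---------------------------------------------------------------------------

def svm_protocol(
    table: pd.DataFrame,
    dimension: str,
    feature_cols: list[str],
    iterations: int = 100,
    seed: int = 0,
    test_size: float = 0.3,
    group_by_subject: bool = False,
    loo_training_auc: bool = False,
) -> EvalResult:
    """Repeated stratified-split SVM evaluation with median-AUC selection.

    For each of ``iterations`` seeded splits: hold out ``test_size`` of the
    epochs (stratified on the label; optionally grouped by subject so no
    subject spans both sides), fit an RBF-kernel SVM at default
    regularization on the rest, and score the held-out epochs with the
    decision function.  The reported AUC is the median over iterations;
    accuracy/precision/sensitivity/specificity/F1 come from the iteration
    whose AUC realizes that median.

    ``loo_training_auc`` switches the per-iteration AUC to a
    leave-one-out estimate inside the training portion (one refit per
    training point — expensive; intended for small tables).  Point
    metrics still come from the held-out epochs.
    """
    col = f"label_{dimension}"
    sub = table.dropna(subset=feature_cols + [col])
    x = sub[feature_cols].to_numpy(dtype=float)
    y = (sub[col] == "high").to_numpy().astype(int)
    if len(set(y)) < 2:
        raise ValueError("need both classes")
    if y.size < 20:
        raise ValueError("need at least 20 epochs")
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=iterations)
    aucs = np.empty(iterations)
    per_iter: list[EvalResult] = []
    subjects = sub["subject_id"].to_numpy() if group_by_subject else None
    for k, s in enumerate(split_seeds):
        if group_by_subject:
            uniq = np.unique(subjects)
            r = np.random.default_rng(int(s))
            test_subj = r.choice(uniq, size=max(1, int(round(test_size * uniq.size))),
                                 replace=False)
            mask = np.isin(subjects, test_subj)
            xtr, xte, ytr, yte = x[~mask], x[mask], y[~mask], y[mask]
        else:
            xtr, xte, ytr, yte = train_test_split(
                x, y, test_size=test_size, random_state=int(s) % 2**32,
                stratify=y,
            )
        if len(set(yte)) < 2 or len(set(ytr)) < 2:  # degenerate split: redraw
            s2 = int(rng.integers(0, 2**31 - 1))
            xtr, xte, ytr, yte = train_test_split(
                x, y, test_size=test_size, random_state=s2, stratify=y)
        clf = SVC(kernel="rbf")
        clf.fit(xtr, ytr)
        scores = clf.decision_function(xte)
        res = roc_metrics(scores, yte)
        per_iter.append(res)
        if loo_training_auc:
            loo_scores = np.empty(ytr.size)
            for j in range(ytr.size):
                keep = np.arange(ytr.size) != j
                sub_clf = SVC(kernel="rbf")
                sub_clf.fit(xtr[keep], ytr[keep])
                loo_scores[j] = sub_clf.decision_function(xtr[j : j + 1])[0]
            aucs[k] = roc_metrics(loo_scores, ytr).auc
        else:
            aucs[k] = res.auc
    median_auc = float(np.median(aucs))
    pick = int(np.argmin(np.abs(aucs - median_auc)))
    best = per_iter[pick]
    return EvalResult(
        accuracy=best.accuracy, auc=median_auc, precision=best.precision,
        sensitivity=best.sensitivity, specificity=best.specificity, f1=best.f1,
        roc_fpr=best.roc_fpr, roc_tpr=best.roc_tpr,
        iteration_aucs=aucs, n_iterations=iterations,
    )


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

def correlation_matrix(
    table: pd.DataFrame,
    families: dict[str, tuple[str, ...]],
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise feature correlations plus intra/inter-family |r| summaries.

    Returns ``(corr, summary)`` where ``summary`` is a family-by-family
    table of the mean absolute off-diagonal correlation within and between
    families.  Constant features produce NaN rows/columns (flagged, kept).
    """
    cols = [c for fam in families.values() for c in fam if c in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 epochs for correlations")
    corr = table[cols].corr(method=method)
    fams = list(families)
    summary = pd.DataFrame(index=fams, columns=fams, dtype=float)
    for fa in fams:
        for fb in fams:
            ca = [c for c in families[fa] if c in corr.index]
            cb = [c for c in families[fb] if c in corr.index]
            block = corr.loc[ca, cb].to_numpy(dtype=float)
            if fa == fb:
                iu = np.triu_indices_from(block, k=1)
                vals = block[iu]
            else:
                vals = block.ravel()
            summary.loc[fa, fb] = float(np.nanmean(np.abs(vals))) if vals.size else np.nan
    return corr, summary
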