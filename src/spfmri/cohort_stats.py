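"""Cohort-level statistics for two-group grading studies.

Implements the full evaluation pipeline: inter-reader agreement (ICC),
Spearman correlation matrix with Bonferroni control, Mann-Whitney group
comparison, ROC analysis with Youden-index threshold selection, paired
DeLong AUC comparison, and leave-one-out cross-validated accuracy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortTable",
    "ROCResult",
    "DeLongResult",
    "spearman_rho",
    "mann_whitney",
    "icc_agreement",
    "roc_analysis",
    "delong_test",
    "loocv_accuracy",
    "bonferroni_alpha",
    "correlation_matrix",
    "grading_report",
    "DEFAULT_PARAMETERS",
]

log = logging.getLogger(__name__)

#: Canonical parameter column order for reports.
DEFAULT_PARAMETERS = (
    "ADC_0_1000", "SPF", "f", "D", "D_star", "Ktrans", "v_e", "v_p",
)


class CohortTable:
    """Per-subject, per-reader parameter values with binary grade labels.

    Wraps a DataFrame with columns ``subject_id``, ``grade`` (low/high)
    and one column per parameter; duplicate two-reader measurements may
    be supplied as ``<param>_r1`` / ``<param>_r2`` pairs, in which case
    :meth:`averaged` collapses them to their mean for downstream
    statistics (mirroring consensus-by-averaging after near-perfect
    inter-reader agreement).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "subject_id" not in df.columns or "grade" not in df.columns:
            raise ValueError("table needs subject_id and grade columns")
        if df["subject_id"].duplicated().any():
            raise ValueError("duplicated subject_id")
        grades = set(df["grade"].unique())
        if not grades <= {"low", "high"}:
            raise ValueError(f"grade labels must be 'low'/'high', got {grades}")
        self.df = df

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def parameter_columns(self) -> list[str]:
        base = [c for c in self.df.columns if c not in ("subject_id", "grade")]
        out, seen = [], set()
        for c in base:
            root = c[:-3] if c.endswith(("_r1", "_r2")) else c
            if root not in seen:
                seen.add(root)
                out.append(root)
        return out

    def reader_pair(self, param: str) -> np.ndarray | None:
        c1, c2 = f"{param}_r1", f"{param}_r2"
        if c1 in self.df.columns and c2 in self.df.columns:
            return self.df[[c1, c2]].to_numpy(float)
        return None

    def averaged(self) -> "CohortTable":
        """Collapse ``_r1``/``_r2`` reader pairs to their per-subject mean."""
        df = self.df.copy()
        for p in self.parameter_columns:
            pair = self.reader_pair(p)
            if pair is not None:
                df[p] = pair.mean(axis=1)
                df = df.drop(columns=[f"{p}_r1", f"{p}_r2"])
        return CohortTable(df)

    def values(self, param: str) -> np.ndarray:
        if param not in self.df.columns:
            raise KeyError(f"unknown column {param!r}")
        return self.df[param].to_numpy(float)

    @property
    def labels(self) -> np.ndarray:
        return (self.df["grade"] == "high").to_numpy(bool)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    youden: float
    direction: str  # 'greater': positive if value > threshold; 'less': value <= threshold


@dataclass(frozen=True)
class DeLongResult:
    auc_1: float
    auc_2: float
    delta: float
    variance_of_delta: float
    z: float
    p_value: float
    degenerate: bool = False


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; p by t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need equal-length vectors with at least 4 entries")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("rho undefined for a constant vector")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    n = x.size
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        return rho_c, 0.0
    t = rho_c * math.sqrt((n - 2) / (1.0 - rho_c**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho_c, p


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts (x > y) pairs with ties counted 1/2.  Exact enumeration of
    all label assignments when n_x + n_y <= 12 and the pooled sample has
    no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # number of (x > y) pairs, ties as 1/2
    has_ties = np.unique(pooled).size < pooled.size

    if n1 + n2 <= 12 and not has_ties:
        # enumerate every way the pooled ranks could split between groups
        all_ranks = np.arange(1, n1 + n2 + 1)
        us = np.array([
            sum(c) - n1 * (n1 + 1) / 2.0 for c in combinations(all_ranks, n1)
        ])
        p = 2.0 * min(np.mean(us <= u1), np.mean(us >= u1))
        return float(u1), float(min(p, 1.0))

    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = 0.0
    if has_ties:
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u1), 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = float(2.0 * stats.norm.sf(z))
    return float(u1), min(p, 1.0)


def icc_agreement(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_subjects, 2) array with no missing cells.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] != 2:
        raise ValueError("ratings must be subjects x 2 readers")
    if r.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    if not np.all(np.isfinite(r)):
        raise ValueError("missing cells are not allowed")
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((r - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def _auc_rank(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank method (Mann-Whitney U / (n1*n2), ties halved)."""
    pos = values[labels]
    n1, n2 = pos.size, values.size - pos.size
    ranks = stats.rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def roc_analysis(values, labels, positive: str | None = None) -> ROCResult:
    """ROC analysis with Youden-maximizing threshold selection.

    ``labels`` is boolean (True = positive class) or a 'low'/'high'
    vector with ``positive='high'`` by default.  The direction is
    auto-selected so AUC >= 0.5 and recorded: 'greater' predicts
    positive for value > threshold, 'less' for value <= threshold.
    Youden ties break toward the cut with higher specificity.
    Sensitivity/specificity are apparent (evaluated on the same data).
    """
    values = np.asarray(values, dtype=float)
    labels = _as_bool_labels(labels, positive)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    auc = _auc_rank(values, labels)
    direction = "greater"
    if auc < 0.5:
        auc = 1.0 - auc
        direction = "less"

    pos = values[labels]
    neg = values[~labels]
    cuts = np.unique(values)
    if direction == "greater":
        sens = np.array([(pos > c).mean() for c in cuts])
        spec = np.array([(neg <= c).mean() for c in cuts])
    else:
        sens = np.array([(pos <= c).mean() for c in cuts])
        spec = np.array([(neg > c).mean() for c in cuts])
    youden = sens + spec - 1.0
    best_j = youden.max()
    tied = np.flatnonzero(np.isclose(youden, best_j))
    best = tied[np.argmax(spec[tied])]
    return ROCResult(
        auc=auc,
        threshold=float(cuts[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        youden=float(youden[best]),
        direction=direction,
    )


def _as_bool_labels(labels, positive):
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    positive = positive or "high"
    return labels == positive


def _placements(values, labels):
    pos = values[labels]
    neg = values[~labels]
    # psi(x, y) = 1[x > y] + 0.5*1[x == y]
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)  # per positive
    v01 = cmp.mean(axis=0)  # per negative
    return v10, v01, float(cmp.mean())


def delong_test(values_1, values_2, labels, positive: str | None = None) -> DeLongResult:
    """Paired DeLong comparison of two AUCs measured on the same subjects."""
    v1 = np.asarray(values_1, dtype=float)
    v2 = np.asarray(values_2, dtype=float)
    labels = _as_bool_labels(labels, positive)
    if v1.shape != v2.shape or v1.shape != labels.shape:
        raise ValueError("paired inputs must share one shape")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    v10_1, v01_1, auc1 = _placements(v1, labels)
    v10_2, v01_2, auc2 = _placements(v2, labels)
    m, n = v10_1.size, v01_1.size
    delta = auc1 - auc2
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        degenerate = True
        p = 1.0 if delta == 0 else 0.0
        return DeLongResult(auc1, auc2, delta, max(var, 0.0), 0.0, p, degenerate)
    z = delta / math.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(auc1, auc2, float(delta), float(var), float(z), p)


def loocv_accuracy(values, labels, positive: str | None = None):
    """Leave-one-out cross-validated classification accuracy.

    For each held-out subject the Youden threshold (and direction) is
    re-estimated on the remaining n-1 subjects and applied to the
    held-out value.  The applied decision boundary is the midpoint
    between the selected cut and the next training value above it (the
    standard generalization of a cut placed at an observed value), so
    perfectly separated data cross-validate at accuracy 1.  Folds whose
    training split loses a class are skipped (logged) and excluded from
    the denominator.
    """
    values = np.asarray(values, dtype=float)
    labels = _as_bool_labels(labels, positive)
    n = values.size
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    preds, truth = [], []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if labels[keep].all() or not labels[keep].any():
            log.warning("fold %d skipped: training split lost a class", i)
            preds.append(None)
            continue
        roc = roc_analysis(values[keep], labels[keep])
        train = values[keep]
        above = train[train > roc.threshold]
        boundary = (roc.threshold + above.min()) / 2.0 if above.size else roc.threshold
        if roc.direction == "greater":
            pred = values[i] > boundary
        else:
            pred = values[i] <= boundary
        preds.append(bool(pred))
        truth.append((bool(pred), bool(labels[i])))
    if not truth:
        raise ValueError("no usable folds")
    accuracy = float(np.mean([p == t for p, t in truth]))
    return accuracy, preds


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison significance level alpha/m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


def correlation_matrix(
    table: CohortTable, pairs, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman rho, p, and Bonferroni-adjusted significance per pair."""
    t = table.averaged()
    adj = bonferroni_alpha(alpha, len(pairs))
    rows = []
    for a, b in pairs:
        rho, p = spearman_rho(t.values(a), t.values(b))
        rows.append({
            "x": a, "y": b, "rho": rho, "p": p,
            "significant": p < adj,
        })
    out = pd.DataFrame(rows)
    out.attrs["adjusted_alpha"] = adj
    return out


def grading_report(
    table: CohortTable,
    parameters: list[str] | None = None,
    delong_pairs: list[tuple[str, str]] | None = None,
) -> dict:
    """Per-parameter grading summary plus a pairwise DeLong matrix.

    Returns a dict with ``per_parameter`` (DataFrame: group medians and
    IQRs, Mann-Whitney p, ROC metrics, apparent and LOOCV accuracy) and
    ``delong`` (DataFrame of pairwise AUC-difference p-values).
    Sensitivity/specificity columns are apparent (same-data, at the
    Youden threshold); the cross-validated counterpart is the
    ``loocv_accuracy`` column — both are reported and labelled.
    """
    t = table.averaged()
    labels = t.labels
    params = parameters if parameters is not None else [
        p for p in DEFAULT_PARAMETERS if p in t.parameter_columns
    ] + [p for p in t.parameter_columns if p not in DEFAULT_PARAMETERS]

    rows = []
    usable = []
    for p in params:
        try:
            vals = t.values(p)
        except KeyError:
            log.warning("column %s missing: row omitted", p)
            continue
        if not np.any(np.isfinite(vals)):
            log.warning("column %s empty: row omitted", p)
            continue
        lo = vals[~labels]
        hi = vals[labels]
        _, p_mw = mann_whitney(lo, hi)
        roc = roc_analysis(vals, labels)
        acc_cv, _ = loocv_accuracy(vals, labels)
        n_pos, n_neg = int(labels.sum()), int((~labels).sum())
        apparent_acc = (
            roc.sensitivity * n_pos + roc.specificity * n_neg
        ) / (n_pos + n_neg)
        rows.append({
            "parameter": p,
            "low_median": float(np.median(lo)),
            "low_q1": float(np.percentile(lo, 25)),
            "low_q3": float(np.percentile(lo, 75)),
            "high_median": float(np.median(hi)),
            "high_q1": float(np.percentile(hi, 25)),
            "high_q3": float(np.percentile(hi, 75)),
            "mann_whitney_p": p_mw,
            "auc": roc.auc,
            "threshold": roc.threshold,
            "direction": roc.direction,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "youden": roc.youden,
            "apparent_accuracy": apparent_acc,
            "loocv_accuracy": acc_cv,
        })
        usable.append(p)

    if delong_pairs is None:
        delong_pairs = list(combinations(usable, 2))
    dl_rows = []
    for a, b in delong_pairs:
        res = delong_test(t.values(a), t.values(b), labels)
        dl_rows.append({
            "parameter_1": a, "parameter_2": b,
            "auc_1": res.auc_1, "auc_2": res.auc_2,
            "delta": res.delta, "z": res.z, "p": res.p_value,
        })
    return {
        "per_parameter": pd.DataFrame(rows),
        "delong": pd.DataFrame(dl_rows),
    }
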