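"""Univariate screening and threshold diagnostics.

Welch t-tests and chi-square tests with Bonferroni correction, empirical
ROC curves with DeLong confidence intervals, maximum-accuracy threshold
selection, confusion statistics, and diagnostic odds ratios with the
Haldane-Anscombe correction (add 0.5 to every cell when any cell is
empty).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateLabelError, DomainError


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 confusion counts: rows true converter status, columns marker call."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fn, self.fp, self.tn)
        if any(c < 0 for c in cells):
            raise DomainError("contingency cells must be nonnegative")
        if sum(cells) == 0:
            raise DomainError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)

    @classmethod
    def from_scores(cls, scores, labels, threshold: float) -> "ContingencyTable":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        call = scores >= threshold
        return cls(
            tp=int((call & (labels == 1)).sum()),
            fn=int((~call & (labels == 1)).sum()),
            fp=int((call & (labels == 0)).sum()),
            tn=int((~call & (labels == 0)).sum()),
        )


@dataclass
class ConfusionStats:
    sens: float
    spec: float
    acc: float
    ppv: float
    npv: float
    undefined: tuple[str, ...] = ()


def confusion_stats(t: ContingencyTable) -> ConfusionStats:
    """Sensitivity, specificity, accuracy, PPV and NPV from a 2x2 table.

    Ratios with a zero denominator are reported as NaN and named in
    ``undefined`` rather than silently coerced to 0.
    """
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    out = ConfusionStats(
        sens=ratio(t.tp, t.tp + t.fn, "sens"),
        spec=ratio(t.tn, t.tn + t.fp, "spec"),
        acc=(t.tp + t.tn) / t.total,
        ppv=ratio(t.tp, t.tp + t.fp, "ppv"),
        npv=ratio(t.tn, t.tn + t.fn, "npv"),
    )
    out.undefined = tuple(undefined)
    return out


def diagnostic_or(t: ContingencyTable) -> float:
    """Diagnostic odds ratio (tp*tn)/(fn*fp).

    When any cell is empty, 0.5 is added to every cell first
    (Haldane-Anscombe correction), keeping the ratio finite.
    """
    tp, fn, fp, tn = float(t.tp), float(t.fn), float(t.fp), float(t.tn)
    if min(tp, fn, fp, tn) == 0:
        tp, fn, fp, tn = tp + 0.5, fn + 0.5, fp + 0.5, tn + 0.5
    return (tp * tn) / (fn * fp)


def binary_marker_auc(t: ContingencyTable) -> float:
    """AUC of a one-threshold (binary) marker: (sens + spec) / 2."""
    cs = confusion_stats(t)
    if math.isnan(cs.sens) or math.isnan(cs.spec):
        raise DomainError("sens or spec undefined; AUC not computable")
    return (cs.sens + cs.spec) / 2.0


# ---------------------------------------------------------------------------
# ROC analysis

@dataclass
class RocResult:
    points: list[tuple[float, float]]  # (fpr, tpr), monotone nondecreasing
    auc: float
    ci95: tuple[float, float]
    threshold: float
    sens: float
    spec: float
    acc: float
    ppv: float
    npv: float
    odds_ratio: float
    p_auc: float
    direction: int = 1  # +1: higher score calls converter; -1: flipped


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance for scores oriented pos > neg."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tz = _midranks(all_scores)
    tx = _midranks(pos)
    ty = _midranks(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # structural components over positives
    v01 = 1.0 - (tz[m:] - ty) / m    # over negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC with trapezoid AUC, DeLong 95% CI and p vs AUC=0.5.

    Orientation is chosen automatically so the reported AUC is >= 0.5;
    ``direction=-1`` records that lower scores call the converter class.
    The reported threshold maximizes accuracy (see :func:`best_threshold`).
    """
    from sklearn.metrics import roc_curve as _sk_roc

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(scores).all():
        raise DomainError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelError("ROC requires both classes")

    direction = 1
    auc, var = _delong_auc_variance(scores[labels == 1], scores[labels == 0])
    if auc < 0.5:
        direction = -1
        scores = -scores
        auc, var = _delong_auc_variance(scores[labels == 1], scores[labels == 0])

    fpr, tpr, _ = _sk_roc(labels, scores)
    se = math.sqrt(var)
    if se == 0.0:
        ci = (auc, auc)
        p = 1.0 if auc == 0.5 else 0.0
    else:
        ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
        p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)

    thr = _scan_best_threshold(scores, labels)
    table = ContingencyTable.from_scores(scores, labels, thr)
    cs = confusion_stats(table)
    return RocResult(
        points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=auc,
        ci95=ci,
        threshold=thr if direction == 1 else -thr,
        sens=cs.sens,
        spec=cs.spec,
        acc=cs.acc,
        ppv=cs.ppv,
        npv=cs.npv,
        odds_ratio=diagnostic_or(table),
        p_auc=p,
        direction=direction,
    )


def _scan_best_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Max-accuracy threshold over midpoints between adjacent distinct scores.

    Ties broken toward higher specificity, then toward the lower threshold.
    A marker call is positive when score >= threshold.
    """
    distinct = np.unique(scores)
    candidates = [distinct[0] - 1.0]
    candidates += [(a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])]
    candidates.append(distinct[-1] + 1.0)
    best = None
    for thr in candidates:
        t = ContingencyTable.from_scores(scores, labels, thr)
        cs = confusion_stats(t)
        spec = 0.0 if math.isnan(cs.spec) else cs.spec
        key = (cs.acc, spec, -thr)
        if best is None or key > best[0]:
            best = (key, thr)
    return float(best[1])


def best_threshold(scores, labels) -> float:
    """Public wrapper around the exhaustive max-accuracy midpoint scan."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelError("threshold selection requires both classes")
    return _scan_best_threshold(scores, labels)


# ---------------------------------------------------------------------------
# univariate screen

def univariate_screen(
    values: pd.DataFrame,
    labels,
    types: pd.Series | dict | None = None,
    welch: bool = True,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Per-feature two-group tests with Bonferroni correction.

    Continuous features: two-sample t-test (Welch by default; pooled
    variance with ``welch=False``).  Categorical features: chi-square on
    the level-by-class contingency table.  The Bonferroni multiplier is
    the number of features actually tested in this invocation; features
    skipped (single-level categoricals) carry ``skipped=True``.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelError("screen requires both classes")
    if types is None:
        types = {c: "continuous" for c in values.columns}
    types = pd.Series(types)

    rows = []
    for col in values.columns:
        x = values[col].to_numpy()
        kind = types.get(col, "continuous")
        if kind == "categorical":
            levels = np.unique(x)
            if len(levels) < 2:
                rows.append((col, kind, np.nan, np.nan, True))
                continue
            table = np.array(
                [[(x[labels == g] == lv).sum() for lv in levels] for g in (1, 0)]
            )
            res = stats.chi2_contingency(table, correction=continuity_correction)
            rows.append((col, kind, float(res.statistic), float(res.pvalue), False))
        else:
            res = stats.ttest_ind(x[labels == 1], x[labels == 0], equal_var=not welch)
            rows.append((col, kind, float(res.statistic), float(res.pvalue), False))

    out = pd.DataFrame(
        rows, columns=["feature", "type", "statistic", "p_raw", "skipped"]
    ).set_index("feature")
    m = int((~out["skipped"]).sum())
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * m)
    return out


def bonferroni(p, m: int) -> np.ndarray:
    """min(1, m * p); never decreases a p-value."""
    if m < 1:
        raise DomainError("Bonferroni multiplier must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)
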