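"""Performance metrics, DeLong AUC statistics and cohort characteristics.

Accuracy/sensitivity/specificity come from confusion counts; the AUC is the
Mann-Whitney statistic (ties counted 1/2) with its nonparametric DeLong
variance, a symmetric normal 95% CI on the AUC scale, and the paired DeLong
z-test for comparing two classifiers scored on the same cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "AUCResult",
    "ComparisonResult",
    "confusion_metrics",
    "counts_from_rates",
    "counts_from_predictions",
    "roc_auc",
    "roc_curve_points",
    "delong_paired_test",
    "cohort_stats",
    "diameter_histogram_overlap",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    cohort: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def correct(self) -> int:
        return self.tp + self.tn

    @property
    def total(self) -> int:
        return self.positives + self.negatives


def counts_from_predictions(y_true, y_pred, cohort: str = "") -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        cohort=cohort,
    )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity and specificity in %, rounded to 2 decimals.

    A zero denominator leaves the metric as NaN with a ``flags`` entry
    naming it.
    """
    out: dict[str, float] = {}
    flags = []
    if counts.total > 0:
        out["accuracy"] = round(100.0 * counts.correct / counts.total, 2)
    else:
        out["accuracy"] = float("nan")
        flags.append("accuracy")
    if counts.positives > 0:
        out["sensitivity"] = round(100.0 * counts.tp / counts.positives, 2)
    else:
        out["sensitivity"] = float("nan")
        flags.append("sensitivity")
    if counts.negatives > 0:
        out["specificity"] = round(100.0 * counts.tn / counts.negatives, 2)
    else:
        out["specificity"] = float("nan")
        flags.append("specificity")
    if flags:
        out["flags"] = flags  # type: ignore[assignment]
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def counts_from_rates(n_pos: int, sensitivity: float, n_neg: int,
                      specificity: float, cohort: str = "") -> ConfusionCounts:
    """Reconstruct integer confusion counts from printed percentage rates.

    TP = round(sens * n_pos / 100) and TN = round(spec * n_neg / 100) with
    half-away-from-zero rounding; the round trip through
    :func:`confusion_metrics` reproduces rates printed to 2 decimals.
    """
    for r in (sensitivity, specificity):
        if not (0.0 <= r <= 100.0):
            raise ValueError("rates must lie in [0, 100]")
    tp = _round_half_away(sensitivity * n_pos / 100.0)
    tn = _round_half_away(specificity * n_neg / 100.0)
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp, cohort=cohort)


# ---------------------------------------------------------------------------
# DeLong AUC machinery


@dataclass
class AUCResult:
    auc: float
    variance: float
    ci95: tuple[float, float]


@dataclass
class ComparisonResult:
    delta_auc: float
    z: float
    p_value: float
    degenerate: bool = False


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    if x.size == 0 or y.size == 0:
        raise ValueError("both classes must be present")
    # psi(x, y) = 1 if x > y, 1/2 if tied, 0 otherwise
    greater = (x[:, None] > y[None, :]).astype(float)
    ties = (x[:, None] == y[None, :]).astype(float)
    psi = greater + 0.5 * ties
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01


def roc_auc(scores, labels, ci_scale: str = "auc") -> AUCResult:
    """AUC with DeLong variance and 95% CI.

    The CI defaults to the symmetric normal approximation on the AUC scale,
    clipped to [0, 1]; ``ci_scale="logit"`` transforms through the logit for
    a boundary-respecting interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    v10, v01 = _structural_components(scores, labels)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = float(s10 / m + s01 / n)
    se = math.sqrt(var)
    if ci_scale == "logit" and 0 < auc < 1 and se > 0:
        eta = math.log(auc / (1 - auc))
        se_eta = se / (auc * (1 - auc))
        lo, hi = eta - 1.96 * se_eta, eta + 1.96 * se_eta
        ci = (1 / (1 + math.exp(-lo)), 1 / (1 + math.exp(-hi)))
    else:
        ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return AUCResult(auc=auc, variance=var, ci95=ci)


def roc_curve_points(scores, labels) -> np.ndarray:
    """(FPR, TPR) pairs at every score threshold, for plotting/export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])


def delong_paired_test(scores_a, scores_b, labels) -> ComparisonResult:
    """Paired DeLong test for the AUC difference of two score vectors.

    Both classifiers must be scored on the same cases.  The covariance of
    the paired AUCs comes from the DeLong structural components; a zero
    variance of the difference (e.g. identical scores) is reported as
    p = 1 with a degeneracy flag.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired comparison needs equal-length score/label vectors")
    va10, va01 = _structural_components(scores_a, labels)
    vb10, vb01 = _structural_components(scores_b, labels)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    m, n = va10.size, va01.size
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var_diff = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    delta = auc_a - auc_b
    if var_diff <= 0:
        return ComparisonResult(delta_auc=delta, z=0.0, p_value=1.0, degenerate=True)
    z = delta / math.sqrt(var_diff)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return ComparisonResult(delta_auc=delta, z=z, p_value=min(1.0, p))


# ---------------------------------------------------------------------------
# cohort characteristics


def cohort_stats(records: list[dict], numeric=("age", "short_axis", "long_axis"),
                 categorical=("gender", "tumor_location", "histological_grade"),
                 alpha: float = 0.05) -> dict:
    """Per-class characteristics table with rank-sum / binomial p-values.

    Numeric variables: mean +/- SD per class and a Wilcoxon rank-sum p.
    Categorical variables: per-class percentages and a binomial test of the
    metastatic-class proportion against the normal-class proportion.
    p < alpha rows are flagged significant.
    """
    if not records:
        raise ValueError("empty cohort")
    by_class = {0: [r for r in records if r["label"] == 0],
                1: [r for r in records if r["label"] == 1]}
    table: dict[str, dict] = {}
    for var in numeric:
        row: dict = {}
        for cls in (0, 1):
            vals = np.array([r[var] for r in by_class[cls]], dtype=float)
            row[f"class{cls}"] = {"mean": float(vals.mean()) if vals.size else float("nan"),
                                  "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                                  "n": int(vals.size)}
        if len(by_class[0]) >= 2 and len(by_class[1]) >= 2:
            x = [r[var] for r in by_class[0]]
            y = [r[var] for r in by_class[1]]
            p = float(stats.ranksums(x, y).pvalue)
            row["p"] = p
            row["significant"] = p < alpha
        else:
            row["p"] = None
            row["flag"] = "too few cases for a rank-sum comparison"
        table[var] = row
    for var in categorical:
        levels = sorted({r[var] for r in records})
        ref = levels[-1]  # test the proportion of the last (e.g. M/right/well)
        row = {"reference_level": ref}
        props = {}
        for cls in (0, 1):
            vals = [r[var] for r in by_class[cls]]
            props[cls] = sum(v == ref for v in vals) / len(vals) if vals else float("nan")
            row[f"class{cls}_pct"] = {lv: 100.0 * sum(v == lv for v in vals) / len(vals)
                                      for lv in levels} if vals else {}
        if by_class[0] and by_class[1]:
            k = sum(r[var] == ref for r in by_class[1])
            n = len(by_class[1])
            p0 = min(max(props[0], 1e-12), 1 - 1e-12)
            p = float(stats.binomtest(k, n, p0).pvalue)
            row["p"] = p
            row["significant"] = p < alpha
        else:
            row["p"] = None
        table[var] = row
    return table


def diameter_histogram_overlap(long_axes, labels, bin_width: float = 0.25) -> float:
    """Percentage of nodes falling in histogram bins occupied by both classes.

    Fixed-width bins are anchored at the pooled minimum diameter (a
    documented convention); the statistic is 100 x (nodes in shared bins) /
    (total nodes).
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    d = np.asarray(long_axes, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if d.size == 0:
        raise ValueError("empty input")
    bins = np.floor((d - d.min()) / bin_width).astype(int)
    bins_n = set(bins[lab == 0].tolist())
    bins_m = set(bins[lab == 1].tolist())
    shared = bins_n & bins_m
    in_shared = np.isin(bins, sorted(shared)).sum()
    return float(100.0 * in_shared / d.size)
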