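"""Classification metrics, run statistics and nonparametric benchmark tests.

Covers the full evaluation harness used to compare feature-selection and
classifier-tuning methods: confusion-matrix metrics, per-run aggregate
statistics over repeated seeded runs, descriptive statistics, one-way ANOVA,
the one-sample Wilcoxon signed-rank test against a theoretical median (exact
two-sided p by enumeration for small n), and an ordinary-least-squares
regression report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RunStatistics",
    "DescriptiveStats",
    "AnovaResult",
    "WilcoxonResult",
    "RegressionReport",
    "confusion_counts",
    "classification_metrics",
    "metric_arrays",
    "fs_run_statistics",
    "descriptive_stats",
    "anova_oneway",
    "wilcoxon_signed_rank",
    "regression_report",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Derived classification metrics; ``None`` marks an undefined ratio.

    ``precision_ppv`` is the positive predictive value TP/(TP+FP) and
    ``npv`` the negative predictive value TN/(TN+FN); the F score uses the
    harmonic-mean form TP/(TP + 0.5*(FP+FN)).
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision_ppv: float | None
    npv: float | None
    f_score: float | None


def confusion_counts(y_true, y_pred, positive_label) -> ConfusionCounts:
    """One-vs-rest confusion counts for the given positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if positive_label not in y_true and positive_label not in y_pred:
        raise ValueError(f"label {positive_label!r} absent from both label vectors")
    t = y_true == positive_label
    p = y_pred == positive_label
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        TN=int(np.sum(~t & ~p)),
        FP=int(np.sum(~t & p)),
        FN=int(np.sum(t & ~p)),
    )


def metric_arrays(tp, tn, fp, fn) -> dict[str, np.ndarray]:
    """Vectorized metric formulas; undefined ratios come back as NaN.

    Accepts scalars or broadcastable arrays. This is the single source of
    the formulas; :func:`classification_metrics` is the scalar wrapper.
    """
    tp = np.asarray(tp, dtype=float)
    tn = np.asarray(tn, dtype=float)
    fp = np.asarray(fp, dtype=float)
    fn = np.asarray(fn, dtype=float)

    def div(num, den):
        den = np.asarray(den, dtype=float)
        out = np.full(np.broadcast_shapes(np.shape(num), den.shape), np.nan)
        np.divide(num, den, out=out, where=den > 0)
        return out

    return {
        "accuracy": div(tp + tn, tp + tn + fp + fn),
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "precision_ppv": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
        "f_score": div(tp, tp + 0.5 * (fp + fn)),
    }


def classification_metrics(counts: ConfusionCounts) -> MetricsReport:
    """All six confusion-matrix metrics; zero-denominator metrics are None."""
    if counts.total <= 0:
        raise ValueError("confusion counts must cover at least one sample")
    arrays = metric_arrays(counts.TP, counts.TN, counts.FP, counts.FN)
    vals = {k: (None if np.isnan(v) else float(v)) for k, v in arrays.items()}
    return MetricsReport(**vals)


@dataclass
class RunStatistics:
    """Aggregates of the per-run best fitness over M independent runs."""

    mean_fitness: float
    best_fitness: float
    worst_fitness: float
    std_fitness: float | None
    average_error: float
    average_select_size: float
    n_runs: int


def fs_run_statistics(results: Sequence) -> RunStatistics:
    """Aggregate a list of per-run feature-selection results.

    ``average_select_size`` is the mean selected fraction (selected count /
    total features), matching the sub-unit magnitudes reported for subset
    sizes; ``average_error`` is the mean per-run validation misclassification
    rate; the standard deviation uses the M-1 denominator and is None for a
    single run.
    """
    if not results:
        raise ValueError("need at least one run")
    fitness = np.array([r.best_fitness for r in results], dtype=float)
    errors = np.array([r.error_rate for r in results], dtype=float)
    sizes = np.array([r.best_mask.selected_fraction for r in results], dtype=float)
    m = fitness.size
    return RunStatistics(
        mean_fitness=float(fitness.mean()),
        best_fitness=float(fitness.min()),
        worst_fitness=float(fitness.max()),
        std_fitness=float(fitness.std(ddof=1)) if m >= 2 else None,
        average_error=float(errors.mean()),
        average_select_size=float(sizes.mean()),
        n_runs=m,
    )


@dataclass
class DescriptiveStats:
    n: int
    minimum: float
    maximum: float
    median: float
    q25: float
    q75: float
    value_range: float
    mean: float
    std: float | None
    sem: float | None


def descriptive_stats(values) -> DescriptiveStats:
    """Min/max/median/quartiles/range/mean/std/sem of a sample.

    Quartiles use linear interpolation between order statistics; the standard
    deviation uses the n-1 denominator (None for n = 1) and sem = std/sqrt(n).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    std = float(x.std(ddof=1)) if x.size >= 2 else None
    return DescriptiveStats(
        n=int(x.size),
        minimum=float(x.min()),
        maximum=float(x.max()),
        median=float(np.median(x)),
        q25=float(np.percentile(x, 25)),
        q75=float(np.percentile(x, 75)),
        value_range=float(x.max() - x.min()),
        mean=float(x.mean()),
        std=std,
        sem=(std / math.sqrt(x.size)) if std is not None else None,
    )


@dataclass
class AnovaResult:
    ss_treatment: float
    ss_residual: float
    ss_total: float
    df_treatment: int
    df_residual: int
    df_total: int
    ms_treatment: float
    ms_residual: float
    f_stat: float
    p_value: float
    degenerate: bool = False

    def format_p(self) -> str:
        return "p < 0.0001" if self.p_value < 1e-4 else f"p = {self.p_value:.4f}"


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA with the textbook sum-of-squares split.

    With zero residual variance the F statistic is reported infinite with
    p = 0 and the ``degenerate`` flag set.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_treatment = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_residual = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    ss_total = float(((all_values - grand) ** 2).sum())
    df_treatment = len(arrays) - 1
    df_residual = all_values.size - len(arrays)
    ms_treatment = ss_treatment / df_treatment
    degenerate = ss_residual == 0.0
    if degenerate:
        ms_residual = 0.0
        f_stat = math.inf
        p_value = 0.0
    else:
        ms_residual = ss_residual / df_residual
        f_stat = ms_treatment / ms_residual
        p_value = float(stats.f.sf(f_stat, df_treatment, df_residual))
    return AnovaResult(
        ss_treatment=ss_treatment,
        ss_residual=ss_residual,
        ss_total=ss_total,
        df_treatment=df_treatment,
        df_residual=df_residual,
        df_total=all_values.size - 1,
        ms_treatment=ms_treatment,
        ms_residual=ms_residual,
        f_stat=f_stat,
        p_value=p_value,
        degenerate=degenerate,
    )


@dataclass
class WilcoxonResult:
    w_stat: float  # sum of signed ranks (positive minus negative)
    sum_positive_ranks: float
    sum_negative_ranks: float
    p_two_tailed: float
    n: int
    exact: bool


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the one-sample signed-rank statistic.

    Enumerates the null distribution of W+ = sum of ranks with positive sign
    over all 2^n equiprobable sign assignments via a polynomial-product
    dynamic program. Midranks are handled by working on doubled ranks
    (integers even under .5 ties).
    """
    doubled = np.rint(2 * ranks).astype(int)
    max_sum = int(doubled.sum())
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: max_sum + 1 - r]
        counts = counts + shifted
    total = counts.sum()  # == 2**n
    w2 = int(round(2 * w_plus))
    p_ge = counts[w2:].sum() / total
    p_le = counts[: w2 + 1].sum() / total
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def wilcoxon_signed_rank(values, theoretical_median: float = 0.0) -> WilcoxonResult:
    """One-sample Wilcoxon signed-rank test against a theoretical median.

    Zero differences are dropped. Ties in |difference| receive midranks.
    For n <= 25 the two-sided p is exact (full enumeration of sign
    assignments); above that a normal approximation with tie correction and
    continuity correction is used.
    """
    x = np.asarray(values, dtype=float)
    diffs = x - theoretical_median
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        raise ValueError("all differences equal the theoretical median; test undefined")
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    w_minus = float(ranks[diffs < 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
        exact = True
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
        exact = False
    return WilcoxonResult(
        w_stat=w_plus - w_minus,
        sum_positive_ranks=w_plus,
        sum_negative_ranks=w_minus,
        p_two_tailed=p,
        n=n,
        exact=exact,
    )


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    r_square: float
    f_stat: float
    p_value: float
    n: int


def regression_report(x, y) -> RegressionReport:
    """Ordinary least squares y = slope*x + intercept with t-based 95% CIs.

    The F statistic is the squared slope t statistic (1, n-2 df); a constant
    x is rejected, a constant y yields slope 0 with R-squared 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope undefined")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    se_slope, se_int = float(res.stderr), float(res.intercept_stderr)
    r = float(res.rvalue)
    if math.isnan(r):  # constant y
        r = 0.0
    tcrit = float(stats.t.ppf(0.975, n - 2))
    if se_slope > 0:
        t_slope = slope / se_slope
        f_stat = t_slope**2
        p_value = float(res.pvalue)
    else:  # perfect fit
        f_stat = math.inf
        p_value = 0.0
    return RegressionReport(
        slope=slope,
        intercept=intercept,
        se_slope=se_slope,
        se_intercept=se_int,
        ci95_slope=(slope - tcrit * se_slope, slope + tcrit * se_slope),
        ci95_intercept=(intercept - tcrit * se_int, intercept + tcrit * se_int),
        r_square=r**2,
        f_stat=f_stat,
        p_value=p_value,
        n=n,
    )
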