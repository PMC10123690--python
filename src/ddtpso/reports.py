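"""Tabular report builders for the evaluation harness.

Builds the standard comparison tables — per-method run statistics,
descriptive statistics, ANOVA and Wilcoxon summaries — as pandas DataFrames
and writes them as CSV or JSON.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .metrics import (
    AnovaResult,
    DescriptiveStats,
    RunStatistics,
    WilcoxonResult,
    descriptive_stats,
    wilcoxon_signed_rank,
)

__all__ = [
    "run_statistics_table",
    "descriptive_table",
    "anova_table",
    "wilcoxon_table",
    "write_table",
]


def run_statistics_table(stats_by_method: dict[str, RunStatistics]) -> pd.DataFrame:
    """Methods as columns; error/size/fitness aggregate rows."""
    rows = {
        "Average error": {m: s.average_error for m, s in stats_by_method.items()},
        "Average select size": {m: s.average_select_size for m, s in stats_by_method.items()},
        "Average fitness": {m: s.mean_fitness for m, s in stats_by_method.items()},
        "Best fitness": {m: s.best_fitness for m, s in stats_by_method.items()},
        "Worst fitness": {m: s.worst_fitness for m, s in stats_by_method.items()},
        "Std. fitness": {m: s.std_fitness for m, s in stats_by_method.items()},
    }
    return pd.DataFrame(rows).T


def descriptive_table(values_by_method: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Descriptive statistics per method (methods as columns)."""
    cols = {}
    for method, values in values_by_method.items():
        d: DescriptiveStats = descriptive_stats(values)
        cols[method] = {
            "Number of values": d.n,
            "75% Percentile": d.q75,
            "25% Percentile": d.q25,
            "Maximum": d.maximum,
            "Median": d.median,
            "Minimum": d.minimum,
            "Range": d.value_range,
            "Std. error of mean": d.sem,
            "Std. deviation": d.std,
            "Mean": d.mean,
        }
    return pd.DataFrame(cols)


def anova_table(result: AnovaResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "SS": [result.ss_treatment, result.ss_residual, result.ss_total],
            "DF": [result.df_treatment, result.df_residual, result.df_total],
            "MS": [result.ms_treatment, result.ms_residual, None],
            "F (DFn, DFd)": [
                f"F ({result.df_treatment}, {result.df_residual}) = {result.f_stat:.4g}",
                None,
                None,
            ],
            "p Value": [result.format_p(), None, None],
        },
        index=["Treatment", "Residual", "Total"],
    )


def wilcoxon_table(
    values_by_method: dict[str, Sequence[float]],
    theoretical_median: float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    cols = {}
    for method, values in values_by_method.items():
        r: WilcoxonResult = wilcoxon_signed_rank(values, theoretical_median)
        d = descriptive_stats(values)
        cols[method] = {
            "Theoretical median": theoretical_median,
            "Actual median": d.median,
            "Sum of negative ranks": -r.sum_negative_ranks,
            "Sum of signed ranks (W)": r.w_stat,
            "Sum of positive ranks": r.sum_positive_ranks,
            "p value (two tailed)": r.p_two_tailed,
            "Exact or estimate": "Exact" if r.exact else "Estimate",
            "Significant (alpha = %.2f)?" % alpha: "Yes" if r.p_two_tailed < alpha else "No",
            "Number of values": r.n,
        }
    return pd.DataFrame(cols)


def write_table(df: pd.DataFrame, path: str | Path, fmt: str = "csv") -> Path:
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path)
    elif fmt == "json":
        df.to_json(path, orient="index", indent=2)
    else:
        raise ValueError(f"unknown format {fmt!r}; use csv or json")
    return path
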