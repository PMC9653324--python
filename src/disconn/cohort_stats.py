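"""Cohort-level aggregation, hypothesis tests and threshold sensitivity.

Per-patient comparison metrics are summarised as median [p25, p75]
(linear-interpolation quantiles; missing values excluded listwise per
metric).  Volume contrasts use the unpaired two-sample Wilcoxon rank-sum
(Mann-Whitney) test and metric-vs-lesion-size relationships the Spearman
rank correlation, both two-sided at alpha = 0.05 with raw p-values.
Threshold sensitivity is quantified by the normalised range of variation

    nRV(k) = 100 * |max k - min k| / |max k|

of a metric's median k over the (t_iSD, t_dSD) threshold grid; nRV is
undefined when the maximal median is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05

#: quantile convention recorded in output metadata
QUANTILE_METHOD = "linear"


def _clean(values: Iterable) -> np.ndarray:
    arr = np.array([v for v in values if v is not None], dtype=float)
    return arr[~np.isnan(arr)]


@dataclass
class CohortSummary:
    metric_name: str
    values: list
    median: float
    p25: float
    p75: float
    n: int
    quantile_method: str = QUANTILE_METHOD


def summarize(values: Iterable, metric_name: str = "") -> CohortSummary:
    """Median and 25th/75th percentiles; missing values dropped first."""
    vals = list(values)
    arr = _clean(vals)
    if arr.size == 0:
        raise ValueError("need at least one non-missing value")
    p25, med, p75 = np.percentile(arr, [25, 50, 75], method=QUANTILE_METHOD)
    return CohortSummary(metric_name, vals, float(med), float(p25), float(p75),
                         n=int(arr.size))


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample rank-sum (Mann-Whitney U) test.

    Exact enumeration when the smaller sample has <= 8 values and there
    are no ties; tie-corrected normal approximation otherwise.  Returns
    (U statistic of x, two-sided p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples need at least one value")
    if np.ptp(np.concatenate([x, y])) == 0:
        # fully tied data carry no rank information
        return float(x.size * y.size / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float | None, float | None]:
    """Spearman rank correlation (Pearson on mid-ranks, t-approximation p).

    Undefined (None, None) when either sample has zero rank variance.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    rho, p = stats.spearmanr(x, y)
    if np.isnan(rho):
        return None, None
    return float(rho), float(p)


def nrv(medians) -> float | None:
    """Normalised range of variation over a threshold grid, in percent.

    ``medians`` is a mapping from (t_isd, t_dsd) to a metric median, or a
    plain iterable of medians.  Missing (None / NaN) cells are ignored;
    all-missing input is an error; a zero maximal median makes the value
    undefined (None).
    """
    if isinstance(medians, Mapping):
        vals = medians.values()
    else:
        vals = medians
    arr = _clean(vals)
    if arr.size == 0:
        raise ValueError("need at least one non-missing median")
    mx = arr.max()
    if mx == 0:
        return None
    return float(100.0 * abs(mx - arr.min()) / abs(mx))


@dataclass
class SensitivityGrid:
    """Medians per (t_iSD, t_dSD) cell and nRV per (pair, metric)."""

    t_dsd_values: tuple[float, ...]
    t_isd_values: tuple[float, ...]
    medians: pd.DataFrame          # pair, metric, t_isd, t_dsd, median
    nrv: pd.DataFrame              # pair, metric, nrv
    quantile_method: str = QUANTILE_METHOD


def sensitivity_analysis(medians: pd.DataFrame,
                         t_dsd_values: Sequence[float],
                         t_isd_values: Sequence[float]) -> SensitivityGrid:
    """Validate a full threshold grid of medians and derive nRV per metric.

    ``medians`` must be tidy with columns pair, metric, t_isd, t_dsd and
    median, covering every cell of the grid for every (pair, metric);
    missing cells are an error that lists them.
    """
    required = {"pair", "metric", "t_isd", "t_dsd", "median"}
    if not required.issubset(medians.columns):
        raise ValueError(f"medians frame needs columns {sorted(required)}")
    full = {(round(ti, 6), round(td, 6))
            for ti in t_isd_values for td in t_dsd_values}
    rows = []
    for (pair, metric), sub in medians.groupby(["pair", "metric"]):
        have = {(round(ti, 6), round(td, 6))
                for ti, td in zip(sub["t_isd"], sub["t_dsd"])}
        missing = sorted(full - have)
        if missing:
            raise ValueError(
                f"incomplete threshold grid for ({pair}, {metric}); "
                f"missing cells {missing}")
        try:
            value = nrv(sub["median"].tolist())
        except ValueError:
            value = None
        rows.append({"pair": pair, "metric": metric, "nrv": value})
    return SensitivityGrid(
        t_dsd_values=tuple(t_dsd_values), t_isd_values=tuple(t_isd_values),
        medians=medians.reset_index(drop=True),
        nrv=pd.DataFrame(rows))
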