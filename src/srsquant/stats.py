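"""Two-sided Wilcoxon rank-sum comparisons of per-region metrics.

Irradiated (30 Gy) and control (0 Gy) regions are compared per timepoint
with the two-sided Wilcoxon rank-sum (Mann–Whitney) test — a nonparametric
test of equal population medians, appropriate for the ~10 regions per arm
the imaging protocol yields.  Small tie-free samples (pooled n ≤ 12) are
handled by exact enumeration of the rank-sum null distribution; larger or
tied samples use the normal approximation with tie-corrected variance and
a continuity correction.

P-values are mapped to the conventional star annotation
(ns, *p<0.05, **p<0.01, ***p<0.001, ****p<0.0001).  No multiple-testing
adjustment is applied by default; Bonferroni and Benjamini–Hochberg options
are available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import ValidationError
from .quantify import RegionMeasurement

__all__ = ["TestResult", "wilcoxon_rank_sum", "significance_stars",
           "compare_conditions", "exact_rank_sum_distribution"]

#: Largest pooled sample size for which the exact null is enumerated.
EXACT_N_MAX = 12


@dataclass
class TestResult:
    """Outcome of one two-sample rank-sum comparison."""

    statistic: float  # rank sum of the first sample
    p_value: float
    method: str  # "exact" or "normal_approximation"
    n_x: int
    n_y: int
    stars: str
    warnings: tuple[str, ...] = ()


def significance_stars(p: float) -> str:
    """Star label for a p-value: ****<1e-4, ***<1e-3, **<0.01, *<0.05, else ns."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value must lie in [0, 1], got {p}")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def exact_rank_sum_distribution(n_x: int, n_y: int) -> dict[int, float]:
    """Null distribution of the rank sum of a size-n_x sample, tie-free.

    Enumerates all C(n_x+n_y, n_x) equally likely rank assignments.
    """
    n = n_x + n_y
    total = math.comb(n, n_x)
    dist: dict[int, int] = {}
    for combo in itertools.combinations(range(1, n + 1), n_x):
        w = sum(combo)
        dist[w] = dist.get(w, 0) + 1
    return {w: c / total for w, c in dist.items()}


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the sum of pooled ranks of ``x`` (ties get average
    ranks).  With pooled n ≤ 12 and no ties the two-sided p comes from full
    enumeration of the null rank-sum distribution; otherwise from the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction.  Two-sided p = min(1, 2 × smaller tail).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    n = n_x + n_y

    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)  # average ranks for ties
    w = float(ranks[:n_x].sum())

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if np.all(pooled == pooled[0]):
        return TestResult(statistic=w, p_value=1.0, method="degenerate",
                          n_x=n_x, n_y=n_y, stars="ns",
                          warnings=("all pooled values identical",))

    if n <= EXACT_N_MAX and not has_ties:
        dist = exact_rank_sum_distribution(n_x, n_y)
        w_int = int(round(w))
        lower = sum(p for s, p in dist.items() if s <= w_int)
        upper = sum(p for s, p in dist.items() if s >= w_int)
        p = min(1.0, 2.0 * min(lower, upper))
        method = "exact"
    else:
        mean = n_x * (n + 1) / 2.0
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return TestResult(statistic=w, p_value=1.0, method="degenerate",
                              n_x=n_x, n_y=n_y, stars="ns",
                              warnings=("zero rank variance",))
        z = max(abs(w - mean) - 0.5, 0.0) / math.sqrt(var)
        p = min(1.0, 2.0 * scipy.stats.norm.sf(z))
        method = "normal_approximation"

    return TestResult(statistic=w, p_value=p, method=method,
                      n_x=n_x, n_y=n_y, stars=significance_stars(p))


def adjust_pvalues(pvalues: Sequence[float], method: str = "none") -> np.ndarray:
    """Optional multiplicity adjustment: none (default), bonferroni, or bh."""
    p = np.asarray(pvalues, dtype=float)
    if method == "none":
        return p
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        return adj
    raise ValidationError(f"unknown adjustment method {method!r}")


def compare_conditions(
    measurements: Iterable[RegionMeasurement],
    metric: str,
    condition_x: str = "30 Gy",
    condition_y: str = "0 Gy",
    p_adjust: str = "none",
) -> pd.DataFrame:
    """Rank-sum comparison of a metric between two conditions per timepoint.

    Returns a DataFrame with one row per timepoint at which both conditions
    are present (timepoints missing an arm are skipped, recorded in the
    ``skipped`` attribute of the result), carrying the per-arm n, the rank
    statistic, the two-sided p-value, the method used and the star label.
    """
    records = list(measurements)
    if not records:
        raise ValidationError("no measurements supplied")
    valid_metrics = {"ld_area_per_cell", "lipid_intensity_per_cell",
                     "protein_intensity_per_cell", "cell_area_per_cell"}
    if metric not in valid_metrics:
        raise ValidationError(f"unknown metric {metric!r}; choose from {sorted(valid_metrics)}")

    rows = []
    skipped = []
    for tp in sorted({m.timepoint for m in records}):
        x = [getattr(m, metric) for m in records
             if m.timepoint == tp and m.condition == condition_x]
        y = [getattr(m, metric) for m in records
             if m.timepoint == tp and m.condition == condition_y]
        if not x or not y:
            skipped.append(tp)
            continue
        res = wilcoxon_rank_sum(x, y)
        rows.append({"timepoint": tp, "metric": metric,
                     "n_30Gy" if condition_x == "30 Gy" else "n_x": res.n_x,
                     "n_0Gy" if condition_y == "0 Gy" else "n_y": res.n_y,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "method": res.method, "stars": res.stars})
    table = pd.DataFrame(rows)
    if not table.empty and p_adjust != "none":
        table["p_value"] = adjust_pvalues(table["p_value"].to_numpy(), p_adjust)
        table["stars"] = [significance_stars(p) for p in table["p_value"]]
    table.attrs["skipped_timepoints"] = skipped
    return table
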