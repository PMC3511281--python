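"""Population-level summaries: contingency tables, distance histograms,
magnitude comparisons, and count-to-percentage tabulations.

Percentages are rounded half-up to one decimal place, the convention of
printed summary tables in this field. The Mann-Whitney comparison of
response magnitudes uses exact permutation enumeration for combined
samples up to 20 and the tie-corrected normal approximation above that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CellClass
from .io import Region, SortQuality
from .psth import ResponseCategory

__all__ = [
    "UnitResult",
    "CohortSummary",
    "GroupComparison",
    "tabulate",
    "responders_by_distance",
    "compare_magnitudes",
    "proportion_from_counts",
    "row_percentages",
    "round_half_up",
]

#: column order of response categories in summary tables
CATEGORIES = [
    ResponseCategory.NONE,
    ResponseCategory.INCREASE,
    ResponseCategory.DECREASE,
    ResponseCategory.COMBINATION,
]

#: combined-sample size at and below which the Mann-Whitney p is exact
EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class UnitResult:
    """Per-unit analysis record feeding the cohort summary."""

    unit_id: str
    region: Region
    sort_quality: SortQuality
    category: ResponseCategory
    cell_class: Optional[CellClass] = None
    magnitude: Optional[float] = None
    latency_ms: Optional[float] = None
    suppression_ms: Optional[float] = None
    distance_mm: Optional[float] = None
    qc_passed: bool = True


@dataclass(frozen=True)
class CohortSummary:
    """Counts and row percentages by group, plus derived population stats.

    ``table`` rows are regions plus striatal cell classes (QC-passed
    single units only); columns are response categories. ``percentages``
    is row-normalized x100 at one decimal. ``magnitude_stats`` holds mean,
    SD and n of fold-changes among INCREASE units per region.
    """

    table: pd.DataFrame
    percentages: pd.DataFrame
    magnitude_stats: pd.DataFrame
    distance_hist: pd.Series


@dataclass(frozen=True)
class GroupComparison:
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    group_sizes: tuple[int, int]
    method: str  # "exact" or "asymptotic"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def row_percentages(counts: Sequence[int], decimals: int = 1) -> list[float]:
    """Row-normalized percentages of a count vector, rounded half-up."""
    total = sum(counts)
    if total <= 0:
        raise ValueError("row total must be positive")
    return [round_half_up(100.0 * c / total, decimals) for c in counts]


def proportion_from_counts(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage ``100 * numerator / denominator`` at the given precision.

    Before rounding, complementary proportions sum to exactly 100:
    ``p(a, b) + p(b - a, b) == 100``.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return round_half_up(100.0 * numerator / denominator, decimals)


_STRIATAL_CLASSES = [CellClass.PAN, CellClass.TAN, CellClass.FSN]


def tabulate(results: Sequence[UnitResult]) -> CohortSummary:
    """Aggregate per-unit results into the population contingency table.

    Region rows count every analyzed unit in that region; striatal class
    rows (PAN/TAN/FSN) count only QC-passed single units carrying that
    label. Row percentages sum to 100 up to rounding.

    Raises
    ------
    ValueError
        On duplicate unit ids.
    """
    ids = [r.unit_id for r in results]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate unit ids in results")

    cat_cols = [c.value for c in CATEGORIES]
    rows: dict[str, list[UnitResult]] = {}
    for region in (Region.PUTAMEN, Region.GPE, Region.VL, Region.OTHER):
        grp = [r for r in results if r.region is region]
        if grp:
            rows[region.value] = grp
    for cls in _STRIATAL_CLASSES:
        grp = [
            r
            for r in results
            if r.region is Region.PUTAMEN
            and r.cell_class is cls
            and r.qc_passed
            and r.sort_quality is SortQuality.SINGLE
        ]
        if grp:
            rows[cls.value] = grp

    table = pd.DataFrame(0, index=list(rows), columns=cat_cols, dtype=int)
    for name, grp in rows.items():
        for r in grp:
            table.loc[name, r.category.value] += 1

    pct = table.apply(
        lambda row: pd.Series(row_percentages(row.to_numpy()), index=cat_cols), axis=1
    )

    mag_rows = {}
    for region in (Region.PUTAMEN, Region.GPE, Region.VL):
        mags = [
            r.magnitude
            for r in results
            if r.region is region
            and r.category is ResponseCategory.INCREASE
            and r.magnitude is not None
        ]
        if mags:
            arr = np.asarray(mags, dtype=float)
            mag_rows[region.value] = {
                "mean": arr.mean(),
                "sd": arr.std(ddof=1) if arr.size > 1 else np.nan,
                "n": arr.size,
            }
    magnitude_stats = pd.DataFrame(mag_rows).T if mag_rows else pd.DataFrame(
        columns=["mean", "sd", "n"]
    )

    return CohortSummary(
        table=table,
        percentages=pct,
        magnitude_stats=magnitude_stats,
        distance_hist=responders_by_distance(results),
    )


def responders_by_distance(
    results: Sequence[UnitResult], bin_width: float = 1.0
) -> pd.Series:
    """Counts of responding units per ``[k*w, (k+1)*w)`` mm distance bin.

    Responders are units with any category other than NONE. Responders
    without a recorded distance are excluded with a warning.
    """
    responders = [r for r in results if r.category is not ResponseCategory.NONE]
    missing = sum(1 for r in responders if r.distance_mm is None)
    if missing:
        warnings.warn(
            f"excluding {missing} responding unit(s) without distance to injection",
            stacklevel=2,
        )
    dists = np.array([r.distance_mm for r in responders if r.distance_mm is not None])
    if dists.size == 0:
        return pd.Series(dtype=int, name="n_responders")
    n_bins = int(np.floor(dists.max() / bin_width)) + 1
    idx = np.floor(dists / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.Series(
        counts,
        index=pd.Index(np.arange(n_bins) * bin_width, name="distance_bin_mm"),
        name="n_responders",
    )


def _u_statistic(ranks: np.ndarray, na: int) -> float:
    """U of the first group from combined (tie-averaged) ranks."""
    return float(ranks[:na].sum() - na * (na + 1) / 2)


def compare_magnitudes(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupComparison:
    """Two-sided Mann-Whitney comparison of two fold-change samples.

    For combined n <= 20 the p-value is exact: all assignments of the
    pooled values to the two groups are enumerated and the two-sided p is
    the probability of a min(U_a, U_b) at least as extreme as observed
    (ties handled through midranks). Larger samples use the tie-corrected
    normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = _u_statistic(ranks, na)

    if na + nb <= EXACT_MW_MAX_N:
        u_min_obs = min(u_a, na * nb - u_a)
        total = 0
        extreme = 0
        rank_arr = ranks
        offset = na * (na + 1) / 2
        for combo in combinations(range(na + nb), na):
            u = rank_arr[list(combo)].sum() - offset
            u_min = min(u, na * nb - u)
            total += 1
            if u_min <= u_min_obs + 1e-9:
                extreme += 1
        p = extreme / total
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return GroupComparison(
        statistic=u_a, p_value=min(1.0, float(p)), group_sizes=(na, nb), method=method
    )
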