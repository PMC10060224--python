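"""Quantifications for the validation assays around a dropout screen.

These are the small, exactly defined computations that accompany screen
follow-up experiments: GFP competition-assay dropout (d0-normalized),
threshold fractions of per-cell foci counts, mitosis-outcome proportions
with Wilson intervals, ChIP dot-blot relative enrichment, caliper tumor
volume, and the two-sample t-tests used to compare experiment groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DropscreenError


def normalize_competition(
    series: pd.DataFrame,
    *,
    timepoint_col: str = "timepoint",
    value_col: str = "gfp_percent",
    group_cols: Optional[Sequence[str]] = None,
    d0_label: str = "d0",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize %GFP trajectories to their day-0 value.

    Input is tidy: one row per (group, timepoint) with the measured %GFP of
    guide-carrying cells.  Returns the normalized table (day 0 = 100%) and a
    per-group summary with ``fold_dropout = gfp_d0 / gfp_final`` (final =
    last timepoint in row order).  A final value of 0 yields an infinity
    sentinel with ``depleted_out=True``.
    """
    if timepoint_col not in series or value_col not in series:
        raise DropscreenError(
            f"competition table needs columns {timepoint_col!r}, {value_col!r}"
        )
    groups = list(group_cols) if group_cols else []
    normalized = series.copy()
    summary_rows = []
    grouped = (
        normalized.groupby(groups, sort=False)
        if groups
        else [((), normalized)]
    )
    norm_col = f"{value_col}_normalized"
    for key, grp in grouped:
        d0_rows = grp[grp[timepoint_col] == d0_label]
        if d0_rows.empty:
            raise DropscreenError(f"group {key!r}: missing {d0_label!r} timepoint")
        d0 = float(d0_rows[value_col].iloc[0])
        if d0 <= 0:
            raise DropscreenError(f"group {key!r}: {d0_label} value must be > 0")
        normalized.loc[grp.index, norm_col] = 100.0 * grp[value_col] / d0
        final = float(grp[value_col].iloc[-1])
        depleted_out = final == 0
        fold = math.inf if depleted_out else d0 / final
        row = dict(zip(groups, key if isinstance(key, tuple) else (key,)))
        row.update(
            {"gfp_d0": d0, "gfp_final": final, "fold_dropout": fold,
             "depleted_out": depleted_out}
        )
        summary_rows.append(row)
    return normalized, pd.DataFrame(summary_rows)


def foci_fraction(counts: Sequence[int], k: int) -> float:
    """Percentage of cells with at least ``k`` foci."""
    arr = np.asarray(counts)
    if arr.size == 0:
        raise DropscreenError("no cells supplied")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise DropscreenError("foci counts must be non-negative integers")
    return 100.0 * float((arr >= k).mean())


@dataclass(frozen=True)
class OutcomeProportion:
    """A reported event proportion with its 95% Wilson interval."""

    n_event: int
    n_total: int
    percent: float  # unrounded
    percent_rounded: int  # the reporting style used in figure text
    ci_low: float  # 95% Wilson bounds, on the percent scale
    ci_high: float


def outcome_proportion(n_event: int, n_total: int) -> OutcomeProportion:
    """Proportion of cells with an outcome, e.g. normal vs aberrant mitosis."""
    if n_total < 1:
        raise DropscreenError("n_total must be >= 1")
    if not 0 <= n_event <= n_total:
        raise DropscreenError("n_event must lie in [0, n_total]")
    pct = 100.0 * n_event / n_total
    lo, hi = proportion_confint(n_event, n_total, alpha=0.05, method="wilson")
    return OutcomeProportion(
        n_event=n_event,
        n_total=n_total,
        percent=pct,
        percent_rounded=int(round(pct)),
        ci_low=100.0 * float(lo),
        ci_high=100.0 * float(hi),
    )


def chip_relative_enrichment(
    chip_signal,
    input_signal,
    reference_pair: Optional[tuple[float, float]] = None,
):
    """Input-normalized ChIP signal relative to a reference sample.

    ``ratio = (chip/input) / (chip_ref/input_ref)``.  Without an explicit
    reference the first sample serves as its own reference (enrichment 1).
    """
    chip = np.asarray(chip_signal, dtype=float)
    inp = np.asarray(input_signal, dtype=float)
    if np.any(inp <= 0):
        raise DropscreenError("input signals must be > 0")
    enrich = chip / inp
    if reference_pair is None:
        ref = enrich.flat[0] if enrich.ndim else float(enrich)
    else:
        chip_ref, input_ref = reference_pair
        if input_ref <= 0:
            raise DropscreenError("reference input signal must be > 0")
        ref = chip_ref / input_ref
    if ref <= 0:
        raise DropscreenError("reference enrichment must be > 0")
    out = enrich / ref
    return float(out) if out.ndim == 0 else out


def tumor_volume(length_mm: float, width_mm: float, height_mm: float) -> float:
    """Caliper tumor volume, the ellipsoid formula
    ``V = (4*pi/3) * (a/2) * (b/2) * (c/2) = (pi/6) * a * b * c`` in mm^3."""
    dims = (length_mm, width_mm, height_mm)
    if any(d < 0 for d in dims):
        raise DropscreenError("tumor dimensions must be >= 0")
    return math.pi / 6.0 * length_mm * width_mm * height_mm


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    paired: bool
    exact_difference: bool = False  # zero-variance paired difference


def two_sample_ttest(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> TTestResult:
    """Two-tailed two-sample t-test.

    Unpaired default is the pooled-variance Student test; Welch is available
    behind a flag.  A paired comparison with a constant nonzero difference
    (zero variance of differences) is flagged ``exact_difference`` with
    ``p = 0`` rather than raising.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise DropscreenError("each group needs at least 2 values")
    if paired:
        if xa.size != ya.size:
            raise DropscreenError("paired test requires equal-length groups")
        diff = xa - ya
        if np.ptp(diff) == 0:
            if diff[0] == 0:
                return TTestResult(0.0, float(xa.size - 1), 1.0, True)
            t = math.inf if diff[0] > 0 else -math.inf
            return TTestResult(t, float(xa.size - 1), 0.0, True,
                               exact_difference=True)
        res = stats.ttest_rel(xa, ya)
        return TTestResult(float(res.statistic), float(res.df),
                           float(res.pvalue), True)
    res = stats.ttest_ind(xa, ya, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.df),
                       float(res.pvalue), False)
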