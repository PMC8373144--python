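"""Recombination-efficacy quantification and its statistics.

Editing efficacy is read out three ways in the emulated experiment: GFP+
cell percentages from flow cytometry (the recombination reporter
reconstitutes GFP), per-lane band percentages from Southern blots (parental
/ DSB / recombinant molecules), and the relation between the two — GFP+
percentage regressed on the DSB signal accumulated over the induction
time course.  A one-way ANOVA asks whether guide-RNA folding energy bins
explain efficacy differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class LaneQuant:
    """Background-subtracted per-species percentages of one gel lane."""

    percentages: dict[str, float]

    def __getitem__(self, species: str) -> float:
        return self.percentages[species]


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def lane_percentages(signals: Mapping[str, float], background: float = 0.0) -> LaneQuant:
    """Percent of lane signal per molecular species after background
    subtraction: 100 * (band - background) / sum(bands - background).

    Negative background-corrected bands are clipped to 0 with a warning.
    Scale-invariant: multiplying all signals and the background by any
    positive constant leaves every percentage unchanged.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    corrected = {}
    for name, sig in signals.items():
        v = sig - background
        if v < 0:
            warnings.warn(f"band {name!r} below background; clipped to 0")
            v = 0.0
        corrected[name] = v
    total = sum(corrected.values())
    if total <= 0:
        raise ValueError("no signal above background in the lane")
    return LaneQuant({k: 100.0 * v / total for k, v in corrected.items()})


def gate_gfp(
    events: pd.DataFrame,
    fluorescence_column: str = "log10_fluorescence",
    fixed_threshold: float = 3.0,
    min_events: int = 500,
) -> tuple[float, float]:
    """GFP-positive percentage by density-valley gating.

    A kernel-density estimate of log10 fluorescence is evaluated on a grid;
    when two modes are present the gate is placed at the density minimum
    between the two highest modes, otherwise at ``fixed_threshold``.
    Returns ``(gfp_positive_percent, threshold_used)``.
    """
    if len(events) == 0:
        raise ValueError("empty event table")
    if len(events) < min_events:
        raise ValueError(f"need >= {min_events} events, got {len(events)}")
    x = np.asarray(events[fluorescence_column], dtype=float)
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min() - 0.5, x.max() + 0.5, 512)
    dens = kde(grid)
    # candidate modes must be substantial, not tail blips of the KDE
    maxima = [
        i for i in range(1, len(grid) - 1)
        if dens[i] >= dens[i - 1] and dens[i] > dens[i + 1]
        and dens[i] >= 0.10 * dens.max()
    ]
    threshold = fixed_threshold
    if len(maxima) >= 2:
        top_two = sorted(sorted(maxima, key=lambda i: dens[i], reverse=True)[:2])
        lo, hi = top_two
        valley = lo + int(np.argmin(dens[lo : hi + 1]))
        # require a genuine valley (bimodal), not a shoulder
        if dens[valley] < 0.8 * min(dens[lo], dens[hi]):
            threshold = float(grid[valley])
    pct = 100.0 * float(np.mean(x > threshold))
    return pct, threshold


def cumulative_dsb(
    dsb_percent_series: Sequence[float],
    times: Sequence[float] | None = None,
    mode: str = "sum",
) -> float:
    """Total DSB signal accumulated over an induction time course.

    Default is the plain sum of per-timepoint DSB percentages; a
    trapezoidal time-integral (per hour) is available for sensitivity
    analysis when ``times`` are given.
    """
    vals = np.asarray(dsb_percent_series, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two timepoints")
    if mode == "sum":
        return float(vals.sum())
    if mode == "trapezoid":
        if times is None:
            raise ValueError("trapezoid mode requires timepoints")
        return float(np.trapezoid(vals, np.asarray(times, dtype=float)))
    raise ValueError(f"unknown mode {mode!r}")


def regress_efficacy(
    cumulative_dsb_values: Sequence[float], gfp_percent_values: Sequence[float]
) -> RegressionSummary:
    """Ordinary least squares of GFP+ percentage on cumulative DSB, with R²
    and the two-sided p-value for the slope."""
    x = np.asarray(cumulative_dsb_values, dtype=float)
    y = np.asarray(gfp_percent_values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=len(x),
    )


def anova_energy(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA of efficacy values across energy groups.

    Returns (F, p).  All-identical constant groups give F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = []
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
        arrays.append(arr)
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    if np.isnan(f):  # zero within-group variance and zero between: no effect
        return 0.0, 1.0
    return float(f), float(p)


def bin_energy_tertiles(delta_g: Mapping[str, float | None]) -> dict[str, list[str]]:
    """Group guide ids by folding-energy tertile; unstructured guides
    (ΔG None) form their own 'unstructured' group.  Used as the default
    grouping for :func:`anova_energy` when the predictor is continuous."""
    structured = {k: v for k, v in delta_g.items() if v is not None}
    groups: dict[str, list[str]] = {"unstructured": [k for k, v in delta_g.items() if v is None]}
    if structured:
        vals = np.array(list(structured.values()))
        q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
        groups["stable_tertile"] = [k for k, v in structured.items() if v <= q1]
        groups["mid_tertile"] = [k for k, v in structured.items() if q1 < v <= q2]
        groups["weak_tertile"] = [k for k, v in structured.items() if v > q2]
    return {k: v for k, v in groups.items() if v}
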