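"""Mode tracking of pollen phase distributions during pre-hydration.

Partially dehydrated pollen reorganises its membranes while held in
saturated air; in impedance terms the dead-population phase mode slides
from 192° down to 188° over roughly 5.5 h while the viable mode stabilises
at 198°, so the dead–viable phase separation Δ grows with hydration time
and viability is best measured once Δ has plateaued.

This module estimates per-time-step kernel-density global modes of the
dead and viable phase distributions, the separation Δ = |mode_viable −
mode_dead|, and the regression of viability change on separation change
across the course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gating import GateSet, assign_events, population_stats, viability_percent
from .impedance import RegressionFit, fit_linear

__all__ = [
    "KernelDensityEstimate",
    "kde",
    "global_mode",
    "analyze_hydration",
    "viability_separation_regression",
    "best_hydration_time",
]

logger = logging.getLogger(__name__)

SERIES_COLUMNS = [
    "time_min",
    "viability_pct",
    "mode_viable_deg",
    "mode_dead_deg",
    "separation_deg",
    "dead_amp_mean",
]


@dataclass(frozen=True)
class KernelDensityEstimate:
    """Gaussian-kernel density on a regular phase grid (degrees)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


def kde(values, bandwidth: float | None = None, grid_step: float = 0.05) -> KernelDensityEstimate:
    """Gaussian kernel density estimate of a phase sample.

    Bandwidth defaults to Silverman's rule; the evaluation grid covers the
    data range ± 5 bandwidths at ``grid_step`` (≤ 0.05°) resolution, wide
    enough that the trapezoidal integral of the density is 1 to ~1e−6.
    Requires at least 30 values (the global mode is unstable below that).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 30:
        raise ValueError(f"need at least 30 values for a stable mode, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        # degenerate sample: all values equal; KDE is a spike at that value
        sd = max(abs(x[0]) * 1e-9, 1e-9)
    if bandwidth is None:
        est = stats.gaussian_kde(x, bw_method="silverman")
        bandwidth = float(est.factor * x.std(ddof=0))
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        est = stats.gaussian_kde(x, bw_method=bandwidth / x.std(ddof=0))
    step = min(grid_step, 0.05)
    lo = x.min() - 5.0 * bandwidth
    hi = x.max() + 5.0 * bandwidth
    grid = np.arange(lo, hi + step, step)
    density = est(grid)
    return KernelDensityEstimate(grid=grid, density=density, bandwidth=float(bandwidth))


def global_mode(estimate: KernelDensityEstimate) -> float:
    """Phase of the global density maximum (ties → lowest phase)."""
    # argmax returns the first maximum; the grid is ascending, so exact ties
    # resolve to the lowest phase.
    return float(estimate.grid[int(np.argmax(estimate.density))])


def analyze_hydration(
    tables: pd.DataFrame,
    gateset: GateSet,
    bandwidth: float | None = None,
) -> pd.DataFrame:
    """Quantify a hydration course with one fixed gate set.

    ``tables`` is an event table covering several ``time_min`` steps (as
    produced by the hydration generator).  Per step the events are gated,
    sterile-excluded viability is computed, and KDE global modes of the
    dead and viable phase distributions give the separation
    Δ = |mode_viable − mode_dead|.  Steps where either population is empty
    (or too small for a stable mode) get NaN modes and are logged.

    Returns a tidy frame with columns ``time_min, viability_pct,
    mode_viable_deg, mode_dead_deg, separation_deg, dead_amp_mean,
    bandwidth_deg``.
    """
    if "time_min" not in tables.columns:
        raise ValueError("event table lacks a time_min column")
    pcol = f"phase{int(round(gateset.channel_mhz))}_deg"
    acol = f"amp{int(round(gateset.channel_mhz))}"
    rows = []
    for t, step in tables.groupby("time_min", sort=True):
        labels = assign_events(step, gateset)
        st = population_stats(step, labels)
        viab = viability_percent(st, exclude_sterile=True)
        modes = {}
        bws = []
        for cls in ("viable", "dead"):
            phases = step.loc[labels == cls, pcol].to_numpy(dtype=float)
            if phases.size < 30:
                logger.warning(
                    "time %s: %s population too small (%d events); mode undefined",
                    t, cls, phases.size,
                )
                modes[cls] = np.nan
            else:
                est = kde(phases, bandwidth=bandwidth)
                modes[cls] = global_mode(est)
                bws.append(est.bandwidth)
        dead_amp = step.loc[labels == "dead", acol]
        rows.append(
            {
                "time_min": float(t),
                "viability_pct": viab,
                "mode_viable_deg": modes["viable"],
                "mode_dead_deg": modes["dead"],
                "separation_deg": abs(modes["viable"] - modes["dead"]),
                "dead_amp_mean": float(dead_amp.mean()) if len(dead_amp) else np.nan,
                "bandwidth_deg": float(np.mean(bws)) if bws else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("time_min", ignore_index=True)


def viability_separation_regression(
    series: pd.DataFrame, differenced: bool = True
) -> RegressionFit:
    """Regress viability on dead–viable phase separation across the course.

    With ``differenced`` (the default) the fit is of per-step changes in
    viability on per-step changes in |Δ|; otherwise levels on levels.
    Steps with undefined Δ are dropped (their count is logged).
    """
    ok = series.dropna(subset=["viability_pct", "separation_deg"])
    dropped = len(series) - len(ok)
    if dropped:
        logger.warning("dropping %d steps with undefined separation", dropped)
    if len(ok) < 4:
        raise ValueError(f"need at least 4 defined steps, got {len(ok)}")
    viab = ok["viability_pct"].to_numpy(dtype=float)
    sep = np.abs(ok["separation_deg"].to_numpy(dtype=float))
    if differenced:
        return fit_linear(np.diff(sep), np.diff(viab))
    return fit_linear(sep, viab)


def best_hydration_time(series: pd.DataFrame) -> float:
    """Earliest time at which viability is within one standard error of max.

    The standard error of a single step's viability is estimated from the
    short-scale noise of the series itself (median absolute successive
    difference / √2); on a flat series this is ~0 and the first step wins,
    on a strictly rising one the last step does.
    """
    if len(series) == 0:
        raise ValueError("empty hydration series")
    ok = series.dropna(subset=["viability_pct"]).sort_values("time_min")
    viab = ok["viability_pct"].to_numpy(dtype=float)
    times = ok["time_min"].to_numpy(dtype=float)
    if viab.size == 1:
        return float(times[0])
    diffs = np.abs(np.diff(viab))
    se = float(np.median(diffs)) / np.sqrt(2.0) if diffs.size else 0.0
    target = viab.max() - se
    idx = int(np.argmax(viab >= target))
    return float(times[idx])
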