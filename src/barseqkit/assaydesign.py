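"""Bioassay arithmetic for designing pooled fitness screens.

Growth-curve metrics (generations grown, doubling time), dose-response
inhibition and IC interpolation, sequencing read-budget coverage, and
serial-transfer planning.  A screen's drug dose is typically chosen at
the IC20 — the concentration inhibiting pool growth by 20% relative to
the solvent control after a stated number of generations — and
long-exposure assays reach their total generations through serial
transfers into fresh medium every ~5 generations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 readings over time (hours), strictly increasing times."""

    times: tuple[float, ...]
    od: tuple[float, ...]
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.size != y.size:
            raise ValueError("times and od must have equal length")
        if t.size < 3:
            raise ValueError("growth curve needs at least 3 points")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        if not (y > 0).all():
            raise ValueError("OD readings must be positive")


@dataclass(frozen=True)
class DoseResponse:
    """Percent inhibition over non-negative, increasing doses (µM).

    Small negative inhibition values (down to -10%) are tolerated as
    measurement noise; dose 0 must be present as the control anchor.
    """

    doses: tuple[float, ...]
    inhibition: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        y = np.asarray(self.inhibition, dtype=float)
        if d.size != y.size:
            raise ValueError("doses and inhibition must have equal length")
        if (d < 0).any() or not (np.diff(d) > 0).all():
            raise ValueError("doses must be non-negative and increasing")
        if d[0] != 0:
            raise ValueError("dose 0 (control anchor) must be present")
        if (y < -10).any() or (y > 100).any():
            raise ValueError("inhibition must lie in [-10, 100] percent")


def generations_grown(od_start: float, od_end: float) -> float:
    """Population doublings between two OD600 readings: log2(end/start)."""
    if od_start <= 0 or od_end <= 0:
        raise ValueError("OD readings must be positive")
    if od_end < od_start:
        raise ValueError("od_end must be >= od_start")
    return math.log2(od_end / od_start)


def doubling_time(curve: GrowthCurve, window: tuple[float, float] | None = None):
    """Doubling time from the log-linear growth phase.

    Least-squares slope of log2(OD) against time within the window;
    doubling time is 1/slope in the curve's time units.  Returns None
    when the fitted slope is not positive (no growth).
    """
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.od, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    if t.size < 3:
        raise ValueError("need at least 3 points in the window")
    slope = stats.linregress(t, np.log2(y)).slope
    if slope <= 0:
        return None
    return 1.0 / slope


def _time_at_generations(curve: GrowthCurve, gens: float) -> float:
    """Time when the curve has grown by ``gens`` doublings (interpolated)."""
    t = np.asarray(curve.times, dtype=float)
    g = np.log2(np.asarray(curve.od, dtype=float) / curve.od[0])
    if gens < g.min() - 1e-12 or gens > g.max() + 1e-12:
        raise ValueError(
            f"curve {curve.condition!r} never reaches {gens} generations"
        )
    return float(np.interp(gens, g, t))


def _od_at_time(curve: GrowthCurve, time: float) -> float:
    t = np.asarray(curve.times, dtype=float)
    if time < t[0] - 1e-12 or time > t[-1] + 1e-12:
        raise ValueError(f"time {time} outside curve {curve.condition!r} span")
    return float(np.interp(time, t, np.asarray(curve.od, dtype=float)))


def percent_inhibition(
    treated: GrowthCurve, control: GrowthCurve, at_generations: float = 5.0
) -> float:
    """Growth inhibition of the treated culture, in percent.

    Evaluated at the time the CONTROL has grown by ``at_generations``
    doublings (linear interpolation between readings): anchoring to
    control generations rather than wall-clock matches how IC values
    are defined.
    """
    t_eval = _time_at_generations(control, at_generations)
    od_t = _od_at_time(treated, t_eval)
    od_c = _od_at_time(control, t_eval)
    return 100.0 * (1.0 - od_t / od_c)


def ic_interpolate(dr: DoseResponse, target_inhibition: float = 20.0) -> float:
    """Dose at which inhibition first reaches the target, by piecewise
    log-linear interpolation.

    The dose axis is logarithmic; the zero-dose control anchor is placed
    at half the smallest nonzero dose for the log axis.  The first
    crossing from below is returned; an exactly-observed target returns
    that dose.  Raises when the target is not bracketed by the data.
    """
    d = np.asarray(dr.doses, dtype=float)
    y = np.asarray(dr.inhibition, dtype=float)
    if not ((y >= target_inhibition).any() and (y <= target_inhibition).any()):
        raise ValueError(
            f"target {target_inhibition}% not bracketed: observed inhibition "
            f"spans [{y.min():.3g}, {y.max():.3g}]%"
        )
    nonzero = d[d > 0]
    if nonzero.size == 0:
        raise ValueError("dose-response needs at least one nonzero dose")
    x = np.where(d > 0, d, nonzero.min() / 2.0)
    logx = np.log(x)
    for i in range(len(d)):
        if y[i] == target_inhibition:
            return float(d[i])
        if i + 1 < len(d) and y[i] < target_inhibition <= y[i + 1]:
            frac = (target_inhibition - y[i]) / (y[i + 1] - y[i])
            return float(np.exp(logx[i] + frac * (logx[i + 1] - logx[i])))
    raise ValueError(
        f"no upward crossing of {target_inhibition}% found in dose-response"
    )


def reads_per_tag(total_reads: int, n_strains: int, tags_per_strain: int = 2) -> float:
    """Expected sequencing reads per strain per tag.

    A 5-6 million read budget over a ~5,500-strain pool with two tags
    per strain yields ~500 reads per strain per tag.
    """
    if total_reads <= 0 or n_strains <= 0 or tags_per_strain <= 0:
        raise ValueError("all arguments must be positive")
    return total_reads / (n_strains * tags_per_strain)


def transfers_needed(total_generations: float, generations_per_cycle: float) -> int:
    """Serial transfers to reach a total generation count.

    The initial growth cycle is not a transfer: 20 generations at 5 per
    cycle needs 3 transfers; a single 5-generation cycle needs none.
    """
    if total_generations <= 0 or generations_per_cycle <= 0:
        raise ValueError("generation counts must be positive")
    if total_generations < generations_per_cycle:
        raise ValueError("total must be at least one cycle")
    return math.ceil(total_generations / generations_per_cycle) - 1
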