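"""Arrival times of free tracer along the stem and the transport velocity.

Once the trapped component has been subtracted, the free curve G(t) at each
stem position records the bolus passing that position.  Its mean arrival time

    T = int t G(t) dt / int G(t) dt

is computed with the integrals truncated at an upper bound UB placed at the
half-height of G's trailing edge: the first temporal moment of roughly the
first 50-70% of the free tracer, which suppresses the confounding late-time
effects of bidirectional movement and reversible trapping.  A simpler
alternative takes the arrival time at the half-height of the leading edge.

Plotting position against arrival time for all ROIs and fitting a line
(ordinary least squares, position regressed on time) gives the transport
velocity V (mm/s) as the slope; the trapping probability per unit length is
then s = sv / V (1/mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateFitError, UnfittableCurveError
from .kinetic_model import KineticFit
from .tac_data import TimeActivityCurve

__all__ = [
    "ArrivalEstimate",
    "PlantResult",
    "half_height_upper_bound",
    "mean_arrival_time",
    "half_height_arrival_time",
    "fit_velocity",
    "trapping_per_length",
    "convert_units",
]

#: Fraction of the free-curve maximum at which the truncation bound and the
#: leading-edge arrival time are placed.  "Half-height" = 0.5.
DEFAULT_HEIGHT_FRACTION = 0.5

METHOD_MEAN_ARRIVAL = "mean_arrival"
METHOD_HALF_HEIGHT = "half_height_leading_edge"


@dataclass(frozen=True)
class ArrivalEstimate:
    """Arrival time of the free tracer at one stem position."""

    roi_label: str
    position_mm: float
    arrival_time_s: float
    upper_bound_s: float = float("nan")
    method: str = METHOD_MEAN_ARRIVAL


@dataclass(frozen=True)
class PlantResult:
    """Per-plant transport estimates.

    ``sv_mean``/``sv_sd`` are the unweighted mean and sample (n-1) s.d. of
    the per-ROI trapping rates; ``velocity_mm_s`` is the slope of the
    position-vs-arrival-time line; ``s_per_mm = sv_mean / velocity_mm_s``.
    """

    plant_id: str
    n_rois: int
    sv_mean: float
    sv_sd: float
    velocity_mm_s: float
    intercept_mm: float
    r_squared: float
    s_per_mm: float
    arrival_method: str = METHOD_MEAN_ARRIVAL
    arrival_estimates: tuple[ArrivalEstimate, ...] = ()
    fits: tuple[KineticFit, ...] = ()
    skipped_rois: tuple[str, ...] = ()


def _as_times_values(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, TimeActivityCurve):
        return curve.mid_time, curve.values
    times, values = curve
    return np.asarray(times, dtype=float), np.asarray(values, dtype=float)


def _check_positive_max(g: np.ndarray) -> float:
    gmax = float(np.max(g))
    if gmax <= 0:
        raise UnfittableCurveError("free curve has no positive maximum")
    return gmax


def half_height_upper_bound(
    curve, height_fraction: float = DEFAULT_HEIGHT_FRACTION
) -> float:
    """Trailing-edge truncation bound for the mean-arrival-time integrals.

    Returns the first time after the free curve's peak at which it crosses
    down through ``height_fraction * max(G)``, linearly interpolated between
    the bracketing frame mid-times.  If the curve never falls below that
    level, the last mid-time is returned.
    """
    times, g = _as_times_values(curve)
    gmax = _check_positive_max(g)
    level = height_fraction * gmax
    peak = int(np.argmax(g))
    for k in range(peak + 1, g.size):
        if g[k] < level <= g[k - 1]:
            frac = (g[k - 1] - level) / (g[k - 1] - g[k])
            return float(times[k - 1] + frac * (times[k] - times[k - 1]))
    return float(times[-1])


def mean_arrival_time(curve, upper_bound_s: float) -> float:
    """First temporal moment of the free curve, truncated at ``upper_bound_s``.

    Both integrals run from t = 0 (the curve is extended with a zero at the
    origin when its first mid-time is positive) to the upper bound, by the
    trapezoidal rule on the frame mid-times; the final partial interval is
    split at the bound by linear interpolation.  An infinite bound uses the
    whole curve.
    """
    times, g = _as_times_values(curve)
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        g = np.concatenate([[0.0], g])
    if np.isfinite(upper_bound_s) and upper_bound_s < times[-1]:
        keep = times < upper_bound_s
        g_ub = float(np.interp(upper_bound_s, times, g))
        times = np.concatenate([times[keep], [upper_bound_s]])
        g = np.concatenate([g[keep], [g_ub]])
    denom = float(np.trapezoid(g, times))
    if denom <= 0:
        raise UnfittableCurveError(
            "free curve integral is non-positive below the upper bound"
        )
    return float(np.trapezoid(times * g, times)) / denom


def half_height_arrival_time(
    curve, height_fraction: float = DEFAULT_HEIGHT_FRACTION
) -> float:
    """Leading-edge arrival time: first upward crossing of half the maximum.

    A simpler bolus-tracking statistic than the mean arrival time, using
    only the rising edge of the free curve.
    """
    times, g = _as_times_values(curve)
    gmax = _check_positive_max(g)
    level = height_fraction * gmax
    if g[0] >= level:
        return float(times[0])
    for k in range(1, g.size):
        if g[k] >= level > g[k - 1]:
            frac = (level - g[k - 1]) / (g[k] - g[k - 1])
            return float(times[k - 1] + frac * (times[k] - times[k - 1]))
    raise UnfittableCurveError("free curve never reaches the half-height level")


def fit_velocity(estimates: list[ArrivalEstimate]) -> tuple[float, float, float]:
    """OLS fit of stem position (mm) on arrival time (s).

    Returns ``(velocity_mm_s, intercept_mm, r_squared)``; the slope carries
    mm/s directly.  Requires >= 2 estimates with distinct arrival times.
    """
    if len(estimates) < 2:
        raise DegenerateFitError("velocity fit needs at least 2 arrival estimates")
    t = np.array([e.arrival_time_s for e in estimates], dtype=float)
    x = np.array([e.position_mm for e in estimates], dtype=float)
    if np.ptp(t) == 0:
        raise DegenerateFitError("all arrival times identical; velocity undefined")
    res = stats.linregress(t, x)
    r2 = float(res.rvalue) ** 2 if np.isfinite(res.rvalue) else 1.0
    return float(res.slope), float(res.intercept), r2


def trapping_per_length(sv_mean: float, velocity_mm_s: float) -> float:
    """Trapping probability per unit stem length, s = sv / V (1/mm)."""
    if velocity_mm_s <= 0:
        raise ValueError(
            "velocity must be positive (non-positive V signals failed or "
            "reversed transport)"
        )
    return sv_mean / velocity_mm_s


# Exact scale factors between the SI-ish working units (s, mm) and the
# reporting units (min, cm) used in summaries.
_UNIT_FACTORS = {
    ("1/s", "1/min"): 60.0,
    ("mm/s", "cm/min"): 6.0,
    ("1/mm", "1/cm"): 10.0,
    ("fraction", "percent"): 100.0,
}


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between supported unit pairs (exact scale factors).

    Supported: 1/s <-> 1/min, mm/s <-> cm/min, 1/mm <-> 1/cm,
    fraction <-> percent.
    """
    if (from_unit, to_unit) in _UNIT_FACTORS:
        return value * _UNIT_FACTORS[(from_unit, to_unit)]
    if (to_unit, from_unit) in _UNIT_FACTORS:
        return value / _UNIT_FACTORS[(to_unit, from_unit)]
    raise ValueError(f"unsupported unit conversion {from_unit!r} -> {to_unit!r}")
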