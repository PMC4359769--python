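"""Forward simulator of petiolar-bolus radiotracer transport in a stem.

A finite bolus of tracer is fed at the stem base (x = 0) over a few minutes
and advected upward at constant velocity ``v`` (mm/s); while moving, tracer
is irreversibly trapped with probability ``s`` (1/mm) per unit length and
stays where it was trapped.  The free concentration at height ``x`` is then

    G(x, t) = A * exp(-s x) * h(t - x/v),

where ``h`` is the administration profile — a rectangle of the feeding
duration smoothed by a Gaussian of s.d. ``dispersion_sigma_s`` (drop-by-drop
absorption is not instantaneous) — and ``exp(-s x)`` is the survival of free
tracer past ``x``.  The trapped concentration accumulates as

    B(x, t) = s v * int_0^t G(x, t') dt',

so the trapping rate per unit time the kinetic fitter should recover at any
position is exactly ``sv = s * v``, and arrival times are linear in ``x``
with slope ``1/v``.

The observation step averages M = G + B over each PET frame, attributes the
average to the frame mid-time, and adds per-frame Gaussian noise with s.d.
equal to ``noise_cv`` times the curve maximum (the standard proportional
approximation for reconstructed, corrected PET concentrations; raw-count
Poisson statistics are not modeled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import special

from .tac_data import FrameSchedule, PlantManifest, TimeActivityCurve, standard_frame_schedule

__all__ = [
    "SimTruth",
    "SimPlant",
    "free_curve_at_position",
    "trapped_curve_at_position",
    "observe_plant",
    "make_paper_like_cohort",
]

#: Dense quadrature step (s) used for trapped-curve integrals and frame averages.
DENSE_DT_S = 1.0

#: Default temporal spread of the administered bolus at x = 0 (s); drop
#: absorption smooths the nominal rectangle on roughly this scale.
DEFAULT_SIGMA0_S = 30.0

#: Default free-tracer amplitude at x = 0 in normalized units (1/mm): a
#: bolus of ~100 mm spatial extent carrying the administered activity.
DEFAULT_AMPLITUDE_PER_MM = 0.01

# Ranges spanned by the reference cohort, used by make_paper_like_cohort:
# per-plant velocity (mm/s), trapping per length (1/mm), administration
# duration (s), administered activity (Bq) and ROI count.
VELOCITY_RANGE_MM_S = (0.214, 0.566)
TRAPPING_RANGE_PER_MM = (0.00034, 0.00131)
ADMIN_DURATION_RANGE_S = (180.0, 300.0)
ACTIVITY_RANGE_BQ = (3.2e6, 1.0e7)
N_ROI_RANGE = (5, 8)
ROI_SPACING_MM = 5.0
FIRST_ROI_MM = 5.0


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters of one synthetic plant."""

    velocity_mm_s: float
    s_per_mm: float
    admin_duration_s: float
    roi_positions_mm: tuple[float, ...]
    admin_amplitude_per_mm: float = DEFAULT_AMPLITUDE_PER_MM
    dispersion_sigma_s: float = DEFAULT_SIGMA0_S
    noise_cv: float = 0.0
    rng_seed: int = 0
    plant_id: str = "sim"

    def __post_init__(self) -> None:
        if self.velocity_mm_s <= 0:
            raise ValueError("velocity must be positive")
        if self.s_per_mm < 0:
            raise ValueError("trapping per length must be non-negative")
        if self.admin_duration_s <= 0:
            raise ValueError("administration duration must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        pos = np.asarray(self.roi_positions_mm, dtype=float)
        if pos.size == 0 or np.any(pos < 0) or np.any(np.diff(pos) <= 0):
            raise ValueError("ROI positions must be >= 0 and strictly increasing")

    @property
    def sv_per_s(self) -> float:
        """Trapping probability per unit time implied by (s, v)."""
        return self.s_per_mm * self.velocity_mm_s


class SimPlant(NamedTuple):
    """One simulated plant: ground truth, manifest, and observed curves."""

    truth: SimTruth
    manifest: PlantManifest
    curves: list[TimeActivityCurve]


def _input_profile(truth: SimTruth, tau: np.ndarray) -> np.ndarray:
    """Unit-height rectangle of the feeding duration, Gaussian-smoothed.

    The rectangle is delayed by four smoothing s.d.s so the smoothed profile
    is causal (no tracer before administration starts); the residual
    non-causal tail (< 1e-4 of peak) is clipped to zero.
    """
    sig = truth.dispersion_sigma_s * np.sqrt(2.0)
    t0 = 4.0 * truth.dispersion_sigma_s
    h = 0.5 * (
        special.erf((tau - t0) / sig)
        - special.erf((tau - t0 - truth.admin_duration_s) / sig)
    )
    return np.where(tau >= 0.0, h, 0.0)


def free_curve_at_position(truth: SimTruth, x_mm: float, times_s) -> np.ndarray:
    """Free concentration G(x, t) at stem height ``x_mm`` (normalized 1/mm)."""
    if x_mm < 0:
        raise ValueError("stem position must be non-negative")
    t = np.asarray(times_s, dtype=float)
    survival = np.exp(-truth.s_per_mm * x_mm)
    return truth.admin_amplitude_per_mm * survival * _input_profile(
        truth, t - x_mm / truth.velocity_mm_s
    )


def trapped_curve_at_position(truth: SimTruth, x_mm: float, times_s) -> np.ndarray:
    """Trapped concentration B(x, t) = s v * cumulative integral of G."""
    t = np.asarray(times_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    t_max = float(np.max(t)) if t.size else 0.0
    dense = np.arange(0.0, t_max + DENSE_DT_S, DENSE_DT_S)
    g = free_curve_at_position(truth, x_mm, dense)
    cum = np.concatenate([[0.0], np.cumsum((g[1:] + g[:-1]) / 2.0 * np.diff(dense))])
    return truth.sv_per_s * np.interp(t, dense, cum)


def _frame_average(dense_t: np.ndarray, dense_m: np.ndarray, schedule: FrameSchedule,
                   admin_offset_s: float) -> np.ndarray:
    """Average dense M(t_admin) over each scanner-time frame (M = 0 pre-admin)."""
    cum = np.concatenate(
        [[0.0], np.cumsum((dense_m[1:] + dense_m[:-1]) / 2.0 * np.diff(dense_t))]
    )
    a = np.clip(schedule.start - admin_offset_s, 0.0, None)
    b = np.clip(schedule.end - admin_offset_s, 0.0, None)
    integ = np.interp(b, dense_t, cum) - np.interp(a, dense_t, cum)
    return integ / schedule.duration


def observe_plant(
    truth: SimTruth,
    schedule: FrameSchedule | None = None,
    admin_offset_s: float = 60.0,
    administered_activity_bq: float = 7.2e6,
    age_days: float | None = None,
) -> SimPlant:
    """Observe a synthetic plant through a PET frame schedule.

    The returned curves are on the *scanner* time axis (administration starts
    ``admin_offset_s`` into the scan), mirroring what the scanner exports;
    the analysis pipeline is expected to rebase them.  Noise is reproducible
    from ``truth.rng_seed``.
    """
    schedule = schedule or standard_frame_schedule()
    span = schedule.span_s - admin_offset_s
    dense = np.arange(0.0, span + DENSE_DT_S, DENSE_DT_S)
    rng = np.random.default_rng(truth.rng_seed)
    curves = []
    for i, x in enumerate(truth.roi_positions_mm):
        m = free_curve_at_position(truth, x, dense) + trapped_curve_at_position(
            truth, x, dense
        )
        values = _frame_average(dense, m, schedule, admin_offset_s)
        if truth.noise_cv > 0:
            # sd proportional to the local signal (CV = noise_cv per frame,
            # so s.d. = noise_cv * max(M) at the curve maximum)
            values = values * (1.0 + rng.normal(0.0, truth.noise_cv, size=values.shape))
        curves.append(
            TimeActivityCurve(
                schedule=schedule,
                values=values,
                roi_label=f"roi{i:02d}",
                position_mm=float(x),
            )
        )
    manifest = PlantManifest(
        plant_id=truth.plant_id,
        administered_activity_bq=administered_activity_bq,
        administration_duration_s=truth.admin_duration_s,
        roi_positions_mm={c.roi_label: c.position_mm for c in curves},
        admin_offset_s=admin_offset_s,
        age_days=age_days,
    )
    return SimPlant(truth=truth, manifest=manifest, curves=curves)


def make_paper_like_cohort(
    n_plants: int,
    seed: int,
    noise_cv: float = 0.05,
    schedule: FrameSchedule | None = None,
    admin_offset_s: float = 60.0,
) -> list[SimPlant]:
    """Simulate a cohort with per-plant parameters drawn across the reference ranges.

    Velocity, trapping-per-length, administration duration and administered
    activity are drawn uniformly from the ranges observed in the reference
    cohort; each plant gets 5-8 ROIs spaced 5 mm apart starting 5 mm above
    the administration node.
    """
    if n_plants < 1:
        raise ValueError("need at least one plant")
    rng = np.random.default_rng(seed)
    plants = []
    for i in range(n_plants):
        n_rois = int(rng.integers(N_ROI_RANGE[0], N_ROI_RANGE[1] + 1))
        positions = tuple(FIRST_ROI_MM + ROI_SPACING_MM * np.arange(n_rois))
        truth = SimTruth(
            velocity_mm_s=float(rng.uniform(*VELOCITY_RANGE_MM_S)),
            s_per_mm=float(rng.uniform(*TRAPPING_RANGE_PER_MM)),
            admin_duration_s=float(rng.uniform(*ADMIN_DURATION_RANGE_S)),
            roi_positions_mm=positions,
            noise_cv=noise_cv,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
            plant_id=f"sim{i:03d}",
        )
        plants.append(
            observe_plant(
                truth,
                schedule=schedule,
                admin_offset_s=admin_offset_s,
                administered_activity_bq=float(rng.uniform(*ACTIVITY_RANGE_BQ)),
                age_days=float(np.round(rng.uniform(20.0, 26.0))),
            )
        )
    return plants


def truth_records(plants: list[SimPlant]) -> list[dict]:
    """Flat key-value ground-truth records (for writing truth files)."""
    recs = []
    for p in plants:
        recs.append(
            {
                "plant_id": p.truth.plant_id,
                "velocity_mm_s": p.truth.velocity_mm_s,
                "s_per_mm": p.truth.s_per_mm,
                "sv_per_s": p.truth.sv_per_s,
                "admin_duration_s": p.truth.admin_duration_s,
                "dispersion_sigma_s": p.truth.dispersion_sigma_s,
                "noise_cv": p.truth.noise_cv,
                "rng_seed": p.truth.rng_seed,
                "n_rois": len(p.truth.roi_positions_mm),
            }
        )
    return recs
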