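"""Cross-plant aggregation of kinetic results.

Each quantity (trapping rate sv, velocity V, trapping per length s, plus the
administration metadata) is summarized by its unweighted mean, sample (n-1)
standard deviation, standard error of the mean, coefficient of variation and
a 95% confidence interval taken as mean +/- 2 s.e.m.  Conversions to the
reporting units (1/min, cm/min, 1/cm) are exact scale factors, so the
converted mean equals the mean of converted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, log10, sqrt

import numpy as np

from .arrival_velocity import PlantResult, convert_units
from .exceptions import InsufficientDataError, ReportError
from .tac_data import PlantManifest

__all__ = [
    "QuantitySummary",
    "CohortSummary",
    "summarize_cohort",
    "ninety_five_cl",
    "render_table1",
    "cohort_table_tsv",
    "format_value_with_sd",
]


@dataclass(frozen=True)
class QuantitySummary:
    """Mean and dispersion of one quantity across plants."""

    mean: float
    sd: float
    sem: float
    cv_percent: float
    cl95: tuple[float, float]
    n: int


@dataclass(frozen=True)
class CohortSummary:
    """Per-quantity summaries across a cohort of plants."""

    n_plants: int
    quantities: dict[str, QuantitySummary]

    def __getitem__(self, key: str) -> QuantitySummary:
        return self.quantities[key]


def ninety_five_cl(mean: float, sem: float) -> tuple[float, float]:
    """95% confidence limits as mean +/- 2 * s.e.m. (sem must be >= 0)."""
    if sem < 0:
        raise ValueError("standard error must be non-negative")
    return (mean - 2.0 * sem, mean + 2.0 * sem)


def _summarize(values) -> QuantitySummary:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    n = arr.size
    if n < 2:
        raise InsufficientDataError("dispersion statistics need at least 2 plants")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    sem = sd / sqrt(n)
    cv = 100.0 * sd / abs(mean) if mean != 0 else float("inf")
    return QuantitySummary(mean=mean, sd=sd, sem=sem, cv_percent=cv, cl95=ninety_five_cl(mean, sem), n=n)


def summarize_cohort(
    results: list[PlantResult], manifests: list[PlantManifest] | None = None
) -> CohortSummary:
    """Aggregate per-plant results (and optional manifests) across a cohort.

    Keys always present: ``sv_per_s``, ``v_mm_s``, ``s_per_mm`` and their
    reporting-unit twins ``sv_per_min``, ``v_cm_min``, ``s_per_cm``.  With
    manifests, ``age_days`` (when recorded), ``activity_mbq`` and
    ``admin_duration_s`` are added.
    """
    if len(results) < 2:
        raise InsufficientDataError("cohort summary needs at least 2 plants")
    q: dict[str, QuantitySummary] = {}
    q["sv_per_s"] = _summarize(r.sv_mean for r in results)
    q["v_mm_s"] = _summarize(r.velocity_mm_s for r in results)
    q["s_per_mm"] = _summarize(r.s_per_mm for r in results)
    for src, dst, pair in (
        ("sv_per_s", "sv_per_min", ("1/s", "1/min")),
        ("v_mm_s", "v_cm_min", ("mm/s", "cm/min")),
        ("s_per_mm", "s_per_cm", ("1/mm", "1/cm")),
    ):
        base = q[src]
        f = convert_units(1.0, *pair)
        q[dst] = QuantitySummary(
            mean=base.mean * f,
            sd=base.sd * f,
            sem=base.sem * f,
            cv_percent=base.cv_percent,
            cl95=(base.cl95[0] * f, base.cl95[1] * f),
            n=base.n,
        )
    if manifests:
        if len(manifests) != len(results):
            raise InsufficientDataError("one manifest per plant result is required")
        ages = [m.age_days for m in manifests]
        if all(a is not None for a in ages):
            q["age_days"] = _summarize(ages)
        q["activity_mbq"] = _summarize(m.administered_activity_bq / 1e6 for m in manifests)
        q["admin_duration_s"] = _summarize(m.administration_duration_s for m in manifests)
    return CohortSummary(n_plants=len(results), quantities=q)


def format_value_with_sd(value: float, sd: float, sig: int = 3, pad: int = 0) -> str:
    """Render ``mean(s.d.)`` with the s.d. in units of the mean's last digits.

    ``0.000287`` with s.d. ``0.000220`` at 3 significant figures renders as
    ``0.000287(220)``; ``pad`` left-pads the parenthesized digits with zeros.
    """
    if value == 0:
        return f"0({sd:g})"
    exponent = floor(log10(abs(value))) - (sig - 1)
    decimals = max(0, -exponent)
    digits = int(round(sd / 10.0**exponent))
    return f"{value:.{decimals}f}({str(digits).zfill(pad)})"


def _require(result: PlantResult, name: str):
    val = getattr(result, name, None)
    if val is None or (isinstance(val, float) and not np.isfinite(val)):
        raise ReportError(f"plant {result.plant_id!r} is missing field {name!r}")
    return val


_HEADER = (
    "plant_id",
    "age_days",
    "activity_mbq",
    "admin_duration_s",
    "n_rois",
    "sv_per_s",
    "v_mm_s",
    "s_per_mm",
)


def _table_rows(
    results: list[PlantResult], manifests: list[PlantManifest] | None
) -> list[tuple[str, ...]]:
    manifests = manifests or [None] * len(results)
    rows = []
    for r, m in zip(results, manifests):
        for name in ("sv_mean", "sv_sd", "velocity_mm_s", "s_per_mm", "n_rois"):
            _require(r, name)
        age = f"{m.age_days:g}" if m is not None and m.age_days is not None else ""
        act = f"{m.administered_activity_bq / 1e6:.2f}" if m is not None else ""
        dur = f"{m.administration_duration_s:g}" if m is not None else ""
        rows.append(
            (
                r.plant_id,
                age,
                act,
                dur,
                str(r.n_rois),
                format_value_with_sd(r.sv_mean, r.sv_sd, sig=3, pad=3),
                f"{r.velocity_mm_s:.3f}",
                f"{r.s_per_mm:.5f}",
            )
        )
    summary = summarize_cohort(results, manifests if manifests[0] is not None else None)
    mean_row = [f"Mean (s.d., n = {summary.n_plants})"]
    for key, sig in (("age_days", 3), ("activity_mbq", 2), ("admin_duration_s", 3)):
        if key in summary.quantities:
            s = summary[key]
            mean_row.append(format_value_with_sd(s.mean, s.sd, sig=sig))
        else:
            mean_row.append("")
    mean_row.append("")
    mean_row.append(format_value_with_sd(summary["sv_per_s"].mean, summary["sv_per_s"].sd))
    mean_row.append(format_value_with_sd(summary["v_mm_s"].mean, summary["v_mm_s"].sd))
    mean_row.append(format_value_with_sd(summary["s_per_mm"].mean, summary["s_per_mm"].sd, sig=2))
    rows.append(tuple(mean_row))
    return rows


def render_table1(
    results: list[PlantResult], manifests: list[PlantManifest] | None = None
) -> str:
    """Aligned plain-text per-plant results table with a cohort mean row.

    Columns: plant id, age, administered activity (MBq), administration
    duration (s), number of ROIs, sv mean(s.d.) in 1/s, V in mm/s, s in 1/mm.
    """
    rows = [_HEADER, *_table_rows(results, manifests)]
    widths = [max(len(row[i]) for row in rows) for i in range(len(_HEADER))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in rows
    )


def cohort_table_tsv(
    results: list[PlantResult], manifests: list[PlantManifest] | None = None
) -> str:
    """Same table as :func:`render_table1` but tab-separated."""
    rows = [_HEADER, *_table_rows(results, manifests)]
    return "\n".join("\t".join(row) for row in rows)
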