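"""Reference cohort of published per-plant kinetic estimates.

Three greenhouse-grown rapid-cycling *Brassica oleracea* plants imaged by
dynamic PET after petiolar administration of [18F]fluoride.  The raw scanner
data were never deposited, so what is reproducible from the record are the
per-plant estimates (trapping rate sv with its across-ROI s.d., and the
velocity V) together with the administration metadata; every derived and
aggregate quantity — s = sv/V, cohort means/s.d.s, unit conversions and the
velocity confidence statistics — recomputes from these numbers.

Used by the worked example, the report CLI, and validation scripts.
"""

from __future__ import annotations

from .arrival_velocity import PlantResult, trapping_per_length
from .tac_data import PlantManifest

__all__ = ["reference_results", "reference_manifests"]

# plant_id, age (days), administered activity (MBq), administration duration
# (s), number of stem ROIs, sv mean and across-ROI s.d. (1/s), velocity (mm/s)
_REFERENCE_PLANTS = (
    ("RBo019", 20.0, 3.18, 240.0, 6, 0.000287, 0.000220, 0.326),
    ("RBo021", 20.0, 8.53, 300.0, 8, 0.000191, 0.000058, 0.566),
    ("RBo026", 26.0, 9.96, 180.0, 5, 0.000280, 0.000029, 0.214),
)


def reference_results() -> list[PlantResult]:
    """Per-plant results of the reference cohort (s derived as sv/V)."""
    results = []
    for pid, _age, _act, _dur, n_rois, sv, sv_sd, v in _REFERENCE_PLANTS:
        results.append(
            PlantResult(
                plant_id=pid,
                n_rois=n_rois,
                sv_mean=sv,
                sv_sd=sv_sd,
                velocity_mm_s=v,
                intercept_mm=float("nan"),
                r_squared=float("nan"),
                s_per_mm=trapping_per_length(sv, v),
            )
        )
    return results


def reference_manifests() -> list[PlantManifest]:
    """Administration metadata of the reference cohort.

    ROI positions were not published per plant; nominal 5 mm-spaced
    positions matching each plant's ROI count stand in (only the count and
    the administration columns enter any summary).
    """
    manifests = []
    for pid, age, act_mbq, dur, n_rois, _sv, _sd, _v in _REFERENCE_PLANTS:
        positions = {f"roi{i:02d}": 5.0 + 5.0 * i for i in range(n_rois)}
        manifests.append(
            PlantManifest(
                plant_id=pid,
                administered_activity_bq=act_mbq * 1e6,
                administration_duration_s=dur,
                roi_positions_mm=positions,
                admin_offset_s=60.0,
                age_days=age,
            )
        )
    return manifests
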