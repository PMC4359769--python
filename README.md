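# stemkin

Compartmental kinetic analysis of radiotracer bolus transport in plant stems
from dynamic PET time-activity curves.

When a finite bolus of a positron-emitting tracer (e.g. [¹⁸F]fluoride) is fed
into a cut petiole, it is carried up the stem by xylem bulk flow while a small
fraction binds irreversibly along the way. A dynamic PET scan of the plant
yields, for each stem cross-section (ROI) at height *x*, a time-activity curve
M(t): activity concentration per vertical mm of stem, normalized per
administered activity. `stemkin` turns those curves into three physiological
transport parameters:

* **sv** (1/s) — trapping probability per unit time,
* **V** (mm/s) — bolus transport velocity up the stem,
* **s = sv/V** (1/mm) — trapping probability per unit stem length,

plus cross-plant summaries, for plant physiologists and radiotracer-imaging
groups studying ion and nutrient transport *in vivo*.

## Model

Observed activity splits into a free (moving) and a trapped (immobile)
compartment,

```
M(t) = G(t) + B(t),          dB/dt = sv · G(t) = sv · (M(t) − B(t)),
```

with B(0) = 0. For each ROI, sv is the single fitted parameter, chosen so
that at a late final-condition time t_f (default 55 min) all observed
activity is trapped: B(t_f) = M(t_f). The free curve G = M − B then records
the bolus passing that position; its mean arrival time

```
T = ∫ t·G(t) dt / ∫ G(t) dt,
```

truncated at the trailing half-height of G (the first 50–70 % of the free
tracer), is computed per ROI. An ordinary least-squares fit of position
against arrival time gives V as the slope, and s = sv_mean / V. A simpler
leading-edge half-height arrival time is available as a cross-check, and a
sensitivity variant refits sv so that only e.g. 80 % of M(t_f) is trapped.

Because the original scanner data were never deposited, the package also
ships a forward simulator (`synthetic_data`): a Gaussian-smoothed rectangular
feeding bolus advected at constant velocity with first-order per-length
trapping, observed through the real 20×1 min + 8×5 min PET frame schedule
with proportional Gaussian noise. Its ground truth (s, v) is the oracle for
parameter-recovery tests, and a bundled reference cohort of three published
*Brassica oleracea* plants anchors the summary statistics.

## Worked example

Simulate one noise-free plant at the reference-cohort mean parameters and
run the full analysis:

```python
import numpy as np
import stemkin as sk

truth = sk.SimTruth(
    velocity_mm_s=0.368, s_per_mm=0.00084, admin_duration_s=240.0,
    roi_positions_mm=tuple(5.0 + 5.0 * np.arange(6)), noise_cv=0.0, rng_seed=1,
)
plant = sk.observe_plant(truth)                    # scanner-time TACs + manifest
result = sk.analyze_plant(plant.curves, plant.manifest)
print(f"sv  = {result.sv_mean:.6g} 1/s")
print(f"V   = {result.velocity_mm_s:.4f} mm/s")
print(f"s   = {result.s_per_mm:.6g} 1/mm")
```

prints

```
sv  = 0.000309124 1/s
V   = 0.3673 mm/s
s   = 0.000841504 1/mm
```

i.e. the pipeline recovers the simulated trapping rate s·v = 0.00030912 1/s
to <0.01 %, the velocity 0.368 mm/s to 0.2 %, and the per-length trapping
0.00084 1/mm to 0.2 %. The same analysis runs from files via the CLI
(`stemkin simulate`, `stemkin fit`), and `stemkin report` renders the
reference cohort:

```
plant_id            age_days  activity_mbq  admin_duration_s  n_rois  sv_per_s       v_mm_s      s_per_mm
RBo019              20        3.18          240               6       0.000287(220)  0.326       0.00088
RBo021              20        8.53          300               8       0.000191(058)  0.566       0.00034
RBo026              26        9.96          180               5       0.000280(029)  0.214       0.00131
Mean (s.d., n = 3)  22.0(35)  7.2(36)       240(60)                   0.000253(54)   0.369(180)  0.00084(49)
```

Parenthesized values are sample standard deviations in units of the last
printed digits.

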