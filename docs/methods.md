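# Methods

## The compartment model

Each stem region of interest (ROI) observes activity per unit stem length
M(t) (units 1/mm after normalization per administered activity), assumed to
be the sum of free tracer G(t) moving with xylem bulk flow and irreversibly
trapped tracer B(t):

    M(t) = G(t) + B(t),     dB/dt = sv (M(t) − B(t)),     B(0) = 0.

The trapping rate sv (1/s) is the product of the trapping probability per
unit length s (1/mm) and the local velocity v (mm/s). Working assumptions:
transport is unidirectional and upward; trapped tracer never releases or
moves; decay correction has already been applied (no decay term anywhere);
the model uses only curve shape, so incomplete positron capture (a global
scale factor) does not bias it.

Time is measured from the start of petiolar administration. Raw curves are
stored on the scanner clock and rebased explicitly (default offset 60 s);
frames whose mid-time precedes administration are dropped because the model
domain starts at t = 0.

## Fitting sv: the final condition

sv is fixed per ROI by requiring that at a late time t_f a target fraction
(default 1.0) of the observed activity is trapped, B(t_f) =
target_fraction · M(t_f). The default t_f is the nominal late-frame
mid-time of 55 min (3300 s); a "computed" mode uses the actual mid-time of
the last rebased frame (3390 s for the standard schedule) — both are
provided because the two conventions differ slightly and the protocol's
bookkeeping is a matter of choice. M(t_f) and B(t_f) are linearly
interpolated between the bracketing frame mid-times.

B(t; sv) is integrated by an implicit trapezoidal march,

    B_k = [B_{k−1}(1 − q) + q (M_{k−1} + M_k)] / (1 + q),   q = sv·Δt/2,

on a grid refined so no step exceeds 15 s, with M interpolated linearly
between frame mid-times and from (0, 0) to the first observed point (tracer
physically arrives after administration starts). Single steps across 5-min
frames would be badly inaccurate for trapping rates near the top of the
bracket range (at sv·Δt = 3 the one-step update overshoots a constant
signal by 26 %); with substepping the march agrees with a stiff ODE solve
on a 100×-refined grid to better than 1e-3 relative for sv ≤ 0.01 1/s,
which the test suite asserts.

The root in sv is found by bisection (relative tolerance 1e-8) on [0,
sv_hi], sv_hi doubled from 0.01 1/s; failure to bracket below 10 1/s raises
a no-convergence error (the curve is inconsistent with complete
irreversible trapping, e.g. still rising at t_f). B(t_f; sv) is provably
nondecreasing in sv for any nonnegative M while sv·t_f ≤ 1 — the regime all
physiological fits land in (sv ~ 1e-4..1e-3 1/s) — so the root is unique
there. On noisy curves a second, spurious crossing can appear at sv ~ 1 1/s
where B tracks M quasi-statically and the final condition is met only
because noise dips at t_f; fitted rates above 0.01 1/s (trapping time
constant < 100 s, an order of magnitude beyond the physical range) are
therefore rejected as non-convergent. Noise is otherwise taken literally:
negative increments of B are not clamped, since clamping would bias sv
upward.

The sensitivity sweep refits with target fractions below 1 (e.g. 0.8,
"only 80 % of the final observed activity is trapped") to probe how
strongly results lean on the everything-trapped assumption; on noise-free
synthetic plants the downstream velocity changes by well under 1 %.

## Arrival times and velocity

The mean arrival time T = ∫ t G dt / ∫ G dt is computed by the trapezoidal
rule on frame mid-times from t = 0, with the integrals truncated at an
upper bound UB placed where G first falls through half its maximum after
the peak (linear interpolation between mid-times; the final partial
interval is split at UB). Truncation at the trailing half-height keeps
roughly the first 50–70 % of the free tracer and suppresses late-time
confounds (bidirectional movement, reversible trapping); the height
fraction is configurable (default 0.5). Each ROI uses its own curve's UB.
A leading-edge alternative takes the first upward crossing of the
half-height instead.

Velocity is the slope of an ordinary least-squares fit of position (mm,
response) on arrival time (s, predictor), so the slope carries mm/s
directly; the intercept is unconstrained and R² is reported. Errors-in-
variables treatments are out of scope. Per plant, sv is summarized as the
unweighted mean over ROI fits with sample (n−1) s.d., and s = sv_mean / V.

ROIs whose curves cannot be fitted (no signal at t_f, no-convergence) are
skipped and recorded; at least two fittable ROIs are required per plant.

## Cohort summaries

Each quantity is summarized by unweighted mean, sample (n−1) s.d., s.e.m. =
s.d./√n, coefficient of variation = 100·s.d./|mean|, and a 95 % confidence
interval of mean ± 2·s.e.m. (the ±2 rule, not a t-quantile — with n = 3
plants a t-quantile would give a far wider band than the convention used in
the reference record). Unit conversions (1/s→1/min ×60, mm/s→cm/min ×6,
1/mm→1/cm ×10, fraction→percent ×100) are exact scale factors, so converted
summaries equal summaries of converted values. The table renderer prints
"mean(s.d.)" with the s.d. expressed in units of the mean's last printed
digits, e.g. 0.000287(220).

## The synthetic stem-transport generator

The simulator emulates the structure the analysis assumes:

* **Input profile**: a unit-height rectangle of the administration duration
  (drawn from 180–300 s across cohorts) convolved with a Gaussian of s.d.
  σ₀ = 30 s, idealizing drop-by-drop absorption at the cut petiole. The
  profile is delayed by 4σ₀ and clipped at τ < 0 so it is causal; without
  the delay the smoothing tail would place tracer before administration
  begins, and its truncation at t = 0 — which differs between stem
  positions — breaks the exact linearity of arrival time in position. σ₀ is
  fixed at injection: the model fitted downstream has no dispersion-growth
  term, so the simulator does not grow dispersion with x either.
* **Transport and trapping**: G(x, t) = A·e^(−s·x)·h(t − x/v); the
  exponential is the survival of free tracer past x under per-length
  trapping s, and the trapped curve is B(x, t) = s·v·∫₀ᵗ G dt′ (dense
  quadrature at 1 s), so the trapping rate the fitter should recover is
  exactly s·v and trapped tracer stays where it bound. ROIs are point
  samples at their center (slice thickness 1.21 mm ≪ bolus length ≈ 90 mm).
* **Observation**: M = G + B is averaged over each frame of the 20×1 min +
  8×5 min schedule (administration starting 60 s into the scan) and
  attributed to the frame mid-time.
* **Noise**: per-frame Gaussian with s.d. proportional to the local signal
  (CV = `noise_cv` per frame, hence s.d. = noise_cv·max(M) at the curve
  maximum). Proportional Gaussian noise is the standard approximation for
  reconstructed, corrected PET concentrations; it understates noise on
  near-zero frames, and genuine Poisson count noise is not modeled.
* **Cohorts**: per-plant parameters are drawn uniformly across the
  reference ranges (v 0.214–0.566 mm/s, s 0.00034–0.00131 1/mm, duration
  180–300 s), with 5–8 ROIs spaced 5 mm apart from 5 mm above the node —
  matching the reference cohort's ROI counts and a typical young
  *B. oleracea* stem.

What passing recovery tests show: the estimator chain is consistent with
its own forward model at realistic parameter scales and sampling. What they
do not show: robustness to features real stems add — growing dispersion,
bidirectional or phloem transport below the node, reversible binding,
image-domain effects (partial volume, smoothing, positron escape), or
correlated noise between frames.

## Numerical choices and problem sizes

* March substep 15 s; simulator quadrature 1 s; bisection rtol 1e-8.
* Recovery studies: noise-free, a 3-plant cohort (the study size) drawn
  across the reference ranges; stochastic, 100 replicate plants at the
  cohort-mean parameters with 5 % noise — together a few tens of seconds on
  one core.
* Degenerate inputs raise typed errors: empty rebased curves, non-positive
  M(t_f), identical arrival times, cohorts of fewer than two plants.

## Known limitations

* **Trailing-edge aliasing**: with 60-s frames and a ~34 s effective edge
  width, the half-height upper bound wobbles by a few seconds depending on
  where the bolus falls within the frame grid. For fast plants (v near
  0.55 mm/s) arrival times span less than one frame across the ROI ladder,
  and the wobble can alias into the velocity slope, limiting noise-free V
  recovery to ~2–4 % in the worst draws (sv recovery is unaffected,
  < 0.01 %). Smoother crossing estimators (monotone-cubic, probit,
  histospline) were evaluated and did not reduce the alias.
* At 5 % noise, 10–20 % of simulated plants lose too many ROIs to the
  no-convergence guard and are excluded; reported medians are over the
  analyzable plants.
* The everything-trapped final condition is exactly satisfiable only
  asymptotically when the free tracer has fully cleared; curves still
  carrying free activity at t_f are rejected rather than extrapolated.
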