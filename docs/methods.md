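# Methods

This note documents the models, the synthetic plant, the controller
internals, the numerical choices, and the limits of what a green test
establishes. Units: temperatures °C, times in minutes inside the simulator
and hours inside the kinetics, moisture in % dry basis internally and
% wet basis at sensor/reporting surfaces, accumulated temperature in
°C·min.

## 1. Thin-layer kinetics (`eatdry.kinetics`)

The Weibull form `MR(t) = a + b·exp(−k t^N)` with MR on dry-basis moisture
is used throughout; its closed-form time inverse drives window selection
and the simulator's equivalent-time stepping. Fitting is bounded nonlinear
least squares on MR scale (a ∈ [−0.2, 0.3], b ∈ [0.5, 1.5], k ∈ (0, 10],
N ∈ (0.3, 3]) with three seeded starts; goodness of fit is reported as R²,
the reduced χ² = Σ(obs−pred)²/(n−p), and the RMSE. Degenerate inputs
(constant curves, non-convergence) return a failed `FitReport`, never an
exception.

The laboratory regression surfaces that map drying conditions to the four
constants are not public, so the package declares a parametric stand-in
(`ParamMapConfig`): anchors (a=0, b=1, N=1.1, k_ref at 105 °C) with
log-linear condition sensitivities, k strictly increasing in air
temperature (cT = 0.012 /°C) and velocity, decreasing in humidity. **The
same map is the simulator's ground truth** (with a configurable rate
mismatch, below), so the controller's model-correction step has a real,
known error to recover — the central test of the data-driven half of the
method.

**Calibration.** k_ref = 0.5248852 h⁻ᴺ is the unique value for which window
selection on the continuous preset returns exactly 12,000 °C·min, the
stated initial window of the reference campaign: with Tf = mean hot air =
106.67 °C, Te = 25.08 °C (equilibrium model at exhaust ERH 0.5 and the
16.96 % d.b. target), γ = 0.539 and the 25.5→14.5 % w.b. moisture path,
t = AT₀/((Tf−Te)·60·(1+γ)) = 1.593 h and k_ref follows from the Weibull
inverse. This is a declared calibration, not a fit.

## 2. Equilibrium temperature (`eatdry.equilibrium`)

Te is the zero point of effective accumulated temperature. The
three-parameter corn-desorption constants are A = 4.218, B = −32.013,
C = −0.0274. Because the published algebraic arrangement of this model
family is ambiguous in secondary sources, the module keeps a registry of
forms; the default is

```
Te = ln[(1−ERH)/(−ln ERH)] − A − B·EMC^C
```

which gives Te ≈ 25.2 °C at ERH = 0.5, EMC = 14.5 % d.b. — physically
plausible against windows of ~12,000 °C·min over a few hours at 90–110 °C —
and is strictly decreasing in EMC. An alternative plain log-difference form
is registered as `"plain"`; everything downstream depends only on the Te
contract (finite, deterministic, decreasing in EMC), not the form. In the
closed loop Te is evaluated at the exhaust-air relative humidity (ambient
RH plus a configurable evaporative pickup, default +0.15) and the *target*
moisture.

## 3. Accumulated-temperature calculators (`eatdry.eat`)

`accumulated_temperature` discretizes the integral left-rectangle-wise with
negative increments clipped: cooling below Te does not erase drying
history. The dryer form `AT₁ = Σ cᵢ(T̄ᵢ−Te)(tx+0.5)` uses zone pass counts
cᵢ = Vᵢ/Vp; three coefficient sets are selectable:

* `printed` (default): (11.5, 13.5, 13.5, 21.2) — the published counts,
  with 13.5 on *each* of the middle and lower zones as the published
  zone-time derivation implies;
* `geometry`: derived from the configured volumes — identical for zones
  1–3, but 20.2 for the cooling+discharge block where the published figure
  is 21.2 (the inconsistency is asserted by a dedicated test and left
  unresolved);
* `printed-literal`: (11.5, 27, 27, 21.2) — reproduces the published
  closed form bit-exactly, which multiplies the *sum* of the middle and
  lower excesses by 27; kept for reproduction, not used by default.

`solve_discharge_interval` is the exact algebraic inverse in tx, floored at
a configurable minimum (default 1 min); a non-positive excess sum raises
`CannotActuateError` (grain at equilibrium — no interval can accumulate
temperature).

## 4. The simulated plant (`eatdry.dryer_sim`)

The bed is an ordered queue of discharge quanta (8 L slabs; 58 full plus
one 5.73 L fractional slab for the 469.733 L reference column). Top-down:
upper drying, middle drying, middle tempering, lower drying, lower
tempering, cooling, discharge (tempering under its drying section; the
combined middle/lower volumes split 50/50, giving a geometry-derived
tempering ratio γ = 107.971/200.353 = 0.539).

Per time step (dt = 0.1 min, ≤ 1 min enforced):

* **Drying** advances each slab along the local Weibull curve by the
  equivalent-time method (invert at the current MR, add dt, re-evaluate),
  using the ground-truth map at the local *air* temperature. Exposure is
  weighted by the slab's volume overlap with the drying sections. The
  overlap weighting matters: assigning slabs to sections by midpoint lets
  the single fractional slab shift every slab above it across section
  boundaries by a whole discharge period, which injects a spurious
  ±0.3 % w.b. square wave with bed-turnover period into the outlet. With
  overlap weighting the residual path quantization is ~±0.05 % w.b.
* **Grain temperature** follows a first-order lag toward the section air
  (τ_g = 15 min, declared synthetic ground truth — the reference rig
  publishes no heat-transfer model), holds through tempering, and relaxes
  to ambient in the cooling/discharge block.
* **EAT** accumulates max(T_grain − Te, 0)·dt per slab.

Discharges happen every tx + 0.5 min (0.5 min is the fixed wheel turn),
quantized to the step grid: bottom slab out (moisture reported wet-basis,
the outlet sensor's basis), fresh slab in on top, volume conserved.

**Inlet moisture** models one wet-corn lot per run: the lot mean is drawn
uniformly from the stated 24.7–26.3 % w.b. delivery range (seeded), and
slabs fluctuate around it as an AR(1) with stationary sd 0.15 % w.b.
(ρ = 0.95), clipped to the range. The published campaign ranges (inlet
moisture, ambient temperature, ambient RH) are across-test ranges, so the
within-run variation is within-lot scale; the *lot offset* is exactly the
kind of persistent model error the data-driven window adjustment exists to
absorb. An earlier generator draft that spread the full range as within-run
drift made the control band provably unattainable for any controller
(drift time constant ≈ transit delay) and was revised on those grounds.

**Simulator-vs-controller mismatch.** The plant's rate anchor is
0.87 × the controller's (config `truth_k_scale`), i.e. the grain dries
~15 % slower than the controller's prior. Under this mismatch the
converged window lands at ≈13,100–13,900 °C·min, the same territory as the
reference campaign's realized setpoint sequence (12,000 → 13,842 → 14,753 →
13,198 °C·min), which is emulated qualitatively, not reproduced.

## 5. The controller (`eatdry.controller`)

Per discharge event the controller reads the outlet sensor, the zone
temperature means and Te, then:

1. **predicts** the outlet moisture one bed turnover ahead by an OLS line
   through the last W = 30 discharges (W = 10 amplifies slope noise ~6× at
   this horizon and was widened accordingly);
2. **classifies** the predicted deviation: |dev| > δ₁ = 0.5 % w.b. →
   window-area change (ADJUST); above a 0.05 dead band → aspect-ratio
   change only (ADAPT); else HOLD;
3. **acts**. ADAPT re-solves tx from the measured zone temperatures so the
   realized EAT equals AT_set, rate-limited to ±20 % per event, floored and
   capped (1–30 min), plus a small additive trim from the explicit control
   law u(k) = k_H(T_i−T₀) + k_SΣT_i + k_I·ΔT_i/Δt_i (T₀ an EWMA baseline;
   default gains small — the EAT inversion carries the loop).

**Window adjustment** is mechanism + data in sequence. The GA (real-coded,
tournament-3 selection, BLX-0.5 crossover 0.9, Gaussian mutation 0.1,
elitist, population 40 × 50 generations, fully seeded) searches correction
genes (Δa additive ±0.02; b, k, N relative ±8 %, ±30 %, ±5 %) applied to a
**section-aware internal model**: each observed slab's exposure in the
upper/middle/lower drying sections is reconstructed from the discharge
history (volumes below its entry height × mean period during its transit)
and the Weibull curve is advanced sequentially through the three sections
at their own k(T). Fitness is the KS objective on the prediction
residuals. A single-temperature model misprices the 110/100/110 °C path by
~5 % in k, which is why the path model exists.

The window-area moves are incremental, in discharge-period space (where the
theoretical and realized EAT scales cancel):

* the **first** change after a 0.85-turnover warmup is mechanism-driven:
  ΔAT = 0.9·AT·(P* − P_steady)/P_steady, with P* the period at which a full
  transit reaches the target per the corrected model and P_steady the
  period the current window implies at steady state (cap 30 %);
* later changes are **feedback trims** (gain 0.7, cap 5 %, cooldown 20
  events) on the median of the last 15 outlet readings, *compensated for
  moves still in transit*: a move's effect only surfaces once slabs that
  were above the drying sections at the move reach the outlet, and the
  geometry-derived surfacing profile is subtracted Smith-predictor style.
  Because the constants are refit at every adjustment, repeated trims act
  as integral action without wind-up on the transit delay.

Supporting estimates, all derivable from what the rig instruments provide:

* **lot moisture**: the first ~26 discharges leave the dryer undried (they
  start below the lowest drying section), so their median reading measures
  the lot's inlet moisture directly and removes the offset/rate confound
  from the GA fit;
* **steady-state heat model**: the first-order lag propagated through the
  zone sequence, resolved with the period by fixed-point iteration; it
  matches the simulated steady EAT denominator to 0.03 % and supplies the
  initial interval, the one-shot anchor, and a warmup cap on the adaptation
  period (a cold bed understates the zone excesses and would otherwise
  balloon the interval);
* **feedforward**: a hot-air setpoint change that persists ≥ 3 events
  rescales the window by the ratio of model-required windows at the new
  and old conditions (the ratio cancels persistent biases; it is not
  entered in the trim compensation because the plant-side step cancels
  it). Sub-period pulses are deliberately ignored, matching the observed
  pulse immunity of the reference rig.

The published method does not state how u(k) actuates the hardware, the
prediction window/horizon, the GA ranges, or the adjustment timing; all of
the above are this package's design choices, config-exposed, with defaults
recorded (and source-tagged) in `presets/default.yaml`.

## 6. What the green tests do and do not establish

The closed-loop acceptance runs show that *under this synthetic plant* —
Weibull kinetics with a known mismatch, first-order grain heating, one
drifting lot per run, ideal sensors — the controller keeps the outlet
within the ±0.5 % w.b. specification band after two bed turnovers, on the
continuous, step, pulse and sinusoid schedules at the fixed test seeds
(typical worst-case 0.3–0.48 % w.b.; occasional seeds outside the tested
set reach ~0.55–0.6 during correction transients). They do not establish
performance on a physical dryer: kernel-internal moisture gradients,
airflow maldistribution, sensor noise and delay, shrinkage, and
quality-related constraints are all outside the model. The hardware-rig
accuracy figures of the original campaign (−0.189–0.337 % continuous,
−0.58–0.3 % step) are measurements of a different (physical) system and
are deliberately not reproduction targets; the specification band is.

## 7. Numerical choices and degenerate inputs

* Weibull inversion clamps target moisture ratios into (a+10⁻³, a+b−10⁻³);
  outside-reachable targets raise `UnreachableMoistureError`.
* The period-for-moisture root solve is 60-step bisection on [0.6, 180] min
  (MR strictly decreasing in the period).
* Discharge times are quantized to the simulation grid; dt defaults to
  0.1 min and is capped at 1 min for stable equivalent-time tracking.
* GA seeds derive from the configured base seed and the event index
  ((seed·100003 + event) mod 2³¹), so whole runs are bit-reproducible.
* Left-rectangle EAT discretization is exact for piecewise-constant traces
  (no dt dependence), which the property suite asserts.
* Pass counts are reported to one decimal and kept fractional; the
  simulator handles the fractional boundary slab by volume-overlap
  weighting rather than rounding residence to whole periods.
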