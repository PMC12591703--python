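# Methods

`oabayes` simulates and analyzes the offset-analgesia (OA) paradigm
under noisy thermal stimulation. This note documents the models, the
parameter choices and their rationale, the synthetic-data assumptions,
and the numerical decisions a user extending the package should know
about.

## The paradigm

A trial holds the skin at a 32 °C baseline for 5 s, ramps at 6 °C/s to
a 45 °C plateau, then steps through three phases: T1 (5 s at 45 °C),
T2 (5 s at 47 °C) and T3 (15 s back at 45 °C), before ramping down.
The small 47 → 45 °C offset at T3 onset produces a disproportionate,
transient drop in perceived pain — offset analgesia. Pain is reported
on a visual analogue scale (VAS) anchored so that 50 corresponds to the
plateau percept, at four beeps: R0 (4 s into T2) and R1/R2/R3
(5/10/15 s into T3). In the noise conditions the T3 temperature
fluctuates at 3 Hz between 44 and 46 °C around the same 45 °C mean,
following one of two fixed disturbance realizations ("sequence #1/#2").

The realized disturbance sequences of the original experiment are not
published; the library defines its stand-in sequences by two fixed
seeds (`SEQ1_SEED = 101`, `SEQ2_SEED = 202`). The disturbance waveform
is a trapezoid-pulse train: every 1/3 s a new level is drawn (uniform
on [44, 46] by default; a three-level variant is available), reached at
10 °C/s and held for the rest of the cycle, giving ~70–200 ms ramps and
~130–260 ms holds. The final cycle returns to 45 °C so that the
down-ramp is sample-identical across conditions. Traces are sampled at
30 Hz; phase labels are attached per sample with left-closed,
right-open phase intervals.

## The two observer models

**Deterministic dynamic model.** Perceived pain is the state `p` of a
damped second-order linear system,
`p'' + 2ζω p' + ω² p = g ω² u(t)`, driven by
`u = temperature − 45 °C`. Underdamping makes an abrupt drop in `u`
launch a decaying oscillation whose first trough is the OA undershoot.
Defaults `ω = 0.7 rad/s`, `ζ = 0.3`, `g = 1` put the trough
`π/(ω√(1−ζ²)) ≈ 4.7 s` after the offset — at the first rating beep —
with the oscillation decaying over the rest of T3. Because the system
is a linear map of its input, its output differs between the two
disturbance sequences; this direct sequence sensitivity is the
property the Bayesian alternative is contrasted against. Integration
is fixed-step classical RK4 on the trace grid with the drive linearly
interpolated at half steps; it matches the analytic underdamped step
response to better than 1e-6 and halving the step changes the
trajectory by less than 1e-5 relative.

**Recursive Bayesian tonic/phasic filter.** The noxious drive is
decomposed into a tonic level `x` (random walk, process variance
`q_tonic`) and a phasic transient `dx` (AR(1) with per-step decay `a`,
process variance `q_phasic`), observed as `u = x + dx + noise` with
observation variance `r`. The posterior is computed exactly by a
two-state Kalman filter; the phasic posterior mean is the model of
subjective pain. After the offset the tonic estimate is still partly
elevated, so the phasic estimate is driven negative (the OA
undershoot) and relaxes back as the tonic estimate is corrected.

The observation variance is estimated online from the innovation
stream: `r ← max(r_min, (1−β) r + β (δe² − H P Hᵀ))`, where `δe` is
the innovation centered on its exponentially weighted running mean and
`δe²` is winsorized at `(3σ)² = 9 S` of the predicted innovation
variance `S`. Two refinements over the textbook squared-innovation
estimator matter here, and both are standard devices from adaptive
filtering:

* **centering** — a persistent innovation bias (an as-yet-unabsorbed
  stimulus step) is evidence of a changed state, not of observation
  noise; the raw `e²` form mistakes it for noise, which collapses the
  gain, which preserves the bias — a self-sustaining low-gain
  deadlock. Centering leaves sustained biases to the state update.
* **gating** — a single surprise innovation (a stimulus edge) is
  clipped before entering the variance estimate, so one step cannot
  inflate `r`, while sustained fluctuation ratchets it up within a few
  steps. The raw form is available via
  `center_innovations=False` / `innovation_clip=inf`.

When the 3 Hz disturbance starts, innovations fluctuate persistently,
`r` rises, the Kalman gain falls, and the filter stops chasing the
disturbance: the phasic estimate decays back toward zero at its own
rate `a` — faster than the conventional condition's recovery, and
essentially independent of the particular disturbance realization.
This is the mechanism behind both the attenuation of OA by noise and
its sequence invariance.

**Filter rate.** The filter steps at 3 Hz (`step_rate_hz`), taking
every m-th sample of the 30 Hz trace as an observation, with
zero-order-hold outputs on the trace grid. This models a perceptual
evidence-accumulation rate much slower than the physical sampling: at
3 Hz each observation lands on a fresh disturbance level, so the
disturbance is genuinely unpredictable to the observer. A 30 Hz filter
can always partially track the ~300 ms holds, which both reintroduces
sequence dependence and starves the innovation-variance estimator.

**Startup.** The recursion starts when the stimulus first reaches the
plateau (end of the initial ramp), initialized at `[u, 0]` with the
configured prior variances. The 32 °C baseline lies far below the
heat-pain threshold, where a linear drive `temp − 45` is not a
meaningful nociceptive quantity, and the rating scale is anchored to
the plateau percept; a linear time-invariant filter cannot both absorb
a 13 °C sub-threshold excursion and sustain a multi-second 2 °C-scale
undershoot. Starting at plateau arrival also makes the constant
(familiarization) condition's predicted rating exactly the VAS anchor
of 50.

**Default filter parameters** (per 3 Hz step): `a = 0.90` (phasic time
constant ≈ 3.3 s), `q_tonic = 1e-6`, `q_phasic = 8e-4`,
`r_obs0 = 0.065`, `r_min = 2e-4`, `β = 0.07` (noise-level learning
over a few seconds), gate at 3σ. These were calibrated once so that
the simulated group pattern reproduces the qualitative phenomenology
of the paradigm: R0 above the anchor; a deep undershoot at R1 in both
offset conditions; slow monotone recovery in the conventional
condition; markedly faster recovery under noise (positive
timing-by-stimulus interaction); and near-identical responses to the
two disturbance sequences (max aggregate difference ≈ 0.02 drive
units, versus ≈ 0.29 for the deterministic model).

## Linkage and model comparison

Aggregates are window means over 1 s ending at each beep (`window_s`,
0 = single sample). Drive units map to the VAS through the affine link
`VAS = 50 + slope × aggregate` with default slope 30 VAS/°C-equivalent,
placing the conventional R1 rating near VAS 35. Clipping to [0, 100]
is applied only to reported ratings, never during fitting.

Three per-rating predictors are compared by OLS of VAS on each — M1:
window-mean stimulus temperature (as drive); M2: deterministic pain
state; M3: phasic estimate — all on identical observations (R0–R3 of
the offset and noise test trials, pooled across participants). Gaussian
ML criteria use `k = 3` (intercept, slope, residual variance);
`BIC = k ln n − 2ℓ`; Bayes factors use the BIC approximation
`BF_ab = exp((BIC_b − BIC_a)/2)`, always reported alongside the exact
log value to survive overflow. Participant structure is deliberately
not modelled at this stage; it belongs to the mixed-model analysis.

## Mixed-model analysis

T3 ratings (R1–R3 of offset-stimulus trials) are analyzed with
`vas ~ timing * stimulus + (1 | participant)` and, on noise trials
only, `vas ~ timing * sequence + (1 | participant)`, with half-unit
sum-to-zero codings (R1/R2/R3 = −0.5/0/+0.5; conventional/noise =
−0.5/+0.5; sequence #1/#2 = −0.5/+0.5). Conventional trials carry no
sequence code and are excluded from the sequence analysis.

Fitting is maximum likelihood with the fixed effects profiled out by
GLS: for the random-intercept model, `V⁻¹` reduces to group-sum
corrections with weight `ψ/(1 + n_g ψ)` where `ψ = σ_b²/σ_e²`, so the
profiled deviance is a 1-D function of `ψ`, optimized by bounded
scalar search in log space with the `ψ = 0` boundary (OLS) checked
explicitly. Inference uses residual-style degrees of freedom
`df = n − p − (g − 1)` and two-sided t tests; effect sizes are Cohen's
`d = 2t/√df`. With 528 observations, 4 fixed effects and 22
participants this gives df = 503, and the `d = 2t/√df` convention
reproduces published effect sizes from their t statistics to two
decimals. ML (not REML) keeps the profiled likelihood simple and the
boundary well-behaved; at the scales simulated here the difference is
immaterial. The implementation is cross-checked against
`statsmodels` MixedLM in the test suite, and its null calibration
(type-I error at α = 0.05 within [0.025, 0.085] over 200 simulated
datasets) is part of the acceptance tests.

## Synthetic data

The generator reproduces the study design exactly: 22 participants,
2 constant familiarization trials, then 8 test trials (4 conventional,
2 per noise sequence), first test trial always conventional, the
remaining 7 in seeded random order. Ratings are the observer's
noise-free VAS prediction per condition and timing, plus a Gaussian
participant intercept (SD 8 VAS, drawn once per participant) and
i.i.d. Gaussian report noise (SD 10 VAS), clipped to [0, 100]. The
noise SDs were chosen so that the simulated standard errors are on the
scale typical of a 22-participant VAS study (intercept SE ≈ 1.6,
stimulus SE ≈ 0.9).

What the generator deliberately does not emulate: habituation or
sensitization across trials, site-to-site variability, peripheral
thermal transfer between thermode and receptor (the commanded waveform
is taken as the effective stimulus), heteroscedastic or skewed report
noise, and participant-specific model parameters. Passing tests
therefore demonstrate that the pipeline recovers the structure it
assumes — not that real raters behave this way.

## Numerical choices and verification

* The two-state filter is verified against an independent brute-force
  oracle: recursive Bayes on a dense 2-D grid (discretized Gaussian
  transition kernels and likelihood, 0.02 spacing), agreeing with the
  Kalman recursion to better than 1e-3 on random short sequences. The
  oracle refuses grids coarser than the smallest kernel SD and aborts
  if posterior mass reaches the grid edge.
* The filter covariance update uses the Joseph form with explicit
  re-symmetrization; positive semi-definiteness is asserted each step
  (tolerance −1e-10 on eigenvalues) and its long-run value matches an
  independent fixed-point iteration of the Riccati recursion to 1e-8.
* Window aggregation matches sample times with half-sample tolerance,
  so beep times falling exactly on grid points behave predictably; a
  zero-length window degenerates to the nearest sample.
* Trace CSVs round-trip exactly (`float_precision="round_trip"` on
  read); the pipeline's `report.json` is byte-identical for identical
  config and master seed, with per-stage seeds derived from the master
  seed through `numpy.random.SeedSequence`.
* Population SD (divide by n) is used in `phase_stats` for
  determinism in degenerate segments.

## Known limitations

* The adaptive-noise mechanism (centered, gated innovation-variance
  tracking) is this package's explicit modelling choice for how the
  observer learns the disturbance level within a trial; other
  mechanisms (per-condition fixed `r`, cross-trial learning) would
  produce the same qualitative contrast and can be emulated with
  `beta_adapt = 0` and a chosen `r_obs0`.
* The deterministic model's exact published parameterization is not
  reproduced; the canonical damped second-order form with DC gain is
  used, parameterized to the paradigm's timing.
* Sub-threshold dynamics (below the 45 °C plateau-anchored range) are
  outside both models' domain; simulations are meaningful from plateau
  arrival onward.
* Satterthwaite or Kenward-Roger degrees of freedom are not
  implemented; the residual-style df is a deliberate simplification
  consistent with the effect-size convention above.
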