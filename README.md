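# oabayes

Simulation and analysis of **offset analgesia (OA) under noisy noxious
input**: does perceived pain track every wiggle of the stimulus, or
does the brain filter high-frequency disturbances out of a stable pain
estimate?

Offset analgesia is the disproportionate, transient drop in perceived
pain after a small abrupt decrease in a noxious thermal stimulus
(here 47 → 45 °C). Two computational accounts make opposite
predictions when a 3 Hz random temperature disturbance (44–46 °C) is
superimposed after the offset:

* a **deterministic dynamic model** — pain is the state `p` of a
  damped second-order system, `p'' + 2ζω p' + ω² p = g ω² u(t)` with
  drive `u = T − 45 °C`; being a linear map of its input, it responds
  differently to every disturbance realization;
* a **recursive Bayesian model** — a two-state Kalman filter tracks a
  tonic level `x` and a phasic transient `Δx` of the drive, with the
  observation variance learned online from innovations; perceived pain
  is the phasic posterior mean `Δx̄`, which undershoots after the
  offset, recovers faster under noise (the disturbance is discounted
  as observation noise), and is nearly identical across disturbance
  sequences.

The package is aimed at computational pain researchers and
psychophysicists: it generates the full stimulus set and experimental
design, runs both observer models, produces synthetic VAS rating
datasets with participant structure, and reproduces the statistical
workflow — random-intercept linear mixed models with half-unit factor
codings and Cohen's `d = 2t/√df`, plus regression model comparison via
BIC-approximated Bayes factors `BF = exp(ΔBIC/2)`.

## Worked example

```python
import numpy as np
import oabayes as oa

protocol = oa.Protocol()                      # 32 °C baseline, T1/T2/T3 = 45/47/45 °C
schedule = oa.rating_schedule(protocol)       # beeps: R0 in T2; R1/R2/R3 at 5/10/15 s of T3
traces   = oa.build_condition_traces(protocol)

bayes = oa.BayesParams()
for cond in ("conventional", "noise_seq1", "noise_seq2"):
    ft  = oa.run_filter(traces[cond], bayes)
    agg = oa.phasic_at_ratings(ft, schedule)  # drive units; 0 = VAS 50
    print(cond, np.round(agg, 3))
```

prints

```
conventional [ 0.386 -0.379 -0.357 -0.345]
noise_seq1   [ 0.386 -0.324 -0.154 -0.12 ]
noise_seq2   [ 0.386 -0.348 -0.175 -0.123]
```

Reading: at R0 (during the 47 °C phase) the phasic estimate is
elevated (+0.39 ≈ VAS 62 at the default link of 30 VAS per unit).
After the offset, all conditions undershoot the plateau percept at R1
(≈ VAS 38–40, the OA response). The conventional condition recovers
slowly (−0.38 → −0.35), while under the noise conditions the filter
raises its noise estimate, stops tracking the input, and the phasic
estimate relaxes back much faster (−0.32 → −0.12) — and the two
disturbance sequences produce nearly identical values (max difference
0.024, versus 0.294 for the deterministic model on the same traces).

The `examples/` directory walks through each capability: stimulus
construction, both models, the synthetic 22-participant study with
mixed-model analysis, BIC/Bayes-factor model comparison, and the
one-config end-to-end pipeline (`oabayes.run_all`), which writes all
stage artifacts plus a byte-reproducible `report.json`.

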