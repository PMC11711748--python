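# beltquest

Adaptive estimation of just-noticeable inter-leg speed differences in
split-belt treadmill walking, as a tested, reusable pipeline.

Walkers on a split-belt treadmill (one belt per leg, independently driven)
can detect surprisingly small speed differences between their legs. The
standard way to measure this is a two-alternative forced-choice (2AFC)
task: at quasi-random intervals one belt is briefly accelerated or
decelerated, the walker reports which belt feels faster, and an adaptive
staircase converges on the just-noticeable difference (JND). `beltquest`
implements everything such a study needs after the hardware:

* **`beltquest.quest`** — a from-scratch QUEST staircase: a discretized
  posterior over the threshold `T`, updated each trial with the Weibull
  likelihood `p(x;T) = δγ + (1−δ)[1 − (1−γ)exp(−10^{β(x_w−T_w)})]`
  (γ = 0.5, δ = 0.01, β = 3.5; working units log10 m/s by default, linear
  optional), with mode placement, clamped intensities, credible-interval
  widths, and trial-log replay.
* **`beltquest.observers`** — virtual participants: lognormally distributed
  true thresholds (5th–95th percentile ratio ≈ 7), correlated across
  perturbation directions, Weibull responses with lapses, ~2.6%
  non-responses, and integer steps-to-response latencies in the 3–10-step
  window.
* **`beltquest.session`** — the protocol simulator: four 25–35-trial blocks
  per participant (two per direction, counterbalanced), staircase-driven
  intensities, replayable CSV trial logs.
* **`beltquest.gait`** — the offline signal chain: cubic-spline gap filling,
  Savitzky–Golay smoothing (124 ms), GRF-based step detection (524 ms
  filter; maxima plus turning points), steps-to-response counting, and a
  synthetic two-belt GRF generator with scripted ground truth.
* **`beltquest.stats`** — the analysis: paired t-tests with JZS Bayes
  factors (Cauchy prior, scale 0.707, by numerical integration), Pearson
  correlations with stretched-beta Bayes factors (width 0.333), test–retest
  reliability with the attenuation ceiling `r_max = √(r11·r22)`, interval
  Bayes factors, and Deming regression.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import numpy as np
from beltquest import (PopulationSpec, ProtocolConfig, QuestParams,
                       analyze_study, run_study, sample_population)

pop = sample_population(PopulationSpec(n=48, seed=0))
study = run_study(pop, QuestParams(), ProtocolConfig(), rng=1)
report = analyze_study(study)

jnd = report["jnd"]
rel = report["stability"]["reliability"]
print(f"mean JND (increase): {jnd['increase']['mean_pct']:.1f}% of baseline")
print(f"mean JND (decrease): {jnd['decrease']['mean_pct']:.1f}% of baseline")
print(f"type difference: t({jnd['type_difference']['df']}) = "
      f"{jnd['type_difference']['statistic']:.2f}, BF10 = {jnd['type_difference']['bf10']:.2f}")
print(f"5th-95th percentile factor: {jnd['increase']['percentile_factor']:.1f} (increase), "
      f"{jnd['decrease']['percentile_factor']:.1f} (decrease)")
print(f"reliability: r11 = {rel['r11']:.2f}, r22 = {rel['r22']:.2f}")
print(f"cross-type r = {rel['r12']['r']:.2f} vs ceiling r_max = {rel['r_max']:.2f} "
      f"(t({rel['comparison']['df']}) = {rel['comparison']['statistic']:.2f})")
print(f"steps to response: {report['timing']['steps_mean']:.2f} "
      f"± {report['timing']['steps_sd']:.2f}")
print(f"non-response fraction: {report['nonresponse_fraction']:.3f}")
```

prints

```
mean JND (increase): 6.7% of baseline
mean JND (decrease): 7.2% of baseline
type difference: t(47) = -1.04, BF10 = 0.26
5th-95th percentile factor: 7.3 (increase), 5.9 (decrease)
reliability: r11 = 0.88, r22 = 0.93
cross-type r = 0.74 vs ceiling r_max = 0.90 (t(46) = -1.65)
steps to response: 5.67 ± 1.69
non-response fraction: 0.023
```

Both perturbation types land near a 7% JND with a Bayes factor favouring no
type difference, between-participant spread spans roughly a factor of 7
between the 5th and 95th percentiles, and the cross-type correlation sits
below its reliability-implied ceiling √(0.88·0.93) ≈ 0.90 — with a latent
inter-type correlation of 0.8 in the generator, that is exactly where it
should be. Steps-to-response and non-response rates match the generator's
calibration targets.

The same pipeline runs from the shell:

```sh
beltquest simulate-study --seed 7 --out runs/demo      # trial log + manifest
beltquest analyze --in runs/demo/trial_log.csv --out runs/demo/report.json
beltquest simulate-grf --steps 40 --cadence 1.9 --noise 20 --seed 1 --out runs/grf.csv
```

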