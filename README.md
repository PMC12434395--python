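# atcost

Competition growth modelling, cost-of-resistance estimation, in-silico
adaptive-therapy trials and longitudinal subclone tracking for
platinum-resistant high-grade serous ovarian cancer (HGSC).

Adaptive therapy (AT) modulates drug dose by tumor response in order to
*maintain* a drug-sensitive population that competitively suppresses the
resistant one, instead of eliminating it at maximum tolerated dose and
releasing the resistant clone.  The strategy only works if resistance
carries a fitness cost under resource limitation.  `atcost` is a toolbox
for the quantitative side of that program, aimed at researchers modelling
tumor evolutionary dynamics:

- **Growth models** — closed-form logistic growth (rates in
  doublings/day) and the two-population Lotka–Volterra competition system

      dS/dt = ln2·gs·S·(1 − (S + α_sr R)/Ks)
      dR/dt = ln2·gr·R·(1 − (R + α_rs S)/Kr)

  with nonlinear least-squares fitting of monocultures
  (`LogisticGrowthModel`) and detection of competition as deviation from
  the independent-growth (α = 0) prediction.
- **Fitness-gap estimation** — the slope of log2(S/R) against time
  estimates g = gs − gr directly in doublings/day; series at different
  seeding ratios are time-aligned onto a reference line and pooled
  (`FitnessGapModel`).
- **Trial engine** — per-mouse tumor courses under vehicle, standard
  carboplatin (60 mg/kg every 4 days × 3) or adaptive weekly dosing with
  a response-band controller; Kaplan–Meier medians, Mantel–Cox log-rank,
  cumulative dose and dose-per-day endpoints (`run_trial`).
- **Subclone tracker** — an emergent resistant subclone shifts
  purity-corrected segment copy numbers by r_t·Δ_seg; alternating least
  squares with integer Δ and a parsimony rule recovers the subclonal
  ratio per sample, with 95% CIs from a 150×75% segment-subsampling
  bootstrap, and correlates subclone growth with a CA125-like burden
  marker (`SubcloneMixtureModel`, `bootstrap_ci`, `correlate_burden`).
- **Synthetic data** — seeded generators for every input shape
  (cocultures, drug pulses, mouse cohorts, longitudinal copy-number
  series) with ground truth attached, so every stage is testable without
  any external data.

See `docs/methods.md` for model assumptions, parameter defaults and
numerical choices.

## Worked example

Estimate the fitness gap from three simulated low-resource cocultures
(true gap 0.08 doublings/day, 5% count noise, triplicates), then track a
resistant subclone across four longitudinal copy-number samples:

```python
import numpy as np
from atcost import *
from atcost.fitness import FitnessGapModel, ratio_series

cfg = SimConfig(seed=7, noise_cv=0.05, sampling_times=tuple(np.linspace(0, 12, 10)))
model = CompetitionModel(
    PopulationParams(0.50, 1e9, "sensitive"),
    PopulationParams(0.42, 1e9, "resistant"),
)
series = [ratio_series(gen_coculture(model, (fs, 1 - fs), 1e5, cfg))
          for fs in (0.15, 0.5, 0.85)]
print(FitnessGapModel(series, reference="15:85").fit().summary())

ser = gen_cn_series(60, 20, [0.0, 0.1, 0.3, 0.6], (0.6, 0.5, 0.7, 0.65),
                    SimConfig(seed=7, cn_noise_sd=0.05), days=[0, 60, 120, 180])
segs = call_resistance_segments(ser.baseline, ser.later)
print(bootstrap_ci(ser.baseline, ser.later, segs, seed=7).summary())
```

```
Fitness gap fit  (slope of log2 S:R ratio vs time)
==================================================
g = gs - gr (doublings/day)           0.0809  (SE 0.0004)
intercept (log2 units)               -2.5206
R^2                                   0.9975
points                                    90
  offset[15:85] = +0.000 days
  offset[50:50] = +31.097 days
  offset[85:15] = +62.361 days

Subclonal ratio estimates
========================================
P1-s1                day    60.0  r = 0.110  [0.062, 0.143]
P1-s2                day   120.0  r = 0.315  [0.267, 0.340]
P1-s3                day   180.0  r = 0.593  [0.513, 0.621]
segments used: 20; sum|delta| = 29
```

The pooled slope recovers the 0.08 doublings/day gap with the three
seeding ratios collapsing onto one line (the time offsets are the
staggering needed to do so), and the tracker recovers the true subclonal
ratios 0.1/0.3/0.6 within its confidence bands.

A full end-to-end run (simulate → fit growth → estimate fitness →
trial → track subclone → correlate) is available from the command line:

```bash
atcost run-all --demo --seed 17 --out demo_run/
```

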