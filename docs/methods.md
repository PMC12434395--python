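# Methods

`atcost` models the population dynamics that make adaptive therapy (AT)
work in platinum-resistant high-grade serous ovarian cancer (HGSC): a
drug-sensitive population S and a drug-resistant population R compete for
limited resources, the resistant population pays a proliferative fitness
cost in the absence of drug, and treatment transiently reverses the
fitness ranking.  The package covers four linked analyses: (1) logistic /
competition growth modelling of coculture experiments, (2) estimation of
the fitness gap g = gs − gr, (3) an in-silico carboplatin trial comparing
standard and adaptive dosing, and (4) tracking of an emergent resistant
subclone in longitudinal segment-level copy-number profiles.

## Growth and competition model

Growth rates are expressed in doublings/day throughout; integrators
convert to intrinsic exponential rates via ln 2.  Monocultures follow the
closed-form logistic

    N(t) = K / (1 + (K/N0 − 1) e^(−ln2 · g · t)).

Cocultures follow the two-species Lotka–Volterra-logistic system

    dS/dt = ln2 · gs · S · (1 − (S + α_sr R)/Ks)
    dR/dt = ln2 · gr · R · (1 − (R + α_rs S)/Kr)

α_sr is the per-capita effect of R on S, α_rs the converse.  The presets
use α = 1 on both sides (a fully shared resource pool), the minimal model
consistent with competition under one carrying capacity.  Low-resource
in-vitro preset: gs = 0.50, gr = 0.42 doublings/day (gap 0.08), K = 2×10⁶
cells.  Setting both α to 0 yields the independent-growth null used as
the "predicted from monoculture" reference.

`simulate_competition` integrates with DOP853 at rtol 1e-10 (LSODA with a
0.5-day step cap when a time-dependent kill term is present); at α = 0 it
agrees with the closed form to better than 1e-6 relative error over 60
days, which the test suite asserts.

### Fitting

`LogisticGrowthModel` fits (g, K, N0) by nonlinear least squares on
log-counts (multiplicative measurement noise; a linear-scale flag is
available), parameterized as (g, log K, log N0).  Starting values come
from the data (early log2 slope for g, max count for K); five
latin-hypercube restarts are attempted only if the first solve fails.
Standard errors are delta-method values from the Jacobian.  Two
identifiability flags are raised rather than erroring: a log2 range
under 0.5 doublings flags the growth rate, and data whose maximum stays
below K̂/2 (or fewer than 5 distinct times) flag the carrying capacity.

### Competition detection

`competition_deviation` reports, per population, the mean over time of
log2(observed/predicted) with a confidence interval; negative values mean
suppression below the independent-growth null.  With the study's three
technical replicates a percentile bootstrap over replicate means is
badly anti-conservative, so the default interval is a Student-t interval
over replicate means (the bootstrap remains available via
`method="bootstrap"`).  When the prediction comes from *fitted*
monoculture parameters, the fit error is a systematic offset shared by
all replicates and is usually the dominant error term; passing
`prediction_draws` (parameter draws from the two monoculture fits,
`sample_prediction_draws`) folds that spread into the interval.  Without
it the interval covers only replicate noise and the null test is
miscalibrated.

## Fitness-gap estimation

Under exponential growth log2(S/R)(t) is linear in t with slope
g = gs − gr, independent of the seeding composition.  The reference
series (by convention the lowest sensitive seeding ratio) is fitted by
OLS with replicates as independent points; every other series is then
shifted in time so that its first point lies exactly on the reference
line (offset = (y₀ − intercept)/g − t₀), and a single pooled OLS refit is
reported.  Log base 2 makes the slope directly comparable to growth
rates in doublings/day; natural-log input can be converted via the
`log_base` argument.  Zero counts are dropped with a warning rather than
pseudocounted.  A replicate-cluster bootstrap SE is available
(`cluster_bootstrap=`); a reference slope of exactly zero triggers an
intercept-only vertical alignment with a warning.  Near carrying
capacity the instantaneous ratio slope shrinks by (1 − N/K), so the
linear model targets the exponential phase; recovery tests generate data
far below K.

## Drug effect model

Platinum kill is an Emax dose response shaped in time by a delay kernel:

    kill(dose, τ) = kill_max · dose/(dose + EC50) · k(τ),

where k is a gamma density (shape `lag_shape`, mean `lag_mean`)
normalized to unit peak and truncated at `effect_duration`, so the
instantaneous kill rate at the effect peak of an EC50 dose is
kill_max/2.  The resistant population receives the same rate multiplied
by `resistance_factor` ∈ [0, 1].  Higher doses act earlier: the kernel
mean contracts as lag_mean · (1 − accel · dose/(dose + EC50)).  A fixed
kernel would make the sensitive-fraction nadir *later* at higher dose
(a stronger pulse takes longer to decay back to the growth-gap
threshold), which contradicts the observed dose ordering; the
contraction restores it.

In-vitro defaults (doses in µmol/L): kill_max 1.0/day, EC50 0.3,
lag_mean 7 d, lag_shape 8, effect_duration 12 d, resistance_factor 0.2,
accel 0.5.  These were calibrated once against the qualitative facts the
model must reproduce — sensitive-fraction nadirs 5–12 days after a day-6
pulse, strictly deeper and earlier as dose increases over
{0.1, 0.5, 1.0} µmol/L — and then frozen; with them the simulated nadir
lags are 12.0/9.5/8.5 days.

## In-silico carboplatin trial

Scales follow the caliper-volume convention of 10⁴ cells/mm³.  The
xenograft preset uses gs = 0.35, gr = 0.27 doublings/day and
K = 2.5×10⁷ cells (a 2 500 mm³ flank tumor) so that untreated tumors
pass the 1 440 mm³ humane endpoint while competition still matters at
endpoint sizes.  The effective engrafted burden is 10⁵ cells per flank
(10 mm³); engraftment efficiency is folded into this number.  Mouse
heterogeneity enters through independent lognormal initial-size jitter
per flank (CV 0.3) and lognormal growth-rate multipliers per mouse
(CV 0.1).  In-vivo drug preset (mg/kg): kill_max 1.2/day, EC50 20,
lag_mean 3 d, shape 3, effect_duration 7 d, resistance_factor 0.1,
accel 0.3 — at the 60 mg/kg reference dose the sensitive kill rate well
exceeds net growth, so standard therapy halts sensitive-majority tumors
only transiently while weekly adaptive dosing can hold them.

Protocols: standard therapy (ST) gives 60 mg/kg every 4 days × 3 doses;
vehicle gives none; AT gives one initial 60 mg/kg dose, then re-evaluates
weekly from the fractional change of the *target* tumor volume since the
last decision (the nontarget flank is never consulted).  The modulation
table is a reconstruction constrained by the protocol facts (initial
60 mg/kg, weekly interval, doses decaying below 3 mg/kg or omitted):
growth ≥ +10% → ×1.5 capped at 60; within ±10% → ×1.0; shrinkage ≥ 10%
→ ×0.5; doses below 1 mg/kg are omitted.  The controller keeps its
internal dose state when a dose is omitted, so treatment re-escalates on
regrowth.  Enrollment occurs when a flank first reaches 300 mm³ (that
flank becomes the target); the course ends when either flank reaches
1 440 mm³ or 20 weeks after treatment start.  The printed endpoint
"1.44 cm²" is dimensionally a volume here and is implemented as
1 440 mm³.  Events are recorded on the integer-day monitoring grid
(crossings rounded up).  The survival clock starts at injection by
default (`survival_clock="treatment"` switches to treatment start, the
convention for dose-per-day summaries).

Kaplan–Meier medians and the two-group Mantel–Cox log-rank test are
computed via lifelines; a median is reported as undefined (None) when
the survival curve never crosses 0.5.  Dose per day is cumulative dose
divided by days on study.

## Subclone tracking from copy-number profiles

Observed segment copy number in a sample with tumor purity ρ is modelled
as ρ·CN_tumor + (1 − ρ)·2; `purity_correct` inverts this (clipping
negatives with a warning).  For an emergent subclone at fraction r_t
carrying private integer alterations Δ_seg, the purity-corrected shift
from the baseline (diagnostic) profile satisfies

    shift[t, seg] = r_t · Δ_seg.

**Calling.**  A segment is resistance-specific when its final-sample
shift exceeds a threshold and the shift sequence is monotone in that
direction (tolerance for backsteps).  The stated defaults (0.1 and 0.05
CN units) act as floors: purity division amplifies segment noise
(shift SD ≈ √2·σ/ρ), so fixed thresholds would admit noise-level shifts
at low purity.  After an initial pass the shift-noise SD is estimated
from the uncalled (clonal) segments by a MAD and the effective
thresholds grow to 3σ (detection) and 1.5σ (monotonicity); at zero noise
the defaults apply unchanged.

**Estimation.**  Alternating least squares: given Δ,
r_t = ΣΔ·shift/ΣΔ² clipped to [0, 1]; given r, Δ_seg is the rounded
regression slope, forced nonzero and bounded to |Δ| ≤ 3 (subclone CNAs
are small integer changes; an unbounded integer scale lets the fit trade
scale for noise).  The iteration starts at Δ = sign(final shift), with
additional integer-scale starts (×2, ×3) to handle data that force r
past 1 at unit scale, and each fixed point is polished by integer
coordinate descent scored with re-optimized ratios, making small
instances agree exactly with exhaustive enumeration.  Exact scale
degeneracies (all data fit by (Δ, r) and (2Δ, r/2)) are resolved by
minimal Σ|Δ| (parsimony).  With few samples, inflating every |Δ| by one
notch buys the fit finer slope granularity and lowers the SSE by about
3σ² per segment purely by chance (measured on synthetic panels); a
parsimony penalty of 6σ² per unit |Δ| (σ from the clonal-segment MAD)
removes that incentive while leaving genuine signal, of order Σr_t² per
segment, untouched.  At σ = 0 the penalty vanishes and selection reduces
to exact-tie parsimony.  A patient with fewer than three samples gets a
`two_sample_unreliable` flag and a warning: with one post-baseline
sample, ongoing copy-number instability is indistinguishable from
subclone-private alteration and the ratio may be overestimated.

**Confidence intervals.**  The estimator is re-run 150 times on random
75% subsets of the called segments (without replacement).  An
m-out-of-n subsample deviates from the full-sample estimate with
variance (1/m − 1/n)s², which is *smaller* than the full estimator's own
error s²/n, so the raw 2.5–97.5 percentile band would systematically
undercover; the percentile deviations are therefore rescaled by
√(m/(n−m)) (≈1.73 at 75%) and centred on the full-sample estimate,
clipped to [0, 1].  Fewer than four called segments flag the CI as
unstable.  Empirical calibration at the validation conditions (0.05 CN
noise, 20 resistant segments, purities 0.5–0.7, true r = 0.1/0.3/0.6)
gives ~94% coverage of the nominal 95% band.

**Burden correlation.**  Subclone growth rates are per-interval
differences (r_{t₂} − r_{t₁})/(t₂ − t₁) in fraction/day, with the
diagnostic sample prepended at ratio 0 when its day is supplied; a
compare-to-baseline mode is available behind `mode="from_baseline"`
because the two definitions appear interchangeably in this kind of
analysis and per-interval is the default here.  Rates are paired with
the burden-marker value at the later time point of each interval and
pooled across patients into one Pearson correlation.

## Synthetic data generator

All generators draw from sub-streams spawned deterministically from one
seed plus a stream label (recorded in the attached ground truth), so a
config reproduces its datasets byte-for-byte.  Count noise is
multiplicative lognormal with CV 0.05 by default, with zero-mean log
noise so log-scale fits see unbiased residuals; segment noise is
additive Gaussian (SD 0.05 CN units by default).  Baseline clonal copy
numbers are drawn from an aneuploid, 2–3-centred distribution over
{1..6}; resistant deltas are drawn from {−2, −1, 1, 2} subject to
CN ≥ 0.  A configurable fraction of clonal segments ("decoys") receive a
transient perturbation in exactly one *interior* sample, emulating
unrelated copy-number instability; a perturbation in the final sample
would be indistinguishable from late-emerging resistance and is not
generated (with fewer than three samples no decoys are generated).  The
CA125-like marker is linear in the per-interval subclone growth rate
(intercept 60 kIU/L, scale 2×10⁴ per fraction/day, Gaussian SD 8) —
these constants only set the correlation strength, not its existence.

The generator emulates population sizes, measurement noise, drug
response and mixture dilution; it does **not** emulate spatial tumor
structure, passaging bottlenecks, cell-cycle or apoptosis state,
pharmacokinetics, sequencing depth or GC artifacts, or segmentation
error (segments are the atomic unit; 500 by default, smaller in tests).
Passing tests therefore demonstrate internal consistency and statistical
calibration of the estimators under the stated noise model, not
performance on real sequencing data.

## Problem sizes in the validation suite

Chosen as the package's own validation design: growth-parameter recovery
uses 200 replicates of 30 time points at 5% noise; fitness-gap recovery
40 replicates per gap in {0.02, 0.08, 0.20} doublings/day; the trial
comparison 20 seeds × 8 mice per arm; subclone recovery and CI
calibration 200 replicates of 60-segment panels (20 resistant) with 150
bootstrap subsamples each; the acceptance script reports the same
quantities at 100 replicates.

## Known limitations

- The competition model is well-mixed and non-spatial; competitive
  suppression only operates near carrying capacity, so durable adaptive
  control of tumors far below K is outside what this model can produce.
- The AT rule table is a reconstruction; absolute survival times in the
  trial engine are preset-dependent and only orderings and dose
  accounting are treated as meaningful.
- The subclone tracker assumes a single emergent subclone with a shared
  segmentation across samples and purity supplied by the caller; joint
  purity estimation and multi-subclone deconvolution are out of scope.
- ΔΔCt quantification assumes 100% amplification efficiency.
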