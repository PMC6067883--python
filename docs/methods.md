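# Methods

## Scope and data model

plethykit analyses unrestrained whole-body plethysmography (UWBP)
recordings of mouse breathing. The unit of raw data is a uniformly sampled
respiratory flow trace (ml/s, inspiration positive); the unit of derived
data is a *breath table*, one row per breath with onset, T_I, T_E, cycle
length (onset-to-next-onset), inspiratory tidal volume T_V (positive-lobe
integral), expiratory volume, and peak flows. Two analysis modes mirror the
two recording preparations: **adult** (juvenile, ~P21) and **pup**
(neonatal, ~P7), which differ in quality-control rules and protocol
lengths. All filters are flag-only: rows are never dropped, so every stage
sees the same indexing.

"Breath length" throughout (apnea rule, IBI irregularity) is the full
cycle length, onset to next onset. Post-expiratory pauses therefore count
toward a breath's length; an apnea realised as a pause after expiration is
a long breath, which is the phenomenon the apnea rule is meant to catch.
Using T_I + T_E instead would make pauses invisible.

## Breath segmentation

Breath onsets are zero up-crossings of the flow signal. Noise robustness
comes from a hysteresis amplitude `min_amplitude` (default 5× the robust
noise SD of the trace, estimated from the median absolute deviation of the
first difference): a lobe counts only if its peak magnitude exceeds the
band, and sub-band ripple can neither start nor split a lobe. Crossing
times are linearly interpolated between samples, so timing error is well
below one sample period. T_I runs from the inspiratory up-crossing to the
down-crossing, T_E from the down-crossing to the end of the expiratory
lobe; the remainder of the cycle is pause. The last breath of a trace has
no next onset, so its cycle length is T_I + T_E.

Flow sign convention is inspiration-positive; an `invert` flag accommodates
recordings with the opposite convention. A flat or sub-threshold trace
yields an empty table with a warning; NaN samples are an error.

## Quality control

**Adult filters.** A breath is excluded iff T_I < 0.03 s or T_E > 10 s
(strict inequalities; breaths exactly at a bound are retained). Minutes
whose breathing frequency exceeds 500 breaths/min are excluded as
sniffing/exploration rather than resting breathing.

**Pup rules.** A breath is accepted iff (a) peak inspiratory flow precedes
peak expiratory flow; (b) 0.005 ml ≤ T_V ≤ 1.0 ml; (c) T_I ≥ 0.02 s and
T_I ≤ 2 T_E; (d) inspiratory volume is within 50–150% of the paired
expiratory volume. Acceptance bounds are inclusive; the first failed rule
(in a–d order) is recorded as the reject reason. Rule (c) is deliberately
the physiologically sensible orientation of the pair of T_I bounds: the
opposite reading (reject when T_I *exceeds* 0.02 s) would reject
essentially every real breath, so it cannot be what a working pipeline
applies.

**RINX.** For each recording minute, the rejection index is the percentage
of the minute *not* covered by accepted breaths:
RINX = 100 × (60 − covered seconds)/60. The direction matters: minutes are
included iff RINX < 40% (strictly), and plausible recordings sit around
15–20%, which is only consistent with RINX measuring the rejected, not the
used, fraction. An animal enters the analysis iff it has ≥ 3 reliable
(RINX < 40%) minutes in room air *and* ≥ 3 during the gas challenge; group
reports give counts and nearest-integer percentages.

## Event definitions

**Sigh**: breath n is a sigh iff T_V(n) ≥ 2.5× and T_I(n) ≥ 1.25× the mean
over the previous five retained breaths (conjunction). The mean — rather
than median or every-breath — is the conventional reading of "the previous
five breaths"; both factors are configurable. Earlier sighs are excluded
from the five-breath baseline so a sigh cannot inflate the baseline of the
next one; the first five retained breaths are never sighs.

**Apnea**: breath n is an apnea iff cycle(n) > 0.5 s (strict) and
cycle(n) ≥ 2× the mean cycle of the six surrounding retained breaths
(three before, three after). Breaths without three retained neighbours on
each side are never apneas. Surrounding breaths are used as-is, events
included — the definition states no exclusion, and excluding them would
make calls order-dependent. An apnea is **post-sigh** if a sigh occurred
one or two retained breaths earlier (window configurable), else
**spontaneous**. Event rates divide counts by the analysed duration in
hours, counting included minutes only.

**IBI irregularity**: |L(n+1) − L(n)| / L(n) per consecutive retained
pair; pairs spanning a rejected breath are skipped, not bridged — bridging
would fabricate intervals that never occurred. The per-animal aggregate is
the mean (the median is also exposed); scores are invariant under uniform
time rescaling.

## Chemoresponse normalization

Protocols: adult 20 baseline / 9 challenge / 15 recovery minutes (44 in
all); pup 5 baseline / 5 challenge, no recovery. Gases: hypoxia (10% O₂)
or hypercapnia (5% CO₂, 21% O₂). Each minute's parameter (T_V, V_f or
V_E = V_f × T_V) is divided by the mean over *included* baseline minutes.
Excluded minutes propagate as NaN and are never interpolated; they also
stay out of the baseline mean, so a sniffing bout cannot contaminate the
denominator (the alternative — averaging minutes one to twenty regardless —
was rejected for exactly that reason). The normalization is exactly
scale-invariant, and the mean of normalized values over contributing
baseline minutes is exactly 1.

## Tidal-volume correction

Chamber-measured volumes are rescaled to body conditions by a
Drorbaugh–Fenn-style multiplicative gas-law factor

factor = [T_body (P_B − P_H2O,chamber)] / [T_chamber (P_B − P_sat,body)]

with temperatures in kelvin, chamber water-vapour pressure from relative
humidity × saturation pressure (Arden Buck equation) and the body assumed
saturated at core temperature. Defaults: body 37 °C, chamber 24 °C at 50%
relative humidity, 760 mmHg. The factor is 1 when body and chamber states
coincide, and the correction is linear in raw volume. This is an
approximation of the classical barometric correction, not a replication of
any specific published variant; the constants are a `CorrectionConstants`
record the caller can replace wholesale.

## Statistics

*Serial tests.* Two-tailed two-sample t-tests (pooled variance by default,
Welch optional) at each compared minute. The per-minute significance
threshold is α / m where m counts the minutes actually compared (≥ 2
animals per group after NaN removal); for the full adult protocol
m = 44 and α = 0.05 gives 0.0011. Minutes missing in either group reduce
m — the divisor follows the comparisons actually made.

*Two-way ANOVA.* genotype × treatment via an ordinary least-squares fit
with Type-II sums of squares (cell sizes in such experiments are rarely
balanced, and Type II is the standard choice when the interaction is not
the primary hypothesis; configurable). Tukey–Kramer pairwise comparisons
over the four cells run only when an omnibus effect reaches 0.05. An
all-constant response is reported as zero sums of squares with F = 0
rather than NaN. Degenerate designs (a factor with one level, a cell with
fewer than two observations) are errors naming the offending cell.

*Chi-square.* Pearson on 2×2 tables, df = 1, no continuity correction; it
equals the squared pooled-z two-proportion statistic, an identity the test
suite asserts numerically.

*t-tests.* Student by default; both-groups-constant with equal means
returns t = 0, p = 1 by convention.

## Synthetic data generator

The generator is the package's validation instrument: it emulates the
study conditions, not any measured effect size.

Cycle lengths and tidal volumes are log-normal — positive support and a
right skew, like real breathing — with defaults of 0.25 s mean cycle
(240 breaths/min), 0.15 ml tidal volume, and 10% CV, resting values for
juvenile mice. The control profile plants 25 sighs/h and 10 apneas/h
(post-sigh probability 0.3); the apnea-prone profile 60 sighs/h,
40 apneas/h, probability 0.5, with a sustained hypoxic respiratory
depression (V_f to 0.6× baseline) and a blunted hypercapnic response,
against the control's biphasic hypoxic and brisk hypercapnic curves. These
curves are qualitative phenotype shapes, chosen once; no figure-derived
number is treated as ground truth.

Two constructions make detector validation exact rather than statistical:

1. **Margins.** Planted events exceed their defining thresholds by 25%
   (sighs: 2.5 × 1.25 on T_V and 1.25 × 1.25 on T_I vs the previous five;
   apneas: cycle = max(0.625 s, 2.5 × surrounding mean)).
2. **Clipping.** Background log-normal deviates are clipped to ±2.5 σ and
   to a hard ×1.3 multiplicative band, so the worst-case ratio of any
   background breath to the mean of its neighbours is 1.3² ≈ 1.69 — below
   the 2× apnea and 2.5× sigh gates deterministically. Planted events are
   kept ≥ 12 breaths apart (post-sigh apneas excepted, at sigh + 1), so no
   event sits in another's baseline or surround window.

Recovery tests can therefore assert precision = recall = 1.0 exactly.
Waveform rendering draws each breath as an inspiratory half-sine of area
T_V and duration T_I followed by an expiratory half-sine, with lobe
samples renormalised so the discrete trapezoid integral equals the
tabulated volume exactly; remaining cycle time is zero-flow pause, plus
optional Gaussian noise. The default sampling rate is 1 kHz with unit
calibration — recording hardware parameters are not published for this
preparation, and nothing downstream depends on the choice beyond the
≥ 4-samples-per-half-wave representability bound. Artifact corruption
overwrites windows with high-amplitude broadband noise whose segmentation
products fail the pup T_I rule, driving RINX up by at least the window
fraction. Session simulation works at minute resolution: baseline minutes
fluctuate around the profile's resting values with 2% within-minute CV;
challenge/recovery minutes are multiplied by the profile's response curve.

What the generator does *not* emulate: drift and baseline wander, chamber
pressure artifacts from posture changes, temperature/humidity dynamics,
sniffing bouts with genuinely fast breathing, or breath-shape variation
beyond the half-sine. Passing recovery tests therefore demonstrates that
the detectors implement their definitions exactly, not that the
definitions themselves are robust to every real-world confound.

## Numerical conventions

- Boundary conventions are inclusive on acceptance bounds (T_V = 0.005 ml
  accepted) and strict where the defining phrase is strict ("longer than
  0.5 s"; RINX "less than 40%"; V_f "higher than 500").
- Minute indexing is 1-based, so baseline is minutes 1–20.
- Determinism: every stochastic routine takes an integer seed and uses an
  isolated `numpy.random.Generator`; identical inputs and seed give
  byte-identical outputs, and the pipeline manifest records the config
  hash and seed.
- V_E = V_f × T_V holds exactly for every emitted minute summary.

## Problem sizes in validation

The test suite and the reproduction script size their simulations for
interactive iteration: event recovery uses twenty 1-hour breath tables
(~290 000 breaths, ~1 700 planted events), segmentation round-trips use
90-second waveforms at 1 kHz, and the null calibration of the serial
scheme uses 500 simulated experiments with 8 animals per group. The
familywise error check compares the observed false-positive count against
the one-sided 99.9% binomial envelope of the nominal 5% bound — the
correct finite-sample rendering of "FWER ≤ α" for a Monte-Carlo estimate
whose true value (1 − (1 − 0.05/44)⁴⁴ ≈ 0.0494) sits just below the bound.

## Known limitations

- Vendor breath-calling (proprietary conditioning coefficients, EF50-type
  shape criteria) is not reproduced; segmentation is a transparent
  zero-crossing scheme validated on synthetic waveforms.
- Neonatal apnea/sigh scoring in the original preparations was done by a
  trained observer; here the algorithmic adult definitions are applied in
  pup mode as a stated stand-in.
- The temperature correction approximates the classical barometric
  formula; studies needing a specific published variant should substitute
  their own factor.
- Only the t-test path of the serial comparison scheme is implemented;
  per-minute ANOVA for >2 groups is not.
- Whether per-animal irregularity should aggregate as mean or median is a
  judgement call; the mean is the default and both are reported.
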