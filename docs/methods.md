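# Methods

This note documents the models, conventions and numerical choices behind
`resisleep`, and what its synthetic data do and do not establish.

## Scope and data model

The package analyzes rodent polysomnography from a social-defeat
resilience paradigm: multichannel EEG/LFP/EMG recordings (EDF), 10-s-epoch
hypnograms (`WAKE`/`NREM`/`REM`/`ARTIFACT`), social-avoidance trajectories,
and study metadata on a zeitgeber clock (ZT0 = lights on, 12:12
light:dark). Epochs are half-open, 0-based intervals anchored at the
recording start; hypnograms travel as sidecar CSV rather than embedded EDF
annotations so the signal container stays dialect-independent. Artifact
epochs are excluded from every statistic — never interpolated — and all
denominators (e.g. minutes of NREM) count retained epochs only. Whether
the <5% artifact load should be assessed per recording or pooled is left
open in the source conventions; the package reports it per recording as a
statistic, not a filter criterion.

## Behavioral phenotyping

The avoidance test is two consecutive 3-min sessions in a 30x30 cm arena
with a 9x9 cm cage at the midpoint of one wall (empty first, then holding
a novel target mouse). The interaction ratio is `int = t_f / t_e`, the
time within 15 cm of the occupied cage over the time within 15 cm of the
empty cage. Zone membership is measured to the nearest point of the cage
footprint (geometry-faithful reading of "within 15 cm of the cage");
center-distance is available as an option. Classification is strict:
`int > 1.1` resilient, `int < 0.9` susceptible, anything else undefined
and excluded from sleep analyses (but kept in behavioral summaries).
`t_e = 0` leaves the ratio undefined and flagged, never silently infinite.
Some published figure legends print the ratio inverted (`t_e/t_f`); only
`t_f/t_e` is consistent with "ratio > 1.1 = resilient", so that form is
implemented and the discrepancy is noted in the behavior module docs.

## Spectral analysis

One FFT per 10-s epoch gives exactly 0.1 Hz resolution; there is no
within-epoch Welch averaging. A Hann window with the standard power
correction is applied uniformly (the source conventions specify Hann only
for coherence; uniformity keeps epoch spectra and coherence consistent,
and the window is configurable). Spectra are one-sided densities in
signal-units²/Hz, so the band integral (edge bins inclusive) has power
units and Parseval holds against window-corrected time-domain power to
float precision. Slow-wave activity (SWA) is 0.5–4 Hz power in NREM;
theta is 6–10 Hz; "total" is 0.5–30 Hz. Figure conventions in this
literature plot "power density"; the package computes densities and
integrates to band power, with both normalizations offered: percentage of
the paired baseline day's epoch-weighted 24-h mean, or percentage of
total (0.5–30 Hz) power per bin. Zero denominators flag bins as missing.

Slow-wave energy (SWE) is the cumulative sum of (delta-band power x epoch
duration) over NREM epochs; other states contribute zero. The recovery
statistic compares cumulative recovery-day and baseline-day traces on the
same ZT grid at successive bin ends (120 min default) and reports the
elapsed time at the start of the first bin whose end satisfies
recovery >= baseline — 0 when the first bin already does, an infinite
sentinel when the window never suffices. Cumulative (rather than
instantaneous) comparison is noise-robust and matches the "time to reach
baseline levels" reading. For restriction studies the traces accumulate
from restriction *start*, so the enforced-wake deficit is part of the
recovery trace; elapsed time is reported from restriction end. This is
the only reading under which a slow-recovering animal can take many hours
to "reach baseline" despite elevated post-restriction SWA.

## Waking wave incidence (I_2-6)

Signals are band-passed 2–6 Hz with a 4th-order Butterworth filter
applied forward-backward. Zero-phase filtering preserves peak timing
against the hypnogram at the cost of doubling the effective stopband
attenuation; the single-pass variant is available. Candidate events are
negative half-waves (down-going to up-going zero-crossing pairs), with
amplitude the magnitude of the interior minimum. The retention threshold
is the 70th percentile of wake-peak amplitudes, computed once per
recording and channel over the analysis period (a global threshold;
per-window recomputation is an option since the original routine's scope
is unspecified). Retention is strict (>), so heavy ties can retain fewer
than 30%. Incidence is retained peaks per minute of wake in each bin —
wake minutes, not total minutes, form the denominator, and bins without
wake are flagged missing. The percentile threshold scales with the data,
making incidence invariant to overall signal rescaling.

## Phase coherence

Coherence between same-rate channel pairs is computed in 10-min bins of
successive non-overlapping 2-s Hann-windowed chunks (M = 300 chunks/bin,
0.5 Hz resolution), as magnitude-squared coherence:
|Σ F(x)F(y)*|² / (Σ|F(x)|² Σ|F(y)|²). This normalization is bounded in
[0, 1] by Cauchy–Schwarz, equals 1 for identical inputs, and has
expectation 1/M for independent Gaussian processes — the calibration the
tests verify. A printed formula in the source literature omits the
per-frequency normalization structure; that literal form is available
behind a flag for comparison but is not bounded by 1 and is not used.
Only per-chunk mean removal is applied; stored range is 0.5–20 Hz.
"NREM coherence" restricts to bins whose scored epochs are >50% NREM
(the state-restriction convention is ambiguous in the source; both
continuous and state-filtered modes are provided). The
coherence-vs-interaction-ratio relationship is an OLS regression of
ratios on per-animal band-averaged coherence with the F-test for nonzero
slope on (1, n−2) df.

## Statistics

Holm–Šidák step-down adjustment maintains the family-wise error rate;
paired/independent t and one-way ANOVA wrap SciPy; repeated-measures
ANOVA delegates to statsmodels' `AnovaRM` (routine statistics are
deliberately not reimplemented; an independent implementation serves as a
cross-check in the tests). The sample-size calculation uses the
two-sample normal approximation `n = ceil((z_{1-α/2}+z_{1-β})² 2σ²/Δ²)`;
with σ = 14.6 min and Δ = 25 min at α = 0.05, power 0.8 it returns 6 per
group. A noncentral-t iteration (returning 7 for the same inputs) is
offered, but the normal approximation is the default because it is the
variant consistent with study-planning practice for these inputs; the
two-sample form is used because a paired design does not yield the same
planning number cleanly.

## Synthetic data generator

The generator produces data with the statistical structure the analyses
assume; it is a testing instrument, not a biophysical model.

**State process.** A semi-Markov chain with geometric dwells: wake →
NREM; NREM → REM (p = 0.35) or wake; REM → NREM (p = 0.2) or wake. The
NREM dwell mean is a phenotype parameter (12 epochs resilient, 9
susceptible — resilient mice have the longer, less fragmented bouts).
Wake dwell means are *derived* from target sleep fractions (0.62 light,
0.36 dark) so baseline sleep amount is matched across phenotypes — a
requirement for restriction to remove similar amounts of sleep from both,
as the sleep-lost analyses assume — while bout lengths still differ.
Enforced-wake windows (ZT0–6 or ZT0–8) are filled with wake plus 2%
brief-intrusion leakage (enforced wakefulness is never perfect; the
source gives no number, 2% keeps total non-wake under the 5% invariant
together with the 1.5% random artifact labeling). After restriction,
sleep drive is transiently elevated with a linearly decaying boost over
6 h scaled by the phenotype's rebound gain (susceptible larger — the
greater recovery-sleep response). Post-defeat days move
`post_defeat_dark_sleep_shift` minutes of NREM from light to dark by
flipping whole runs (60 min resilient, 0 susceptible — the
resilient-only sleep reorganization).

**Signals.** Each channel is a sum of per-epoch-amplitude-modulated
band-limited Gaussian sources, synthesized spectrally (random-phase FFT
bins, one inverse FFT per source): delta 0.5–4 Hz (NREM-dominant), theta
6–10 Hz (REM-dominant), state-dependent broadband noise, plus discrete
negative 2–6 Hz half-waves during wake (base 25/min, lognormal
amplitudes) whose density is multiplied by `wave_incidence_gain` after
restriction ends. NREM delta amplitude follows a two-process-style
homeostat S (exponential rise toward saturation during wake, τ = 8 h;
exponential decay in NREM, τ = 2.2 h; amplitude ∝ 0.35 + 1.3 S), which
produces the declining light-period SWA and the post-restriction
rebound; rebound gains additionally scale delta amplitude for 6 h after
restriction. EEG and vmPFC-LFP channels carry separate baseline and
rebound gains because the phenotype contrasts run in opposite directions
at the two sites: susceptible mice have the higher EEG baseline SWA and
the larger EEG rebound, while resilient mice have the higher vmPFC
baseline power and the faster vmPFC SWE recovery. LFP channels mix a
shared delta source with channel-private noise; the mixing weight sets
EEG–LFP coherence and is the infralimbic phenotype knob (0.75 resilient
vs 0.45 susceptible, with per-animal spread 0.06 in cohort simulations;
prelimbic weight is common to both phenotypes, as only infralimbic
coherence tracks the behavior). EMG is state-scaled broadband noise
(high wake, low NREM, lowest REM).

**Behavior.** Avoidance trajectories are Ornstein–Uhlenbeck paths
alternating between a near-cage attractor and a far-corner attractor with
lightly jittered dwells; the near-dwell fraction of the target session is
the empty-cage fraction times a lognormal ratio target (post-defeat
medians 1.6 resilient, 0.55 susceptible; pre-defeat 1.0). Effect sizes in
signal or behavioral units are nowhere quantified in the source
literature, so all defaults were calibrated once to reproduce the
qualitative group directions, never animal-level numbers.

**What passing tests show.** Synthetic recordings have stationary
Gaussian band structure, memoryless dwells, and artifact epochs that are
random relabelings rather than genuine interference. Real recordings
have 1/f backgrounds, movement artifacts correlated with state
transitions, scorer disagreement, and electrode drift. Passing tests
establish that the implementations compute their definitions correctly
and that the pipeline recovers structure of the kind it targets at
realistic effect sizes — not that any biological claim generalizes.

## Problem sizes

Cohort-level evaluations use scaled-down but structure-preserving sizes,
chosen as the package's own desk-scale defaults: signals at 100 Hz (all
modelled content is below 30 Hz; epoch-FFT and coherence resolutions
depend only on epoch/chunk duration), 24-h days for sleep-architecture
and SWE analyses, 20-min recordings for coherence cohorts, 20
cohorts/seed-pairs of 16 mice (8 per phenotype) for recovery checks, and
1000 permutations for the regression calibration. Acquisition-faithful
rates (400 Hz EEG, 2 kHz LFP) work identically and are the defaults for
file-backed workflows.

## Known limitations

- The generator's dwell distributions are geometric; real bout-length
  distributions are heavier-tailed.
- The homeostat is shared across channels of a class; regional
  homeostasis is reduced to two fixed gain pairs.
- Coherence control by linear source mixing ignores phase lags; only
  magnitude-squared coherence is modelled, not directionality.
- Automated sleep staging is out of scope: hypnograms are inputs
  (ground truth when simulated, scored files otherwise).
- EDF support is plain 16-bit EDF; EDF+ annotations and vendor dialects
  are not read.
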