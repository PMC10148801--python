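# Methods

This note records the statistical procedures implemented by `adaptmtl`, the
modeling choices behind the synthetic-data generator, and the numerical
conventions that make results reproducible. It is written for a reader who
wants to know exactly what each number produced by the package means.

## Conventions

All spike times are continuous milliseconds relative to stimulus onset.
Every analysis window is half-open, `[start, end)`, so sample membership is
unambiguous at any sampling rate. Firing rates are Hz = count / window
length. Two response windows are deliberately distinct and kept as separate
named constants: the z-score *activation* window [100, 1000) ms and the
tuning / response-criterion window [0, 1000) ms; the baseline window is
[−500, 0) ms. All statistical tests are two-tailed.

## Task structure and the sequence generator

A session is 10 runs; each run presents all 100 stimuli (10 categories × 10
exemplars; 5 manmade and 5 natural categories) once as target, preceded by
one extra leading image that is discarded from analysis. A target is
*primed* when the preceding image shares its semantic category. Across a
session every stimulus must be primed on exactly 5 of its 10 presentations.

The generator is constructive rather than rejection-based. Each stimulus is
first assigned its primed runs (a random 5-of-10 choice, re-drawn if some
category would need all its exemplars primed within one run, which would be
unrealizable). Within a run the stimuli of each category are grouped into
consecutive same-category blocks: block leaders realize control
presentations, later block members primed ones. Blocks are ordered with no
two same-category blocks adjacent by shuffle-plus-local-search with bounded
restarts; exhausting the attempt budget raises an explicit error — the
constraints are never silently relaxed. A built-in checker verifies every
invariant (permutation per run, prime column = preceding presentation, no
self-priming, condition consistent with category match, exact 5/5 condition
counts) and is itself exercised against hand-corrupted tables.

## Reaction-time and accuracy model

RTs follow a shifted lognormal, `RT = shift + exp(N(mu_c, sigma))`, with the
condition effect additive on the law's median. Defaults: control median
713 ms, primed advantage 109 ms, shift 250 ms, `sigma` 0.35, error rates
2.0% (control) and 0.6% (primed). The medians and error rates are the
session-level values the analyses are expected to reproduce; shift and
sigma are conventional values giving realistic right skew (they are not
estimated from data). Note the analysis summarizes sessions by *mean* RT,
and the mean of a lognormal exceeds its median, so recovered session-mean
medians sit ~15–20 ms above the law medians — an expected property, not a
bias. A configurable fraction of trials (default 2%) is replaced by planted
outliers drawn 3.2–6 SD from the mixture mean (80% slow lapses, 20% fast
anticipations, floored at 50 ms), flagged in a ground-truth column so the
±2.5 SD exclusion rule can be scored. Correctness is Bernoulli per
condition.

The RT outlier rule follows the analysis definition exactly: per session,
M and SD are computed over *all* of that session's target trials (conditions
pooled), and a trial is excluded iff it lies outside M ± 2.5 SD. Because an
extreme trial inflates the SD it is judged against, a single outlier in a
very short session can survive the rule; the tests assert this faithful
behavior rather than an idealized one. Sessions with fewer than 2 trials
raise (SD undefined). The behavioral contrast is a Wilcoxon signed-rank
test over per-session condition means (the session is the unit of
observation); incorrect trials are excluded from RT averaging by default
(configurable). The response-priming control drops control trials whose
prime belongs to the other manmade/natural meta-category before averaging.
Signed-rank tests use the normal approximation with `zsplit` zero handling
so fully degenerate inputs (all differences zero) yield p = 1 rather than an
error; at least 6 sessions are required.

## Single-unit generator

Each unit is an inhomogeneous Poisson process: baseline rate `b` (default
5 Hz) everywhere except a response window `[onset, onset + duration)`
(defaults 300 ms + 600 ms), where the rate is `b × gain(stimulus)`. A small
set of *tuned* stimuli — drawn from one semantic category, so primed and
control presentations of a response-eliciting stimulus differ only in prime
category — carries non-increasing gains, default (10, 7, 5, 4): a graded
"semantic tuning curve" rather than an all-or-none response, with all four
tuned stimuli reliably detectable by the response criterion at 10 trials
and α = 0.001 (a weaker tail, e.g. gain 2, is statistically invisible at
this trial count and would empty the ≥4-responsive-stimuli selection that
the tuning analysis is defined on). Mechanisms modulate primed trials only:
fatiguing multiplies all tuned gains by `1 − attenuation`; sharpening
multiplies only gains at ranks ≥ 2; facilitation multiplies the response
*duration* instead; `none` does nothing. Default attenuation 0.3. An
optional pre-stimulus gain on primed trials emulates spreading activation
for power analyses of the pre-stimulus test (default 1.0 = none).

Spike trains are sampled per trial from the piecewise-constant rate
(Poisson counts per segment, uniform times within segments), stored as one
concatenated sorted array with per-trial offsets. Same seed → byte-identical
output.

What the generator does *not* emulate: spike waveforms and sorting noise,
cross-trial rate drift, bursting/refractory structure within the Poisson
process, carry-over of the previous trial's response into the next trial's
baseline window, overlap between the neural populations coding prime and
target beyond the gain rules, and any coupling between units or between
units and the iEEG signal. Passing tests therefore show the *statistics*
behave as designed under their own assumptions, not that real MTL data meet
those assumptions.

## Response criterion (binwise rank-sum + Simes)

Spikes are counted in 19 overlapping 100 ms bins (aligned 0–1000 ms, offset
50–950 ms). For each bin, a two-sided rank-sum test compares the 10
per-trial rates of the stimulus against the distribution of baseline rates
of all trials. The baseline distribution is computed in 100 ms bins tiling
[−500, 0) ms — the same bin width as the test bins. This length matching is
essential: rate distributions from windows of different lengths differ in
shape even at identical mean rate (a 100 ms bin at 3 Hz is zero on 74% of
trials; a 500 ms window on 22%), so a rank-sum of bin rates against
whole-window rates rejects under a homogeneous Poisson null for over half
of all unit–stimulus pairs. With matched bins the test is exchangeable
under the null and the measured false-positive rate is ~0.2–0.3% of null
pairs at 3–5 Hz baseline (mildly above 1% only at ≤1 Hz, where the normal
approximation strains against extreme discreteness).

The rank-sum uses the normal approximation with tie correction and
continuity correction, verified element-for-element against
`scipy.stats.mannwhitneyu(method="asymptotic")`; because the baseline
sample is shared by all 1900 tests of a unit, the statistics are computed
with two `searchsorted` passes against the sorted baseline rather than full
re-ranking. Criterion (a) is the Simes global test over the 19 p-values at
α = 0.001 (reject iff any sorted p(i) ≤ i·α/19; valid under the positive
dependence of overlapping bins); (b) mean [0, 1000) ms rate above the mean
baseline rate; (c) ≥ 1 spike in the response window in at least half of the
stimulus' trials. A stimulus is response-eliciting iff all three hold.

## Tuning curves, rank contrasts, and the profile classifier

Units with ≥ 4 response-eliciting stimuli (configurable to 2 or 3) enter
the tuning analysis. Per unit, stimuli are ranked by descending mean rate
in [0, 1000) ms pooled over conditions, ties broken by stimulus id (stable,
deterministic). Primed and control per-rank means (5 trials each) are both
normalized by FRmax, the control rate of the rank-1 stimulus, so the
control curve is 1 at rank 1 by construction; FRmax = 0 excludes the unit
with a warning. Per rank 1–4, primed vs control is tested with a paired
t-test (with 95% CI) and a Wilcoxon signed-rank test, both reported.
Between-rank contrasts of attenuation (control − primed) are computed in
absolute normalized units and *relative* to the control value at each rank;
the relative form is what distinguishes shape-preserving from
shape-changing reductions. A unit × rank × condition table can be exported
for external ANOVA.

The population profile classifier operationalizes the mechanism
definitions. Sharpening means non-optimal stimuli are *disproportionally*
attenuated while the optimal stimulus is spared; fatiguing means
attenuation at the optimal stimulus is at least proportional. The label is

* `sharpening` iff the rank-2 contrast is significant with primed <
  control, the relative attenuation is significantly stronger at rank 2
  than rank 1, **and** at least twice as strong;
* `fatiguing` iff the rank-1 contrast is significant with primed < control
  and the sharpening signature is absent;
* `indeterminate` otherwise.

Two deliberate asymmetries: a *negative* attenuation gradient (stronger at
rank 1) never disqualifies fatiguing — it is the fatiguing direction by
definition — and the sharpening signature demands a material (≥ 2×) ratio,
not just statistical detectability, because the estimated rank ordering
leaves small systematic gradients of either sign even under a purely
proportional reduction (the [0, 1000) ms window includes ~400 ms of
unattenuated baseline firing, and order statistics of noisy pooled rates
bias the top ranks). At study scale (88 amygdala-like sharpening units, 123
MTL-like fatiguing units, attenuation 0.3) the classifier recovers the
generating mechanism in ≥ 95% of replicate cohorts and labels no-mechanism
cohorts indeterminate in ≥ 90%.

## Burst analysis

For units with estimated baseline rate above 2 Hz, per-trial response
extent is the contiguous spike run (≥ 3 spikes) in [0, 2000) ms maximizing
the Poisson surprise `S = −log10 P(≥ k spikes in T | baseline rate)`,
accepted when `S ≥ 2` (threshold configurable; the exhaustive run search
makes acceptance on homogeneous trains threshold-controlled — ~48% of null
trials at S ≥ 2, <1% at S ≥ 6). Onset/offset are the run's first/last
spike. At or below 2 Hz, where run statistics are uninformative, the
first spike in [100, 1000) ms gives a latency only (no duration). The
duration contrast across units compares per-unit median durations primed vs
control, restricted to each unit's response-eliciting stimuli so that
no-response trials do not dilute the estimate.

## iEEG path

Raw traces (continuous with onsets, or per-trial epochs at a native rate
≥ 512 Hz) are resampled to 256 Hz (`resample_poly`, rational ratio, line
padding), bandpass-filtered 0.1–80 Hz with a zero-phase order-2 Butterworth
(forward–backward; phase preservation protects the latency analyses; ≥ 20 dB
at 100 Hz after both passes), segmented to [−1000, 2000) ms and
baseline-corrected by subtracting the [−200, 0) ms mean. Epoched inputs are
demeaned before filtering: the 0.1 Hz corner is slow relative to a 4 s
epoch, and the DC step would otherwise leave a transient inside the
segment. Events whose segment would cross a recording edge are dropped with
a warning.

Artifact rejection applies two rules to the full segment set with no
iterative re-computation, OR-combined (both thresholds are derived from the
same input set, so application order is irrelevant): segment max-ratio
> 2.5 against the median of absolute maxima, and segment
median-absolute-sample ratio > 2.5 against the median of those medians. The
inequality is strict, so a constructed ratio of exactly 2.5 is retained.
ERPs are per-condition arithmetic means over clean segments; a grand
average over session ERPs is provided. Peak latency is the signed extremum
inside a half-open window (ties → earliest sample; flat windows warn and
return the first sample), compared across sessions with the signed-rank
test.

The ERP simulator is a sum of Gaussians (default: −8 at 270 ms, +10 at
500 ms, −3 at 900 ms, FWHM 120/240/500 ms) scaled and latency-shifted per
condition (defaults: primed ×0.8, −16 ms), plus 1/f noise of configurable
SD (default 4, same units as the template) generated by spectral shaping.
Artifacts multiply a random 200–400 ms span by a factor (default 10) at a
configurable rate with ground-truth flags. The simulator produces either
analysis-rate segments directly or wider raw epochs at a native rate for
the preprocessing path. It does not emulate line noise, electrode drift,
channel-specific spectra, or any dependence between the iEEG and the
simulated units.

## Cluster-based permutation statistics

A paired t-test runs at every sample; samples with zero difference variance
get t = 0, p = 1 with a warning. Clusters are maximal runs of consecutive
samples with p below the cluster-forming α (default 0.001) and a common
t-sign (mixed-sign runs split — summed t of a mixed run is uninterpretable).
The permutation null swaps condition labels independently per pair,
implemented as sign flips of the difference traces; per permutation the
maximum positive and minimum negative cluster sums are recorded (0 when no
cluster forms) — the max-statistic convention, which controls familywise
error. An observed positive cluster is significant iff its sum strictly
exceeds the 99th percentile of the positive-tail null (mirrored for
negative clusters); a Monte-Carlo p-value `(1 + #{null ≥ observed}) /
(1 + n_perm)` is reported alongside, since a percentile decision alone
cannot be compared across n_perm. When `n_perm ≥ 2^n_pairs` the null is
computed by exhaustive sign-flip enumeration with a warning. The
permutation t-statistics are vectorized (the second moment of the
differences is sign-invariant), which makes calibration studies cheap:
measured familywise rate under the null is ~1.8–4% against the nominal ~2%
implied by the two 1% tails, and a 100 ms effect at 10× noise SD is
detected essentially always.

## Pipeline and reproducibility

`RunConfig` holds every constant (windows, α levels, permutation counts,
generator parameters, cohort composition) with validation at load time;
analysis constants default to the study values (cluster α 0.001, 1000
permutations, criterion α 0.001, ≥4 responsive stimuli, 200–400 / 400–750 ms
latency windows, 2 Hz burst cutoff). One global seed is expanded through
`numpy.random.SeedSequence` into per-stage, per-session, per-unit streams,
so stages can be rerun in isolation. The JSON report embeds the package
version, the resolved configuration and its SHA-256 hash, and the seed;
identical (config, seed) pairs produce byte-identical reports. Units are
simulated against the first session's trial table — the unit analyses need
one realized sequence, and pooling units across simulated sessions would
only replicate the same generative law.

## Problem sizes in the test suite

The suite validates at the sizes the statistics are designed for while
staying desk-scale: 50 sessions for sequence constraints; 300 null datasets
(20 pairs × 768 samples, 500 permutations) plus 100 power replicates for
cluster calibration; 1000 random instances against the brute-force cluster
enumerator and 10⁵ vectors against the brute-force Simes rule; 30 null
units (3000 unit–stimulus pairs) and 50 planted responses for the response
criterion; 40 replicate cohorts per mechanism at 88/123 units for
mechanism recovery; 100 cohorts of 59 sessions for the behavioral
contrast; 59 sessions for peak-latency recovery. The default `run_all`
configuration (12 sessions, 24 + 32 units) is sized for interactive use;
all counts are configuration, not statistical necessities.

## Known limitations

* The rank-sum normal approximation is slightly anticonservative for very
  sparse units (≤ 1 Hz baseline); an exact test is not provided.
* The Poisson-surprise search scores runs by their realized extent, which
  biases surprise upward for selected runs; the acceptance threshold is
  therefore a tuning knob, not a calibrated p-value.
* Tuning analyses assume exactly balanced 5/5 condition splits per
  stimulus, as the paradigm guarantees; unbalanced designs are not handled.
* The profile classifier is a decision rule for population-level summaries;
  it does not attribute mechanisms to individual units.
* iEEG preprocessing assumes already-referenced traces; re-referencing and
  channel selection are upstream, data-curation concerns.
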