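# adaptmtl

Analyses for distinguishing single-neuron mechanisms of **neural
adaptation** — *sharpening*, *fatiguing*, and *facilitation* — in a semantic
priming task with simultaneous intracranial EEG and single-unit recordings
from the human medial temporal lobe (amygdala, hippocampus, entorhinal and
parahippocampal cortex), together with a synthetic-session generator so
that every stage of the pipeline can be validated without patient data.

## The problem

In the paradigm, participants view runs of 100 images (10 semantic
categories × 10 exemplars, half manmade / half natural) and make a
manmade/natural decision for each. Sequences are arranged so that each
image is preceded half the time by an image of the *same* category
(**primed**) and half the time by a *different* category (**control**).
Behavioral adaptation shows up as faster reaction times on primed targets;
neural adaptation as reduced event-related potentials (ERPs). Three
single-neuron accounts could produce that macroscopic reduction:

* **sharpening** — a neuron keeps firing to its optimal stimulus but
  disproportionally reduces firing to non-optimal stimuli;
* **fatiguing** — firing is reduced proportionally to all
  response-eliciting stimuli, preserving the tuning-curve shape;
* **facilitation** — the *duration* of firing shortens on primed trials.

The package implements the statistics that separate these accounts:

* **behavior** — per-session RT outlier exclusion (mean ± 2.5 SD), Wilcoxon
  signed-rank contrasts of per-session mean RT and accuracy, with an
  optional control for response priming (dropping control trials whose
  prime affords the other motor response);
* **ieeg** — resampling to 256 Hz, zero-phase 0.1–80 Hz bandpass,
  segmentation to [−1000, 2000) ms, baseline correction over [−200, 0) ms,
  two median-ratio artifact filters (threshold 2.5), per-condition ERPs,
  and peak-latency contrasts (negative peaks in 200–400 ms, positive in
  400–750 ms);
* **cluster_stats** — sample-wise paired t-tests with cluster-based
  permutation inference: clusters are maximal sign-homogeneous runs with
  p < 0.001, scored against the 99th/1st percentile of per-permutation
  extreme cluster t-sums from paired label swaps (1000 permutations, exact
  enumeration for small n);
* **spikes** — firing-rate z-scores against the [−500, 0) ms baseline law,
  the binwise response criterion (rank-sum tests in 19 overlapping 100 ms
  bins with a Simes correction at α = 0.001, plus rate- and
  spike-presence conditions), semantic tuning curves normalized to the
  control-condition rate of the top-ranked stimulus (FRmax), per-rank
  primed-vs-control contrasts with a population profile classifier,
  Poisson-surprise burst detection (first-spike latency below 2 Hz
  baseline), and the pre-stimulus spreading-activation test;
* **synth** — generators for stimulus sets, constraint-satisfying trial
  sequences, shifted-lognormal RTs with planted outliers, inhomogeneous-
  Poisson spike trains with graded tuning under a configurable ground-truth
  mechanism, and ERP-like segments with pink noise and injected artifacts;
* **pipeline** — a declarative `RunConfig`, deterministic seed fan-out, and
  `run_all` producing a single reproducible JSON report.

## Worked example

```python
from adaptmtl.pipeline import RunConfig, run_all
from adaptmtl.synth import MechanismSpec, PopulationGroup

config = RunConfig(
    n_sessions=8, n_perm=500,
    cohort=(PopulationGroup("AM", 24, MechanismSpec(mechanism="sharpening")),
            PopulationGroup("HC", 32, MechanismSpec(mechanism="fatiguing"))),
)
report = run_all(config, seed=7)

rt = report["stages"]["behavior"]["all_trials"]["rt"]
print(f"RT primed {rt['median_primed_ms']:.0f} ms vs control "
      f"{rt['median_control_ms']:.0f} ms (signed-rank p = {rt['pvalue']:.3f})")
for c in report["stages"]["ieeg"]["clusters"]:
    if c["significant"]:
        print(f"cluster {c['start_ms']:.0f}-{c['end_ms']:.0f} ms, size {c['clustersize']}, "
              f"sum t = {c['sum_t']:.1f}, p = {c['p_mc']:.3g}")
pl = report["stages"]["ieeg"]["peak_latency"]["early_negative"]
print(f"early negative peak: primed {pl['median_primed_ms']:.1f} ms vs "
      f"control {pl['median_control_ms']:.1f} ms (p = {pl['pvalue']:.3g})")
for group, t in report["stages"]["spikes"]["tuning"].items():
    ps = ", ".join(f"rank {r['rank']}: p = {r['pvalue']:.2g}" for r in t["ranks"])
    print(f"{group}: profile = {t['profile']} ({ps})")
```

prints

```
RT primed 624 ms vs control 728 ms (signed-rank p = 0.012)
cluster 246-367 ms, size 31, sum t = 538.9, p = 0.00778
cluster 410-684 ms, size 70, sum t = -1286.2, p = 0.00389
cluster 938-969 ms, size 8, sum t = 59.5, p = 0.0117
cluster 984-1020 ms, size 9, sum t = 63.7, p = 0.0117
early negative peak: primed 252.0 ms vs control 265.6 ms (p = 0.0112)
AM: profile = sharpening (rank 1: p = 0.45, rank 2: p = 6.3e-12, rank 3: p = 5e-10, rank 4: p = 1.3e-09)
MTL: profile = fatiguing (rank 1: p = 2.8e-17, rank 2: p = 5.6e-11, rank 3: p = 9.6e-14, rank 4: p = 2.3e-10)
```

Reading the output: primed targets are answered ~100 ms faster; the ERP
difference forms an early positive and a later negative cluster (the
primed ERP is flattened in both directions relative to control); the early
negative ERP peak arrives ~14 ms earlier on primed trials; and the
tuning-curve rank contrasts recover the generating mechanism of each
simulated population — in the amygdala-like cohort the rank-1 (optimal)
stimulus is spared while ranks 2+ are attenuated (sharpening), whereas in
the hippocampus-like cohort all ranks are attenuated proportionally
(fatiguing).

A command-line interface mirrors this:

```bash
adaptmtl simulate --config cfg.yaml --seed 1 --out sessions/   # write CSV/HDF5 sessions
adaptmtl analyze  --config cfg.yaml --seed 1 --out run/        # write run/report.json
```

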