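# Methods

This note documents the models, conventions and numerical choices behind
`calseize`, in the spirit of a package's statistical methods appendix.

## Signal model and ΔF/F₀

A recording is a single whole-brain fluorescence trace per larva, sampled
uniformly (default 1.33 Hz, 1 h).  Multi-ROI tables are supported; the
whole-brain signal is one designated column or the column mean
(`PipelineConfig.roi`).  The baseline F₀ at frame *k* is the
`baseline_percentile`-th percentile (default 1) of the raw values within a
window of `baseline_window_s` seconds centred on *k* and truncated — not
padded — at the recording edges, so no data are fabricated at the
boundaries.  Percentiles use linear interpolation between order statistics
(the common default).  A trailing-window mode exists because the original
edge-handling convention of such analyses is rarely stated; both modes are
covered by the same brute-force oracle in the tests.  A window longer than
the recording degrades to a single global percentile with a warning; a
window whose fluorescence is entirely non-positive is an error, since
ΔF/F₀ = 100·(F−F₀)/F₀ is undefined there.  The 150 s default suits
ordinary activity; 300 s is used for seizure recordings, whose long ictal
plateaus would otherwise drag the percentile upward.

Scaling the raw fluorescence by c > 0 scales F₀ by c and leaves ΔF/F₀
unchanged (tested).

## Event tiers

An event is a maximal run of frames with ΔF/F₀ strictly above a threshold
("above 5%" excludes equality); its onset is the first supra-threshold
frame, its offset one sampling interval after the last, amplitude the
maximal ΔF/F₀ in the run.  No minimum duration, hysteresis or refractory
period is imposed.  Events touching a recording edge are kept and flagged
truncated.

Tier membership ("above 5%", "above 10%") is decided by peak amplitude on
the events detected at the lowest tier.  This is deliberate: re-detecting
boundaries at each tier's own threshold (available as `tier_mode="rerun"`)
can split one low-tier event into several high-tier runs, so tier counts
would not be nested — amplitude classification guarantees
count(≥10%) ≤ count(≥5%) on every trace, which is what "number of events
above X%" means here.  A `band` mode ([5, 10)%) supports sensitivity
analyses.  The hypoactivity exclusion filter removes events with amplitude
> 50% AND duration > 20 s (the literal conjunction; an OR mode is
selectable), and can never remove an event of amplitude ≤ 50% in AND mode.

AUC is the trapezoidal integral of ΔF/F₀ over time (%·s), exact for
piecewise-linear traces; windowed AUC integrates each half-open window and
averages.  Per-larva AUC is normalised by the control-group mean.

## Seizures and alignment

Candidate seizures are runs above the 50% boundary; a candidate qualifies
when its maximum reaches the 100% peak threshold (inclusive).  Onset/offset
are the boundary crossings; a run still above the boundary at the end of
the recording is kept, flagged truncated, measured to the trace end, and —
because its duration is a lower bound — excluded from duration statistics
by default while still counting toward seizure numbers and seizing
fractions.  A larva "exhibits seizures" iff at least one is detected; the
seizing fraction is 100·n_seizing/n_total, rounded to the reporting
precision requested (2 decimals by default, 1 where conventional).

For overlays every seizure is aligned at the first frame reaching
`align_fraction` (default 0.5) of its own maximum.  Segments cover
[align − pre_s, align + post_s) (defaults 0 and 400 s, long enough for
multi-minute seizures), NaN-padded outside the recording.  The mean and
SEM are computed per time point over contributing traces; SEM uses the
n−1 normalisation and is defined as 0 where a single trace contributes.
Per-seizure AUC integrates the aligned segment with NaN gaps as 0; time to
peak runs from the segment start to the maximum.  Aligning an
already-aligned single trace reproduces it, and SEM scales as 1/√n for
i.i.d. noise (both tested).

## Group statistics

Continuous measures use the two-sided Wilcoxon–Mann–Whitney test: the
exact null distribution when the smaller group has ≤8 observations and the
pooled sample is tie-free, otherwise the normal approximation with
mid-ranks and tie correction.  The reported effect is the difference of
medians (second group minus first).  Counts use a negative-binomial (NB2)
regression of count on a group indicator with log link, coefficients and
dispersion estimated jointly by maximum likelihood; the effect is the rate
ratio e^β with a Wald p-value (a likelihood-ratio option exists).  When
the dispersion estimate collapses to the zero boundary the NB information
matrix is singular; the model then reduces to Poisson, and the
implementation falls back to a Poisson GLM Wald test, recording a warning
in the comparison.  Degenerate data (an all-zero group, perfect
separation) yield the empirical rate ratio with p = 1 and an instability
flag rather than an exception, keeping batch runs deterministic.
Shapiro–Wilk results are attached for transparency but do not switch the
test — the pipeline stays nonparametric for continuous measures.  No
multiple-testing correction is applied; comparisons are reported
individually, as is conventional for per-figure panel tests.

## qPCR

Technical replicates are averaged per sample × gene before any
differencing.  The per-sample reference value combines the three reference
genes; the arithmetic mean of reference Cts equals −log₂ of the geometric
mean of their expression levels 2^(−Ct), so the two exposed aggregation
modes (`mean_ct`, `geomean_expression`) are algebraically identical —
both are kept for interface clarity.  ΔCt = Ct_target − Ct_ref,
ΔΔCt = mean ΔCt(case) − mean ΔCt(control), fold = 2^(−ΔΔCt); perfect
doubling is assumed once dilution-series efficiencies
(E = 10^(−1/slope) − 1, acceptable within [0.9, 1.1]) have been verified
equal.  An efficiency-corrected mode uses per-gene bases (1+E) and the
geometric mean of reference levels; with E ≡ 1 it coincides with ΔΔCt.
Fold changes are invariant to a constant Ct offset (instrument shift) and
to reference-gene permutation, and noiseless panels generated with any
true fold change f return f to machine precision (all tested).

## Synthetic data

The generator composes, on a positive baseline B with slow sinusoidal
multiplicative drift, a percent-scale kernel sum S(t):
F = B·(1+drift)·(1+S/100) + ε, ε ~ N(0, σ²), clipped at 0.  Multiplicative
composition keeps a kernel of configured amplitude A at exactly A percent
ΔF/F₀ wherever the baseline estimator tracks B.  Transients rise linearly
over `rise_s` and decay exponentially with time constant `decay_s`; the
decay tail is truncated once it falls below 0.5% ΔF/F₀ so that quiet
frames sit exactly at baseline — this makes the percentile baseline exact
on noiseless traces and keeps every threshold crossing analytically
available (up-crossing t₀ + rise·thr/A; down-crossing
t₀ + rise + τ·ln(A/thr)).  Seizure kernels add a plateau and either an
"abrupt" linear fall or a "tapering" slow exponential decline, emulating
the rapid resolution of control seizures versus the minutes-long tapering
seen when galanin signalling is removed.  Kernels are placed by rejection
sampling with a minimum gap (so tails die out between events and the
closed forms stay valid) and event kernels avoid seizure supports; at high
rate × duration products this overlap-avoidance thins the realised count
below the nominal Poisson draw, so rate parameters should be read as
nominal intensities, accurate in the sparse regime the defaults occupy.
Per-larva generators are spawned from a root seed, so one seed fully
determines a cohort and permuting group labels permutes outputs without
hidden coupling.

Defaults mirror the experimental conditions: 3600 s at 1.33 Hz, small
events 5–10% and large events 10–50% ΔF/F₀, seizures ≥100% with gradual
onset, 1% additive noise, 5% drift.  Where a quantity is not dictated by
those conditions (kernel time constants, drift period, Ct noise), values
were chosen once as field-typical and are documented in the dataclasses.
The generator emulates trace phenomenology, not biophysics: it does not
model photon noise, motion artefacts, GCaMP indicator kinetics/saturation,
network dynamics or spatial structure.  Passing detection-recovery tests
therefore demonstrates correctness of the algorithms under the stated
signal model, not robustness to every artefact of real recordings.

Exact-recovery guarantees hold for the noiseless, drift-free
configuration; with noise and drift enabled, detection near threshold is
necessarily statistical (noise can split or add crossings), which is why
group-level claims are always made within a single noise model.

## Problem sizes and determinism

The test suite and the acceptance script use shortened recordings
(120–1200 s) and modest cohort sizes; every algorithm is
length-invariant, and the defaults retain the full 1-h study conditions.
Pipeline runs are deterministic given inputs and config: reports are
byte-identical across reruns with one seed.  For that reason the run
manifest records per-stage record counts always but wall-clock timings
only on request (`include_timing=True`).

## Known limitations

- Tier semantics, window centering and percentile interpolation are
  conventions where the field's scripts differ; all are configurable and
  the defaults are stated above.
- The negative-binomial Wald p-value is anti-conservative at very small n;
  the LRT option is preferable below ~10 animals per group.
- Truncated seizures bias duration and AUC downward if included; they are
  excluded from duration tests by default but retained in counts.
- The ΔΔCt model assumes shared amplification efficiency; use the
  efficiency-corrected mode when dilution series disagree.
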