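# Methods

## Data model

The unit of analysis is a *bout*: one uninterrupted series of barks from
a single individual, annotated as onset/offset times in seconds on the
recording timeline. Onsets must be strictly increasing; two events with
the same onset are rejected rather than merged, since silently merging
would bias the inter-onset intervals. Raw annotations keep absolute
times; every metric re-zeroes to the first onset, so all indices are
translation invariant by construction. The study design assumed
throughout is one bout per individual, two age classes (adult, pup).

Raven Pro selection tables are accepted in their standard export
dialect (tab-delimited, one row per selection per view). Rows that
duplicate a selection across spectrogram/waveform views are deduplicated
by the `Selection` id. The required columns are matched by their exact
Raven names `Begin Time (s)` / `End Time (s)`; all other columns are
preserved as opaque metadata. Times are treated as a continuous
timeline; the event-CSV round trip preserves six decimals, beyond
millisecond-level annotation precision.

## Indices

Definitions as in the README. Numerical conventions that the formulas
alone do not fix:

* **Unbiased CV** uses the n−1 sample standard deviation and the
  correction factor (1 + 1/(4n)) with n = number of values. It is
  reported as a fraction, not a percentage.
* **nPVI** uses the standard 100-scaled pairwise form. A pair summing to
  zero contributes 0 (the limit of the formula). This matters for nPVI
  of beat-precision values, where exact zeros are common (the first
  element is always on beat); for the same reason beat-precision values
  below 1e-9 are snapped to exactly 0 — the nPVI term is discontinuous
  at a zero pair (0 for (0,0), maximal for (0, ε)), so round-off noise
  must not masquerade as an off-beat element.
* **Integer ratios** are computed over consecutive interval pairs,
  r_k = IOI_k/(IOI_k+IOI_{k+1}), the construction under which isochrony
  gives 0.5.
* **Beat precision** divides the nearest-beat deviation by T/2 by
  default, making the index span [0, 1] with 1 the worst case (midway
  between beats); `normalization="period"` divides by T instead. The
  template is anchored at the first onset and the phase is not
  optimised: the first element scores 0 by construction and is included
  in per-bout summaries by default (`include_first=False` drops it).
  Both conventions are exposed, and the pipeline's `convention_sweep`
  option reports all four combinations, because the source convention
  for this family of goodness-of-fit scores is not standardised.
* **Minimum bout length** is 3 events (2 IOIs), the smallest size at
  which CV, nPVI and ratios are all defined; shorter bouts are excluded
  with a logged reason.
* All computation is double precision; rounding to 2 decimals happens
  only at presentation.

## Template period under beat dropout

The beat frequency index is f = 1/mean(IOI), and for a bout with a bark
on every beat the template period 1/f is the natural choice. Under beat
dropout, however, mean IOI overestimates the period (an interval
spanning two ticks counts double), which would misalign the template,
inflate beat precision for sequences with silent beats, and misclassify
doubled intervals as off-grid. The template period is therefore
estimated robustly by default: seed with the median IOI (robust while
multi-beat intervals are a minority), assign each IOI its nearest
integer multiplicity within the silent-beat tolerance, refine the period
as Σ(on-grid IOIs)/Σ(multiplicities), iterate twice. With no dropout
every multiplicity is 1 and the estimate equals the mean IOI exactly, so
the two template choices coincide on fully voiced bouts. The literal
`template_period="mean-ioi"` alternative is kept for comparison. The
estimator fails gracefully but is not magic: if most beats are skipped
(median IOI itself a multiple of the period) the seed locks onto a
multiple of the true period.

**Silent beats** are counted per interval: multiplicity m = round(IOI/T)
if |IOI/T − m| ≤ tol and m ≥ 1, contributing m − 1; otherwise the
interval is flagged off-grid, contributes nothing, and is logged. The
default tol = 0.25 (quarter period) is far above the jitter level of
adult-like sequences (CV ≈ 0.08), so near-isochronous intervals are
never misclassified, while still separating m from m+1 unambiguously.

## Statistical stage

Element-level variables (all IOIs, all integer ratios, pooled across
individuals) are compared with Welch's unequal-variance t-test; this
pooling ignores within-individual correlation and the output labels it
as such. Per-sequence indices (one value per bout) use the Mann-Whitney
U test: exact null distribution when both groups have ≤ 20 values and no
ties, normal approximation with tie correction otherwise. The headline
statistic is the U of the first (adult) group, the same number R's
`wilcox.test` prints as W; the complementary U is also reported
(U_a + U_b = n_a·n_b). All tests are two-sided. No multiple-testing
correction is applied: each comparison uses a different dependent
variable, so no group is tested twice.

Beat precision is regressed on beat frequency by OLS (statsmodels),
pooling both classes. The mixed model of beat precision on mean bark
duration uses a random intercept per age class, fitted by REML
(statsmodels MixedLM). With only two grouping levels a random slope
would be unidentifiable and singular fits (zero random-intercept
variance) are common; they are flagged, not treated as failures.
Fixed-effect p-values from the mixed model are Wald z, and the report
names this; small-sample df corrections (Satterthwaite, Kenward-Roger)
are not applied. Both model reports include scaled residual quantiles
(residual/σ̂); for a numerically perfect fit (σ̂ ≈ 0) raw residuals are
reported instead.

## Synthetic bouts

The generator emulates a bout as a jittered isochronous point process
with dropout: grid b_k = kT, each beat voiced independently with
probability p (beat 0 forced voiced — a bout starts with a bark), voiced
beats displaced by Gaussian jitter truncated to (−T/2, T/2) so that
jitter can never reorder events or detach an onset from its generating
beat. Durations are normal, truncated to (0, 0.9T). Jitter is
phase-coupled (about the fixed grid), matching the assumption behind the
beat-precision construct that a stable underlying template exists; an
accumulating random-walk variant is available behind
`jitter_model="random-walk"` for sensitivity analysis, and produces the
high beat-precision values (≈ 0.5) typical of drifting real sequences.

Preset regimes:

| preset | T (s) | σ (s) | p | beats per bout | durations (s) |
|--------|-------|-------|-----|---------------|----------------|
| adult  | 0.31  | 0.017 | 1.0 | uniform 8–25  | 0.12 ± 0.03 |
| pup    | 0.35  | 0.020 | 0.85| uniform 6–20  | 0.12 ± 0.03 |

Periods and the dropout contrast express the observed regimes (adult
bouts isochronous with interval CV ≈ 0.08 at ≈ 3.2 Hz; pup bouts slower,
more variable, with skipped beats). The jitter SDs are calibrated via
sd(IOI) = σ√2 on the grid model so the adult preset reproduces CV ≈
0.08; this is a calibration of the generator, not a measured quantity.
Bout-length ranges are declared conveniences — no bout-length
distribution is implied by the data.

What the generator does **not** emulate: tempo drift within a bout,
correlated jitter, amplitude/spectral structure, inter-individual
period variation beyond bout length, or behavioural context. Passing
tests on synthetic data therefore certify the estimators and the
pipeline plumbing under the stated point-process model, not the
empirical values of any wild population; in particular real sequences
appear to drift, which raises beat precision far above the
phase-coupled model's values.

## What the acceptance script computes

`scripts/acceptance.py` simulates one 17-vs-17 study (the design's
sample size) at the presets, runs the full pipeline on it, and reports
the per-class index means, the group-test statistics, and both
regression fits; then, by Monte-Carlo: recovery of the adult beat rate
(≈ 3.23 Hz) and unbiased CV (≈ 0.08) over 1000 bouts, the
dropout dissociation (nPVI increase vs. beat-precision shift), the
empirical type-I error of both group tests over 5000 null datasets at
n = 17 vs 17, and the power of the CV comparison over 200 replicate
studies. Problem sizes are chosen so the whole script runs in well under
a minute on one core while keeping Monte-Carlo error small relative to
the effects measured.

## Known limitations

* The period estimator assumes single-beat intervals are the majority.
* Pooled element-level tests ignore within-individual correlation
  (flagged in output).
* With two random-intercept levels the mixed model is frequently
  singular; its Wald-z p-values are anti-conservative at small n.
* Beat precision saturates near 0.5 for drifting sequences, compressing
  differences between strongly non-isochronous regimes.
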