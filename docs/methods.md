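# Methods

## The measurement model

Each synthetic object emulates one run of a six-sensor metal-oxide array
over a caged sample of worker bees: a 600-s exposure phase sampling the
headspace above the object, then a 600-s regeneration phase on filtered
ambient air, one reading per second per sensor. The generator's signal
model is deliberately the simplest one consistent with the analysis'
assumptions (rapid stabilization, additive device and insert offsets,
per-second noise):

    exposure[t, s]     = B[d, s] + I[m, s] + A[c, s] · (1 − e^(−t/τ_r)) + ε
    regeneration[t, s] = B[d, s]           + A[c, s] · e^(−t/τ_d)       + ε

with `t = 1..600` (1-based seconds), device baseline `B`, insert odor shift
`I` (absent during regeneration, which draws air through a carbon filter),
class plateau amplitude `A`, and `ε ~ N(0, σ²)` i.i.d. The class-1
amplitude row is the zero vector by construction: an empty chamber emits no
odor, so class-1 recordings on two devices differ exactly by the baseline
difference — the anchor for the baseline-correction checks.

### Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| τ_r (rise) | 40 | s | satisfies e^(−270/τ_r) < 0.01, so the signal is stabilized at the 270-s feature reference |
| τ_d (decay) | 40 | s | symmetric with the rise; leaves a small, exactly computable amplitude carry-over in the regeneration mean |
| σ (noise) | 1% of max amplitude | sensor units | visible but small per-second noise; recomputed from the amplitude matrix if not given |
| amplitudes | O(20–80) | sensor units | the source study reports no raw magnitudes (the device data are proprietary), so scales are conventions chosen once |
| baselines | O(100), devices differ by 5–12 | sensor units | same convention; device offsets large relative to noise so correction matters |
| n_per_class | 10 | objects | ten objects per class per device/insert run, the study's design |

A scalar **separation** knob (in `GeneratorConfig.default`) rescales the
class-5/6/7 amplitude vectors about their common mean: `separation = 1` is
the stated default (cleanly separable), values near 0 collapse the
odor-emitting classes into near-indistinguishability. Class 1 stays at zero
amplitude regardless, so it remains trivially separable — only the 5/6/7
structure is tunable.

Per-object noise seeds are derived from `(seed, device, insert, class,
replicate)` through `numpy.random.SeedSequence`, so any subset of the study
is reproducible without global RNG state.

### What the generator does *not* emulate

Sensor chemistry (heater power, humidity, ppm response curves), drift
across days, channel switching, warm-up, and any correlation structure in
the noise. A green synthetic-recovery test therefore establishes that the
pipeline's arithmetic behaves as designed on data with the assumed
structure — not that the published accuracies on the proprietary recordings
are reproduced. Those printed values are checked only for internal
arithmetic consistency (balanced accuracy vs per-class accuracies, column
extrema vs the quoted best/worst spreads).

## Feature extraction

The descriptor of sensor *s* is the raw exposure reading at the 1-based
reference second `t_ref = 270` (a trailing window mean is available but
defaults to width 1, since the method names a single reference second).
Baseline differential correction subtracts an ambient-air reference taken
from the object's **own regeneration phase** — the only 600-s ambient record
per measurement — aggregated as the arithmetic mean over all 600 s. The
phrase describing the reference ("the values from the last 600 s of the
ambient air measurement") is plural, implying aggregation; the mean is the
noise-robust reading, and a single-last-reading alternative is exposed as
`regen_stat="last"`. In the noiseless limit the corrected descriptor is

    A·(1 − e^(−270/τ_r)) + I − A · mean_t e^(−t/τ_d)

— device-free, which is exactly what the inter-device tests assert.

## Class signatures

Per attribute, all rows of a table (classes pooled) are min-max normalized
into [a, b] = [0, 1]; class means are taken on the normalized values and
squared. Degenerate ranges (max = min) map every value to `a` by
convention. Squaring preserves the per-attribute ordering of the
non-negative class means; the signature is invariant to positive affine
rescalings of any raw attribute because the normalization absorbs them.

## Classifiers

Ten classifiers, named `m1..m10` in the study's order: `{canberra,
euclidean, manhattan, maxminnormalized} × {1nn, 811}` plus `eps=0.01.nb`
and `eps=0.01.nb2`.

- **Distances.** Canberra terms with denominator 0 (both coordinates zero)
  contribute 0. The `maxminnormalized` metric is Euclidean distance on
  coordinates mapped by `(v − min)/(max − min)` using the *training-table*
  extrema; constant attributes map to 0 and out-of-range test values are
  not clipped.
- **811 weighted voting.** The original rule lives in an inaccessible
  reference, so this package commits to a documented convention: every
  training row votes for its own class with weight `1/(d + δ)`, δ = 1e−10.
  When the query coincides with a training row the singular vote dominates
  and the rule converges to 1-NN, which the tests assert.
- **ε-indiscernibility NB.** Per attribute and class, the fraction of the
  class's rows within `ε · range` of the query; `nb` sums the six
  fractions, `nb2` weights the sum by the class prior `|c|/N` (the study
  never defines the distinction; the prior weighting is this package's
  convention, kept behind one function so it is replaceable). A constant
  attribute degenerates to exact equality.
- **Ties** (equal distances, vote sums, or scores) resolve to the lowest
  label, numeric labels before merged rest-labels — full determinism for
  regression tests.

## Evaluation

"5×MCCV5" is realized as 5 groups × 5 repetitions = 25 independent
stratified random splits; the split percentage is not stated in the source,
so `test_fraction` defaults to 0.5 and is configurable (printed accuracies
are therefore not point-reproducible even apart from the proprietary data).
Per class, `round(test_fraction · n_class)` rows go to test; every class
must land on both sides. The same plan is reused for all classifiers, and
baseline-corrected options (V–VIII) reuse the plan seeds of their
uncorrected twins (the correction flag is simply not part of the seed
derivation), so correction effects are paired comparisons.

Per split: per-class accuracy = correct/size; balanced accuracy = unweighted
class mean (identity enforced to 1e−12); "true positive rate" of class c =
correct_c / predicted-as-c, defined as 0 when nothing is predicted c (the
source is silent; this avoids undefined divisions at this scale); coverage
is identically 1 because every classifier is total. Split records are
averaged arithmetically.

## Numerical and design choices

- The normalization interval printed ambiguously as "[0.1]" is read as
  [0, 1], matching the (b − a) form of the normalization formula.
- Signature normalization extrema pool all classes, since the formula
  references attribute-wide min/max.
- CSV readings serialize with 6 decimals; round-trip tests tolerate the
  resulting 5e−7 quantization.
- Seeds derived from the user seed stay within uint32.

## Known limitations

- The 811 and nb/nb2 conventions are this package's committed readings of
  underspecified originals; results for those four classifiers are
  convention-dependent.
- Synthetic amplitudes/noise are conventions, not estimates of the real
  device; only orderings and qualitative effects (insert, device, baseline
  correction) transfer.
- Two rows of the published Option-I results table are internally
  inconsistent as printed (their per-class entries appear displaced); the
  consistency tests document and exclude exactly those two rows.
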