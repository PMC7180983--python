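# Methods

## Signal model

A 30-s chair–stand recording is a uniformly sampled back-to-backrest distance
trace: 10 Hz, ~300 samples, sitting baseline around 15 cm, standing excursions
commonly up to 50 cm. Sample *i* occurs at exactly *i*/rate seconds (0-based);
the time column in signal CSVs is advisory, sample order is authoritative,
because the sensor emits at a fixed 100-ms cadence. Raw recordings are finite
and non-negative; the missing marker (NaN, serialized `NA`) appears only after
preprocessing.

## Moving filters

Both detectors use centered sliding windows that shrink at the edges and skip
missing values; a window with no finite member yields the missing marker.
Window lengths in seconds are converted to samples by rounding and promoting
even counts to the next odd count so the window has a symmetric center
(0.7 s @ 10 Hz → 7 samples; 4 s → 41). Centered (rather than trailing)
windows avoid a phase lag that would bias every event time by half a window.
The median of an even number of finite values is the mean of the two central
order statistics. Implementation rides on `pandas.Series.rolling`; the test
suite holds it to an independent brute-force per-index window scan, exactly,
over randomized sequences with and without missing values.

## Algorithm v1 — moving median + peak thresholds

1. Outlier reset: readings > 70 cm (far beyond any upright distance) are set
   to 15 cm, a typical sitting distance.
2. 0.7-s moving median.
3. Strict local maxima of the filtered trace; a plateau contributes its first
   index.
4. Adaptive merge: PDT = DF × median gap (in samples) between consecutive
   maxima; chains of maxima with successive gaps < PDT collapse into one
   peak (height = maximum of the group, index = its argmax, earliest on
   ties). The gap median is computed over **all** maxima before any merging —
   the only reading that avoids a circular definition (the merge radius would
   otherwise depend on its own output). With fewer than two maxima the PDT is
   undefined and no merging occurs.
5. Validation: peaks with filtered height > PHT are counted.

All comparisons are strict (> 70, > PHT). Defaults DF = 0.5, PHT = 30 cm were
fixed by grid calibration on synthetic annotated signals (the calibration
module reproduces the procedure) and are exposed via config/CLI.

## Algorithm v2 — moving minimum + adaptive sitting–standing threshold

1. Outlier nulling: readings > 99 cm become NaN. A recording whose every
   sample is nulled is rejected as unusable.
2. 0.7-s moving minimum → the envelope of local minima. A one-sample spike is
   invisible to it as long as one finite neighbor remains in the window.
3. SST = movmin₄ₛ + ATW·(movmed₄ₛ − movmin₄ₛ) computed on the preprocessed
   signal with 4-s windows; ATW = 0 gives the moving minimum, ATW = 1 the
   moving median.
4. Binary standing signal: filtered > SST, with any missing comparison
   evaluating to sitting (a nulled outlier must never create a standing
   state). Stand-up events are rising edges; an initial standing state at
   t = 0 is not an edge, because the test scores completed stand-ups.
5. Merge cascade, in order: edges closer than MPD (seconds) merge into one
   peak; peaks whose above-threshold extents are separated by fewer than
   MSBP samples merge; peaks whose **filtered-envelope** maximum does not
   exceed MSD (cm) are discarded.

Defaults ATW = 0.5, MPD = 1.0 s, MSBP = 5 samples, MSD = 25 cm, set by the
same synthetic calibration.

### Peak summary: two heights, one purpose each

The MSD validity check reads the *filtered envelope* maximum over the peak's
extent: spurious spikes cannot inflate it, so a noise bump near the sitting
baseline cannot smuggle itself past the validity threshold. The *reported*
event height and index are the NaN-aware maximum of the preprocessed signal
over the extent — the highest actual reading the subject produced — with the
argmax as the event index (first index on ties). Reading the reported summary
off the filtered trace instead would make event tuples sensitive to nulled
outliers: removing a window's unique minimum (any sample on a monotone ramp)
raises the moving-minimum output there, shifting run boundaries by a sample.

A stronger statement is not achievable: *no* event-index convention is exactly
invariant to outlier injection, because the injected spike destroys the
information at its sample, and whichever sample a tie-break or boundary
convention is anchored to can be the one destroyed (the first sample of a
standing plateau, the threshold-crossing sample, a trapezoid knee under
interpolation — each has a one-spike placement that moves the index by one).
What holds, and what the tests assert over hundreds of randomized trials, is
that injected isolated >99-cm samples never create or destroy an event and
never move one by more than a single sample period (0.1 s).

The MSBP distance is measured between above-threshold extents (the number of
consecutive sitting-state samples separating two peaks) rather than between
argmax indices; besides being the natural reading of "samples between peaks",
this absorbs one-sample resurgent runs that can appear just after a falling
ramp when an outlier was nulled mid-descent.

## Calibration

`calibrate()` reproduces the tuning procedure: an exhaustive grid over the
detector's thresholds, scored by mean **absolute** count error against
manually annotated signals. A signed mean error would reward cancelling
over- and under-counts and was rejected. Ties break first on the magnitude of
the mean signed bias, then on grid order; a detector failure on a signal
scores as that signal's full annotated count (worst case) rather than
aborting the search. The scikit-learn `fit` method of the detector estimators
wraps exactly this search.

## Reliability and classifier statistics

Agreement between the manual count and an algorithm is ICC(A,1) — the
single-rater, absolute-agreement, two-way model: with subject, rater and
residual mean squares MSR, MSC, MSE from the n×2 two-way ANOVA,

ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),  k = 2.

The 95% CI uses the F-bounds with Satterthwaite degrees of freedom; the
significance test is F = MSR/MSE on (n−1, (n−1)(k−1)) df. The implementation
is an explicit mean-squares computation, cross-checked in the tests against
pingouin's ICC and an independently written sums-of-squares oracle (agreement
to 1e-10). Interpretation bands are left-closed: [0, 0.5) poor, [0.5, 0.75)
moderate, [0.75, 0.9) good, [0.9, 1] excellent — the left-closed convention
makes 0.86 read "good" and 0.50 read "moderate". Each result carries the
point-estimate band and a "supported" band classifying the CI lower bound:
the level of reliability the data actually guarantee. A rating table with
zero total variance has no defined ICC and is rejected with an error.

Normative classification maps a score to below-average (< 25th percentile),
average (25th–75th, inclusive at both ends — the worked examples do not
discriminate the boundary, so inclusion is a documented convention), or
above-average (> 75th) for the subject's gender and age band. The shipped
band table is a synthetic, user-replaceable fixture consistent with the
canonical worked examples; it is not a reproduction of any published table.
Subjects whose gender or age is unknown cannot be classified and are excluded
with a warning, mirroring how such subjects must be dropped in practice.

Classifier performance against the no-information rate (NIR, the most-common
class frequency — 0.75 in the motivating cohort) reports: accuracy, exact
Clopper–Pearson 95% CI, a one-sided exact binomial p-value for accuracy >
NIR, Cohen's h = 2·asin√acc − 2·asin√NIR, and the power of the one-sample
proportion test by the arcsine-transform normal approximation,
power = Φ(h·√n − z₀.₉₅); at h = 0 the power equals α by construction.

## Synthetic data: what it emulates, and what it does not

One sit–stand–sit cycle is a trapezoid: sitting dwell, linear rise (default
0.5–0.6 s) to the standing plateau, standing dwell, linear fall. A
distance-vs-time trace between a torso and a backrest genuinely dwells at
both extremes, which a sinusoid would not capture. Ground truth records every
cycle's stand-up time and validity exactly; detector tests compare against
it, never against eyeballed counts.

Generator features, with defaults chosen once as the simulated test conditions:

* **Readings are quantized** (0.5 cm in the cohorts) — ultrasound rangers
  report discrete range bins. Quantization is what keeps a low-noise standing
  plateau genuinely flat after median filtering, so the young regime presents
  one local maximum per cycle, as smooth real recordings do.
* **Invalid attempts**: a cycle truncates at 40 cm (not fully upright) with
  per-cycle probability `invalid_rate` (3.3% in the older cohort, ~11 invalid
  per ~330 transitions spread over a handful of subjects).
* **Spikes** are narrow (one sample) with a clean reading between consecutive
  spikes, arriving as a Poisson process of bursts with geometric sizes;
  spikes within a burst share a base height (one artefact source → similar
  echo range) jittered ±8 cm, drawn from a range straddling the 99-cm
  ceiling so both outlier-handling branches are exercised. The young regime
  uses sparse isolated spikes (0.1 burst/s, size 1); the older regime uses
  0.5 burst/s with mean size 4 over a 0.8-s span. This geometry is exactly
  what lets dense bursts dominate a 0.7-s median window (≥4 of 7 samples)
  while a 0.7-s minimum always finds a clean sample — solid spike blocks
  would defeat the minimum too and contradict the observed behaviour the
  regimes encode.
* **Elevated sitting baseline**: per-dwell sitting levels rise by a uniform
  offset (`baseline_cm`) when a subject does not lean back fully; ~10% of
  older-cohort subjects draw offsets of 8–16 cm. When filtered minima exceed
  ~30 cm, the SST can sit above a shallow sitting dwell and merge adjacent
  cycles — the documented one-event-miss failure mode.
* **Cadence**: young subjects draw periods of 1.9–2.6 s (~12–15 cycles per
  test), older subjects 2.4–3.8 s (~8–12 cycles, mean score ≈ 11, the
  clinical scale for this population).

All randomness flows from one seed; cohorts derive per-subject seeds by
counter, so generation is bit-reproducible.

What the generator does **not** model: chair motion, posture-specific echo
geometry, sensor beam physics, or any biomechanical model of the sit-to-stand
movement — it encodes observed signal features, not mechanisms. Passing tests
therefore demonstrate that each algorithm behaves as designed under the
documented noise regimes, not that it meets any particular accuracy on real
clinical recordings.

## Numerical and design choices

* Strict inequalities at every threshold (> 70 cm, > 99 cm, > PHT, > MSD).
* Plateau local maxima report their first index; argmax ties break earliest.
* Problem sizes in the test and acceptance runs (100 clean signals, 200
  spike trials, 50-signal cohorts, 1000 oracle tables) were sized to give
  stable verdicts across seeds while keeping a full run around half a
  minute.
* Parameter defaults are honest package defaults, not fitted clinical
  values: the original tuned DF/PHT/ATW/MPD/MSBP/MSD were never published,
  so defaults were re-derived by the package's own calibration procedure on
  synthetic fixtures.

## Known limitations

* No real human recordings ship with the package; the end-to-end reliability
  run in
  `scripts/acceptance.py` operates on a synthetic older cohort and is
  descriptive of the generator + detector pair, not of the device.
* The CI for ICC(A,1) is asymptotic in the Satterthwaite sense and can be
  wide or degenerate for n < 5 subjects; the rating-table type enforces
  n ≥ 2 and flags zero-variance tables rather than guessing.
* Algorithm v1 deliberately implements the historical behaviour, including
  its documented fragility to clustered artefacts; it is retained as the
  comparison baseline, not as a recommended counter.
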