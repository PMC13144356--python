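# Methods

This note documents the models, parameter choices and numerical conventions
behind `whistlekit`, and what its synthetic-data tests do and do not show
about field recordings.

## Problem and pipeline

Several delphinids produce *repeated stereotyped whistles*: narrow-band
tonal calls whose frequency-modulation pattern (the contour) recurs many
times in a recording, often in bouts, and which may carry identity
information analogous to bottlenose dolphin signature whistles.  The
pipeline identifies and characterizes such types from single-channel
recordings in six stages:

1. **simulate** — generate a ground-truth repertoire (and optional audio);
2. **extract** — spectrogram, tonal peak tracking, fragment merging,
   duration filter, SNR classing;
3. **categorize** — unsupervised contour categorization by adaptive
   resonance over dynamic-time-warping (DTW) similarity, run globally or
   within each visual type ("sequenced");
4. **agree** — confusion tables, dominant-category agreement, Hungarian
   label-matched pairwise agreement, Cohen's and Fleiss' kappa;
5. **bouts** — repetition, bout segmentation and inter-whistle-interval
   (IWI) statistics;
6. **features** — seven acoustic parameters per contour and a
   correlation-matrix PCA with Kaiser retention.

## Whistle definition and extraction rules

A whistle is a tonal trace of at least 100 ms (inclusive boundary).
Consecutive fragments separated by strictly less than 200 ms form one
contour when the pattern is continuous across the junction: frequencies
within 2 kHz *and* mean peak powers within 12 dB (pieces of one whistle
share its source level; chance noise-peak runs sit just above the
tonality threshold and must not be glued onto a nearby strong whistle).
The gap is bridged by linear interpolation.  Extraction is automatic
single-peak tracking: per spectrogram frame the strongest bin is a
candidate if it exceeds the frame median by the tonality threshold (6 dB
default), and candidates link across frames while the jump stays within
1 kHz/frame.  This is a deterministic stand-in for interactive,
human-edited contour extraction; it cannot separate overlapping whistles
(the stronger peak wins), which is documented rather than guessed around.

A per-frame median threshold cannot by itself reject wide-band noise: the
maximum over ~1000 noise bins sits ~10 dB above the frame median by order
statistics alone.  Rejection instead comes from persistence — chance
peak-link runs are short and never survive the 100 ms duration filter —
and the guaranteed property is *zero contours from whistle-free noise*,
verified over a minute of synthetic noise.

Spectrogram defaults are FFT 2048, Hann window, 50% overlap, 2–25 kHz
band, PSD scaling (`onesided2X`, so band-integrated power equals signal
power).  SNR classes quantify the qualitative high/medium/low grades as
mean peak-over-median excess along the trace: >= 15 dB high, >= 6 dB
medium, else low.  These two thresholds are invented quantifications and
are config-exposed.

## DTW similarity

Aligned frequency pairs score `100 * min(f, g) / max(f, g)`; contour
similarity is the **mean** local score along the best admissible warp
path.  The warp factor `W` (default 3) bounds local stretching: a point of
either contour may align with at most `W` points of the other (at most
`W - 1` consecutive single-sequence steps).  A uniform stretch up to
factor `W` with unchanged frequency values therefore aligns perfectly;
beyond `W` no full alignment exists and similarity is reported as 0.
Because path length varies, maximizing the mean is a fractional objective;
it is solved exactly by Dinkelbach iteration over an additive dynamic
program (numba-compiled) and verified against exhaustive path enumeration
on all pairs of up to 8 points.  Ties prefer the diagonal step, so
alignments are deterministic.  Contours are compared on a common 5 ms
sampling grid, finer than any contour feature at the analysis bandwidth.

## Adaptive-resonance categorization

Parameters: vigilance 96.00 %, warp factor 3, bias 1e-6, learning rate
0.1, at most 100 iterations.  Each presented contour computes its
similarity to every category reference, scans categories by descending
activation (similarity + bias x reference length, the ART "choice"
tie-breaker; at bias 1e-6 it only matters for exact ties) and joins the
first whose raw similarity reaches vigilance, else founds a new category.
On joining, the member is warped onto the reference path and each
reference point moves `learning_rate` of the way toward the mean aligned
member frequency; reference length moves toward the member length at the
same rate, with linear re-sampling.  Presentation order is ascending
contour id on every pass (determinism); the first pass initializes the
assignment and is not counted, and the run converges when a counted pass
reassigns nothing.  Empty categories are deleted at pass end.  Singleton
pruning is a reporting-stage option used by the global analysis.

These internals are a contract-level stand-in: the activation and update
formulas of the original MATLAB implementation are not published in the
source study, so this package fixes explicit, testable definitions with
the same stated parameters rather than chasing bit-compatibility.

## Agreement statistics

Judges and the categorizer use free label vocabularies, so labels are
first aligned one-to-one by maximum overlap (Hungarian assignment on the
confusion table); pairwise agreement is the matched fraction, and Cohen's
kappa is computed on the matched tables (unmatched labels stay distinct).
Fleiss' kappa uses the standard item x category count formulation.
Dominant-category agreement is `100 * max(split)/n`, rounded half away
from zero — the convention under which the consistent published splits
reproduce their printed percentages; two published rows (D: 10/1 of 11
printed 90, O: 17/25 of 42 printed 59) are inconsistent with any single
rounding rule and are excluded from assertions.  Outlier raters are
flagged when their mean pairwise agreement with the others falls more than
2 group-SDs below the group mean.

## Bouts and IWIs

A type is repeated when >= 3 successive whistles occur with every
onset-to-onset gap <= 30 s (sliding per-gap reading, not a fixed tiling;
the alternative is expressible via the window parameter).  Maximal such
runs are bouts.  IWIs are onset-to-onset (onset is the only timestamp all
contours share after merging) and are summarized both within bouts and
over whole per-type series.  The distribution summary restricts to
IWIs <= 60 s, with half-open classes [0.3, 4), [4, 10), [10, 60] and a 1-s
histogram whose first bin spans [0.3, 1); the fraction above 60 s is
reported separately.

## Acoustic features and PCA

W_dur is `(n_points - 1) * dt`; F_min/F_max/F_start/F_end/F_mean/F_range
follow directly from the trace.  PCA standardizes the seven variables and
decomposes the correlation matrix (the variables mix seconds and kHz, so
covariance PCA would be unit-dominated; a covariance option exists).
Components are ordered by decreasing eigenvalue, the dominant loading of
each component is made positive (eigenvector signs are arbitrary), and
retention follows the strict Kaiser rule (eigenvalue > 1).  Category
ellipses (centroid + 2-SD axes from the 2x2 score covariance) are drawn
only for labels with more than 20 members.

## Synthetic repertoire generator

The generator emulates the structure of a three-day encounter series:

- **Templates.**  Up to 50 piecewise-linear contour types across five
  shape families (upsweep, downsweep, stepped, multi-inflection, flat),
  frequencies confined to 1.9–16.1 kHz (the span of observed parameter
  ranges).  Candidates are rejection-sampled until every pairwise DTW
  similarity of noiseless renders stays below 94 %, a margin under the 96
  vigilance.  Frequency steps inside stepped templates are capped at
  1.8 kHz, below the 2 kHz merge-continuity bound, so a tracker split at
  the discontinuity remains re-joinable — the generator only plants
  whistles that the extraction rules can recover as single contours.
- **Exemplars.**  Per-segment durations get independent lognormal warps
  (log-SD 0.08) and the trace a smooth frequency offset (SD 0.05 kHz,
  4-knot interpolation).  Measured on 100 default-jitter pairs,
  within-type similarity stays >= 96 % (typically ~99) and between-type
  similarity < 96 % (typically < 90) — the separability contract that
  makes exact planted-category recovery a fair acceptance test.  Field
  repertoires need not be this separable; the published sequenced analysis
  itself shows types splitting under the same vigilance.
- **Timing.**  IWIs are lognormal(mu = 1.42, sigma = 1.01) truncated at
  0.3 s — moment-matched to a 6.9 +/- 9.2 s mean/SD with mode near 1.5 s —
  floored so consecutive whistles never overlap.  Whistles come in bouts
  (default size 3–20) separated by 35–90 s gaps; bouts of different types
  are scheduled sequentially, so no two whistles overlap in time
  (single-peak tracking could not recover overlaps anyway).  Background
  non-repeated whistles are singleton types (truth label `noise`)
  inserted at ~1/min.
- **SNR.**  Classes are drawn from the repeated-whistle mix of the source
  inventory (11.5 % high / 47 % medium / 41.5 % low) and realized at
  synthesis as per-class spectrogram SNR targets of 26 / 13 / 5 dB over
  the noise floor of a 2048-point Hann analysis window; the classes are
  generator-side amplitudes, not post-hoc estimates.
- **Audio.**  Phase-continuous FM tones (no harmonics; the analysis
  concerns fundamental contours) with 5 ms cosine ramps over white
  Gaussian noise, default 96 kHz.  Temporal gaps inside stepped templates
  are bridged in the trace, mirroring the merge rule, rather than rendered
  as silence.

Default scale is 8 types with 3–20 exemplars over 3 days — deliberately
desk-scale; the full published dataset (25 types, 1015 repeated whistles,
262 min of audio) is represented by packaged count-table fixtures, not
regenerated.  All randomness flows from one seed through named
substreams, so every artifact is a pure function of the configuration.

## Numerical conventions and degenerate inputs

- Resampling preserves both endpoints exactly and uses the nearest point
  count to the requested spacing (exact spacing whenever the duration is a
  multiple of it).
- Similarity of unalignable pairs (length ratio beyond the warp bound)
  is 0; `dtw_align` raises instead, so callers can distinguish.
- Contour CSVs write floats with `%.17g` and parse with round-trip float
  precision: write -> read -> write is byte-identical.
- Empty IWI input yields an empty-summary marker, not an error; an empty
  contour set, incomplete rating table, degenerate kappa (p_e = 1) and
  constant PCA columns raise typed errors.
- Selection tables use Hz and seconds (Raven convention); everything
  internal is kHz and seconds.

## Known limitations

- Single-peak tracking cannot disentangle simultaneous whistles; the
  generator avoids overlaps, so end-to-end tests do not probe that case.
- SNR class thresholds and the extraction thresholds are explicit
  quantifications of what was a human judgment in the original workflow.
- The categorizer is order-deterministic by construction; sensitivity to
  presentation order (unknown for the original tool) is not modeled.
- Low-SNR whistles (5 dB synthesis target, 6 dB tonality threshold) are
  mostly not recovered from audio — intended, as recovery guarantees
  apply to high-SNR whistles only.
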