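# Methods

## The data format

Files are HDF5. Each root-level group is one unit of time-aligned data and
carries at least one of:

- `data` — a `samples × channels` float64 matrix (time is the first axis);
- `timespans` — an `N × 2` float64 array of `[start, end)` intervals, with an
  optional parallel string dataset `labels` naming each interval's condition;
- `timestamps` — an `N` float64 vector of event times.

All times are seconds on a single axis with 0 = recording start; intervals
are half-open so adjacent blocks never double-count a boundary sample. Group
metadata lives under `props`, one HDF5 dataset per property, camelCase
names. Only `title` and `type` are required; `type` is a controlled but
user-extensible vocabulary (`schema.yaml`) naming the recording modality or
the behavior/stimulus kind. `props/roi/*` and `props/stats/*` are arbitrary
named arrays dimension-matched to `data`; `props/preprocessing/text` holds
free-text provenance; root-level `fileHeader` holds experiment description
and subject attributes.

Validator severities: broken contracts (missing `title`/`type`, `roi`/`stats`
shape mismatch, inverted or non-finite intervals, a group with no datasets,
duplicate group names) are errors and block writing; advisory findings
(unknown property or type names — with a case-insensitive suggestion for
near-misses like `SamplingRate`, a data group without `samplingRate`, more
channels than samples, an empty file) are warnings. Reading is available in
two modes: strict (structural errors raise, naming the group and field) and
best-effort (model plus violation list), so search and visualization can
still operate on imperfect files. The grouping advisor recommends one group
for data sharing time span, sampling rate and kind, and separate groups
otherwise; it is symmetric and reflexive.

One `data` matrix per group is assumed. The shipped property vocabulary is a
minimal plausible set and is explicitly extensible via a custom schema file.

## Feature extraction

Windows are non-overlapping, laid from t = 0; a window holds
`round(duration × samplingRate)` samples and the trailing partial window is
dropped. Defaults: durations {0.5, 1, 1.5, 5} s, band 60–100 Hz. Per window
and channel, band power is the sum of magnitude-squared raw FFT coefficients
over bins whose center frequency lies in [60, 100] Hz, both edges inclusive.
No taper or detrending is applied: the procedure is deliberately minimal,
the DC bin lies outside the band, and per-channel z-scoring (population
denominator, ddof = 0, configurable to sample) absorbs any normalization
constant. Parseval sanity: summing magnitude-squared rfft coefficients over
all bins, counting interior bins twice, equals `N·Σx²`.

A channel whose band power never varies across windows (e.g. a dead
electrode) has no z-score; its column is set to zero and flagged rather than
NaN so downstream correlations stay defined. Durations yielding fewer than
two windows are skipped (z-scoring undefined). Only groups typed ECoG or EEG
are featurized; every other type is an annotation source.

## Similarity, significance, index

Similarity between two windows is the Pearson correlation of their length-n
feature vectors (n = channel count — the only sample size available for the
per-pair correlation). Significance is the two-tailed p-value of
t = r·√((n−2)/(1−r²)) under Student's t with n−2 degrees of freedom, exact
under normality; r = ±1 maps to p = 0 and a constant vector to a "no
similarity" sentinel treated as never significant. α = 0.05, two-tailed,
no multiple-testing correction, exposed as configuration.

A pair enters the index iff r > 0 and p ≤ α. Per query window, significant
targets are run-length encoded as maximal consecutive spans, each holding
its start index and per-window p-values; the on-disk sidecar stores, per
timescale, CSR-style row pointers plus the two aligned lists (run starts,
concatenated p-values with run lengths). Both directions of each unordered
pair are stored — O(1) row lookup at the cost of 2× space. The self pair is
stored and returned by default (flag to drop it). When a timescale has at
most 2048 windows the raw correlation matrix is kept on the index for
programmatic use.

Queries resolve to the largest timescale ≤ the query length; queries shorter
than the smallest timescale clamp to it (the rule is otherwise undefined
below 500 ms). The query row is the grid window containing the query start
(floor division; boundary times belong to the window starting there).

## Synthetic sessions

The generator emulates a block-design sensory session on a 32-channel array
at desk scale. Defaults, chosen once: 1000 Hz sampling, forty 1.5 s blocks
cycling A/rest/B/rest (60 s total), gamma amplitudes A = 2.0 and B = 2.5 on
overlapping half-array channel subsets (channels 1–16 and 9–24 of 32), gamma
drawn per block and channel uniformly from 60–100 Hz (80 ± 20) with random
phase, over unit-amplitude 1/f background noise, seed 1. The 32-channel /
1.5 s geometry mirrors a typical rodent visual-grating session; the 60 s
length keeps index construction and ROC evaluation to seconds on one CPU.
The noise-free variant drops the background noise and the rest blocks
(all-zero rest windows would have undefined correlations) and is the
deterministic-separation fixture.

1/f noise is white Gaussian noise whose positive-frequency Fourier
amplitudes are scaled by 1/√f (DC zeroed), rescaled to unit standard
deviation per channel. The per-block frequency jitter makes band powers vary
across channels and blocks (via spectral leakage) instead of being rank-1,
and overlapping condition subsets make retrieval non-trivial. What the
generator does *not* emulate: line noise, movement and electrode artifacts,
non-stationary background, volume conduction, or realistic cortical
dynamics — passing tests demonstrate the pipeline's correctness and its
behavior under controlled effect sizes, not performance on real recordings.

## Retrieval ROC

Every window is a query in turn; its candidates are all other windows with
defined correlations (the self window is excluded — its r = 1 would inflate
TPR trivially). Positives are candidates sharing the query's condition
label, taken from the labelled stimulus timespans; a window's label is that
of the block containing its midpoint. At each threshold on a fixed common
grid (r ∈ {−1, −0.99, …, 1}), predicted positives are candidates with
r ≥ threshold; TPR = TP/(TP+FN), FPR = FP/(FP+TN). Queries with no
positive or no negative candidates are skipped. TPR and FPR are averaged
across queries per threshold — the only convention that keeps the per-query
sweeps jointly well-defined — and AUC is the trapezoid integral of the
averaged curve anchored at (0,0) and (1,1). The fixed grid discretizes r to
0.01, so exact invariance of AUC under monotone transforms of r holds for
data-derived threshold grids, which `averaged_roc` accepts.

## Numerical choices and edge cases

- Band edges inclusive on bin centers; bins are `k·fs/N`.
- Correlations are clipped to [−1, 1] against rounding before the t
  transform.
- Timescale selection tolerates 1e-9 float slack at boundary equality
  (1.5 s query → 1.5 s scale).
- Sidecars (features, index) record a SHA-256 of the source file; the CLI
  rebuilds stale indices automatically.
- End-to-end determinism: one integer seed fixes the whole synthetic
  stream; repeat CLI runs produce byte-identical JSON/TSV.

## Problem sizes used in tests

Test and acceptance runs use the 60 s default synthetic session (40 windows
at the 1.5 s scale), 200-window null simulations for index calibration and
chance-level ROC, a 200-rep shuffled-label null for the retrieval AUC
comparison, and 100 randomly generated files for format round-trip checks —
sizes picked so the full suite completes in well under a minute of compute
per module while keeping the statistical checks meaningful.

## Known limitations

- High-gamma band power is the only feature; it suits ECoG but is noisy for
  scalp EEG.
- Search is within-file only; no cross-file or cross-modality comparison.
- No multiple-testing correction on the per-pair significance test: with
  many windows, 2.5% of null pairs are indexed by construction.
- The p-value treats the n channels as independent samples of a bivariate
  normal; spatial correlation between electrodes makes the effective n
  smaller, so stored "significance" is a ranking device, not inference.
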