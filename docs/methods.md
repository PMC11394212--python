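# Methods

## Scope and data model

`binbat` analyses basophil activation test (BAT) data: per-sample event
tables (events × channels) from flow cytometry, grouped into experiments
of one donor — exactly one unstimulated tube, an anti-IgE positive
control and any number of allergen tubes. The universal in-memory object
is the `EventTable`: a finite numeric matrix, unique ordered channel
names, per-channel transformed flags, and a channel map binding logical
markers to physical channels. Inputs are assumed compensated upstream;
no spillover correction is applied.

## Intensity scale

Fluorescence channels are transformed with `asinh(x / cofactor)`,
cofactor 150 by default (5 would suit mass-cytometry intensities); the
transform is strictly monotone and commutes with quantiles, so
calibration may be reasoned about on either scale. Forward scatter stays
linear because the singlet gate uses the linear FSC-A/FSC-H
proportionality. Side scatter is asinh-transformed with cofactor 1000:
the binning grid and the threshold search operate in transformed units
with a single bin width, and a raw linear SSC axis (10³–10⁵ units) is
incommensurate with the fluorescence axes; a large cofactor keeps the
transformed SSC range (~0–6) aligned with them. All cofactors and
methods are config-exposed per channel; re-transforming a transformed
channel is an error rather than a silent no-op.

## Pregating

Doublets: a Theil–Sen line of FSC-H on FSC-A is fit on a fixed-size
(2000-event) subsample drawn with a fixed seed *after* a canonical sort
of the rows, so the retained set is invariant to input row order. Events
with |residual| > k·MAD (k = 4 by default) are removed. Debris and
thrombocytes: events with FSC-A below the debris floor are removed, and
events below the thrombocyte floor that are *also* below the median side
scatter of the surviving events (small AND low). The default floors are
0.25× and 0.4× the median FSC-A of the sample — relative floors track
the instrument's scale and the actual debris load, where a fixed
quantile would always remove a fixed event fraction. Both are
overridable in linear units. Pregating is a pure filter: values are
never modified.

## Binning and quadrant statistics

The transformed x/y plane (side scatter vs FcεRIα for the automated
workflow) is cut into half-open square bins `[low, low+w) × [low,
low+w)`, w = 0.2 transformed units by default, anchored at the origin.
Quadrant thresholds are snapped to grid lines so bin and quadrant
boundaries coincide; "left" is x strictly below the x threshold, "upper"
is y at or above the y threshold. Per bin: event count, density
(fraction of gated events), percentage of events with z strictly above
the z threshold, mean z of all events (MSI), and mean z of only the
z-positive events (MSI+ — *absent*, never zero, for bins without
positives). Bins with fewer than `min_cells_per_bin` events (default 10)
keep their counts but are flagged and excluded from colour scaling,
which min–max normalises a chosen statistic to [0, 1] per sample
(blue → red; a flat statistic maps everything to 0.5; flagged bins are
grey). The implementation is vectorised but exactly equals a per-event
loop; the test suite asserts that equality on ≤1000-event fixtures.

## Automated threshold calibration

All thresholds are fixed on the donor's unstimulated sample and then
frozen.

**Axis thresholds (SSC, FcεRIα).** Candidates are nearest-rank quantiles
of the sample (SSC grid: 5–50%; FcεRIα grid: 99.0–99.8%), snapped to the
bin grid. A candidate pair is feasible when the upper-left quadrant holds
between 0.05% and 3% of gated events (a plausible basophil frequency)
and its CD32-positive fraction — at a provisional CD32 cut placed at the
sample's 40th CD32 percentile — is at least 70%. Among feasible
candidates the pair with the highest CD32 purity wins. Purity is
compared at 0.5-percentage-point resolution: once contamination is
negligible, raw purity differences between candidates are sampling noise
plus the FcεRIα–CD32 correlation within basophils, and maximising them
exactly would always pick the most extreme, lowest-yield candidate.
Near-ties therefore resolve by larger quadrant count, then lower FcεRIα
threshold, then lower SSC threshold — deterministically and in favour of
basophil yield. No feasible candidate is a calibration failure, which
surfaces as a blocking QC flag.

**z thresholds (CD63, CD32).** The threshold for a target positive
percentage t is the nearest-rank (100 − t)-th percentile of the
basophil-quadrant values — the k-th smallest value with k = ⌈(100−t)/100
· n⌉ — with positivity strictly above the threshold. The realised
positive fraction is then the largest value ≤ t achievable on the
empirical distribution, exact to one event (granularity 100/n percentage
points) and bit-reproducible. Defaults follow the assay conventions:
t = 1% for CD63 (the activation false-positive floor) and t = 70% for
CD32 (the red-percentage rule). Calibration needs ≥ 10 basophil events
(error below), warns below 50, and warns on a degenerate (constant)
distribution, where the strictly-above rule yields 0% positives.

**Regime sensitivity of the 1% rule.** If the unstimulated sample truly
contains activated basophils at exactly the calibration target (1%),
the threshold placement has two regimes: when the number of activated
events is at most the granularity count ⌊n/100⌋ the threshold lands in
the gap between the resting and activated CD63 components, and
stimulated samples are read essentially unbiased; when the activated
count overshoots, the threshold lands *inside* the activated component
and stimulated readouts are attenuated by roughly
(⌊n/100⌋+1)/(activated+1). This is a property of the calibration
convention itself, not of the implementation; at n ≈ 1000 basophils the
unbiased regime holds for ~58% of random samples. The seeded recovery
tests exercise the typical (unbiased) regime; the cohort-agreement test
averages over both.

## Workflow, calls and QC

Per experiment: transform → pregate every tube → calibrate on the
unstimulated tube → apply the frozen thresholds everywhere → per-sample
results → calls → QC. The decision rules are package choices, exposed in
config and echoed as rule strings in every result document: a donor is a
RESPONDER when the positive-control CD63+% is ≥ 10% (below: IgE
non-responder, all allergen calls UNDETERMINED); an allergen is POSITIVE
when its CD63+% is ≥ 5% AND ≥ 2× the unstimulated baseline. QC flags:
LOW_EVENTS (< 5000 gated, warning), LOW_BASOPHILS (< 50 warning, < 10
blocking), EMPTY_QUADRANT (blocking), THRESHOLD_OUT_OF_RANGE (any frozen
threshold outside the channel's observed span — by default the [min,
max] of the sample, config-exposed as a percentile pair; a narrower span
such as [0.1, 99.9] would routinely flag legitimately calibrated CD63
thresholds sitting in the sparse inter-component gap),
CALIBRATION_FAILED (blocking) and DEGENERATE_Z (warning). Blocking flags
suppress calls for the affected sample. Results are written as a
round-trippable JSON document per experiment (embedding the thresholds,
the config and its hash), a per-sample CSV, and an append-only
experiment index; identical inputs and config produce byte-identical
outputs.

## Cohort statistics

The Wilcoxon matched-pairs signed-rank test discards zero differences
(classic convention — the equal pairs are tallied separately), midranks
ties, and uses the exact null distribution of W⁺ for n ≤ 12 (dynamic
programming over doubled ranks, two-sided p = 2·min(cdf, sf) capped at
1) or the normal approximation with tie-corrected variance and 0.5
continuity correction otherwise. Pearson correlation delegates to
`scipy.stats.pearsonr` with constant-vector guarding. Outlier flagging
uses |difference| > Q3 + 1.5·IQR with nearest-rank quartiles — the same
quartile convention used by the violin summaries, which trim a total of
3% by default (half per tail, nearest-rank percentile bounds, so the
trim of {1..100} removes exactly {1, 100}).

## Synthetic whole-blood generator

Populations and default fractions: basophils 0.005, lymphocytes 0.28,
monocytes 0.08, dendritic cells 0.01, neutrophils 0.555, debris 0.04,
thrombocytes 0.03; 2% of emitted events are doublets, built by merging
two parent events (FSC-A summed, FSC-H the maximum, fluorescence and SSC
summed raw). Marker components are Gaussian on the transformed scale and
inverted to raw units before emission, so the pipeline's own transform
runs on every sample. Basophils are SSC-low (2.2 ± 0.25), FcεRIα-high
(4.5 ± 0.35), CD32-positive (4.4 ± 0.3), CD123-positive and
HLA-DR-negative; (FcεRIα, CD32) are drawn from a shared-latent bivariate
normal with correlation 0.6. Resting CD63 is 0.8 ± 0.4, activated CD63
5.5 ± 0.4 (≥ 4 scale units of separation so the 1% rule has a
well-defined tail); activated basophils have CD32 shifted down 0.4 units
(which produces the CD63–CD32 anticorrelation), and allergic donors have
the basophil CD32 baseline shifted down 0.3 units. Activation fractions
per condition: unstimulated 0.01; positive control 0.40 (responder) or
0.02 (non-responder); allergen 0.30 for an allergic responder, else
0.01. Neutrophil CD32 is set at 3.0 ± 0.4 — clearly positive, but below
the monocyte/basophil level — so that the 40th CD32 percentile used as
the provisional purity cut falls below the basophil CD32 component;
dendritic cells (FcεRIα 2.6 ± 0.35, SSC 3.2) are the designed near-miss
population for the axis search.

What the generator does *not* emulate: spectral spillover and
autofluorescence, acquisition-time drift, dead cells, eosinophil
autofluorescence, heavy-tailed instrument noise, and donor-to-donor
variation beyond the allergic CD32 shift and condition activation
levels. Passing tests therefore demonstrate the correctness and
robustness of the *analysis logic* under the assumed statistical
structure, not clinical performance on real instruments.

## Problem sizes in the tests

The deep end-to-end checks use 230 000 events per sample (~1000
basophil-quadrant events after pregating, the operating point at which
nearest-rank granularity is 0.1 percentage points), the cohort checks 50
experiments of three tubes each; unit and property tests use hundreds to
tens of thousands of events. The acceptance script uses 150 000 events
(~700 basophil-quadrant events).

## Known limitations

- Per-donor (not per-plate) threshold calibration is the only supported
  mode; there is no re-calibration on stimulated samples by design.
- Only classic asinh scaling is provided (no logicle/biexponential).
- The FCS reader covers list-mode float/double and uniform 16/32-bit
  integer FCS 3.0/3.1 files with one data set; the writer emits 32-bit
  float FCS 3.1.
- The activation-call cutoffs (10% responder, 5% + 2× baseline) are
  pragmatic BAT conventions, not validated diagnostic thresholds; every
  result document carries the rule strings used.
- Dose–response (CD-sens) analysis and CD203c readouts are out of scope.
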