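# Methods

`cawave` reimplements, as a tested library, the analysis chain used for
live Ca²⁺ imaging of the cochlear sensory epithelium (GCaMP6f in
supporting cells and hair cells) together with the companion qPCR
workflow for unfolded-protein-response (UPR) marker genes.  This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic-data tests do and do not demonstrate.

## ROI extraction

A recording is a single-channel stack with pixel size *p* (default
11/56 ≈ 0.196 µm/px) and frame interval Δt (default 2 s).  The field is
tiled from the top-left corner with non-overlapping 56 × 56-px ROIs
(11 × 11 µm, slightly larger than one cell); partial tiles at the right
and bottom edges are dropped, so a 1400 × 728-px frame yields
25 × 13 = 325 ROIs.  The trace of ROI *i* is the arithmetic mean of its
pixels per frame.  Boxes are half-open in 0-based pixel coordinates and
an ROI's physical position is its box center, which makes inter-ROI
distances (and hence wave speeds) unambiguous.  Input movies are assumed
already oriented (hair-cell rows horizontal); no registration, bleach or
background correction is applied.

## Baseline and peak detection

A Ca²⁺ peak is a maximal contiguous excursion of an ROI trace above
F₀ + k·σ with k = 10.  F₀ and σ are the baseline fluorescence and
baseline SD, estimated robustly because baseline frames are not
labelled: median and 1.4826·MAD over the frames that survive an
iterative exclusion (two passes) of frames more than 5 MADs (≈ 3.4
robust SDs) above the running median — a one-sided cut that strips
event frames including most of the decay tails while losing < 0.1 % of
Gaussian baseline frames.  If fewer than `baseline_min_fraction`
(default 20 %) of frames survive, the estimate falls back to the global
median/MAD and the ROI is flagged.  The robust scale stays within a few
percent of truth while events occupy ≲ 30 % of the recording.

An excursion whose onset lies within `min_separation` of the end of the
previous excursion is merged into it.  This is a debounce against
threshold chatter: near a slow downward crossing the noisy trace
re-crosses the threshold several times over a few seconds.  The default
window is two frame intervals; because chatter scales with the noise
crossing time, kinetics analyses of multi-second decays at 0.1-s
sampling should widen it (we use 5 s), while rate analyses of
high-SNR events at 2-s frames can disable it (the trace then moves
≥ 5 σ per sample through the threshold, so chatter cannot occur).

Onset and offset crossings are linearly interpolated between the
bracketing samples.  Events still above threshold at the last frame are
kept with `complete=False` and excluded from mean decay times
(censoring).

## Kinetics

* **Rise time** — time from baseline departure (the last upward
  interpolated crossing of F₀ on the rising limb) to the half-maximum
  crossing.  On a noiseless linear ramp of duration R this equals R/2,
  independent of amplitude.
* **Decay time** — time from the peak sample to the first interpolated
  downward crossing of the detection threshold F₀ + 10σ.  For a clean
  exponential decay from amplitude A·σ this equals τ·ln(A/10), e.g.
  27.19 s for A = 100, τ = 11.81 s, and 2.52 s for τ = 1.094 s.

A known limitation: with i.i.d. sample noise, the *first* downward
crossing is a first-passage time and comes systematically early when the
decay crosses the threshold slowly.  At a crossing slope of s σ per
second and sampling step h, the bias is roughly the m* solving
∫ₘ*^∞ Φ(−m) dm = s·h — about 1.3 s for τ ≈ 12 s at 0.1-s sampling with
unit noise, and negligible (< 0.1 s) for τ ≈ 1 s.  Mean decay times of
slow transients measured from noisy traces are therefore a few percent
short of the noiseless closed form.  We keep the first-crossing
definition (the natural reading of "return below threshold"); the
last-crossing alternative has the same bias with opposite sign.

* **Steady state** — the mean raw fluorescence over a 300-s window.
* **Rates** — peaks/s is the event count over the recording duration,
  per field by default, with an optional ROI-region mask (inner sulcus /
  hair-cell region / outer sulcus).

## Wave clustering and propagation

Events are grouped into intercellular Ca²⁺ (ICS) waves by single-linkage
connected components of the relation: link two events iff their ROI
centers are ≤ `d_max` apart (default 16.5 µm = 1.5 ROI pitches) **and**
their onsets differ by ≤ `dt_max` (default 3.3 s = d_max at a minimum
speed of 5 µm/s).  Components with ≥ `min_members` (default 3) events
are waves; smaller components remain isolated peaks.  Clustering is
order-invariant, and loosening either link parameter can only merge
components.

The wave origin is the ROI center of the earliest-onset member (ties:
lowest ROI index); the wave start is that onset.  Speed comes from the
origin-constrained least-squares fit of member lags on member distances
(Δt = d/v, so v = Σd²/Σd·Δt); it uses every member, is exact on
noiseless radial waves, and is flagged undefined when all members are
simultaneous or co-located.  Distance is the maximum member distance
from the origin; wave rate is count/duration.

Caveat: lags are measured from the earliest *member*, so if a wave
actually starts between cells, the origin-constrained fit overestimates
speed (≈ +30 % for an origin half a pitch off).  The synthetic studies
therefore place initiation sites on cell centers, matching the estimator's
model; on real data the same bias applies to waves whose trigger lies
between ROIs.

## Fast/slow transient classification

Hair-cell transients are classified from morphology dynamics.  Per cell
ROI and frame, pixels brighter than background + 5 robust SDs are
segmented (background from the ROI's 3-px border ring, keeping the
estimate local), components smaller than 4 px are discarded, and the
component overlapping the baseline centroid is tracked.  The cell's
`max_area_ratio` is its maximum area over the baseline (median) area,
and `fragmented` is set when ≥ 2 components appear where the baseline
had one.  A transient is **slow** iff `max_area_ratio ≥ 1.2` (area cut
configurable) or the cell fragmented, else **fast**.  The rule is total
and deterministic; the published separation is only shown graphically,
so the 1.2 cut is a package choice sitting well between "no change"
(ratio ≈ 1) and the modelled swelling (1.5× radius → 2.25× area).
Prevalence is the percentage of all cells in the field (silent cells
included) with ≥ 1 event of a label, rounded half-up to one decimal —
7 of 80 → 8.8 %, 13 of 80 → 16.3 %.

## qPCR / UPR statistics

Relative expression is 2^(−ΔCt) with ΔCt = Ct(gene) − Ct(Gapdh); samples
with Gapdh Ct > 24 are excluded.  Fold change divides by the arithmetic
mean of the unexposed control group's expressions (the control mean fold
is exactly 1).  The per-sample Chop/S-Xbp1 expression ratio indexes the
proapoptotic-vs-prohomeostatic balance of the UPR; the reference gene
cancels in it.  ROUT-style outlier removal is adapted to univariate
group columns: residuals from the median, robust scale RSDR = 68.27th
percentile of |residuals| × n/(n−1), two-tailed t p-values on
studentized residuals (df = n−1), Benjamini–Hochberg at q = 1 %, one
removal pass, and no removal below n = 5.  Group comparisons dispatch on
per-group Shapiro–Wilk normality (α = 0.05): Student's t or Mann–Whitney
for two groups, one-way ANOVA with Dunnett comparisons against the
control for more.  The gene-panel workflow is the composition
expression → fold → per-gene two-tailed t, with no cross-gene
multiplicity correction by default (a BH option exists upstream of it).

## Synthetic recordings

The generator emulates exactly what the pipeline consumes:

* static cells (disks of radius 3 µm in movies) on a known field, one
  per ROI, baseline fluorescence plus i.i.d. Gaussian noise per frame
  (and per pixel in movies);
* transients with a linear rise (default 1 s) to an amplitude expressed
  in noise SDs (default 20) followed by exponential decay (default
  τ = 2 s), planted either as per-cell Poisson processes or at fixed
  times for worked examples;
* radial waves from point initiation sites at constant speed (default
  15.5 µm/s) with a hard radius cutoff (default 44 µm); member
  activation times are exactly start + distance/speed;
* slow transients (default τ = 60 s) on a configurable fraction of
  outer hair cells, with radial swelling up to `swell_factor` (default
  1.5) tracking the transient and fragmentation into two disjoint
  half-area blobs once the transient decays to half-maximum.

Randomness is one stream per seed with fixed substreams per cell, per
wave site and per ROI, so adding a cell perturbs nothing else.  Not
modelled: indicator binding kinetics and bleaching, optical PSF, motion,
diffusive (non-ballistic) wave fronts, and correlated noise.  Tests
passing on these recordings therefore validate the *estimators*
(thresholds, clustering, regression, segmentation logic), not robustness
to optical artifacts of real movies.

## Benchmark studies and problem sizes

`cawave.studies` fixes the benchmark conditions used by the acceptance
tests and `scripts/acceptance.py`: 20 noiseless 8-member chain waves for
each speed (lags 0.3943 s and 0.7097 s per 11-µm step, i.e. 27.9 and
15.5 µm/s); wave-rate simulations with 6 sites × 0.005 /s over 3000 s
and 40 sites × 0.005 /s over 600 s (nominal 0.03 and 0.20 waves/s);
peak-rate simulations with 95 × 0.02 /s and 75 × 0.01 /s over 600 s
(nominal 1.90 and 0.75 peaks/s), 10 seeds each; decay studies with 50
(τ = 11.81 s) and 100 (τ = 1.094 s) isolated 100-σ transients at 0.1-s
sampling on 600-s traces; and the 80-cell movie fixture with 7 fast and
13 slow transient cells.  These sizes keep the full benchmark set within
a few minutes on one core while leaving Monte-Carlo SEMs at the
percent level.

Two systematic effects are visible at these settings and are expected,
not bugs: (i) at 0.02 events/s per cell with ≥ 2-s-wide events, ~9 % of
transients overlap a neighbouring excursion and are merged by the
one-event-per-excursion rule, so the detected 1.74 peaks/s sits below
the planted 1.90; (ii) the first-crossing decay estimate of the
τ = 11.81 s fixture averages ≈ 25.4 s rather than the noiseless 27.2 s
(first-passage bias above).  Both are quantified in the corresponding
test docstrings and reproduced deterministically by the studies.
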