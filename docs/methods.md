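# Methods

This note records the models, conventions and numerical choices behind
`dendropatch`, and what its synthetic benchmarks do and do not demonstrate.

## Expression ranking

**Normalization.** Microarray-style intensity atlases are renormalized so
every tissue column shares a common median: each column is divided by its own
median and multiplied by the grand median of the input matrix. The target
scale is arbitrary — after the subsequent log₂ transform and per-probe mean
centering, only relative values survive, and the log base cancels entirely in
Pearson correlations. Log₂ is used because fold changes are the natural unit
of expression work. Nonpositive intensities are rejected with the offending
probe and tissue named; a pipeline that silently clipped them could fabricate
enrichment.

**Clustering.** Probe rows are clustered agglomeratively with distance
*d*(x, y) = 1 − *r*(x, y) (Pearson) and unweighted average linkage (UPGMA),
via `scipy.cluster.hierarchy`. UPGMA heights are monotonically
non-decreasing, which the `ClusterTree` type asserts. The test suite checks
the merge heights against a deliberately naive oracle that recomputes every
cluster-pair distance from scratch at each step. Zero-variance rows make the
correlation undefined and are rejected by name rather than patched with an
arbitrary distance.

**Cluster selection.** Historically this step was done by eye on a heat map.
To make it reproducible, the tree is cut into *k* flat clusters and the
cluster with the highest mean normalized expression over caller-supplied
marker tissues is returned; ties go to the cluster containing the lowest leaf
index. The choice of *k* is the caller's; the planted-block benchmark uses
the smallest *k* that can separate the block.

**Ranking.** Genes are ranked by descending between-tissue ratio
value_a/value_b with ties broken by ascending gene symbol, so reruns are
bit-stable. Reference genes with a known side ("high" / "low") each carry a
threshold; validation reports pass/fail and rank per gene. Ratios are
reported at 6 decimal places, the precision of the printed reference tables;
the returned values are unrounded. Gene-level values from probe-level
matrices are the mean over a gene's probes; the bundled reference tables are
gene-level givens and bypass aggregation.

## Ratiometric imaging

All grids are 0-indexed, row-major, (row, col) = (y, x). Physical
calibration (µm/px, s/frame) travels with every image.

**Gaussian low-pass.** `scipy.ndimage.gaussian_filter` with reflective
boundaries (preserves the image mean; an impulse's mass is conserved). The
default sigma is 1.0 px and configurable — the procedure calls for a
low-pass step but no width, and at 1 px the filter suppresses shot noise
while leaving µm-scale structures intact.

**Local background subtraction.** Each pixel has the mean intensity of
*background* pixels (outside the supplied cell mask) within a Euclidean,
center-to-center, radius-inclusive distance of 40 µm subtracted. The radius
converts to pixels with no rounding. Pixels with no background inside the
radius fall back to the global background mean and are flagged in a returned
mask rather than silently blended. The windowed means are computed by disk
convolution — direct when the operation count is small, FFT otherwise, with
window counts re-rounded to integers so only the intensity sums carry FFT
rounding (~1e-12 relative). The operation is exactly invariant to adding a
constant to the whole image, which the tests assert.

**Ratio images.** ratio = POI/cytosol wherever the cytosolic reference
exceeds `min_cyto`; other pixels are marked invalid, never raised on. The
default cutoff is 5× the estimated background SD: below that, the reference
carries no volume information and the ratio diverges. Ratios are invariant
to common rescaling of both channels (illumination changes cancel).

## Patch quantification

**Detection.** The threshold is `factor` × the mean valid ratio within the
dendrite mask, with `factor` = 3.0: ">200 % above the average" is read
literally as average + 2×average. The alternative ">2× average" reading is
available by passing `factor=2.0`. Components use 8-connectivity (standard
for bright blobs) and a minimum area of 4 px to suppress single-pixel noise.
The mean is taken over the dendrite mask, not the whole cell. Detection is
invariant to positive rescaling of the ratio image since the threshold
scales with the mean.

**Six-region measurement.** Background sectors: one 10 px square per 90°
angular sector (centered on E/N/W/S) around the patch centroid, each at the
smallest distance at which it lies entirely outside the cell; the procedure
calls for "four sectors outside the cell adjacent to the region of interest"
without geometry, and the angular-sector rule is always placeable around a
shaft that crosses the field of view. The dendrite reference region is the
dendrite-mask band at 2–5 µm Euclidean distance from the patch, minus every
patch pixel — a stand-in for arc distance along the shaft that coincides
with it for straight-to-moderately-curved dendrites. The enrichment double
ratio is exactly invariant to uniform rescaling of all six means and to a
common offset applied to a channel's (patch, dendrite, background) triplet.
A fully uniform input (no contrast in either channel) returns 1.0 by
definition; any other nonpositive denominator is an error naming the
offending difference, since a patch dimmer than the background means the
measurement, not the biology, failed.

**Drug response.** Both epochs are maximum-projected; patches are detected
on the *before* projection only and the same masks are reused after, so a
patch that dissolves still contributes its (reduced) signal. Normalized
enrichment is mean patch ratio / mean shaft ratio (shaft = dendrite minus
all patches), which cancels global illumination changes — an after epoch
that is a scaled copy of before yields change = 1.0 exactly.

**Statistics.** Welch's two-sample, two-tailed t-test with
Welch–Satterthwaite degrees of freedom (`scipy.stats.ttest_ind`,
`equal_var=False`); the tests verify it against a hand transcription of the
formulas.

## Protrusion dynamics

**Classification.** Four classes, applied in order: present in every frame →
*static*; onset after frame 0, present through the last frame, persistence
≥ 3 min → *stabilized*; present from frame 0, gone before the last frame,
persistence ≥ 3 min → *collapsed*; otherwise *transient*. Persistence counts
the onset frame — (offset − onset + 1) × Δt — and the 3-minute comparison is
inclusive. These conventions are stated because presence counting is
ambiguous at frame boundaries; the brute-force oracle in the tests encodes
the same reading independently.

**Acquisition defaults** are 10 min at 60 s per frame (frames at 0, Δt, …,
T inclusive); a 15 s mode supports the interval-dependence analysis. Both
are configurable.

**Track extraction.** The shaft mask is supplied or derived as pixels
foreground in ≥ 90 % of frames, opened with a 2 px disk to shave off static
thin protrusions. Nodes are frames where the foreground half-width sampled
on the shaft medial axis reaches 1.5× the median baseline half-width — a
"thickened region" rule with an explicit number, since the original
identification was morphological and manual. The inscribed disks of a
detected thickening (dilated 1.5 px for rasterization slivers) are assigned
to the shaft, and protrusion candidates are the remaining foreground
components that touch the shaft or a node zone and extend ≥ 0.5 µm beyond
the baseline shaft; per-frame length is the maximal distance of a component
pixel from the shaft. Detections link across frames greedily by nearest
position within 1 µm (configurable) with gap closing over one missing
frame. A track's origin is its most shaft-proximal detection over its
lifetime, because an active node displaces the apparent base outward.

**Node association.** A protrusion links to the nearest node (within the
link radius) active at or before its onset. De novo protrusions are those
with onset > 0; protrusions already present at frame 0 cannot be attributed
and are excluded from the node-emergence denominator. Each node event counts
once in the dynamic-event numerator regardless of how many protrusions it
seeded. The node-emergence fraction is offered both pooled across
protrusions and per group (e.g. per neuron) then averaged, since either
estimator is defensible.

**Summary statistics.** dynamic-per-static rate = (transient + stabilized +
collapsed + node events) / static, reported as undefined (None) when no
static protrusion exists. Filopodia density is protrusions per 10 µm over
the proximal 100 µm of each dendrite path (arc length from the soma end of
the supplied polyline), averaged across dendrites; origins project onto a
densified polyline and must lie within 2 µm of it.

**Interval subsampling** keeps only frames on the coarser grid (which must
be an integer multiple of the native interval); events whose lifetime falls
entirely between retained frames vanish, and node links are recomputed on
the resampled data. Because subsampling can only remove nodes and delay
onsets, the node-emergence fraction at 60 s sampling does not exceed the
15 s fraction on the planted benchmarks — the mechanism by which short-lived
nodes are undercounted at coarse intervals.

## Synthetic data

**Scenes.** The dendrite is a constant-width tube around a polyline
(default: a straight 2 µm-wide shaft across a 256 × 96 px field at
0.2 µm/px). The cytosolic reference fills the cell mask at a constant
amplitude (default 1000 intensity units) over an optional background level
and gradient; the protein-of-interest channel equals the reference times the
planted enrichment field. Patches are disk-shaped multiplier regions —
uniform enrichment *E* inside the footprint — so that any sub-region of a
patch has mean enrichment exactly *E*; a truncated-Gaussian profile
(renormalized so the footprint mean is still *E*) is available for
soft-edged realism, at the cost of making region means depend on the mask
used. Node-flagged patches additionally thicken the shaft locally while
active. Protrusions grow along the local shaft normal at a configured
µm/frame rate, dwell, and retract; they are rendered as 1 px lines dilated
by a 1 px disk. Camera noise adds N(0, σ²ᵣₑₐd + photon_scale · value) per
pixel. One seeded generator per scene makes identical configs bit-identical.

**What the generator does not emulate:** optics (no PSF convolution, no
z-blur), photobleaching, dendrite motion or growth, out-of-focus structures,
and non-Gaussian camera artifacts. Passing the recovery benchmarks therefore
shows the *estimators* are unbiased and correctly implemented under the
stated noise model — not that segmentation or measurement would be this
clean on real microscopy.

**Benchmark conditions.** Enrichment recovery plants 50 patches at
*E* = 1.8 — the regime of the ~80 % patch enrichment the method is used to
measure — at signal-to-noise 10 (read noise = amplitude/10) over a
background of 100; the mean estimate must fall within 5 % of the truth.
Node-emergence recovery plants an exact fraction of 0.83 (round(n·f) of
n = 200 de novo protrusions seeded by nodes) — exact-fraction planting
matches the ground-truth contract (the planted fraction is a recorded
quantity, not a sampling target) and keeps the benchmark about estimator
recovery rather than binomial noise. The interval study draws node lifetimes
uniformly from 30–90 s, protrusion durations from 2–5 min, at a 15 s native
interval over 10 min, and compares mean fractions over 50 seeds between the
15 s and 60 s grids. Expression benchmarks plant a 30-gene block at 8-fold
enrichment in 5 of 20 tissues under 0.3 log-SD multiplicative noise, within
a 200-gene matrix — block recovery requires ≥ 90 % of block genes in the
selected cluster.

**Event generators at track level** (`generate_tracks`,
`generate_node_protrusion_events`) emit `ProtrusionTrack`/`NodeEvent`
objects directly, bypassing rendering; they exist so classification and
linking can be benchmarked at sample sizes (hundreds of events, dozens of
seeds) that full image rendering would make needlessly slow.

## Known limitations

- The dendrite reference region uses Euclidean, not arc, distance from the
  patch; on a sharply folded dendrite the band could include pixels from a
  different branch segment.
- Node detection assumes the baseline shaft is stationary; a drifting
  dendrite would need registration first (out of scope).
- The ">200 % above the average ratio" threshold rule is scale-free but
  sensitive to the dendrite-mask definition; masks should exclude the soma.
- Track linking is greedy nearest-neighbor; crossing protrusions closer than
  the link radius can swap identities. The planted benchmarks space events
  beyond the link radius, so they do not exercise this failure mode.
- The printed reference tables are treated as gene-level inputs; whether the
  original values were single-probe or probe-averaged is not recorded in
  them.
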