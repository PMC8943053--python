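# Methods

`plateworm` re-implements, as a tested library, the analysis stack of a
multiwell-plate worm imaging system: one camera of a six-camera array sees a
4×4 block of a 96-well square-well plate at 12.4 µm/px and 25 fps; wells are
detected by fitting a tiled template; dark moving objects are segmented,
linked into tracks, filtered by a convolutional worm/non-worm classifier,
classified into motion modes, and summarised into per-well behavioural
features; population statistics quantify the blue-light escape response;
and experiment-record CSVs are merged into per-(video, well) metadata.
All of it runs end to end on synthetic data with known ground truth.

## The synthetic plate simulator

The simulator is first-class, tested code; its defaults define the study
conditions used throughout the test suite.

**Geometry.** A camera field of view is 672×672 px containing a 4×4 block of
square wells on a 160 px pitch with a 130 px bright inner square
(≈ 8 mm wells on a 9 mm pitch at 80.6 px/mm, with the wall shadow eating
into the opening). Wall bands are darkened by `wall_dark_frac` (default
0.5); agar is grey level 200 and worm bodies 60, with additive Gaussian
sensor noise (σ = 2 grey levels by default). Raster convention throughout:
0-based pixel indices, origin top-left, y down, half-open well boxes.

**Worms.** Three worms per well by default (the standard assay dispenses
three). A worm is a sinusoidal tube: body length 80 px (≈ 1 mm adult),
width 7 px, undulation amplitude 6 px, wavelength 40 px. The body length is
exactly two undulation wavelengths, which keeps the midline centroid from
wobbling with phase. Motion is a three-state (forward/backward/stationary)
discrete-time Markov chain at frame resolution whose sticky defaults give
worm-like bout durations — forward runs ≈ 4 s, reversals ≈ 1.6 s, pauses
≈ 5 s. Blue light multiplies every transition probability *into* the
forward state by `light_bias` and renormalises rows, which gives
closed-form stationary distributions for calibration tests. Moving worms
steer smoothly away from well walls at a bounded turn rate (8 rad/s);
bodies never teleport, because a discontinuous heading would break any
orientation tracking downstream — an early reflective-boundary variant did
exactly that. Worm centroids stay inside the well's inner square (a
ground-truth invariant); bodies may overhang into the wall shadow, as real
worms touch walls.

**Debris.** Non-worm objects span the morphologies the classifier must
reject: Gaussian-ish blobs, straight scratches, and well-corner crescents.
The classes are separable from worms *by construction*: scratches are thin
agar marks (≤ 4 px wide vs ≥ 5 px worm bodies), crescents are broad arcs.
An earlier scratch parameterisation overlapped the worm width range and
made the two classes genuinely ambiguous; the class definitions were
tightened so that each class is what it claims to be.

**ROI dataset.** Labelled 80×80 masked crops mimic the tracker's masking
step: pixels farther than a 5 px halo from the object are exactly 0.
Images carry the same sensor noise as rendered sessions, and 40% of
objects sit against a dark wall band, matching the distribution of crops
taken near well edges. Unmasked pixels are clipped to ≥ 1 so that zero
remains reserved for masking.

**What the simulator does not emulate** (and hence what passing tests do
not show about real data): optics (blur, vignetting, lens distortion),
850 nm illumination physics, worm self-occlusion and coiling, pose detail
beyond a sinusoid, contact interactions between worms, developmental or
physiological variability, and the acquisition software's binary
frame-store chunk format (frames here are plain PNGs plus an index).
Quantitative claims here are about algorithmic correctness and
calibration, not about biological effect sizes.

## Well detection

A two-level template (bright inner square on a dark wall band) is tiled on
a lattice parameterised by `(row_offset, col_offset, row_pitch, col_pitch)`;
grid dimensions come from configuration. The objective is the mean absolute
difference between the min-max-normalised frame and the min-max-normalised
tiled template, minimised by SciPy's differential evolution with a fixed
seed. Because the template is two-level, the objective reduces to box sums
over the well interiors, which a precomputed integral image yields in
O(wells) per evaluation; a ±2 px integer sweep after the optimiser
guarantees a local optimum on the pixel lattice. Box edges are rounded to
whole pixels — sub-pixel placement is meaningless against >100 px wells.
Equality between the fast objective and a direct pixelwise render is
property-tested. A residual above 0.25 sets a low-confidence flag (clean
aligned frames sit near 0.02–0.2 depending on worm load; structureless
frames cannot do better than ≈ 0.3). Fitting on the median static
background (≤ 100 evenly spaced frames) removes worms and is preferred
when frames are available. Well names map camera id → 4×4 block of the
8×12 plate (cameras tiled 2×3, row-major, names A1–H12).

## Segmentation, tracking, motion modes

Putative worms are dark connected components (absolute grey threshold,
default 80, or Otsu over well interiors) within area bounds (80–2500 px²).
Midlines come from skeletonisation, ordered by walking from an endpoint.
Masked frames zero pixels farther than a halo from every object (Euclidean
distance transform — identical to dilation by a disk, which the tests use
as an independent oracle). Linking is greedy nearest-neighbour between
consecutive frames with a `max_step` gate; a missed frame closes the track
for good, so track counts exceed worm counts by design.

Head/tail is resolved per track: midline orientations are first aligned
frame-to-frame by shape distance, then the whole track is flipped if the
net displacement along the tail→head axis is negative (head leads during
forward motion; ties stay as found). Motion mode uses the centroid
velocity projected on the tail→head axis, smoothed over a centred 0.4 s
window: |v| < 0.1 body lengths/s ⇒ stationary, otherwise the sign decides
forward/backward. These two thresholds are package defaults (the upstream
description leaves them open); they expose all three modes under the
simulator's kinematics, and per-frame accuracy against ground truth on
noiseless single-worm sessions is ≥ 95%, with residual errors concentrated
at bout boundaries where any finite smoothing window must blur.

## The worm/non-worm classifier

Architecture (fixed): eight 3×3 stride-1 convolutions, each followed by
ReLU; 2×2 max-pool after every second convolution (80→40→20→10→5);
batch normalisation after convolutions 3 and 7; dropout (0.5) before a
single fully connected layer with two logits. With the default channel
plan (32, 64, 64, 128, 128, 256, 256, 256) the stack has 1,765,954
trainable parameters. The engine is a compact numpy implementation
(im2col convolution, pooling, batch norm, dropout, Adam, softmax
cross-entropy) whose gradients are verified numerically in development.

Preprocessing: masked (zero) pixels are shifted to the 95th percentile of
the unmasked grey values (linear-interpolation percentile convention —
stated because percentile definitions differ), then min-max scaled to
[0, 1]; the fill step stops the artificial mask edge from dominating.

Training: cross-entropy, Adam at 10⁻⁴, batch 64, 80/10/10
train/validation/test split stratified by class, best-validation weights
retained, early stopping (patience 5). Training batches are augmented with
random flips and right-angle rotations — orientation is arbitrary for
plate crops, so these are label-preserving. Two presets exist: the
full-width default plan (used for architecture and parameter-count
checks) and a `compact` plan (8, 8, 16, 16, 32, 32, 32, 32, 12 epochs)
with identical topology, sized so that training 2000 synthetic ROIs takes
minutes on one CPU core; on that set it reaches ≈ 98% held-out accuracy.

Inference on tracks samples one ROI per whole second of track duration
(the first frame of each second — a deterministic phase); tracks shorter
than a second use every frame. The object is a valid worm iff the median
worm probability is strictly greater than 0.5.

## Photoresponse statistics

The population readout divides, per well and time point, the number of
tracked worms in each mode by the total tracked — time points with zero
tracked worms are undefined and excluded, never imputed as zero.
Well-averaged curves carry 95% CIs from a nonparametric bootstrap over
wells (default n = 1000 resamples; percentile method). Window logic is
half-open and timestamp-based (the frame index, not frame counts, carries
time). Prevalent-mode downsampling takes the modal mode in nonoverlapping
2 s windows; ties break stationary > forward > backward, so no movement is
claimed on ties. The per-pulse response is the mean over the 10 s window
just before the end of each stimulus minus the 10 s just after — the
stimulus-elevated level minus the recovered level, so a positive forward
delta is an evoked response. The baseline shift is the final 5 min minus
the initial 5 min, per mode; across modes the shifts sum to zero whenever
all samples are defined.

Calibration facts the suite verifies: time-averaged aggregated fractions
recover the chain's stationary distribution within 3 SE, and the bootstrap
CI for the well-averaged forward fraction attains 95% ± 3% empirical
coverage at the serial-stimulation sample size of 144 wells. (At much
smaller well counts the percentile bootstrap is expected to undercover —
that is a property of the method, not of this implementation.)

## Feature pipeline

Tracks summarise into one averaged vector per well (worm identity is not
maintained across gaps, so the well is the sample unit). The reduced
catalogue — length, midbody width, mean absolute curvature for five body
parts (head, neck, midbody, hips, tail), overall speed, per-mode time
fractions and per-mode speeds — is listed in `docs/feature_catalogue.md`;
all downstream machinery is width-agnostic, so the 3×3076 = 9228 and
3×256 = 768 concatenation contracts hold for any per-period width.

Matrix processing order: drop samples with > 40% missing features; drop
features missing in > 20% of samples within any interval group (the 10 s
window in time-resolved mode, the recording period in summary mode);
impute remaining gaps with the within-interval column mean; z-normalise
(zero-variance columns are dropped and reported). PCA fixes component
signs (largest-magnitude loading positive) for reproducible plots.
Group statistics use Kruskal–Wallis with tie correction and
Benjamini–Yekutieli FDR control; for two small tie-free groups an exact
permutation tail is available (enumerated by dynamic programming over
rank sums) and matches the exact Mann–Whitney two-sided p. Fingerprints
cluster with complete linkage on correlation distance (1 − Pearson r) on
both axes. The compound screen fits, per (compound, feature), a linear
mixed model with a fixed compound effect and a random intercept per
imaging day (REML), tests compound wells against the control group, and
controls the FDR across features per compound with Benjamini–Hochberg
(the step-up choice is configurable); compounds observed on a single day
are unestimable and flagged, not silently dropped.

## Strain classification protocol

20% of the wells of each strain (rounded to nearest) are held out first.
Candidate feature-set sizes {2⁷ … 2¹¹} (clipped to the available width)
are scored by repeated stratified cross-validation; inside each training
fold, recursive feature elimination with random-forest importances (10% of
remaining features dropped per iteration — a package default, configurable)
selects the candidate set, and a forest trained on it is scored on the
fold's held-out part. The best size is re-selected on the full training
set, hyperparameters are tuned by grid search (n_estimators 200:200:2000;
max_features all/sqrt — "auto" is interpreted as all features, the
historical convention; max_depth 10:10:110 and none; min_samples_split
2/5/10; min_samples_leaf 1/2/4), and the test split is touched exactly
once. Defaults are 4 CV folds (compatible with ~16–27 training wells per
strain) and 20 repeats; a `fast` preset (3 folds, 3 repeats, reduced grid)
exists for routine runs. A usage audit logs the sample ids each stage
consumed, making the train/test firewall checkable. Chance is
1/(number of strains) — 9% for an 11-strain panel.

## Metadata provenance

The record schemas (wormsorter, manual metadata, source plate, robot log,
imaging-to-source map, video index) are defined by this package — the
upstream pipeline names the files but not their columns — and documented
in `docs/metadata_schemas.md`. Wormsorter well ranges are inclusive
rectangles ("A1-B12") plus comma lists, matching how sorters dispense row
blocks. Merges are pure functions with fail-fast semantics: overlapping
ranges, robot-log wells absent from the wormsorter, duplicate (run, rig)
rows, and unmatched videos all raise with the offending keys listed.
Repeated runs are byte-identical, and the fixture round-trip
(generate CSVs → read → compile) reproduces the generator's expected
final table byte for byte.

## Problem sizes used by the test suite

The suite runs the full pipeline at sizes chosen to keep a complete run
on one CPU core in the tens of minutes while leaving every statistical
check adequately powered: 10–30 s rendered sessions (16–48 worms), 50
random plates for detection robustness, a 2000-image ROI set for the
classifier, 200 replicates for bootstrap coverage, 60 null replicates for
FDR calibration, and an 11-strain × 20-well panel for the classification
protocol. Published quantities that depend on data that cannot be
regenerated (the 43,561 annotated real ROIs, the CeNDR strain recordings)
are replaced by the corresponding synthetic-property checks; the reduced
feature catalogue stands in for the full 3076-feature extraction, with
the dimension contracts guaranteed structurally.

## Known limitations

- The motion-mode definition (projection + smoothing + threshold) is this
  package's own; the upstream tracker's exact algorithm lives in its pose
  estimation code and differs in unknown details.
- Head/tail resolution by majority displacement fails for worms that
  genuinely travel backwards for most of a track — rare under the default
  chain, but a real failure mode.
- The greedy linker never re-identifies a worm after a gap; statistics
  that need long per-worm series (e.g. prevalent-mode downsampling over
  minutes) should be fed well-level series or ground-truth modes.
- MixedLM occasionally sits at the boundary (zero day variance) on null
  features; such fits fall back to p = 1, which is conservative.
- The CNN engine is CPU-only and unoptimised beyond im2col; it is sized
  for the synthetic task, not for the 43k-image real dataset.
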