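# Methods

This note documents the models implemented in `aimtk`, the parameter
choices that matter, what the synthetic phantoms do and do not emulate,
and the numerical conventions. It states no empirical result beyond what
the test suite and `scripts/acceptance.py` compute themselves.

## The phantom world

Each synthetic field of view contains `n_cells` non-overlapping elliptical
cells placed by rejection sampling (at most 1000 attempts per cell; an
explicit `PackingError` names the constraint when placement is
infeasible). A cell is an equal-area ellipse: for equivalent radius *r*
(uniform in `cell_radius_range`, default 10–16 px) and eccentricity *e*
(uniform in its class's range), the semi-axes are a·b = r² with
b/a = √(1 − e²). Each cell carries a circular nucleus of radius
`nucleus_radius_fraction`·r (default 0.4; overridable per class, e.g. a
shrunken nucleus for a "dead" class).

**Transmitted light.** The TL image is a relief rendering of a cell
"height map" (cos² bump per cell, modulated by a class-specific radial
texture): mid-gray 0.5 plus `tl_gain` (default 2.0) times the horizontal
gradient of the Gaussian-smoothed height map (σ = 1 px), which mimics the
shear shading of differential interference contrast. The nucleus is
rendered as denser material: a flat absorption disc (`nucleus_absorption`,
default 0.35, darkens the interior uniformly with a sharp edge) plus a
refractile bright rim (`nucleus_rim_gain`, default 0.8, the gradient
magnitude of the smoothed disc). Without these two terms the nucleus
boundary is optically ambiguous in TL — the relief dipole vanishes at the
bump apex — and no pixel classifier, however strong, can localize it;
darker, bright-rimmed nuclei are also what dense chromatin looks like in
transmitted light.

**Fluorescence.** Each FL channel renders one structure (nucleus;
optional puncta or fibers) as a flat bright level 0.05 + 0.9·intensity on
a 0.05 background. Flat two-level rendering is deliberate: it makes
zero-noise label generation exactly solvable, which pins down the
label-factory contract.

**Noise.** Clean images are Poisson-resampled (`poisson_scale` photons per
unit intensity; 0 disables) and then given additive Gaussian noise
(`gaussian_sigma`), the standard shot-plus-read camera model. Truth masks
are always noise-free. "Moderate noise" in the tests means
σ = 0.02, 200 photons/unit.

**Motion.** Static; Brownian with per-axis steps N(0, √(2D)) so that
E|Δr|² = 4D per frame (the 2-D diffusion law, used as a physics oracle);
or a persistent walk at `speed` px/frame whose heading performs a random
walk with step std (1 − persistence)·π/2. Cells reflect at the field
border so truth tracks keep full length; scheduled `Event`s switch a
cell's class and/or motion at an exact frame. All randomness derives from
`numpy.random.SeedSequence([seed, stream, frame])`, so identical specs are
bit-identical, and per-frame noise does not depend on how many frames were
rendered before.

**What the phantom does not emulate:** optical point-spread functions and
polarization DIC physics, 3-D structure, photobleaching, cell division and
contact, intensity drift, and the texture richness of real cells. A green
test therefore establishes contract correctness and desk-scale
learnability/trackability — not performance on real microscopy.

## Label generation (HK-means)

Fluorescence frames are clustered into K intensity classes by 1-D K-means:
seeds at the (i + 0.5)/K quantiles of the **distinct** intensity values,
Lloyd iterations to centroid tolerance 1e-6 or 100 iterations, classes
ordered by ascending centroid. Seeding on distinct values rather than on
the raw pixel distribution is deliberate: microscopy foreground is sparse
(often < 5 % of pixels), so pixel-mass quantiles all fall on the
background level and the seeding collapses; distinct-value quantiles keep
the determinism and the affine-equivariance of the rule (an affine
intensity map transforms seeds and centroids alike, leaving labels
unchanged) while recovering two-level images exactly. Classes above the
darkest are foreground. The hierarchical step is a size filter: connected
foreground components (8-connectivity) with area outside
`object_area_bounds` are reset to background. Images with fewer distinct
values than K collapse to that many classes with a warning.

ROI datasets are built one ROI per foreground component, centered on the
component centroid rounded half away from zero; crops crossing the image
border are reflect-padded and flagged `padded`. Splits are **by sample,
never by ROI** — e.g. rule (2, 1): two replicates train, one validates —
and `DatasetSplit.assert_no_leakage()` re-checks disjointness on every
assembled dataset.

## In-silico staining (pixel segmenter)

The segmenter is a fixed multiscale convolutional filter bank feeding a
seeded MLP read-out. Per scale σ ∈ {1, 2, …, 2^depth} px it computes
Gaussian-smoothed intensity, gradient magnitude (raw and re-smoothed at
2σ), Laplacian and local standard deviation, plus the raw intensity —
1 + 5(depth+1) features per pixel (16 at the default depth 2). The
read-out is a single-hidden-layer MLP (`base_channels` units, default 64,
Adam, learning rate 1e-3) trained for `epochs` (default 30) passes; with
`class_weights="balanced"` each pass resamples equal pixel counts per
class (capped at `pixels_per_class`), which implements inverse-frequency
weighting for the rare foreground. Per-epoch loss and validation pixel
accuracy are logged in a `TrainReport`; the best validation epoch's
weights are kept. Initialization is forced at build time with a constant
dummy batch so that two models built from the same config and seed have
identical parameter checksums before any data are seen.

This filter-bank-plus-MLP design replaces a full encoder–decoder network:
the execution environment provides no deep-learning framework, and the
desk-scale contract (CPU-minutes training, seeded determinism, per-pixel
probability simplex, tiling) is what the package guarantees. The `depth`
and `input_size` parameters keep the encoder–decoder interface — input
size must be divisible by 2^depth, the coarsest feature scale.

Frames larger than `input_size` are processed by tiling with 50 % overlap
and triangular-window blending of the per-pixel probabilities (renormalized
after averaging); smaller frames are reflect-padded. Tile seams agree with
an untiled pass to within a few percent because the features themselves
are translation invariant.

A shuffled-label control run with natural class frequencies collapses to
the majority-class prior (empty foreground), confirming that a green
staining test reflects image information rather than leakage.

## Cell proposal and ROI classification

The default proposer is label-free: gradient energy |∇G₁.₅ ∗ I| is
smoothed at σ = box_side/8, thresholded by Otsu, and connected components
above `min_area` become detections (center = centroid, score = mean
normalized energy). Alternatively a trained segmenter's foreground
components serve as proposals. Greedy non-maximum suppression drops any
box with IoU ≥ 0.5 against a kept higher-scoring box; featureless frames
yield no detections. On zero-noise phantoms with well-separated cells the
proposer is exhaustive and localizes centers to a few pixels; it is a
contract-compatible stand-in for a detection network, not a reproduction
of one.

The ROI classifier resizes each odd-sided ROI (default 101 px, 41 px in
the scaled-down tests) to a 16×16 grid, standardizes it per patch (zero
mean, unit variance; constant patches map to the zero vector and remain
classifiable), and applies a seeded single-hidden-layer MLP (64 units).
Training logs per-epoch loss and validation accuracy, keeps the best
epoch, and reports the validation confusion matrix. Arg-max ties break to
the lowest class index.

**Permutation control.** The no-leakage control permutes *all*
supervision — training and validation labels; permuting training labels
alone lets best-epoch selection on clean validation labels pick whichever
noise-fit happens to align with the truth (a measurable effect). Because
a deterministic MLP's errors on clustered data are strongly correlated
across items, single-run null accuracy scatters well beyond item-level
binomial noise; chance behaviour is therefore asserted on the mean over
several permutations, with a per-run ceiling far below the informed
model's accuracy.

## Tracking

One target is a cosine-windowed appearance template plus
foreground/background intensity histograms (`n_bins = 32` over [0, 1];
foreground from the box interior, background from the surrounding
search-window ring). Per frame, over a search window of
`search_scale`× (default 2×) the box side centered on the previous
position:

- correlation response: FFT-based normalized cross-correlation of the
  template (peak 1.0 on an exact match);
- histogram response: per-pixel foreground probability
  h_fg/(h_fg + h_bg) (Bayes with equal priors), box-averaged;
- fusion: each map min-max rescaled to [0, 1] (flat maps become 0.5),
  then (1 − α)·corr + α·hist with α = 0.3; the new center is the arg-max
  (row-major first index on ties).

The *reported score* is taken from the **raw** responses at the chosen
peak — clipped NCC and box foreground probability — because the rescaled
map's maximum is 1 by construction and carries no confidence. Template
and histograms update by exponential moving averages (η_cf = 0.01,
η_hist = 0.04; histogram normalization is preserved exactly). The
hyper-parameter defaults follow the published correlation-filter/
histogram ensemble tracker family; all are exposed in `TrackParams`.
Tracking is translation-only — no scale or rotation adaptation — and
deterministic.

Multi-object management: tracks seed from frame-0 detections; every
`detect_interval` frames detections re-run and are matched greedily
(descending detection score, nearest active track within `gate_radius`);
unmatched detections spawn tracks. A track ends when its raw response
stays below `min_response` for `max_lost` consecutive frames or its
center leaves the frame. Association is greedy nearest-neighbor rather
than global assignment — sufficient at phantom densities and deterministic;
the detector argument is pluggable.

## Trajectory analysis

Per track frame, an odd-sided ROI is cropped at the track coordinate
(reflect-padded at borders). Nucleus area is the pixel count of the
segmented foreground component whose centroid lies nearest the ROI
center (0 / absent when no foreground survives), converted to µm² by the
squared pixel size. Each classifier head yields a per-frame probability
vector. Cumulative displacement is the running sum of Euclidean step
lengths; MSD is time-averaged per track,
MSD(τ) = mean_t |r(t+τ) − r(t)|², with ensemble averaging offered as a
separate aggregate. Frames convert to minutes via `frame_interval_min`
(5 min for the cancer-cell-style videos, 3 min for the immune-cell-style
ones).

State changes are detected by a threshold-persistence rule: the event
frame is the first index where the designated class probability reaches
`threshold` (default 0.5) and stays there for `persistence` (default 3)
consecutive frames. The rule is this package's formalization — reported
transition times in label-free viability/maturation studies do not come
with an explicit rule — and both knobs are configurable; probability
series are not smoothed by default.

## Metrics

- Recall = TP/(TP+FN) and IoU = TP/(TP+FP+FN) per foreground class, by
  direct pixel counting; a class absent from the truth (recall) or from
  both masks (IoU) scores 1.
- BF score: boundary pixels are foreground pixels with a background
  4-neighbor (the image border counts as background). Distances are exact
  Euclidean via `distance_transform_edt`, matched strictly `< θ`; θ below
  1 is read as a fraction of the image diagonal √(h²+w²), default 0.0075.
  Precision = fraction of predicted boundary near the truth boundary,
  recall the converse, BF = 2PR/(P+R). Conventions: both boundaries empty
  → 1; exactly one empty → 0; P = R = 0 → 0. The test suite verifies
  equality to 1e-12 against an all-pairs distance oracle.
- Accuracy = trace/total of the confusion matrix (rows = truth), the
  micro-average of per-class (TP+TN)/(TP+FP+TN+FN). Predicted labels
  absent from the truth add a row/column with a warning.
- One-vs-rest ROC per class: thresholds sweep the distinct scores, tied
  scores move together, AUC by trapezoid — equal to the midrank
  Mann–Whitney pair statistic. Classes absent from the truth are omitted
  rather than scored 0.
- Per-image scores are averaged unweighted across an evaluation set.

## Reproducibility and I/O

Every stochastic component takes an explicit seed and is bit-reproducible.
Stacks are multi-page TIFF (or directories of PNG/TIFF), 8/16-bit
round-trip lossless; masks are integer-labelled TIFF (never palettized);
tracks and reports are headered UTF-8 CSV with '.' decimals. The pipeline
writes its fully resolved configuration and a SHA-256 manifest beside its
outputs. Coordinates are (x, y) = (column, row), 0-based, pixel centers
at integers, everywhere.

## Known limitations

- The staining backend is a filter-bank pixel classifier: it has no
  learned spatial context beyond the feature support, so it will not
  match a trained encoder–decoder on textures whose label depends on
  long-range shape.
- The tracker has no scale/rotation adaptation and no division handling;
  crossing cells can swap identities (association is greedy).
- Phantom parameters (SNR, cell density, radii) are free knobs chosen for
  plausibility at 20–40× magnification, not calibrated to any real
  dataset; headline scores on real microscopy are out of reach by design.
- `propose_cells` assumes roughly cell-sized gradient blobs; confluent
  fields need the segmenter-based proposer.
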