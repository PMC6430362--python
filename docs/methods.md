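# Methods

This note documents the models, algorithms and numerical choices behind
`spectralbeads`, and what the synthetic test scenes do and do not establish
about behaviour on real microscope data.

## Imaging model and assumptions

The pipeline assumes beads imaged in a monolayer with a low-NA objective:
each bead subtends roughly 10–20 px, appears as a dark ring on a bright
background in bright-field, carries its spectral code as LNP luminescence in
the bead core, and shows bound probe as a thin fluorescent ring coincident
with the dark bright-field ring. All coordinates are (row, col), 0-based;
rectangles are half-open `(row0, col0, height, width)`. Intensities are
assumed non-negative after loading; floating-point negatives are clipped at
zero with a warning.

## Bead finding and segmentation

Edge pixels are found by adaptive Gaussian thresholding: foreground where
`I < G_sigma(I) - offset`, with the Gaussian local mean over a `block_size`
window (σ = (block_size−1)/6, reflective boundaries). Defaults
`block_size = 15`, `offset = 11` suit dark-ring beads of 10–20 px at
bright-field contrasts of ~150 counts; both are exposed because the offset's
sign/scale is a library convention (dark-object polarity here), not a
mathematical constant.

Interior seeds are the 4-connected holes of the edge mask; blobs touching
the image border are discarded because a bead cut by the frame cannot be
quantified. Seeds expand by a watershed over the negated Euclidean distance
transform, constrained to the filled blob, so touching beads split along
the geometric ridge and every pixel receives at most one label
deterministically. Region definitions: ring = the thresholded edge pixels
of a bead (its width therefore follows from image contrast, not a fixed
parameter), core = the enclosed fill, whole = ring ∪ core, background = an
annulus grown `background_annulus_px` (default 3 px) beyond the bead with
nearest-bead ownership where annuli would collide, never overlapping any
bead. Candidates outside 50–150% of the accepted bead area (a circle at the
midpoint of the expected diameter range) or with eccentricity > 0.65 are
removed; survivors are renumbered in row-major centroid order, which fixes
the "numbering by location" convention.

A circular Hough transform (`find_circles`) is provided as a fallback
detector; it returns idealized circles and no morphology, so the watershed
route is preferred whenever shape-based filtering matters.

## Reference spectra and unmixing

Reference spectra come from single-species bead sets (median over the
pooled core pixels of all found beads, per channel) plus a background
spectrum (median over a user-chosen bead-free rectangle, pooled across
files). Columns are normalized to unit sum: the absolute scale of a
spectrum trades off exactly against its unmixed weight, so normalization
changes per-species weight scales but cancels in every ratio; unit-sum
columns simply make weights comparable across species. Normalization is
idempotent and the assembled system must be square or overdetermined.

Unmixing is unconstrained ordinary least squares solved through one QR
factorization of `A` shared by all pixels and files (identical to per-pixel
solves to ~1e-10; verified in tests). Weights may dip below zero under
noise and are preserved for QC. Rank deficiency is reported with the names
of the collinear columns. Ratio images are defined only where the reference
weight exceeds a floor of `1e-12 × max(reference weight)`; other pixels are
NaN rather than infinities. The background weight is never ratioed — its
role is the non-bead filter below.

## Extraction and the non-bead filter

Per-bead statistics are medians over region masks (robust to hot pixels);
totals and pixel counts are carried along, and a diameter-normalized total
is provided as a derived column for users who prefer summed intensities.
Background subtraction is strictly local — each bead's own annulus — so
gradients from illumination, reflections or slide tilt cancel per bead;
negative background-subtracted signals are preserved so that non-binders
average to zero instead of a positive floor.

Bubbles and dust mimic beads in bright-field but carry no embedded
luminescence. The filter computes the mean and sample SD (ddof = 1) of the
invariant-species and unmixed-background core medians over all objects in
the experiment (a per-file switch exists) in a single pass and removes
objects deviating more than `n_sd` (default 2) SD in either quantity. With
fewer than 3 objects the filter is skipped; removing more than half of all
objects trips a loud warning since that indicates degenerate statistics
rather than artifacts.

## Decoding

**ICP.** The observed ratio cloud is registered onto the designed targets
with an affine transform `transformed = raw · T + o` (row vectors, full
d × d matrix: the data→target direction; the designed table is the fixed
frame everything is reported in). Each iteration matches beads to nearest
targets (ties to the lower code index), trims the `trim_pct`% (default 1%)
of beads with the largest matched distance — recomputed fresh each
iteration, not cumulative — and re-solves the augmented least-squares
system on the surviving raw ratios. Convergence uses the relative
transform-change cost
`Δ = (Σ(T_new−T_old)² + Σ(o_new−o_old)²)/(ΣT_new² + Σo_new²)`
with full-matrix sums, tolerance 1e-4, max 100 iterations. The initial
transform is diagonal — per dimension, SD(target levels)/SD(observed
ratios), with a mean-matching offset — computed on the beads nearest the
data's median centre (excluding the same top percentile ICP trims), so a
single gross outlier cannot collapse the initial scale. Population SD
(ddof = 0) is used here; with equal beads per code the data and target SDs
then cancel exactly for already-registered data.

**GMM.** Classification uses a supervised full-covariance Gaussian mixture:
one component per code, means initialized at the target coordinates, equal
initial weights, covariances at `sigma0 · I` (default 1e-5, the scale of a
tight cluster in ratio units). Because means start on the targets and
clusters are separated by design, EM refines rather than permutes —
component index equals code index by construction. Weights are free after
initialization (a `freeze_weights` switch pins them equal). Each bead gets
its maximum-responsibility code with the responsibility as probability
(log-sum-exp normalized over codes) and its log. An optional `min_prob`
post-filter marks ambiguous beads as code −1 (off by default).

**QC.** Confidence ellipse axis lengths are `2 z √λ` per covariance
eigenvalue with `z` the exact two-sided normal quantile (1.95996… at 95%,
conventionally printed 1.96); eigenvectors give the orientation. Cluster
quality reports codes found, designed codes with zero beads (missing), and
the mean silhouette coefficient on the transformed ratios under the
assigned labels. The silhouette's full range is [−1, 1]; for clustered bead
data it lives in (0, 1], reaching exactly 1 when clusters collapse to
points, and it is flagged undefined with fewer than two distinct codes.

## Synthetic scenes

The generator renders: bright-field (background 200, ring 50, core 190
counts — contrasts the default threshold settings detect without tuning),
emission channels as `A·w` per bead-core pixel with `w` = code ratios × a
per-bead invariant-species level draw (1000 ± 5%), a constant
background-spectrum term (level 100) and Gaussian read noise (SD 2), and a
fluorescence channel with ring-localized signal (500 ± 20) over background
under a linear illumination gradient (±7.5%). Beads (diameter 14 px) are
placed on a seed-shuffled jittered grid with ≥ 2 px separation — placement
cannot overlap by construction and is bit-reproducible from the seed.
Artifacts are rendered as dark rings with zero LNP weights. Per-bead code
noise is Gaussian per ratio dimension with SD = `ratio_noise_frac` ×
nearest-level spacing (default 10%) plus an optional `level_noise_slope` ×
level term (default 0) emulating the empirically observed growth of cluster
SD with mean LNP level from Poisson-like encapsulation.

The default code library is 48 codes (4 Dy × 4 Sm × 3 Tm levels over
[0, 0.9]), matching a realistic peptide-library design in three ratio
dimensions. End-to-end checks use ~40 beads per code (48-code recovery) and
20 scenes of 2,000 beads + 100 artifacts (filter purity) — sizes chosen so
the whole suite completes in well under an hour on one CPU while keeping
per-cluster and per-scene statistics meaningful.

What the synthetic scenes do **not** model: optical point-spread blur and
defocus, shot-noise-exact photon statistics, camera nonlinearity and fixed
pattern noise, bead aggregates/stacking out of the monolayer, and spectral
cross-talk beyond the linear mixing model. Passing tests therefore
establish the correctness of the algorithms under the stated imaging model,
not robustness to every optical artifact of a real instrument; the
adaptive-threshold and filter defaults remain the knobs to adjust on real
data.

## Degenerate inputs and tie-breaks

Empty edge masks and fully filtered scenes yield empty results, not errors.
Nearest-target ties go to the lower code index; watershed label collisions
are resolved deterministically by the flooding order of the distance
transform. Zero-SD dimensions (data or targets) are an error naming the
dimension. Zero-area background regions make the affected statistic NaN and
flag the bead. CSV round trips preserve names and values to float-text
precision (`%.12g`).

## Known limitations

* The 2-SD filter is single-pass; heavily contaminated samples (≫ 5%
  artifacts) inflate the SD and can let marginal artifacts survive.
* The affine ICP cannot correct nonlinear (per-level) ratio distortions.
* Per-code kinetics across repeated imaging of the same field fit the data
  schema (the set dimension) but no dedicated kinetics analytics are
  provided.
* The circle-finding fallback reports idealized geometry only.
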