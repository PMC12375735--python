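# Methods

## Measurement model

The pipeline treats a 2D fluorescence image (a maximum-intensity
Z-projection of a thick section) as a calibrated raster with pixel size in
µm/pixel, and the analysis region (the manually traced lobe border) as an
input binary mask. All densities are normalised to the ROI area; nothing
outside the ROI is ever measured.

### Segmentation

1. **Perona–Malik anisotropic diffusion** (explicit 4-neighbour scheme,
   conductance `g(∇I) = exp(−(∇I/κ)²)`). Defaults: 10 iterations, step 0.2
   (stability requires ≤ 0.25), κ = 10% of the image dynamic range.
   Iterations = 0 disables it.
2. **Tubeness**: Gaussian-scale Hessian at σ (default 4 pixels, the
   conventional plugin setting; may be given in µm), eigenvalues
   λ₁ ≥ λ₂; output |λ₂| where λ₂ < 0, else 0. Bright ridges respond; blobs
   and dark ridges do not. Single-scale by design.
3. **Binarization** inside the ROI: Otsu (default), a percentile, or an
   absolute level. The applied threshold is recorded in every report.
   Optional cleanup: drop 8-connected objects below `min_object_px`
   (default off).

Validity domain of the single-scale filter (measured on noise-free
capsules at 1 µm/pixel, σ = 4): segmented area is within 10% of truth for
vessel radii ≈ 7–10 µm, overestimated ~40% at radius 2 (the filter
reconstructs a band of width tied to σ), underestimated 11–19% at radii
4–6, and collapses for radii ≳ 10 µm, where the response hollows at the
core and the mask can split into two parallel bands. Radius *measurements*
(below) are nevertheless accurate over 2–9.5 µm because the measured mask
tracks the true width even where its area is biased; quantitative area
comparisons should stay within the mid-range or use a scale-matched σ.

### Skeleton graph

The vessel mask is thinned with Lee's topology-preserving method
(Zhang–Suen retracts the tips of diagonal vessels by many pixels, which
truncates end branches). Skeleton pixels are classified by 8-neighbour
count: endpoints (1), slab (2), junction (≥ 3); 8-adjacent junction pixels
merge into one junction cluster = one branch point. Branches are the
traced paths between nodes; tracing order is raster-deterministic.
Node-free loops count as single branches; isolated pixels as zero-length
branches.

**Branch length** is measured on the ordered pixel path as a
resampled-chord polyline (every 3rd pixel plus the last; default). The
classical axial-1/diagonal-√2 step rule is available as
`length_method="steps"`, but it overestimates digital straight lines by up
to 8.2% at ~22.5° orientation, which is why it is not the default; the
chord estimator is orientation-unbiased to ~1%.

Two optional robustness operations, both off by default so the bare
published procedure is what runs unless asked otherwise:

- **Spur pruning** (`prune_spurs_um`): iteratively remove endpoint twigs
  shorter than a threshold that hang off junctions (thinning artifacts on
  noisy wide vessels), re-thinning after each pass; whole isolated branches
  are never removed.
- **Junction merging** (`junction_merge_um`): thinning can resolve one
  anatomical branch point of a thick junction into two triple-points
  bridged by 1–3 pixels; junction–junction branches shorter than the
  threshold (set it near the largest vessel diameter) are absorbed into a
  single cluster.

### Radii and stratification

The exact Euclidean distance map assigns every mask pixel its distance to
the nearest background pixel *center* (so a one-pixel-wide line has
centerline value 1). Centerline radii are `EDM × skeleton × pixel size`.
The per-branch radius is the **median** of its centerline radii, excluding
the 2 pixels adjacent to a junction cluster at either end (the EDM is
inflated where vessels meet); mean and max are available. On digitized
capsules this estimator reads `r + 1` pixels for an integer true radius
`r` — the half-pixel wall convention plus pixel quantization — so radius
recovery is accurate to ≤ 1 µm at 1 µm/pixel across 2–12 µm.

Branches are classified small/large at 7 µm (inclusive ≤ on small) and
short/long at 20 µm (inclusive ≤ on short); both thresholds are
configuration, not constants. Stratified totals satisfy exact conservation
(small + large = total; large∩short + large∩long = large). Length
histograms use right-closed bins (0,20], (20,40], (40,60], (60,∞), so a
branch exactly at a threshold lands in the same class in both views; the
4-bin default matches the 3 numerator degrees of freedom of the
interaction test.

### Group statistics

Per-metric comparisons use the classical pooled-variance (Student)
two-tailed unpaired *t*; the branch-length distribution uses a balanced
two-way repeated-measures (split-plot) ANOVA with group between-subject
and length-bin within-subject, computed from closed-form sums of squares;
the interaction F carries df ((g−1)(b−1), (N−g)(b−1)). No sphericity
correction is applied by default; Greenhouse–Geisser is available and
reports its ε. Post-hoc per-bin *t*-tests are Bonferroni-adjusted with
m = number of bins, and m is always reported. Shapiro–Wilk (3 ≤ n ≤ 5000)
assesses normality. Significance is 0.05 throughout.

## Synthetic data: what it emulates and what it does not

Vessels are **capsules** — straight centerline segments dilated by a
constant radius with disc caps — so mask membership, length, radius and
junction topology are analytically exact. Junction/endpoint ground truth
is defined on the specification graph (a point where ≥ 3 segment ends meet
is a junction), not on the raster, because raster junction geometry is
resolution-dependent. Rendering adds a Gaussian PSF (σ 1 µm) and noise
(default Gaussian, sd 5% of the foreground–background range); the
ground-truth mask is independent of blur and noise.

**Trees** (`sample_tree`): binary branching, radii tapering geometrically
from the root. Defaults model a thin capillary-scale tree — root radius
2.5 µm, taper 0.9, branch lengths 60–100 µm, branching angles 0.8–1.3 rad
— the regime in which skeleton morphometry is exact: junction-end
displacement of skeleton branch lengths is bounded by roughly
radius/sin(branch angle) (~3 px), so branches an order of magnitude longer
than the radius keep every branch inside a 5% length tolerance.
Characterization over 150 trees: topology recovery exact, 0/1050 branch
lengths outside max(5%, 2 px). Trees whose non-adjacent limbs would
approach within their summed radii are rejected and resampled, since
colliding capsules would create raster junctions absent from the
ground-truth graph. Short, thick, acute-angled trees leave this validity
domain: junction blobs then swallow or split branches, and counts are no
longer exact — a property of skeleton-based morphometry generally, not of
this implementation.

**Two-group studies** (`generate_study`): each sample is a field of
scattered, mutually non-overlapping segments in a 512 × 512 µm frame.
Branch counts per length bin are Poisson with intensities (32, 24, 16, 8)
over bins (0,20], (20,40], (40,60], (60,110] µm — short-branch dominated,
as capillary beds are. Independent Poisson bins with unequal means have
unequal variances and so mildly violate sphericity; the measured type-I
rate of the uncorrected interaction test under the null is ≈ 6.1% at
α = 0.05 (10,000 simulations, Monte-Carlo s.e. 0.24%) — inside a 5 ± 1.5%
calibration band, with the inflation attributable entirely to that
sphericity deviation (equal means give ≈ 5.1%).
A branch at least 35 µm long is a large-calibre vessel (radius 8–9.5 µm)
with probability 0.5, otherwise small (2–5 µm): an isolated capsule
shorter than ~2 diameters is a blob, not a tube, and lies outside the
validity domain of ridge segmentation, and calibres above ~10 µm hollow
out under the σ = 4 filter — both constraints keep the phantom inside the
method's operating range. Placement enforces an 8 µm wall-to-wall
clearance (twice the filter scale) so neighbouring vessels stay resolvable.
Group effects are multipliers on the expected short-branch count and on
the probability (hence expected total length) of large-calibre vessels;
the default "KO" group uses 0.3 for both, a strong phenotype. Ground
truth is generated identically with or without geometric placement, so
statistical calibration studies can skip rendering.

The generator does **not** emulate: curved or tapering vessels within a
branch, connected network topology in the study fields (segments are
isolated, so every branch has two endpoints), staining texture,
out-of-focus light, 3D structure, or anatomically realistic spatial
organisation. Passing tests therefore demonstrate correctness of the
measurement chain under known geometry and noise, not performance on real
histology.

## Analysis settings for the simulated noisy studies

The effect-direction study (and the example script) runs the pipeline with
`min_object_px=30`, `prune_spurs_um=12`, `junction_merge_um=12`: noise
specks smaller than any true vessel are dropped, skeleton twigs below the
shortest generated branch (6 µm, with margin) are pruned, and split
junction blobs of wide vessels are re-merged. These are the documented
robustness options a practitioner enables for noisy data; the pipeline
defaults keep all three off.

## Numerical choices and degenerate inputs

- All randomness flows from named integer seeds (NumPy `SeedSequence`
  spawning); identical inputs and configuration reproduce outputs
  bit-exactly, and tie-breaks in branch tracing follow raster scan order.
- Empty ROI → error; a threshold that empties the mask → warning + empty
  report; empty mask → empty skeleton and zero-valued report.
- Zero pooled variance in the *t*-test: equal means give t = 0, p = 1;
  unequal means are an error. Constant samples are rejected by
  Shapiro–Wilk. Incomplete or unbalanced ANOVA tables raise errors naming
  the missing cells.
- Validation studies use these problem sizes: 11 capsule calibres, 50
  trees (7 branches each), 1,000 random ≤ 32×32 masks against the
  brute-force EDM, 2,000 simulated null studies, and one 10-sample
  rendered study at 512 × 512 µm — sized so the whole validation runs in a
  few minutes on one CPU.

## Known limitations

- Single-scale tubeness bounds the measurable calibre range (~2–9.5 µm
  radius at σ = 4 and 1 µm/pixel); wider vessels need a larger σ or a
  multi-scale filter, which is out of scope.
- Branch lengths near junctions carry an irreducible uncertainty of a few
  pixels (medial-axis triple points shift by up to ~radius/sin(angle)).
- The per-branch radius summary is a median over a discretized EDM and
  carries the +0.5…1 pixel wall-convention bias; sub-pixel wall
  localisation is out of scope.
- The ANOVA assumes a complete balanced design; missing sections/animals
  must be handled upstream.
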