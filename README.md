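# vesselmorph

Automated morphometry of fluorescently labelled vascular networks in 2D
microscopy images — built for studies that compare vascular architecture
between experimental groups, such as knockout-vs-control comparisons of the
pituitary posterior-lobe capillary bed stained with isolectin B4.

Given a calibrated grayscale image (a maximum-intensity Z-projection) and a
manually traced region-of-interest mask, the pipeline measures:

- **vascular density** — segmented vessel area / ROI area;
- **branch and branch-point densities** per 10,000 µm² of ROI, from a
  skeleton-graph decomposition of the segmented vessels;
- **branch lengths** and their distribution over configurable bins
  (default (0,20], (20,40], (40,60], (60,∞) µm);
- **centerline radii** — for a centerline pixel, the Euclidean distance to
  the nearest background pixel (the vessel wall), read off the exact
  Euclidean distance map (EDM): `radius = EDM × skeleton × pixel size`;
- **stratified totals** — total centerline length of small-radius (≤ 7 µm)
  vs large-radius (> 7 µm) vessels, cross-split at 20 µm branch length;
- per-study **group statistics**: two-tailed unpaired Student *t*-tests per
  metric, a balanced two-way repeated-measures (split-plot) ANOVA whose
  group × length-bin interaction tests whether the group difference varies
  across the branch-length distribution (df = ((g−1)(b−1), (N−g)(b−1)); for
  2 groups of 5 across 4 bins, (3, 24)), Bonferroni-adjusted per-bin
  post-hoc tests, and Shapiro–Wilk normality checks.

The segmentation chain is the classical single-scale workflow: Perona–Malik
anisotropic diffusion, a Hessian "tubeness" ridge filter at scale σ = 4
pixels (output |λ₂| where λ₂ < 0), and thresholding (Otsu by default)
restricted to the ROI. Auxiliary measurements include the Cavalieri
serial-section volume estimator (Σ areas × 180 µm interval) and
object-based double-positive (colocalization) cell counting.

Because real microscopy ground truth is unknowable, the package ships a
**synthetic vessel generator**: networks of capsules (line segments dilated
by a constant radius) with analytically exact masks, lengths, radii and
junction topology, rendered with Gaussian PSF blur and noise; plus a
two-group study generator in which one group has fewer short branches and
fewer large-radius vessels. Every pipeline stage is validated against this
ground truth.

## Worked example

`examples/measure_single_vessel.py` renders one vessel of radius 5 µm and
length 100 µm with blur and noise, then measures it:

```
true:     1 branch, length 100.0 µm, radius 5.0 µm
measured: 1 branch(es), total length 102.0 µm, small-radius total 102.0 µm,
          large-radius total 0.0 µm
vascular density 0.0605 (vessel area / ROI area), threshold used 1.690
```

The measured length (102 µm vs 100) reflects pixel-level digitization; the
vessel is correctly classified small-radius (5 ≤ 7 µm), so the large-radius
stratum stays empty. `examples/two_group_study.py` runs a full simulated
knockout study; with the default design it prints, among other tables,

```
branch-length distribution: interaction F(3,24) = 12.99, p = 3.04e-05
```

i.e. the group difference in branch counts is concentrated in specific
length bins — by construction, the short-branch bins. The other examples
demonstrate skeleton-graph recovery on a known tree, radius/length
stratification, and the volume/colocalization utilities.

## Command line

A thin CLI wraps the library for batch use:

```bash
vesselmorph simulate --out study/ --n-per-group 5 --seed 0
vesselmorph run-sample image.tif roi.tif --pixel-size 1.0 --out report.json
vesselmorph run-study study/manifest.csv --pixel-size 1.0 --out results/
```

All parameters live in a YAML config (`--config`); every report embeds the
fully resolved configuration so results are reproducible bit-exactly.

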