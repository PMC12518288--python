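# plantreg

Multi-view plant point-cloud registration and morphological phenotyping.

Six colored point clouds of a potted plant — one per viewing angle (0°,
60°, ..., 300°), each reconstructed at an arbitrary scale — are merged into
a single metric 3D model, from which plant height, crown width and per-leaf
length/width are measured. The pipeline stages are:

1. **Preprocessing** — dark-noise color filtering (all RGB channels below a
   threshold, default 50), optional axis-aligned cropping, and statistical
   outlier removal on the mean-of-k-NN-distances statistic.
2. **Scale calibration** — the pot rim is located by color, a thin
   horizontal slice is cut and a circle fitted (algebraic Kåsa fit with
   nonlinear refinement); per-view radii γ₀..γ₅ drive per-view scale
   factors (reference view γ₂ by default) and, given the known pot
   diameter, a metric scale.
3. **Sphere localization** — six colored calibration spheres are segmented
   by color and each is fitted with an enhanced RANSAC: density-adaptive
   inlier threshold, weighted scoring `w = inlier_fraction / (μ + σ + ε)`
   over surface residuals, geometric constraints (radius window, center
   range) over the top-K candidates, and Levenberg–Marquardt refinement.
4. **Registration** — same-labeled sphere centers in adjacent views form
   corresponding pairs; SVD (Kabsch) gives pairwise rigid transforms that
   are chained to the 0° reference frame, then point-to-point ICP
   (max 100 iterations, RMSE tolerance 1e-8, trimmed correspondences)
   refines each view against the accumulated model before merging.
5. **Traits** — height above the pot rim, crown width as the diameter of
   the XY convex hull, and leaf length/width as literal two-point chords
   along the leaf's principal axes.

A synthetic scene generator (`plantreg.synth`) produces ground-truthed
multi-view acquisitions — pot cylinder, marker ring, parametric plant with
optionally curved leaves, per-view scale drift, hemispheric visibility
culling, Gaussian noise, dark leaf-edge points and uniform outliers — so
every stage is testable without real scans.

## CLI

```sh
# generate a ground-truthed synthetic scene bundle
plantreg synth --preset noisy --seed 7 --out scene/

# run the full pipeline on six views
plantreg register --views scene/view_0.ply scene/view_1.ply scene/view_2.ply \
    scene/view_3.ply scene/view_4.ply scene/view_5.ply \
    --known-pot-diameter 16 --seed 7 --out run/

# individual stages
plantreg spheres --cloud scene/view_0.ply --seed 7
plantreg traits --cloud run/merged.ply --leaf-labels 8,9 --reference-z 8.0
plantreg evaluate --test run/merged.ply --reference scene/world.ply
```

`register` writes `merged.ply`, per-view 4×4 transform matrices
(`transform_view*.txt`), a `report.json` with per-view γᵢ, scale factors,
sphere weights, ICP RMSE and overlap fractions, and `traits.tsv` when
labels are available. A YAML config (`--config`) can override any stage's
parameters; CLI flags win over config keys.

## File formats

Point clouds are PLY (ASCII or binary little-endian) with `x,y,z` doubles,
`red,green,blue` uchar, and an optional integer `label` property (−1 =
unlabeled). Coordinates are centimetres, z-up, pot base near z = 0.
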