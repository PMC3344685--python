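# Methods

`prostereo` implements design-based stereology — the inference of 3D
quantities (volume, length, surface, number) from 2D sections — and
validates every estimator against synthetic tissue with analytically known
truth.  This note records the models, the numerical choices, and what the
validation does and does not demonstrate.

## The phantom model

A phantom is a rectangular tissue block discretized on a cubic voxel grid
(labels: lumen, epithelium, stroma; the block occupies the half-open box
`[0, edge)` per axis and a voxel's position is its center).  Glandular
tubules are straight capped cylinders: a lumen core of radius `r_lu` over
the axial interval `[t_ep, L − t_ep]`, wrapped in an epithelial shell of
outer radius `r_lu + t_ep` with flat epithelial end caps, so tubules are
closed and the lumen never touches the block boundary.  Real acini are
branched tubulo-alveolar structures; straight cylinders are used because
all the identities under test (Delesse, `Lv = 2·Q_A`, cycloid `Sv`) are
shape-generic, and cylinders admit closed-form truth.  Sphere suspensions
(lumen balls in epithelial shells) are available for surface validation.

Placement is rejection sampling: isotropic (or fixed-axis) orientation,
centerline entirely inside the block, non-overlap enforced with one voxel
of clearance; a bounded attempt budget turns an over-dense request into a
`PackingError`.  If overlap is explicitly allowed, a contested voxel goes
to the nearest centerline.  Stromal particles (mast cells, macrophages)
are seeded with per-class Poisson counts of mean `density × stroma volume`
and positions uniform over stroma.

Two consequences of this construction matter for sampling:

* **Non-overlap caps the glandular volume fraction.** Randomly placed hard
  cylinders cannot approach the ~80% glandular fraction of real prostate;
  the cohort simulator therefore scales the published volume-density
  targets to a packable level (scale 0.12) while keeping the between-group
  ratios.  The weight/volume channel — the study's headline endpoint —
  uses the published means and SDs directly.
* **The block is inhomogeneous.** Because centerlines are confined to the
  interior, a stroma-only layer hugs the boundary.  Pooled ratio
  estimators remain unbiased only if every part of the block is sampled
  with equal intensity; see the weighting note below.

## Ground truth

* `Vv`: exact voxel counting (so section-based estimates are compared with
  the discretized object they actually sample, not the continuum limit).
* `Lv`: summed generator centerline length over block volume.
* `Sv`: voxel-face counting of the lumen|epithelium interface multiplied
  by 2/3.  Face counting measures the surface integral of
  `|nx|+|ny|+|nz|`, which is exactly 3/2 of the area for a sphere or any
  isotropically oriented surface; `scripts/calibrate_surface_factor.py`
  reproduces the factor (0.662–0.666 for balls of radius 10–100 voxels).
  For a *fixed-axis* cylinder the face factor is 4/π, not 3/2, so the
  voxel `sv` of fixed-orientation phantoms is biased; closed forms from
  the generator (`phantom.analytic_truth`) are exact in every case.
* `Nv`: particle count over stroma voxel volume.

## Sampling design

IUR planes are drawn directly: azimuth uniform on `[0, 2π)`, cosine of the
colatitude uniform on `[0, 1]`, offset uniform over the block's support
along the normal — distribution-equivalent to the physical two-step
rotation protocol and exactly testable.  Each plane carries a "vertical"
axis (the projection of the global z axis onto the plane; x if degenerate)
for cycloid orientation; under IUR sampling any fixed convention is valid.

A full digital section assigns each pixel the label of the voxel
containing its center (default pixel = voxel size; finer sampling only
exposes the voxel cut's own disconnections).  Systematic square fields
with a single uniform random start tile the section; fields without
tissue are skipped and the survivors are subsampled systematically to the
requested count (default 22 per section).

**Inverse-sampling-fraction weighting.** When a fixed number of fields is
drawn from sections that offer different numbers of tissue-containing
candidates, each section's sums must be scaled by
`candidates / sampled` before pooling, otherwise sparse (corner-grazing,
stroma-rich) sections are over-represented — on these phantoms an
unweighted pool underestimates glandular `Vv` by >10%.
`systematic_fields(..., return_info=True)` exposes the weight and every
pooled estimator in the package applies it.

Per-animal ratio estimates (ratio-of-sums over one animal's fields) carry
the usual small-sample ratio bias, of order 1/sections; validation of
estimator unbiasedness therefore tests the grand pooled ratio across
replicates, with a Monte-Carlo SE from the replicate spread by
ratio-estimator linearization.

## Estimators and their numerical choices

* **Delesse `Vv`** — pooled compartment pixels over pooled in-block
  pixels (ratio of sums, never mean of ratios).
* **Profile counting / `Lv = 2 Q_A`** — a profile is one 8-connected
  component of lumen ∪ epithelium.  The unbiased counting frame uses the
  half-open forbidden rule `{x < x0, y ≥ y0} ∪ {y < y0, x < x1}` (left
  edge with its upward extension; lower edge with the downward extension
  at the lower-right corner), which counts each connected profile exactly
  once under a frame tiling — verified by an exhaustive tiling test.  Two
  digital pre-processing steps were calibrated once against a continuum
  tube–plane intersection oracle and then frozen: a 3×3 binary closing
  (voxel aliasing opens 1-pixel gaps in thin oblique profiles) and a
  4-pixel minimum profile area (aliasing specks and sub-pixel tangential
  slivers are not identifiable profiles).  The `Q_A` denominator is the
  in-tissue area inside the frame, which equals the full frame area for
  interior frames and keeps boundary frames unbiased.
  Counting *tube* profiles rather than centerline transections carries an
  intrinsic positive bias of ≈ `π r_out / L` (the tube's mean caliper
  exceeds `L/2` by `π r_out / 2`); the identity is therefore validated on
  thin, long tubules (`r_out/L = 1/140`, bias ≈ 2%) and the default
  fat-tubule cohort phantoms report `Lv` with this approximation, exactly
  as the method does on real acini.
* **Cycloid `Sv = 2 I / L_T`** — arcs `(a(θ−sinθ), a(1−cosθ))`,
  `θ ∈ [0, π]` (length `4a`, minor axis along the vertical), tiled over
  each field.  Intercepts are exact polyline intersections between the
  arcs and a *sub-pixel* boundary: the lumen indicator is Gaussian
  smoothed (σ = 0.8 px) and its 0.5-level contour extracted.  Counting
  raw label transitions along the arc, or intersecting the unsmoothed
  marching-squares contour, systematically overcounts by ~5–8% because
  the pixel staircase is crossed multiple times where the arc runs
  obliquely; the smoothed contour removes the staircase (the level-set
  shift it introduces is `O(σ²κ)`, ≈ 0.02 px here).  A crossing is
  scored only when the labels flanking it along the arc belong to the
  requested compartment pair.  `L_T` is the arc length over in-block
  pixels.
* **Optical disector `Nv`** — the look-up plane sits at depth 0, the
  reference plane at depth `h`; a (point) particle is counted when its
  depth lies in the half-open interval `(0, h]` — in focus at the look-up
  plane means excluded — and its lateral position falls in the counting
  frame (half-open rectangle for points).  Stacked disectors and tiled
  frames therefore count every particle exactly once (asserted as integer
  equality).  `Nv` divides by delineated stroma area on the reference
  section × `h`.
* **Scalar conversions** — `Vt` = fresh weight × 1.0 mm³/mg (specific
  gravity 1), `V = Vv·Vt/100`, `L = Lv·Vt`, `S = Sv·Vt`.  The source
  tables print `L` divided by 1000 and `S` divided by 100; `paper_scale` /
  `paper_mode` flags reproduce those reporting conventions, dimensionally
  standard values are the default internally.

## Densitometry

Optical density per pixel is `log10(I_ref / max(I, 1))` against a white
reference, clipped at OD 3 to bound the log blow-up of near-zero pixels;
IOD is the sum over a fixed rectangle centred on the nucleus (default
21×21 px, 100 nuclei per group).  Synthetic nuclei are Gaussian-profile
absorbers on a bright background; a group's `transmittance_factor m`
subtracts `log10 m` from every stained pixel's OD (floored at 0), so
doubling transmittance lowers IOD without breaking the background.  No
background subtraction is applied (fixed reference white); the choice is
exposed as the `incident_reference` argument.

## Statistics

Balanced two-way fixed-effects ANOVA with interaction from explicit
cell/marginal means (`SS_total = SS_A + SS_B + SS_AB + SS_err` holds to
1e-9 by construction and is asserted); pooled-variance two-sided Student
t; Mann-Whitney U from midranks with exact enumeration when
`n_a + n_b ≤ 12` without ties, else a tie-corrected normal approximation
with continuity correction.  Tail probabilities come from scipy's F/t/
normal distributions; statsmodels and scipy serve as independent oracles
in the tests only.  Group summaries are mean ± sample SD (n−1); a single
observation reports SD 0 with an explicit `sd_defined = False` flag.
Significance is flagged at p ≤ 0.05; no multiple-testing correction is
applied by default (an optional Holm adjustment is provided).  Which
endpoints receive t vs Mann-Whitney is not fixed by the emulated design;
the report computes both for morphometric endpoints and Mann-Whitney for
counts, and says so.

## Cohort simulator defaults

Six groups (control/treated × 43, 63, 93 days), 5 animals each.  Fresh
weights are truncated normals with the published group means ± SD (e.g.
C93 423.08 ± 74.44 mg vs CBZ93 260.24 ± 46.80 mg, an effect of ≈ 2.6
pooled SD).  Phantom targets: published `Lv` magnitudes; volume densities
scaled by 0.12 (see above); per-animal targets jittered with CV 0.10.
Particle intensities for mast cells/macrophages are *synthetic* defaults
(the published values exist only as figures) that preserve the reported
significance directions; the treated 93-day group's nuclei transmit 2× the
light of controls.  Default sampling effort per animal: 3 IUR sections ×
22 fields of 0.2 mm (block 0.8 mm, voxel 4 µm, section thickness 5 µm),
10 disector stacks (frame 0.4 mm, h = 0.05 mm).  Relative prostate weight
is weight/body-weight × 100 when a body weight is supplied; the published
relative-weight column for the 93-day groups is not arithmetically
consistent with any plausible body weight and is not used.

## Validation battery and problem sizes

`tests/test_acceptance.py` and `scripts/acceptance.py` run the same
experiments (the script re-runs them from scratch and writes JSON):

1. volume = weight identity on all six published rows (exact);
2. `V = Vv·Vt/100` on the treated 93-day rows (≤ 0.5–1%);
3. `L = Lv·Vt/1000` on three published rows (≤ 1%);
4. Delesse: 500 replicates × 5 IUR sections × 22 fields on the
   fat-tubule phantom; grand pooled estimate within 3 Monte-Carlo SE of
   voxel truth per compartment;
5. `Lv`: 150 sections × 22 fields on the thin-tubule phantom (240 tubules,
   `r_out/L` = 1/140), within 5% of centerline truth;
6. cycloid `Sv`: 150 sections on a 60-ball suspension, within 5%, and
   `sv/vv = 3/r` within 5%;
7. disector: a 20 × 4 × 4 tiling of the seeded stroma block counts every
   particle exactly once, and 110 pooled IUR disectors land within 3
   counting SE of the 150 mm⁻³ intensity;
8. statistics: exact Mann-Whitney equals enumeration on all 20 untied
   3-vs-3 rankings; the ANOVA identity closes to 1e-9; the pairwise t's
   empirical type-I error over 10⁴ null simulations is 5 ± 1%;
9. IOD: exact scale equivariance, monotonicity, and correct group-mean
   ordering in 100/100 replicates at a 2× transmittance contrast;
10. power: the C93-vs-CBZ93 weight decrease is detected (t, p ≤ 0.05) in
    ≥ 80% of 200 simulated cohorts (observed ≈ 92–94%).

The problem sizes above are the package's validation design; the whole
battery runs in about two minutes.

## What passing does and does not show

The phantoms share the estimators' geometric assumptions exactly (sharp
labels, point particles, no deformation); passing demonstrates the
correctness of the sampling design and counting rules, not robustness to
staining artifacts, tissue shrinkage, lost caps, segmentation error, or
branched gland topology — none of which are simulated.  Printed-table
checks validate internal arithmetic of the published summaries, not the
biology.  One published cell (C93 stroma volume) deviates 3.2% from the
product of its printed factors; the consistency check reports it as a
failed cell rather than masking it, consistent with per-animal products
averaging differently than products of averages.
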