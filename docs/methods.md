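# Methods

`rhizofract` emulates a two-system root-phenotyping experiment: contrasting
soybean-like root architectures are grown *in silico*, imaged either as 2-D
binary photographs (rhizobox) or as 3-D CT-like voxel volumes (pot), reduced
to unit-thickness skeletons, and measured for total root length and
box/cube-counting fractal dimension (FD). This note records the models,
parameters and numerical choices, and what the synthetic data can and cannot
show about real plants.

## Root growth model

Roots are polylines in cm grown by discrete steps. The coordinate frame is
right-handed with z pointing downward from the sowing point at the
top-center of the domain. At each step the heading `d` is updated as

    d <- normalize((1 - g) * d + g * e_z) + Gaussian deflection,

where `g` is the `gravitropism` weight in [0, 1] and the deflection is an
isotropic Gaussian vector (SD 0.18 per step, module constant) followed by
re-normalization. This is the simplest model that produces both a nearly
straight, plunging taproot and wandering laterals. Laterals experience only
15 % of the nominal gravitropic pull (`LATERAL_GRAVITROPISM_FACTOR`):
applied at full strength, every lateral turns vertical within two steps and
the architectural contrast between archetypes collapses.

Laterals arise as a Poisson process along their parent: the count is
Poisson(`lateral_density_per_cm` x parent arc length) with attachment
positions uniform along the arc (a memoryless model matching the per-cm
parameterization). Branch polar angles are Gaussian
(`branch_angle_mean_deg` +/- `branch_angle_sd_deg` from the local parent
tangent) with uniform azimuth; lateral lengths are log-normal, specified by
natural-scale mean and SD. A secondary bears tertiaries with probability
`tertiary_prob`, reusing the same spawning density; tertiary lengths are
the secondary length distribution scaled by 0.35 (`TERTIARY_LENGTH_SCALE`),
so tertiaries stay visibly shorter than their parents. Branching stops at
order 2.

Confinement: a growth step that would exit the domain is clipped at the
boundary and the next step is re-aimed inward (no reflection, which would
produce artificial wall-running density). The length budget is consumed by
*realized* arc length, so an unbranched taproot with a 10 cm budget has a
ground-truth length of exactly 10 cm. All randomness flows through a single
`numpy.random.default_rng(seed)` stream consumed in segment-id order;
equal (params, domain, seed) reproduce a system bitwise.

### Archetypes

The two presets encode the qualitative contrast between a taproot-dominant
cultivar and a highly branched one at the V1 stage. No quantitative
branching rates are available for the real cultivars, so the constants were
chosen once to give realistic magnitudes and the documented ordering, not to
match any measured mean:

| parameter | casino | woodstock |
|---|---|---|
| taproot_length_cm | 20 | 24 |
| step_cm | 0.5 | 0.5 |
| lateral_density_per_cm | 0.25 | 2.0 |
| lateral_length_mean_cm (SD) | 1.0 (0.5) | 4.0 (2.0) |
| tertiary_prob | 0.02 | 0.6 |
| branch_angle_mean_deg (SD) | 70 (15) | 65 (20) |
| gravitropism | 0.85 | 0.75 |

Expected ground-truth totals are roughly 25 cm (casino-like) and 540 cm
(woodstock-like) in the rhizobox — the same order of magnitude as published
2-D measurements of such cultivars, with a fold change of about 20x. In the
13-cm pot the contrast compresses (wall clipping curtails long laterals),
mirroring the smaller contrast real 3-D systems show.

## Imaging surrogates

*2-D photographs.* A rhizobox system is projected along its thin (y) axis
onto a (z, x) image covering the 40.6 x 25.4 cm face. Each polyline edge is
rasterized by its **supercover** — every pixel the continuous segment
passes through, found by splitting the segment at all gridline crossings
and flooring interval midpoints — which guarantees 8-connectivity of
1-px-wide roots; optional dilation sets a thicker line. Cells are
`floor(coordinate / pitch)`, grids anchored at the array origin, so
rasterization is translation-consistent for whole-pitch shifts.

*3-D CT volumes.* Systems are voxelized by the 3-D supercover on a
`VoxelGrid` (array order z, y, x; slice 0 at the sowing depth; grid
centered on the sowing point in x/y), then dilated by `radius_voxels`.
The clinical-geometry grid (512 x 512 x 500 voxels of 0.21 x 0.21 x 0.2 mm,
1.156 dm^3 per pot) is supported; the default desk-scale grid is 128^3 over
the 15 x 13 cm pot (~1.2 x 1.2 x 1.0 mm voxels). The CT surrogate assigns
one intensity to root voxels and one to the medium plus i.i.d. Gaussian
noise — a minimal two-material model sufficient to exercise thresholding;
it omits beam hardening, partial-volume blur and soil heterogeneity, so
segmentation scores here are upper bounds on real-scan performance.
Default contrast/noise (60/0 +/- 10) is arbitrary and exposed in config.

## Segmentation

A global threshold followed by 26-connected component filtering (keep the
component containing a known sowing index, else all components of at least
`min_component_voxels`). The default threshold is the **valley of the
iteratively smoothed 256-bin histogram** (`skimage.filters
.threshold_minimum`) rather than Otsu: root voxels are only a few percent
of a scanned pot, and under that class imbalance Otsu's variance criterion
cuts inside the dominant medium mode (measured Dice 0.10 on a standard
phantom where the valley split reaches 0.99). Otsu and a fixed threshold
remain selectable. A split that keeps the majority of the volume is treated
as "no root detected" (warning + empty mask), since roots are never the
majority material. No morphological cleanup is applied by default.

## Skeletonization

2-D thinning and 3-D medial-axis thinning (simple-point deletion with
directional sub-iterations) via `skimage.morphology.skeletonize`. The
normative contract — skeleton a subset of the mask, unit thickness,
connected-component count preserved, idempotent — is what the test suite
checks; the specific published algorithm behind it is an implementation
detail. No spur pruning by default; `prune_skeleton` exposes optional
tip-erosion pruning (it slightly lowers FD by removing short branches).

## Traits

*Total root length.* The skeleton's foreground cells form a graph
(8-neighborhood in 2-D, 26 in 3-D) with edge weight the Euclidean distance
between cell centers under the per-axis pitch. Length is the total weight
of a minimum-spanning forest (scipy), converted to cm. The MST avoids
double-counting diagonal+orthogonal cliques and its total weight is unique
even under ties, hence deterministic. Digitization bias: on 2-D rasterized
polylines the estimate lands within +/- 4 % of geometric truth (the chain
overestimate of oblique runs roughly cancels skeleton end erosion); in 3-D
the 26-neighbor chain overestimates oblique runs by up to ~10 %. Full
systems in 2-D *underestimate* ground truth because projection overlaps
distinct roots — the same occlusion that affects real photographs.

*Fractal dimension.* Dyadic scale schedule s = 1, 2, 4, ..,
floor(min_dim / 4) (at least 3 boxes per axis at the coarsest scale; at
least 4 scales required), grids anchored at the array origin with no offset
optimization, occupied counts, unweighted OLS of log N on log(1/s). No
automatic linear-range selection — reproducibility is preferred, and the
fit diagnostic r^2 is exposed instead. The anchored dyadic construction
makes every estimate provably lie in [0, dims]; digitized Euclidean objects
recover their integer dimensions exactly (point 0, line 1, plane 2,
volume 3). Because the real study's exact scale schedule and fit range are
not published, numeric equality with its printed FD values is not claimed;
the reproducible surfaces are the hard bounds, the Euclidean limits, and
the archetype ordering.

## Reporting

Per-plant records aggregate to mean +/- SD per archetype x system, with the
sample (n-1) SD; published tables of this kind do not always state whether
"+/-" is SD or SE, and this package documents its choice as SD. Groups of
one plant report SD as missing, never zero. `run_pipeline` derives every
plant's seed arithmetically from the base seed and logs all seeds and
parameters, so a rerun under the same config is byte-identical.

## Problem sizes

Default analysis sizes — chosen as desk-scale conditions that keep all
Monte-Carlo surfaces (confinement, bounds, ordering) well sampled — are
0.05 cm/px for 2-D images (813 x 509 px), 128^3 voxels for 3-D batch
analyses, 64^3 for segmentation phantoms, and 25-30 seeds per archetype
per system for batch statistics.

## Known limitations

- No physiological realism: no nutrient/water response, no diameter
  tapering (a single rasterization thickness), no root decay.
- The CT surrogate's noise model is additive Gaussian only; real scans
  contain correlated artifacts that would lower segmentation Dice.
- 3-D skeleton length carries the digital chain-length overestimate noted
  above; calibrated length estimators are out of scope.
- FD estimates depend mildly on the scale schedule; only the default dyadic
  schedule is validated here.
- Real-plant trait values cannot be recomputed from synthetic data; the
  pipeline reproduces the *structure* of the comparison (tables, ratios,
  orderings and bounds), not the measured numbers.
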