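# Methods

This note documents the models, conventions, and numerical choices behind
`svpools`, and what the synthetic validation does and does not establish.

## Data model and inclusion filters

A *section* is one representative middle cross-section of a synapse: vesicle
centers in nm, a recycled/resting label per vesicle (recycled =
photoconverted PC+), one or more active-zone (AZ) polyline traces, and an
optional cluster-boundary polygon. All geometry is continuous 2D in nm;
there is no pixel grid.

Sections enter group analysis only if

1. recycled fraction **strictly** exceeds 0.049 (a section at exactly 0.049
   is excluded) — low-fraction sections cannot be distinguished from
   spurious labeling events such as spontaneous recycling or misclassified
   dense-core vesicle profiles;
2. total vesicle count is at most 100 (the bound itself is included), which
   keeps single-section comparisons uniform across groups;
3. exactly one AZ is present (multi-AZ sections are ambiguous for
   AZ-referenced measures).

The three rules are applied conjunctively; a section violating several
records the first reason in the fixed order low_fraction →
too_many_vesicles → multi_az, so reports are deterministic. Sections with
zero recycled vesicles fall under the low-fraction rule (fraction 0) rather
than a special case. Sections with no vesicles or no AZ are recorded as
`invalid`.

Vesicle radius defaults to 20 nm (small synaptic vesicles are ≈ 40 nm in
diameter) and may be overridden per record; it matters only for the
surface-based AZ-pool geometry below.

## Orientation and distances

Each section is rigidly re-oriented: the principal axis of the AZ trace is
rotated to horizontal, the AZ center translated to the origin, and the
section rotated a further 180° if the vesicle centroid lies below the axis.
Only rotation and translation are used — pairwise distances are preserved to
machine precision — so the lateral handedness of a section is arbitrary
(sections are sampled at all orientations in the tissue), and orientation
output is unique only up to a left-right mirror. For a curved AZ trace the
"horizontal through the origin" and "center at the origin" conventions can
disagree by the center's residual offset from the fitted line; we pin the
center to the origin.

All quantitative distance statistics use the raw Euclidean distance from
each vesicle *center* to the nearest point on the AZ polyline (interior
segment projections included), computed with exact point–segment geometry.
Distances are never taken from the normalized density-map coordinates.

## Density maps

Per-section 10×10 maps place each vesicle of one pool into a grid cell by
normalizing its coordinates to the cluster extent (the supplied boundary
polygon's bounding box, or the bounding box of all vesicle centers). Bins
are half-open with the final bin closed, so boundary vesicles are never
dropped. Each pool is normalized to itself (cells sum to 1). Population
maps average each section's map with its left-right mirror image, average
across sections, apply a Gaussian filter (default σ = 1 grid cell,
reflective boundaries), then fold and renormalize once more. The final fold
makes the mirror symmetry exact in floating point rather than approximate;
σ and the boundary mode are configurable. These maps are visual summaries
only and feed no hypothesis test.

## Clustering index

For each focal recycled vesicle and each cumulative radius r (20 nm steps,
up to the smallest multiple of the step covering the maximal pairwise
distance), the local fraction is

    (# recycled within r of the focal, focal excluded)
    / (# vesicles within r of the focal, focal excluded),

averaged over focal vesicles; focal vesicles with empty neighborhoods at a
radius are skipped at that radius, and the number contributing is recorded.
The normalization reference is the focal-excluded whole-cluster fraction
(N_R − 1)/(N − 1), which forces the index to exactly 1 at the enclosing
radius (the value is written directly there so floating summation cannot
perturb the identity). Cumulative bins (not annuli) are the default because
the index is defined by its convergence to the whole-cluster value.

When a section has exactly one recycled vesicle the reference is 0 and the
normalized index is undefined; we return NaN (the absolute fractions remain
defined) and population-level tests skip NaN contributions. Profiles of
different sections end at different radii; when aligned on a common grid, a
profile evaluated beyond its own end contributes its limiting value 1 (all
vesicles enclosed) — the mathematically forced continuation of the
cumulative definition.

Per-radius population tests are two-tailed one-sample t tests of the
per-synapse indices against 1 (default α = 0.01; configurable). Radii where
fewer than two synapses contribute, or where the sample is exactly constant,
are reported untestable rather than significant. The *peak cluster
amplitude* is the arithmetic mean of the index over the 40–240 nm window
(11 radii); truncated profiles are averaged over the radii they cover and
flagged. Note that with a hard-core packing of 40 nm minimum center
separation, the 40 nm bin has empty neighborhoods and is untestable — a
geometric property, not a software limitation.

## Compartments

Vesicles are banded by center-to-nearest-AZ distance: active zone [0, 35),
front [35, 100), middle [100, 300), rear/side [300, 800] nm; distances
beyond 800 nm are clamped to rear/side with a warning. Bands are half-open
so every distance maps to exactly one compartment. Compartment-restricted
clustering profiles restrict both focal vesicles and neighbors to the
band's members; bands with fewer than two vesicles or fewer than two
recycled members (undefined normalization) are omitted for that synapse.

Group comparisons use a two-way ANOVA (condition × compartment, type II sums
of squares via OLS) on per-synapse compartment values, with per-compartment
unpaired t tests adjusted by both Sidak and Bonferroni (both are reported;
neither is privileged), and one-way Kruskal–Wallis across compartments
within a condition. Designs with an empty or singleton cell are refused
with a diagnostic naming the cell.

## AZ-associated pool

A vesicle belongs to the AZ-associated pool iff

1. its membrane approaches the release-site membrane within 20 nm:
   (nearest-AZ center distance − radius) ≤ 20 nm, and
2. it has a clear line of sight: the straight segment from its center to
   its nearest AZ point intersects no other vesicle's disc interior.
   Tangency does not occlude (strict inequality).

The gap rule is surface-based because the criterion refers to the membrane;
compartment bands are center-based because they are stated as vesicle
distances without a membrane qualifier. Both conventions are exposed as
configuration. Membership is monotone in the gap parameter. An empty pool
yields an undefined (flagged) fraction, not an error.

## Statistical conventions

Group summaries are mean ± SEM with the sample SD (n−1 denominator);
SEM = SD/√n. The "potentiated" threshold is control mean + 2·SD, and
classification above it is strict. Quartile bins sort ascending and split
into 4 contiguous bins with remainders given to the upper bins (n = 7 →
sizes 1, 2, 2, 2); the top-25% subset takes the highest ⌈n/4⌉ values.
The high-fraction matched subset sorts controls descending and selects the
prefix (k ≥ 2) whose mean is closest to the target, ties toward larger k.
Two-sample comparisons are two-tailed unpaired t tests; variance
comparisons put the larger sample variance in the F numerator with
two-sided p = min(1, 2·SF). Correlations are Spearman rank (average ranks
for ties); constant vectors are an error, not rho = 0. The size-corrected
correlation fits an ordinary least-squares line of fraction on total
vesicle count in the reference group and rank-correlates the test group's
residuals from that line against count; the linear form matches the linear
fits used alongside the scatterplots this analysis summarizes.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth per section:

- **Geometry**: a flattened ellipse (default semi-axes 400 × 300 nm,
  centered 0.6·b above the AZ line and cut at y = 0) bounds the cluster;
  the AZ is a 200 nm horizontal segment centered on the flat bottom.
- **Packing**: random sequential adsorption with minimum center separation
  equal to the hard-core diameter (default 2 × 20 nm). RSA rather than a
  Gibbs sampler because densities here (≤ 100 vesicles/section, ≈ 72% of
  the RSA jamming count at most) are far from the regime where RSA's
  structure differs materially, and RSA is simple and exactly reproducible.
  Packing that places fewer than 90% of the requested count after 10⁴·count
  attempts raises an error naming the attempted density.
- **Counts**: lognormal (median 45, σ = 0.35), clipped to [10, 100] —
  matched to the per-synapse totals implied by the study's pooled vesicle
  counts (≈ 44 vesicles/section).
- **Fractions**: per-synapse recycled probability p from a Beta law
  re-parameterized by (mean, SD), so condition defaults can be set directly
  from printed summary statistics: control (0.16, 0.10), LTP (0.30, 0.21),
  forskolin (0.22, 0.14).
- **AZ bias**: per-vesicle recycled probabilities proportional to
  exp(−d_AZ/λ) (default λ = 150 nm for LTP/forskolin, none for control),
  rescaled to expected fraction p; probabilities capped at 1 with the
  excess redistributed over uncapped vesicles — an approximation to the
  target expectation that is exact whenever no cap binds.
- **Contagion** (off by default): the recycled count is drawn
  Binomial(n, p), then realized as seed vesicles plus their k nearest
  neighbors, preserving the drawn count exactly and planting local label
  clustering.

Reproducibility is bit-exact from (config, seed); study generation derives
child seeds from a master seed via `SeedSequence`.

**What the generator does not emulate**: the negative correlation between
synapse size and recycled fraction seen in real terminals (p is drawn
independently of the count), vesicle-size heterogeneity, curved or tilted
active zones, section-to-section tracing noise, and any 3D structure.
Passing tests therefore validate the *estimators and their calibration*
under the modeled structure, not biological claims about real tissue; the
size–fraction analyses are instead validated with explicitly constructed
planted-trend fixtures.

## Problem sizes in the validation suite

The calibration and recovery suites use 100 seeds × 72 synapses (parameter
recovery), 100 runs × 50 synapses (clustering null), 1000 repeats for
type-I calibration of the t and Kruskal–Wallis tests, and 40 seeds ×
20 synapses for planted-effect detection — sizes chosen to hold
Monte-Carlo error on each pass criterion comfortably below the margin being
asserted while keeping the default test run short.

## Known limitations

- The clustering index is undefined (NaN) for sections with one recycled
  vesicle; such sections still pass the inclusion filters when small.
- The AZ-bias rescaling is approximate when per-vesicle probability caps
  bind (strong bias with high p), slightly deflating the realized fraction.
- Orientation of a section whose AZ trace is strongly curved pins the AZ
  center, not the best-fit line, to the origin.
- The two-way ANOVA assumes per-cell normality of compartment values;
  fractions near 0 or 1 violate this, which is why the Kruskal–Wallis
  variant is also reported.
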