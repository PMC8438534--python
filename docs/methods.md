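# Methods

## Scope and model

`phenoscreen` reconstructs an image-based screening pipeline for
low-phosphorus tolerance in rice seedling panels grown under two
phosphorus regimes ("control" and "deficient"). It has four analysis
layers — image-derived geometry, derived physiology, tolerance indices,
and multivariate screening statistics — plus a synthetic-data layer that
generates both kinds of input with known ground truth.

The statistical backbone is the balanced two-way fixed-effects model

    Y_ijk = mu + alpha_i + beta_j + gamma_ij + e_ijk

for genotype i, P concentration j and replicate k. The simulator is the
generative inverse of this model: genotype effects i.i.d. N(0, sigma2_g),
interactions N(0, sigma2_gc), residuals N(0, sigma2_e), and a fixed
additive shift `conc_effect` on the deficient arm.

## Image geometry

Segmentation converts RGB to HSB and keeps pixels inside three inclusive
windows. The thresholds are configurable; the defaults (hue 60–180°,
saturation ≥ 0.25, brightness ≥ 0.20) capture green foliage on light
backgrounds and were fixed before any tuning against outputs. An
8-connected largest-component filter (on by default) suppresses colour
speckle, mirroring common ImageJ practice on thin leaves.

All geometry uses foreground *pixel centres* in (row, col) coordinates,
origin top-left. Consequences worth knowing:

- a single pixel has projected area of one pixel but zero hull area;
- a filled axis-aligned w × h pixel rectangle has hull area
  (w−1)(h−1) px², not wh;
- projected area can exceed hull area only through this convention's
  boundary half-pixels, so no inequality between the two is asserted
  beyond the hull-vertex allowance.

Calliper length is the maximum Feret diameter computed by the antipodal
rotating-calipers pass over the convex hull (scipy's Qhull provides the
hull; area by the shoelace formula, perimeter by edge sum). The minimum
enclosing circle uses Welzl's randomized incremental algorithm over hull
vertices with a fixed shuffle seed, making results deterministic; the
containment tolerance is 1e-10 of the point-set span. Eccentricity is
the moment-ellipse form sqrt(1 − l2/l1) from the eigenvalues of the
second central moment matrix of all foreground pixels; a formal
definition was chosen because "degree of radial symmetry" admits
several. Degenerate inputs: a single pixel gives eccentricity 0 and MEC
diameter 0; an exactly collinear foreground gives hull area 0 (with a
warning), perimeter twice the segment length, and eccentricity 1.

Leaf inclination is the angle between the upward image vertical
(decreasing row) and the lamina-joint → blade vector, in [0, 180]°,
computed at user- or generator-supplied landmarks. Automatic leaf
landmarking is out of scope — the measurement this emulates was manual.

Calibration comes from a line of known physical length; the scale is
known_length_mm divided by the endpoint distance in pixels. The
synthetic renderer records exact float endpoints in a JSON sidecar, so
scale recovery on synthetic data is exact by construction.

## Synthetic plants

The renderer draws leaves as half-open oriented boxes (membership of a
pixel centre: 0 ≤ t < L along the axis, |s| < W/2 across it) radiating
from a stem point; the top view uses the horizontal projection
L·sin(inclination) of each blade, side views draw the full blade at its
inclination, mirrored between front and back. An optional filled disk
("rosette") provides radially symmetric fixtures. Realism is explicitly
not a goal: the design goal is that ground truth be computable by brute
force from the noise-free mask — hull area via Qhull's own area, calliper
by exhaustive pairwise distances, MEC by exhaustive search over all
pair-diameter circles and triple circumcircles of hull vertices (capped
at 200 vertices), eccentricity in closed form. These oracles are
deliberately independent of the measurement-side implementations so the
two can check each other.

Gaussian pixel noise, when requested, is added after geometry is fixed;
ground truth always refers to the noise-free mask. The calibration line
is drawn in pure red, far from the default green segmentation window.

What the generator does *not* emulate: overlapping plants in one frame,
shadows and specular highlights, soil or solution background clutter,
perspective distortion, and curved or tapering blades. Passing the
end-to-end tests therefore shows the measurement chain is correct on
clean silhouettes at known scale, not that segmentation is robust to
field imagery.

## Derived physiology

PUE = (tissue P under control − under deficiency) / P applied. The
protocol this follows leaves the denominator's units unstated relative
to tissue P (mg/g vs mg/plant); it is treated as a user-supplied
positive scalar and simply sets the units of the result. Contribution
percentages share one kernel, 100·part/denominator, with the denominator
selecting the named measure (total leaf weight, total dry weight, shoot
or root dry weight). Total dry weight is defined as the sum of the
supplied parts (leaves + stem + root), which makes the dry-matter
partition sum to exactly 100 per plant. Contributions are computed per
replicate and then averaged within genotype × treatment, preserving
within-genotype variance for downstream statistics. The signed relative
difference 100·(deficient − control)/control is oriented so an increase
under deficiency (e.g. root thickening) is positive.

## Tolerance indices

The seven indices follow the classical forms (see README table). Two
definitional choices are worth flagging:

- MPI is the mean of the two arm means, [(Yns + Ys)]/2. A widely
  reprinted typographical form, "Yns + Ys/2", would break the exact
  identities Yns = MPI + TOL/2 and Ys = MPI − TOL/2 and give MPI the
  wrong units; the mean-productivity reading is used.
- Stress intensity, which appears in SSI's denominator, uses the
  Fischer–Maurer convention SI = 1 − Ȳs/Ȳns, with grand means taken as
  unweighted means over genotype means (equal to replicate means in a
  balanced design, and the genotype-mean convention otherwise).

Missing-value policy: SSI is undefined (NaN) when SI = 0; a genotype
with zero control mean gets NaN SSI and DTE with a warning while its
other indices remain defined; grand means exclude genotypes missing an
arm. Ranking uses average ranks for ties, descending for maximum-pattern
indices and ascending for minimum-pattern ones; the better half by rank
is labelled "tolerant". Index–trait correlations are computed against
deficient-arm genotype means, matching how such tables are usually
presented.

## Screening statistics

ANOVA uses the textbook balanced decomposition from cell and marginal
means, with each term's F tested against the error mean square and SS%
reported as the term's share of the total sum of squares (summing to
100 with the error term included). Unbalanced input is rejected with
advice rather than silently reweighted; the design this serves was
balanced, and a Type-I/II/III choice would otherwise leak in silently.
An independent cross-check against statsmodels' `anova_lm` is kept in
the test suite.

Heritability is estimated within one treatment from the one-way
genotype ANOVA: sigma2_g = max(0, (MS_G − MS_E)/r) (negative estimates
truncated to zero, keeping H² in [0, 100]), sigma2_p = sigma2_g +
sigma2_e/r, H² = 100·sigma2_g/sigma2_p. With both mean squares zero
(constant data) H² is reported as 0. GCV (not universally defined the
same way) is 100·sqrt(sigma2_g)/mean, the standard genotypic coefficient
of variation; CV is 100·sd/mean; skewness is the adjusted
Fisher–Pearson coefficient. Note that within a treatment the
between-genotype variance includes any G×C interaction variance; the
recovery tests therefore simulate with sigma2_gc = 0.

Correlation p-values are unadjusted two-sided t-tests; a Bonferroni
flag (default off) multiplies by the number of pairs, since the
convention this mirrors reports significance stars without naming a
correction.

PCA is computed by SVD of the column-centred (optionally unit-scaled)
genotype × trait matrix; explained percentages come from squared
singular values and sum to 100 over the min(n−1, p) retained
components. The sign of each component is fixed by requiring its
largest-magnitude loading to be positive, so results are deterministic
across runs and BLAS builds. The selection rule labels genotypes by
PC1/PC2 sign quadrant and flags them superior/inferior per selection
trait against the panel mean as threshold; the returned selection takes,
from each occupied quadrant, the genotype with the most and the one with
the fewest superior flags, guaranteeing representatives of contrasting
response from every quadrant.

Ward clustering uses scipy's `linkage(method="ward")` (the D2 criterion
on Euclidean distances) after optional row Z-scoring with the population
standard deviation, Z = (x − mu)/sigma — the heat-map convention in
which each row (trait) is scaled independently. Constant rows are an
error naming the row. Flat labels come from cutting at a requested
cluster count.

## Pipeline and determinism

The driver runs simulate → extract → indices → screen, with every source
of randomness derived from one seed. Each output file's SHA-256 is
recorded in a JSON manifest; a failing stage is recorded and stops the
run without deleting earlier outputs. PNG encoding, CSV formatting,
Welzl's fixed shuffle and seeded NumPy generators make repeat runs
byte-identical, which the test suite asserts.

## Problem sizes

The verification suite uses 50 random masks for the geometry oracles,
30 rendered views for end-to-end recovery, 1000 random stress pairs for
the index identities, and 50 simulations of 500 genotypes × 5 replicates
for heritability recovery — sizes chosen so Monte-Carlo error is well
inside the asserted tolerances (e.g. mean H² within 3 points of the true
95.24% at sigma2_g = 4, sigma2_e = 1, r = 5) while the whole suite runs
in well under a minute on one CPU.

## Known limitations

- No automatic leaf detection or landmarking; leaf angles need supplied
  points.
- Segmentation is colour-threshold based and tuned for controlled-light
  imagery on light backgrounds, not field scenes.
- Variance components come from fixed-effects ANOVA, not REML; the
  heritability formula assumes a balanced design.
- The renderer draws one plant per image; multi-plant scenes (several
  plants photographed together) are out of scope.
- Index aggregation across traits into a composite score is deliberately
  not provided; indices are inspected per trait.
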