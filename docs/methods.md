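# Methods

`lacumorph` quantifies osteocyte lacunae in 3D micro-CT volumes of cortical
and trabecular bone and runs the cohort statistics a clinical bone-biopsy
study would apply on top of those measurements. Because biopsy scans of
this kind are rarely shareable, the package ships a synthetic phantom and
cohort generator with exact ground truth; every stage is validated against
that ground truth or against closed-form/quadrature oracles.

## Image model and segmentation

A scan is a 3D grayscale grid with an isotropic voxel size in micrometers
(axis order z, y, x; physical position of a voxel center is
`(index + 0.5) * voxel_size`). Anisotropic voxels are rejected outright:
every shape metric below silently breaks under anisotropy, so there is no
fallback.

Mineralized bone and void are separated by a per-sample threshold, Otsu's
criterion on the histogram of in-region voxels. This is the deterministic
counterpart of thresholding "individualized" to each sample's gray-value
distribution; it assumes a roughly bimodal in-region histogram and fails
loudly on degenerate (constant) regions. Voids are the below-threshold
voxels inside the analyzed region. Connected components use
26-connectivity for voids (bone is implicitly 6-connected — the
complementary pair avoids topological paradoxes) and are classified by
volume:

* `sub_resolution` below `v_min` (default 50 um^3) — noise specks;
* `lacuna` between `v_min` and `v_max` (default 2000 um^3) and not
  touching the grid border;
* `large_void` otherwise — vascular canals, marrow space, and any
  border-truncated void.

The bounds bracket reported lacunar volume medians (~130–200 um^3) with
generous margins; both are configurable because the lacuna/pore boundary
is a convention, not a fact. Border-touching components are never lacunae
(a truncated shape biases every metric) but do count toward cortical
porosity. Ct.Po is the large-void fraction of the tissue volume; lacunar
porosity (~0.3%) is deliberately excluded so the number tracks the
vascular pore system.

## Per-lacuna morphometry

* **Lc.V** — voxel count x voxel_size^3.
* **Lc.SA** — area of a marching-cubes isosurface at the 0.5 level of the
  component's indicator grid after Gaussian pre-smoothing with sigma = 0.5
  voxel. Raw voxel-face counting overestimates the area of smooth surfaces
  by up to ~50% (staircase effect) and would bias sphericity low by a
  comparable factor. The smoothing width matters at lacunar scale: the
  minor axis of a typical lacuna is only 3–4 voxels at 1.2 um, and a
  1-voxel sigma erodes such shapes enough to underestimate their area by
  30–50%. Sigma 0.5 keeps digitized spheres and lacuna-scale ellipsoids
  within ~7% of their analytic areas; this was chosen by measuring clean
  digitized shapes against the quadrature oracle, and the unmeshable-speck
  fallback (voxel-face counting) is flagged on the record.
* **Lc.Sr** (sphericity) — `pi^(1/3) (6 V)^(2/3) / SA`, exactly 1 for a
  sphere. Values marginally above 1 can occur for tiny near-spheres by
  discretization; they are clamped to 1 and flagged.
* **Semi-axes** — from the eigenvalues of the voxel-position covariance
  tensor, `semi_axis_i = sqrt(5 lambda_i)`. For a solid uniform ellipsoid
  this is exact, and it is far more robust at small voxel counts than a
  least-squares surface fit. Components with fewer than 4 voxels or a
  rank-deficient covariance are flagged degenerate, with shape metrics
  left unassigned.
* **Lc.O** (oblateness) — `2 (b - c)/(a - c) - 1`, in [-1, 1]: -1 for
  prolate (cigar, b = c), +1 for oblate (disc, a = b), 0 for a sphere
  (near-sphere convention: a - c < 1e-6 a maps to 0). The definition is an
  isolated one-line function so an alternative convention can be swapped
  in; the sign convention here makes elongated lacunae negative, matching
  how prolate-leaning lacunar populations are reported.

## Tissue metrics

* **BV/TV** — bone voxels over envelope voxels (%).
* **Ct.Th** — mean local thickness by the largest-inscribed-sphere method:
  each bone voxel gets twice the radius of the largest sphere containing
  it that fits inside the cortex. Implemented as a descending sweep over
  inscribed-sphere radii where each radius costs one Euclidean distance
  transform; radii are binned (default 12 bins, bin-midpoint assignment)
  and the sweep stops once 98% of the bone is assigned, with stragglers
  falling back to their local 2 x EDT. Enclosed micro-voids (lacunae) are
  filled before the transform — Ct.Th is a tissue-scale metric and must
  not collapse because the cortex is peppered with micrometer holes — and
  the grid crop boundary is not treated as surface. On solid slabs the
  method is exact; with lacunar-scale voids it moves by well under 2%.

## Regional classification

Each lacuna is peripheral (< 20 um from the bone surface) or central
(otherwise; exactly at the cutoff is central, since "peripheral" is a
strict inequality). "Surface" means the bone/marrow, bone/exterior and
bone/canal interfaces: before the Euclidean distance transform, lacunar
voids and sub-resolution specks are refilled into the bone so neighboring
lacunae never define each other's surface, while large voids (canals,
marrow) remain background. Distances use the center-offset convention —
a voxel k layers from the surface plane (k = 0 adjacent) maps to
`(k + 0.5) * voxel_size` — and the field-of-view edge is not surface.
The distance is read at the lacuna centroid by default (stable under
segmentation jitter); a nearest-boundary-point variant is available via
`reference="boundary"`.

## Synthetic phantoms

A cortical phantom is a slab (default 72–110 um thick at desk scale)
crossed by straight cylindrical canals along one in-plane axis; a
trabecular phantom is a thresholded smoothed Gaussian random field
(correlation length 24 voxels) cut at the quantile that yields the target
BV/TV (default 15.1%). Plate/rod realism is out of scope: the downstream
quantities only consume BV/TV, surface availability and void geometry.

Lacunae are perfect triaxial ellipsoids with closed-form ground truth:
volume `4/3 pi a b c`, surface area by Gauss–Legendre quadrature of the
parametrized area element (96^2 nodes per octant, agreeing with the
spheroid closed forms to machine precision — there is no elementary closed
form for the triaxial case), sphericity and oblateness from those. Volumes
are log-normal (default median 173 um^3; the within-biopsy spread
sigma_ln = 0.35 is an assumption — published tables report between-biopsy
spread of per-biopsy means, not the lacuna-level distribution). Axis
ratios b/a and c/a are truncated normals around (0.56, 0.35), giving
oblateness ~ -0.35 and realistic ~6 x 3.3 x 2 um semi-axes; orientations
are uniform on the rotation group. Placement draws voxel centers whose
clearance (distance to non-bone and to the grid border) exceeds the
largest semi-axis plus a 4-voxel gap, and rejects candidates whose
dilated-by-gap rasterization touches an already claimed region. The gap
guarantees ground-truth count = connected-component count in the mask, and
4 voxels (rather than the 2 the mask alone would need) keeps that equality
true after PSF blur, which can bridge a 2-voxel bone wall. Exhausted
retries raise an error naming the achievable density.

Rendering: binary rasterization (voxel center inside the analytic
surface), Gaussian point-spread blur (sigma 1 voxel), additive Gaussian
noise; defaults bone 200 / void 50 / noise sd 15 put the image in the
SNR ~ 10 regime where Otsu separation is reliable (bone-mask Dice >= 0.99).

**Partial-volume bias.** The blur erodes thin voids: measured lacunar
volumes run ~7% low on average, with a tail to -20% for lacunae near
100 um^3 whose minor axis is < 2 voxels, and measured sphericity runs
correspondingly high by ~0.04. This is the physics of imaging objects a
few voxels wide, not an estimator defect — the same chain on clean
(unblurred) digitized shapes is accurate to a few percent — so recovery
tests assert median agreement (|dLc.V| <= 10%, |dLc.Sr| <= 0.05,
|dLc.O| <= 0.15 for lacunae >= 100 um^3) rather than per-lacuna bounds.
Counting is unaffected: lacuna recall and precision are >= 0.99, exactly
100/100 per phantom when true volumes are >= 100 um^3.

## Synthetic cohorts

The cohort generator emulates a 35-subject biopsy study: 20 subjects in a
reference group and 15 in a "complicated" group, age ~ N(67, 7.4) years
(median 67, IQR 62–72), 71% male, HbA1c ~ N(56.2, 9.5) mmol/mol, diabetes
duration ~ N(16.1, 7.7) years. True per-subject lacunar parameters embed a
configurable effect map, by default: x1.077 on cortical Lc.V in the
complicated group (on the log scale the analysis models), +0.006 on
cortical Lc.Sr, a slope of 87 mm^-3 per mmol/mol of HbA1c on trabecular
Lc.N/BV, and central/peripheral structure (cortical central:peripheral
Lc.V 166:129 of a 160 um^3 overall median; trabecular 199:146 of 173).
Between-subject noise scales are matched to reported interquartile ranges
(log10 SD 0.060 for Lc.V, SD 3,100 mm^-3 for trabecular Lc.N/BV — the
latter also consistent with an exposure R^2 of ~0.07); they are
assumptions where no variance decomposition is published, and all effects
can be nulled for calibration runs.

Two modes: *tables-only* returns covariates plus true per-subject
parameters and powers the simulation studies (hundreds of cohorts per
minute); *rendered* additionally writes a cortical + trabecular phantom
TIFF pair per subject whose volume-distribution medians, lacunar density
and regional factors are that subject's true values, for end-to-end runs.
Per-subject sub-seeds derive from the cohort seed by a stable spawn-key
scheme, so any subject regenerates identically in isolation.

Desk-scale caveats of the rendered mode: fields of view are ~100–150 um
(not mm), so per-subject lacuna counts are tens, not hundreds of
thousands; absolute sphericity of smooth ellipsoids sits near 0.85–0.95
rather than the ~0.70 of real (rough-walled) lacunae, so rendered-mode
group contrasts are meaningful but absolute Sr values are not comparable
to biopsy tables — the tables-only mode carries the study-scale values;
and 15% BV/TV trabecular struts at this field of view are mostly thinner
than 40 um, so trabecular central lacunae (> 20 um deep) are scarce and
the trabecular central-vs-peripheral contrast is validated on the
tables-only path. Ct.Th from a ~100 um desk-scale slab is reported in mm
like the real metric but is an order of magnitude below clinical cortices.

## Statistics

Group comparisons are OLS of the outcome on a group indicator
(complicated group = 1) adjusted for age and sex (female = 1); exposure
models replace the indicator with a continuous covariate (e.g. HbA1c).
Outcomes are log10-transformed when a Shapiro–Wilk test on the raw values
rejects normality at p < 0.05 and all values are positive — a
deterministic, machine-checkable stand-in for visual histogram
assessment. Central-vs-peripheral contrasts use the two-sided Wilcoxon
signed-rank test on per-sample paired means (exact null distribution for
n <= 25 without ties, normal approximation with tie/zero handling above;
all-zero differences give p = 1 by convention; fewer than 6 pairs is an
error). Models drop incomplete rows and report the n used. Significance
is two-sided p <= 0.05 with no multiple-testing correction — reproducing
the analysis style this pipeline emulates, not endorsing it.

Calibration and recovery, verified by the test suite and
`scripts/acceptance.py`: type-I error of both the adjusted regression and
the Wilcoxon test within [3.5%, 6.5%] over 1000 null replicates; the mean
group coefficient over 100 simulated n=200 cohorts within 30% of
log10(1.077); the mean HbA1c slope over 100 n=34 cohorts within 30% of
87; the exact Wilcoxon branch identical to full sign-flip enumeration for
n <= 10.

## Numerical and design choices

* Aggregation is per-sample means (each biopsy one unit), with
  cohort-level reporting as median (IQR) or mean (SD) per the transform
  rule.
* Label order of void components is deterministic (raster order of first
  voxels), so reruns are byte-identical.
* The pipeline seed fans out to per-subject sub-seeds; segmentation and
  morphometry contain no randomness.
* Degenerate inputs fail loudly: constant histograms, empty masks/
  envelopes, missing voxel sizes, singular design matrices (the collinear
  column is named), and infeasible lacuna placements all raise specific
  errors rather than guessing.
* Problem sizes in the default pipeline (35 subjects, ~80^3–112^3 voxel
  phantoms, ~500–800 lacunae per run) are chosen so a full cohort
  round-trips in about a minute on one core while keeping every regional
  and statistical contrast populated.

## Known limitations

* Measured Lc.V at 1.2 um carries the negative partial-volume bias
  described above; a gray-level-weighted (partial-volume) volume estimator
  would remove most of it and is a natural extension.
* The trabecular architecture is a random field, not plates and rods;
  topology-sensitive metrics (Tb.Th, SMI, connectivity) are out of scope.
* No canalicular network: the canaliculi are below the emulated
  resolution.
* The phantom has no beam hardening, rings, or scanner artifacts; the
  noise is white Gaussian.
* Real lacunae have rough walls; smooth-ellipsoid sphericity is an upper
  bound, so rendered-mode absolute Sr exceeds biopsy-scale values.
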