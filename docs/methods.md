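# Methods

This note documents the models, conventions, and design choices behind
`tmespatial`, in the order data flows through the pipeline.

## Spatial statistics on segmented cells

All spatial quantities are computed on cell centroids in a Cartesian µm
coordinate system; distances are Euclidean ("nucleus-to-nucleus"), and no
statistic depends on origin or axis orientation.

**Densities.** A phenotype's density in a region is the count of cells
carrying that region label divided by the polygon area in mm². IT (the
tumor-nest region) and PT (its stromal complement) are shapely polygons;
point-in-polygon assignment uses `covers`, so boundary points are inside.
Because a point on the IT/PT interface is covered by both, the tie is
broken deterministically to IT — the tumor-nest-centric convention.

**Nearest-neighbor distances.** For a reference phenotype RC and a
neighbor phenotype NC, each RC cell gets the distance to its nearest NC
cell within the same sample (and optionally within one region). Reference
cells with no NC in scope are recorded as neighbor-less and stay in the
denominator of every derived proportion: a "proportion of reference
cells" is always over all reference cells. Equidistant neighbors resolve
to the smallest `cell_id` (the distance is identical either way; only the
identity/phenotype of the neighbor can differ). Searches use a
`scipy.spatial.cKDTree`; correctness is defined by an O(n²) brute-force
scan that the test suite enforces exactly on random instances up to 2000
cells.

**Proximity curves.** P(d) is the cumulative fraction of RC whose nearest
NC lies at distance ≤ d, on a 0–300 µm grid with 5 µm steps. All distance
comparisons in the package are inclusive (≤): "within 15 µm" includes a
cell at exactly 15 µm, and P(0) counts coincident centroids. Curves are
pooled over all cells of a sample by default; per-patient averaging is
available by computing per-sample curves and averaging them, and the
choice is recorded in the run config.

**Effective percentage.** At an effective-contact radius r (default
15 µm, configurable) the package reports *both* readings of the
statistic, because both are informative and the literature uses both: the
per-sub-phenotype effective fraction (what share of Tim3− CTLs are within
r of a G9+ tumor cell) and the composition of the pooled effective cells
(what share of all effective CTLs are Tim3−). The composition is flagged
undefined (None) when no cell is effective. Note the composition is
confounded by abundance — a Tim3− majority among effective cells mostly
reflects a Tim3− majority overall — which is why the per-sub-phenotype
fraction is reported alongside.

**Interaction matrix.** Every cell is paired with its nearest cell of any
*other* phenotype; M[p, q] counts p-cells whose nearest other-phenotype
cell is a q. The diagonal is structurally zero and row sums equal the
number of p-cells that have at least one other-phenotype cell in the
sample (the chord-diagram arc sizes). A single-phenotype sample yields an
all-zero matrix with a warning rather than an error.

**Density correlations.** Across-sample correlations of two phenotype
densities (Pearson or Spearman, two-tailed p from scipy). A zero-variance
vector yields an undefined flag, never a number.

## Survival analysis

Continuous biomarkers are dichotomized at the cohort median; values
strictly above the median are "high" and ties go to "low", which keeps the
high group strictly above the cutoff and makes the split deterministic.
The Kaplan–Meier product-limit estimator (via `lifelines`) provides the
overall survival rate, with 5 years taken as exactly 60 months and
`survival_at` returning the right-continuous step value; at tied times
events are processed before censorings. Groups are compared with the
two-tailed log-rank test (df = groups − 1). Frequency tables use
Pearson's chi-square without continuity correction (the conventional
choice at these cohort sizes); a Yates-corrected variant is a keyword
away. Greenwood confidence bands and Cox regression are out of scope for
v1. The joint two-marker stratification crosses two median splits into up
to four groups and reports per-group OSR plus optional pairwise log-rank
tests.

## Assay metrics

* `specific_lysis = 100 × (death − basal) / (100 − basal)`. The
  denominator is (100 − basal), the standard cytotoxicity-assay
  background correction; the function is undefined at basal = 100 and is
  not clipped post hoc.
* `realtime_norm = (control − sample) / control` for plate-reader death
  kinetics against a full-kill positive control; it is ≤ 1, equals 1 only
  at zero sample signal, and *lower* values mean *less* death.
* `kctl = ηkt / ηctl` — targets killed per effector.
* JC-1: ratio = red aggregate / green monomer fluorescence; with a
  control ratio, the fold change is sample/control, rendered as an
  "n-fold decrease" (n = 1/fold-change) when below 1.
* Immunoreactivity: `IR = (n_positive / n_total_tumor_cells) × intensity`
  with DAPI-counted tumor cells in the denominator. The staining
  intensity is by default the mean per-cell marker intensity over *all*
  tumor-region cells of the ROI; a mean over positive cells only is an
  equally defensible convention and the value is caller-supplied, so
  either mode is available. ROI stratification splits at the mean (not
  median) of the stratifying intensity, matching how intensity-based
  tumor groups are usually formed.

## Differential correlation

Patients are stratified at the median of per-patient averaged granzyme-B
expression (ties to low). Within each group all pairwise gene
correlations are computed with two-tailed p-values. The default
correlation is Spearman — the robust choice at the small group sizes this
analysis targets — with Pearson available; both appear in the literature
for this analysis and the package does not attempt to adjudicate. Pairs
are classified at α = 0.05 (two-tailed, no multiple-testing correction by
default; Benjamini–Hochberg is available) into conserved-positive /
conserved-negative / lost-in-low / lost-in-high / sign-flipped /
null-in-both. An undefined correlation (constant gene) counts as
non-significant. At n ≈ 5–6 per group even |r| ≈ 0.8 is frequently
non-significant; the recovery simulations in the test suite use
n = 200/group precisely because classification at the small-cohort scale
is power-limited — a limitation of the analysis design itself, which the
package surfaces rather than hides.

## Synthetic data: what it emulates and what it does not

**Tissue.** Tumor cells are a homogeneous Poisson process with intensity
λ (default 2000 cells/mm², a typical carcinoma epithelial density)
restricted to the IT region — a union of circular nests (default three
nests of radius 250 µm in a 1.5 × 1.5 mm window) discretized as 64-gons
so polygon areas used as density denominators are exact. Each tumor cell
is independently G9+ with probability `p_g9_positive` (default 0.5).
Immune cells are placed per phenotype in exact requested counts (defaults
300 CD8+Tim3−, 80 CD8+Tim3+, 200 CD4+ — a Tim3-scarce CTL infiltrate): a
fraction ρ (default 0.6) is "attracted", i.e. positioned at a uniformly
chosen G9+ tumor cell plus an isotropic Gaussian displacement of sd
σ (default 20 µm, on the order of 1–2 cell diameters), the rest uniform
in the window. Attracted placements that leave the window are re-drawn
(up to 100 times, then clipped) to avoid the edge pile-up that plain
clipping causes. If attraction is requested but no G9+ tumor cell exists,
placement falls back to uniform with a warning. CD8 cells are GzB+ with
probability 0.5 by default so that cytolytic-subset analyses have
something to chew on. Marker intensities are log-normal (log-median
ln 0.05 AU, log-sd 0.5, dimmed ~4.5× for marker-negative cells). The
generator works at the segmented-cell level only: no pixels, no staining
artifacts, no spatial autocorrelation beyond the nest/attraction
structure, no cell-size or shape variation — so passing tests demonstrate
correctness of the statistics, not robustness to segmentation error.

**Cohort.** Event times are exponential with hazard
`h0 · exp(β_g9·g9 + β_cd8·cd8)` and administrative censoring (defaults:
n = 92 patients, h0 = 0.005/month giving S(60) ≈ 0.74 at baseline,
β_g9 = 0.7, β_cd8 = −0.7, 10-year horizon). Survival couples to the
tissue model only through scalar covariates, not through geometry.

**Killing assay.** Killed targets are
`Binomial(T, k_max·(1 − exp(−(E/T)^γ)))` with defaults T = 200, E:T grid
{0.5, 1, 5}, k_max = 0.8, γ = 0.7. For γ ≤ 1 the expected per-capita
efficacy k_max·(1 − e^(−x^γ))/x is strictly decreasing in x = E/T, which
reproduces the saturation phenomenon that per-capita killing is highest
at low E:T ratios. This is a thinning model, not a per-CTL agent
simulation — only the kctl summary is consumed downstream.

**Expression panels.** Each group is a zero-mean Gaussian with its own
correlation matrix (validated symmetric, unit-diagonal, PSD; sampling via
eigen-factorization so semi-definite matrices work). The default panel
plants anti-correlations (−0.65) for the galectin-9/necroptosis and
autophagy pairs in the high group, positive conserved pairs (0.4–0.6) in
both, and default group sizes 5/6. The planted magnitudes are population
parameters chosen jointly PSD-feasible alongside the conserved pairs;
small-sample sample correlations will scatter widely around them.

**Reproducibility.** One master integer seed; each generator derives an
independent stream via a fixed `SeedSequence` spawn-key offset
(tissue = 0, cohort = 1, killing = 2, expression = 3), so adding draws to
one generator never perturbs another's output, and identical seed +
config yields byte-identical files.

## Numerical choices and degenerate inputs

* Inclusive (≤) comparisons everywhere a radius or bin edge appears.
* Median/mean cutoffs: ties to "low"; all-equal input labels everything
  low with a warning.
* Undefined statistics (zero-variance correlation, empty effective pool)
  are flagged, never silently numeric.
* Named exceptions: `ConfigError` for invalid configuration,
  `SchemaError` for missing/bad table columns (naming the column),
  `InputError` for bad runtime values (naming the cell/patient where
  possible).
* Nearest-neighbor ties are resolved by smallest cell_id; the tie scan
  inspects the 8 nearest candidates, which covers any realistic
  continuous-coordinate input (more than 8 exactly equidistant neighbors
  would require a pathological lattice).

## Test problem sizes

The brute-force contracts run on 10 random instances of 100–2000 cells;
calibration uses 1000 null simulations at n = 50/group (log-rank) and
1000 multinomial tables at n = 200 (chi-square); generator-recovery uses
100 seeds at n = 400/group (survival ordering) and n = 200/group
(differential correlation). These sizes give the simulations comfortable
statistical resolution for the asserted bounds while keeping the full
suite fast enough to run on every change.

## Known limitations

* No Ripley's K/cross-K, kernel density maps, or permutation null models;
  the proximity statistics are first-order only.
* No spatial coupling between tissue geometry and survival beyond scalar
  covariates.
* The synthetic tissue cannot stand in for segmentation-quality or
  staining-normalization questions; intensities are treated as given
  ("arbitrary units"), and flag derivation from intensities is an
  explicit opt-in with user-supplied thresholds.
* Interaction-matrix counts depend on the tie rule only in measure-zero
  configurations, but exact replications of published chord diagrams
  additionally depend on the upstream phenotyping rules, which differ
  between studies.
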