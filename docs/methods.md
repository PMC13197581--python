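# Methods

This note documents the models behind each module, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
choices a user should know before trusting the output.

## Clonality statistics

Samples are diploid multilocus genotypes (MLGs) over a fixed panel of
microsatellite loci; allele calls are unordered pairs of integer fragment
sizes, and a locus is either fully called or fully missing (all-zero in
GENEPOP). Two samples are ramets of one genet iff their MLGs are
identical. Genotypic richness is

    R = (G - 1) / (N - 1)

with G genets among N ramets, so R = 0 is monoclonal and R = 1 all
unique. The denominator is N − 1 (not N), which reproduces the
conventional tabulated values, e.g. (G, N) = (9, 45) → 0.18 and
(40, 43) → 0.93.

Missing data in clone matching defaults to `exact` (missing matches only
missing); a `permissive` mode lets missing loci match anything, merging
greedily in input order so the partition stays deterministic. Exact
matching can split one genet with a dropout into two; permissive matching
can merge distinct genets — which is appropriate depends on the scoring
error rate of the panel.

P_gen of an MLG is its Hardy–Weinberg probability, `prod_l p_a p_b (2 if
het)`, computed from allele frequencies over **unique genets only** (ramet
replicates would bias frequencies toward dominant clones); no F_IS
correction is applied. P_sex for an MLG observed n times among N samples
is the binomial tail probability of at least n independent draws of that
genotype. For clones shared across sites, frequencies are pooled over
the involved sites and N is the pooled sample count — a conservative
conditioning, since the pooled frequencies already include the clone's
own alleles.

Per-site diversity uses unique genets: Na is the mean allele count per
locus, Ho the fraction of heterozygous calls averaged over loci, and He
the sample-size-unbiased expected heterozygosity
`(2n/(2n-1)) (1 - sum p^2)` per locus, averaged over loci.

## F-statistics and matrix tests

Differentiation is the Weir–Cockerham (1984) estimator: per locus and
allele, the among-site (a), among-genet-within-site (b) and within-genet
(c) variance components are computed from site sample sizes, allele
frequencies and heterozygote-carrier frequencies; the multilocus
estimate is θ = Σa / Σ(a+b+c) over all alleles and loci. Monomorphic
loci contribute zero components; negative estimates are reported as
computed (truncating at zero would bias comparisons). Analyses take
unique genets, not ramets.

Pairwise significance permutes genets between the two sites and
recomputes θ (all permutations evaluated in one vectorized pass); the
p-value is `(1 + #{θ_perm ≥ θ_obs}) / (n_perm + 1)` with a default of
2499 permutations, and the significance mask applies Bonferroni
`α / n_pairs` (0.05/120 ≈ 0.0004 at 16 sites).

The Mantel test correlates the strict upper triangles of two
label-aligned symmetric matrices and permutes rows and columns of the
second jointly; the p-value is one-tailed for positive association (the
isolation-by-distance convention), 9999 permutations by default,
bit-reproducible given a seed. The optional natural-log transform
requires strictly positive off-diagonal entries — zero flows must be
floored or excluded by the caller, and this choice materially affects
flow-based Mantel statistics, so no particular flow symmetrization is
built in.

## Fragment dispersal

The simulator tracks seed-carrying fragments on a rectilinear grid of
depth-averaged hourly currents (bilinear in space, linear in time), with
particle depth z (m below surface) evolved explicitly:

* **Buoyancy stages** — vertical velocity +0.0049 m/s (rising) for days
  0–7, 0.0 for days 7–14, −0.005 m/s (sinking) thereafter. The stage
  velocities are taken from drift observations on a congeneric eelgrass;
  units are m/s.
* **Mortality** — weekly survivor fractions from losses
  (0.25, 0.50, 0.75, 1.00): constant within-week hazard (geometric decay)
  for weeks with partial loss, and a linear ramp of survivors to zero in
  the final week, so S(7 d) = 0.75 and S(28 d) = 0 exactly while
  fragments keep dispersing through week four. Only the first-week and
  final-week losses are empirically grounded; the intermediate escalation
  is a linear assumption and is configurable. Each step kills with
  probability 1 − S(t+dt)/S(t).
* **Fates** — leaving the grid or entering a land cell beaches the
  particle (removed); touching the seabed after the 6-h competency delay
  inside a habitat patch settles it permanently; touching bare seabed
  leaves it resting and resuspendable (configurable to lethal); exceeding
  the 28-day drift expires it. Event order per step: advect, buoyancy,
  mortality, beach, settle, age.
* **Integration** — forward Euler, dt = 1 h to match hourly fields, with
  optional random-walk horizontal diffusivity (default 0). The synthetic
  bay's current amplitudes are chosen so the fastest displacement per
  step is below one grid cell.

Releases occur every `release_interval_h` through the season,
`particles_per_release` per patch at uniform-random positions over the
patch's water cells at the surface. The desk-scale default (100
fragments per patch every 12 h over a 30-day season) keeps a full run in
seconds; `DispersalConfig.study_scale()` switches to 1000 fragments
every 3 h over the 92-day seed season. probability[s, d] is the settled
fraction; flow[s, d] = probability × area(s) weights reproductive output
by habitat area (release counts are uniform across patches — the area
weighting lives entirely in the flow matrix); relative inflow is the
column sum excluding self-recruitment.

## Networks

Sites are nodes; an edge joins pairs with pairwise F_ST at or below the
threshold (default 0.04, inclusive). Betweenness uses Brandes'
algorithm, unnormalized, equal shortest paths splitting contribution
fractionally; the weighted default treats F_ST as edge length. Published
degree tables from other software can disagree slightly — threshold
software sometimes applies extra filtering — so network metrics here are
defined purely by the thresholded matrix.

## Beta regression

R is a proportion, so R_i ~ Beta(μ_i φ, (1 − μ_i) φ) with
logit(μ_i) = x_iᵀβ and constant precision φ, fitted by maximum
likelihood (statsmodels' beta model; standard errors from the observed
information). Pseudo-R² is the squared Pearson correlation between the
linear predictor and logit(y). Responses exactly 0 or 1 can be pulled
inside the interval with the Smithson–Verkuilen squeeze
`(y(n−1)+0.5)/n`. AICc = AIC + 2k(k+1)/(n−k−1) ranks all predictor
subsets; the collinearity screen greedily drops, from the worst
|r| ≥ 0.7 pair, the member with the larger mean |r| to the rest.

**Predictor scale.** Seed density and inflow span orders of magnitude
and are conventionally log-transformed. For the bundled published table,
however, only the raw-scale fit reproduces the published coefficient
table (intercept ≈ −0.045 vs −0.035, seed ≈ 2.3 × 10⁻⁴ i.e. "<0.001",
inflow 0.094 vs 0.093) and its pseudo-R² (0.74 vs 0.73); the log–log
fit gives pseudo-R² ≈ 0.53 with the same positive signs. Both scales are
exposed (`recompute_site_statistics(predictor_scale=...)`,
`reproduce-tables --scale`); the raw scale is used when reproducing the
published numbers, and the discrepancy is inherent to the source table,
not to the fitting code. The synthetic generator's truth is on the log
scale.

## Synthetic data

`simulate_genotypes` draws ancestral allele frequencies Dirichlet(1)
with 3–16 alleles per locus (the range seen in the real panel), site
frequencies from the Balding–Nichols model — Dirichlet with parameters
p(1−F)/F, whose among-site variance is F p(1−p), so Weir–Cockerham θ
estimates F — and genets under Hardy–Weinberg within sites. The genet
count is fixed from the site's target R (G = round(1 + R(N−1))), ramets
beyond one per genet are allocated multinomially with geometrically
decaying weights (a dominant-clone law; `clone_dominance` sets the decay),
and sample order is shuffled. Realized R equals the target exactly up to
MLG collisions, which are rejected and redrawn. Defaults follow the
study conditions: 16 sites × 45 samples × 9 loci, F = 0.06, R spread
0.18–0.93.

What it does **not** emulate: null alleles, scoring error, somatic
mutation, linkage, within-site spatial clone structure, or F_IS ≠ 0 —
so passing tests validate the estimators under clean HWE/island-model
assumptions, not robustness to genotyping artifacts.

`simulate_bay` builds an enclosed bay (land border with a mouth),
bowl bathymetry (shallow shore, ~20 m centre), and currents as central
differences of a double-gyre streamfunction — differencing the
streamfunction rather than sampling analytic derivatives makes the
discrete divergence vanish identically — plus a spatially uniform
M2-period tidal oscillation. Patches sit in shallow cells spaced around
the shore with habitat areas spanning over two orders of magnitude, to
exercise the area-weighted flow matrix. It is not a calibrated
hydrodynamic model: no wind forcing, stratification or realistic
coastline.

`simulate_reproduction` draws log seed density lognormally, then R from
the beta law with logit mean β₀ + β_seed log(seed) + β_inflow
log(inflow) (defaults β = (−0.7, 0.25, 0.30), φ = 30, chosen to give
R spanning roughly 0.2–0.95 with both effects positive at realistic
site counts); spathe density is seed density times lognormal noise,
reproducing the strong seed–spathe correlation. The pipeline feeds
dispersal inflow (normalized by mean habitat area to a relative scale of
order 0.1–20) into this generator and uses the resulting R values as the
clonality targets for the genotype panel, so the full synthetic world
carries a recoverable R ~ seed + inflow relationship.

## Numerical choices and problem sizes

* Clone partitions, permutation tests and simulations are deterministic
  given one integer seed; generators use independent substreams.
* Permutation p-values use the add-one convention, never zero.
* Default test and pipeline runs use desk-scale sizes (tens of particles
  per release, hundreds of permutations, 20-replicate calibrations);
  study-scale settings are one config switch away. The mortality-schedule
  check uses 10⁵–2×10⁵ particles, giving a binomial s.e. near 0.1
  percentage points on the 25% first-week loss.
* Degenerate inputs raise early with the offending site/line named:
  sites with fewer than two genets for F-statistics, responses outside
  (0,1) without the squeeze, non-positive entries under log transforms,
  patches without water cells.

## Known limitations

* The Lagrangian model is 2-D (depth-averaged currents) with explicit
  particle depth; vertical shear is not represented. A hook for layered
  fields exists in the field container but the engine samples one layer.
* Permissive clone matching is order-dependent by construction
  (non-transitive compatibility); exact matching is the default.
* Beta regression assumes constant precision; no precision covariates.
* The flow-based Mantel test depends on how zero flows are handled and
  how the asymmetric flow matrix is symmetrized; both are left to the
  caller, and no published value is asserted for it.
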