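# clonescape

Clonal population genetics meets biophysical connectivity, for seagrasses
and other modular marine plants.

Many clonal plants balance sexual reproduction (seeds) against clonal
spread (rhizome growth, drifting fragments). `clonescape` implements the
site-level analysis that links the two: given multi-site microsatellite
panels, per-site reproductive surveys (seed and spathe densities) and a
gridded current field, it quantifies how isolated a site is and whether
isolated sites are more clonal.

The pipeline covers five stages, each usable on its own:

* **Clonality** (`clonescape.genotypes`) — GENEPOP parsing, clone
  detection by multilocus genotype (MLG) identity, genotypic richness
  *R* = (*G* − 1)/(*N* − 1) for *G* distinct MLGs among *N* ramets,
  P<sub>gen</sub>/P<sub>sex</sub> under Hardy–Weinberg, and per-site
  diversity (*Na*, *H*<sub>O</sub>, Nei's unbiased *H*<sub>E</sub>)
  computed from unique genets.
* **Structure** (`clonescape.popgen`) — multilocus Weir–Cockerham
  θ (F<sub>ST</sub>) from the a/b/c variance components, pairwise θ with
  genet-permutation p-values and Bonferroni masking, F<sub>ST</sub>/(1 −
  F<sub>ST</sub>) linearization, and Mantel tests against distance or
  dispersal matrices.
* **Dispersal** (`clonescape.dispersal`) — a Lagrangian simulator for
  seed-carrying fragments with staged buoyancy (positive → neutral →
  sinking over a 28-day drift), weekly-escalating mortality (25% loss in
  week one, total by week four), beaching, and settlement on habitat
  patches after a 6-h competency delay. Settler counts give a
  source × destination probability matrix; scaling rows by source patch
  area gives the flow matrix, whose column sums are each site's relative
  propagule inflow.
* **Networks** (`clonescape.network`) — threshold graphs on pairwise
  F<sub>ST</sub> (edge iff θ ≤ 0.04 by default) with node-degree and
  unnormalized betweenness centrality.
* **Regression** (`clonescape.stats`) — beta regression of *R* (a
  proportion) on seed density and propagule inflow with a logit link and
  constant precision φ, pseudo-R² (squared correlation of the linear
  predictor with logit *R*), AICc all-subsets model selection and a
  collinearity screen.

A synthetic-data module (`clonescape.synthetic_data`) generates all the
inputs — Balding–Nichols microsatellite panels with controlled clonality
and differentiation, an enclosed bay with a divergence-free double-gyre
current field, and reproductive covariates with a known link to
clonality — so the whole pipeline runs and is testable without any field
data.

## Worked example

The package bundles the published per-site summary and pairwise
F<sub>ST</sub> tables for 16 *Heterozostera nigricaulis* sites in Port
Phillip Bay. Recomputing the headline statistics:

```sh
clonescape reproduce-tables --scale raw
```

prints (abridged):

```json
{
  "total_samples": 712,
  "total_mlgs": 472,
  "mean_R": 0.6561637897695045,
  "mean_Na": 5.58125,
  "mean_seed_density": 2185.3206666666665,
  "mean_spathe_density": 1041.3846666666668,
  "seed_spathe_pearson_r": 0.6139238634702788,
  "seed_spathe_pearson_p": 0.014921329349375251,
  "n_pairwise_comparisons": 120,
  "beta_regression": {
    "coef": {"Intercept": -0.0454, "seed_density": 0.000227, "inflow": 0.0939},
    "pseudo_r2": 0.7402,
    "n": 15
  }
}
```

Reading this: 712 ramets collapse to 472 genets (mean *R* = 0.66 — about
a third of samples are clonal resamples); seed and spathe densities are
strongly correlated (r = 0.61, p = 0.015); and over the 15 sites with
reproductive data, seed density and propagule inflow together explain
roughly three quarters of the logit-scale variance in genotypic richness
(pseudo-R² = 0.74), both with positive coefficients — isolated,
seed-poor sites are the clonal ones.

A fully synthetic end-to-end run (bay → dispersal → reproduction →
genotypes → F<sub>ST</sub> → network → regression):

```python
from clonescape.pipeline import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(
    out_dir="out", seed=1,
    synth={"n_sites": 16, "n_patches": 16, "samples_per_site": 45},
    dispersal={"fall_velocities": (-0.002, 0.0, -0.005)},
))
```

which on this seed yields `global_fst = 0.060` (generator target 0.06),
`mean_R = 0.63`, and a regression that recovers the generator's positive
seed and inflow effects (`pseudo_r2 = 0.87`). Per-stage artifacts
(`fst.csv`, `flow.csv`, `inflow.csv`, `sites.csv`, `regression.json`,
`summary.json`) land in `out/`, each stamped with the seed and a
configuration hash.

Every subcommand is also available individually: `clonescape clones`,
`fst`, `mantel`, `disperse`, `network`, `regress`, `synth`, `run`.

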