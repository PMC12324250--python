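# adscreen

Statistical pipeline for a *Drosophila* loss-of-function screen of
Alzheimer's-disease (AD) risk-gene homologs, and for translating the
screen's gene-level phenotypes into per-individual oligogenic risk scores
in a human cohort.

Large AD genome-wide association studies nominate far more candidate
genes than can be characterized mechanistically. One systematic way
through the bottleneck is to knock out the conserved fly homolog of every
candidate and profile the consequences with scalable central-nervous-system
assays: brain histology (vacuolar neurodegeneration), electroretinograms
(retinal neurophysiology), heat/bang stress resilience, and longitudinal
negative-geotaxis climbing in amyloid-β and tau disease models. This
package implements the quantitative machinery of such a screen — every
hit-calling rule, statistical test and integration step — together with a
synthetic-data module that generates inputs with the statistical
structure the analyses assume, so the whole pipeline is testable end to
end without the original raw measurements.

## What it computes

**Assay hit-calling**

* *Structure*: a genotype degenerates when every examined head (≥2)
  carries ≥15 vacuoles (wildtype brains run up to ~10); essential genes
  assayed with two RNAi genotypes must satisfy the rule in both.
* *Function (ERG)*: traces are averaged per fly (5 traces = one
  biological replicate), reduced to three components — the
  light-coincident receptor potential (LCRP) amplitude and the on/off
  transients — and each mutant is compared to its eye-color-matched
  control with a Kruskal–Wallis omnibus test followed by Dunn's pairwise
  z-tests (Holm-adjusted, P<0.05). Genes classify as decreased /
  increased / mixed / none from the directions of significant components.
* *Resilience*: a two-stage design. The primary screen passes genotypes
  whose single heat or bang trial reaches 60% impairment (more than
  double the control averages of 26% heat / 19% bang); candidates are
  re-assayed with independent replicates and confirmed against control
  replicates by Kruskal–Wallis + Dunn at adjusted P<0.05.

**Locomotor modifier analysis.** Climbing speed per vial (mean of ~10
females) is followed over days 5–18. For each strain vs its disease
control the package fits

    speed ~ f(age) + genotype·f(age),  f quadratic,  random intercept per vial

and reports three Holm-adjusted p-values — overall genotype difference,
additive effect (curve shift), interactive effect (slope change) —
plus the signed area between the fitted curves (mm/s·day; negative =
enhancer, positive = suppressor), with a minimum-|area| floor standing in
for manual plot review. A gene is a high-confidence modifier when ≥2
independent strains agree in direction.

**Integration and oligogenic risk.** Assay calls combine into one
phenotype profile per gene; profiles map to four phenotype clusters
(function, structure, bang, heat) whose member genes contribute their
GWAS lead-SNP risk alleles. For a cohort of genotyped individuals, the
per-cluster risk-allele count is standardized (z-scores), a PCA is run on
the standardized matrix, individuals are ordered by their projection onto
the stratifying component, and each row is centered on its own mean for
heatmap rendering.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on
generated data and the shipped gene panel (gene names real; phenotype
flags synthetic demonstration data):

```sh
python analysis/01_simulate_screen.py      # 20-gene demo screen
python analysis/02_call_hits.py            # structure / ERG / stress calls
python analysis/03_locomotor_modifiers.py  # volcano table + gene calls
python analysis/04_integrate_phenotypes.py # profiles, summary, clusters
python analysis/05_risk_scores.py          # cohort scores, PCA, heatmap
```

`04_integrate_phenotypes.py` prints the panel's set arithmetic:

```
50 of 100 genes carry >=1 CNS phenotype (structure 18, function 35, heat 7, bang 3)
modifiers: 9 abeta + 22 tau (3 shared) -> union 28
98% of panel genes expressed in the adult brain
cluster sizes: {'function': 30, 'structure': 17, 'bang': 3, 'heat': 7}
```

i.e. half the panel shows at least one CNS requirement, the modifier
union follows by inclusion–exclusion (9 + 22 − 3 = 28), and the function
cluster keeps only decreased-depolarization genes (30) while one
structure gene lacking a GWAS lead SNP is excluded from its cluster.
`05_risk_scores.py` then simulates a 99-person cohort containing two
anticorrelated risk subgroups and reports:

```
component 1 separates the subgroups (point-biserial r = 0.87, 45% of variance)
its loadings: {'function': 0.66, 'structure': 0.62, 'bang': -0.39, 'heat': -0.16}
```

— the function/structure loadings share one sign and the resilience
(bang/heat) loadings the other, so the projection splits the cohort into
a structure/function-risk subgroup and a resilience-risk subgroup.

A subcommand-per-stage CLI wraps the same library surface
(`adscreen run-all --seed 2 --out results/pipeline`, plus `simulate`,
`erg`, `histology`, `stress`, `climb`, `integrate`, `riskscore`,
`fixtures`), driven by a single YAML config with unknown keys rejected.

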