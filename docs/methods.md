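# Methods

This note documents the statistical models behind `adscreen`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical edge cases.

## Hit-calling rules

**Brain structure.** Wildtype fly brains can carry up to ~10 small
vacuoles, so a genotype is annotated as degenerating only when *every*
examined head (≥2 per genotype) has ≥15 vacuoles. "Consistently ≥15" is
read as all-heads — the strictest reading, and the one that parallels the
both-RNAi requirement for essential genes; a mean-across-heads variant is
available via `rule="mean"`. Raising the threshold can only remove hits
(monotonicity is tested).

**ERG components.** A trace is summarized by three non-negative
magnitudes: LCRP amplitude (mean voltage over the plateau window minus
the pre-onset baseline), the on transient (largest excursion beyond the
plateau level, in the depolarizing direction, shortly after light onset)
and the off transient (largest excursion beyond baseline, repolarizing
direction, after offset). Traces follow the corneal-negative convention
(depolarization negative); all features are baseline-referenced and
therefore invariant to constant voltage offsets and to rigid time shifts
of the stimulus window. Because no measurement windows are standard, they
are explicit configuration with defaults: baseline = 200 ms pre-onset, on
window = 100 ms post-onset, plateau = trailing 50% of the stimulus, off
window = 200 ms post-offset. LCRP defaults to the plateau *mean* (robust
to transient overlap); a peak mode is available.

**Group comparisons.** Mutant-vs-control comparisons for ERG components
and stress-replicate fractions use a Kruskal–Wallis omnibus test followed
by Dunn's pairwise z-tests on pooled mid-ranks with the tie-corrected
variance. The adjustment across the mutant-vs-control family is Holm by
default (order-preserving and uniformly no less powerful than
Bonferroni, which remains available). When every observation in a family
is tied the ranks are degenerate; the comparisons are flagged and
reported with p = 1 rather than computed from a zero variance. One
omnibus family is formed per call (an assay batch); batch composition is
the caller's choice.

**Stress two-stage design.** The primary screen is a single pass/fail
trial per genotype at the 60% impairment cutoff — more than double the
control averages the generator is calibrated to (26% heat, 19% bang) —
so inference happens only at the replicate stage, where candidates are
confirmed against control replicates at Holm-adjusted P<0.05 *and*
impairment above the control's. Candidates with fewer than 3 replicates
are reported as unconfirmable, never silently dropped. Under null
simulation the two-stage design's confirmed false-positive rate is well
under 1%: a null genotype must first draw ≥6/10 impaired (probability
≈1% at p=0.26) and then separate from control replicates by rank.

## Longitudinal locomotor model

The observation unit is a vial's mean climbing speed at one age
(4 vials × ~10 females per genotype; days 5–18; 6 timepoints in the tau
model, 9 in the amyloid-β model, which declines later). The model is

    y_vt = β₀ + f(age_t) + g_v·(γ₀ + γᵀf(age_t)) + b_v + ε_vt,
    b_v ~ N(0, σ_vial²),  ε ~ N(0, σ²)

with f a quadratic polynomial by default (configurable linear/log-age):
a quadratic captures the curvature of progressive decline with few
timepoints without risking overfit. Random structure is an intercept per
vial only — four vials cannot identify random slopes.

Estimation and testing exploit the balanced design (every vial observed
at every shared age; unshared ages are dropped). Fixed effects come from
OLS on the full design, which equals GLS for a balanced random-intercept
model. The error decomposes into two orthogonal strata with exact F
statistics under normality:

* **additive effect** (curve shift): one-way ANOVA of genotype on the
  per-vial mean speeds, F(1, V−2) — the between-vial stratum;
* **interactive effect** (slope/curvature change): F-test of the
  genotype×f(age) terms after absorbing per-vial fixed intercepts — the
  within-vial stratum;
* **overall genotype effect**: Fisher's combination (−2Σlog p ~ χ²₄) of
  the two stratum p-values, which are independent under the model, so
  the combination is exactly calibrated under the null.

This closed-form route was chosen over iterative likelihood fitting
because it is exactly calibrated at the null (simulated p-values are
uniform; the suite checks Kolmogorov–Smirnov distance), deterministic,
and fast enough for 500-gene screens; a test cross-checks the coefficient
estimates against an independently fitted mixed model. Degenerate inputs
are handled explicitly: a zero-residual stratum reports p = 1 when the
effect sum of squares is also zero (identical groups) and a floored
p ≤ 1e−300 otherwise (noiseless separation).

The three p-values are Holm-adjusted *within each strain* (the family the
per-strain volcano plot reports). Modifier status requires any of the
three adjusted p-values below α = 0.05 by default ("interaction only" is
a config option), plus an effect-size gate: the signed area between the
fitted strain and control curves (trapezoidal integral over the shared
age span, mm/s·day) must exceed 10% of the area under the control curve.
The floor is the codified stand-in for the study practice of visually
confirming that significant results are meaningful; reproducibility
demands an explicit rule. Sign convention: positive area = faster than
the disease control = suppressor. Gene-level calls require ≥2 strains
with the same direction; any opposite-direction strain flags a conflict
and blocks the call. Direction is assessed on the phenotype only; allele
class (loss vs gain of function) rides along as metadata.

## Synthetic generator

The generator produces every input table under one root seed with named
substreams, so any single table is reproducible in isolation and
identical configurations yield byte-identical output.

* **Vacuole counts**: Poisson, mean 5 for normal genotypes and 25 for
  degenerating ones. Only the ≤10 control observation and the ≥15 rule
  constrain reality here; these means give clean separation so the
  calling rule's sensitivity/specificity is a meaningful measurement.
* **Stress trials**: Binomial(10, p) with control p = 0.26 (heat) / 0.19
  (bang) and 0.85 for stress-sensitive genotypes; one primary trial and
  5 replicates per genotype/stressor.
* **ERG traces**: baseline, a plateau step during the 1-s stimulus
  (12 mV depolarization stored as negative voltage), flat-topped 20-ms
  on/off transient excursions (4 / 5 mV) and additive Gaussian noise
  (SD 0.5 mV) at 1 kHz. Flat-topped transients make the noiseless
  generator→extractor round trip exact, which the suite exploits as an
  oracle. Effect genotypes scale all three components by a ratio
  (default 0.5).
* **Climbing**: baseline 12 mm/s at day 5 declining 0.5 mm/s·day, vial
  intercept SD 0.2, residual SD 0.5, modifier shift −1.5 mm/s and slope
  change −0.10 mm/s·day.
* **Cohort genotypes**: dosage ~ Binomial(2, f) per SNP, baseline
  f = 0.3, with optional subgroups whose f is raised/lowered by a delta
  (default 0.2) at SNPs of enriched/depleted clusters, clamped to
  (0.001, 0.999).

What the generator does **not** emulate: husbandry and batch effects,
trace drift or electrode artifacts, vacuole spatial structure,
non-binomial overdispersion in stress trials, linkage disequilibrium or
ancestry structure among cohort SNPs, and missing-data mechanisms other
than missing-completely-at-random. Passing tests therefore demonstrate
that the statistical machinery behaves as designed under its assumed
sampling models — not that those models exhaust real screen data.

## Risk scores and PCA

Per-cluster risk-allele counts use dosage (0/1/2) by default; a carrier
mode (0/1 per SNP) is a flag, since either reading of "number of risk
alleles" is defensible. Within a cluster, a lead SNP shared by two member
genes is counted once (dedup avoids double-weighting one variant;
per-gene counting is a flag). The function cluster keeps only
decreased-depolarization genes by default — the phenotype the risk-score
design names — with an include-all flag for the increased/mixed classes.
Genes without GWAS provenance (rare-variant evidence) carry no lead SNP
and are excluded from clusters with a logged note.

Standardization is column-wise z-scoring with the sample SD (n−1;
population SD available). A zero-variance cluster raises an error naming
the cluster rather than emitting zeros. Missing genotypes are imputed at
counting time with the per-SNP mean over observed individuals (preserves
column means); strict mode refuses missingness.

PCA is an eigendecomposition of the covariance of the standardized
matrix. Components are ordered by decreasing eigenvalue; round-off
negative eigenvalues are clipped to zero (rank deficiency reports zero
variance rather than failing). Eigenvector sign is arbitrary, so a fixed
convention is applied — the first cluster's (ERG) loading is made
non-negative, falling back to the next nonzero loading — making outputs
comparable across runs. The sort component defaults to the second
principal component, but because "which component stratifies" is an
empirical observation rather than a rule, `best_separating_component`
reports the component that best separates any supplied subgroup labels
(largest point-biserial correlation). Heatmap rows are each centered on
their own mean and permuted into projection order with ties broken by
individual id.

## Problem sizes and tolerances

Monte-Carlo checks use 10⁴ draws with 3-standard-error tolerances for
marginal calibration; the null-calibration check uses 400 simulated
datasets with a KS-distance bound of 0.08; the operating-characteristic
experiments use 200 genotypes (structure), 500 genotypes × 2 stressors
(stress null), 500 genes × 2 strains (modifier recovery) and 50 seeded
cohort replicates (subgroup recovery). Numerical tolerances: orthonormal
loadings and reconstruction to 1e−8, z-score moments to 1e−10, exact
equality for the noiseless ERG round trip and the analytic
area-between-curves cases.

## Known limitations

* The locomotor strata are exact only for balanced designs; badly
  unbalanced data are truncated to the shared age grid.
* Dunn p-values use the normal approximation; at the smallest replicate
  counts (3–5) decisions near P≈0.05 can differ from an exact
  permutation test (the suite checks agreement away from the threshold).
* The per-batch composition of Kruskal–Wallis families (which genotypes
  are tested together) changes Holm's multiplicity burden; the package
  leaves batch assignment to the caller.
* Eligibility bookkeeping (essential/lethal triage, eye-color matching,
  sex metadata) is structural only; no attempt is made to model the
  underlying biology.
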