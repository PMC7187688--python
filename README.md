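# ethnoprs

Ethnicity-stratified polygenic risk modeling for a binary disease outcome
with a continuous endophenotype — built for the question of how well
genetic risk models transfer between ancestry groups. The motivating
setting is COPD, where an FEV1-like lung-function trait drives SNP
screening and the disease status is the prediction target, and where the
causal architecture may differ substantially between populations.

The package covers the full stratified workflow:

1. **Simulation** — multi-ethnic cohorts under the Balding–Nichols model
   (a single `Fst` knob for population divergence), with configurable SNP
   heritability, per-population causal sets with a tunable
   cross-population overlap, clinical covariate effects, and
   liability-threshold case definitions. Every downstream stage is
   testable against known ground truth.
2. **I/O and QC** — PLINK BED/BIM/FAM and a TSV dosage dialect; variant
   filters (call rate ≤ 5% missing, MAF ≥ 5%, exact Hardy–Weinberg test
   p ≥ 1e-5) and sample filters (call rate, covariate completeness) with
   fully balanced removal reports; allele-harmonized intersection of
   cohorts genotyped on different panels.
3. **Mixed-model screening** — GRM construction, REML variance components
   (`y ~ MVN(Zβ, σg²K + σ²I)`, single or chromosome-partitioned), SNP
   heritability `h² = σg²/(σg²+σ²)`, per-SNP BLUP scores
   `G'K⁻¹(y − Zβ̂)/σ̂g²`, and per-SNP regression p-values; top-p selection
   by either criterion and between/within-population overlap reports.
4. **Risk models** — partially-penalized logistic regression (lasso /
   ridge / elastic net on the SNP block only, clinical covariates
   unpenalized) fit by coordinate descent, tuned by nested cross-validation
   (5 stratified outer folds, 10 inner folds, AUC selection) with screening
   recomputed inside each training fold so held-out samples never leak into
   SNP selection; external validation of serialized models on independent
   cohorts with allele matching.
5. **Decomposition** — out-of-fold deviance, McFadden's pseudo-R², and
   per-variable-group contributions `(Δᵢ − Δ_F)/Δ₀ × 100`.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

```python
import numpy as np
from ethnoprs import (
    SimulationConfig, simulate_study, compute_grm, reml_fit,
    CVPlan, cross_validate_pipeline,
)

# two populations, disjoint causal architectures, Fst 0.15
cfg = SimulationConfig(
    n_variants=3000, n_causal=50, target_h2=0.4,
    fst=0.15, cross_population_causal_overlap=0.0, seed=1,
)
pop1, pop2 = simulate_study(cfg, n_samples=[1200, 1200], case_fractions=[0.35, 0.10])

# SNP heritability of the continuous trait
phen = pop1.phenotypes
Z = np.column_stack([np.ones(len(phen)),
                     phen[["age", "sex", "height", "pack_years"]].to_numpy()])
vc, _ = reml_fit(phen["trait"].to_numpy(), Z, compute_grm(pop1.genotypes))
print(f"h2 = {vc.h2:.3f}")

# screened risk model, nested-CV tuned
plan = CVPlan(p_grid=(100,), penalty_grid=("ridge",), n_lambda=5, seed=1)
res = cross_validate_pipeline(pop1.genotypes, pop1.phenotypes, plan)
print(f"mean outer AUC = {res.mean_auc:.3f} (SD {res.sd_auc:.3f})")
```

Output:

```
h2 = 0.505
mean outer AUC = 0.772 (SD 0.015)
```

The heritability estimate sits within sampling error of the simulated 0.4
(the per-replicate standard error at this cohort size is roughly 0.065),
and adding the 100 screened SNPs lifts the cross-validated AUC well above
what age, sex and pack-years alone achieve (about 0.70 on this cohort).

The same workflow is scriptable from the shell:

```bash
ethnoprs simulate --config sim.yaml --out cohort --seed 1
ethnoprs qc --geno cohort_POP1 --pheno cohort_POP1.pheno.tsv --out clean
ethnoprs reml --geno clean --pheno clean.pheno.tsv --out h2.json
ethnoprs screen --geno clean --pheno clean.pheno.tsv --p 100 --out top.tsv
ethnoprs cv --geno clean --pheno clean.pheno.tsv --out cv.json
ethnoprs run --config pipeline.yaml   # full multi-population workflow
```

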