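# bivarped

Family-based co-heritability estimation and bivariate Haseman–Elston GWAS
for paired quantitative traits in extended pedigrees.

## The problem

Some late-life diseases leave correlated fingerprints in very different
tissues — for example, a specific lens opacity (cortical cataract, an
ordinal 0–4 wedge grade) and MRI markers of medial-temporal brain atrophy
(temporal horn volume). If the pair of traits shares genetic influences,
two things follow: siblings should show *cross-trait* correlation (trait A
in one sib correlating with trait B in the other), and a joint, bivariate
association scan should find variants that univariate scans of either trait
miss. `bivarped` implements the full analysis chain for this design, for
biostatisticians working with sibling/pedigree cohorts:

1. **Phenotype preparation** (`bivarped.pheno`) — worse-eye selection,
   ordinal grading (grade = min(wedges, 4)), annual change of longitudinal
   volumes, age/sex residualization, and the rank-based inverse normal
   transform Φ⁻¹((r(y) − 1/3)/(n + 1/3)).
2. **Genotype QC** (`bivarped.qc`) — marker call rate ≥ 98 %, founder
   MAF ≥ 2 %, exact Hardy–Weinberg test (founders, P ≥ 10⁻⁶), imputation
   RSQ ≥ 0.8 for dosage markers, subject call rate ≥ 98 %, and greedy LD
   pruning (r² > 0.8, 1500-SNP windows, 150-SNP steps); plus Mendelian
   inconsistency masking (`bivarped.pedigree`).
3. **Co-heritability** (`bivarped.famcorr`) — self and cross-trait sibling
   correlations with pedigree-bootstrap standard errors; h² = 2r for sib
   intraclass correlations, with the cross-trait analogue for
   co-heritability.
4. **Association** (`bivarped.hemodel`) — the core: a bivariate two-level
   Haseman–Elston (tHE) regression

       (y₁ᵢₖ, y₂ᵢₖ) ≃ β xᵢₖ + b zᵢₖ + eᵢₖ,   Ωₖ = Σ_g ⊗ 2Φₖ + Σ_e ⊗ I,

   fitted by iterative generalized least squares (level 1: GLS of the
   stacked traits on fixed effects; level 2: OLS of residual cross-products
   on kinship 2Φ and identity to update Σ_g, Σ_e), with first-level Wald
   tests (2 df joint, 1 df univariate), SNP×SNP interaction models,
   per-SNP variance-explained, genome scans with Manhattan/QQ coordinate
   output, and the genomic inflation factor λ.
5. **Synthetic cohorts** (`bivarped.simulate`) — a gene-dropping generator
   (pedigree structures, MAF spectra, AR(1) LD, causal SNPs, polygenic
   covariance Σ_g ⊗ 2Φ, covariate effects, missingness, Mendelian errors)
   so every stage is testable without any restricted data.

Input formats are plain text: 5-column pedigree files, classic PLINK text
PED/MAP, TSV dosage and phenotype tables.

## Worked example

```python
import pandas as pd
from bivarped.simulate import SimulationConfig, simulate_dataset
from bivarped.pedigree import kinship, enumerate_sib_pairs
from bivarped.famcorr import cross_trait_sib_correlation, heritability_from_sib
from bivarped.hemodel import TheModelSpec, fit_bivariate_the, wald_test

cfg = SimulationConfig(seed=5, n_pedigrees=500, structure=("nuclear", 2),
                       n_markers=1, maf_spectrum=[0.3],
                       causal_markers=[(0, 0.25, 0.25)])
ped, g, pheno, _ = simulate_dataset(cfg)
phi = kinship(ped)
t = pheno.set_index("subject_id")

pairs = enumerate_sib_pairs(ped)
r_cross = cross_trait_sib_correlation(t["trait1"], t["trait2"], pairs)
print(f"cross-sib r = {r_cross.estimate:.3f} over {r_cross.n_units} pairs")

snp = pd.Series(g.values[:, 0], index=g.subject_ids, name="snp")
fit = fit_bivariate_the(
    TheModelSpec(traits=t[["trait1", "trait2"]], fixed_effects=snp.to_frame()),
    phi, ped)
stat, df, p = wald_test(fit, ["trait1:snp", "trait2:snp"])
print(f"beta = ({fit.coef('trait1:snp'):.3f}, {fit.coef('trait2:snp'):.3f}), "
      f"joint Wald = {stat:.1f} ({df} df), p = {p:.2e}")
```

prints (seed 5):

```
cross-sib r = 0.206 over 500 pairs
beta = (0.171, 0.199), joint Wald = 36.9 (2 df), p = 9.87e-09
```

The cross-sib correlation is close to its polygenic expectation
(0.5·σ_g,12 ≈ 0.24 under the generator defaults, slightly diluted here by
the unadjusted age/sex covariate variance); the joint 2-df Wald test
recovers the planted per-allele effects (0.25 on each trait, MAF 0.3)
within sampling error, far past genome-wide significance at this sample
size.

There is also a CLI for shell pipelines:

```sh
bivarped simulate --fixture null_scan --out data/
bivarped qc --ped data/genotypes.ped --map data/genotypes.map --out qc/
bivarped coherit --pheno data/phenotypes.tsv --ped data/pedigree.tsv \
                 --traits trait1,trait2 --out coherit.tsv
bivarped gwas --ped data/pedigree.tsv --geno-ped qc/clean.ped \
              --geno-map qc/clean.map --pheno data/phenotypes.tsv \
              --trait1 trait1 --trait2 trait2 --covar age,sex --out gwas/
bivarped run --fixture null_scan --out run1/    # all of the above, hashed
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at run time: the two
Bonferroni significance thresholds at their printed precision, and the
empirical power of the joint bivariate Wald test for a rare (MAF 0.01)
large-effect (1.3 SD per allele on both traits) SNP across 300 simulated
three-generation pedigrees at genome-wide α, over 200 seeded replicates:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It takes about a minute on one CPU and writes one JSON object keyed by
target id.
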