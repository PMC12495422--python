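# pathrisk

Genotype-only discovery of disease-risk-associated pathways, and of the
interactions among them.

Given nothing but genotypes, per-gene eQTL weight models, GWAS summary
statistics and a pathway (gene-set) catalog, the pipeline

1. **QCs the genotypes** (call-rate, MAF, Hardy–Weinberg exact test,
   strand-ambiguous and duplicated variants) and checks for population
   structure with a Tracy–Widom test on the leading principal component;
2. **predicts genetically regulated expression (GReX)**: for each gene
   `g`, `expr(g, i) = Σ_v w_gv · dosage_i(effect allele of v)` over the
   gene's model variants, with allele orientation (swap / strand
   complement) resolved against the VCF;
3. **scores every pathway in every individual by ssGSVA**: a Gaussian
   kernel CDF per gene across individuals (bandwidth SD/4), per-individual
   gene ranking with the symmetric rank statistic `|rank − p/2|`, and a
   weighted hit-minus-miss random walk whose extreme deviations give a
   score in [−1, 1];
4. **scores disease risk by a PRS**: summary statistics are harmonized to
   the genotypes (sign flips for swapped alleles, strand complements,
   ambiguous A/T–C/G variants dropped) and
   `PRS(i) = Σ_j β_j · dosage_ij / (2M)`;
5. **tests pathway–risk dependence with the HHG statistic**: for every
   ordered pair of individuals the remaining ones are cross-classified by
   distance in the PRS and in the pathway score, and the Pearson χ² of the
   2×2 tables is summed — sensitive to non-monotone dependence that rank
   correlation misses.  Empirical P values come from adaptive permutation
   (1000–10000 permutations, early stop after 15 extreme events), are
   corrected to Storey q-values, and significance uses the per-region rule:
   the empirical P whose q-value is closest to 0.05 sets each pathway's
   critical value at its ⌈P·B⌉-th most extreme permuted statistic;
6. **models pathway interactions by factor analysis**: identically scored
   pathways are collapsed to one random representative, factorability is
   checked (KMO, Bartlett), PCA extraction (eigenvalue > 1) with varimax
   rotation iteratively removes variables never loading ≥ 0.6 and
   single-variable factors, and the resulting structure is fit as a
   maximum-likelihood confirmatory factor model
   `Σ(θ) = ΛΦΛᵀ + Θ` on the Spearman correlation matrix, with standard
   errors, t-values and modification indices.

Real cohort-scale inputs of this kind are access-restricted, so the
package ships a first-class synthetic-data module
(`pathrisk.simulate`) that generates all inputs with the statistical
structure the analysis assumes — HWE genotypes, causal risk variants,
weight models coupled to them, planted risk-associated pathways,
gene-sharing pathway blocks and ordinal stage phenotypes — plus the
ground truth needed for recovery testing.

## Worked example

The numbered scripts under `analysis/` run a complete desk-scale study
(173 individuals, 1500 variants, 300 genes, 200 pathways of which 10 are
planted as truly risk-associated):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_qc_and_structure.py
...
python analysis/07_pathway_interaction_sem.py
```

Output of the run shipped as the default configuration:

```
Tracy-Widom statistic -1.929 (P ~ 0.704) -> no significant structure
predicted 300 genes for 173 individuals (value range -7.61 to 11.67)
scored 200 of 200 pathways; 100% of pathways have high-ratio quantified genes
  Spearman rho with group: 0.49 (P = 7.7e-12)
  Spearman rho with braak: 0.49 (P = 1e-11)
  Spearman rho with thal: 0.56 (P = 1.5e-15)
51 of 200 pathways significantly associated with the risk score
  (selected empirical P = 0.022, q at selection = 0.050)
recall of planted sets: 100% (10 scored)
KMO = 0.709; Bartlett chi2 = 3532.3 (df 1275, P = 7.98e-211)
5 factors over 17 pathways; F_ML = 1.0153 (chi2 = 174.6); 16 loadings with t > 2
```

Reading this: the homogeneous simulated cohort shows no stratification;
the risk score correlates ≈0.5 with the binary group and the two ordinal
stages (the generator's calibration target); all 10 planted pathways are
recovered by the HHG permutation procedure; and the significant pathways
organize into 5 factors whose loadings are almost all significant
(t > 2).

The same stages are exposed as a CLI (`pathrisk simulate / qc / predict /
score / prs / associate / sem`) operating on VCF, GMT and TSV files.

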