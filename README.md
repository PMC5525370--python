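# wgsbatch

Detect and mitigate **batch effects** in multi-sample whole-genome-sequencing
(WGS) genotype data.

When WGS cohorts are assembled from samples sequenced with different vendors,
chemistries or library preparations, systematic technical differences between
the groups can masquerade as biology: a case-control GWAS in which batch is
confounded with phenotype will produce genome-wide-significant (GWS,
*p* < 5×10⁻⁸) associations that are pure artifact.  `wgsbatch` implements a
two-part strategy for analysts facing this problem:

1. **Detection.**  Six per-sample quality metrics — Ti/Tv in non-coding and
   coding regions, % of carried variants confirmed in a gold catalogue
   (e.g. 1000 Genomes high-confidence SNPs), % heterozygous calls, mean
   genotype quality (GQ) and median read depth — are computed from the joint
   VCF and decomposed by PCA.  Batches that are invisible in the standard
   genotype PCA (which reflects population structure) separate into distinct
   clouds in the metrics PCA; a 2-means + silhouette score quantifies the
   separation and, given batch labels, the agreement of the unsupervised
   split with them.

2. **Mitigation.**  Three site-level filters target batch-driven GWS sites:
   * **LD concordance** — drop a GWS site if it loses significance after
     genotypes are corrected to be consistent with surrounding haplotypes by
     an external haplotype-inference tool (e.g. Beagle), supplied as a second
     VCF;
   * **differential GQ** — per site and per genotype class (hom-ref / het /
     hom-alt), a 2×2 Pearson χ² of batch against GQ dichotomized at 60; the
     site is dropped if any class has *p* < 10⁻⁴;
   * **GQ20Mx** — set genotypes with GQ < 20 to missing, then drop sites
     whose missing fraction exceeds x % (GQ20M30 recommended; GQ20M10 and
     GQ20M05 presets available).

   The recommended pipeline applies LD → DiffGQ → GQ20M30 to the GWS set,
   crediting each removed site to the first filter that catches it.

Around these sit a standard GWAS engine (missingness/MAF/HWE QC, per-site
logistic regression of phenotype on additive genotype with covariates,
genomic inflation λ_GC and its small-sample rescaling
λ₁₀₀₀ = 1 + (λ_GC − 1)(1/n₁ + 1/n₂)/(2/1000), MAF- and GC-stratified), a
Monte-Carlo power study for the differential-GQ test, and a synthetic
two-batch cohort generator with planted artifacts and ground-truth labels.

## Worked example

Generate a synthetic batch-affected cohort (500 samples per batch, 1000
sites, 15 % of sites with a +30 batch-2 GQ shift, 5 % with +0.20 batch-2
missingness, 5 % with batch-2 heterozygote over-calling), then detect and
filter the batch effect:

```python
import numpy as np
import wgsbatch as wb

cohort, samples, truth = wb.generate_cohort(seed=1)
batch = [s.batch for s in samples]

# Detection: quality-metrics PCA separates the batches ...
coding = wb.RegionSet([("1", 0, 500_000)], "coding")
gold = wb.GoldVariantSet([(s.chrom, s.pos, s.alt_allele) for s in cohort.sites[::2]])
profiles = wb.compute_profiles(cohort, coding, gold)
sep = wb.separation_score(wb.metrics_pca(profiles).scores, batch)
print(f"metrics-PCA agreement with batch: {sep.agreement_with_batch:.3f}")

# ... while the standard genotype PCA barely reacts to quality-only artifacts.

# Mitigation: batch-as-phenotype GWAS, then the recommended filter pipeline
pheno = np.asarray([s.phenotype for s in samples], float)
records = wb.logistic_assoc(cohort, pheno)
corrected = wb.logistic_assoc(wb.make_ld_corrected(cohort, truth), pheno)
decisions, summary = wb.recommended_pipeline(cohort, batch, records, corrected)
print(summary.table[["filter", "n_removed", "pct_cumulative"]].to_string(index=False))
print(wb.evaluate_recovery(truth, decisions).to_string(index=False))
```

Output:

```
metrics-PCA agreement with batch: 0.997
 filter  n_removed  pct_cumulative
     LD         27           100.0
 DiffGQ          0           100.0
GQ20M30          0           100.0
         label  n_sites  n_removed  fraction_removed
         clean      750          0              0.00
      gq_shift      150          0              0.00
  diff_missing       50          0              0.00
genotype_error       50         27              0.54
```

Reading: the 27 genome-wide-significant sites in the batch GWAS are all
planted genotype-error sites; the LD stage removes every one of them (the
idealised haplotype corrector reverts the errors, so they lose significance),
and no clean site is touched.  The GQ-shift sites never reach genome-wide
significance — their genotypes are fine — which is why the differential-GQ
filter matters in practice for sites where quality *and* association artifact
coincide, and why its sensitivity is characterised separately by the power
study: at a GQ difference of 15 (σ = 5) with 500 samples per group it rejects
~80 % of the time at α = 10⁻⁴.

A `wgsbatch` CLI mirrors the library: `ingest`, `metrics`, `pca`, `gpca`,
`gwas`, `filter`, `simulate`, `synth` (see `wgsbatch --help`).

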