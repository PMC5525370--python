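# Methods

This note records the statistical models, conventions and design choices
behind `wgsbatch`, in the order the method runs.

## Cohort representation and conventions

The central object is a sites × samples triple of matrices: additively coded
genotypes (0 hom-ref, 1 het, 2 hom-alt, −1 missing), genotype quality (GQ,
NaN where the genotype is missing) and read depth (DP, "as reported" — joint
callers that locally reassemble reads may emit depths that differ from the
effective depth at the variant call, and no correction is attempted).

* Positions are 1-based internally (the VCF convention); BED intervals are
  0-based half-open and converted only at the query boundary.
* Half-calls (`./1`) are conservatively treated as missing.
* Multiallelic records are removed (and counted), not split; splitting is
  out of scope, matching the QC convention of the association engine.
* Sites are kept strictly (chromosome, position, alt) sorted, with natural
  chromosome ordering, so repeated reads and reports are deterministic.
* GQ is stored as given, without re-capping: all filters compare against
  fixed cutoffs, so rescaling would change behaviour.

## Per-sample quality metrics

Six metrics per sample: Ti/Tv among carrier SNP sites outside and inside a
coding track, percent of carrier sites confirmed in a gold catalogue,
percent heterozygous calls, mean GQ and median depth.  Conventions that the
literature leaves open, fixed here:

* **percent het denominator** — all non-missing genotype calls at cohort
  sites, hom-ref included (a "carrier-only" switch exists).  Published
  per-sample heterozygosity values in the 7–8 % range are consistent with
  the hom-ref-inclusive denominator on a joint VCF.
* **mean GQ** averages over all non-missing genotypes of every class.
* **gold matching** requires (chrom, pos, alt) equality, not position alone,
  to avoid false confirmations; a sample's carrier site counts once whether
  het or hom-alt.
* **median depth** is taken over all reported depth values, including
  no-call genotypes that still carry a DP entry (depth is evidence about the
  assay, not the call).
* With a region mask, every metric is recomputed on the unmasked sites only;
  this is verified to be identical to physically subsetting the cohort.

Between-batch comparison uses the two-sided Wilcoxon rank-sum test — exact
null distribution when both groups have ≤ 8 samples and no ties (so an
enumeration oracle applies), midrank/tie-corrected normal approximation
otherwise — with Bonferroni adjustment across the metrics actually tested
(6 by default).

## Batch detection by PCA

**Metrics PCA** standardises each metric to zero mean and unit SD and takes
the SVD, i.e. a decomposition of the metric correlation structure.
Zero-variance metrics are dropped with a warning; missing metric values are
mean-imputed; eigenvector signs are fixed so the largest-magnitude loading
is positive.  One consequence of standardisation is worth stating plainly: a
batch signal confined to a *single* metric cannot preferentially occupy the
top component, because every standardised column has the same variance — the
leading eigenvector is only pulled toward the batch direction when two or
more metrics co-vary with batch.  That is also what real chemistry changes
produce (shifts in several quality metrics at once), and the synthetic
generator emulates it (below).

**Genotype PCA** uses EIGENSTRAT scaling: genotypes mean-imputed at missing
entries, centred by 2p̂ and divided by √(2p̂(1−p̂)) per site, restricted to
SNPs with MAF ≥ 0.05 and missingness ≤ 0.10 by default, thinned uniformly
along the genome to at most `n_sites` (uniform thinning stands in for LD
pruning, which would require an external pruning pass; at the scales this
package targets the spectrum is indistinguishable).  At least five
components are returned when available, matching the usual covariate count.

**Separation score**: 2-means on the first two PC scores (fixed seed, 10
restarts) and the mean silhouette of that split.  With batch labels given,
agreement is the best label-permutation match (≥ 0.5 by construction).  The
score is reported, not thresholded — "batch effect present" is a judgement
the analyst makes; in the synthetic calibrations, well-separated batches
score agreement ≥ 0.95 while artifact-free cohorts sit near 0.5.

## Association engine and genomic inflation

QC runs in a fixed order: exclusion list → samples with missingness > 20 % →
sites with missingness > 50 % → sites with MAF < 1 % → sites with
HWE-in-controls *p* < 10⁻⁵.  All bounds are strict inequalities.  HWE uses
the 1-df Pearson χ² against expected counts from the estimated allele
frequency (an exact test is a possible extension; the χ² form is documented
and is what the enumeration-free oracle checks).  The controls are the
phenotype-0 group — in a batch GWAS, batch 1.

Association is a per-site logistic regression of phenotype on additive
genotype plus covariates (typically the first five genotype-PCA
eigenvectors), fit by Newton/IRLS on samples with a non-missing genotype,
with a Wald p for the genotype term.  Monomorphic sites are flagged rather
than fit; non-convergence and quasi-separation (unbounded genotype
coefficient) are reported as `non_converged` with an unset p — there is no
Firth fallback, a documented limitation.

Genomic inflation: λ_GC is the median of the 1-df χ² quantiles of the
p-values divided by 0.45494 (the 1-df χ² median).  The small-sample
rescaling is

    λ₁₀₀₀ = 1 + (λ_GC − 1) · (1/n_cases + 1/n_controls) / (1/1000 + 1/1000),

which makes inflation comparable across study sizes and reduces to the
identity at 1000/1000.  Published λ₁₀₀₀ values quoted to two decimals follow
a truncation convention (1.2568 prints as 1.25); `lambda_1000_printed`
reproduces that convention, validated against three independent published
(λ_GC, n₁, n₂) → λ₁₀₀₀ configurations, while `lambda_1000` returns full
precision.  Stratified inflation partitions records by MAF
([0.01, 0.05), [0.05, 0.5]) or by the 25-bp-window GC fraction
((0, 0.2], …, (0.8, 1]) and reports λ per stratum.

## Batch filters

* **GQ20Mx**: genotypes with GQ < 20 (strict) become missing; a site is
  filtered when the post-masking missing fraction strictly exceeds x.
  Genotypes that were called but carry no GQ value are treated as failing
  the GQ cut, loudly.  The removed sets nest by stringency:
  GQ20M05 ⊇ GQ20M10 ⊇ GQ20M30 on any cohort.
* **Differential GQ**: dichotomy "at GQ60" is (GQ ≥ 60) vs (GQ < 60) —
  the boundary side is configurable since either reading is defensible.
  Plain Pearson χ² without continuity correction (a Yates switch exists).
  A genotype class whose 2×2 table has any zero margin is skipped — the
  statistic is undefined there, and an absent class is covered by the other
  two.  Already-missing genotypes never enter the tables.  The test is
  invariant to any GQ translation that does not cross the 60 boundary.
* **LD concordance**: only GWS sites are eligible; an eligible site is
  filtered when it is absent, monomorphic or no longer GWS in the
  association run on haplotype-corrected genotypes.  The correction itself
  is an external step; the package consumes its output.  The synthetic
  module ships an idealised corrector (revert planted errors) for
  end-to-end testing only.
* **Recommended pipeline**: LD → DiffGQ → GQ20M30 on the GWS site set, with
  sequential attribution (a site counts toward the first filter that removes
  it) and a final removed set equal to the union — so attribution, not
  membership, depends on stage order.

## Power simulation

The differential-GQ power model draws group-1 GQ from Uniform(0, 99) and
group-2 GQ from Uniform(0, 99) + Normal(μ, σ), dichotomizes at 60, and
applies the same 2×2 χ² at α = 10⁻⁴; power is the rejection fraction over
1000 replicates per cell (σ ∈ {1, 5, 10}, μ ∈ [0, 20], n ∈ {250, 500,
1000}).  Values are continuous and not clipped to [0, 99] — the sum
distribution is used as stated, and dichotomization makes clipping
immaterial (a clip switch exists for sensitivity analysis).  A two-proportion
normal approximation (P(GQ ≥ 60) = 39/99 vs ≈ 0.545 at μ = 15, almost
σ-free) provides an independent closed-form oracle; at μ = 15, n = 500 it
predicts power ≈ 0.82, and the Monte-Carlo estimate at the reference point
is ~0.80.  Seeding: each (μ, σ, n) cell derives its own deterministic
stream from the master seed, so grids reproduce cell by cell and in any
evaluation order.

## Synthetic cohort generator

The generator is the test bed for every stage, with ground truth attached.
Defaults — chosen once as the package's study conditions — are 500 samples
per batch and 1000 sites:

* **clean sites (75 %)**: Hardy-Weinberg genotypes at allele frequencies ~
  Uniform(0.05, 0.5), GQ ~ Uniform(0, 99) (the power-model baseline),
  2 % missingness, identically in both batches;
* **gq_shift sites (15 %)**: batch-2 GQ shifted by +30;
* **diff_missing sites (5 %)**: batch-2 missingness raised by +0.20;
* **genotype_error sites (5 %)**: batch-2 hom-ref calls re-called as het
  with probability 0.4 — the haplotype-inconsistent heterozygote
  over-calling pattern that creates spurious batch associations and that an
  LD corrector can revert;
* a chemistry-style coverage difference: batch-2 depth ~ Poisson(32) vs
  Poisson(30).  Depth never touches genotypes, so together with the GQ shift
  it gives the quality-metric PCA the multi-metric batch signature real
  chemistry changes produce while leaving genotype PCA blind — the
  detection contrast the package is built around.

What the generator deliberately does **not** model: linkage disequilibrium
between sites (so LD-based correction is idealised, not simulated),
per-sample coverage dispersion (real cohorts' depth distributions overlap
between batches far more), indel-specific error processes, and read-level
artifacts.  Consequently, passing synthetic calibrations demonstrates the
machinery — correct statistics, calibrated type-I error, recovery of
planted artifacts — not performance on any real cohort; cohort-scale
removal percentages reported for real studies require the original data.

Truth labels (one per site) plus the pre-corruption genotype matrix are
returned, so sensitivity (removed/injected per artifact class) and the
clean-site removal rate are exact.  In the shipped calibrations, the
recommended pipeline removes ≥ 90 % of artifact sites that reach genome-wide
significance and ≤ 5 % of clean sites, and the differential-GQ filter under
permuted batch labels rejects each genotype class at its nominal 10⁻⁴ rate.

## Numerical details

* All randomness flows through `numpy.random.Generator` seeded from
  explicit arguments; derived streams use `SeedSequence` spawn keys.
* 2-means uses scikit-learn's KMeans with `n_init=10, random_state=0`;
  silhouette via scikit-learn.
* Logistic fits: statsmodels `Logit` with Newton steps, 50 iterations;
  coefficients with |β| > 15 or exploding standard errors are treated as
  separated and flagged.
* Degenerate inputs resolve to unset values with warnings rather than
  errors wherever the quantity is genuinely undefined (all-identical PCA
  points, empty inflation strata, zero-transversion Ti/Tv, all-masked
  profiles); impossible requests (no samples, constant phenotype,
  rank-deficient covariates) raise.
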