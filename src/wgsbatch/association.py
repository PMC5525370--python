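"""Case-control association engine: QC, logistic regression, genomic inflation.

The QC pipeline applies, in a fixed order, the standard array-era filters:
sample exclusions, per-sample missingness, per-site missingness, minor allele
frequency, and Hardy-Weinberg equilibrium in controls.  Association is a
per-site logistic regression of phenotype on the additively coded genotype
with optional covariates (typically the first five genotype-PCA
eigenvectors), with a Wald p-value for the genotype term.

Genomic inflation lambda_GC is the median association chi-square divided by
the 1-df chi-square median (~0.4549); lambda_1000 rescales it to an
equivalent study of 1000 cases and 1000 controls:

    lambda_1000 = 1 + (lambda_GC - 1) * (1/n_cases + 1/n_controls) / (2/1000)

so that inflation estimates are comparable across study sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MISSING, CohortGenotypes

__all__ = [
    "QCParams",
    "QCReport",
    "ASSOCIATION_COLUMNS",
    "apply_qc",
    "hwe_chi_square",
    "logistic_assoc",
    "lambda_gc",
    "lambda_1000",
    "lambda_1000_printed",
    "stratified_inflation",
    "MAF_BINS",
    "GC_BINS",
    "genome_wide_significant",
]

#: Median of the 1-df chi-square distribution.
_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

#: Default stratification bin edges.
MAF_BINS = (0.01, 0.05, 0.5)
GC_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

#: Column contract for association-record DataFrames.
ASSOCIATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "maf",
    "missing_rate",
    "hwe_p_controls",
    "effect",
    "p_value",
    "status",
    "gc_fraction",
]


@dataclass
class QCParams:
    """Thresholds of the standard GWAS QC pipeline (all exclusive bounds)."""

    site_max_missing: float = 0.50
    sample_max_missing: float = 0.20
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    gws_threshold: float = 5e-8
    n_covariate_pcs: int = 5

    def __post_init__(self) -> None:
        for name in ("site_max_missing", "sample_max_missing", "maf_min", "hwe_p_min", "gws_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must lie in (0, 1)")


@dataclass
class QCReport:
    """Counts removed per QC rule, in application order."""

    n_samples_in: int
    n_sites_in: int
    excluded_samples: int = 0
    high_missing_samples: int = 0
    high_missing_sites: int = 0
    low_maf_sites: int = 0
    hwe_failed_sites: int = 0
    n_samples_out: int = 0
    n_sites_out: int = 0

    def validate(self) -> None:
        if self.n_samples_in - self.excluded_samples - self.high_missing_samples != self.n_samples_out:
            raise AssertionError("sample removal counts inconsistent")
        if (
            self.n_sites_in - self.high_missing_sites - self.low_maf_sites - self.hwe_failed_sites
            != self.n_sites_out
        ):
            raise AssertionError("site removal counts inconsistent")


def hwe_chi_square(n_homref: int, n_het: int, n_homalt: int) -> float:
    """1-df Pearson chi-square test of Hardy-Weinberg equilibrium.

    Expected genotype counts are derived from the estimated allele frequency;
    monomorphic sites and exact fits return p = 1.
    """
    counts = (n_homref, n_het, n_homalt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n_homref + n_het) / (2 * n)  # reference allele frequency
    if p in (0.0, 1.0):
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    observed = np.asarray(counts, dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    if chi2 < 1e-12:  # exact fit up to floating-point noise
        return 1.0
    return float(stats.chi2.sf(chi2, 1))


def _genotype_counts(genotypes: np.ndarray) -> tuple[int, int, int]:
    return (
        int(np.sum(genotypes == 0)),
        int(np.sum(genotypes == 1)),
        int(np.sum(genotypes == 2)),
    )


def apply_qc(
    cohort: CohortGenotypes,
    phenotype: np.ndarray,
    params: QCParams | None = None,
    sample_exclusions: Sequence[str] = (),
) -> tuple[CohortGenotypes, QCReport]:
    """Apply the standard QC pipeline in its fixed order.

    1. drop samples on the exclusion list (e.g. relatedness),
    2. drop samples with missingness > ``sample_max_missing``,
    3. drop sites with missingness > ``site_max_missing``,
    4. drop sites with MAF < ``maf_min``,
    5. drop sites failing HWE in controls (phenotype 0) at ``hwe_p_min``.

    *phenotype* is a 0/1 array aligned with ``cohort.samples``; HWE is
    evaluated in the controls (label 0) only.  Returns the filtered cohort
    and a :class:`QCReport` of per-step removal counts.
    """
    params = params or QCParams()
    phenotype = np.asarray(phenotype)
    if phenotype.shape[0] != cohort.n_samples:
        raise ValueError("phenotype length must match the number of samples")
    report = QCReport(n_samples_in=cohort.n_samples, n_sites_in=cohort.n_sites)

    excl = set(sample_exclusions)
    keep = np.asarray([s not in excl for s in cohort.samples])
    report.excluded_samples = int((~keep).sum())
    cohort = cohort.subset_samples(keep)
    phenotype = phenotype[keep]

    miss = cohort.missing_rate_per_sample()
    keep = miss <= params.sample_max_missing
    report.high_missing_samples = int((~keep).sum())
    cohort = cohort.subset_samples(keep)
    phenotype = phenotype[keep]
    if cohort.n_samples == 0:
        raise ValueError("QC removed every sample")

    site_miss = cohort.missing_rate_per_site()
    keep = site_miss <= params.site_max_missing
    report.high_missing_sites = int((~keep).sum())
    cohort = cohort.subset_sites(keep)

    g = cohort.genotype.astype(float)
    g[g == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_hat = np.nanmean(g, axis=1) / 2.0
    maf = np.minimum(p_hat, 1 - p_hat)
    maf[~np.isfinite(maf)] = 0.0
    keep = maf >= params.maf_min
    report.low_maf_sites = int((~keep).sum())
    cohort = cohort.subset_sites(keep)

    controls = phenotype == 0
    hwe_p = np.ones(cohort.n_sites)
    for i in range(cohort.n_sites):
        gc = cohort.genotype[i, controls]
        gc = gc[gc != MISSING]
        if gc.size:
            hwe_p[i] = hwe_chi_square(*_genotype_counts(gc))
    keep = hwe_p >= params.hwe_p_min
    report.hwe_failed_sites = int((~keep).sum())
    cohort = cohort.subset_sites(keep)
    if cohort.n_sites == 0:
        raise ValueError("QC removed every site")

    report.n_samples_out = cohort.n_samples
    report.n_sites_out = cohort.n_sites
    report.validate()
    return cohort, report


def _fit_logistic(y: np.ndarray, design: np.ndarray) -> tuple[float, float, bool]:
    """Newton/IRLS logistic fit; returns (beta_genotype, wald_p, converged).

    The genotype term is column 1 of *design* (column 0 is the intercept).
    Convergence failure or quasi-separation (unbounded genotype coefficient)
    is reported, not hidden.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, design)
            res = model.fit(method="newton", maxiter=50, disp=0, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return float("nan"), float("nan"), False
    beta = float(res.params[1])
    se = float(res.bse[1])
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged or not math.isfinite(se) or abs(beta) > 15 or se > 100:
        return beta, float("nan"), False
    z = beta / se
    return beta, float(2 * stats.norm.sf(abs(z))), True


def logistic_assoc(
    cohort: CohortGenotypes,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-site logistic regression of phenotype on additive genotype.

    Fits intercept + genotype + covariates on samples with a non-missing
    genotype at each site and reports the Wald p for the genotype term.
    Returns a DataFrame with :data:`ASSOCIATION_COLUMNS`; monomorphic sites
    get status ``monomorphic`` and separation/non-convergence is flagged as
    ``non_converged`` with an unset p-value.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if phenotype.shape[0] != cohort.n_samples:
        raise ValueError("phenotype length must match samples")
    if len(np.unique(phenotype)) < 2:
        raise ValueError("phenotype is constant; need cases and controls")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != cohort.n_samples:
            raise ValueError("covariate rows must match samples")
        if np.linalg.matrix_rank(covariates) < covariates.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    controls = phenotype == 0
    rows = []
    for i, site in enumerate(cohort.sites):
        g = cohort.genotype[i].astype(float)
        obs = g != MISSING
        missing_rate = float(np.mean(~obs))
        gi = g[obs]
        yi = phenotype[obs]
        p_hat = gi.mean() / 2.0 if gi.size else float("nan")
        maf = float(min(p_hat, 1 - p_hat)) if math.isfinite(p_hat) else float("nan")
        gc = cohort.genotype[i, controls]
        gc = gc[gc != MISSING]
        hwe_p = hwe_chi_square(*_genotype_counts(gc)) if gc.size else float("nan")
        base = {
            "chrom": site.chrom,
            "pos": site.pos,
            "ref": site.ref_allele,
            "alt": site.alt_allele,
            "variant_class": site.variant_class,
            "maf": maf,
            "missing_rate": missing_rate,
            "hwe_p_controls": hwe_p,
            "gc_fraction": site.gc_fraction,
        }
        if gi.size == 0 or len(np.unique(gi)) < 2:
            rows.append({**base, "effect": float("nan"), "p_value": float("nan"), "status": "monomorphic"})
            continue
        cols = [np.ones(gi.size), gi]
        if covariates is not None:
            cols.extend(covariates[obs].T)
        design = np.column_stack(cols)
        beta, p, ok = _fit_logistic(yi, design)
        rows.append(
            {**base, "effect": beta, "p_value": p, "status": "ok" if ok else "non_converged"}
        )
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)


def lambda_gc(p_values: Sequence[float]) -> float:
    """Genomic inflation factor from a collection of association p-values.

    Median of the implied 1-df chi-square statistics divided by the 1-df
    chi-square median (0.45494).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no valid p-values")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)


def lambda_1000(lambda_gc_value: float, n_cases: int, n_controls: int) -> float:
    """Rescale lambda_GC to an equivalent 1000-case / 1000-control study."""
    if n_cases < 1 or n_controls < 1:
        raise ValueError("group sizes must be positive")
    return 1.0 + (lambda_gc_value - 1.0) * (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)


def lambda_1000_printed(lambda_gc_value: float, n_cases: int, n_controls: int) -> float:
    """lambda_1000 at the 2-decimal reporting precision (truncated).

    Published lambda_1000 values are conventionally quoted to two decimals by
    truncation; this helper reproduces that reporting convention.
    """
    return math.floor(lambda_1000(lambda_gc_value, n_cases, n_controls) * 100) / 100


def genome_wide_significant(records: pd.DataFrame, threshold: float = 5e-8) -> pd.Series:
    """Boolean mask of records with a valid p-value strictly below *threshold*."""
    return (records["status"] == "ok") & (records["p_value"] < threshold)


def stratified_inflation(
    records: pd.DataFrame,
    strata: str = "maf",
    n_cases: int | None = None,
    n_controls: int | None = None,
    bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """lambda_GC (and lambda_1000 when group sizes given) per MAF or GC stratum.

    ``strata="maf"`` partitions on minor allele frequency with default bins
    [0.01, 0.05) and [0.05, 0.5]; ``strata="gc"`` partitions on the 25-bp
    GC fraction with default bins (0, 0.2], ..., (0.8, 1].  Empty strata get
    an unset lambda with a warning.
    """
    if strata == "maf":
        edges = np.asarray(bins if bins is not None else MAF_BINS, dtype=float)
        values = records["maf"].to_numpy(dtype=float)
        right = False  # [low, high) except the last bin which is closed
    elif strata == "gc":
        edges = np.asarray(bins if bins is not None else GC_BINS, dtype=float)
        values = records["gc_fraction"].to_numpy(dtype=float)
        right = True  # (low, high], with the first bin closed at 0
    else:
        raise ValueError("strata must be 'maf' or 'gc'")
    p = records["p_value"].to_numpy(dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if right:
            sel = (values > lo) & (values <= hi)
            if lo == edges[0]:
                sel |= values == lo
        else:
            sel = (values >= lo) & (values < hi)
            if hi == edges[-1]:
                sel |= values == hi
        sel &= np.isfinite(values) & np.isfinite(p)
        row = {"stratum": f"({lo:g}, {hi:g}]" if right else f"[{lo:g}, {hi:g})", "n_tests": int(sel.sum())}
        if sel.any():
            lam = lambda_gc(p[sel])
            row["lambda_gc"] = lam
            row["lambda_1000"] = (
                lambda_1000(lam, n_cases, n_controls) if n_cases and n_controls else float("nan")
            )
        else:
            warnings.warn(f"empty stratum {row['stratum']}", stacklevel=2)
            row["lambda_gc"] = float("nan")
            row["lambda_1000"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
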