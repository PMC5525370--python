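"""Per-sample quality metrics and between-batch comparison.

Six metrics summarise each sample's call set: Ti/Tv in non-coding and coding
regions, percent of carried variants confirmed in a gold catalogue (the
classic "% confirmed in 1000 Genomes" check), percent heterozygous calls,
mean genotype quality and median read depth.  Batch differences in these
metrics are what the metrics-PCA batch detector picks up; they are compared
formally between two batches with a two-sided Wilcoxon rank-sum test and a
Bonferroni adjustment across the metrics tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import (
    MISSING,
    CohortGenotypes,
    GoldVariantSet,
    RegionSet,
    SampleInfo,
    VariantSite,
)

__all__ = [
    "QualityProfile",
    "GroupComparison",
    "METRIC_NAMES",
    "titv_ratio",
    "percent_confirmed",
    "percent_het",
    "compute_profiles",
    "profiles_to_frame",
    "compare_groups",
    "bonferroni_alpha",
]

METRIC_NAMES = (
    "titv_noncoding",
    "titv_coding",
    "pct_confirmed_gold",
    "pct_het",
    "mean_gq",
    "median_depth",
)


@dataclass
class QualityProfile:
    """The six per-sample quality metrics (``nan`` marks an unset metric)."""

    sample_id: str
    titv_noncoding: float
    titv_coding: float
    pct_confirmed_gold: float
    pct_het: float
    mean_gq: float
    median_depth: float


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance level after a Bonferroni adjustment.

    E.g. 16 candidate loci at family alpha 0.05 -> 0.05/16 = 0.003125.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    return family_alpha / n_tests


def _carrier_mask(genotypes: np.ndarray) -> np.ndarray:
    return genotypes >= 1


def titv_ratio(
    genotypes: np.ndarray,
    sites: Sequence[VariantSite],
    region: RegionSet | None = None,
    within: bool = True,
) -> float:
    """Transition/transversion ratio over SNP sites where the sample carries
    at least one alternate allele.

    With *region* given, only sites inside (``within=True``) or outside the
    region are counted.  Returns ``nan`` when no transversion carrier sites
    exist (0/0 is unset, not an error).
    """
    genotypes = np.asarray(genotypes)
    is_snp = np.asarray([s.variant_class == "SNP" for s in sites], dtype=bool)
    use = is_snp & _carrier_mask(genotypes)
    if region is not None:
        member = region.mask_sites(sites)
        use &= member if within else ~member
    changes = np.asarray([s.snp_change == "transition" for s in sites], dtype=bool)
    n_ti = int(np.sum(use & changes))
    n_tv = int(np.sum(use & ~changes))
    if n_tv == 0:
        return float("nan")
    return n_ti / n_tv


def percent_confirmed(
    genotypes: np.ndarray, sites: Sequence[VariantSite], gold: GoldVariantSet
) -> float:
    """Percent of the sample's carrier sites whose (chrom, pos, alt) is in *gold*.

    Each carrier site counts once regardless of het/hom-alt state.  A sample
    with no variant calls yields ``nan``.
    """
    if len(gold) == 0:
        raise ValueError("gold set is empty")
    carrier = _carrier_mask(np.asarray(genotypes))
    n_carrier = int(carrier.sum())
    if n_carrier == 0:
        return float("nan")
    in_gold = gold.contains_sites(sites)
    return 100.0 * int(np.sum(carrier & in_gold)) / n_carrier


def percent_het(genotypes: np.ndarray, denominator: str = "all") -> float:
    """Percent heterozygous calls for one sample.

    ``denominator="all"`` (default) counts all non-missing genotype calls at
    cohort sites, hom-ref included; ``"carrier"`` restricts to calls carrying
    an alternate allele.
    """
    genotypes = np.asarray(genotypes)
    if denominator == "all":
        denom = int(np.sum(genotypes != MISSING))
    elif denominator == "carrier":
        denom = int(np.sum(_carrier_mask(genotypes)))
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if denom == 0:
        raise ValueError("no eligible genotype calls for percent_het")
    return 100.0 * int(np.sum(genotypes == 1)) / denom


def compute_profiles(
    cohort: CohortGenotypes,
    coding: RegionSet,
    gold: GoldVariantSet | None = None,
    mask: RegionSet | None = None,
    het_denominator: str = "all",
) -> list[QualityProfile]:
    """Compute one :class:`QualityProfile` per sample.

    Ti/Tv is split by the *coding* region track (non-coding = outside).  With
    *mask* given, all metrics are computed only on sites outside the mask --
    the pattern used to ask whether batch differences survive removal of
    repeat-masked or otherwise difficult regions.  A mask covering every site
    yields all-``nan`` profiles with a warning.
    """
    keep = np.ones(cohort.n_sites, dtype=bool)
    if mask is not None and len(mask) > 0:
        keep &= ~mask.mask_sites(cohort.sites)
    if not keep.any():
        warnings.warn("mask covers all sites; all metrics are unset", stacklevel=2)
        return [
            QualityProfile(s, *([float("nan")] * 6)) for s in cohort.samples
        ]
    sub = cohort.subset_sites(keep) if not keep.all() else cohort
    coding_member = coding.mask_sites(sub.sites) if len(coding) else np.zeros(sub.n_sites, bool)
    in_gold = gold.contains_sites(sub.sites) if gold is not None and len(gold) else None

    is_snp = np.asarray([s.variant_class == "SNP" for s in sub.sites], dtype=bool)
    is_ti = np.asarray([s.snp_change == "transition" for s in sub.sites], dtype=bool)

    profiles = []
    for j, sample_id in enumerate(sub.samples):
        g = sub.genotype[:, j]
        carrier = g >= 1
        snp_carrier = is_snp & carrier

        def _titv(sel: np.ndarray) -> float:
            n_tv = int(np.sum(sel & ~is_ti))
            return float("nan") if n_tv == 0 else int(np.sum(sel & is_ti)) / n_tv

        titv_nc = _titv(snp_carrier & ~coding_member)
        titv_cd = _titv(snp_carrier & coding_member)
        if in_gold is not None and carrier.any():
            pct_gold = 100.0 * int(np.sum(carrier & in_gold)) / int(carrier.sum())
        else:
            pct_gold = float("nan")
        non_missing = g != MISSING
        denom = int(carrier.sum()) if het_denominator == "carrier" else int(non_missing.sum())
        pct_h = 100.0 * int(np.sum(g == 1)) / denom if denom else float("nan")
        gq = sub.gq[:, j]
        mean_gq = float(np.nanmean(gq)) if np.isfinite(gq).any() else float("nan")
        dp = sub.depth[:, j]
        median_dp = float(np.nanmedian(dp)) if np.isfinite(dp).any() else float("nan")
        profiles.append(
            QualityProfile(sample_id, titv_nc, titv_cd, pct_gold, pct_h, mean_gq, median_dp)
        )
    return profiles


def profiles_to_frame(profiles: Sequence[QualityProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame indexed by sample_id, one column per metric."""
    rows = {p.sample_id: [getattr(p, m) for m in METRIC_NAMES] for p in profiles}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_NAMES))


@dataclass
class GroupComparison:
    """Between-batch comparison of metric distributions.

    ``table`` has one row per metric: group means/SDs, the rank-sum statistic,
    the raw two-sided p and the Bonferroni-adjusted p (raw p x number of
    metrics tested, capped at 1).
    """

    group_labels: tuple[str, str]
    table: pd.DataFrame
    n_tests: int


def compare_groups(
    profiles: Sequence[QualityProfile],
    sample_info: Sequence[SampleInfo],
    metrics: Sequence[str] = METRIC_NAMES,
) -> GroupComparison:
    """Wilcoxon rank-sum comparison of each metric between two batches.

    The exact null distribution is used when both groups have <= 8 samples
    (and no ties); otherwise the normal approximation with midrank tie
    correction.  P-values are Bonferroni-adjusted across the metrics tested.
    """
    frame = profiles_to_frame(profiles)
    batch_of = {s.sample_id: s.batch for s in sample_info}
    missing = [sid for sid in frame.index if sid not in batch_of or not batch_of[sid]]
    if missing:
        raise ValueError(f"samples without batch label: {missing[:5]}")
    batches = frame.index.map(batch_of)
    labels = sorted(set(batches))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 batch labels, got {labels}")
    g1 = frame[batches == labels[0]]
    g2 = frame[batches == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each batch needs >= 2 samples")
    n_tests = len(metrics)
    rows = []
    for metric in metrics:
        x = g1[metric].to_numpy(dtype=float)
        y = g2[metric].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"metric {metric!r} is unset for an entire group")
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {
                "metric": metric,
                f"mean_{labels[0]}": float(np.mean(x)),
                f"sd_{labels[0]}": float(np.std(x, ddof=1)),
                f"mean_{labels[1]}": float(np.mean(y)),
                f"sd_{labels[1]}": float(np.std(y, ddof=1)),
                "statistic": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_bonferroni": min(1.0, float(res.pvalue) * n_tests),
            }
        )
    return GroupComparison(
        group_labels=(labels[0], labels[1]),
        table=pd.DataFrame(rows).set_index("metric"),
        n_tests=n_tests,
    )
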