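"""Site-level batch-effect filters and the recommended combined pipeline.

Three filters target sites whose genome-wide-significant association is an
artifact of batch rather than biology:

* **GQ20Mx** -- set genotypes with GQ < 20 to missing, then remove sites whose
  missing-genotype fraction exceeds x% (GQ20M30 is the recommended setting;
  GQ20M10 and GQ20M05 are stricter presets).
* **Differential GQ** -- per site and per genotype class (hom-ref, het,
  hom-alt), a 2x2 Pearson chi-square of batch against GQ dichotomized at 60;
  the site is removed if any class tests below 1e-4.
* **LD concordance** -- a GWS site is removed when the association no longer
  reaches genome-wide significance after genotypes have been corrected to be
  consistent with surrounding haplotypes by an external haplotype-inference
  tool (the corrected call set is consumed as a second VCF / association run).

The recommended pipeline applies LD -> differential GQ -> GQ20M30 to the GWS
site set with sequential attribution: a site counts toward the first filter
that removes it, while the final removed set is the union of the three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MISSING, CohortGenotypes, RegionSet, VariantSite

__all__ = [
    "FilterParams",
    "FilterSummary",
    "pearson_chi2_2x2",
    "gq_missingness_filter",
    "differential_gq_filter",
    "ld_concordance_filter",
    "region_mask_filter",
    "recommended_pipeline",
    "summarize",
    "summarize_locus_table",
]

_GENOTYPE_CLASSES = {"hom_ref": 0, "het": 1, "hom_alt": 2}


@dataclass
class FilterParams:
    """Thresholds of the batch filters.

    ``max_missing_fraction`` selects the GQ20Mx preset: 0.30 (GQ20M30,
    recommended), 0.10 or 0.05.  ``yates`` toggles the continuity correction
    of the 2x2 chi-square (off by default).
    """

    gq_min: float = 20.0
    max_missing_fraction: float = 0.30
    gq_dichotomy: float = 60.0
    diff_gq_alpha: float = 1e-4
    gws_threshold: float = 5e-8
    yates: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must lie in (0, 1)")
        for name in ("diff_gq_alpha", "gws_threshold"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.gq_min < 0 or self.gq_dichotomy < 0:
            raise ValueError("GQ thresholds must be non-negative")

    @classmethod
    def preset(cls, name: str, **overrides) -> "FilterParams":
        """GQ20Mx presets by name: 'GQ20M30', 'GQ20M10' or 'GQ20M05'."""
        fractions = {"GQ20M30": 0.30, "GQ20M10": 0.10, "GQ20M05": 0.05}
        if name not in fractions:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(fractions)}")
        return cls(max_missing_fraction=fractions[name], **overrides)

    @property
    def gq20mx_name(self) -> str:
        return f"GQ20M{round(self.max_missing_fraction * 100):02d}"


def pearson_chi2_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) for the 2x2 table [[a, b], [c, d]].

    Returns ``(chi2, p)``; any zero margin leaves both unset (``nan``) since
    the statistic is undefined.  *yates* applies the continuity correction.
    """
    a, b, c, d = (int(a), int(b), int(c), int(d))
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return float("nan"), float("nan")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff * diff / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def gq_missingness_filter(
    cohort: CohortGenotypes, params: FilterParams | None = None
) -> tuple[CohortGenotypes, pd.DataFrame]:
    """The GQ20Mx filter: mask low-GQ genotypes, drop high-missingness sites.

    Genotypes with GQ < ``gq_min`` become missing (genotypes with an absent
    GQ value are treated the same way, loudly); a site is filtered when its
    post-masking missing fraction strictly exceeds ``max_missing_fraction``.
    Returns the masked cohort (all sites, genotypes masked) and a per-site
    decision table.
    """
    params = params or FilterParams()
    called = cohort.genotype != MISSING
    no_gq = called & ~np.isfinite(cohort.gq)
    if no_gq.any():
        warnings.warn(
            f"{int(no_gq.sum())} called genotype(s) lack a GQ value; "
            f"treating them as GQ < {params.gq_min:g} (set to missing)",
            stacklevel=2,
        )
    low = called & (no_gq | (cohort.gq < params.gq_min))
    genotype = cohort.genotype.copy()
    genotype[low] = MISSING
    gq = cohort.gq.copy()
    gq[low] = np.nan
    depth = cohort.depth.copy()
    masked = CohortGenotypes(
        sites=list(cohort.sites),
        samples=list(cohort.samples),
        genotype=genotype,
        gq=gq,
        depth=depth,
        n_multiallelic_dropped=cohort.n_multiallelic_dropped,
    )
    miss = masked.missing_rate_per_site()
    filtered = miss > params.max_missing_fraction
    frame = masked.site_frame()
    frame["filter"] = params.gq20mx_name
    frame["filtered"] = filtered
    frame["missing_rate_post_mask"] = miss
    frame["reason"] = [
        f"post-mask missing rate {m:.4f} > {params.max_missing_fraction:g}" if f else ""
        for m, f in zip(miss, filtered)
    ]
    return masked, frame


def differential_gq_filter(
    cohort: CohortGenotypes,
    batch: Sequence[str],
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Differential genotype-quality filter between two batches.

    Per site and per genotype class, the non-missing genotypes of that class
    are cross-tabulated as batch x (GQ >= 60 vs GQ < 60) and tested with a
    1-df Pearson chi-square (no continuity correction by default).  A class
    with any zero margin is skipped; the site is filtered when the smallest
    tested class p-value falls below ``diff_gq_alpha``.  Genotypes that are
    missing, or called without a GQ value, do not enter the tables.
    """
    params = params or FilterParams()
    batch = np.asarray(batch)
    if batch.shape[0] != cohort.n_samples:
        raise ValueError("batch labels must match the number of samples")
    labels = np.unique(batch)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 batch labels, got {list(labels)}")
    in_b1 = batch == labels[0]
    has_gq = np.isfinite(cohort.gq)
    high = has_gq & (cohort.gq >= params.gq_dichotomy)

    frame = cohort.site_frame()
    class_p = {}
    for cname, code in _GENOTYPE_CLASSES.items():
        member = (cohort.genotype == code) & has_gq
        a = (member & high)[:, in_b1].sum(axis=1)  # batch1, GQ >= cut
        b = (member & ~high)[:, in_b1].sum(axis=1)
        c = (member & high)[:, ~in_b1].sum(axis=1)
        d = (member & ~high)[:, ~in_b1].sum(axis=1)
        n = a + b + c + d
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        testable = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
        diff = np.abs(a * d - b * c).astype(float)
        if params.yates:
            diff = np.maximum(diff - n / 2.0, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = n * diff * diff / (r1 * r2 * c1 * c2)
        p = np.full(cohort.n_sites, np.nan)
        p[testable] = stats.chi2.sf(chi2[testable], 1)
        class_p[cname] = p
        frame[f"p_{cname}"] = p
    p_matrix = np.column_stack(list(class_p.values()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        min_p = np.nanmin(p_matrix, axis=1)
    filtered = np.isfinite(min_p) & (min_p < params.diff_gq_alpha)
    frame["filter"] = "DiffGQ"
    frame["filtered"] = filtered
    frame["min_p"] = min_p
    frame["reason"] = [
        "; ".join(
            f"{cname} p={class_p[cname][i]:.3g}"
            for cname in _GENOTYPE_CLASSES
            if np.isfinite(class_p[cname][i])
        )
        if filtered[i]
        else ""
        for i in range(cohort.n_sites)
    ]
    return frame


_JOIN_KEYS = ["chrom", "pos", "ref", "alt"]


def ld_concordance_filter(
    records_original: pd.DataFrame,
    records_corrected: pd.DataFrame,
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """LD-concordance filter over two association runs.

    Only sites that are genome-wide significant in the original run are
    eligible.  An eligible site is filtered when, in the association run on
    the haplotype-corrected genotypes, it is absent, monomorphic, or no
    longer below the GWS threshold.  Other sites are marked not applicable.
    """
    params = params or FilterParams()
    merged = records_original.merge(
        records_corrected[_JOIN_KEYS + ["p_value", "status"]],
        on=_JOIN_KEYS,
        how="left",
        suffixes=("", "_corrected"),
        indicator=True,
    )
    if len(merged) == 0 or (merged["_merge"] == "both").sum() == 0:
        raise ValueError("no sites join between original and corrected records")
    eligible = (merged["status"] == "ok") & (merged["p_value"] < params.gws_threshold)
    present = (merged["_merge"] == "both") & (merged["status_corrected"] == "ok")
    still_gws = present & (merged["p_value_corrected"] < params.gws_threshold)
    filtered = eligible & ~still_gws
    out = merged[_JOIN_KEYS + (["variant_class"] if "variant_class" in merged else [])].copy()
    out["filter"] = "LD"
    out["applicable"] = eligible
    out["filtered"] = filtered
    out["p_original"] = merged["p_value"]
    out["p_corrected"] = merged["p_value_corrected"]
    reasons = []
    for i in range(len(merged)):
        if not filtered.iloc[i]:
            reasons.append("" if eligible.iloc[i] else "not applicable (not GWS)")
        elif not present.iloc[i]:
            reasons.append("absent or monomorphic in LD-corrected genotypes")
        else:
            reasons.append(
                f"p_original={merged['p_value'].iloc[i]:.3g}, "
                f"p_corrected={merged['p_value_corrected'].iloc[i]:.3g} >= "
                f"{params.gws_threshold:g}"
            )
    out["reason"] = reasons
    return out


def region_mask_filter(sites: Sequence[VariantSite], mask: RegionSet) -> pd.DataFrame:
    """Filter sites whose position falls inside a region mask."""
    member = mask.mask_sites(sites)
    frame = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref_allele for s in sites],
            "alt": [s.alt_allele for s in sites],
            "variant_class": [s.variant_class for s in sites],
        }
    )
    frame["filter"] = "RegionMask"
    frame["filtered"] = member
    frame["reason"] = [
        f"inside {mask.label or 'mask'}" if m else "" for m in member
    ]
    return frame


@dataclass
class FilterSummary:
    """Per-filter and cumulative removal counts, split by variant class."""

    table: pd.DataFrame  # one row per pipeline stage, in application order
    n_universe: int
    n_removed_total: int

    @property
    def pct_removed_total(self) -> float:
        return 100.0 * self.n_removed_total / self.n_universe if self.n_universe else 0.0


def _summary_from_stage_sets(
    stage_removed: list[tuple[str, set]], universe: pd.DataFrame
) -> FilterSummary:
    """Build a FilterSummary from per-stage removed key sets (attribution order)."""
    klass = dict(
        zip(
            map(tuple, universe[_JOIN_KEYS].itertuples(index=False, name=None)),
            universe["variant_class"],
        )
    )
    n_snp = int((universe["variant_class"] == "SNP").sum())
    n_indel = len(universe) - n_snp
    seen: set = set()
    rows = []
    for name, removed in stage_removed:
        attributed = removed - seen
        seen |= removed
        a_snp = sum(1 for k in attributed if klass.get(k) == "SNP")
        rows.append(
            {
                "filter": name,
                "n_removed": len(attributed),
                "n_removed_snp": a_snp,
                "n_removed_indel": len(attributed) - a_snp,
                "pct_removed": 100.0 * len(attributed) / len(universe) if len(universe) else 0.0,
                "n_cumulative": len(seen),
                "pct_cumulative": 100.0 * len(seen) / len(universe) if len(universe) else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    if n_snp:
        table["pct_removed_snp"] = 100.0 * table["n_removed_snp"] / n_snp
    if n_indel:
        table["pct_removed_indel"] = 100.0 * table["n_removed_indel"] / n_indel
    return FilterSummary(table=table, n_universe=len(universe), n_removed_total=len(seen))


def recommended_pipeline(
    cohort: CohortGenotypes,
    batch: Sequence[str],
    records_original: pd.DataFrame,
    records_corrected: pd.DataFrame | None = None,
    params: FilterParams | None = None,
) -> tuple[pd.DataFrame, FilterSummary]:
    """Apply LD -> differential GQ -> GQ20M30 to the GWS site set.

    *records_original* (and optionally *records_corrected*, from an
    association run on externally LD-corrected genotypes) determine the GWS
    universe; *cohort* supplies the genotype/GQ matrices the two GQ-based
    filters need.  Attribution is sequential -- a site counts toward the
    first filter that removes it -- while the final removed set equals the
    union of the three filters' removals.  Returns per-site decisions for the
    GWS universe and a :class:`FilterSummary`.
    """
    params = params or FilterParams()
    gws = (records_original["status"] == "ok") & (
        records_original["p_value"] < params.gws_threshold
    )
    universe = records_original.loc[gws, _JOIN_KEYS + ["variant_class", "p_value"]].reset_index(
        drop=True
    )
    if len(universe) == 0:
        warnings.warn("no genome-wide significant sites; nothing to filter", stacklevel=2)
        empty = universe.assign(filtered=pd.Series(dtype=bool), filter="", reason="")
        return empty, _summary_from_stage_sets(
            [("LD", set()), ("DiffGQ", set()), (params.gq20mx_name, set())], universe
        )
    gws_keys = set(map(tuple, universe[_JOIN_KEYS].itertuples(index=False, name=None)))
    key_of = {s.key: i for i, s in enumerate(cohort.sites)}
    idx = [key_of[k] for k in map(tuple, universe[_JOIN_KEYS].itertuples(index=False, name=None)) if k in key_of]
    if len(idx) != len(universe):
        raise ValueError("some GWS sites are absent from the cohort matrices")
    sub = cohort.subset_sites(np.asarray(idx))

    stage_removed: list[tuple[str, set]] = []
    reason_of: dict[tuple, str] = {}
    filter_of: dict[tuple, str] = {}

    if records_corrected is not None:
        ld = ld_concordance_filter(records_original, records_corrected, params)
        ld_removed = {
            tuple(r)
            for r, f in zip(ld[_JOIN_KEYS].itertuples(index=False, name=None), ld["filtered"])
            if f
        } & gws_keys
        for _, row in ld[ld["filtered"]].iterrows():
            key = tuple(row[k] for k in _JOIN_KEYS)
            reason_of.setdefault(key, row["reason"])
            filter_of.setdefault(key, "LD")
    else:
        warnings.warn("no LD-corrected records supplied; skipping the LD stage", stacklevel=2)
        ld_removed = set()
    stage_removed.append(("LD", ld_removed))

    dgq = differential_gq_filter(sub, batch, params)
    dgq_removed = {
        tuple(r)
        for r, f in zip(dgq[_JOIN_KEYS].itertuples(index=False, name=None), dgq["filtered"])
        if f
    }
    for _, row in dgq[dgq["filtered"]].iterrows():
        key = tuple(row[k] for k in _JOIN_KEYS)
        reason_of.setdefault(key, row["reason"])
        filter_of.setdefault(key, "DiffGQ")
    stage_removed.append(("DiffGQ", dgq_removed))

    _, gq20 = gq_missingness_filter(sub, params)
    gq20_removed = {
        tuple(r)
        for r, f in zip(gq20[_JOIN_KEYS].itertuples(index=False, name=None), gq20["filtered"])
        if f
    }
    for _, row in gq20[gq20["filtered"]].iterrows():
        key = tuple(row[k] for k in _JOIN_KEYS)
        reason_of.setdefault(key, row["reason"])
        filter_of.setdefault(key, params.gq20mx_name)
    stage_removed.append((params.gq20mx_name, gq20_removed))

    decisions = universe.copy()
    keys = list(map(tuple, universe[_JOIN_KEYS].itertuples(index=False, name=None)))
    removed_union = ld_removed | dgq_removed | gq20_removed
    decisions["filtered"] = [k in removed_union for k in keys]
    decisions["filter"] = [filter_of.get(k, "") for k in keys]
    decisions["reason"] = [reason_of.get(k, "") for k in keys]
    summary = _summary_from_stage_sets(stage_removed, universe)
    return decisions, summary


def summarize(decisions: pd.DataFrame, universe: Sequence[VariantSite] | pd.DataFrame) -> FilterSummary:
    """Counts and percentages of sites removed, per filter and cumulatively.

    *decisions* is a concatenation of per-filter decision tables (columns
    ``chrom, pos, ref, alt, filter, filtered``); *universe* lists every site
    under consideration with its variant class.  Decision sites missing from
    the universe raise.
    """
    if isinstance(universe, pd.DataFrame):
        uni = universe[_JOIN_KEYS + ["variant_class"]].copy()
    else:
        uni = pd.DataFrame(
            {
                "chrom": [s.chrom for s in universe],
                "pos": [s.pos for s in universe],
                "ref": [s.ref_allele for s in universe],
                "alt": [s.alt_allele for s in universe],
                "variant_class": [s.variant_class for s in universe],
            }
        )
    uni_keys = set(map(tuple, uni[_JOIN_KEYS].itertuples(index=False, name=None)))
    dec_keys = set(map(tuple, decisions[_JOIN_KEYS].itertuples(index=False, name=None)))
    stray = dec_keys - uni_keys
    if stray:
        raise ValueError(f"{len(stray)} decision site(s) absent from the universe")
    stage_removed = []
    for name in decisions["filter"].unique():
        sel = decisions[(decisions["filter"] == name) & decisions["filtered"]]
        stage_removed.append(
            (str(name), set(map(tuple, sel[_JOIN_KEYS].itertuples(index=False, name=None))))
        )
    return _summary_from_stage_sets(stage_removed, uni)


def summarize_locus_table(
    table: pd.DataFrame, significance_alpha: float = 0.05 / 16
) -> pd.DataFrame:
    """Summarise a per-locus filter-verdict table from a candidate analysis.

    Expects one row per confirmed locus with boolean (or ``F``/``NF``)
    columns named after filters (e.g. ``GQ20M05``, ``GQ20M30``, ``DiffGQ``)
    and, optionally, ``p_value`` / ``ld_corrected_p`` columns from which the
    LD verdict is derived: a locus is LD-filtered when its original p-value
    is significant at *significance_alpha* but the LD-corrected one is not.
    Returns per-filter removal counts plus the recommended combination
    (LD + DiffGQ + GQ20M30) as the union of its members.
    """

    def _as_bool(col: pd.Series) -> pd.Series:
        if col.dtype == bool:
            return col
        return col.astype(str).str.strip().str.upper().eq("F")

    verdicts = {}
    for col in table.columns:
        if col.upper().startswith("GQ20M") or col.replace(" ", "").lower() in ("diffgq", "diff_gq"):
            name = "DiffGQ" if "GQ20M" not in col.upper() else col.upper().replace(" ", "")
            verdicts[name] = _as_bool(table[col])
    if {"p_value", "ld_corrected_p"} <= set(table.columns):
        orig_sig = table["p_value"].astype(float) < significance_alpha
        corr_sig = table["ld_corrected_p"].astype(float) < significance_alpha
        verdicts["LD"] = orig_sig & ~corr_sig
    n = len(table)
    rows = [
        {"filter": name, "n_filtered": int(v.sum()), "pct_filtered": 100.0 * v.sum() / n}
        for name, v in verdicts.items()
    ]
    combo_members = [m for m in ("LD", "DiffGQ", "GQ20M30") if m in verdicts]
    if combo_members:
        combined = np.zeros(n, dtype=bool)
        for m in combo_members:
            combined |= verdicts[m].to_numpy()
        rows.append(
            {
                "filter": "+".join(combo_members),
                "n_filtered": int(combined.sum()),
                "pct_filtered": 100.0 * combined.sum() / n,
            }
        )
    return pd.DataFrame(rows)
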