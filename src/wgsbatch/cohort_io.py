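"""Reading, writing and in-memory representation of a multi-sample genotype cohort.

The central container is :class:`CohortGenotypes`: sites x samples matrices of
additively coded genotypes (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing),
genotype quality (GQ) and read depth (DP), plus per-site (:class:`VariantSite`)
and per-sample (:class:`SampleInfo`) metadata.  Every downstream stage --
quality metrics, PCA batch detection, association testing, and the batch
filters -- consumes this object.

Coordinate conventions: VCF positions are 1-based and kept 1-based internally;
BED intervals are 0-based half-open and converted only at the query boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "VariantSite",
    "CohortGenotypes",
    "SampleInfo",
    "RegionSet",
    "GoldVariantSet",
    "classify_variant",
    "gc_fraction",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "load_regions",
    "load_gold_set",
    "read_sample_table",
    "write_site_report",
]

#: Genotype code for a missing call (``./.`` or half-calls such as ``./1``).
MISSING = -1

_NUCLEOTIDES = frozenset("ACGT")
_TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))


def classify_variant(ref_allele: str, alt_allele: str) -> tuple[str, str]:
    """Classify a biallelic variant as SNP/indel and transition/transversion.

    Returns ``(variant_class, snp_change)`` where *variant_class* is ``"SNP"``
    or ``"indel"`` and *snp_change* is ``"transition"``, ``"transversion"`` or
    ``"not-applicable"`` (for indels).  Transitions are the purine-purine
    (A<->G) and pyrimidine-pyrimidine (C<->T) substitutions.
    """
    ref = ref_allele.upper()
    alt = alt_allele.upper()
    if not ref or not alt:
        raise ValueError("alleles must be non-empty")
    bad = (set(ref) | set(alt)) - _NUCLEOTIDES
    if bad:
        raise ValueError(f"invalid allele characters: {sorted(bad)!r}")
    if ref == alt:
        raise ValueError(f"identical ref and alt allele {ref!r}")
    if len(ref) == 1 and len(alt) == 1:
        pair = frozenset((ref, alt))
        change = "transition" if pair in _TRANSITION_PAIRS else "transversion"
        return "SNP", change
    return "indel", "not-applicable"


def gc_fraction(window_sequence: str) -> float:
    """GC fraction of the 25-bp window around a site: (#G + #C) / (25 - #N).

    Ns are excluded from the denominator; an all-N window yields ``nan``.
    """
    seq = window_sequence.upper()
    if len(seq) != 25:
        raise ValueError(f"expected a 25-bp window, got length {len(seq)}")
    if set(seq) - (_NUCLEOTIDES | {"N"}):
        raise ValueError("window may contain only A, C, G, T, N")
    n_n = seq.count("N")
    if n_n == 25:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / (25 - n_n)


@dataclass
class VariantSite:
    """One biallelic variant site (1-based position)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str = field(default="")
    snp_change: str = field(default="")
    gc_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.variant_class:
            self.variant_class, self.snp_change = classify_variant(
                self.ref_allele, self.alt_allele
            )
        if not (np.isnan(self.gc_fraction) or 0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must lie in [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def _chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome ordering: numeric names first, then lexicographic."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


@dataclass
class SampleInfo:
    """Per-sample metadata: batch label, optional binary phenotype, covariates."""

    sample_id: str
    batch: str = ""
    phenotype: int | None = None  # 1 = case, 0 = control, None = unset
    covariates: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class CohortGenotypes:
    """Sites x samples genotype, GQ and depth matrices with metadata.

    Invariants enforced by :meth:`validate`: the three matrices share
    dimensions, genotype codes come from {0, 1, 2, MISSING}, GQ is NaN
    wherever the genotype is missing, and sites are (chrom, pos, alt) sorted.
    """

    sites: list[VariantSite]
    samples: list[str]
    genotype: np.ndarray  # int8, MISSING = -1
    gq: np.ndarray  # float, NaN = missing
    depth: np.ndarray  # float, NaN = unset
    n_multiallelic_dropped: int = 0

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.validate()

    def validate(self) -> None:
        shape = (len(self.sites), len(self.samples))
        for name in ("genotype", "gq", "depth"):
            mat = getattr(self, name)
            if mat.shape != shape:
                raise ValueError(f"{name} matrix shape {mat.shape} != {shape}")
        codes = np.unique(self.genotype)
        bad = set(codes.tolist()) - {MISSING, 0, 1, 2}
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")
        # GQ must be missing wherever the genotype is missing.
        self.gq[self.genotype == MISSING] = np.nan
        if np.nanmin(self.gq, initial=0.0) < 0:
            raise ValueError("negative GQ value")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_keys(self) -> list[tuple[str, int, str, str]]:
        return [s.key for s in self.sites]

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "ref": [s.ref_allele for s in self.sites],
                "alt": [s.alt_allele for s in self.sites],
                "variant_class": [s.variant_class for s in self.sites],
            }
        )

    def missing_rate_per_site(self) -> np.ndarray:
        return (self.genotype == MISSING).mean(axis=1)

    def missing_rate_per_sample(self) -> np.ndarray:
        return (self.genotype == MISSING).mean(axis=0)

    def subset_sites(self, index: np.ndarray) -> "CohortGenotypes":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CohortGenotypes(
            sites=[self.sites[i] for i in index],
            samples=list(self.samples),
            genotype=self.genotype[index].copy(),
            gq=self.gq[index].copy(),
            depth=self.depth[index].copy(),
            n_multiallelic_dropped=self.n_multiallelic_dropped,
        )

    def subset_samples(self, index: np.ndarray) -> "CohortGenotypes":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CohortGenotypes(
            sites=list(self.sites),
            samples=[self.samples[i] for i in index],
            genotype=self.genotype[:, index].copy(),
            gq=self.gq[:, index].copy(),
            depth=self.depth[:, index].copy(),
            n_multiallelic_dropped=self.n_multiallelic_dropped,
        )

    def sorted_by_position(self) -> "CohortGenotypes":
        order = sorted(
            range(self.n_sites),
            key=lambda i: (
                _chrom_sort_key(self.sites[i].chrom),
                self.sites[i].pos,
                self.sites[i].alt_allele,
            ),
        )
        return self.subset_sites(np.asarray(order))


class RegionSet:
    """A labelled set of genomic intervals (0-based half-open, as in BED).

    Intervals are merged and sorted on construction; point queries take
    1-based positions (the internal convention) and are O(log n).
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]], label: str = ""):
        self.label = label
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for start, end in ivs:
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            arr = np.asarray(merged, dtype=np.int64)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._starts, key=_chrom_sort_key):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append((chrom, int(s), int(e)))
        return out

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a single 1-based position."""
        return bool(self.contains_many([chrom], np.asarray([pos]))[0])

    def contains_many(self, chroms: Sequence[str], pos: np.ndarray) -> np.ndarray:
        """Vectorised membership of 1-based positions."""
        pos = np.asarray(pos, dtype=np.int64)
        out = np.zeros(len(pos), dtype=bool)
        chroms = np.asarray(chroms)
        for chrom in np.unique(chroms):
            starts = self._starts.get(str(chrom))
            if starts is None:
                continue
            ends = self._ends[str(chrom)]
            sel = chroms == chrom
            zero_based = pos[sel] - 1
            idx = np.searchsorted(starts, zero_based, side="right") - 1
            hit = (idx >= 0) & (zero_based < ends[np.clip(idx, 0, len(ends) - 1)])
            out[sel] = hit
        return out

    def mask_sites(self, sites: Sequence[VariantSite]) -> np.ndarray:
        return self.contains_many([s.chrom for s in sites], np.asarray([s.pos for s in sites]))


def load_regions(path: str | Path, label: str = "") -> RegionSet:
    """Load a BED file (0-based half-open) into a merged :class:`RegionSet`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            intervals.append((parts[0], start, end))
    return RegionSet(intervals, label=label or Path(path).stem)


class GoldVariantSet:
    """Trusted variant catalogue keyed by (chrom, pos, alt)."""

    def __init__(self, entries: Iterable[tuple[str, int, str]]):
        self.entries = frozenset((str(c), int(p), str(a)) for c, p, a in entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return (str(key[0]), int(key[1]), str(key[2])) in self.entries

    def contains_sites(self, sites: Sequence[VariantSite]) -> np.ndarray:
        return np.asarray(
            [(s.chrom, s.pos, s.alt_allele) in self.entries for s in sites], dtype=bool
        )


def load_gold_set(path: str | Path) -> GoldVariantSet:
    """Load a gold variant set from VCF (uses ALT alleles) or TSV (chrom, pos, alt)."""
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        from cyvcf2 import VCF

        entries = []
        for record in VCF(str(path)):
            for alt in record.ALT:
                entries.append((record.CHROM, record.POS, alt))
        return GoldVariantSet(entries)
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in table.columns]
    if {"chrom", "pos", "alt"} <= set(cols):
        table.columns = cols
    else:  # headerless three-column file
        table = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "alt"], dtype={0: str})
    return GoldVariantSet(zip(table["chrom"].astype(str), table["pos"], table["alt"]))


def read_sample_table(path: str | Path) -> list[SampleInfo]:
    """Read sample metadata TSV: sample_id, optional batch/phenotype, covariates.

    Phenotype accepts 0/1 or case/control strings; remaining numeric columns
    are collected into the per-sample covariate vector.
    """
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    if "sample_id" not in table.columns:
        raise ValueError("sample table must have a 'sample_id' column")
    if table["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample table")
    known = {"sample_id", "batch", "phenotype"}
    cov_cols = [c for c in table.columns if c not in known]
    out = []
    for _, row in table.iterrows():
        pheno = None
        if "phenotype" in table.columns and not pd.isna(row["phenotype"]):
            raw = str(row["phenotype"]).strip().lower()
            pheno = {"case": 1, "control": 0, "1": 1, "0": 0}.get(raw)
            if pheno is None:
                raise ValueError(f"unrecognised phenotype value {row['phenotype']!r}")
        out.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                batch=("" if "batch" not in table.columns or pd.isna(row["batch"]) else str(row["batch"])),
                phenotype=pheno,
                covariates=row[cov_cols].to_numpy(dtype=float) if cov_cols else np.empty(0),
            )
        )
    return out


def read_cohort_vcf(path: str | Path, drop_multiallelic: bool = False) -> CohortGenotypes:
    """Read a multi-sample VCF into a :class:`CohortGenotypes`.

    Biallelic records become one site each.  Multiallelic records are dropped
    and counted when *drop_multiallelic* is set, otherwise they raise.  ``./.``
    and half-calls map to missing; an absent GQ field maps to missing GQ with
    a warning.  Sites are returned (chrom, pos, alt) sorted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if not vcf.samples:
        raise ValueError(f"{path}: VCF has no samples")
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    genotype_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    n_multi = 0
    gq_absent = 0
    for record in vcf:
        if len(record.ALT) != 1:
            if drop_multiallelic:
                n_multi += 1
                continue
            raise ValueError(
                f"{path}: multiallelic record at {record.CHROM}:{record.POS} "
                "(pass drop_multiallelic=True to remove such records)"
            )
        sites.append(VariantSite(record.CHROM, record.POS, record.REF, record.ALT[0]))
        codes = np.empty(len(samples), dtype=np.int8)
        for j, alleles in enumerate(record.genotypes):
            a = alleles[:-1]  # last element is the phased flag
            if len(a) < 2 or min(a) < 0:
                codes[j] = MISSING  # no-call or half-call
            else:
                codes[j] = int(a[0] > 0) + int(a[1] > 0)
        genotype_rows.append(codes)
        gq = np.asarray(record.gt_quals, dtype=float)
        if gq.size == 0 or np.all(gq < 0):
            gq = np.full(len(samples), np.nan)
            gq_absent += 1
        else:
            gq[gq < 0] = np.nan
        gq_rows.append(gq)
        dp_field = record.format("DP")
        if dp_field is None:
            dp = np.full(len(samples), np.nan)
        else:
            dp = dp_field[:, 0].astype(float)
            dp[dp < 0] = np.nan  # negative sentinel = missing
        depth_rows.append(dp)
    if gq_absent:
        warnings.warn(
            f"{gq_absent} record(s) had no GQ values; their GQ is set to missing",
            stacklevel=2,
        )
    shape = (len(sites), len(samples))
    cohort = CohortGenotypes(
        sites=sites,
        samples=samples,
        genotype=np.vstack(genotype_rows) if sites else np.empty(shape, dtype=np.int8),
        gq=np.vstack(gq_rows) if sites else np.empty(shape),
        depth=np.vstack(depth_rows) if sites else np.empty(shape),
        n_multiallelic_dropped=n_multi,
    )
    return cohort.sorted_by_position()


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _fmt_number(x: float) -> str:
    if np.isnan(x):
        return "."
    if float(x).is_integer():
        return str(int(x))
    return f"{x:g}"


def write_cohort_vcf(cohort: CohortGenotypes, path: str | Path) -> None:
    """Write the cohort as a VCF v4.2 with GT:GQ:DP genotype fields."""
    cohort = cohort.sorted_by_position()
    chroms = []
    for s in cohort.sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(cohort.samples) + "\n")
        for i, site in enumerate(cohort.sites):
            cells = []
            for j in range(cohort.n_samples):
                gt = _GT_STRINGS[int(cohort.genotype[i, j])]
                cells.append(f"{gt}:{_fmt_number(cohort.gq[i, j])}:{_fmt_number(cohort.depth[i, j])}")
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t{site.alt_allele}"
                f"\t.\t.\t.\tGT:GQ:DP\t" + "\t".join(cells) + "\n"
            )


def write_site_report(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-site result table as TSV, deterministically ordered.

    Rows are sorted by (chrom, pos) when those columns are present; column
    order is preserved.  An empty table produces a header-only file with a
    warning.
    """
    if table.empty:
        warnings.warn(f"writing header-only site report to {path}", stacklevel=2)
    out = table
    if {"chrom", "pos"} <= set(table.columns) and not table.empty:
        out = table.sort_values(
            ["chrom", "pos"],
            key=lambda col: col.map(lambda v: _chrom_sort_key(str(v))) if col.name == "chrom" else col,
            kind="mergesort",
        )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
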