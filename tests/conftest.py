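"""Shared fixtures: tiny hand-built cohorts and text fixtures written on the fly."""

from __future__ import annotations

import numpy as np
import pytest

from wgsbatch import CohortGenotypes, VariantSite

# A 2-site x 3-sample VCF with a clean genotype spread, a no-call, and one
# multiallelic record to exercise the drop-and-count path.
TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\t.\tA\tG\t.\t.\t.\tGT:GQ:DP\t0/0:50:30\t0/1:60:31\t1/1:70:32
1\t200\t.\tC\tT\t.\t.\t.\tGT:GQ:DP\t0/1:45:28\t./.:.:.\t0/0:80:33
1\t300\t.\tA\tG,T\t.\t.\t.\tGT:GQ:DP\t0/1:50:30\t0/2:50:30\t0/0:50:30
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(TINY_VCF)
    return path


def build_cohort(
    genotype,
    gq=None,
    depth=None,
    alleles=None,
    chrom="1",
    start_pos=100,
    spacing=100,
):
    """Build a small cohort from explicit matrices (NaN GQ where missing)."""
    genotype = np.asarray(genotype, dtype=np.int8)
    n_sites, n_samples = genotype.shape
    if gq is None:
        gq = np.full(genotype.shape, 90.0)
    gq = np.asarray(gq, dtype=float).copy()
    gq[genotype == -1] = np.nan
    if depth is None:
        depth = np.full(genotype.shape, 30.0)
    if alleles is None:
        alleles = [("A", "G")] * n_sites
    sites = [
        VariantSite(chrom, start_pos + i * spacing, ref, alt)
        for i, (ref, alt) in enumerate(alleles)
    ]
    samples = [f"S{j + 1}" for j in range(n_samples)]
    return CohortGenotypes(
        sites=sites,
        samples=samples,
        genotype=genotype,
        gq=gq,
        depth=np.asarray(depth, dtype=float),
    )


def random_cohort(rng, n_sites=60, n_samples=20, missing_rate=0.05):
    """Random but valid cohort for property tests."""
    af = rng.uniform(0.1, 0.5, size=n_sites)
    u = rng.random((n_sites, n_samples))
    hom_ref = (1 - af[:, None]) ** 2
    het = 2 * af[:, None] * (1 - af[:, None])
    genotype = np.where(u < hom_ref, 0, np.where(u < hom_ref + het, 1, 2)).astype(np.int8)
    genotype[rng.random((n_sites, n_samples)) < missing_rate] = -1
    gq = np.floor(rng.uniform(0, 99, size=(n_sites, n_samples)))
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("AT", "A"), ("C", "CT")]
    alleles = [pairs[i] for i in rng.integers(0, len(pairs), size=n_sites)]
    return build_cohort(genotype, gq=gq, alleles=alleles)
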