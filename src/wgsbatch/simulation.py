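"""Monte-Carlo power study for the differential-GQ test and a synthetic
batch-affected cohort generator.

The power simulation follows the differential-GQ model: group 1 genotype
qualities are drawn from Uniform(0, 99) and group 2 from Uniform(0, 99) +
Normal(mu, sigma), values are dichotomized at GQ60, and the same 2x2 Pearson
chi-square used by the differential-GQ filter is evaluated at alpha = 1e-4.
Simulated GQ values are continuous and deliberately not clipped to [0, 99]
(the sum distribution is taken as-is); dichotomization makes both choices
immaterial in practice, and a clip switch exists for sensitivity analysis.

The cohort generator plants three kinds of batch artifacts on top of clean
Hardy-Weinberg sites so that every detector and filter in the package can be
exercised against a known truth: a batch-2 GQ shift, batch-2 differential
missingness, and batch-2 heterozygote over-calling (genotype errors that
create a spurious batch association and are inconsistent with the underlying
haplotypes, hence correctable by an idealised LD corrector).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import MISSING, CohortGenotypes, SampleInfo, VariantSite

__all__ = [
    "PowerSpec",
    "PowerResult",
    "SyntheticSpec",
    "SyntheticTruth",
    "simulate_diffgq_power",
    "power_grid",
    "generate_cohort",
    "make_ld_corrected",
    "evaluate_recovery",
]


@dataclass
class PowerSpec:
    """One cell of the differential-GQ power study."""

    mu: float = 15.0
    sigma: float = 5.0
    n_per_group: int = 500
    reps: int = 1000
    alpha: float = 1e-4
    gq_dichotomy: float = 60.0
    clip: bool = False  # clip simulated GQ to [0, 99] (sensitivity analysis only)

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class PowerResult:
    """Monte-Carlo rejection rate with its binomial standard error."""

    spec: PowerSpec
    power: float
    mc_se: float
    seed: int


def _cell_seed(seed: int, mu: float, sigma: float, n: int) -> np.random.SeedSequence:
    """Deterministic per-cell seed stream so grids reproduce cell-by-cell."""
    return np.random.SeedSequence(
        entropy=int(seed), spawn_key=(int(round(mu * 1000)), int(round(sigma * 1000)), int(n))
    )


def simulate_diffgq_power(spec: PowerSpec, seed: int = 0) -> PowerResult:
    """Monte-Carlo power of the differential-GQ 2x2 chi-square test.

    Per replicate, ``n_per_group`` GQ values are drawn for each group,
    dichotomized at ``gq_dichotomy``, cross-tabulated against group and
    tested with the 1-df Pearson chi-square; the rejection fraction over
    ``reps`` replicates at ``alpha`` is the power.  Deterministic given
    *seed* (the same per-cell stream :func:`power_grid` uses).
    """
    rng = np.random.default_rng(_cell_seed(seed, spec.mu, spec.sigma, spec.n_per_group))
    crit = stats.chi2.isf(spec.alpha, 1)
    n = spec.n_per_group
    rejections = 0
    done = 0
    chunk = max(1, min(spec.reps, int(5e6 // max(n, 1))))
    while done < spec.reps:
        r = min(chunk, spec.reps - done)
        g1 = rng.uniform(0, 99, size=(r, n))
        g2 = rng.uniform(0, 99, size=(r, n)) + rng.normal(spec.mu, spec.sigma, size=(r, n))
        if spec.clip:
            g1 = np.clip(g1, 0, 99)
            g2 = np.clip(g2, 0, 99)
        a = (g1 >= spec.gq_dichotomy).sum(axis=1).astype(float)
        c = (g2 >= spec.gq_dichotomy).sum(axis=1).astype(float)
        b, d = n - a, n - c
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        testable = (c1 > 0) & (c2 > 0)  # row margins are n > 0 by construction
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = 2 * n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        rejections += int(np.sum(testable & (chi2 > crit)))
        done += r
    power = rejections / spec.reps
    return PowerResult(
        spec=spec,
        power=power,
        mc_se=math.sqrt(power * (1 - power) / spec.reps),
        seed=seed,
    )


def power_grid(
    mus: Sequence[float],
    sigmas: Sequence[float] = (1.0, 5.0, 10.0),
    ns: Sequence[int] = (250, 500, 1000),
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """Full factorial power grid over (mu, sigma, n_per_group).

    Each cell draws from its own deterministic seed stream derived from the
    master *seed*, so any cell reproduces the single-spec result and the grid
    is reproducible regardless of evaluation order.
    """
    if not (len(mus) and len(sigmas) and len(ns)):
        raise ValueError("grid axes must be non-empty")
    rows = []
    for sigma in sigmas:
        for n in ns:
            for mu in mus:
                res = simulate_diffgq_power(
                    PowerSpec(mu=mu, sigma=sigma, n_per_group=n, reps=reps, alpha=alpha),
                    seed=seed,
                )
                rows.append(
                    {
                        "mu": mu,
                        "sigma": sigma,
                        "n_per_group": n,
                        "reps": reps,
                        "power": res.power,
                        "mc_se": res.mc_se,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SyntheticSpec:
    """Conditions of the synthetic two-batch cohort.

    Defaults give 500 samples per batch and 1000 sites of which 15% carry a
    batch-2 GQ shift of +30, 5% batch-2 extra missingness of +0.20 and 5%
    batch-2 heterozygote over-calling at rate 0.4; the remaining 75% are
    clean.  Baseline GQ is Uniform(0, 99) (the differential-GQ power model),
    baseline missingness 2%, allele frequencies Uniform(0.05, 0.5) under
    Hardy-Weinberg in both batches.  A chemistry-style coverage difference
    accompanies the quality artifacts: batch-2 read depth is Poisson with
    mean ``baseline_depth + depth_shift`` (depth never touches genotypes, so
    it is visible to the quality metrics but not to genotype PCA).
    """

    n_samples_per_batch: tuple[int, int] = (500, 500)
    n_sites: int = 1000
    fraction_gq_shift_sites: float = 0.15
    gq_shift: float = 30.0
    fraction_diff_missing_sites: float = 0.05
    missingness_delta: float = 0.20
    fraction_genotype_error_sites: float = 0.05
    genotype_error_rate: float = 0.4
    baseline_missingness: float = 0.02
    baseline_depth: float = 30.0
    depth_shift: float = 2.0
    af_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        fr = (
            self.fraction_gq_shift_sites
            + self.fraction_diff_missing_sites
            + self.fraction_genotype_error_sites
        )
        if fr > 1:
            raise ValueError("artifact fractions sum to more than 1")
        if min(self.n_samples_per_batch) < 1 or self.n_sites < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of the generated cohort.

    ``labels`` has one row per site with its artifact class ({clean,
    gq_shift, diff_missing, genotype_error}) and the injected parameters;
    ``true_genotype`` is the pre-corruption genotype matrix (what an ideal
    haplotype corrector would restore).
    """

    labels: pd.DataFrame
    true_genotype: np.ndarray


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]


def generate_cohort(
    spec: SyntheticSpec | None = None, seed: int = 0
) -> tuple[CohortGenotypes, list[SampleInfo], SyntheticTruth]:
    """Generate a two-batch cohort with planted batch artifacts.

    Clean sites have identical genotype, GQ and missingness distributions in
    both batches (Hardy-Weinberg genotypes at a drawn allele frequency, GQ ~
    Uniform(0, 99)).  Artifact sites perturb batch 2 only: ``gq_shift`` adds
    ``spec.gq_shift`` to every batch-2 GQ; ``diff_missing`` raises batch-2
    missingness by ``spec.missingness_delta``; ``genotype_error`` re-calls
    batch-2 hom-ref genotypes as hets with probability
    ``spec.genotype_error_rate``, creating a spurious batch association.
    Fully reproducible given *seed*.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(99,)))
    n1, n2 = spec.n_samples_per_batch
    n_samples = n1 + n2
    m = spec.n_sites
    batch2 = np.zeros(n_samples, dtype=bool)
    batch2[n1:] = True

    n_shift = round(spec.fraction_gq_shift_sites * m)
    n_miss = round(spec.fraction_diff_missing_sites * m)
    n_err = round(spec.fraction_genotype_error_sites * m)
    labels = np.array(
        ["gq_shift"] * n_shift
        + ["diff_missing"] * n_miss
        + ["genotype_error"] * n_err
        + ["clean"] * (m - n_shift - n_miss - n_err)
    )
    rng.shuffle(labels)

    af = rng.uniform(*spec.af_range, size=m)
    u = rng.random((m, n_samples))
    hom_ref = (1 - af[:, None]) ** 2
    het = 2 * af[:, None] * (1 - af[:, None])
    genotype = np.where(u < hom_ref, 0, np.where(u < hom_ref + het, 1, 2)).astype(np.int8)
    true_genotype = genotype.copy()

    err_sites = labels == "genotype_error"
    flips = (
        err_sites[:, None]
        & batch2[None, :]
        & (genotype == 0)
        & (rng.random((m, n_samples)) < spec.genotype_error_rate)
    )
    genotype[flips] = 1

    gq = np.floor(rng.uniform(0, 99, size=(m, n_samples)))
    gq[labels == "gq_shift"] = gq[labels == "gq_shift"] + np.where(batch2, spec.gq_shift, 0.0)

    miss_p = np.full((m, n_samples), spec.baseline_missingness)
    miss_p[np.ix_(labels == "diff_missing", batch2)] += spec.missingness_delta
    missing = rng.random((m, n_samples)) < miss_p
    genotype[missing] = MISSING
    gq[missing] = np.nan

    depth_mean = np.where(batch2, spec.baseline_depth + spec.depth_shift, spec.baseline_depth)
    depth = np.maximum(
        rng.poisson(np.broadcast_to(depth_mean, (m, n_samples))).astype(float), 1.0
    )
    depth[missing] = np.nan

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    sites = [
        VariantSite("1", 1000 * (i + 1), *_ALLELE_PAIRS[pair_idx[i]]) for i in range(m)
    ]
    samples = [f"B1_{i:04d}" for i in range(n1)] + [f"B2_{i:04d}" for i in range(n2)]
    cohort = CohortGenotypes(
        sites=sites, samples=samples, genotype=genotype, gq=gq, depth=depth
    )
    infos = [
        SampleInfo(sample_id=s, batch="batch2" if b else "batch1", phenotype=int(b))
        for s, b in zip(samples, batch2)
    ]
    truth_frame = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref_allele for s in sites],
            "alt": [s.alt_allele for s in sites],
            "label": labels,
            "allele_frequency": af,
            "gq_shift": np.where(labels == "gq_shift", spec.gq_shift, 0.0),
            "missingness_delta": np.where(labels == "diff_missing", spec.missingness_delta, 0.0),
            "genotype_error_rate": np.where(
                labels == "genotype_error", spec.genotype_error_rate, 0.0
            ),
        }
    )
    return cohort, infos, SyntheticTruth(labels=truth_frame, true_genotype=true_genotype)


def make_ld_corrected(cohort: CohortGenotypes, truth: SyntheticTruth) -> CohortGenotypes:
    """Idealised haplotype-corrected call set: injected genotype errors reverted.

    Stands in for an external haplotype-inference run when testing the LD
    concordance filter end to end; real correction (e.g. Beagle) is an
    external input, not part of this package.
    """
    if truth.true_genotype.shape != cohort.genotype.shape:
        raise ValueError("truth matrix does not match the cohort")
    genotype = truth.true_genotype.copy()
    genotype[cohort.genotype == MISSING] = MISSING  # keep observed missingness
    return CohortGenotypes(
        sites=list(cohort.sites),
        samples=list(cohort.samples),
        genotype=genotype,
        gq=cohort.gq.copy(),
        depth=cohort.depth.copy(),
    )


def evaluate_recovery(
    truth: SyntheticTruth, decisions: pd.DataFrame
) -> pd.DataFrame:
    """Sensitivity per artifact class and the clean-site removal rate.

    *decisions* must carry ``chrom, pos, ref, alt, filtered`` for the sites
    it judged; truth sites absent from the decision table count as not
    removed (sites the pipeline never evaluated, e.g. non-GWS ones).  A
    decision site missing from the truth raises.
    """
    key_cols = ["chrom", "pos", "ref", "alt"]
    truth_keys = set(map(tuple, truth.labels[key_cols].itertuples(index=False, name=None)))
    removed = set(
        map(
            tuple,
            decisions.loc[decisions["filtered"], key_cols].itertuples(index=False, name=None),
        )
    )
    stray = removed - truth_keys
    if stray:
        raise ValueError(f"{len(stray)} decision site(s) not present in the truth")
    rows = []
    keys = list(map(tuple, truth.labels[key_cols].itertuples(index=False, name=None)))
    was_removed = np.asarray([k in removed for k in keys])
    for label in ["clean", "gq_shift", "diff_missing", "genotype_error"]:
        sel = (truth.labels["label"] == label).to_numpy()
        n = int(sel.sum())
        n_rm = int(np.sum(was_removed & sel))
        rows.append(
            {
                "label": label,
                "n_sites": n,
                "n_removed": n_rm,
                "fraction_removed": n_rm / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
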