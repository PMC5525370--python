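"""Batch detection via PCA of quality metrics, plus genotype PCA.

A batch effect that is invisible in the standard genotype PCA (which reflects
population structure) often shows up clearly when the PCA is run on the
per-sample quality-metric vectors instead: samples processed with different
chemistry or library preparation separate into well-delineated clouds.  The
numeric separation score here (2-means + silhouette) quantifies that visual
delineation and, when batch labels are known, how well the unsupervised split
matches them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .cohort_io import MISSING, CohortGenotypes
from .sample_metrics import QualityProfile, profiles_to_frame

__all__ = [
    "PCAResult",
    "SeparationAssessment",
    "metrics_pca",
    "genotype_pca",
    "separation_score",
]


@dataclass
class PCAResult:
    """Scores (samples x k), loadings (variables x k), variance fractions."""

    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    dropped_variables: list[str]
    sample_ids: list[str]
    variable_names: list[str]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def _svd_pca(x: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of a column-centred matrix; returns (scores, loadings, var_fractions)."""
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    total_var = float(np.sum(s**2))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    var_frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    # Fix eigenvector sign: largest-magnitude loading positive.
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return scores, loadings, var_frac


def metrics_pca(profiles: Sequence[QualityProfile] | pd.DataFrame) -> PCAResult:
    """PCA of standardised per-sample quality metrics.

    Each metric column is centred and scaled to unit SD (so the decomposition
    is of the metric correlation structure); zero-variance metrics are dropped
    with a warning; missing metric values are mean-imputed.
    """
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    if len(frame) < 3:
        raise ValueError("metrics PCA needs at least 3 samples")
    x = frame.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns drop below
        col_mean = np.nanmean(x, axis=0)
    nan_mask = ~np.isfinite(x)
    if nan_mask.any():
        x = np.where(nan_mask, np.broadcast_to(col_mean, x.shape), x)
    sd = np.std(x, axis=0, ddof=0)
    keep = sd > 0
    dropped = [c for c, k in zip(frame.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance metrics: {dropped}", stacklevel=2)
    if keep.sum() < 2:
        raise ValueError("need >= 2 metrics with nonzero variance")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    n_components = min(len(frame) - 1, int(keep.sum()))
    scores, loadings, var_frac = _svd_pca(z, n_components)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_frac,
        dropped_variables=dropped,
        sample_ids=list(frame.index),
        variable_names=[c for c, k in zip(frame.columns, keep) if k],
    )


def genotype_pca(
    cohort: CohortGenotypes,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
    n_sites: int = 250_000,
    n_components: int = 10,
) -> PCAResult:
    """Standard GWAS-style PCA of common-SNP genotypes.

    Sites are restricted to SNPs with MAF >= *maf_min* and missingness <=
    *max_missing*, thinned uniformly along the genome to at most *n_sites*.
    Genotypes are mean-imputed at missing entries and given EIGENSTRAT
    scaling: centred by 2p and divided by sqrt(2p(1-p)) per site.
    """
    g = cohort.genotype.astype(float)
    g[g == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN site rows
        p_hat = np.nanmean(g, axis=1) / 2.0
    miss = np.mean(~np.isfinite(g), axis=1)
    is_snp = np.asarray([s.variant_class == "SNP" for s in cohort.sites], dtype=bool)
    maf = np.minimum(p_hat, 1 - p_hat)
    ok = is_snp & np.isfinite(p_hat) & (maf >= maf_min) & (miss <= max_missing) & (maf > 0)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("no sites pass the genotype-PCA site filters")
    if idx.size > n_sites:  # uniform genomic thinning stands in for LD pruning
        idx = idx[np.linspace(0, idx.size - 1, n_sites).round().astype(int)]
    sub = g[idx]
    p = p_hat[idx][:, None]
    x = (sub - 2 * p) / np.sqrt(2 * p * (1 - p))
    x[~np.isfinite(sub)] = 0.0  # mean imputation after centring
    x = x.T  # samples x sites
    x -= x.mean(axis=0)
    k = min(max(n_components, 5), cohort.n_samples - 1, idx.size)
    scores, loadings, var_frac = _svd_pca(x, k)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_frac,
        dropped_variables=[],
        sample_ids=list(cohort.samples),
        variable_names=[f"{cohort.sites[i].chrom}:{cohort.sites[i].pos}" for i in idx],
    )


@dataclass
class SeparationAssessment:
    """2-means split of the first two PCs with a silhouette separation score."""

    score: float
    cluster_labels: np.ndarray
    agreement_with_batch: float  # nan when no batch labels supplied


def separation_score(
    scores: np.ndarray, batch: Sequence[str] | None = None, random_state: int = 0
) -> SeparationAssessment:
    """Quantify two-group separation in a 2-D PCA score plot.

    Runs 2-means (10 restarts, fixed seed) and reports the mean silhouette of
    the split; with batch labels given, also the best label-permutation
    agreement (>= 0.5 by construction).  All-identical points leave the score
    unset with a warning.
    """
    pts = np.asarray(scores, dtype=float)[:, :2]
    if len(pts) < 4:
        raise ValueError("separation score needs >= 4 samples")
    if np.allclose(pts, pts[0]):
        warnings.warn("all points identical; silhouette undefined", stacklevel=2)
        return SeparationAssessment(float("nan"), np.zeros(len(pts), dtype=int), float("nan"))
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
    labels = km.fit_predict(pts)
    if len(np.unique(labels)) < 2:
        warnings.warn("degenerate 2-means split; silhouette undefined", stacklevel=2)
        return SeparationAssessment(float("nan"), labels, float("nan"))
    score = float(silhouette_score(pts, labels))
    agreement = float("nan")
    if batch is not None:
        batch = np.asarray(batch)
        uniq = np.unique(batch)
        if len(uniq) != 2:
            raise ValueError(f"expected 2 batch labels, got {list(uniq)}")
        b = (batch == uniq[1]).astype(int)
        match = float(np.mean(labels == b))
        agreement = max(match, 1.0 - match)
    return SeparationAssessment(score, labels, agreement)
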