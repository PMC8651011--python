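"""Normalization and diversity statistics for ASV count tables.

Alpha diversity (richness, Shannon entropy in nats, Pielou evenness) is
computed on rarefied counts; beta diversity is Bray-Curtis dissimilarity
on the CSS+log2 normalized table (raw relative abundances available via
a flag), embedded by classical principal-coordinates analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import CountMatrix, ValidationError

logger = logging.getLogger("micronet")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def rarefy(counts: CountMatrix, depth: int | None = None, seed: int = 0) -> CountMatrix:
    """Subsample each sample to ``depth`` reads without replacement.

    A single seeded multivariate-hypergeometric draw per sample; the
    default depth is the smallest library size, matching rarefaction to
    the smallest library.
    """
    sums = counts.sample_sums()
    if depth is None:
        depth = int(sums.min())
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    if (sums < depth).any():
        bad = [s for s, t in zip(counts.sample_ids, sums) if t < depth]
        raise ValidationError(f"depth {depth} exceeds library size of samples: {bad}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts.counts)
    for j in range(counts.n_samples):
        col = counts.counts[:, j]
        if sums[j] == depth:
            out[:, j] = col  # exhaustive subsample
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountMatrix(list(counts.taxon_ids), list(counts.sample_ids), out)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def alpha_diversity(counts: CountMatrix) -> pd.DataFrame:
    """Per-sample richness S, Shannon H (nats) and Pielou J = H/ln S.

    J is reported missing (NaN) when S <= 1, where ln S vanishes.
    Callers are expected to pass rarefied counts; this is not enforced.
    """
    counts.validate_sample_sums()
    c = counts.counts.astype(float)
    totals = c.sum(axis=0)
    p = c / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    H = -plogp.sum(axis=0)
    S = (c > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        J = np.where(S >= 2, H / np.log(np.maximum(S, 2)), np.nan)
    return pd.DataFrame(
        {"richness": S.astype(int), "shannon": H, "pielou": J}, index=counts.sample_ids
    )


# ---------------------------------------------------------------------------
# CSS normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizedMatrix:
    """CSS + log2 normalized abundances (taxa x samples)."""

    values: np.ndarray
    scaling_factors: np.ndarray
    css_quantile: float
    css_scale: float
    taxon_ids: list[str]
    sample_ids: list[str]


def css_normalize(
    counts: CountMatrix, quantile: float = 0.5, scale: float = 1000.0
) -> NormalizedMatrix:
    """Cumulative-sum-scaling normalization followed by log2.

    For sample j, the scaling factor s_j is the sum of counts up to the
    per-sample ``quantile`` of its nonzero counts; normalized values are
    log2(1 + c_ij * scale / s_j). This removes library-size bias driven
    by a few dominant taxa, unlike total-sum scaling.
    """
    if not 0 < quantile < 1:
        raise ValidationError("quantile must be in (0,1)")
    if scale <= 0:
        raise ValidationError("scale must be positive")
    c = counts.counts
    s = np.empty(counts.n_samples)
    for j in range(counts.n_samples):
        col = c[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValidationError(f"sample {counts.sample_ids[j]} has no nonzero counts")
        q = np.quantile(nz, quantile)
        s[j] = col[col <= q].sum()
        if s[j] == 0:
            raise ValidationError(
                f"sample {counts.sample_ids[j]} has zero cumulative sum at quantile {quantile}"
            )
    values = np.log2(1.0 + c * scale / s)
    return NormalizedMatrix(
        values=values,
        scaling_factors=s,
        css_quantile=quantile,
        css_scale=scale,
        taxon_ids=list(counts.taxon_ids),
        sample_ids=list(counts.sample_ids),
    )


# ---------------------------------------------------------------------------
# Bray-Curtis distance
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric distances over samples with zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValidationError("distance matrix diagonal must be zero")

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.d[np.ix_(idx, idx)])


def bray_curtis(values: np.ndarray, sample_ids: list[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows (samples x taxa).

    d(x,y) = sum|x-y| / sum(x+y), in [0,1]; a pair of all-zero samples
    gets distance 0 (logged), making d a total function.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative values")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(values.shape[0])]
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(values, metric="braycurtis"))
    if np.isnan(d).any():
        logger.warning("all-zero sample pair(s) in Bray-Curtis; distance set to 0")
        d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(sample_ids), d)


# ---------------------------------------------------------------------------
# Principal coordinates analysis (classical scaling)
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    variance_explained: np.ndarray  # per retained axis, over positive eigenvalues


def pcoa(dist: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by
    the square roots of the positive eigenvalues. Negative eigenvalues
    (Bray-Curtis is a semimetric) are reported but excluded from both
    the coordinates and the variance-explained denominator.
    """
    n = len(dist.sample_ids)
    if not 1 <= k < n:
        raise ValidationError(f"k must be in [1, {n - 1}]")
    D2 = dist.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    n_pos = int((eigvals > tol).sum())
    if k > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues; truncating", k, n_pos)
        k = max(n_pos, 0)
    pos = eigvals[:n_pos]
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k]) if k else np.zeros((n, 0))
    var_exp = (eigvals[:k] / pos.sum()) if n_pos else np.zeros(0)
    return OrdinationResult(coordinates=coords, eigenvalues=eigvals, variance_explained=var_exp)
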