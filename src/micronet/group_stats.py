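"""Hypothesis tests for diversity and community comparisons.

Rank tests and ANOVA delegate to scipy; PERMANOVA and ANOSIM are
implemented here because the pipeline requires seeded, bit-reproducible
label permutations and the (b+1)/(m+1) permutation p-value estimator.
A LEfSe-style biomarker stage combines a per-taxon Kruskal-Wallis
screen with a bootstrapped linear-discriminant effect size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community_metrics import DistanceMatrix, NormalizedMatrix
from .core_io import ValidationError, stable_seed

logger = logging.getLogger("micronet")


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    n_per_group: list[int]
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "statistic": None if np.isnan(self.statistic) else float(self.statistic),
            "p_value": None if np.isnan(self.p_value) else float(self.p_value),
            "n_per_group": list(self.n_per_group),
            **{k: v for k, v in self.details.items()},
        }


@dataclass
class PermanovaResult:
    R2: float
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int
    n_per_group: list[int]
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "R2": float(self.R2),
            "pseudo_F": None if np.isinf(self.pseudo_F) else float(self.pseudo_F),
            "p_value": float(self.p_value),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_per_group": list(self.n_per_group),
            **self.details,
        }


@dataclass
class BiomarkerRecord:
    taxon: str
    enriched_class: str
    kw_p_value: float
    lda_score: float


# ---------------------------------------------------------------------------
# Rank and ANOVA tests (scipy-backed)
# ---------------------------------------------------------------------------

_EXACT_N = 12  # combined size up to which tie-free exact distributions are used


def wilcoxon_rank_sum(x, y, paired: bool = False) -> TestResult:
    """Two-sided Wilcoxon test: rank-sum (unpaired) or signed-rank (paired).

    Exact null distribution for small tie-free samples (combined n up to
    12), otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValidationError("paired test requires equal-length samples")
        if len(x) < 2:
            raise ValidationError("paired test requires n >= 2")
        d = x - y
        nz = d[d != 0]
        if nz.size == 0:
            return TestResult("signed_rank_W", 0.0, 1.0, [len(x), len(y)], {"paired": True})
        ties = len(np.unique(np.abs(nz))) < nz.size
        method = "exact" if (nz.size <= _EXACT_N and not ties) else "approx"
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", alternative="two-sided", method=method, correction=False
        )
        return TestResult(
            "signed_rank_W",
            float(res.statistic),
            float(min(res.pvalue, 1.0)),
            [len(x), len(y)],
            {"paired": True, "method": method},
        )
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs >= 2 observations")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        w = len(x) * (len(pooled) + 1) / 2.0  # expected rank sum of x
        return TestResult(
            "rank_sum_W", w, 1.0, [len(x), len(y)], {"paired": False, "method": "degenerate"}
        )
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= _EXACT_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank sum of x
    return TestResult(
        "rank_sum_W",
        w,
        float(min(res.pvalue, 1.0)),
        [len(x), len(y)],
        {"paired": False, "method": method},
    )


def oneway_anova(groups) -> TestResult:
    """Classical one-way fixed-effects ANOVA F-test."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    a = len(groups)
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = (a - 1, N - a)
    if ss_within == 0 and ss_between == 0:
        return TestResult("F", float("nan"), float("nan"), [len(g) for g in groups], {"df": df})
    if ss_within == 0:
        return TestResult("F", float("inf"), 0.0, [len(g) for g in groups], {"df": df})
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = float(stats.f.sf(f, *df))
    return TestResult("F", float(f), p, [len(g) for g in groups], {"df": df})


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return TestResult("H", 0.0, 1.0, [len(g) for g in groups], {"df": len(groups) - 1})
    h, p = stats.kruskal(*groups)
    return TestResult("H", float(h), float(p), [len(g) for g in groups], {"df": len(groups) - 1})


def bh_adjust(pvals) -> list[float]:
    """Benjamini-Hochberg adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return []
    return list(multipletests(pvals, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# Distance-based permutation tests
# ---------------------------------------------------------------------------


def _group_indicators(labels) -> tuple[list, np.ndarray]:
    labels = np.asarray(labels)
    names = sorted(set(labels.tolist()))
    z = np.stack([labels == g for g in names])
    return names, z


def _validate_groups(dist: DistanceMatrix, labels, min_size: int = 2):
    labels = np.asarray(labels)
    if len(labels) != len(dist.sample_ids):
        raise ValidationError("labels length must match distance matrix")
    names, z = _group_indicators(labels)
    if len(names) < 2:
        raise ValidationError("need >= 2 groups")
    sizes = z.sum(axis=1)
    if (sizes < min_size).any():
        bad = [n for n, s in zip(names, sizes) if s < min_size]
        raise ValidationError(f"groups with < {min_size} samples: {bad}")
    return names, z.astype(float), sizes


def _permanova_F_R2(D2: np.ndarray, Z: np.ndarray, sizes: np.ndarray):
    """Pseudo-F and R2 for a stack of group-indicator matrices.

    Z has shape (n_groups, n_perms, N); returns arrays of length n_perms.
    """
    N = D2.shape[0]
    a = Z.shape[0]
    ss_total = D2[np.triu_indices(N, k=1)].sum() / N
    ss_within = np.zeros(Z.shape[1])
    for g in range(a):
        zg = Z[g]
        ss_within += np.einsum("pi,ij,pj->p", zg, D2, zg) / (2.0 * sizes[g])
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / (a - 1)) / (ss_within / (N - a))
        F = np.where(ss_within == 0, np.inf, F)
    R2 = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    return F, R2


def permanova(
    dist: DistanceMatrix, labels, n_permutations: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Partitions the sum of squared distances between and within groups;
    the p-value counts seeded label permutations with pseudo-F at least
    the observed one, using the (b+1)/(m+1) estimator so p is never 0.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    names, z, sizes = _validate_groups(dist, labels)
    D2 = dist.d**2
    N = D2.shape[0]
    F_obs, R2_obs = _permanova_F_R2(D2, z[:, None, :], sizes)
    F_obs, R2_obs = float(F_obs[0]), float(R2_obs[0])
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(N) for _ in range(n_permutations)])
    Zp = np.stack([z[g][perms] for g in range(len(names))])
    F_perm, _ = _permanova_F_R2(D2, Zp, sizes)
    exceed = int(np.sum(F_perm >= F_obs - 1e-12))
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(
        R2=R2_obs,
        pseudo_F=F_obs,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        n_per_group=[int(s) for s in sizes],
        details={"groups": names},
    )


def pairwise_permanova(
    dist: DistanceMatrix, labels, n_permutations: int = 999, seed: int = 0
) -> list[PermanovaResult]:
    """Two-group PERMANOVA for every unordered group pair, BH-adjusted."""
    labels = np.asarray(labels)
    names = sorted(set(labels.tolist()))
    results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ga, gb = names[i], names[j]
            keep = np.isin(labels, [ga, gb])
            ids = [s for s, k in zip(dist.sample_ids, keep) if k]
            res = permanova(
                dist.subset(ids),
                labels[keep],
                n_permutations,
                stable_seed(seed, ga, gb),
            )
            res.details["pair"] = (ga, gb)
            results.append(res)
    adjusted = bh_adjust([r.p_value for r in results])
    for r, adj in zip(results, adjusted):
        r.details["p_adjusted"] = float(adj)
    return results


def anosim(dist: DistanceMatrix, labels, n_permutations: int = 999, seed: int = 0) -> TestResult:
    """ANOSIM: rank-based between- vs within-group distance comparison.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = N(N-1)/2 pairwise distances ranked jointly (average ties);
    one-sided permutation p-value as in PERMANOVA. R is emitted together
    with its square, since report conventions differ.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    names, z, sizes = _validate_groups(dist, labels)
    N = len(dist.sample_ids)
    iu = np.triu_indices(N, k=1)
    ranks_cond = stats.rankdata(dist.d[iu])
    R = np.zeros((N, N))
    R[iu] = ranks_cond
    R += R.T
    M = N * (N - 1) / 2.0
    total = ranks_cond.sum()
    n_within = sum(s * (s - 1) / 2.0 for s in sizes)
    n_between = M - n_within
    if n_between == 0:
        raise ValidationError("no between-group pairs")

    def r_stat(Z: np.ndarray) -> np.ndarray:
        s_within = np.zeros(Z.shape[1])
        for g in range(Z.shape[0]):
            zg = Z[g]
            s_within += np.einsum("pi,ij,pj->p", zg, R, zg) / 2.0
        rw = s_within / n_within
        rb = (total - s_within) / n_between
        return (rb - rw) / (M / 2.0)

    r_obs = float(r_stat(z[:, None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(N) for _ in range(n_permutations)])
    Zp = np.stack([z[g][perms] for g in range(len(names))])
    r_perm = r_stat(Zp)
    p = (1.0 + int(np.sum(r_perm >= r_obs - 1e-12))) / (1.0 + n_permutations)
    return TestResult(
        "ANOSIM_R",
        r_obs,
        p,
        [int(s) for s in sizes],
        {
            "R_squared": r_obs**2,
            "n_permutations": n_permutations,
            "seed": seed,
            "groups": names,
        },
    )


# ---------------------------------------------------------------------------
# LEfSe-style biomarker discovery
# ---------------------------------------------------------------------------

_LEFSE_BOOTSTRAPS = 30
_LEFSE_SCALE = 1.0e6  # abundances rescaled per sample to one million units


def _lda_axis(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Unit-norm pooled-covariance discriminant direction, class vs rest."""
    a, b = X[mask], X[~mask]
    S = np.cov(a, rowvar=False) * (len(a) - 1) + np.cov(b, rowvar=False) * (len(b) - 1)
    S = np.atleast_2d(S) / max(len(a) + len(b) - 2, 1)
    reg = 1e-3 * np.trace(S) / S.shape[0] + 1e-12
    w = np.linalg.solve(S + reg * np.eye(S.shape[0]), a.mean(axis=0) - b.mean(axis=0))
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lefse_markers(
    norm: NormalizedMatrix,
    labels,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    seed: int = 0,
) -> list[BiomarkerRecord]:
    """Class biomarkers: Kruskal-Wallis screen + LDA effect size.

    Taxa passing the per-taxon Kruskal-Wallis test at ``alpha`` are
    scored on abundances rescaled per sample to 1e6 units: over seeded
    bootstrap resamples, a one-vs-rest discriminant axis is fit and the
    taxon's contribution to the class-mean separation along it is
    averaged with its raw mean difference; the score is log10 of that
    effect (floored at one unit). Records with score > ``lda_threshold``
    are returned, labeled with the class of highest mean abundance.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValidationError("need >= 2 classes")
    if len(labels) != len(norm.sample_ids):
        raise ValidationError("labels length must match samples")
    values = np.asarray(norm.values, dtype=float)
    if alpha <= 0:
        return []
    # Kruskal-Wallis screen per taxon
    survivors = []
    for t in range(values.shape[0]):
        groups = [values[t, labels == c] for c in classes]
        res = kruskal_wallis(groups)
        if res.p_value < alpha:
            survivors.append((t, res.p_value))
    if not survivors:
        return []
    # rescale each sample to 1e6 total units for the effect-size scale
    colsum = values.sum(axis=0)
    colsum[colsum == 0] = 1.0
    X6 = (values / colsum * _LEFSE_SCALE).T  # samples x taxa
    idx = [t for t, _ in survivors]
    Xs = X6[:, idx]
    rng = np.random.default_rng(seed)
    n = Xs.shape[0]
    effects = np.zeros((len(classes), len(idx)))
    n_boot = np.zeros(len(classes))
    for _ in range(_LEFSE_BOOTSTRAPS):
        boot = rng.integers(0, n, size=n)
        yb = labels[boot]
        Xb = Xs[boot]
        for ci, c in enumerate(classes):
            mask = yb == c
            if mask.sum() < 2 or (~mask).sum() < 2:
                continue
            w = _lda_axis(Xb, mask)
            delta = Xb[mask].mean(axis=0) - Xb[~mask].mean(axis=0)
            effects[ci] += (np.abs(w * delta) + np.abs(delta)) / 2.0
            n_boot[ci] += 1
    with np.errstate(invalid="ignore"):
        effects = effects / np.where(n_boot[:, None] > 0, n_boot[:, None], 1.0)
    records = []
    for k, (t, kw_p) in enumerate(survivors):
        effect = float(effects[:, k].max())
        score = float(np.log10(max(effect, 1.0)))
        if score > lda_threshold:
            means = [X6[labels == c, idx[k]].mean() for c in classes]
            enriched = classes[int(np.argmax(means))]
            records.append(BiomarkerRecord(norm.taxon_ids[t], enriched, float(kw_p), score))
    return records
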