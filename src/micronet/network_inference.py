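"""Signed sparse association-network inference for ASV count tables.

Counts are mapped to unconstrained space with the centered log-ratio
(CLR) transform, then a conditional-independence graph is estimated by
neighborhood selection: each taxon's CLR abundance is lasso-regressed on
all others, and an edge is a nonzero regression coefficient (combined
across the two regression directions by an "or"/"and" rule). The lasso
penalty is chosen by StARS stability selection: the graph is re-fit on
many random subsamples along a penalty path and the least-penalized
graph whose edge-selection instability stays below a threshold is kept.
Edge signs come from the regression coefficients, so a positive edge is
a positive partial (not marginal) association between two taxa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.linear_model import lasso_path

from .core_io import CountMatrix, ValidationError, stable_seed

logger = logging.getLogger("micronet")


@dataclass
class InferenceConfig:
    """Tuning parameters of the CLR + lasso + StARS procedure."""

    pseudocount: float = 1.0
    lambda_path_length: int = 30
    lambda_min_ratio: float = 0.01
    n_subsamples: int = 20
    stars_beta: float = 0.05
    edge_rule: str = "or"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValidationError("lambda_min_ratio must be in (0,1)")
        if self.n_subsamples < 2:
            raise ValidationError("n_subsamples must be >= 2")
        if not 0 < self.stars_beta < 0.5:
            raise ValidationError("stars_beta must be in (0, 0.5)")
        if self.edge_rule not in ("or", "and"):
            raise ValidationError("edge_rule must be 'or' or 'and'")
        if self.lambda_path_length < 2:
            raise ValidationError("lambda_path_length must be >= 2")


def subsample_size(n: int) -> int:
    """StARS subsample size: floor(10*sqrt(n)) for large n, else 80% of n.

    The 10*sqrt(n) rule only makes sense once it is well below n
    (n > 144); below that the standard fallback of floor(0.8*n) keeps
    genuine subsampling variation, without which instability is
    underestimated and the penalty grossly under-selected.
    """
    b = int(np.floor(10 * np.sqrt(n))) if n > 144 else int(np.floor(0.8 * n))
    return min(b, n - 1)


@dataclass
class AssociationNetwork:
    """Undirected signed graph over taxa inferred from one sample group."""

    nodes: list[str]
    edges: dict  # (a, b) with a < b -> (sign, weight)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValidationError("duplicate node identifiers")
        clean = {}
        for pair, (sign, weight) in self.edges.items():
            a, b = pair
            if a == b:
                raise ValidationError(f"self-loop on {a}")
            if a not in node_set or b not in node_set:
                raise ValidationError(f"edge endpoint not in node set: {pair}")
            if sign not in (1, -1):
                raise ValidationError(f"edge sign must be +1/-1, got {sign}")
            key = (a, b) if a < b else (b, a)
            if key in clean:
                raise ValidationError(f"duplicate edge {key}")
            clean[key] = (int(sign), float(weight))
        self.edges = clean

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return set(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), (sign, weight) in self.edges.items():
            g.add_edge(a, b, sign=sign, weight=weight)
        return g

    def without_node(self, node: str) -> "AssociationNetwork":
        nodes = [n for n in self.nodes if n != node]
        edges = {k: v for k, v in self.edges.items() if node not in k}
        return AssociationNetwork(nodes, edges, dict(self.provenance))


# ---------------------------------------------------------------------------
# CLR transform
# ---------------------------------------------------------------------------


def clr_transform(counts: CountMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform; returns samples x taxa, rows sum to 0."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    x = np.log(counts.counts.T.astype(float) + pseudocount)
    return x - x.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Neighborhood selection (Meinshausen-Buhlmann lasso regressions)
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; constant columns are zeroed and flagged."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 1e-12
    if not ok.all():
        logger.info("excluding %d constant column(s) from regressions", int((~ok).sum()))
    xs = np.where(ok, (x - mu) / np.where(ok, sd, 1.0), 0.0)
    return xs, ok


def lambda_max(clr: np.ndarray) -> float:
    """Smallest penalty at which every neighborhood is empty.

    With standardized columns, the lasso solution for every response is
    identically zero once the penalty reaches the largest absolute
    marginal covariance max_{i!=j} |x_i . x_j| / n.
    """
    xs, _ = _standardize(np.asarray(clr, dtype=float))
    n = xs.shape[0]
    c = np.abs(xs.T @ xs) / n
    np.fill_diagonal(c, 0.0)
    return float(c.max())


def _neighborhood_path(xs: np.ndarray, ok: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Directed coefficients B[l, i, j]: predictor i in regression of j at lambdas[l]."""
    n, p = xs.shape
    L = len(lambdas)
    B = np.zeros((L, p, p))
    others = np.arange(p)
    for j in range(p):
        if not ok[j]:
            continue
        mask = others != j
        preds = others[mask & ok]
        if preds.size == 0:
            continue
        with warnings.catch_warnings():
            # near-dense fits at the smallest penalties may stop at the
            # iteration cap; the residual duality gap is far below the
            # coefficient scale that decides edge membership
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(xs[:, preds], xs[:, j], alphas=lambdas, max_iter=2000)
        # lasso_path returns coefficients ordered by decreasing alpha
        order = np.argsort(-lambdas)
        inv = np.empty_like(order)
        inv[order] = np.arange(L)
        B[:, preds, j] = coefs.T[inv]
    return B


def _combine(nonzero: np.ndarray, edge_rule: str) -> np.ndarray:
    swap = np.swapaxes(nonzero, -1, -2)
    return (nonzero | swap) if edge_rule == "or" else (nonzero & swap)


def neighborhood_select(
    clr: np.ndarray, lam: float, edge_rule: str = "or"
) -> tuple[np.ndarray, np.ndarray]:
    """Single-penalty neighborhood selection.

    Returns (adjacency, B): symmetric boolean adjacency after combining
    the two regression directions by ``edge_rule``, and the directed
    coefficient matrix B[i, j] (predictor i in the regression of j).
    """
    clr = np.asarray(clr, dtype=float)
    n, p = clr.shape
    if n < 4:
        raise ValidationError("neighborhood selection requires >= 4 samples")
    if p < 3:
        raise ValidationError("neighborhood selection requires >= 3 taxa")
    if lam <= 0:
        raise ValidationError("lambda must be positive")
    xs, ok = _standardize(clr)
    B = _neighborhood_path(xs, ok, np.array([lam]))[0]
    adj = _combine(B != 0, edge_rule)
    np.fill_diagonal(adj, False)
    return adj, B


@dataclass
class StarsResult:
    lambda_selected: float
    lambdas: np.ndarray
    instability: np.ndarray
    sup_instability: np.ndarray
    edge_frequency: np.ndarray  # p x p selection frequency at the selected lambda
    subsample_size: int


def lambda_path(clr: np.ndarray, config: InferenceConfig) -> np.ndarray:
    lmax = lambda_max(clr)
    if lmax <= 0:
        raise ValidationError("degenerate data: all marginal covariances zero")
    return np.geomspace(lmax, lmax * config.lambda_min_ratio, config.lambda_path_length)


def stars_select(
    clr: np.ndarray, config: InferenceConfig, sample_ids=None
) -> StarsResult:
    """StARS penalty selection over seeded without-replacement subsamples.

    Instability at each penalty is the mean over node pairs of
    2*theta*(1-theta), theta being the across-subsample selection
    frequency of the pair; the running supremum from the dense end is
    compared with ``stars_beta`` and the smallest penalty still under
    the threshold is selected. Subsample draws are derived from the seed
    and the *sorted* sample identifiers, so sample order is irrelevant.
    """
    clr = np.asarray(clr, dtype=float)
    n, p = clr.shape
    b = subsample_size(n)
    if b < 4:
        raise ValidationError(f"subsample size {b} too small (need >= 4 samples)")
    lambdas = lambda_path(clr, config)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    sorted_order = np.argsort(np.asarray(sample_ids, dtype=str))
    rng = np.random.default_rng(stable_seed(config.seed, tuple(sorted(map(str, sample_ids)))))
    L = len(lambdas)
    freq = np.zeros((L, p, p))
    for _ in range(config.n_subsamples):
        pick = rng.choice(n, size=b, replace=False)
        rows = sorted_order[pick]
        xs, ok = _standardize(clr[rows])
        B = _neighborhood_path(xs, ok, lambdas)
        freq += _combine(B != 0, config.edge_rule)
    theta = freq / config.n_subsamples
    pair_inst = 2 * theta * (1 - theta)
    iu = np.triu_indices(p, k=1)
    instability = pair_inst[:, iu[0], iu[1]].mean(axis=1)
    sup = np.maximum.accumulate(instability)
    admissible = np.nonzero(sup <= config.stars_beta)[0]
    sel = int(admissible[-1]) if admissible.size else 0
    return StarsResult(
        lambda_selected=float(lambdas[sel]),
        lambdas=lambdas,
        instability=instability,
        sup_instability=sup,
        edge_frequency=theta[sel],
        subsample_size=b,
    )


# ---------------------------------------------------------------------------
# Full inference
# ---------------------------------------------------------------------------


def infer_network(
    counts: CountMatrix, config: InferenceConfig | None = None, group: str | None = None
) -> AssociationNetwork:
    """Infer the signed association network of one sample group.

    Absent taxa are dropped; the StARS-selected penalty is re-applied to
    the full data to produce the final edge set. Each edge's sign is the
    sign of the directional coefficient of larger magnitude (ties go to
    the direction predicting the later taxon from the earlier one) and
    its weight is the mean of the two directional coefficients. Taxa
    left without neighbors stay in the network as degree-0 nodes.
    """
    if config is None:
        config = InferenceConfig()
    cm = counts.drop_absent_taxa()
    # canonical sample order: makes the result bit-identical under any
    # permutation of the input columns
    cm = cm.select_samples(sorted(cm.sample_ids))
    if cm.n_taxa < 3:
        raise ValidationError(f"need >= 3 present taxa, got {cm.n_taxa}")
    if cm.n_samples < 4:
        raise ValidationError(f"need >= 4 samples, got {cm.n_samples}")
    clr = clr_transform(cm, config.pseudocount)
    stars = stars_select(clr, config, sample_ids=cm.sample_ids)
    adj, B = neighborhood_select(clr, stars.lambda_selected, config.edge_rule)
    edges = {}
    taxa = cm.taxon_ids
    for i, j in zip(*np.nonzero(np.triu(adj, k=1))):
        c_ij, c_ji = B[i, j], B[j, i]  # i predicting j, j predicting i
        chosen = c_ij if abs(c_ij) >= abs(c_ji) else c_ji
        sign = 1 if chosen > 0 else -1
        weight = (c_ij + c_ji) / 2.0
        edges[(taxa[i], taxa[j]) if taxa[i] < taxa[j] else (taxa[j], taxa[i])] = (sign, weight)
    provenance = {
        "group": group,
        "config": {
            "pseudocount": config.pseudocount,
            "lambda_path_length": config.lambda_path_length,
            "lambda_min_ratio": config.lambda_min_ratio,
            "n_subsamples": config.n_subsamples,
            "stars_beta": config.stars_beta,
            "edge_rule": config.edge_rule,
            "seed": config.seed,
        },
        "lambda_selected": stars.lambda_selected,
        "subsample_size": stars.subsample_size,
        "n_samples": cm.n_samples,
    }
    return AssociationNetwork(nodes=list(taxa), edges=edges, provenance=provenance)
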