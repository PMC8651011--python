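"""Synthetic ASV count tables with known association structure.

The generative model is logistic-normal multinomial: per sample a
latent Gaussian abundance vector is drawn from a known sparse
precision-matrix graph, pushed through a softmax to a composition, and
observed as a multinomial read-count draw at a realistic sequencing
depth. The nonzero off-diagonal pattern of the precision matrix is the
ground-truth association graph that the inference stage targets.

Treatment effects are planted on the latent means: per-taxon fold
changes, random silencing of a fraction of taxa (richness suppression)
and knockout of the highest-betweenness hub taxa of the true graph.
Silenced taxa get exactly zero probability mass, so richness effects
are exact. A study generator assembles paired T0/T1 samples per subject
across the five treatment arms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core_io import ARMS, CountMatrix, SampleMetadata, ValidationError, stable_seed

TOPOLOGIES = ("band", "cluster", "scale_free", "star")

#: Precision-matrix off-diagonal magnitudes: detectable partial
#: correlations at the study's sample sizes without being trivial.
EDGE_MAGNITUDE = (0.2, 0.5)
_DIAG_MARGIN = 0.10  # Gershgorin margin ensuring positive definiteness

#: Default library-size range: typical per-sample 16S read depths.
DEFAULT_DEPTH_RANGE = (10_000, 100_000)


@dataclass
class GroundTruthNetwork:
    """Planted conditional-dependence graph with its precision matrix."""

    n_taxa: int
    topology: str
    edges: set  # unordered index pairs (i, j), i < j
    precision_matrix: np.ndarray
    seed: int
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.taxon_ids:
            width = len(str(self.n_taxa - 1))
            self.taxon_ids = [f"ASV{i:0{width}d}" for i in range(self.n_taxa)]
        eigmin = float(np.linalg.eigvalsh(self.precision_matrix).min())
        if eigmin <= 0:
            raise ValidationError(f"precision matrix not positive definite (min eig {eigmin})")
        nz = {
            (i, j)
            for i, j in zip(*np.nonzero(np.triu(self.precision_matrix, k=1)))
        }
        if nz != {(min(i, j), max(i, j)) for i, j in self.edges}:
            raise ValidationError("precision-matrix pattern does not match edge set")

    def covariance(self) -> np.ndarray:
        """Latent covariance, rescaled to unit variances (correlation form)."""
        sigma = np.linalg.inv(self.precision_matrix)
        d = 1.0 / np.sqrt(np.diag(sigma))
        return sigma * np.outer(d, d)

    def base_log_mean(self) -> np.ndarray:
        """Heterogeneous baseline log-abundances, fixed by the truth seed."""
        rng = np.random.default_rng(stable_seed(self.seed, "base_mean"))
        return rng.normal(0.0, 1.0, self.n_taxa)

    def edge_taxon_pairs(self) -> set:
        return {
            tuple(sorted((self.taxon_ids[i], self.taxon_ids[j]))) for i, j in self.edges
        }

    def hub_taxa(self, k: int) -> list[str]:
        """The k highest-betweenness taxa of the true graph (ties by id)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_taxa))
        g.add_edges_from(self.edges)
        btw = nx.betweenness_centrality(g, normalized=False)
        deg = dict(g.degree())
        order = sorted(range(self.n_taxa), key=lambda i: (-btw[i], -deg[i], self.taxon_ids[i]))
        return [self.taxon_ids[i] for i in order[:k]]


@dataclass
class EffectSpec:
    """Planted treatment effect applied to T1 samples of one arm."""

    richness_drop: float = 0.0
    fold_changes: dict = field(default_factory=dict)  # taxon id -> multiplicative shift
    hub_knockout: int = 0
    depth_range: tuple = DEFAULT_DEPTH_RANGE
    silenced_taxa: list | None = None  # explicit override of the random drop

    def __post_init__(self) -> None:
        if not 0 <= self.richness_drop < 1:
            raise ValidationError("richness_drop must be in [0,1)")
        if self.hub_knockout < 0:
            raise ValidationError("hub_knockout must be >= 0")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValidationError("depth_range must satisfy 1 <= min <= max")


@dataclass
class SyntheticStudy:
    counts: CountMatrix
    meta: SampleMetadata
    truth: dict  # arm -> GroundTruthNetwork
    effects: dict  # arm -> EffectSpec

    def __post_init__(self) -> None:
        df = self.meta.table
        per_subject = df.groupby("subject_id")["timepoint"].agg(list)
        for subject, tps in per_subject.items():
            if sorted(tps) != ["T0", "T1"]:
                raise ValidationError(
                    f"subject {subject} must have exactly one T0 and one T1 sample"
                )


# ---------------------------------------------------------------------------
# Graph topologies and precision matrices
# ---------------------------------------------------------------------------


def _topology_edges(n_taxa: int, topology: str, edge_density, seed: int, bandwidth=None) -> set:
    rng = np.random.default_rng(stable_seed(seed, "topology", topology))
    max_edges = n_taxa * (n_taxa - 1) // 2
    if topology == "star":
        return {(0, j) for j in range(1, n_taxa)}
    if topology == "band":
        if bandwidth is None:
            target = edge_density * max_edges if edge_density else n_taxa - 1
            bandwidth = max(1, round(target / (n_taxa - 1)))
        if bandwidth >= n_taxa:
            raise ValidationError("bandwidth must be < n_taxa")
        return {
            (i, j)
            for i in range(n_taxa)
            for j in range(i + 1, min(i + bandwidth + 1, n_taxa))
        }
    if topology == "scale_free":
        m = 1
        if edge_density:
            m = max(1, round(edge_density * max_edges / n_taxa))
        if m >= n_taxa:
            raise ValidationError("density infeasible for scale_free topology")
        g = nx.barabasi_albert_graph(n_taxa, m, seed=int(rng.integers(2**31)))
        return {tuple(sorted(e)) for e in g.edges}
    if topology == "cluster":
        n_blocks = 3 if n_taxa >= 9 else 2
        blocks = np.array_split(rng.permutation(n_taxa), n_blocks)
        candidates = [
            (min(i, j), max(i, j))
            for block in blocks
            for ai, i in enumerate(block)
            for j in block[ai + 1 :]
        ]
        target = round(edge_density * max_edges) if edge_density else len(candidates) // 2
        if target > len(candidates):
            raise ValidationError(
                f"density infeasible for cluster topology ({target} > {len(candidates)})"
            )
        pick = rng.choice(len(candidates), size=target, replace=False)
        return {candidates[i] for i in pick}
    raise ValidationError(f"unknown topology {topology!r}; known: {TOPOLOGIES}")


def generate_true_network(
    n_taxa: int,
    topology: str,
    edge_density: float | None = None,
    seed: int = 0,
    bandwidth: int | None = None,
) -> GroundTruthNetwork:
    """Build a planted graph and a positive-definite precision matrix.

    Edge off-diagonals are drawn uniformly from +/-[0.2, 0.5]; the
    diagonal is set to the absolute row sum plus a margin (diagonal
    dominance), which guarantees positive definiteness by Gershgorin.
    """
    if n_taxa < 3:
        raise ValidationError("n_taxa must be >= 3")
    edges = _topology_edges(n_taxa, topology, edge_density, seed, bandwidth)
    rng = np.random.default_rng(stable_seed(seed, "precision"))
    omega = np.zeros((n_taxa, n_taxa))
    lo, hi = EDGE_MAGNITUDE
    for i, j in sorted(edges):
        mag = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        omega[i, j] = omega[j, i] = mag
    np.fill_diagonal(omega, np.abs(omega).sum(axis=1) + _DIAG_MARGIN)
    return GroundTruthNetwork(
        n_taxa=n_taxa, topology=topology, edges=set(edges), precision_matrix=omega, seed=seed
    )


# ---------------------------------------------------------------------------
# Count sampling
# ---------------------------------------------------------------------------


def _silenced_set(truth: GroundTruthNetwork, effect: EffectSpec | None, seed: int) -> set:
    if effect is None:
        return set()
    silenced = set(effect.silenced_taxa or [])
    unknown = silenced - set(truth.taxon_ids)
    if unknown:
        raise ValidationError(f"unknown silenced taxa: {sorted(unknown)}")
    if effect.silenced_taxa is None and effect.richness_drop > 0:
        k = int(round(effect.richness_drop * truth.n_taxa))
        rng = np.random.default_rng(stable_seed(seed, "silence"))
        silenced |= set(rng.choice(truth.taxon_ids, size=k, replace=False))
    if effect.hub_knockout:
        if effect.hub_knockout >= truth.n_taxa:
            raise ValidationError("hub_knockout must be < n_taxa")
        silenced |= set(truth.hub_taxa(effect.hub_knockout))
    return silenced


def sample_counts(
    truth: GroundTruthNetwork,
    n_samples: int,
    depth_range: tuple | None = None,
    effect: EffectSpec | None = None,
    seed: int = 0,
    sample_ids: list | None = None,
) -> CountMatrix:
    """Draw a logistic-normal multinomial count table from the truth.

    Latent vectors come from N(mu, Sigma) with Sigma the (unit-variance)
    inverse precision matrix; mu is the truth's baseline log-mean,
    shifted by log fold changes; silenced taxa get zero probability
    exactly. Library sizes are uniform over ``depth_range``.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if depth_range is None:
        depth_range = effect.depth_range if effect is not None else DEFAULT_DEPTH_RANGE
    lo, hi = int(depth_range[0]), int(depth_range[1])
    if lo < 1 or hi < lo:
        raise ValidationError("depth_range must satisfy 1 <= min <= max")
    p = truth.n_taxa
    mu = truth.base_log_mean().copy()
    silenced = _silenced_set(truth, effect, seed)
    if effect is not None:
        for taxon, fc in effect.fold_changes.items():
            if taxon not in truth.taxon_ids:
                raise ValidationError(f"fold-change taxon {taxon!r} not in truth")
            if fc <= 0:
                raise ValidationError("fold changes must be positive")
            mu[truth.taxon_ids.index(taxon)] += np.log(fc)
    keep = np.array([t not in silenced for t in truth.taxon_ids])
    rng = np.random.default_rng(stable_seed(seed, "counts"))
    chol = np.linalg.cholesky(truth.covariance())
    latent = mu + rng.standard_normal((n_samples, p)) @ chol.T
    z = np.where(keep, latent, -np.inf)
    z = z - z.max(axis=1, keepdims=True)
    comp = np.exp(z)
    comp /= comp.sum(axis=1, keepdims=True)
    depths = rng.integers(lo, hi + 1, size=n_samples)
    counts = np.stack([rng.multinomial(d, c) for d, c in zip(depths, comp)]).T
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    return CountMatrix(list(truth.taxon_ids), list(sample_ids), counts)


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

_ARM_FIELDS = {
    "water_vehicle": ("water", "vehicle", "none"),
    "water_oea": ("water", "OEA", "oral"),
    "alcohol_vehicle": ("alcohol", "vehicle", "none"),
    "alcohol_oral_oea": ("alcohol", "OEA", "oral"),
    "alcohol_ip_oea": ("alcohol", "OEA", "ip"),
}


def default_effects(truth: GroundTruthNetwork) -> dict:
    """The emulated study conditions, one EffectSpec per arm.

    Directions follow the study's findings: alcohol suppresses richness
    and shifts several taxa; oral OEA under alcohol shows the strongest
    richness loss; i.p. OEA reassembles the community by knocking out
    the highest-betweenness hubs rather than by richness loss.
    """
    ids = truth.taxon_ids
    up = {ids[i]: 4.0 for i in range(0, min(3, len(ids)))}
    down = {ids[i]: 0.25 for i in range(3, min(6, len(ids)))}
    return {
        "water_vehicle": EffectSpec(),
        "water_oea": EffectSpec(fold_changes={ids[0]: 2.0}),
        "alcohol_vehicle": EffectSpec(richness_drop=0.10, fold_changes={**up, **down}),
        "alcohol_oral_oea": EffectSpec(richness_drop=0.30, fold_changes=dict(up)),
        "alcohol_ip_oea": EffectSpec(richness_drop=0.05, hub_knockout=3),
    }


#: Per-arm subject counts of the emulated study design.
DEFAULT_ARM_SIZES = {
    "water_vehicle": 6,
    "water_oea": 11,
    "alcohol_vehicle": 8,
    "alcohol_oral_oea": 7,
    "alcohol_ip_oea": 7,
}


def generate_study(
    arm_sizes: dict | None = None,
    base_truth: GroundTruthNetwork | None = None,
    effects: dict | None = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Assemble a paired two-timepoint study across the five arms.

    Every subject contributes a baseline T0 sample (no effect) and a
    T1 sample carrying its arm's planted effect; all samples share the
    same base ground-truth graph.
    """
    if arm_sizes is None:
        arm_sizes = dict(DEFAULT_ARM_SIZES)
    if base_truth is None:
        base_truth = generate_true_network(60, "cluster", edge_density=0.05, seed=seed)
    unknown = set(arm_sizes) - set(ARMS)
    if unknown:
        raise ValidationError(f"unknown arm label(s): {sorted(unknown)}")
    if any(v < 3 for v in arm_sizes.values()):
        raise ValidationError("each arm needs >= 3 subjects")
    if effects is None:
        effects = default_effects(base_truth)
    tables = []
    sample_ids: list[str] = []
    records = []
    for arm in sorted(arm_sizes):
        n = arm_sizes[arm]
        liquid, pretreat, route = _ARM_FIELDS[arm]
        effect = effects.get(arm, EffectSpec())
        t0_ids = [f"{arm}.R{i}.T0" for i in range(n)]
        t1_ids = [f"{arm}.R{i}.T1" for i in range(n)]
        t0 = sample_counts(
            base_truth, n, effect.depth_range, None,
            seed=stable_seed(seed, arm, "T0"), sample_ids=t0_ids,
        )
        t1 = sample_counts(
            base_truth, n, effect.depth_range, effect,
            seed=stable_seed(seed, arm, "T1"), sample_ids=t1_ids,
        )
        tables.extend([t0.counts, t1.counts])
        sample_ids.extend(t0_ids + t1_ids)
        for i in range(n):
            records.append(
                {
                    "sample_id": t0_ids[i],
                    "subject_id": f"{arm}.R{i}",
                    "timepoint": "T0",
                    "liquid": liquid,
                    "pretreatment": pretreat,
                    "route": "none",
                }
            )
            records.append(
                {
                    "sample_id": t1_ids[i],
                    "subject_id": f"{arm}.R{i}",
                    "timepoint": "T1",
                    "liquid": liquid,
                    "pretreatment": pretreat,
                    "route": route,
                }
            )
    counts = CountMatrix(
        list(base_truth.taxon_ids), sample_ids, np.concatenate(tables, axis=1)
    )
    meta = SampleMetadata.from_records(records)
    truth = {arm: base_truth for arm in arm_sizes}
    return SyntheticStudy(counts=counts, meta=meta, truth=truth, effects=dict(effects))


def truth_report(study: SyntheticStudy) -> dict:
    """JSON-serializable ground-truth record (edges + effects per arm)."""
    out: dict = {"arms": {}}
    for arm, truth in study.truth.items():
        effect = study.effects.get(arm, EffectSpec())
        out["arms"][arm] = {
            "topology": truth.topology,
            "n_taxa": truth.n_taxa,
            "edges": sorted(list(pair) for pair in truth.edge_taxon_pairs()),
            "effect": {
                k: v
                for k, v in dataclasses.asdict(effect).items()
                if k != "silenced_taxa" or v
            },
        }
    return out
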