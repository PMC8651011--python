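"""Community-reassembly ("attack") simulation.

Starting from one group's count table and its inferred network, taxa
are removed one at a time — either in decreasing order of betweenness
centrality (targeted) or uniformly at random — and the network is
re-inferred from the reduced count data at every step. Each step's
degree distribution is compared with a reference distribution (e.g.
another arm's network) by total-variation distance; the match point is
the first step at which the distance falls below a tolerance. The
contrast between the targeted match point and the spread of random
replicates indicates whether two communities differ by the loss of a
few structurally central taxa rather than by random taxon loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix, SampleMetadata, ValidationError, select_arm, stable_seed
from .network_inference import AssociationNetwork, InferenceConfig, infer_network
from .network_metrics import DegreeDistribution, betweenness, degree_distribution

logger = logging.getLogger("micronet")


@dataclass
class AttackConfig:
    mode: str = "targeted"
    n_remove: int = 10
    n_replicates: int = 20
    recompute_betweenness: bool = False
    distance: str = "total_variation"
    epsilon: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("targeted", "random"):
            raise ValidationError("mode must be 'targeted' or 'random'")
        if self.n_remove < 1:
            raise ValidationError("n_remove must be >= 1")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.distance != "total_variation":
            raise ValidationError("only the total_variation distance is supported")
        if not 0 <= self.epsilon <= 1:
            raise ValidationError("epsilon must be in [0,1]")


@dataclass
class AttackStep:
    step: int
    removed_taxon: str | None
    network: AssociationNetwork
    degree_dist: DegreeDistribution
    distance: float | None  # to the reference distribution, if one was given


@dataclass
class AttackTrajectory:
    steps: list
    mode: str
    replicate: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.steps, self.steps[1:]):
            if cur.network.n_nodes != prev.network.n_nodes - 1:
                raise ValidationError("node count must decrease by exactly 1 per step")


def degree_dist_distance(a: DegreeDistribution, b: DegreeDistribution) -> float:
    """Total-variation distance between two degree histograms, in [0,1]."""
    degrees = set(a.frequencies) | set(b.frequencies)
    return 0.5 * sum(
        abs(a.frequencies.get(k, 0.0) - b.frequencies.get(k, 0.0)) / 100.0 for k in degrees
    )


def _betweenness_order(net: AssociationNetwork) -> list[str]:
    """Nodes by decreasing betweenness; ties by degree desc, then id asc."""
    btw = betweenness(net)
    deg = dict(net.to_networkx().degree())
    return sorted(net.nodes, key=lambda v: (-btw[v], -deg[v], v))


def _resolve_group(counts, meta, group) -> CountMatrix:
    if meta is not None and group is not None:
        return select_arm(counts, meta, group)
    return counts.drop_absent_taxa()


def _run_trajectory(
    cm: CountMatrix,
    net0: AssociationNetwork,
    order,
    inference: InferenceConfig,
    config: AttackConfig,
    reference: DegreeDistribution | None,
    mode: str,
    replicate: int | None = None,
) -> AttackTrajectory:
    def dist_to_ref(dd):
        return degree_dist_distance(dd, reference) if reference is not None else None

    dd0 = degree_distribution(net0)
    steps = [AttackStep(0, None, net0, dd0, dist_to_ref(dd0))]
    current = cm
    net = net0
    removal = list(order)
    for k in range(1, config.n_remove + 1):
        if config.recompute_betweenness and mode == "targeted":
            victim = _betweenness_order(net)[0]
        else:
            victim = removal[k - 1]
        keep = [t for t in current.taxon_ids if t != victim]
        current = current.select_taxa(keep)
        net = infer_network(current, inference)
        dd = degree_distribution(net)
        steps.append(AttackStep(k, victim, net, dd, dist_to_ref(dd)))
    return AttackTrajectory(
        steps=steps,
        mode=mode,
        replicate=replicate,
        provenance={"n_remove": config.n_remove, "epsilon": config.epsilon, "seed": config.seed},
    )


def targeted_attack(
    counts: CountMatrix,
    meta: SampleMetadata | None = None,
    group: str | None = None,
    inference: InferenceConfig | None = None,
    config: AttackConfig | None = None,
    reference: DegreeDistribution | None = None,
) -> AttackTrajectory:
    """Iterative removal of taxa in decreasing betweenness order.

    The removal order is computed once from the initial network (per-step
    recomputation behind ``recompute_betweenness``); each removal deletes
    the taxon's row from the count table and re-infers the network.
    """
    inference = inference or InferenceConfig()
    config = config or AttackConfig()
    if config.mode != "targeted":
        raise ValidationError("config.mode must be 'targeted'")
    cm = _resolve_group(counts, meta, group)
    if config.n_remove >= cm.n_taxa:
        raise ValidationError(
            f"n_remove={config.n_remove} must be < {cm.n_taxa} available taxa"
        )
    net0 = infer_network(cm, inference, group=group)
    order = _betweenness_order(net0)[: config.n_remove]
    if config.recompute_betweenness:
        logger.info("recomputing betweenness after each removal")
    return _run_trajectory(cm, net0, order, inference, config, reference, "targeted")


def random_attack(
    counts: CountMatrix,
    meta: SampleMetadata | None = None,
    group: str | None = None,
    inference: InferenceConfig | None = None,
    config: AttackConfig | None = None,
    reference: DegreeDistribution | None = None,
) -> list[AttackTrajectory]:
    """Replicated uniform-random taxon removal with per-step re-inference."""
    inference = inference or InferenceConfig()
    config = config or AttackConfig()
    if config.mode != "random":
        raise ValidationError("config.mode must be 'random'")
    cm = _resolve_group(counts, meta, group)
    if config.n_remove >= cm.n_taxa:
        raise ValidationError(
            f"n_remove={config.n_remove} must be < {cm.n_taxa} available taxa"
        )
    net0 = infer_network(cm, inference, group=group)
    trajectories = []
    for r in range(config.n_replicates):
        rng = np.random.default_rng(stable_seed(config.seed, "random_attack", r))
        order = list(rng.permutation(net0.nodes))[: config.n_remove]
        trajectories.append(
            _run_trajectory(cm, net0, order, inference, config, reference, "random", r)
        )
    return trajectories


def match_point(
    traj: AttackTrajectory, reference: DegreeDistribution, epsilon: float = 0.1
) -> int | None:
    """First step whose degree distribution is within epsilon of the reference."""
    for step in traj.steps:
        d = degree_dist_distance(step.degree_dist, reference)
        if d <= epsilon:
            return step.step
    return None


def trajectory_summary(
    traj: AttackTrajectory, reference: DegreeDistribution | None, epsilon: float
) -> dict:
    from .network_metrics import components

    rows = []
    for s in traj.steps:
        n_comp, _ = components(s.network)
        rows.append(
            {
                "step": s.step,
                "removed_taxon": s.removed_taxon,
                "nodes": s.network.n_nodes,
                "edges": s.network.n_edges,
                "components": n_comp,
                "distance": s.distance,
            }
        )
    out = {"mode": traj.mode, "replicate": traj.replicate, "steps": rows}
    if reference is not None:
        mp = match_point(traj, reference, epsilon)
        out["match_point"] = mp
        out["epsilon"] = epsilon
    return out


def write_trajectory(traj: AttackTrajectory, path) -> None:
    from .network_metrics import components

    rows = []
    for s in traj.steps:
        n_comp, _ = components(s.network)
        rows.append(
            (s.step, s.removed_taxon or "", s.network.n_nodes, s.network.n_edges, n_comp,
             "" if s.distance is None else s.distance)
        )
    pd.DataFrame(
        rows, columns=["step", "removed_taxon", "nodes", "edges", "components", "distance"]
    ).to_csv(path, sep="\t", index=False)
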