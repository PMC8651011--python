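"""Core data model, I/O and pipeline orchestration.

The universal input of every analysis stage is an ASV count table
(taxa x samples, non-negative integers) plus per-sample metadata
describing the paired two-timepoint, five-arm study design:
each subject contributes one baseline sample (T0) and one
post-treatment sample (T1) from one of five arms (water or alcohol
binge, with vehicle or OEA pretreatment, OEA given orally or i.p.).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("micronet")

TIMEPOINTS = ("T0", "T1")
LIQUIDS = ("water", "alcohol")
PRETREATMENTS = ("vehicle", "OEA")
ROUTES = ("none", "oral", "ip")

#: The five T1 study arms.
ARMS = (
    "water_vehicle",
    "water_oea",
    "alcohol_vehicle",
    "alcohol_oral_oea",
    "alcohol_ip_oea",
)

METADATA_COLUMNS = ("sample_id", "subject_id", "timepoint", "liquid", "pretreatment", "route")


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


class ParseError(ValueError):
    """Input file cannot be parsed."""


def stable_seed(*parts) -> int:
    """Derive a deterministic sub-seed (< 2**31) from arbitrary parts.

    Uses CRC32 of the repr of the parts, so results are stable across
    processes and platforms (unlike Python's salted ``hash``).
    """
    text = "\x1f".join(repr(p) for p in parts)
    return zlib.crc32(text.encode()) % (2**31)


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Taxa x samples non-negative integer abundance table."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_taxa, n_samples), integer

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integral")
            self.counts = np.round(self.counts).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {name} identifiers: {dupes}")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    # -- basic properties --------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def validate_sample_sums(self) -> None:
        sums = self.sample_sums()
        if (sums == 0).any():
            bad = [s for s, t in zip(self.sample_ids, sums) if t == 0]
            raise ValidationError(f"zero-sum samples: {bad}")

    # -- subsetting --------------------------------------------------------

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountMatrix(list(taxon_ids), list(self.sample_ids), self.counts[idx, :])

    def drop_absent_taxa(self) -> "CountMatrix":
        """Drop taxa with zero total count (cannot carry signal); logged."""
        present = self.counts.sum(axis=1) > 0
        n_dropped = int((~present).sum())
        if n_dropped:
            logger.info("dropping %d absent taxa from %d", n_dropped, self.n_taxa)
        keep = [t for t, p in zip(self.taxon_ids, present) if p]
        return CountMatrix(keep, list(self.sample_ids), self.counts[present, :])


def read_count_table(path, orientation: str = "taxa_rows") -> CountMatrix:
    """Read a TSV count table; normalize orientation to taxa x samples."""
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.index[numeric.isna().argmax()]
            raise ParseError(f"non-numeric cell at row {row!r}, column {col!r}")
        if (numeric < 0).any():
            row = df.index[(numeric < 0).argmax()]
            raise ParseError(f"negative cell at row {row!r}, column {col!r}")
        df[col] = numeric
    if orientation == "samples_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    cm = CountMatrix.from_dataframe(df)
    cm.validate_sample_sums()
    return cm


def write_count_table(cm: CountMatrix, path) -> None:
    cm.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Validated per-sample study metadata (one row per sample)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        df = df[list(METADATA_COLUMNS)].astype(str).reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise ValidationError(f"duplicate sample_id in metadata: {dupes}")
        for col, allowed in (
            ("timepoint", TIMEPOINTS),
            ("liquid", LIQUIDS),
            ("pretreatment", PRETREATMENTS),
            ("route", ROUTES),
        ):
            bad = sorted(set(df[col]) - set(allowed))
            if bad:
                raise ValidationError(f"unknown {col} value(s) {bad}; allowed: {allowed}")
        # route is "none" exactly for baseline samples and vehicle arms
        expect_none = (df["timepoint"] == "T0") | (df["pretreatment"] == "vehicle")
        bad = df.loc[expect_none != (df["route"] == "none"), "sample_id"]
        if len(bad):
            raise ValidationError(
                f"route must be 'none' iff timepoint=T0 or pretreatment=vehicle; "
                f"violated by samples {sorted(bad)}"
            )
        self.table = df

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, str]]) -> "SampleMetadata":
        return cls(pd.DataFrame(list(records)))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def validate_against(self, cm: CountMatrix) -> None:
        missing = sorted(set(cm.sample_ids) - set(self.sample_ids))
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")

    def arm_of(self, sample_id: str) -> str | None:
        """The T1 arm label of a sample, or None for T0 samples."""
        row = self.table.set_index("sample_id").loc[sample_id]
        if row["timepoint"] == "T0":
            return None
        if row["pretreatment"] == "vehicle":
            return f"{row['liquid']}_vehicle"
        if row["liquid"] == "water":
            return "water_oea"
        return f"alcohol_{row['route']}_oea"

    def samples_in_arm(self, arm: str) -> list[str]:
        if arm == "T0":
            return list(self.table.loc[self.table["timepoint"] == "T0", "sample_id"])
        if arm not in ARMS:
            raise ValidationError(f"unknown arm {arm!r}; known: {ARMS} or 'T0'")
        return [s for s in self.sample_ids if self.arm_of(s) == arm]


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def select_arm(cm: CountMatrix, meta: SampleMetadata, arm: str) -> CountMatrix:
    """Count sub-table of one arm (or 'T0'), absent taxa dropped."""
    samples = meta.samples_in_arm(arm)
    if not samples:
        raise ValidationError(f"no samples in arm {arm!r}")
    return cm.select_samples(samples).drop_absent_taxa()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Full pipeline configuration; every RNG draw derives from these seeds."""

    rarefaction_seed: int = 0
    css_quantile: float = 0.5
    css_scale: float = 1000.0
    n_permutations: int = 999
    beta_on_css: bool = True  # Bray-Curtis on CSS+log2 values; False = raw proportions
    lefse_alpha: float = 0.05
    lefse_lda_threshold: float = 2.0
    stats_seed: int = 0
    inference: "InferenceConfig" = None  # type: ignore[assignment]
    attack: "AttackConfig" = None  # type: ignore[assignment]
    attack_arm: str = "alcohol_oral_oea"
    attack_reference_arm: str = "alcohol_ip_oea"
    run_attack: bool = False

    def __post_init__(self) -> None:
        from .network_inference import InferenceConfig
        from .attack_sim import AttackConfig

        if self.inference is None:
            self.inference = InferenceConfig()
        elif isinstance(self.inference, dict):
            self.inference = InferenceConfig(**self.inference)
        if self.attack is None:
            self.attack = AttackConfig()
        elif isinstance(self.attack, dict):
            self.attack = AttackConfig(**self.attack)
        if not 0 < self.css_quantile < 1:
            raise ValidationError("css_quantile must be in (0,1)")
        if self.css_scale <= 0:
            raise ValidationError("css_scale must be positive")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be a positive integer")
        if not 0 <= self.lefse_alpha <= 1:
            raise ValidationError("lefse_alpha must be in [0,1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Network I/O
# ---------------------------------------------------------------------------


def write_network(net, path_graphml, path_edges) -> None:
    """Write an association network as GraphML plus a TSV edge list.

    Node attribute ``taxon_id``; edge attributes ``sign`` (+1/-1) and
    ``weight``. Round-trip via :func:`read_network` reproduces the node
    set and the signed edge set exactly.
    """
    g = nx.Graph()
    for node in net.nodes:
        g.add_node(node, taxon_id=node)
    rows = []
    for (a, b), (sign, weight) in sorted(net.edges.items()):
        g.add_edge(a, b, sign=int(sign), weight=float(weight))
        rows.append((a, b, int(sign), float(weight)))
    nx.write_graphml(g, path_graphml)
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "sign", "weight"]).to_csv(
        path_edges, sep="\t", index=False
    )


def read_network(path_graphml):
    from .network_inference import AssociationNetwork

    g = nx.read_graphml(path_graphml)
    nodes = [str(n) for n in g.nodes]
    edges = {}
    for a, b, data in g.edges(data=True):
        key = tuple(sorted((str(a), str(b))))
        edges[key] = (int(data["sign"]), float(data.get("weight", 0.0)))
    return AssociationNetwork(nodes=nodes, edges=edges, provenance={"source": str(path_graphml)})


# ---------------------------------------------------------------------------
# JSON report helpers
# ---------------------------------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json_report(data: Mapping, path) -> None:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(_jsonify(data), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, counts: CountMatrix, meta: SampleMetadata, out_dir):
    """Run every analysis stage and write the report bundle to ``out_dir``.

    Stages: rarefaction + alpha-diversity with Wilcoxon tests, CSS
    normalization, Bray-Curtis + PCoA, PERMANOVA (global and pairwise)
    and ANOSIM over T1 arms, per-taxon ANOVA scan, LEfSe-style
    biomarkers, per-arm network inference with topology properties, and
    (optionally) the targeted-attack simulation.

    Returns the report dict; all randomness derives from config seeds so
    a rerun with identical inputs is byte-identical on disk.
    """
    from . import attack_sim, community_metrics, group_stats, network_inference, network_metrics

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts.validate_sample_sums()
    meta.validate_against(counts)

    report: dict = {"config": config.to_dict()}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("alpha_diversity")
        depth = int(counts.sample_sums().min())
        rare = community_metrics.rarefy(counts, depth, seed=config.rarefaction_seed)
        alpha = community_metrics.alpha_diversity(rare)
        alpha.to_csv(out / "diversity.tsv", sep="\t", index_label="sample_id")
        report["rarefaction_depth"] = depth

        stage("alpha_tests")
        arm_samples = {arm: meta.samples_in_arm(arm) for arm in ARMS}
        arm_samples = {a: s for a, s in arm_samples.items() if len(s) >= 2}
        subj = meta.table.set_index("sample_id")["subject_id"]
        t0_of = {}
        t0_rows = meta.table[meta.table["timepoint"] == "T0"]
        for _, r in t0_rows.iterrows():
            t0_of[r["subject_id"]] = r["sample_id"]
        alpha_tests = []
        for metric in ("richness", "shannon"):
            for arm, samples in arm_samples.items():
                paired_t0 = [t0_of.get(subj[s]) for s in samples]
                if any(p is None for p in paired_t0):
                    continue
                res = group_stats.wilcoxon_rank_sum(
                    alpha.loc[paired_t0, metric].to_numpy(),
                    alpha.loc[samples, metric].to_numpy(),
                    paired=True,
                )
                alpha_tests.append(
                    {"metric": metric, "comparison": f"T0_vs_{arm}", **res.to_dict()}
                )
            arms = sorted(arm_samples)
            for i in range(len(arms)):
                for j in range(i + 1, len(arms)):
                    res = group_stats.wilcoxon_rank_sum(
                        alpha.loc[arm_samples[arms[i]], metric].to_numpy(),
                        alpha.loc[arm_samples[arms[j]], metric].to_numpy(),
                        paired=False,
                    )
                    alpha_tests.append(
                        {
                            "metric": metric,
                            "comparison": f"{arms[i]}_vs_{arms[j]}",
                            **res.to_dict(),
                        }
                    )
        report["alpha_tests"] = alpha_tests

        stage("normalization_ordination")
        norm = community_metrics.css_normalize(counts, config.css_quantile, config.css_scale)
        if config.beta_on_css:
            beta_values = norm.values.T
        else:
            beta_values = (counts.counts / counts.sample_sums()).T
        dist = community_metrics.bray_curtis(beta_values, sample_ids=counts.sample_ids)
        k = min(3, counts.n_samples - 1)
        ord_res = community_metrics.pcoa(dist, k)
        coords = pd.DataFrame(
            ord_res.coordinates,
            index=dist.sample_ids,
            columns=[f"axis{i + 1}" for i in range(ord_res.coordinates.shape[1])],
        )
        coords.to_csv(out / "ordination.tsv", sep="\t", index_label="sample_id")
        report["ordination"] = {
            "eigenvalues": list(ord_res.eigenvalues[: max(k, 5)]),
            "variance_explained": list(ord_res.variance_explained[:k]),
        }

        stage("community_tests")
        t1_samples = [s for a in sorted(arm_samples) for s in arm_samples[a]]
        labels = [meta.arm_of(s) for s in t1_samples]
        sub = dist.subset(t1_samples)
        seed = stable_seed(config.stats_seed, "permanova")
        perma = group_stats.permanova(sub, labels, config.n_permutations, seed)
        report["permanova"] = perma.to_dict()
        report["pairwise_permanova"] = [
            r.to_dict()
            for r in group_stats.pairwise_permanova(sub, labels, config.n_permutations, seed)
        ]
        report["anosim"] = group_stats.anosim(
            sub, labels, config.n_permutations, stable_seed(config.stats_seed, "anosim")
        ).to_dict()

        stage("taxon_scan")
        rel = counts.counts / counts.sample_sums()
        order = np.argsort(-rel.mean(axis=1))[:10]
        scan = []
        groups_idx = {
            arm: [counts.sample_ids.index(s) for s in arm_samples[arm]]
            for arm in sorted(arm_samples)
        }
        for i in order:
            groups = [rel[i, idx] for idx in groups_idx.values()]
            res = group_stats.oneway_anova(groups)
            scan.append({"taxon": counts.taxon_ids[i], **res.to_dict()})
        pvals = [r["p_value"] for r in scan]
        for r, adj in zip(scan, group_stats.bh_adjust(pvals)):
            r["p_adjusted"] = adj
        report["anova_scan"] = scan
        pd.DataFrame(scan).to_csv(out / "anova_scan.tsv", sep="\t", index=False)

        stage("biomarkers")
        t1_idx = [counts.sample_ids.index(s) for s in t1_samples]
        norm_t1 = community_metrics.NormalizedMatrix(
            values=norm.values[:, t1_idx],
            scaling_factors=norm.scaling_factors[t1_idx],
            css_quantile=norm.css_quantile,
            css_scale=norm.css_scale,
            taxon_ids=norm.taxon_ids,
            sample_ids=t1_samples,
        )
        markers = group_stats.lefse_markers(
            norm_t1,
            labels,
            alpha=config.lefse_alpha,
            lda_threshold=config.lefse_lda_threshold,
            seed=stable_seed(config.stats_seed, "lefse"),
        )
        report["biomarkers"] = [dataclasses.asdict(m) for m in markers]

        stage("networks")
        nets = {}
        properties = {}
        for arm in sorted(arm_samples):
            sub_cm = select_arm(counts, meta, arm)
            if sub_cm.n_samples < 4:
                logger.warning("arm %s has <4 samples; skipping network", arm)
                continue
            net = network_inference.infer_network(sub_cm, config.inference, group=arm)
            nets[arm] = net
            props = network_metrics.network_properties(net)
            properties[arm] = dataclasses.asdict(props)
            write_network(net, out / f"network_{arm}.graphml", out / f"network_{arm}_edges.tsv")
            dd = network_metrics.degree_distribution(net)
            pd.DataFrame(
                sorted(dd.frequencies.items()), columns=["degree", "percent"]
            ).to_csv(out / f"degree_dist_{arm}.tsv", sep="\t", index=False)
        report["network_properties"] = properties

        if config.run_attack and config.attack_arm in nets and config.attack_reference_arm in nets:
            stage("attack")
            reference = network_metrics.degree_distribution(nets[config.attack_reference_arm])
            traj = attack_sim.targeted_attack(
                counts,
                meta,
                config.attack_arm,
                config.inference,
                config.attack,
                reference=reference,
            )
            report["attack"] = attack_sim.trajectory_summary(traj, reference, config.attack.epsilon)
            attack_sim.write_trajectory(traj, out / "attack_targeted.tsv")
    except (ValidationError, ParseError):
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    write_json_report(report, out / "report.json")
    return report
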