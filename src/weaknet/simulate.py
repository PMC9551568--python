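"""Synthetic signaling graphs and weakly activated expression cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: a directed signaling graph whose genes are organised into
(possibly overlapping) pathways; a handful of *activated* pathways whose
member genes carry small planted fold changes (the weak-activation regime,
fc roughly 1.1-1.5); two or more independent case/control cohorts with
log-normal expression noise on the TPM scale; and planted signaling
cascades — short directed paths from designated source genes to designated
target genes — recorded as ground truth for recovery testing.

Planted cascades are guaranteed to be shortest routes: after random edges
are sampled, the cascade path is inserted and any random edges that would
shortcut the pair below the planted length are pruned, so the planted path
is a minimal source-to-target cascade by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import networkx as nx
import pandas as pd

from .expression import CASE, CONTROL, LabeledExpressionMatrix, write_expression_tsv
from .genesets import GeneSetCollection, write_gmt
from .graph import SignalingGraph, write_sif


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe a small two-cohort study: a 50-gene signaling universe
    with 5 overlapping pathways, 2 weakly activated pathways (fold changes
    uniform in 1.1-1.5), 80 control + 80 case samples per cohort with
    log-normal noise (sd 0.5 on the natural-log scale), and one planted
    3-hop source-to-target cascade.
    """

    n_genes: int = 50
    n_pathways: int = 5
    pathway_size_range: tuple = (6, 12)
    edge_density_within: float = 0.12
    edge_density_between: float = 0.01
    n_activated_pathways: int = 2
    activation_fc_range: tuple = (1.1, 1.5)
    n_control: int = 80
    n_case: int = 80
    n_cohorts: int = 2
    dispersion: float = 0.5
    baseline_log_mean_range: tuple = (1.0, 5.0)
    planted_cascade_length: int = 3
    n_planted_cascades: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_pathways < 0 or self.n_cohorts < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid pathway_size_range")
        if self.n_pathways > 0 and lo > self.n_genes:
            raise ValueError(
                f"minimum pathway size {lo} does not fit in {self.n_genes} genes"
            )
        if self.n_activated_pathways > self.n_pathways:
            raise ValueError("n_activated_pathways exceeds n_pathways")
        flo, fhi = self.activation_fc_range
        if not (1.0 < flo <= fhi):
            raise ValueError("activation fold changes must exceed 1")
        if not (0 <= self.edge_density_within <= 1 and 0 <= self.edge_density_between <= 1):
            raise ValueError("edge densities must be probabilities")
        if self.n_control < 1 or self.n_case < 1:
            raise ValueError("cohort sizes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.planted_cascade_length < 1:
            raise ValueError("planted_cascade_length must be >= 1")
        if self.n_planted_cascades < 0:
            raise ValueError("n_planted_cascades must be >= 0")
        need = self.n_planted_cascades * (1 + self.planted_cascade_length)
        if need > self.n_genes:
            raise ValueError("planted cascades need more distinct genes than available")


@dataclass
class GroundTruth:
    """The generator's planted structure, for recovery testing."""

    activated_pathways: frozenset
    per_gene_fc: dict[str, float]
    planted_sources: frozenset
    planted_targets: frozenset
    planted_cascade_edges: frozenset

    def to_json(self, path: str | Path) -> None:
        payload = {
            "activated_pathways": sorted(self.activated_pathways),
            "per_gene_fc": {g: self.per_gene_fc[g] for g in sorted(self.per_gene_fc)},
            "planted_sources": sorted(self.planted_sources),
            "planted_targets": sorted(self.planted_targets),
            "planted_cascade_edges": sorted(map(list, self.planted_cascade_edges)),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def generate_signaling_graph(config: SimulationConfig) -> tuple[SignalingGraph, GroundTruth]:
    """Sample the directed pathway graph and plant cascades + activations.

    Deterministic given ``config.seed``. Pathway membership is sampled with
    replacement across pathways (pathways overlap, as real pathway databases
    do); directed edges appear with probability ``edge_density_within``
    between genes sharing a pathway and ``edge_density_between`` otherwise.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    # pathway membership (overlapping across pathways)
    pathways: dict[str, frozenset] = {}
    lo, hi = config.pathway_size_range
    for k in range(config.n_pathways):
        size = min(int(rng.integers(lo, hi + 1)), config.n_genes)
        members = rng.choice(config.n_genes, size=size, replace=False)
        pathways[f"PW{k + 1:03d}"] = frozenset(genes[i] for i in members)

    # shared-pathway indicator
    member_mat = np.zeros((config.n_pathways, config.n_genes), dtype=bool)
    for k, name in enumerate(sorted(pathways)):
        for g in pathways[name]:
            member_mat[k, gene_idx[g]] = True
    share = member_mat.T @ member_mat if config.n_pathways else np.zeros(
        (config.n_genes, config.n_genes), dtype=int
    )

    prob = np.where(share > 0, config.edge_density_within, config.edge_density_between)
    np.fill_diagonal(prob, 0.0)
    adj = rng.random((config.n_genes, config.n_genes)) < prob

    # planted cascades: fresh disjoint node chains source -> ... -> target
    order = rng.permutation(config.n_genes)
    cursor = 0
    cascade_edges: set = set()
    sources: set = set()
    targets: set = set()
    pairs: set = set()
    length = config.planted_cascade_length
    for _ in range(config.n_planted_cascades):
        chain_idx = order[cursor : cursor + length + 1]
        cursor += length + 1
        chain = [genes[i] for i in chain_idx]
        sources.add(chain[0])
        targets.add(chain[-1])
        pairs.add((chain[0], chain[-1]))
        for a, b in zip(chain[:-1], chain[1:]):
            cascade_edges.add((a, b))
            adj[gene_idx[a], gene_idx[b]] = True

    edges = [
        (genes[i], "activation", genes[j])
        for i, j in zip(*np.nonzero(adj))
    ]
    graph = SignalingGraph(edges, nodes=genes, pathways=pathways)

    _prune_shortcuts(graph, pairs, cascade_edges, length)

    # planted weak activations: one fold change per gene in activated pathways
    activated = frozenset(sorted(pathways)[: config.n_activated_pathways])
    per_gene_fc = {g: 1.0 for g in genes}
    activated_genes = sorted(set().union(*(pathways[p] for p in activated)) if activated else set())
    flo, fhi = config.activation_fc_range
    for g in activated_genes:
        per_gene_fc[g] = float(rng.uniform(flo, fhi))

    truth = GroundTruth(
        activated_pathways=activated,
        per_gene_fc=per_gene_fc,
        planted_sources=frozenset(sources),
        planted_targets=frozenset(targets),
        planted_cascade_edges=frozenset(cascade_edges),
    )
    return graph, truth


def _prune_shortcuts(
    graph: SignalingGraph,
    pairs: set,
    cascade_edges: set,
    length: int,
) -> None:
    """Remove random edges that undercut a planted cascade's length.

    For each planted (source, target) pair, while a directed path shorter
    than the planted length exists, delete the first non-planted edge on a
    lexicographically-first shortest path. Deterministic; planted edges are
    never removed (a planted chain cannot itself shortcut its own pair).
    """
    g = graph.nx
    for s, t in sorted(pairs):
        while True:
            try:
                dist = nx.shortest_path_length(g, s, t)
            except nx.NetworkXNoPath:  # pragma: no cover - planted path exists
                break
            if dist >= length:
                break
            path = min(nx.all_shortest_paths(g, s, t))
            removed = False
            for a, b in zip(path[:-1], path[1:]):
                if (a, b) not in cascade_edges:
                    g.remove_edge(a, b)
                    removed = True
                    break
            if not removed:  # pragma: no cover - all-planted short path impossible
                break


def generate_expression_cohorts(
    config: SimulationConfig,
    graph: SignalingGraph,
    truth: GroundTruth,
) -> list[LabeledExpressionMatrix]:
    """Simulate ``n_cohorts`` independent case/control TPM-scale matrices.

    Per cohort, each gene g gets a baseline natural-log mean mu_g drawn
    uniformly from ``baseline_log_mean_range``; expression for a case sample
    is ``exp(Normal(mu_g + log fc_g, dispersion))`` and for a control sample
    ``exp(Normal(mu_g, dispersion))``. Deterministic given ``config.seed``.
    """
    genes = sorted(graph.nodes) if graph.nodes else _gene_names(config.n_genes)
    missing = [g for g in genes if g not in truth.per_gene_fc]
    if missing:
        raise ValueError(f"ground truth lacks fold changes for genes: {missing[:5]}")
    log_fc = np.log([truth.per_gene_fc[g] for g in genes])

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    lo, hi = config.baseline_log_mean_range
    out = []
    for c in range(config.n_cohorts):
        cohort = f"cohort{c + 1}"
        mu = rng.uniform(lo, hi, size=len(genes))
        ctrl_ids = [f"{cohort}_ctrl{i + 1:03d}" for i in range(config.n_control)]
        case_ids = [f"{cohort}_case{i + 1:03d}" for i in range(config.n_case)]
        ctrl = rng.normal(mu[:, None], config.dispersion, (len(genes), config.n_control))
        case = rng.normal(
            (mu + log_fc)[:, None], config.dispersion, (len(genes), config.n_case)
        )
        values = pd.DataFrame(
            np.exp(np.concatenate([ctrl, case], axis=1)),
            index=pd.Index(genes, name="gene"),
            columns=ctrl_ids + case_ids,
        )
        group = {s: CONTROL for s in ctrl_ids} | {s: CASE for s in case_ids}
        out.append(LabeledExpressionMatrix(values, group, cohort))
    return out


def write_simulation(
    outdir: str | Path,
    config: SimulationConfig,
    graph: SignalingGraph,
    truth: GroundTruth,
    cohorts: list[LabeledExpressionMatrix],
) -> dict[str, str]:
    """Write every simulated artifact as plain text; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    meta_rows = []
    for cohort in cohorts:
        p = outdir / f"expression_{cohort.cohort}.tsv"
        write_expression_tsv(cohort, p)
        paths[f"expression_{cohort.cohort}"] = str(p)
        for s in cohort.samples:
            meta_rows.append((s, cohort.group[s], cohort.cohort))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "group", "cohort"])
    paths["metadata"] = str(outdir / "metadata.tsv")
    meta.to_csv(paths["metadata"], sep="\t", index=False)

    paths["graph"] = str(outdir / "signaling_graph.sif")
    write_sif(graph, paths["graph"])

    paths["pathways"] = str(outdir / "pathways.gmt")
    write_gmt(GeneSetCollection(graph.pathways), paths["pathways"])

    planted = GeneSetCollection(
        {
            "planted_sources": truth.planted_sources,
            "planted_targets": truth.planted_targets,
        },
        {
            "planted_sources": "planted cascade source genes",
            "planted_targets": "planted cascade target genes",
        },
    )
    paths["planted_sets"] = str(outdir / "planted_sets.gmt")
    write_gmt(planted, paths["planted_sets"])

    paths["ground_truth"] = str(outdir / "ground_truth.json")
    truth.to_json(paths["ground_truth"])

    paths["config"] = str(outdir / "simulation_config.json")
    Path(paths["config"]).write_text(
        json.dumps(asdict(config), indent=2, sort_keys=True) + "\n"
    )
    return paths
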