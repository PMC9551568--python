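"""End-to-end orchestration: simulate/load -> normalize -> screen -> enrich
-> infer cascades -> distance statistics -> separability.

Every stage writes its intermediates under the output directory and
contributes counts and statistics to a machine-readable JSON report. The
whole run is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cascade import CascadePartition, infer_cascades, summarize_network
from .distances import compare_groups, distance_profiles
from .enrichment import DEFAULT_P_REPORT, enrich_pathways
from .expression import (
    LabeledExpressionMatrix,
    de_two_group,
    intersect_degs,
    normalize_log,
    read_expression_tsv,
    screen_degs,
    tmm_factors,
)
from .genesets import GeneSetCollection, read_gmt, write_gmt
from .graph import SignalingGraph, read_sif, write_graphml, write_sif
from .simulate import (
    GroundTruth,
    SimulationConfig,
    generate_expression_cohorts,
    generate_signaling_graph,
    write_simulation,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_GRID = [(1.5, 0.05), (1.25, 0.05), (1.1, 0.1)]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Single-document configuration of the full analysis.

    Exactly one of *simulation* (a :class:`SimulationConfig`) or the input
    paths (*expression*, *metadata*, *graph*, *gene_sets*) must be given.
    ``source_set``/``target_set`` name entries of the gene-set collection
    used as cascade V0/V1 (simulation runs default to the planted sets).
    """

    simulation: SimulationConfig | None = None
    expression: str | None = None
    metadata: str | None = None
    graph: str | None = None
    gene_sets: str | None = None  # GMT with pathways
    source_set: str = "planted_sources"
    target_set: str = "planted_targets"
    threshold_grid: list = field(default_factory=lambda: list(DEFAULT_THRESHOLD_GRID))
    analysis_fc: float = 1.1
    analysis_p: float = 0.1
    p_report: float = DEFAULT_P_REPORT
    max_depth: int = 6
    tie_policy: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.expression is not None
        if self.simulation is None and not has_paths:
            raise ValueError("config needs a simulation block or input paths")
        if (self.analysis_fc, self.analysis_p) not in [
            (float(fc), float(p)) for fc, p in self.threshold_grid
        ]:
            self.threshold_grid = list(self.threshold_grid) + [
                (self.analysis_fc, self.analysis_p)
            ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("pathway_size_range", "activation_fc_range", "baseline_log_mean_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(**sim)
        if "threshold_grid" in raw:
            raw["threshold_grid"] = [tuple(t) for t in raw["threshold_grid"]]
        return cls(simulation=sim, **raw)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns the report (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "weaknet", "version": __version__},
        "seed": config.seed,
        "parameters": _config_dict(config),
        "stages": {},
        "files": {},
    }

    # -- stage 1: simulate or load ------------------------------------------
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            graph, truth = generate_signaling_graph(sim)
            cohorts = generate_expression_cohorts(sim, graph, truth)
            paths = write_simulation(outdir / "inputs", sim, graph, truth, cohorts)
            gene_sets = GeneSetCollection(
                dict(graph.pathways)
                | {
                    "planted_sources": truth.planted_sources,
                    "planted_targets": truth.planted_targets,
                }
            )
            report["files"].update({k: _rel(v, outdir) for k, v in paths.items()})
            report["stages"]["simulate"] = {
                "n_genes": sim.n_genes,
                "n_graph_edges": graph.n_edges(),
                "n_pathways": len(graph.pathways),
                "activated_pathways": sorted(truth.activated_pathways),
                "cohort_sizes": {
                    c.cohort: {"control": len(c.samples_in_group("control")),
                               "case": len(c.samples_in_group("case"))}
                    for c in cohorts
                },
            }
        else:
            cohorts = read_expression_tsv(config.expression, config.metadata)
            graph = read_sif(config.graph)
            gene_sets = read_gmt(config.gene_sets) if config.gene_sets else GeneSetCollection({})
            if graph.pathways == {} and len(gene_sets):
                graph.pathways.update(
                    {k: gene_sets[k] for k in gene_sets
                     if k not in (config.source_set, config.target_set)}
                )
            truth = None
            report["stages"]["load"] = {
                "cohorts": [c.cohort for c in cohorts],
                "n_graph_nodes": graph.n_nodes(),
                "n_graph_edges": graph.n_edges(),
            }
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError("inputs", "bad-input", str(exc)) from exc

    # -- stage 2: normalize + differential screen per cohort ----------------
    deg_stage: dict = {}
    up_sets, down_sets = [], []
    results = {}
    try:
        for cohort in cohorts:
            factors = tmm_factors(cohort)
            logm = normalize_log(cohort, factors)
            res = de_two_group(logm)
            results[cohort.cohort] = (logm, res)
            res_out = res.copy()
            res_out.insert(0, "gene", res_out.index)
            res_path = outdir / f"deg_{cohort.cohort}.tsv"
            res_out.to_csv(res_path, sep="\t", index=False, float_format="%.6g")
            report["files"][f"deg_{cohort.cohort}"] = _rel(res_path, outdir)

            per_threshold = {}
            for fc, p in config.threshold_grid:
                up = screen_degs(res, fc, p, "up")
                down = screen_degs(res, fc, p, "down")
                per_threshold[f"fc{fc}_p{p}"] = {"n_up": len(up), "n_down": len(down)}
                if (fc, p) == (config.analysis_fc, config.analysis_p):
                    up_sets.append(up)
                    down_sets.append(down)
            deg_stage[cohort.cohort] = per_threshold
    except ValueError as exc:
        raise PipelineError("deg", "test-failed", str(exc)) from exc
    report["stages"]["deg"] = deg_stage

    common_up = intersect_degs(up_sets)
    common_down = intersect_degs(down_sets)
    common_gmt = GeneSetCollection(
        {"common_up": common_up, "common_down": common_down},
        {"common_up": f"fc>={config.analysis_fc} p<={config.analysis_p} up in all cohorts",
         "common_down": f"fc>={config.analysis_fc} p<={config.analysis_p} down in all cohorts"},
    )
    write_gmt(common_gmt, outdir / "common_degs.gmt")
    report["files"]["common_degs"] = "common_degs.gmt"
    report["stages"]["common_degs"] = {
        "threshold": {"fc": config.analysis_fc, "p": config.analysis_p},
        "n_common_up": len(common_up),
        "n_common_down": len(common_down),
    }

    # -- stage 3: pathway over-representation -------------------------------
    try:
        universe = graph.nodes & frozenset(cohorts[0].genes)
        pathway_sets = GeneSetCollection(dict(graph.pathways))
        enr = enrich_pathways(common_up, pathway_sets, universe, config.p_report)
        enr_path = outdir / "enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
        report["files"]["enrichment"] = _rel(enr_path, outdir)
        report["stages"]["enrichment"] = {
            "universe_size": len(universe),
            "query_size": len(common_up & universe),
            "p_report": config.p_report,
            "n_reported": int(enr["reported"].sum()) if not enr.empty else 0,
            "reported_pathways": sorted(enr.loc[enr["reported"], "set_name"])
            if not enr.empty
            else [],
        }
    except ValueError as exc:
        raise PipelineError("enrichment", "bad-universe", str(exc)) from exc

    # -- stage 4: cascade inference -----------------------------------------
    try:
        sources = gene_sets[config.source_set]
        targets = gene_sets[config.target_set]
        partition = CascadePartition.from_sets(sources, targets, graph)
        net = infer_cascades(graph, partition, config.max_depth, config.tie_policy)
        net_graph = SignalingGraph(
            ((u, "activation", v) for u, v in sorted(net.edges)), nodes=net.nodes
        )
        for n, role in net.roles.items():
            net_graph.nx.nodes[n]["role"] = role
        write_sif(net_graph, outdir / "cascade_network.sif")
        write_graphml(net_graph.nx, outdir / "cascade_network.graphml")
        (outdir / "cascade_iterations.json").write_text(
            json.dumps(net.iteration_log, indent=2, sort_keys=True) + "\n"
        )
        report["files"]["cascade_network"] = "cascade_network.sif"
        report["files"]["cascade_iterations"] = "cascade_iterations.json"
        report["stages"]["cascade"] = {
            "n_nodes": len(net.nodes),
            "n_edges": len(net.edges),
            "roles": net.role_counts(),
            "n_iterations": len(net.iteration_log),
            "unreachable_targets": sorted(net.unreachable_targets),
        }
    except (KeyError, ValueError) as exc:
        raise PipelineError("cascade", "inference-failed", str(exc)) from exc

    # -- stage 5: distance statistics ----------------------------------------
    try:
        profile = distance_profiles(
            graph,
            {"sources": partition.v0},
            universe,
            partition.v1 | frozenset(targets),
        )
        prof_path = outdir / "distance_profile.tsv"
        profile.to_csv(prof_path, sep="\t", index=False, float_format="%.6g")
        report["files"]["distance_profile"] = _rel(prof_path, outdir)
        dist_stage: dict = {"n_profiled": int(len(profile))}
        counts = profile.loc[profile["n_reachable_targets"] > 0, "group"].value_counts()
        if counts.get("sources", 0) >= 3 and counts.get("background", 0) >= 3:
            dist_stage["sources_vs_background"] = compare_groups(
                profile, "sources", "background"
            )
        report["stages"]["distance"] = dist_stage
    except ValueError as exc:
        raise PipelineError("distance", "profile-failed", str(exc)) from exc

    # -- stage 6: separability ------------------------------------------------
    try:
        from .separability import separability_report

        sep_stage = []
        for cohort in cohorts:
            logm, _res = results[cohort.cohort]
            subset = {"common_up": common_up} if common_up else {}
            for r in separability_report(logm, subset):
                sep_stage.append(
                    {
                        "cohort": cohort.cohort,
                        "subset": r.gene_subset_name,
                        "beta": r.beta,
                        "abs_beta": r.abs_beta,
                        "odds_ratio": r.odds_ratio,
                        "p_value": r.p_value,
                        "complete_separation": r.complete_separation,
                    }
                )
                coord_path = outdir / f"mds_{cohort.cohort}_{r.gene_subset_name}.tsv"
                r.coordinates.to_csv(coord_path, sep="\t", float_format="%.6g")
                report["files"][f"mds_{cohort.cohort}_{r.gene_subset_name}"] = _rel(
                    coord_path, outdir
                )
        report["stages"]["separability"] = sep_stage
    except ValueError as exc:
        raise PipelineError("separability", "fit-failed", str(exc)) from exc

    write_report(report, outdir)
    return report


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write the JSON report plus a flat TSV summary; verify file references."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    rows = [
        {"section": "software", "key": "version", "value": report["software"]["version"]},
        {"section": "run", "key": "seed", "value": report["seed"]},
    ]
    for stage, payload in sorted(report.get("stages", {}).items()):
        rows.append({"section": stage, "key": "summary", "value": json.dumps(payload, sort_keys=True)})
    pd.DataFrame(rows).to_csv(outdir / "report_summary.tsv", sep="\t", index=False)

    missing = [
        rel for rel in report.get("files", {}).values() if not (outdir / rel).exists()
    ]
    if missing:
        raise PipelineError("report", "missing-files", f"report references absent files: {missing}")
    return path


def _config_dict(config: PipelineConfig) -> dict:
    out = dataclasses.asdict(config)
    out["threshold_grid"] = [list(t) for t in out["threshold_grid"]]
    return out


def _rel(path: str | Path, outdir: Path) -> str:
    return str(Path(path).relative_to(outdir))
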