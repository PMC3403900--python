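"""End-to-end orchestration: expression → candidates → cutoffs → GRN → core.

One YAML-serializable config drives the whole analysis; every stage
writes its artifact as plain TSV/JSON so any step can be rerun
standalone, and the summary JSON reports the network-overview schema
(edge counts by class, experimental-evidence edges, component fraction,
module coverage, core coverage, loop counts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (
    candidate_network,
    coexpression,
    enrichment,
    expression,
    network_analysis,
    scalefree_cutoff,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs, thresholds and the artifact directory for one run."""

    tu_path: str = ""
    an_path: str = ""
    probe_map_path: str = ""
    predicted_path: str = ""
    experimental_path: str | None = None
    gmt_path: str | None = None
    output_dir: str = "coregrn_out"
    alpha: float | None = None  # None: mean of pooled 25% quantiles
    cooks_threshold: float = 0.5
    min_samples: int = 10
    cutoff_grid: list[float] = field(
        default_factory=lambda: [float(c) for c in scalefree_cutoff.DEFAULT_GRID]
    )
    cutoff_tol: float = 0.05
    cutoff_window: int = 2
    c_tf: float | None = None  # fixed cutoffs skip the scan stage
    c_mirna: float | None = None
    core_quantile: float = 0.99
    walk_length: int = 4
    directed_betweenness: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.core_quantile < 1.0:
            raise ValueError("core_quantile must lie in [0, 1)")
        if self.cooks_threshold <= 0:
            raise ValueError("cooks_threshold must be positive")
        if self.min_samples < 4:
            raise ValueError("min_samples must be at least 4")
        for c in (self.c_tf, self.c_mirna):
            if c is not None and not 0.0 <= c < 1.0:
                raise ValueError("fixed cutoffs must lie in [0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all stages; returns the artifact manifest (name → path)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def artifact(name: str, filename: str) -> Path:
        path = outdir / filename
        manifest[name] = str(path)
        return path

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    summary: dict = {}
    try:
        stage("expression")
        panel = expression.read_panel(
            config.tu_path, config.an_path, config.probe_map_path
        )
        alpha = (
            float(config.alpha)
            if config.alpha is not None
            else expression.compute_alpha(panel)
        )
        ratios = expression.merge_probes(
            expression.compute_ratios(panel, alpha), panel.probe_map
        )
        expression.differential_stats(ratios)
        expression.write_ratios(ratios, artifact("ratios", "ratios.tsv"))
        expression.write_stats(ratios, artifact("stats", "stats.tsv"))
        summary["alpha"] = alpha
        summary["n_entities"] = int(ratios.values.shape[0])
        summary["n_patients"] = int(ratios.values.shape[1])
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"expression stage failed: {exc}") from exc

    try:
        stage("candidate_network")
        candidates = candidate_network.load_interactions(
            config.predicted_path, "predicted"
        )
        if config.experimental_path:
            exp = candidate_network.load_interactions(
                config.experimental_path, "experimental"
            )
            candidates = candidate_network.merge_sets(candidates, exp)
        candidates = candidate_network.restrict_to_measured(
            candidates, ratios.values.index
        )
        candidates.write(artifact("candidates", "candidates.tsv"))
        summary["n_candidate_edges"] = len(candidates)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"candidate_network stage failed: {exc}") from exc

    try:
        cutoffs: dict[str, float] = {}
        for cls, fixed in (("TF", config.c_tf), ("miRNA", config.c_mirna)):
            if fixed is not None:
                cutoffs[cls] = float(fixed)
                continue
            stage(f"scan_cutoffs[{cls}]")
            scan = scalefree_cutoff.scan_cutoffs(
                candidates,
                ratios,
                cls,
                grid=config.cutoff_grid,
                cooks_threshold=config.cooks_threshold,
                min_samples=config.min_samples,
            )
            scalefree_cutoff.write_scan(
                scan, artifact(f"scan_{cls}", f"scan_{cls}.tsv")
            )
            cutoffs[cls] = scalefree_cutoff.select_cutoff(
                scan, tol=config.cutoff_tol, window=config.cutoff_window
            )
        summary["cutoffs"] = cutoffs
        summary["cutoffs_scanned"] = {
            "TF": config.c_tf is None,
            "miRNA": config.c_mirna is None,
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"scan_cutoffs stage failed: {exc}") from exc

    try:
        stage("build_grn")
        net = coexpression.build_grn(
            candidates,
            ratios,
            class_cutoffs=cutoffs,
            cooks_threshold=config.cooks_threshold,
            min_samples=config.min_samples,
        )
        net.edges_dataframe().to_csv(
            artifact("grn_edges", "grn_edges.tsv"), sep="\t", index=False
        )
        edges = net.edges_dataframe()
        by_class = (
            edges.groupby(["regulator_class", "target_class"]).size()
            if len(edges)
            else {}
        )
        summary["n_nodes"] = net.n_nodes
        summary["n_edges"] = net.n_edges
        summary["edges_by_class"] = {
            f"{rc}->{tc}": int(n) for (rc, tc), n in dict(by_class).items()
        }
        summary["n_experimental_edges"] = int(
            edges["evidence"].str.contains("experimental").sum()
        ) if len(edges) else 0
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"build_grn stage failed: {exc}") from exc

    try:
        stage("network_analysis")
        if net.n_edges == 0:
            raise ValueError("empty GRN; nothing to analyze")
        component = network_analysis.largest_component(net)
        summary["component_fraction"] = component.n_nodes / net.n_nodes
        modules = network_analysis.detect_modules(
            component, steps=config.walk_length
        )
        classes = {
            n: component.graph.nodes[n].get("entity_class", "")
            for n in component.graph.nodes()
        }
        modules.to_dataframe(classes).to_csv(
            artifact("modules", "modules.tsv"), sep="\t", index=False
        )
        summary["n_modules"] = modules.n_modules
        summary["modularity"] = modules.modularity
        summary["module_coverage_top6"] = modules.coverage(6)
        bet = network_analysis.edge_betweenness(
            component, directed=config.directed_betweenness
        )
        core = network_analysis.extract_core(
            component,
            quantile=config.core_quantile,
            betweenness=bet,
            directed=config.directed_betweenness,
        )
        network_analysis.write_core(core, artifact("core_edges", "core_edges.tsv"))
        summary["core"] = {
            "n_nodes": core.n_nodes,
            "n_edges": core.n_edges,
            "quantile": core.quantile,
            "edge_fraction": core.edge_fraction,
            "betweenness_fraction": core.betweenness_fraction,
            "n_feedforward": core.n_feedforward,
            "n_feedback": core.n_feedback,
            "n_non_regulator_nodes": len(core.non_regulator_nodes),
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"network_analysis stage failed: {exc}") from exc

    if config.gmt_path:
        try:
            stage("enrichment")
            annotations = enrichment.AnnotationCollection.from_gmt(config.gmt_path)
            for module_id in range(1, modules.n_modules + 1):
                members = {
                    n for n, m in modules.assignment.items() if m == module_id
                }
                members &= set(annotations.background)
                if not members:
                    continue
                result = enrichment.hypergeom_enrich(members, annotations)
                enrichment.write_enrichment(
                    result,
                    artifact(
                        f"enrichment_module_{module_id}",
                        f"enrichment_module_{module_id}.tsv",
                    ),
                )
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"enrichment stage failed: {exc}") from exc

    summary["seed"] = config.seed
    with open(artifact("summary", "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(artifact("manifest", "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
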