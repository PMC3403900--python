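"""Synthetic study generator: paired expression panels with planted regulation.

Emulates the study conditions the pipeline was designed for: paired
tumor / adjacent-normal intensity matrices for ~96 patients, a
candidate network of true regulator→target interactions plus decoys,
TF regulation stronger than miRNA regulation (miRNA correlations
negative), injected high-influence outlier samples, heavy-tailed
regulator out-degrees and modular regulator blocks.

Correlations are planted through a shared latent factor: each entity
has a standard-normal log-ratio profile over patients, and a target of
a planted edge with correlation rho is ``rho * L_regulator +
sqrt(1 - rho^2) * noise``.  Each target has exactly one planted
regulator — with loadings near 0.8 a second parent could not hold its
planted Pearson correlation.  Intensities are built on the log2 scale
around RMA-like baselines (N(8, 1)) and exponentiated, so the paired
matrices are strictly positive and roughly log-normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .candidate_network import InteractionRecord, InteractionSet
from .expression import ExpressionPanel

logger = logging.getLogger(__name__)

#: SD of an injected outlier displacement, in units of the profile SD.
OUTLIER_SD = 8.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic panel.

    Defaults: a 96-patient paired cohort, TF signal 0.8 stronger than
    the (negative) miRNA signal 0.6, half of the candidate edges decoys,
    5% of true edges carrying one gross outlier sample.
    """

    n_genes: int = 400
    n_tfs: int = 30
    n_mirnas: int = 25
    n_patients: int = 96
    tf_signal: float = 0.8
    mirna_signal: float = 0.6
    decoy_edge_fraction: float = 0.5
    outlier_fraction: float = 0.05
    n_modules: int = 4
    seed: int = 0
    # structural knobs (fractions of entities wired as targets)
    gene_target_fraction: float = 0.85
    tf_mirna_fraction: float = 0.3
    tf_tf_fraction: float = 0.05
    experimental_fraction: float = 0.1
    two_probe_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tfs", "n_mirnas", "n_patients", "n_modules"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("tf_signal", "mirna_signal"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if not 0.0 <= self.decoy_edge_fraction < 1.0:
            raise ValueError("decoy_edge_fraction must lie in [0, 1)")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth: planted edges, module labels, injected outliers."""

    true_edges: list[tuple[str, str, float]]
    module_labels: dict[str, int]
    outlier_positions: list[tuple[str, str, int]] = field(default_factory=list)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _ in self.true_edges}


def generate_panel(
    config: SyntheticConfig,
) -> tuple[ExpressionPanel, InteractionSet, SyntheticTruth]:
    """Generate a paired TU/AN panel, candidate interactions and the truth.

    The same seed yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    tfs = [f"TF{i:03d}" for i in range(config.n_tfs)]
    mirnas = [f"miR{i:03d}" for i in range(config.n_mirnas)]
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    entity_class = {
        **{t: "TF" for t in tfs},
        **{m: "miRNA" for m in mirnas},
        **{g: "gene" for g in genes},
    }
    regulators = tfs + mirnas

    def tf_rho() -> float:
        sign = 1.0 if rng.random() < 0.7 else -1.0
        return sign * config.tf_signal

    # --- plant true edges (each target has exactly one regulator) -------
    true_edges: list[tuple[str, str, float]] = []
    parent: dict[str, tuple[str, float]] = {}

    n_tftf = round(config.tf_tf_fraction * config.n_tfs)
    if n_tftf and config.n_tfs >= 2:
        targets = rng.choice(np.arange(1, config.n_tfs), size=n_tftf, replace=False)
        for j in sorted(int(j) for j in targets):
            reg = tfs[int(rng.integers(0, j))]
            rho = tf_rho()
            parent[tfs[j]] = (reg, rho)
            true_edges.append((reg, tfs[j], rho))

    n_tfmir = round(config.tf_mirna_fraction * config.n_mirnas)
    if n_tfmir:
        targets = rng.choice(config.n_mirnas, size=n_tfmir, replace=False)
        for j in sorted(int(j) for j in targets):
            reg = tfs[int(rng.integers(0, config.n_tfs))]
            rho = tf_rho()
            parent[mirnas[j]] = (reg, rho)
            true_edges.append((reg, mirnas[j], rho))

    # gene targets wired by preferential attachment on regulator out-degree
    outdeg = np.zeros(len(regulators))
    reg_index = {r: i for i, r in enumerate(regulators)}
    for reg, _, _ in true_edges:
        outdeg[reg_index[reg]] += 1
    n_gene_targets = round(config.gene_target_fraction * config.n_genes)
    target_genes = sorted(
        int(j) for j in rng.choice(config.n_genes, size=n_gene_targets, replace=False)
    )
    for j in target_genes:
        w = outdeg + 1.0
        reg = regulators[int(rng.choice(len(regulators), p=w / w.sum()))]
        rho = tf_rho() if entity_class[reg] == "TF" else -config.mirna_signal
        parent[genes[j]] = (reg, rho)
        true_edges.append((reg, genes[j], rho))
        outdeg[reg_index[reg]] += 1

    # --- module labels: regulator blocks, targets inherit ---------------
    module_labels = {
        r: (i % config.n_modules) + 1 for i, r in enumerate(regulators)
    }
    for ent in genes:
        if ent in parent:
            module_labels[ent] = module_labels[parent[ent][0]]
        else:
            module_labels[ent] = (int(ent[1:]) % config.n_modules) + 1

    # --- latent log-ratio profiles (unit variance per entity) -----------
    n = config.n_patients
    profiles: dict[str, np.ndarray] = {}
    for ent in tfs + mirnas + genes:
        noise = rng.standard_normal(n)
        if ent in parent:
            reg, rho = parent[ent]
            profiles[ent] = rho * profiles[reg] + np.sqrt(1.0 - rho**2) * noise
        else:
            profiles[ent] = noise

    # --- inject gross outliers into leaf gene targets --------------------
    outlier_positions: list[tuple[str, str, int]] = []
    leaf_edges = [
        i for i, (_, tgt, _) in enumerate(true_edges) if entity_class[tgt] == "gene"
    ]
    n_out = round(config.outlier_fraction * len(true_edges))
    n_out = min(n_out, len(leaf_edges))
    if n_out:
        chosen = rng.choice(len(leaf_edges), size=n_out, replace=False)
        for i in sorted(int(c) for c in chosen):
            reg, tgt, _ = true_edges[leaf_edges[i]]
            s = int(rng.integers(0, n))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            profiles[tgt][s] = sign * OUTLIER_SD
            outlier_positions.append((reg, tgt, s))

    # --- probes and paired intensity matrices ----------------------------
    patients = [f"P{i:03d}" for i in range(n)]
    probe_rows = []
    tu_rows, an_rows, probe_ids = [], [], []
    for ent in tfs + mirnas + genes:
        base = 8.0 + rng.standard_normal()
        n_probes = 2 if rng.random() < config.two_probe_fraction else 1
        for p in range(n_probes):
            probe_id = f"{ent}_p{p + 1}"
            offset = 0.3 * rng.standard_normal()
            log_tu = base + offset + profiles[ent] / 2 + 0.05 * rng.standard_normal(n)
            log_an = base + offset - profiles[ent] / 2 + 0.05 * rng.standard_normal(n)
            probe_ids.append(probe_id)
            tu_rows.append(np.exp2(log_tu))
            an_rows.append(np.exp2(log_an))
            probe_rows.append(
                {
                    "probe_id": probe_id,
                    "entity_id": ent,
                    "entity_class": entity_class[ent],
                }
            )
    tu = pd.DataFrame(np.array(tu_rows), index=probe_ids, columns=patients)
    an = pd.DataFrame(np.array(an_rows), index=probe_ids, columns=patients)
    tu.index.name = an.index.name = "probe_id"
    panel = ExpressionPanel(tu=tu, an=an, probe_map=pd.DataFrame(probe_rows))

    # --- candidate set: true edges plus uniform decoys --------------------
    planted_pairs = {(r, t) for r, t, _ in true_edges}
    f = config.decoy_edge_fraction
    n_decoys = round(len(true_edges) * f / (1.0 - f)) if f > 0 else 0
    decoys: list[tuple[str, str]] = []
    seen = set(planted_pairs)
    while len(decoys) < n_decoys:
        reg = regulators[int(rng.integers(0, len(regulators)))]
        pool = genes + mirnas + tfs if entity_class[reg] == "TF" else genes + tfs
        tgt = pool[int(rng.integers(0, len(pool)))]
        if tgt == reg or (reg, tgt) in seen:
            continue
        seen.add((reg, tgt))
        decoys.append((reg, tgt))

    n_exp = round(config.experimental_fraction * len(true_edges))
    exp_idx = set(
        int(i) for i in rng.choice(len(true_edges), size=n_exp, replace=False)
    ) if n_exp else set()
    records = []
    for i, (reg, tgt, _) in enumerate(true_edges):
        evidence = (
            frozenset(["predicted", "experimental"])
            if i in exp_idx
            else frozenset(["predicted"])
        )
        records.append(
            InteractionRecord(
                regulator=reg,
                regulator_class=entity_class[reg],
                target=tgt,
                target_class=entity_class[tgt],
                evidence=evidence,
            )
        )
    for reg, tgt in decoys:
        records.append(
            InteractionRecord(
                regulator=reg,
                regulator_class=entity_class[reg],
                target=tgt,
                target_class=entity_class[tgt],
                evidence=frozenset(["predicted"]),
            )
        )
    candidates = InteractionSet(records)
    truth = SyntheticTruth(
        true_edges=true_edges,
        module_labels=module_labels,
        outlier_positions=outlier_positions,
    )
    logger.info(
        "synthetic panel: %d entities, %d probes, %d true edges, %d decoys, %d outliers",
        len(entity_class),
        len(probe_ids),
        len(true_edges),
        len(decoys),
        len(outlier_positions),
    )
    return panel, candidates, truth


def inject_outliers(
    profile: np.ndarray, indices, magnitude: float = OUTLIER_SD
) -> np.ndarray:
    """Copy of ``profile`` with the given samples moved to mean + magnitude SDs."""
    x = np.array(profile, dtype=float)
    sd = x.std() or 1.0
    x[np.asarray(indices, dtype=int)] = x.mean() + magnitude * sd
    return x


def generate_scalefree_digraph(n_nodes: int, n_edges: int, seed: int) -> nx.DiGraph:
    """Weakly connected preferential-attachment digraph.

    A spanning arborescence is grown first (each new node receives an
    edge from a source drawn with probability proportional to
    out-degree + 1); the remaining edges keep the preferential source
    choice and, while edges remain, target nodes that still have
    in-degree below 2 (then uniform targets).  Out-degrees are
    heavy-tailed as in scale-free regulatory networks, and the
    in-degree redundancy mimics the multi-regulator wiring that lets a
    real regulatory network survive deletion of its top edges.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if n_edges < n_nodes - 1:
        raise ValueError("n_edges must be at least n_nodes - 1 for connectivity")
    if n_edges > n_nodes * (n_nodes - 1):
        raise ValueError("too many edges for a simple digraph")
    rng = np.random.default_rng(seed)
    outdeg = np.zeros(n_nodes)
    indeg = np.zeros(n_nodes, dtype=int)
    edges: set[tuple[int, int]] = set()
    for v in range(1, n_nodes):
        w = outdeg[:v] + 1.0
        u = int(rng.choice(v, p=w / w.sum()))
        edges.add((u, v))
        outdeg[u] += 1
        indeg[v] += 1
    while len(edges) < n_edges:
        w = outdeg + 1.0
        u = int(rng.choice(n_nodes, p=w / w.sum()))
        deficient = np.flatnonzero(indeg < 2)
        if deficient.size:
            v = int(deficient[rng.integers(0, deficient.size)])
        else:
            v = int(rng.integers(0, n_nodes))
        if u == v or (u, v) in edges:
            continue
        edges.add((u, v))
        outdeg[u] += 1
        indeg[v] += 1
    graph = nx.DiGraph()
    graph.add_nodes_from(range(n_nodes))
    graph.add_edges_from(sorted(edges))
    return graph


def generate_modular_graph(
    block_sizes, p_in: float, p_out: float, seed: int
) -> tuple[nx.Graph, dict[int, int]]:
    """Planted-partition graph with edge weights in (0, 1].

    Within-block pairs connect with probability ``p_in``, between-block
    pairs with ``p_out`` (requires p_in > p_out).  Returns the weighted
    undirected graph and the node → block labels.
    """
    if not 0.0 <= p_out < p_in <= 1.0:
        raise ValueError("require 0 <= p_out < p_in <= 1")
    if any(s <= 0 for s in block_sizes):
        raise ValueError("block sizes must be positive")
    rng = np.random.default_rng(seed)
    labels: dict[int, int] = {}
    node = 0
    for b, size in enumerate(block_sizes):
        for _ in range(size):
            labels[node] = b
            node += 1
    graph = nx.Graph()
    graph.add_nodes_from(range(node))
    for i in range(node):
        for j in range(i + 1, node):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                graph.add_edge(i, j, weight=1.0 - rng.random())
    return graph, labels


def write_bundle(
    panel: ExpressionPanel,
    candidates: InteractionSet,
    truth: SyntheticTruth,
    outdir,
) -> dict[str, str]:
    """Write the panel, split interaction files and the truth table as TSV.

    Produces the same dialects the pipeline reads: tu.tsv / an.tsv /
    probe_map.tsv, predicted.tsv and experimental.tsv adjacency lists,
    and truth.tsv (regulator, target, planted_r, is_true).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    panel.tu.to_csv(outdir / "tu.tsv", sep="\t")
    panel.an.to_csv(outdir / "an.tsv", sep="\t")
    panel.probe_map.to_csv(outdir / "probe_map.tsv", sep="\t", index=False)
    predicted = InteractionSet(r for r in candidates if "predicted" in r.evidence)
    experimental = InteractionSet(r for r in candidates if "experimental" in r.evidence)
    predicted.write(outdir / "predicted.tsv")
    experimental.write(outdir / "experimental.tsv")
    planted = {(r, t): rho for r, t, rho in truth.true_edges}
    rows = [
        {
            "regulator": rec.regulator,
            "target": rec.target,
            "planted_r": planted.get((rec.regulator, rec.target), 0.0),
            "is_true": int((rec.regulator, rec.target) in planted),
        }
        for rec in candidates
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    for name in ("tu", "an", "probe_map", "predicted", "experimental", "truth"):
        paths[name] = str(outdir / f"{name}.tsv")
    return paths
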