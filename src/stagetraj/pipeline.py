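"""End-to-end orchestration: simulate/load -> screen -> trajectory -> enrich -> network.

A single :class:`PipelineConfig` drives every stage. In synthetic mode the
generator produces the expression matrix, annotations and interaction table
from one top-level seed (fanned out per stage, so each stage is individually
reproducible); otherwise the same artifacts are read from the configured
paths. All intermediates are written as plain-text tables under the output
directory and summarized in a single JSON report whose bytes are a pure
function of the config and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as stio
from .design import InvalidDesignError, StageDesign, make_design
from .design import DEFAULT_COUNTS, DEFAULT_LABELS
from .diffexp import screen_transitions
from .enrichment import (
    GeneAnnotation,
    compartment_genes,
    enrichment_table,
    hypergeom_enrich,
)
from .network import (
    SizeGuardError,
    annotate_stage,
    hub_subnetwork,
    induce,
    key_chain,
    mcode_modules,
    modules_table,
    read_interactions,
    write_graphml,
)
from .synthetic import DEFAULT_COMPARTMENTS, simulate_dataset
from .trajectory import build_trajectory, count_table, restrict

#: Direction of the per-transition DE sets that feeds each truth class.
_CLASS_DIRECTION = {"continuous_up": "up", "continuous_down": "down"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    outdir: str = "stagetraj_out"
    seed: int = 0
    synthetic: bool = True

    # input paths (used when synthetic=False)
    expression_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    term_metadata_path: str | None = None
    edges_path: str | None = None

    # design
    stage_labels: tuple[str, ...] = DEFAULT_LABELS
    stage_counts: tuple[int, ...] = DEFAULT_COUNTS

    # differential screen
    alpha: float = 0.05
    fc_threshold: float = 1.0

    # compartments (name -> {"terms": {id: name}, "target_class": ...})
    compartments: dict = field(default_factory=lambda: dict(DEFAULT_COMPARTMENTS))

    # enrichment
    enrichment_namespace: str = "BP"
    correction: str = "bonferroni"

    # network
    channel: str = "experimental"
    min_channel_score: int = 1
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_threshold: float = 0.2
    hub_lo: int = 8
    hub_hi: int = 18
    remove_term: str | None = None

    # synthetic-mode generator parameters
    n_genes: int = 2000
    effect: float = 1.5
    sigma: float = 0.5
    class_fractions: dict = field(
        default_factory=lambda: {"continuous_up": 0.1, "continuous_down": 0.1, "null": 0.8}
    )
    n_modules: int = 3
    module_size: int = 6
    intra_density: float = 0.9
    background_density: float = 0.01

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.stage_labels = tuple(cfg.stage_labels)
        cfg.stage_counts = tuple(cfg.stage_counts)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_labels"] = list(self.stage_labels)
        d["stage_counts"] = list(self.stage_counts)
        return d

    def design(self) -> StageDesign:
        return make_design(self.stage_labels, self.stage_counts)

    def hash(self) -> str:
        """Digest of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """Human-readable problems; empty list iff the config is runnable."""
    problems: list[str] = []
    try:
        config.design()
    except InvalidDesignError as exc:
        problems.append(f"design: {exc}")
    if not 0.0 < config.alpha < 1.0:
        problems.append(f"alpha={config.alpha} outside (0, 1)")
    if config.fc_threshold < 1.0:
        problems.append(f"fc_threshold={config.fc_threshold} below 1")
    if not 0.0 <= config.vwp < 1.0:
        problems.append(f"vwp={config.vwp} outside [0, 1)")
    if config.hub_lo < 0 or config.hub_lo > config.hub_hi:
        problems.append(f"hub degree range [{config.hub_lo}, {config.hub_hi}] invalid")
    if config.correction not in ("bonferroni", "bh"):
        problems.append(f"unknown correction {config.correction!r}")
    if not config.synthetic:
        for name in ("expression_path", "metadata_path", "annotation_path",
                     "term_metadata_path", "edges_path"):
            path = getattr(config, name)
            if path is None:
                problems.append(f"{name} required when synthetic mode is off")
            elif not Path(path).exists():
                problems.append(f"{name}: no such file {path}")
    return problems


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the run report (also written
    to ``<outdir>/report.json``)."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("invalid config: " + "; ".join(problems))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design()

    # ---- data ---------------------------------------------------------
    if config.synthetic:
        ds = simulate_dataset(
            design=design,
            seed=config.seed,
            expression_params=dict(
                n_genes=config.n_genes,
                effect=config.effect,
                sigma=config.sigma,
                class_fractions=config.class_fractions,
            ),
            annotation_params=dict(compartments=config.compartments),
            interaction_params=dict(
                n_modules=config.n_modules,
                module_size=config.module_size,
                intra_density=config.intra_density,
                background_density=config.background_density,
            ),
        )
        datadir = out / "data"
        datadir.mkdir(exist_ok=True)
        stio.write_expression(ds.expression, datadir / "expression.tsv")
        stio.write_metadata(ds.metadata, datadir / "metadata.tsv")
        stio.write_truth(ds.truth, datadir / "truth.tsv")
        stio.write_annotation_pairs(ds.annotation_pairs, datadir / "annotation.tsv")
        stio.write_term_metadata(ds.term_metadata, datadir / "terms.tsv")
        stio.write_interactions(ds.edges, datadir / "edges.tsv")
        expr, meta = ds.expression, ds.metadata
        pairs, term_meta, edge_table = ds.annotation_pairs, ds.term_metadata, ds.edges
    else:
        expr = stio.read_expression(config.expression_path)
        meta = stio.read_metadata(config.metadata_path)
        pairs = stio.read_annotation_pairs(config.annotation_path)
        term_meta = stio.read_term_metadata(config.term_metadata_path)
        edge_table = stio.read_interaction_table(config.edges_path)

    annotation = GeneAnnotation.from_tables(pairs, term_meta)

    # ---- per-transition differential screen ---------------------------
    tables, selections = screen_transitions(
        expr, meta, design, alpha=config.alpha, fc_threshold=config.fc_threshold
    )
    de_counts = {}
    with open(out / "selections.jsonl", "w") as fh:
        for sel, tab in zip(selections, tables):
            name = f"{sel.transition[0]}->{sel.transition[1]}"
            tab.to_csv(out / f"de_{sel.transition[0]}_{sel.transition[1]}.tsv",
                       sep="\t", index=False, float_format=stio.FLOAT_FORMAT)
            fh.write(json.dumps({
                "transition": list(sel.transition),
                "up": sorted(sel.up),
                "down": sorted(sel.down),
                "alpha": sel.alpha,
                "fc_threshold": sel.fc_threshold,
            }, sort_keys=True) + "\n")
            de_counts[name] = {"up": len(sel.up), "down": len(sel.down)}

    # ---- trajectories and compartment filtering -----------------------
    stage_labels = design.labels[1:]
    trajectories = {
        "up": build_trajectory([s.up for s in selections], stage_labels, "up"),
        "down": build_trajectory([s.down for s in selections], stage_labels, "down"),
    }
    background = frozenset(expr.index) & frozenset(annotation.gene_terms)
    comp_genes = compartment_genes(annotation, config.compartments)

    trajectory_tables = []
    enrichment_top: dict[str, Any] = {}
    network_report: dict[str, Any] = {}
    graph_full = read_interactions(
        edge_table, channel=config.channel, min_channel_score=config.min_channel_score
    )

    for comp in sorted(config.compartments):
        direction = _CLASS_DIRECTION[config.compartments[comp]["target_class"]]
        traj = restrict(trajectories[direction], comp_genes[comp])
        tab = count_table(traj)
        tab.insert(0, "compartment", comp)
        trajectory_tables.append(tab)
        for label, gene_set in zip(traj.stage_labels, traj.continuing):
            _write_genes(out / f"genes_{comp}_continuing_{label}.txt", gene_set)
        for label, gene_set in zip(traj.stage_labels, traj.deviated):
            _write_genes(out / f"genes_{comp}_deviated_{label}.txt", gene_set)

        # enrichment of each non-empty deviated set
        enrichment_top[comp] = {}
        for label, dev in zip(traj.stage_labels, traj.deviated):
            study = frozenset(dev) & background
            if not study:
                continue
            results = hypergeom_enrich(
                study, background, annotation,
                namespace=config.enrichment_namespace, correction=config.correction,
            )
            etab = enrichment_table(results)
            etab.to_csv(out / f"enrichment_{comp}_{label}.tsv", sep="\t",
                        index=False, float_format=stio.FLOAT_FORMAT)
            if results:
                top = results[0]
                enrichment_top[comp][label] = {
                    "term": top.term, "name": top.name,
                    "p": top.p, "p_adj": top.p_adj, "fold": top.fold,
                }

        # network analysis on all genes ever continuing in this compartment
        graph = induce(graph_full, traj.continuing[0] if traj.continuing else set())
        if config.remove_term:
            from .network import remove_term_nodes

            graph = remove_term_nodes(graph, annotation, config.remove_term)
        modules = mcode_modules(
            graph, vwp=config.vwp, haircut=config.haircut,
            fluff=config.fluff, fluff_threshold=config.fluff_threshold,
        )
        modules_table(modules).to_csv(out / f"modules_{comp}.tsv", sep="\t",
                                      index=False, float_format=stio.FLOAT_FORMAT)
        hub = hub_subnetwork(graph, config.hub_lo, config.hub_hi)
        chain: list[str] | None
        note = None
        if hub.graph.number_of_nodes() == 0:
            chain, note = None, "no node in the hub degree range"
        else:
            try:
                chain = key_chain(hub)
            except SizeGuardError as exc:
                chain, note = None, str(exc)
        if chain:
            pd.DataFrame({"order": range(1, len(chain) + 1), "gene": chain}).to_csv(
                out / f"chain_{comp}.tsv", sep="\t", index=False
            )
        annotated = annotate_stage(graph, traj)
        for v in annotated.nodes:
            annotated.nodes[v]["degree"] = graph.degree(v)
            annotated.nodes[v]["hub"] = v in hub.parent_degree
        for rank, mod in enumerate(modules, start=1):
            for v in mod.members:
                if v in annotated:
                    annotated.nodes[v]["module_rank"] = rank
        write_graphml(annotated, out / f"network_{comp}.graphml")

        network_report[comp] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "modules": [
                {"rank": i + 1, "score": m.score, "size": m.size, "seed": m.seed}
                for i, m in enumerate(modules[:5])
            ],
            "n_hubs": hub.graph.number_of_nodes(),
            "hub_degree_range": [config.hub_lo, config.hub_hi],
            "key_chain": chain,
            "key_chain_note": note,
        }

    traj_table = pd.concat(trajectory_tables, ignore_index=True)
    traj_table.to_csv(out / "trajectory_counts.tsv", sep="\t", index=False)

    report: dict[str, Any] = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "n_genes": int(len(expr)),
            "n_samples": int(expr.shape[1]),
        },
        "de_counts": de_counts,
        "trajectory": {
            comp: _records(tab.drop(columns="compartment"))
            for comp, tab in zip(sorted(config.compartments), trajectory_tables)
        },
        "enrichment_top": enrichment_top,
        "network": network_report,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return report


def _records(tab: pd.DataFrame) -> list[dict]:
    t = tab.astype(object)
    return t.where(t.notna(), None).to_dict("records")


def _write_genes(path: Path, genes) -> None:
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))


def _jsonable(obj):
    if obj is pd.NA:
        return None
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {obj!r}")
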