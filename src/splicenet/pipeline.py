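"""End-to-end orchestration: configuration, stage execution, run manifests.

A single flat configuration (YAML or dict) drives the whole pipeline:
either paths to real inputs (expression TSV, metadata, panel, probe map,
GMT, edge list) or a synthetic block describing a planted design.  Stages
run in order — simulate/load, preprocess, differential expression,
enrichment, network topology — and every stage logs its input/output
counts into a JSON run manifest.  A failing stage aborts the run with the
stage named; partial outputs are kept next to a FAILED marker.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .design import STATES, STUDY_CONTRASTS, TABLE1_GROUP_SIZES, TISSUES
from .differential import (
    deg_sets,
    pairwise_fold_changes,
    select_degs,
    two_way_anova,
    venn_partition,
)
from .enrichment import fisher_overrepresentation
from .network import (
    build_first_order_network,
    classify_topology,
    compare_clusters,
    filter_interactome,
)
from .preprocess import collapse_probes, filter_panel, normalize_matrix
from .synthetic import (
    DesignSpec,
    PlantedEffect,
    plant_interaction_effect,
    plant_state_effect,
    plant_tissue_effect,
    simulate_annotations,
    simulate_expression,
    simulate_interactome,
)
from .preprocess import GenePanel

log = logging.getLogger(__name__)

REAL_INPUT_KEYS = ("matrix", "metadata", "panel", "probe_map", "gmt", "edges")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Flat configuration for a full run; CLI flags override these fields."""

    out_dir: Path
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    alpha: float = 0.05
    fc_cut: float = 2.0
    top_fraction: float = 0.15
    ss_type: int = 3
    gating: str = "effect"
    sd_sample: bool = False
    percentile_shift: float | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' and 'inputs' must be given")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.fc_cut < 1:
            raise ValueError("fc_cut must be >= 1")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.inputs is not None:
            missing = [k for k in ("matrix", "metadata", "probe_map")
                       if k not in self.inputs]
            if missing:
                raise ValueError(f"inputs block missing required fields: {missing}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any], out_dir=None) -> "PipelineConfig":
        data = dict(data)
        if out_dir is not None:
            data["out_dir"] = out_dir
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path, out_dir=None) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data, out_dir=out_dir)

    def to_jsonable(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["out_dir"] = str(d["out_dir"])
        return d


def _planted_effect_from_dict(entry: Mapping[str, Any]) -> PlantedEffect:
    kind = entry.get("kind")
    gene = int(entry["gene"])
    shift = float(entry.get("shift", 2.0))
    if kind == "state_main":
        return plant_state_effect(gene, entry.get("state", "SALS1"), shift)
    if kind == "tissue_main":
        return plant_tissue_effect(gene, entry.get("tissue", TISSUES[0]), shift)
    if kind == "interaction":
        return plant_interaction_effect(gene, shift)
    raise ValueError(f"unknown planted effect kind {kind!r}")


def _group_sizes_from_block(block: Mapping | None) -> dict:
    if block is None:
        return dict(TABLE1_GROUP_SIZES)
    return {(t, s): int(n) for t, states in block.items() for s, n in states.items()}


def spec_from_config(block: Mapping[str, Any], seed: int) -> DesignSpec:
    """Build a DesignSpec from the 'synthetic' config block."""
    effects = [_planted_effect_from_dict(e) for e in block.get("effects", [])]
    return DesignSpec(
        n_genes=int(block["n_genes"]),
        probes_per_gene=int(block.get("probes_per_gene", 1)),
        group_sizes=_group_sizes_from_block(block.get("group_sizes")),
        baseline_log2_mean=float(block.get("baseline_log2_mean", 8.0)),
        noise_sd_log2=float(block.get("noise_sd_log2", 0.5)),
        planted_effects=effects,
        seed=seed,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all artifacts under ``config.out_dir``."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "software": "splicenet",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    stage = "configure"
    try:
        stage = "inputs"
        raw, metadata, probe_map, panel, annotations, interactome = _load_inputs(
            config, out
        )
        manifest["stages"][stage] = {
            "n_probes": raw.shape[0],
            "n_samples": raw.shape[1],
            "n_panel_genes": len(panel) if panel else None,
            "n_terms": len(annotations) if annotations else None,
            "n_edges": len(interactome.edges) if interactome else None,
        }

        stage = "preprocess"
        normalized = normalize_matrix(raw, percentile_shift=config.percentile_shift)
        if panel is not None:
            normalized = filter_panel(normalized, panel, probe_map)
        gene_matrix = collapse_probes(normalized, probe_map)
        pio.write_expression_tsv(normalized, out / "normalized_matrix.tsv")
        pio.write_expression_tsv(gene_matrix, out / "gene_matrix.tsv")
        manifest["stages"][stage] = {
            "n_probes_retained": normalized.shape[0],
            "n_genes": gene_matrix.shape[0],
        }

        stage = "differential"
        anova = two_way_anova(gene_matrix, metadata, ss_type=config.ss_type)
        pairwise = pairwise_fold_changes(gene_matrix, metadata)
        selected = select_degs(anova, pairwise, alpha=config.alpha,
                               fc_cut=config.fc_cut, gating=config.gating)
        degs = deg_sets(selected)
        pio.write_table(anova, out / "anova.tsv")
        pio.write_table(selected, out / "pairwise.tsv", index=False)
        deg_dir = out / "degs"
        deg_dir.mkdir(exist_ok=True)
        for cid in sorted(degs):
            sub = selected[(selected["contrast_id"] == cid)
                           & selected["passes_threshold"]]
            pio.write_table(
                sub[["gene_id", "log2_fc", "direction"]], deg_dir / f"{cid}.tsv",
                index=False,
            )
        effect_sets = {
            "state": set(anova.index[anova["q_state"] < config.alpha]),
            "tissue": set(anova.index[anova["q_tissue"] < config.alpha]),
            "interaction": set(anova.index[anova["q_interaction"] < config.alpha]),
        }
        pio.write_table(venn_partition(effect_sets).to_frame(),
                        out / "venn_effects.tsv", index=False)
        for kind in ("state", "tissue"):
            named = {c.contrast_id: degs.get(c.contrast_id, set())
                     for c in STUDY_CONTRASTS if c.kind == kind}
            pio.write_table(venn_partition(named).to_frame(),
                            out / f"venn_{kind}_contrasts.tsv", index=False)
        manifest["stages"][stage] = {
            "n_significant_any_effect": len(set().union(*effect_sets.values())),
            "n_degs_per_contrast": {c: len(s) for c, s in sorted(degs.items())},
        }

        stage = "enrichment"
        enr_counts = {}
        if annotations is not None:
            enr_dir = out / "enrichment"
            enr_dir.mkdir(exist_ok=True)
            universe = set(gene_matrix.row_ids) & set(annotations.universe)
            for cid, genes in sorted(degs.items()):
                listed = genes & universe
                if not listed:
                    log.warning("contrast %s: no DEGs in the annotation universe; "
                                "skipping enrichment", cid)
                    continue
                directions = _deg_direction_map(selected, cid)
                table = fisher_overrepresentation(
                    listed, annotations, deg_directions=directions,
                    universe=universe,
                )
                pio.write_table(table, enr_dir / f"{cid}.tsv", index=False)
                enr_counts[cid] = int((table["p_bonferroni"] < config.alpha).sum())
        manifest["stages"][stage] = {"n_significant_terms": enr_counts}

        stage = "network"
        topo_by_contrast: dict[str, pd.DataFrame] = {}
        if interactome is not None:
            net_dir = out / "networks"
            net_dir.mkdir(exist_ok=True)
            filtered = filter_interactome(interactome, config.top_fraction)
            pio.write_edge_list_tsv(filtered, net_dir / "filtered_interactome.tsv")
            for con in STUDY_CONTRASTS:
                if con.kind != "state":
                    continue
                genes = degs.get(con.contrast_id, set())
                seed_fc = _deg_direction_map(selected, con.contrast_id)
                seed_fc = {g: fc for g, fc in seed_fc.items() if g in genes}
                if not seed_fc:
                    log.warning("contrast %s: no DEG seeds; skipping network",
                                con.contrast_id)
                    continue
                present = [g for g in seed_fc if g in set(filtered.nodes)]
                if not present:
                    log.warning("contrast %s: no seed maps into the filtered "
                                "interactome; skipping network", con.contrast_id)
                    continue
                net = build_first_order_network(seed_fc, filtered)
                topo = classify_topology(net, sd_sample=config.sd_sample)
                topo_by_contrast[con.contrast_id] = topo
                pio.write_graphml(net, net_dir / f"{con.contrast_id}.graphml")
                pio.write_sif(net, net_dir / f"{con.contrast_id}.sif")
                pio.write_table(topo, net_dir / f"{con.contrast_id}_topology.tsv")
            cmp_dir = out / "comparisons"
            cmp_dir.mkdir(exist_ok=True)
            for tissue, (ca, cb) in {
                "cortex": ("cortex_SALS1_vs_cortex_CTRL", "cortex_SALS2_vs_cortex_CTRL"),
                "spinal": ("spinal_SALS1_vs_spinal_CTRL", "spinal_SALS2_vs_spinal_CTRL"),
            }.items():
                if ca in topo_by_contrast and cb in topo_by_contrast:
                    comparison = compare_clusters(
                        topo_by_contrast[ca], topo_by_contrast[cb],
                        labels=("SALS1", "SALS2"),
                    )
                    pio.write_table(comparison.table,
                                    cmp_dir / f"{tissue}_topology_classes.tsv",
                                    index=False)
        manifest["stages"][stage] = {
            "networks_built": sorted(topo_by_contrast),
            "n_hub_bottlenecks": {
                c: int((t["node_class"] == "hub_bottleneck").sum())
                for c, t in sorted(topo_by_contrast.items())
            },
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _deg_direction_map(selected: pd.DataFrame, contrast_id: str) -> dict:
    sub = selected[selected["contrast_id"] == contrast_id]
    return dict(zip(sub["gene_id"], sub["log2_fc"].astype(float)))


def _load_inputs(config: PipelineConfig, out: Path):
    """Simulate (writing the inputs for provenance) or read real input files."""
    if config.synthetic is not None:
        block = dict(config.synthetic)
        spec = spec_from_config(block, config.seed)
        dataset = simulate_expression(spec)
        genes = dataset.gene_ids
        panel_ids = block.get("panel")
        panel = (GenePanel.from_iterable(spec.gene_label(int(g)) for g in panel_ids)
                 if panel_ids else GenePanel.from_iterable(genes))
        ann_block = block.get("annotations")
        annotations = None
        if ann_block:
            planted = ann_block.get("planted_term")
            planted_term = None
            if planted:
                planted_term = (
                    planted["name"],
                    [spec.gene_label(int(g)) for g in planted["members"]],
                )
            annotations = simulate_annotations(
                genes, int(ann_block.get("n_terms", 20)),
                planted_term=planted_term,
                seed=config.seed + 1,
            )
        net_block = block.get("interactome")
        interactome = None
        if net_block:
            interactome = simulate_interactome(
                n_nodes=int(net_block.get("n_nodes", spec.n_genes)),
                edges_per_new_node=int(net_block.get("edges_per_new_node", 2)),
                planted_hubs=[int(h) for h in net_block.get("planted_hubs", [])],
                seed=config.seed + 2,
                labels=genes if int(net_block.get("n_nodes", spec.n_genes)) == spec.n_genes else None,
            )
        inputs_dir = out / "inputs"
        inputs_dir.mkdir(parents=True, exist_ok=True)
        pio.write_expression_tsv(dataset.matrix, inputs_dir / "expression.tsv")
        pio.write_metadata_tsv(dataset.metadata, inputs_dir / "metadata.tsv")
        pio.write_probe_map_tsv(dataset.probe_map, inputs_dir / "probe_map.tsv")
        pio.write_panel(panel, inputs_dir / "panel.txt")
        pio.write_table(dataset.truth, inputs_dir / "truth.tsv")
        if annotations is not None:
            pio.write_gmt(annotations, inputs_dir / "annotations.gmt")
        if interactome is not None:
            pio.write_edge_list_tsv(interactome, inputs_dir / "interactome.tsv")
        return (dataset.matrix, dataset.metadata, dataset.probe_map, panel,
                annotations, interactome)

    paths = config.inputs
    raw = pio.read_expression_tsv(paths["matrix"])
    metadata = pio.read_metadata_tsv(paths["metadata"])
    probe_map = pio.read_probe_map_tsv(paths["probe_map"])
    panel = pio.read_panel(paths["panel"]) if paths.get("panel") else None
    annotations = pio.read_gmt(paths["gmt"]) if paths.get("gmt") else None
    interactome = (pio.read_edge_list_tsv(paths["edges"])
                   if paths.get("edges") else None)
    return raw, metadata, probe_map, panel, annotations, interactome
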