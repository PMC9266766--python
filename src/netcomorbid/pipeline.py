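"""Config-driven end-to-end analysis run.

Reproduces the full comparison flow between condition gene networks and a
set of target proteins against a global interactome: load → simple
projection → network summaries → hub tables (betweenness, CTS) →
per-(network, target) interactor-overlap enrichment → crosstabs → feedback
loops → pairwise intersections and Venn partition → optional term
enrichment.  The run is deterministic: re-running with the same inputs and
seed produces byte-identical reports, and the provenance block records the
hashes needed to verify that.

All computation happens in memory first; outputs are written only after
every stage succeeds, so a failed run leaves no partial files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator

from . import __version__
from .crosstalk import (
    build_crosstab,
    distinct_gene_count,
    find_feedback_loops,
    target_relation_categories,
    venn_partition,
)
from .enrichment import interactor_enrichment, term_enrichment
from .model import (
    GeneNetwork,
    read_association_table,
    read_edge_table,
    read_gene_list,
    read_term_annotation,
    project_simple,
)
from .topology import betweenness, crosstalk_specificity, hub_ranking, network_summary

__all__ = ["ConditionNetworkSpec", "GeneSetSpec", "PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage failure; the message names the stage and the offending input."""


class ConditionNetworkSpec(BaseModel):
    name: str
    network: Path
    association_table: Optional[Path] = None


class GeneSetSpec(BaseModel):
    name: str
    path: Path


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-friendly)."""

    global_network: Path
    condition_networks: list[ConditionNetworkSpec] = Field(default_factory=list)
    targets: list[str] = Field(default_factory=list)
    gene_sets: list[GeneSetSpec] = Field(default_factory=list)
    annotation: Optional[Path] = None
    universe: Optional[int] = None
    fdr_threshold: float = 0.05
    top_k: int = 10
    loop_max_len: int = 3
    out_dir: Path = Path("netcomorbid_out")
    seed: int = 0

    @field_validator("fdr_threshold")
    @classmethod
    def _fdr_in_unit_interval(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError(f"fdr_threshold must lie in (0, 1), got {v}")
        return v

    @field_validator("loop_max_len")
    @classmethod
    def _loop_len(cls, v: int) -> int:
        if v not in (2, 3):
            raise ValueError(f"loop_max_len must be 2 or 3, got {v}")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def input_paths(self) -> list[Path]:
        paths = [self.global_network]
        for spec in self.condition_networks:
            paths.append(spec.network)
            if spec.association_table is not None:
                paths.append(spec.association_table)
        paths.extend(s.path for s in self.gene_sets)
        if self.annotation is not None:
            paths.append(self.annotation)
        return paths

    def validate_paths(self) -> None:
        missing = [str(p) for p in self.input_paths() if not Path(p).is_file()]
        if missing:
            raise PipelineError(f"stage=validate: missing input files: {missing}")


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_network(path: Path, name: str) -> GeneNetwork:
    with open(path, encoding="utf-8") as fh:
        return read_edge_table(fh, dialect="tsv", name=name)


def _summary_dict(s) -> dict:
    return {
        "n_nodes": s.n_nodes,
        "n_interactions": s.n_interactions,
        "n_pairs": s.n_pairs,
        "avg_neighbors": s.avg_neighbors,
        "density": s.density,
        "centralization": s.centralization,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write ``report.json`` plus per-table TSVs.

    Returns the report as a dictionary.  Any stage error raises
    :class:`PipelineError` naming the stage before anything is written.
    """
    config.validate_paths()
    report: dict = {
        "summaries": {},
        "hubs": {},
        "enrichment": {},
        "skipped_targets": [],
        "crosstabs": {},
        "loops": {},
        "intersections": {},
        "venn": None,
        "term_enrichment": {},
    }
    sidecars: dict[str, str] = {}

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage={name}: {exc}") from exc
                return False

        return _Ctx()

    with stage("load"):
        global_net = _load_network(config.global_network, "global")
        global_simple = project_simple(global_net)
        condition_nets: dict[str, GeneNetwork] = {}
        assoc_tables = {}
        for spec in config.condition_networks:
            condition_nets[spec.name] = _load_network(spec.network, spec.name)
            if spec.association_table is not None:
                with open(spec.association_table, encoding="utf-8") as fh:
                    assoc_tables[spec.name] = read_association_table(fh, condition=spec.name)
        gene_sets = {}
        for spec in config.gene_sets:
            with open(spec.path, encoding="utf-8") as fh:
                gene_sets[spec.name] = read_gene_list(fh)

    with stage("summaries"):
        report["summaries"]["global"] = _summary_dict(network_summary(global_net))
        for name, net in condition_nets.items():
            report["summaries"][name] = _summary_dict(network_summary(net))

    with stage("hubs"):
        for name, net in condition_nets.items():
            simple = project_simple(net)
            bw = betweenness(simple)
            entry = {
                "betweenness_top": hub_ranking(bw, config.top_k),
                "cts_top": [],
            }
            if simple.nodes <= global_simple.nodes and simple.pairs <= global_simple.pairs:
                cts = crosstalk_specificity(simple, global_simple)
                entry["cts_top"] = hub_ranking(cts, config.top_k)
                sidecars[f"nodes_{name}.tsv"] = _per_node_tsv(simple, bw, cts)
            else:
                sidecars[f"nodes_{name}.tsv"] = _per_node_tsv(simple, bw, [])
            report["hubs"][name] = entry

    with stage("enrichment"):
        universe = config.universe if config.universe is not None else "from_global"
        for name, net in condition_nets.items():
            for target in config.targets:
                tgt = target.upper()
                if tgt not in global_net.nodes:
                    report["skipped_targets"].append(
                        {"network": name, "target": tgt, "reason": "absent from global network"}
                    )
                    continue
                res = interactor_enrichment(net, tgt, global_net, universe_size=universe)
                report["enrichment"][f"{name}|{tgt}"] = {
                    "universe_size": res.universe_size,
                    "category_size": res.category_size,
                    "sample_size": res.sample_size,
                    "overlap": res.overlap,
                    "p_value": res.p_value,
                    "log10_p": res.log10_p,
                }

    with stage("crosstabs"):
        for name, table in assoc_tables.items():
            net = condition_nets[name]
            for target in config.targets:
                tgt = target.upper()
                if tgt not in global_net.nodes:
                    continue
                relations = target_relation_categories(global_net, tgt)
                shared = {
                    g: cats for g, cats in relations.items() if g in net.nodes
                }
                if not shared:
                    continue
                ct = build_crosstab(table, shared, target=tgt)
                key = f"{name}|{tgt}"
                report["crosstabs"][key] = {
                    "distinct_genes": distinct_gene_count(ct),
                    "cells": {
                        f"{r.value}|{c.value}": sorted(genes)
                        for (r, c), genes in sorted(
                            ct.cells.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
                        )
                    },
                }
                sidecars[f"crosstab_{name}_{tgt}.tsv"] = ct.to_dataframe().to_csv(sep="\t")

    with stage("loops"):
        for name, net in condition_nets.items():
            loops = find_feedback_loops(net, max_len=config.loop_max_len)
            report["loops"][name] = [
                {
                    "cycle": list(l.cycle),
                    "signs": [s.value for s in l.edge_signs],
                    "loop_sign": l.loop_sign,
                }
                for l in loops
            ]

    with stage("intersections"):
        labeled = {name: set(net.nodes) for name, net in condition_nets.items()}
        labeled.update({name: set(genes) for name, genes in gene_sets.items()})
        names = sorted(labeled)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                common = sorted(labeled[a] & labeled[b])
                report["intersections"][f"{a}&{b}"] = {
                    "count": len(common),
                    "genes": common,
                }
        if len(labeled) >= 2:
            vp = venn_partition(labeled)
            report["venn"] = {
                "&".join(sorted(key)): sorted(genes)
                for key, genes in sorted(
                    vp.regions.items(), key=lambda kv: sorted(kv[0])
                )
            }

    with stage("term_enrichment"):
        if config.annotation is not None:
            with open(config.annotation, encoding="utf-8") as fh:
                annot = read_term_annotation(fh)
            for name, net in condition_nets.items():
                query = net.nodes & annot.universe
                if not query:
                    continue
                records = term_enrichment(
                    query, annot, fdr_threshold=config.fdr_threshold
                )
                report["term_enrichment"][name] = [
                    {
                        "term": r.term,
                        "category_size": r.category_size,
                        "overlap": r.overlap,
                        "p_value": r.p_value,
                        "q_value": r.q_value,
                        "significant": r.significant,
                    }
                    for r in records
                ]

    with stage("provenance"):
        config_payload = json.loads(config.model_dump_json())
        report["provenance"] = {
            "version": __version__,
            "seed": config.seed,
            "config": config_payload,
            "input_hashes": {
                str(p): _sha256_file(Path(p)) for p in sorted(map(str, config.input_paths()))
            },
        }
        report["provenance"]["config_hash"] = hashlib.sha256(
            json.dumps(config_payload, sort_keys=True).encode()
        ).hexdigest()

    with stage("write"):
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        for fname, text in sidecars.items():
            (out / fname).write_text(text, encoding="utf-8")

    return report


def _per_node_tsv(simple, bw_records, cts_records) -> str:
    cts_by_gene = {r.gene: r for r in cts_records}
    deg = simple.degrees()
    lines = ["gene\tdegree\tbetweenness_raw\tbetweenness_norm\tK\tM\tcts"]
    for r in bw_records:
        cts = cts_by_gene.get(r.gene)
        lines.append(
            "\t".join(
                [
                    r.gene,
                    str(deg[r.gene]),
                    f"{r.betweenness_raw:.6g}",
                    f"{r.betweenness_normalized:.6g}",
                    str(cts.K) if cts else "",
                    str(cts.M) if cts else "",
                    f"{cts.cts:.6g}" if cts else "",
                ]
            )
        )
    return "\n".join(lines) + "\n"
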