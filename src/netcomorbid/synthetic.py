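"""Seeded generators for interactome-like fixtures with ground-truth manifests.

Every generator draws from its own named pseudo-random stream derived from a
single integer seed, so adding a generator never perturbs fixtures produced
by another, and identical ``(arguments, seed)`` yield byte-identical files.
Each planted quantity (simple-pair count, module category tallies, target
interactor counts K and k, hub identity, signed loops) is recorded in a
manifest and is exactly recoverable by the corresponding analysis operation
— the parameter-recovery loop is the core validation surface of the whole
package.

The global generator produces a heavy-tailed (preferential-attachment)
degree sequence, matching the hub-dominated structure of text-mined human
interactomes, and layers typed relations (interaction, association,
expression/activity regulation, transport, degradation) over the simple
pairs, including parallel typed edges on a fraction of pairs so that
interaction counts exceed pair counts as they do in real reconstructions.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .model import (
    ConditionAssociationTable,
    ConditionCategory,
    GeneNetwork,
    NetworkValidationError,
    Relation,
    Sign,
    TypedEdge,
    write_association_table,
    write_network,
)

__all__ = [
    "GeneratorManifest",
    "generate_global",
    "plant_condition_module",
    "plant_enriched_target",
    "plant_loops",
    "plant_hub",
    "null_enrichment_pvalues",
    "paper_hg_preset",
    "write_preset",
    "DEFAULT_TYPE_MIXTURE",
]

#: Default relation mixture over typed edges: physical interactions dominate
#: text-mined interactomes, followed by associations and expression control.
DEFAULT_TYPE_MIXTURE: dict[Relation, float] = {
    Relation.INTERACTION: 0.50,
    Relation.ASSOCIATION: 0.15,
    Relation.EXPRESSION_UP: 0.12,
    Relation.EXPRESSION_DOWN: 0.08,
    Relation.ACTIVITY_UP: 0.05,
    Relation.ACTIVITY_DOWN: 0.04,
    Relation.TRANSPORT: 0.03,
    Relation.DEGRADATION: 0.03,
}

#: Fraction of simple pairs carrying a second, parallel typed edge.
_DUPLICATE_EDGE_RATE = 0.15


def _rng(seed: int, stream: str) -> np.random.Generator:
    """One independent generator per (seed, named stream)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(stream.encode()),))
    )


@dataclass
class GeneratorManifest:
    """Ground truth for everything a generator planted."""

    seed: int
    global_spec: dict = field(default_factory=dict)
    modules: list[dict] = field(default_factory=list)
    targets: list[dict] = field(default_factory=list)
    loops: list[dict] = field(default_factory=list)
    hubs: list[dict] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "global_spec": self.global_spec,
                "modules": self.modules,
                "targets": self.targets,
                "loops": self.loops,
                "hubs": self.hubs,
            },
            indent=indent,
            sort_keys=True,
        )


def _gene_symbols(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_global(
    n_genes: int,
    mean_degree: float,
    type_mixture: Mapping[Relation, float] | None = None,
    seed: int = 0,
    name: str = "global",
) -> tuple[GeneNetwork, GeneratorManifest]:
    """Heavy-tailed typed multigraph over ``n_genes`` genes.

    The simple-pair skeleton is a Barabási–Albert preferential-attachment
    graph with ``m = round(mean_degree / 2)`` attachments, giving a realized
    mean simple degree close to ``mean_degree``; typed edges are drawn from
    ``type_mixture`` with random orientations, and a fraction of pairs
    receive a second parallel typed edge.  Deterministic given ``seed``.
    """
    if n_genes < 10:
        raise NetworkValidationError(f"n_genes must be >= 10, got {n_genes}")
    if not 0 < mean_degree < n_genes - 1:
        raise NetworkValidationError(
            f"mean_degree must lie in (0, n_genes - 1), got {mean_degree}"
        )
    mixture = dict(type_mixture or DEFAULT_TYPE_MIXTURE)
    total = sum(mixture.values())
    if total <= 0:
        raise NetworkValidationError("type mixture weights must sum to > 0")
    relations = list(mixture)
    weights = np.array([mixture[r] for r in relations], dtype=float) / total

    rng = _rng(seed, "global")
    m = max(1, int(round(mean_degree / 2)))
    skeleton = nx.barabasi_albert_graph(n_genes, m, seed=int(rng.integers(2**31)))
    symbols = _gene_symbols(n_genes)
    pairs = sorted(
        (symbols[min(u, v)], symbols[max(u, v)]) for u, v in skeleton.edges()
    )

    net = GeneNetwork(name=name, nodes=symbols)
    n_pairs = len(pairs)
    rel_idx = rng.choice(len(relations), size=n_pairs, p=weights)
    flips = rng.random(n_pairs) < 0.5
    dup_mask = rng.random(n_pairs) < _DUPLICATE_EDGE_RATE
    dup_idx = rng.choice(len(relations), size=n_pairs, p=weights)

    def make_edge(a: str, b: str, relation: Relation, flip: bool) -> TypedEdge:
        if relation in (Relation.INTERACTION, Relation.ASSOCIATION):
            return TypedEdge(a, b, relation, directed=False)
        src, tgt = (b, a) if flip else (a, b)
        return TypedEdge(src, tgt, relation, directed=True)

    for i, (a, b) in enumerate(pairs):
        net.add_edge(make_edge(a, b, relations[rel_idx[i]], bool(flips[i])))
        if dup_mask[i] and relations[dup_idx[i]] != relations[rel_idx[i]]:
            # same orientation as the primary edge: parallel relations on a
            # pair never create an artificial 2-cycle
            net.add_edge(make_edge(a, b, relations[dup_idx[i]], bool(flips[i])))

    manifest = GeneratorManifest(seed=seed)
    manifest.global_spec = {
        "name": name,
        "n_genes": n_genes,
        "mean_degree_requested": mean_degree,
        "mean_degree_realized": 2 * n_pairs / n_genes,
        "n_pairs": n_pairs,
        "n_interactions": net.n_interactions,
        "type_mixture": {r.value: mixture[r] / total for r in relations},
    }
    return net, manifest


def plant_condition_module(
    global_net: GeneNetwork,
    size: int,
    category_counts: Mapping[ConditionCategory | str, int] | Sequence[int],
    seed: int = 0,
    condition: str = "condition",
) -> tuple[ConditionAssociationTable, GeneNetwork, dict]:
    """Sample a condition module and assign relation categories exactly.

    ``category_counts`` maps the four informative categories to gene counts
    (a bare sequence is read as up/down/pro/anti); any remainder of the
    module falls into ``other``.  Categories are assigned to disjoint random
    slices so the emitted tallies equal the request exactly.  Returns the
    association table, the induced subnetwork, and the manifest entry.
    """
    if isinstance(category_counts, Mapping):
        counts = {ConditionCategory(c): int(v) for c, v in category_counts.items()}
    else:
        keys = [
            ConditionCategory.UPREGULATED_BY_CONDITION,
            ConditionCategory.DOWNREGULATED_BY_CONDITION,
            ConditionCategory.PRO_CONDITION_ACTIVITY,
            ConditionCategory.ANTI_CONDITION_ACTIVITY,
        ]
        if len(category_counts) != 4:
            raise NetworkValidationError(
                "positional category_counts must be (up, down, pro, anti)"
            )
        counts = dict(zip(keys, (int(v) for v in category_counts)))
    counts.pop(ConditionCategory.OTHER, None)
    if any(v < 0 for v in counts.values()):
        raise NetworkValidationError("category counts must be non-negative")
    if size > global_net.n_nodes:
        raise NetworkValidationError(
            f"module size {size} exceeds network size {global_net.n_nodes}"
        )
    assigned = sum(counts.values())
    if assigned > size:
        raise NetworkValidationError(
            f"category counts sum to {assigned} > module size {size}"
        )

    rng = _rng(seed, "module")
    members = sorted(global_net.nodes)
    module = [members[i] for i in rng.choice(len(members), size=size, replace=False)]
    rng.shuffle(module)

    table = ConditionAssociationTable(condition=condition)
    cursor = 0
    for cat in sorted(counts, key=lambda c: c.value):
        for g in module[cursor : cursor + counts[cat]]:
            table.add(g, cat)
        cursor += counts[cat]
    for g in module[cursor:]:
        table.add(g, ConditionCategory.OTHER)

    subnet = global_net.subnetwork(module, name=f"{condition}|module")
    entry = {
        "condition": condition,
        "size": size,
        "category_counts": {c.value: counts.get(c, 0) for c in counts},
        "n_other": size - assigned,
        "members": sorted(module),
    }
    return table, subnet, entry


def plant_enriched_target(
    global_net: GeneNetwork,
    module_genes: Sequence[str],
    K: int,
    k: int,
    seed: int = 0,
    target_symbol: str = "TARGET1",
) -> tuple[GeneNetwork, dict]:
    """Wire a fresh target gene to exactly ``k`` module and ``K - k`` outside genes.

    The returned network is a copy of ``global_net`` plus the target and its
    ``K`` interaction edges; the manifest entry records (target, K, k).
    """
    module = sorted({g.upper() for g in module_genes})
    missing = set(module) - global_net.nodes
    if missing:
        raise NetworkValidationError(f"module genes absent from network: {sorted(missing)[:5]}")
    if target_symbol.upper() in global_net.nodes:
        raise NetworkValidationError(f"target symbol {target_symbol} already in network")
    if k > min(K, len(module)):
        raise NetworkValidationError(f"k ({k}) exceeds min(K={K}, module={len(module)})")
    outside = sorted(global_net.nodes - set(module))
    if K - k > len(outside):
        raise NetworkValidationError(
            f"K - k ({K - k}) exceeds available outside genes ({len(outside)})"
        )

    rng = _rng(seed, "target")
    inside = [module[i] for i in rng.choice(len(module), size=k, replace=False)]
    out_pick = [outside[i] for i in rng.choice(len(outside), size=K - k, replace=False)]

    net = global_net.copy()
    net.add_node(target_symbol)
    for g in sorted(inside) + sorted(out_pick):
        net.add_edge(TypedEdge(target_symbol, g, Relation.INTERACTION, directed=False))
    entry = {
        "target": target_symbol.upper(),
        "K": K,
        "k": k,
        "inside": sorted(inside),
    }
    return net, entry


def plant_loops(
    net: GeneNetwork,
    cycles: Sequence[tuple[Sequence[str], Sequence[str]]],
    seed: int = 0,
) -> tuple[GeneNetwork, list[dict]]:
    """Add signed directed regulatory cycles (length 2 or 3).

    Each cycle is ``(genes, signs)`` with signs ``"+"``/``"-"`` per step
    ``genes[i] -> genes[i + 1 mod len]``.  Requesting the same ordered pair
    with opposite signs (within the batch or against an existing signed
    regulatory arc) is an error.  Returns the modified copy and the manifest
    entries with canonical cycles.
    """
    sign_map = {"+": Sign.POSITIVE, "-": Sign.NEGATIVE}
    requested: dict[tuple[str, str], Sign] = {}
    for e in net.edges:
        if e.directed and e.sign is not Sign.NONE:
            requested[(e.source, e.target)] = e.sign

    out = net.copy()
    entries = []
    for genes, signs in cycles:
        genes = [g.upper() for g in genes]
        if not 2 <= len(genes) <= 3:
            raise NetworkValidationError(f"cycle length must be 2 or 3, got {len(genes)}")
        if len(set(genes)) != len(genes):
            raise NetworkValidationError(f"cycle nodes must be distinct: {genes}")
        if len(signs) != len(genes):
            raise NetworkValidationError("one sign per cycle step required")
        steps = []
        for i, tok in enumerate(signs):
            if tok not in sign_map:
                raise NetworkValidationError(f"sign must be '+' or '-', got {tok!r}")
            u, v = genes[i], genes[(i + 1) % len(genes)]
            s = sign_map[tok]
            prev = requested.get((u, v))
            if prev is not None and prev is not s:
                raise NetworkValidationError(
                    f"conflicting sign for arc {u} -> {v}: {prev.value} vs {s.value}"
                )
            requested[(u, v)] = s
            steps.append((u, v, s))
        for u, v, s in steps:
            rel = Relation.ACTIVITY_UP if s is Sign.POSITIVE else Relation.ACTIVITY_DOWN
            out.add_edge(TypedEdge(u, v, rel, directed=True))
        # canonical rotation for the manifest
        i = genes.index(min(genes))
        cyc = tuple(genes[i:] + genes[:i])
        sgn = tuple(signs[i:]) + tuple(signs[:i])
        negatives = sum(1 for t in sgn if t == "-")
        entries.append(
            {
                "cycle": list(cyc),
                "signs": list(sgn),
                "loop_sign": "negative" if negatives % 2 else "positive",
            }
        )
    return out, entries


def plant_hub(
    net: GeneNetwork,
    fraction: float = 0.5,
    seed: int = 0,
    hub_symbol: str = "HUB1",
) -> tuple[GeneNetwork, dict]:
    """Add a hub gene wired to a fraction of the existing nodes."""
    if not 0 < fraction <= 1:
        raise NetworkValidationError(f"fraction must be in (0, 1], got {fraction}")
    if hub_symbol.upper() in net.nodes:
        raise NetworkValidationError(f"hub symbol {hub_symbol} already in network")
    rng = _rng(seed, "hub")
    others = sorted(net.nodes)
    degree = max(1, int(round(fraction * len(others))))
    picks = [others[i] for i in rng.choice(len(others), size=degree, replace=False)]
    out = net.copy()
    out.add_node(hub_symbol)
    for g in sorted(picks):
        out.add_edge(TypedEdge(hub_symbol, g, Relation.INTERACTION, directed=False))
    return out, {"hub": hub_symbol.upper(), "degree": degree}


def null_enrichment_pvalues(
    N: int, K: int, n: int, replicates: int, seed: int = 0
) -> np.ndarray:
    """Overlap-test p-values with the overlap drawn at the hypergeometric null.

    Used for type-I calibration: sampling ``k ~ Hypergeometric(N, K, n)``
    and testing it should reject at level alpha no more than alpha of the
    time (exactly alpha up to the discreteness of the support).
    """
    from .enrichment import log_hypergeom_sf

    rng = _rng(seed, "null-calibration")
    ks = rng.hypergeometric(K, N - K, n, size=replicates)
    log10_e = np.log10(np.e)
    return np.array([np.exp(log_hypergeom_sf(N, K, n, int(k))) for k in ks])


# ---------------------------------------------------------------------------
# Preset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """A complete generated study: networks, tables and the manifest."""

    global_net: GeneNetwork
    module_table: ConditionAssociationTable
    module_net: GeneNetwork
    target_symbol: str
    hub_symbol: str
    manifest: GeneratorManifest


def paper_hg_preset(
    seed: int = 0,
    n_genes: int = 30_000,
    mean_degree: float = 6.0,
    module_size: int = 430,
    category_counts: Sequence[int] = (179, 75, 44, 54),
    target_K: int = 147,
    target_k: int = 34,
    hub_fraction: float = 0.5,
) -> SyntheticStudy:
    """The default study fixture.

    A 30,000-gene global network stands in for the (unpublished) universe of
    a text-mined human interactome; a 430-gene condition module carries the
    published hyperglycemia category tallies (179 up, 75 down, 44 condition-
    promoting, 54 condition-opposing); a target gene is wired to K=147
    interactors of which k=34 fall inside the module; a betweenness hub is
    wired to half the module; and a double-negative 2-loop plus one signed
    3-loop are planted among module genes.
    """
    global_net, manifest = generate_global(
        n_genes, mean_degree, seed=seed, name="global"
    )
    table, module_net, module_entry = plant_condition_module(
        global_net, module_size, category_counts, seed=seed, condition="hyperglycemia"
    )
    manifest.modules.append(module_entry)

    module_members = module_entry["members"]
    global_net, target_entry = plant_enriched_target(
        global_net, module_members, target_K, target_k, seed=seed
    )
    manifest.targets.append(target_entry)

    # hub inside the module neighborhood: wire to half the module genes
    rng = _rng(seed, "preset-hub-pick")
    hub_symbol = "HUB1"
    n_hub = max(1, int(round(hub_fraction * len(module_members))))
    picks = [module_members[i] for i in rng.choice(len(module_members), size=n_hub, replace=False)]
    net2 = global_net.copy()
    net2.add_node(hub_symbol)
    for g in sorted(picks):
        net2.add_edge(TypedEdge(hub_symbol, g, Relation.INTERACTION, directed=False))
    manifest.hubs.append({"hub": hub_symbol, "degree": n_hub, "scope": "module"})

    # signed loops among module genes free of pre-existing signed regulation
    # (deterministic: first five such genes in sorted member order, scanned
    # from the sparsely wired end of the attachment sequence)
    signed_arcs = {
        (e.source, e.target)
        for e in net2.edges
        if e.directed and e.sign is not Sign.NONE
    }
    touched = {g for arc in signed_arcs for g in arc}
    free = [g for g in reversed(module_members) if g not in touched]
    if len(free) < 5:
        raise NetworkValidationError(
            "module too densely regulated to plant conflict-free loops"
        )
    a, b, c, d, e = sorted(free[:5])
    net3, loop_entries = plant_loops(
        net2,
        [
            ((a, b), ("-", "-")),  # mutual inhibition: algebraically positive
            ((c, d, e), ("+", "+", "-")),  # odd negatives: negative 3-loop
        ],
        seed=seed,
    )
    manifest.loops.extend(loop_entries)

    module_net = net3.subnetwork(
        list(module_members) + [hub_symbol], name="hyperglycemia|module"
    )
    return SyntheticStudy(
        global_net=net3,
        module_table=table,
        module_net=module_net,
        target_symbol=target_entry["target"],
        hub_symbol=hub_symbol,
        manifest=manifest,
    )


def write_preset(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write global.tsv, module.tsv, assoc.tsv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "global": outdir / "global.tsv",
        "module": outdir / "module.tsv",
        "assoc": outdir / "assoc.tsv",
        "manifest": outdir / "manifest.json",
    }
    with open(paths["global"], "w", encoding="utf-8") as fh:
        write_network(study.global_net, fh)
    with open(paths["module"], "w", encoding="utf-8") as fh:
        write_network(study.module_net, fh)
    with open(paths["assoc"], "w", encoding="utf-8") as fh:
        write_association_table(study.module_table, fh)
    paths["manifest"].write_text(study.manifest.to_json(), encoding="utf-8")
    return paths
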