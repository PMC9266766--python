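"""Cross-network operations.

Tools for comparing a condition network against the interaction neighborhood
of a viral-entry (or any other) target protein: interactor extraction,
crosstab classification grids (how each shared gene relates to the condition
and to the target), gene-set intersections and Venn partitions, and
detection of short signed regulatory feedback loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable, Mapping

from .model import (
    ConditionAssociationTable,
    ConditionCategory,
    GeneNetwork,
    NetworkValidationError,
    Relation,
    Sign,
    TypedEdge,
    normalize_symbol,
    project_simple,
)

__all__ = [
    "TargetCategory",
    "CrosstabTable",
    "FeedbackLoop",
    "VennPartition",
    "interactor_set",
    "target_relation_categories",
    "build_crosstab",
    "distinct_gene_count",
    "intersect_sets",
    "venn_partition",
    "find_feedback_loops",
    "mutual_inhibition_loops",
]


class TargetCategory(str, Enum):
    """How a gene relates to the target protein."""

    UPREGULATED_BY_TARGET = "upregulated_by_target"
    DOWNREGULATED_BY_TARGET = "downregulated_by_target"
    UPREGULATES_TARGET = "upregulates_target"
    DOWNREGULATES_TARGET = "downregulates_target"
    OTHER = "other"


_ROW_ORDER = list(TargetCategory)
_COL_ORDER = list(ConditionCategory)


@dataclass
class CrosstabTable:
    """Target-relation × condition-relation grid of gene sets.

    A gene may occupy several cells: regulatory relations are not exclusive,
    so a gene can, e.g., be downregulated by the target while being both
    upregulated by the condition and itself driving the condition.
    """

    condition: str
    target: str
    cells: dict[tuple[TargetCategory, ConditionCategory], frozenset[str]] = field(
        default_factory=dict
    )

    def cell(self, row: TargetCategory | str, col: ConditionCategory | str) -> frozenset[str]:
        return self.cells.get((TargetCategory(row), ConditionCategory(col)), frozenset())

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.cells.values():
            out |= genes
        return frozenset(out)

    def to_dataframe(self):
        import pandas as pd

        data = {
            col.value: [
                ", ".join(sorted(self.cell(row, col))) for row in _ROW_ORDER
            ]
            for col in _COL_ORDER
        }
        return pd.DataFrame(data, index=[r.value for r in _ROW_ORDER])


@dataclass(frozen=True, slots=True)
class FeedbackLoop:
    """A simple directed regulatory cycle of length 2 or 3.

    ``loop_sign`` is the algebraic product of the step signs: positive for an
    even number of down-regulations, negative for an odd number, and
    undetermined whenever any step carries no sign.  Positive loops amplify a
    perturbation travelling around them; negative loops counteract it.
    """

    cycle: tuple[str, ...]
    edge_signs: tuple[Sign, ...]

    @property
    def loop_sign(self) -> str:
        if any(s is Sign.NONE for s in self.edge_signs):
            return "undetermined"
        negatives = sum(1 for s in self.edge_signs if s is Sign.NEGATIVE)
        return "negative" if negatives % 2 else "positive"

    def __len__(self) -> int:
        return len(self.cycle)


@dataclass(frozen=True)
class VennPartition:
    """Disjoint regions of a labeled family of gene sets.

    Regions are keyed by the frozenset of labels whose sets contain the
    region's genes; only non-empty label combinations appear, and the union
    of all regions equals the union of the inputs.
    """

    labels: tuple[str, ...]
    regions: Mapping[frozenset[str], frozenset[str]]

    def region(self, *labels: str) -> frozenset[str]:
        return self.regions.get(frozenset(labels), frozenset())

    def counts(self) -> dict[frozenset[str], int]:
        return {key: len(genes) for key, genes in self.regions.items()}


def interactor_set(
    global_g: GeneNetwork, target: str
) -> dict[str, list[tuple[Relation, bool, Sign]]]:
    """Direct interactors of ``target`` with their typed-relation annotations.

    Returns ``gene -> [(relation, gene_is_source, sign), ...]`` over every
    typed edge linking the gene to the target; the key set is the target's
    neighborhood in the simple projection (each neighbor once, however many
    parallel edges connect it).
    """
    tgt = normalize_symbol(target)
    if tgt not in global_g.nodes:
        raise NetworkValidationError(f"target {tgt} absent from network")
    out: dict[str, list[tuple[Relation, bool, Sign]]] = {}
    for e in global_g.edges:
        if e.source == tgt:
            out.setdefault(e.target, []).append((e.relation, False, e.sign))
        elif e.target == tgt:
            out.setdefault(e.source, []).append((e.relation, True, e.sign))
    return out


def target_relation_categories(
    global_g: GeneNetwork, target: str
) -> dict[str, set[TargetCategory]]:
    """Classify each interactor of ``target`` into target-relation categories.

    Directed signed regulation from the target maps to up/downregulated-by-
    target, regulation of the target to up/downregulates-target; edges
    without directed sign information (physical interaction, association,
    unsigned transport/degradation) map to ``OTHER``.
    """
    cats: dict[str, set[TargetCategory]] = {}
    for gene, annots in interactor_set(global_g, target).items():
        gene_cats: set[TargetCategory] = set()
        for relation, gene_is_source, sign in annots:
            if not relation.value.startswith(("expression", "activity")) or sign is Sign.NONE:
                gene_cats.add(TargetCategory.OTHER)
            elif gene_is_source:
                gene_cats.add(
                    TargetCategory.UPREGULATES_TARGET
                    if sign is Sign.POSITIVE
                    else TargetCategory.DOWNREGULATES_TARGET
                )
            else:
                gene_cats.add(
                    TargetCategory.UPREGULATED_BY_TARGET
                    if sign is Sign.POSITIVE
                    else TargetCategory.DOWNREGULATED_BY_TARGET
                )
        cats[gene] = gene_cats
    return cats


def build_crosstab(
    cond: ConditionAssociationTable,
    target_relations: Mapping[str, Iterable[TargetCategory | str]],
    target: str = "target",
) -> CrosstabTable:
    """Cross-classify genes by target relation (rows) × condition relation (columns).

    ``cell(r, c)`` holds the genes carrying target category ``r`` and
    condition category ``c``; genes with no condition entry fall into the
    ``OTHER`` column.  Every gene must carry at least one target category.
    """
    cells: dict[tuple[TargetCategory, ConditionCategory], set[str]] = {}
    for gene, t_cats in target_relations.items():
        g = normalize_symbol(gene)
        rows = {TargetCategory(c) for c in t_cats}
        if not rows:
            raise NetworkValidationError(f"gene {g} carries no target category")
        cols = cond.entries.get(g, {ConditionCategory.OTHER})
        for r, c in product(rows, cols):
            cells.setdefault((r, ConditionCategory(c)), set()).add(g)
    return CrosstabTable(
        condition=cond.condition,
        target=normalize_symbol(target) if target else target,
        cells={key: frozenset(genes) for key, genes in cells.items()},
    )


def distinct_gene_count(table: CrosstabTable) -> int:
    """Number of distinct genes across all cells (multi-cell genes counted once)."""
    return len(table.all_genes())


def intersect_sets(a: Iterable[str], b: Iterable[str]) -> frozenset[str]:
    """Normalized intersection of two gene sets."""
    norm_a = {normalize_symbol(g) for g in a}
    norm_b = {normalize_symbol(g) for g in b}
    return frozenset(norm_a & norm_b)


def venn_partition(sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition labeled gene sets into disjoint membership regions."""
    if len(sets) < 2:
        raise NetworkValidationError("venn_partition needs at least 2 input sets")
    normalized = {
        label: frozenset(normalize_symbol(g) for g in genes)
        for label, genes in sets.items()
    }
    membership: dict[str, set[str]] = {}
    for label, genes in normalized.items():
        for g in genes:
            membership.setdefault(g, set()).add(label)
    regions: dict[frozenset[str], set[str]] = {}
    for gene, labels in membership.items():
        regions.setdefault(frozenset(labels), set()).add(gene)
    return VennPartition(
        labels=tuple(normalized),
        regions={key: frozenset(genes) for key, genes in regions.items()},
    )


def _regulatory_arcs(net: GeneNetwork) -> dict[tuple[str, str], Sign]:
    """Collapse directed edges to one arc per ordered pair.

    Undirected interaction/association edges are excluded.  Parallel
    directed edges agreeing in sign keep it; mixed or absent signs yield
    ``Sign.NONE`` (the loop sign then reports as undetermined).
    """
    arcs: dict[tuple[str, str], set[Sign]] = {}
    for e in net.edges:
        if not e.directed:
            continue
        arcs.setdefault((e.source, e.target), set()).add(e.sign)
    out = {}
    for pair, signs in arcs.items():
        signed = signs - {Sign.NONE}
        out[pair] = signed.pop() if len(signed) == 1 else Sign.NONE
    return out


def _canonical(cycle: tuple[str, ...], signs: tuple[Sign, ...]) -> tuple[tuple[str, ...], tuple[Sign, ...]]:
    """Rotate so the lexicographically smallest node starts the cycle."""
    i = cycle.index(min(cycle))
    return cycle[i:] + cycle[:i], signs[i:] + signs[:i]


def find_feedback_loops(net: GeneNetwork, max_len: int = 3) -> list[FeedbackLoop]:
    """All simple directed cycles of length 2..max_len over regulatory arcs.

    Each cycle is reported once, rotated to start at its lexicographically
    smallest node.  ``max_len`` must be 2 or 3; longer motifs are out of
    scope (published comorbidity loop analyses concern 2- and 3-node motifs,
    and enumeration cost grows quickly).
    """
    if max_len not in (2, 3):
        raise NetworkValidationError(f"max_len must be 2 or 3, got {max_len}")
    arcs = _regulatory_arcs(net)
    succ: dict[str, set[str]] = {}
    for (u, v) in arcs:
        succ.setdefault(u, set()).add(v)
    loops: dict[tuple[str, ...], FeedbackLoop] = {}
    # 2-cycles: u -> v and v -> u with u < v
    for (u, v) in arcs:
        if u < v and (v, u) in arcs:
            cycle, signs = (u, v), (arcs[(u, v)], arcs[(v, u)])
            loops[cycle] = FeedbackLoop(cycle, signs)
    if max_len == 3:
        for (u, v) in arcs:
            for w in succ.get(v, ()):
                if w in (u, v):
                    continue
                if u in succ.get(w, ()):
                    cycle, signs = _canonical(
                        (u, v, w), (arcs[(u, v)], arcs[(v, w)], arcs[(w, u)])
                    )
                    loops.setdefault(cycle, FeedbackLoop(cycle, signs))
    return sorted(loops.values(), key=lambda l: (len(l), l.cycle))


def mutual_inhibition_loops(loops: Iterable[FeedbackLoop]) -> list[FeedbackLoop]:
    """2-loops whose both steps are down-regulations.

    Algebraically these are positive loops (two negatives), yet when one
    member is inhibited — e.g. a receptor occupied by a viral protein — the
    motif releases the other member, so it behaves as an amplifier of
    target inhibition.  They are reported separately so the algebraic sign
    convention need not be bent.
    """
    return [
        l
        for l in loops
        if len(l) == 2 and all(s is Sign.NEGATIVE for s in l.edge_signs)
    ]
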