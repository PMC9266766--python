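"""Data model and file I/O for typed gene networks.

The central object is a :class:`GeneNetwork`: a multigraph over gene symbols
whose edges carry a relation type (physical interaction, expression or
activity regulation, transport, degradation, association), an optional
direction and an optional sign.  Text-mining derived interactomes of this
shape routinely contain several typed edges between the same gene pair, so
"interaction" counts refer to the edge *multiset* while all topology
statistics operate on the deduplicated :class:`SimpleGraph` projection.

Gene symbols are normalized to uppercase; matching is exact after
normalization (alias resolution is out of scope).  Self-relations are
rejected: centrality and density conventions here assume simple graphs.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "Relation",
    "Sign",
    "TypedEdge",
    "GeneNetwork",
    "SimpleGraph",
    "ConditionAssociationTable",
    "ConditionCategory",
    "TermAnnotationMap",
    "NetworkParseError",
    "NetworkValidationError",
    "normalize_symbol",
    "read_edge_table",
    "write_network",
    "write_graphml",
    "project_simple",
    "read_gene_list",
    "write_gene_list",
    "read_association_table",
    "write_association_table",
    "read_term_annotation",
]


class NetworkParseError(ValueError):
    """Malformed input line; message names the offending line number."""


class NetworkValidationError(ValueError):
    """Structurally valid input violating a model invariant."""


class Relation(str, Enum):
    """Typed relation kinds carried by edges."""

    INTERACTION = "interaction"
    EXPRESSION_UP = "expression_up"
    EXPRESSION_DOWN = "expression_down"
    ACTIVITY_UP = "activity_up"
    ACTIVITY_DOWN = "activity_down"
    TRANSPORT = "transport"
    DEGRADATION = "degradation"
    ASSOCIATION = "association"


class Sign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"


#: Relations whose sign is fixed by the relation semantics.
_IMPLIED_SIGN: dict[Relation, Sign] = {
    Relation.EXPRESSION_UP: Sign.POSITIVE,
    Relation.ACTIVITY_UP: Sign.POSITIVE,
    Relation.EXPRESSION_DOWN: Sign.NEGATIVE,
    Relation.ACTIVITY_DOWN: Sign.NEGATIVE,
}

#: The only relations that may be undirected.
_UNDIRECTED_OK = frozenset({Relation.INTERACTION, Relation.ASSOCIATION})

_SIGN_TOKEN = {"+": Sign.POSITIVE, "-": Sign.NEGATIVE, "0": Sign.NONE}
_TOKEN_SIGN = {v: k for k, v in _SIGN_TOKEN.items()}


def normalize_symbol(symbol: str) -> str:
    """Uppercase a gene symbol and reject empty / whitespace-bearing tokens."""
    s = symbol.strip().upper()
    if not s:
        raise NetworkValidationError("empty gene symbol")
    if any(c.isspace() for c in s):
        raise NetworkValidationError(f"gene symbol contains whitespace: {symbol!r}")
    return s


@dataclass(frozen=True, slots=True)
class TypedEdge:
    """One typed relation between two distinct genes.

    Up/down expression and activity relations imply their sign; physical
    interaction, association, transport and degradation default to no sign
    unless one is given explicitly.  Only interaction and association may be
    undirected.
    """

    source: str
    target: str
    relation: Relation
    directed: bool = True
    sign: Sign = Sign.NONE

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", normalize_symbol(self.source))
        object.__setattr__(self, "target", normalize_symbol(self.target))
        if self.source == self.target:
            raise NetworkValidationError(
                f"self-relation rejected: {self.source} -> {self.target}"
            )
        implied = _IMPLIED_SIGN.get(self.relation)
        if implied is not None:
            if self.sign not in (Sign.NONE, implied):
                raise NetworkValidationError(
                    f"relation {self.relation.value} implies sign {implied.value}, "
                    f"got {self.sign.value}"
                )
            object.__setattr__(self, "sign", implied)
            if not self.directed:
                raise NetworkValidationError(
                    f"regulatory relation {self.relation.value} must be directed"
                )
        if not self.directed and self.relation not in _UNDIRECTED_OK:
            raise NetworkValidationError(
                f"relation {self.relation.value} cannot be undirected"
            )

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair (sorted)."""
        a, b = self.source, self.target
        return (a, b) if a <= b else (b, a)


class GeneNetwork:
    """Typed multigraph of genes.

    Parameters
    ----------
    name
        Label for provenance tracking.
    edges
        Iterable of :class:`TypedEdge`; multiplicity is preserved and counted.
    nodes
        Optional extra node symbols (isolated genes).  Every edge endpoint is
        added automatically.
    molecule_class
        Optional ``gene -> functional class`` annotation (hormone, receptor,
        enzyme, ...).
    """

    def __init__(
        self,
        name: str = "network",
        edges: Iterable[TypedEdge] = (),
        nodes: Iterable[str] = (),
        molecule_class: Mapping[str, str] | None = None,
    ) -> None:
        self.name = name
        self.edges: list[TypedEdge] = []
        self._nodes: set[str] = set()
        for sym in nodes:
            self._nodes.add(normalize_symbol(sym))
        for e in edges:
            self.add_edge(e)
        self.molecule_class: dict[str, str] = {}
        if molecule_class:
            for g, cls in molecule_class.items():
                g = normalize_symbol(g)
                if g not in self._nodes:
                    raise NetworkValidationError(
                        f"molecule_class annotates unknown gene {g}"
                    )
                self.molecule_class[g] = cls

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_interactions(self) -> int:
        """Size of the typed-edge multiset (parallel edges counted)."""
        return len(self.edges)

    def add_node(self, symbol: str) -> None:
        self._nodes.add(normalize_symbol(symbol))

    def add_edge(self, edge: TypedEdge) -> None:
        self._nodes.add(edge.source)
        self._nodes.add(edge.target)
        self.edges.append(edge)

    def copy(self, name: str | None = None) -> "GeneNetwork":
        return GeneNetwork(
            name=name or self.name,
            edges=list(self.edges),
            nodes=self._nodes,
            molecule_class=self.molecule_class,
        )

    def subnetwork(self, genes: Iterable[str], name: str | None = None) -> "GeneNetwork":
        """Induced subnetwork on ``genes`` (typed edges with both ends inside)."""
        keep = {normalize_symbol(g) for g in genes}
        sub = GeneNetwork(
            name=name or f"{self.name}|induced",
            edges=(e for e in self.edges if e.source in keep and e.target in keep),
            nodes=keep & self._nodes,
        )
        for g in sub.nodes & self.molecule_class.keys():
            sub.molecule_class[g] = self.molecule_class[g]
        return sub

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return (
            self._nodes == other._nodes
            and Counter(self.edges) == Counter(other.edges)
        )

    def __repr__(self) -> str:
        return (
            f"GeneNetwork({self.name!r}, n_nodes={self.n_nodes}, "
            f"n_interactions={self.n_interactions})"
        )


@dataclass(frozen=True)
class SimpleGraph:
    """Deduplicated unordered-neighbor projection of a :class:`GeneNetwork`.

    Each gene pair appears once regardless of how many typed edges connect
    it; isolated nodes are kept.  All topology statistics are defined on this
    projection.
    """

    nodes: frozenset[str]
    pairs: frozenset[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise NetworkValidationError(f"self-pair {a!r}")
            if a > b:
                raise NetworkValidationError(f"pair not in sorted order: {(a, b)!r}")
            if a not in self.nodes or b not in self.nodes:
                raise NetworkValidationError(f"pair endpoint outside node set: {(a, b)!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def neighbors(self, gene: str) -> frozenset[str]:
        g = normalize_symbol(gene)
        if g not in self.nodes:
            raise NetworkValidationError(f"gene {g} not in graph")
        return frozenset(
            b if a == g else a for a, b in self.pairs if g in (a, b)
        )

    def degree(self, gene: str) -> int:
        return len(self.neighbors(gene))

    def degrees(self) -> dict[str, int]:
        d = {g: 0 for g in self.nodes}
        for a, b in self.pairs:
            d[a] += 1
            d[b] += 1
        return d

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.pairs)
        return g


def project_simple(net: GeneNetwork) -> SimpleGraph:
    """Collapse a typed multigraph to its unique unordered gene pairs."""
    return SimpleGraph(
        nodes=net.nodes,
        pairs=frozenset(e.pair for e in net.edges),
        provenance=net.name,
    )


class ConditionCategory(str, Enum):
    """How a gene relates to the condition phenotype (e.g. hyperglycemia)."""

    UPREGULATED_BY_CONDITION = "upregulated_by_condition"
    DOWNREGULATED_BY_CONDITION = "downregulated_by_condition"
    PRO_CONDITION_ACTIVITY = "pro_condition_activity"
    ANTI_CONDITION_ACTIVITY = "anti_condition_activity"
    OTHER = "other"


@dataclass
class ConditionAssociationTable:
    """Gene -> relation-to-condition categories.

    A gene may hold several categories at once (a transcription factor can be
    both upregulated by the condition and itself drive the condition).
    """

    condition: str
    entries: dict[str, set[ConditionCategory]] = field(default_factory=dict)

    def add(self, gene: str, category: ConditionCategory | str) -> None:
        g = normalize_symbol(gene)
        cat = ConditionCategory(category)
        self.entries.setdefault(g, set()).add(cat)

    def genes(self) -> frozenset[str]:
        return frozenset(self.entries)

    def with_category(self, category: ConditionCategory | str) -> frozenset[str]:
        cat = ConditionCategory(category)
        return frozenset(g for g, cats in self.entries.items() if cat in cats)

    def category_counts(self) -> dict[ConditionCategory, int]:
        counts = {c: 0 for c in ConditionCategory}
        for cats in self.entries.values():
            for c in cats:
                counts[c] += 1
        return counts


@dataclass
class TermAnnotationMap:
    """Term -> gene-set annotation over an explicit gene universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise NetworkValidationError(f"term {term!r} annotates no genes")
            stray = genes - self.universe
            if stray:
                raise NetworkValidationError(
                    f"term {term!r} annotates genes outside universe: {sorted(stray)}"
                )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_TSV_HEADER = ["source", "target", "relation", "directed", "sign"]


def _lines(stream: IO[str] | str) -> Iterator[tuple[int, str]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for i, raw in enumerate(stream, start=1):
        yield i, raw.rstrip("\n").rstrip("\r")


def read_edge_table(
    stream: IO[str] | str, dialect: str = "tsv", name: str = "network"
) -> GeneNetwork:
    """Parse a typed edge table.

    ``tsv`` expects a ``source target relation directed sign`` header with
    booleans as ``true``/``false`` and sign as ``+``/``-``/``0``.  ``sif`` is
    the Simple Interaction Format (``source <TAB> relation <TAB> target...``,
    read-only); direction and sign are inferred from the relation kind.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = GeneNetwork(name=name)
    saw_header = False
    for lineno, line in _lines(stream):
        if line.startswith("# node\t"):  # isolated-node directive (round-trip)
            net.add_node(line.split("\t", 1)[1])
            continue
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if dialect == "tsv":
            if not saw_header:
                if [f.strip().lower() for f in fields] != _TSV_HEADER:
                    raise NetworkParseError(
                        f"line {lineno}: expected header {_TSV_HEADER}, got {fields}"
                    )
                saw_header = True
                continue
            if len(fields) != 5:
                raise NetworkParseError(
                    f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            src, tgt, rel_tok, dir_tok, sign_tok = (f.strip() for f in fields)
            try:
                relation = Relation(rel_tok)
            except ValueError:
                raise NetworkParseError(
                    f"line {lineno}: unknown relation token {rel_tok!r}"
                ) from None
            if dir_tok.lower() not in ("true", "false"):
                raise NetworkParseError(
                    f"line {lineno}: directed must be true/false, got {dir_tok!r}"
                )
            if sign_tok not in _SIGN_TOKEN:
                raise NetworkParseError(
                    f"line {lineno}: sign must be one of +/-/0, got {sign_tok!r}"
                )
            try:
                edge = TypedEdge(
                    src,
                    tgt,
                    relation,
                    directed=dir_tok.lower() == "true",
                    sign=_SIGN_TOKEN[sign_tok],
                )
            except NetworkValidationError as exc:
                raise NetworkValidationError(f"line {lineno}: {exc}") from None
        else:  # sif
            if len(fields) < 3:
                raise NetworkParseError(
                    f"line {lineno}: SIF needs at least source, relation, target"
                )
            src, rel_tok = fields[0], fields[1]
            try:
                relation = Relation(rel_tok.strip())
            except ValueError:
                raise NetworkParseError(
                    f"line {lineno}: unknown relation token {rel_tok!r}"
                ) from None
            directed = relation not in _UNDIRECTED_OK
            for tgt in fields[2:]:
                try:
                    net.add_edge(TypedEdge(src, tgt, relation, directed=directed))
                except NetworkValidationError as exc:
                    raise NetworkValidationError(f"line {lineno}: {exc}") from None
            continue
        net.add_edge(edge)
    return net


def write_network(net: GeneNetwork, stream: IO[str]) -> None:
    """Write the canonical TSV dialect (round-trip stable with read)."""
    stream.write("\t".join(_TSV_HEADER) + "\n")
    for e in net.edges:
        stream.write(
            "\t".join(
                [
                    e.source,
                    e.target,
                    e.relation.value,
                    "true" if e.directed else "false",
                    _TOKEN_SIGN[e.sign],
                ]
            )
            + "\n"
        )
    isolated = net.nodes - {g for e in net.edges for g in (e.source, e.target)}
    for g in sorted(isolated):
        stream.write(f"# node\t{g}\n")


def write_graphml(net: GeneNetwork, path: str) -> None:
    """GraphML export for visualization (write-only; parallel edges kept)."""
    import networkx as nx

    g = nx.MultiDiGraph(name=net.name)
    for node in sorted(net.nodes):
        g.add_node(node, molecule_class=net.molecule_class.get(node, ""))
    for e in net.edges:
        g.add_edge(
            e.source,
            e.target,
            relation=e.relation.value,
            directed=e.directed,
            sign=e.sign.value,
        )
    nx.write_graphml(g, path)


def read_gene_list(stream: IO[str] | str) -> set[str]:
    """One symbol per line; ``#`` comments ignored; symbols normalized."""
    genes: set[str] = set()
    for lineno, line in _lines(stream):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        try:
            genes.add(normalize_symbol(body))
        except NetworkValidationError as exc:
            raise NetworkParseError(f"line {lineno}: {exc}") from None
    return genes


def write_gene_list(genes: Iterable[str], stream: IO[str]) -> None:
    for g in sorted({normalize_symbol(x) for x in genes}):
        stream.write(g + "\n")


def read_association_table(
    stream: IO[str] | str, condition: str = "condition"
) -> ConditionAssociationTable:
    """TSV of ``gene <TAB> category`` rows; a gene may appear several times."""
    table = ConditionAssociationTable(condition=condition)
    for lineno, line in _lines(stream):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 2:
            raise NetworkParseError(
                f"line {lineno}: expected gene<TAB>category, got {len(fields)} fields"
            )
        gene, cat_tok = fields
        try:
            cat = ConditionCategory(cat_tok)
        except ValueError:
            raise NetworkParseError(
                f"line {lineno}: unknown category token {cat_tok!r}"
            ) from None
        table.add(gene, cat)
    return table


def write_association_table(table: ConditionAssociationTable, stream: IO[str]) -> None:
    for gene in sorted(table.entries):
        for cat in sorted(table.entries[gene], key=lambda c: c.value):
            stream.write(f"{gene}\t{cat.value}\n")


def read_term_annotation(
    stream: IO[str] | str, universe: Iterable[str] | None = None
) -> TermAnnotationMap:
    """TSV of ``gene <TAB> term`` rows.

    If ``universe`` is omitted it defaults to the annotated genes themselves.
    """
    term_genes: dict[str, set[str]] = {}
    seen: set[str] = set()
    for lineno, line in _lines(stream):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 2:
            raise NetworkParseError(
                f"line {lineno}: expected gene<TAB>term, got {len(fields)} fields"
            )
        gene, term = fields
        g = normalize_symbol(gene)
        term_genes.setdefault(term, set()).add(g)
        seen.add(g)
    if universe is None:
        uni = frozenset(seen)
    else:
        uni = frozenset(normalize_symbol(g) for g in universe)
    return TermAnnotationMap(
        terms={t: frozenset(g) for t, g in term_genes.items()}, universe=uni
    )
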