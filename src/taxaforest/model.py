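"""Low-level taxonomic classes and the forest-structured taxonomy.

The data model mirrors how taxonomic classifications are actually used in
metagenomics and biodiversity informatics: a *taxon* is a named unit of
classification at any rank, a *hierarchy* is one classification (an ordered
chain of taxa from most inclusive to most specific, e.g. Animalia →
Chordata → ... → sapiens), and a :class:`TaxonomyGraph` stores many such
classifications deduplicated into a forest, with the tree structure kept as
an edge list of (supertaxon, subtaxon) internal-ID pairs.

Two taxa with the same name are *not* assumed to be the same taxon: node
identity is the full lineage (names plus ranks of all ancestors), so a
genus name shared between, say, an oomycete and a moth yields two distinct
nodes.  Ranks are opaque labels; no rank ordering is imposed.
"""

from __future__ import annotations

import itertools
import re
import string
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "DatabaseInfo",
    "TaxonId",
    "TaxonName",
    "TaxonRank",
    "Taxon",
    "Hierarchy",
    "TaxonomyGraph",
    "TaxonomyBuilder",
    "id_generator",
    "build_taxonomy",
    "canonical_form",
    "supertaxa",
    "subtaxa",
    "tree_parts",
    "to_hierarchies",
    "validate",
]


# ---------------------------------------------------------------------------
# basic classes


@dataclass(frozen=True)
class DatabaseInfo:
    """A source database: name plus optional URL, description and the
    regular expression its taxon IDs must match."""

    name: str
    url: str | None = None
    description: str | None = None
    id_regex: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("database name must be non-empty")
        if self.id_regex is not None:
            try:
                re.compile(self.id_regex)
            except re.error as exc:
                raise ValueError(
                    f"id_regex {self.id_regex!r} does not compile: {exc}"
                ) from exc


def _db_name(database: DatabaseInfo | str | None) -> str | None:
    if database is None:
        return None
    if isinstance(database, DatabaseInfo):
        return database.name
    return str(database)


@dataclass(frozen=True)
class TaxonId:
    """A taxon identifier from a database (e.g. an NCBI taxid)."""

    value: str
    database: DatabaseInfo | str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", str(self.value))
        if not self.value:
            raise ValueError("taxon id value must be non-empty")
        db = self.database
        if isinstance(db, DatabaseInfo) and db.id_regex is not None:
            if re.fullmatch(db.id_regex, self.value) is None:
                raise ValueError(
                    f"taxon id {self.value!r} does not match {db.name!r} "
                    f"id_regex {db.id_regex!r}"
                )

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class TaxonName:
    """A taxon name, optionally tagged with its source database."""

    value: str
    database: DatabaseInfo | str | None = None

    def __post_init__(self) -> None:
        if not self.value:
            raise ValueError("taxon name must be non-empty")

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class TaxonRank:
    """A rank label such as "genus".  Opaque: no ordering is assumed."""

    value: str
    database: DatabaseInfo | str | None = None

    def __post_init__(self) -> None:
        if not self.value:
            raise ValueError("rank label must be non-empty")

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Taxon:
    """One taxon: a name, and optionally a rank and a database ID.

    Bare strings are accepted anywhere the wrapped classes are expected and
    are promoted with ``database=None``.
    """

    name: TaxonName
    rank: TaxonRank | None = None
    id: TaxonId | None = None

    def __post_init__(self) -> None:
        if isinstance(self.name, str):
            object.__setattr__(self, "name", TaxonName(self.name))
        if isinstance(self.rank, str):
            object.__setattr__(self, "rank", TaxonRank(self.rank))
        if isinstance(self.id, (str, int)):
            object.__setattr__(self, "id", TaxonId(str(self.id)))

    @property
    def name_str(self) -> str:
        return self.name.value

    @property
    def rank_str(self) -> str | None:
        return None if self.rank is None else self.rank.value

    @property
    def id_str(self) -> str | None:
        return None if self.id is None else self.id.value

    def key(self) -> tuple[str, str | None]:
        """The (name, rank) pair used for lineage-based node identity."""
        return (self.name_str, self.rank_str)

    def __str__(self) -> str:
        rank = f" ({self.rank_str})" if self.rank else ""
        return f"{self.name_str}{rank}"


class Hierarchy:
    """One taxonomic classification, most inclusive taxon first."""

    def __init__(self, taxa: Iterable[Taxon | str]):
        self.taxa: tuple[Taxon, ...] = tuple(
            t if isinstance(t, Taxon) else Taxon(t) for t in taxa
        )
        if not self.taxa:
            raise ValueError("a hierarchy must contain at least one taxon")

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self) -> Iterator[Taxon]:
        return iter(self.taxa)

    def __getitem__(self, i):
        return self.taxa[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, Hierarchy) and self.taxa == other.taxa

    def __repr__(self) -> str:
        return "Hierarchy(" + " > ".join(str(t) for t in self.taxa) + ")"

    def keys(self) -> tuple[tuple[str, str | None], ...]:
        return tuple(t.key() for t in self.taxa)


# ---------------------------------------------------------------------------
# internal-ID generation

_LETTERS = string.ascii_lowercase


def id_generator(width: int = 3) -> Iterator[str]:
    """Yield "aaa", "aab", ..., widening when a width is exhausted."""
    while True:
        for combo in itertools.product(_LETTERS, repeat=width):
            yield "".join(combo)
        width += 1


# ---------------------------------------------------------------------------
# the taxonomy graph


class TaxonomyGraph:
    """Deduplicated taxa in a forest, stored as nodes plus a parent map.

    ``nodes`` maps internal ID → :class:`Taxon`; ``parents`` maps internal
    ID → supertaxon internal ID, or None for roots.  Both dicts share the
    same insertion order, which is the storage order used everywhere a
    per-taxon sequence is produced.  The constructor does not validate;
    use :func:`validate` to get a diagnostics report.
    """

    def __init__(
        self,
        nodes: Mapping[str, Taxon] | None = None,
        parents: Mapping[str, str | None] | None = None,
    ):
        self.nodes: dict[str, Taxon] = dict(nodes or {})
        self.parents: dict[str, str | None] = dict(parents or {})
        for tid in self.nodes:
            self.parents.setdefault(tid, None)

    # -- basic accessors ---------------------------------------------------

    def ids(self) -> list[str]:
        return list(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TaxonomyGraph)
            and self.nodes == other.nodes
            and self.parents == other.parents
        )

    @property
    def edges(self) -> list[tuple[str | None, str]]:
        """(supertaxon-or-None, subtaxon) pairs, one per node."""
        return [(self.parents[tid], tid) for tid in self.nodes]

    def children_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {tid: [] for tid in self.nodes}
        for tid in self.nodes:
            parent = self.parents.get(tid)
            if parent is not None and parent in out:
                out[parent].append(tid)
        return out

    def taxon_names(self) -> dict[str, str]:
        return {tid: t.name_str for tid, t in self.nodes.items()}

    def taxon_ranks(self) -> dict[str, str | None]:
        return {tid: t.rank_str for tid, t in self.nodes.items()}

    def lineage(self, taxon_id: str) -> list[str]:
        """IDs from the root down to (and including) ``taxon_id``."""
        chain = [taxon_id]
        seen = {taxon_id}
        while True:
            parent = self.parents.get(chain[-1])
            if parent is None:
                break
            if parent in seen:
                raise ValueError(f"cycle detected at taxon {parent!r}")
            chain.append(parent)
            seen.add(parent)
        return chain[::-1]

    def copy(self) -> "TaxonomyGraph":
        return TaxonomyGraph(dict(self.nodes), dict(self.parents))

    def __repr__(self) -> str:
        n_edges = len(self.nodes)
        return f"<TaxonomyGraph with {len(self.nodes)} taxa, {n_edges} edges>"


class TaxonomyBuilder:
    """Incrementally merge lineages into a deduplicated forest.

    Node identity is the full lineage of (name, rank) pairs from the root,
    so identically named taxa under different ancestors stay distinct.
    """

    def __init__(self) -> None:
        self._ids = id_generator()
        self._by_key: dict[tuple, str] = {}
        self.graph = TaxonomyGraph()

    def add_lineage_ids(self, taxa: Sequence[Taxon]) -> list[str]:
        """Merge one root-first lineage; return node IDs, root first."""
        key: tuple = ()
        parent: str | None = None
        out: list[str] = []
        for taxon in taxa:
            key = key + (taxon.key(),)
            node_id = self._by_key.get(key)
            if node_id is None:
                node_id = next(self._ids)
                self._by_key[key] = node_id
                self.graph.nodes[node_id] = taxon
                self.graph.parents[node_id] = parent
            out.append(node_id)
            parent = node_id
        return out

    def add_lineage(self, taxa: Sequence[Taxon]) -> str:
        """Merge one root-first lineage; return the most specific node's ID."""
        ids = self.add_lineage_ids(taxa)
        if not ids:
            raise ValueError("cannot add an empty lineage")
        return ids[-1]


def build_taxonomy(hierarchies: Iterable[Hierarchy | Sequence[Taxon | str]]) -> TaxonomyGraph:
    """Merge classifications into a deduplicated forest.

    Internal IDs are sequential lowercase base-26 strings ("aaa", "aab", ...)
    assigned in first-encounter order during a root-first, input-order walk,
    so identical input always produces identical IDs.

    Raises ``ValueError`` naming the offending index if a hierarchy is empty.
    """
    builder = TaxonomyBuilder()
    for i, h in enumerate(hierarchies):
        if not isinstance(h, Hierarchy):
            try:
                h = Hierarchy(h)
            except ValueError:
                raise ValueError(f"hierarchy at index {i} is empty") from None
        builder.add_lineage(h.taxa)
    return builder.graph


# ---------------------------------------------------------------------------
# tree queries

Recursion = bool | int


def _depth_limit(recursive: Recursion) -> float:
    if recursive is True:
        return float("inf")
    if recursive is False:
        return 1
    if isinstance(recursive, int) and recursive >= 0:
        return recursive
    raise ValueError(f"recursive must be True, False or a depth >= 0, got {recursive!r}")


def _check_subset(graph: TaxonomyGraph, subset: Iterable[str] | None) -> list[str]:
    if subset is None:
        return graph.ids()
    subset = list(subset)
    unknown = [tid for tid in subset if tid not in graph.nodes]
    if unknown:
        raise KeyError(f"unknown taxon IDs: {unknown}")
    return subset


def _resolve_graph_value(graph: TaxonomyGraph, value: str | Mapping | None):
    """Resolve ``value`` to a per-taxon mapping for plain-graph queries."""
    if value is None:
        return {tid: tid for tid in graph.nodes}
    if isinstance(value, Mapping):
        return value
    builtin = {
        "taxon_ids": lambda: {tid: tid for tid in graph.nodes},
        "taxon_names": graph.taxon_names,
        "taxon_ranks": graph.taxon_ranks,
    }
    if value in builtin:
        return builtin[value]()
    raise KeyError(
        f"cannot resolve value {value!r} on a bare taxonomy; "
        f"available: {sorted(builtin)}"
    )


def supertaxa(
    graph: TaxonomyGraph,
    subset: Iterable[str] | None = None,
    recursive: Recursion = True,
    include_self: bool = False,
    value: str | Mapping | None = None,
) -> dict[str, list]:
    """Ancestors of each queried taxon, nearest supertaxon first.

    ``recursive``: True walks to the root, False returns at most the
    immediate supertaxon, an integer n returns at most n ancestors.
    ``value`` selects what to report per taxon (default: internal IDs).
    """
    ids = _check_subset(graph, subset)
    values = _resolve_graph_value(graph, value)
    limit = _depth_limit(recursive)
    out: dict[str, list] = {}
    for tid in ids:
        chain: list[str] = [tid] if include_self else []
        current = tid
        depth = 0
        while depth < limit:
            parent = graph.parents.get(current)
            if parent is None:
                break
            chain.append(parent)
            current = parent
            depth += 1
        out[tid] = [values[i] for i in chain]
    return out


def subtaxa(
    graph: TaxonomyGraph,
    subset: Iterable[str] | None = None,
    recursive: Recursion = True,
    include_self: bool = False,
    value: str | Mapping | None = None,
) -> dict[str, list]:
    """Descendants of each queried taxon in preorder (depth-first).

    ``recursive`` semantics mirror :func:`supertaxa`: False means immediate
    subtaxa only, an integer bounds the traversal depth.
    """
    ids = _check_subset(graph, subset)
    values = _resolve_graph_value(graph, value)
    limit = _depth_limit(recursive)
    children = graph.children_map()
    out: dict[str, list] = {}
    for tid in ids:
        found: list[str] = [tid] if include_self else []
        stack = [(child, 1) for child in reversed(children[tid])]
        while stack:
            node, depth = stack.pop()
            if depth > limit:
                continue
            found.append(node)
            stack.extend((c, depth + 1) for c in reversed(children[node]))
        out[tid] = [values[i] for i in found]
    return out


_TREE_PART_KINDS = ("roots", "stems", "branches", "leaves")


def tree_parts(
    graph: TaxonomyGraph,
    kind: str,
    value: str | Mapping | None = None,
) -> list:
    """Structural subsets of a taxonomy.

    roots: taxa with no supertaxon.  leaves: taxa with no subtaxon.
    branches: taxa with exactly one supertaxon and one subtaxon.  stems:
    each root plus the chain of successive taxa while the current taxon has
    exactly one immediate subtaxon — i.e. everything before the first split.
    Stems and branches can be removed (with reassignment) without changing
    the relative relationships among the remaining taxa.
    """
    if kind not in _TREE_PART_KINDS:
        raise ValueError(f"unknown tree part {kind!r}; expected one of {_TREE_PART_KINDS}")
    children = graph.children_map()
    values = _resolve_graph_value(graph, value)
    picked: list[str]
    if kind == "roots":
        picked = [tid for tid in graph.nodes if graph.parents.get(tid) is None]
    elif kind == "leaves":
        picked = [tid for tid in graph.nodes if not children[tid]]
    elif kind == "branches":
        picked = [
            tid
            for tid in graph.nodes
            if graph.parents.get(tid) is not None and len(children[tid]) == 1
        ]
    else:  # stems
        stems: set[str] = set()
        for root in (t for t in graph.nodes if graph.parents.get(t) is None):
            current = root
            stems.add(current)
            while len(children[current]) == 1:
                current = children[current][0]
                stems.add(current)
        picked = [tid for tid in graph.nodes if tid in stems]
    return [values[tid] for tid in picked]


def to_hierarchies(graph: TaxonomyGraph) -> list[Hierarchy]:
    """One root-first classification per leaf; inverse of :func:`build_taxonomy`.

    Rebuilding from the result reproduces the node and edge sets (every
    internal node lies on at least one leaf path in a forest).
    """
    children = graph.children_map()
    out = []
    for leaf in (tid for tid in graph.nodes if not children[tid]):
        path = graph.lineage(leaf)
        out.append(Hierarchy([graph.nodes[tid] for tid in path]))
    return out


def canonical_form(graph: TaxonomyGraph):
    """Node and edge sets keyed by full lineage, independent of internal IDs.

    Two graphs have equal canonical forms iff they describe the same
    forest of taxa (same lineages, same supertaxon/subtaxon relations),
    whatever internal IDs or storage order they use.  This is the equality
    used for round-trip contracts.
    """
    keys: dict[str, tuple] = {}
    for tid in graph.nodes:
        keys[tid] = tuple(graph.nodes[a].key() for a in graph.lineage(tid))
    node_set = frozenset(keys.values())
    edge_set = frozenset(
        (keys[parent] if parent is not None else None, keys[child])
        for parent, child in graph.edges
    )
    return node_set, edge_set


def validate(graph: TaxonomyGraph) -> list[str]:
    """Diagnostics report; an empty list means the graph is a valid forest.

    Reports orphan edges (parent IDs missing from the node table), nodes
    missing a parent entry, and cycles.  Multi-parent nodes and duplicate
    IDs cannot be represented in the parent-map encoding, but entries in
    the parent map that name no known node are reported.
    """
    problems: list[str] = []
    for tid in graph.nodes:
        if tid not in graph.parents:
            problems.append(f"node {tid!r} has no edge entry")
    for tid, parent in graph.parents.items():
        if tid not in graph.nodes:
            problems.append(f"edge references unknown subtaxon {tid!r}")
        if parent is not None and parent not in graph.nodes:
            problems.append(f"edge {parent!r}->{tid!r} references unknown supertaxon")
    # cycle detection: walk parents with a visited set
    state: dict[str, int] = {}  # 0 in-progress, 1 done
    for tid in graph.nodes:
        path = []
        current: str | None = tid
        while current is not None and current in graph.nodes:
            if state.get(current) == 1:
                break
            if current in (p for p in path):
                problems.append(f"cycle involving taxon {current!r}")
                break
            path.append(current)
            current = graph.parents.get(current)
        for p in path:
            state[p] = 1
    return problems
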