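"""Readers and writers: FASTA-header lineages, delimited tables, JSON, newick.

Reference sequence databases embed classifications in FASTA headers, each
with its own dialect.  Greengenes prefixes names with single-letter rank
codes (``k__Bacteria; p__Cyanobacteria; c__Synechococcophycideae``), SILVA
uses bare semicolon-separated names
(``Bacteria;Proteobacteria;Gammaproteobacteria``), and RDP intermixes
names and ranks with one separator
(``Root;rootrank;Fungi;domain;Ascomycota``).  :data:`DIALECTS` holds a
preset :class:`HeaderDialect` for each, plus a generic one.

The taxmap JSON document is this package's own versioned schema (schema
version 1); user funcs are not serializable and are dropped with a warning.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

from .model import (
    DatabaseInfo,
    Taxon,
    TaxonId,
    TaxonName,
    TaxonomyGraph,
    TaxonRank,
    tree_parts,
)
from .parsers import (
    ClassSpec,
    ParseFailure,
    ParseResult,
    _assemble,
    parse_classification,
)
from .taxmap import LINK_COLUMN, Taxmap

__all__ = [
    "HeaderDialect",
    "DIALECTS",
    "read_fasta_classifications",
    "read_delimited",
    "write_delimited",
    "serialize_taxmap",
    "deserialize_taxmap",
    "export_newick",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# header dialects


@dataclass(frozen=True)
class HeaderDialect:
    """How to find and parse the lineage inside a FASTA header.

    ``extract_regex`` has one capture group isolating the lineage from the
    rest of the header; ``spec`` then splits the lineage into taxa.
    ``render`` (when available) maps a list of (name, rank) pairs back to
    a header lineage string, raising ValueError if the dialect cannot
    express the lineage (e.g. a rank-coded dialect given unranked taxa).
    """

    name: str
    extract_regex: str
    spec: ClassSpec
    render: Callable[[Sequence[tuple[str, str | None]]], str] | None = None


def _render_greengenes(lineage) -> str:
    parts = []
    for name, rank in lineage:
        if rank is None or re.fullmatch(r"[a-z]", rank) is None:
            raise ValueError(
                f"greengenes headers need single-letter lowercase ranks; "
                f"taxon {name!r} has rank {rank!r}"
            )
        parts.append(f"{rank}__{name}")
    return "; ".join(parts)


def _render_silva(lineage) -> str:
    return ";".join(name for name, _ in lineage)


def _render_rdp(lineage) -> str:
    parts = []
    for name, rank in lineage:
        if rank is None:
            raise ValueError(
                f"rdp headers interleave names and ranks; taxon {name!r} has no rank"
            )
        parts.extend([name, rank])
    return ";".join(parts)


DIALECTS: dict[str, HeaderDialect] = {
    "greengenes": HeaderDialect(
        name="greengenes",
        extract_regex=r"([a-z]__.*)$",
        spec=ClassSpec(
            sep=";",
            regex=r"^\s*([a-z])__(.*)$",
            key=(("taxon_rank", "taxon_rank"), ("taxon_name", "taxon_name")),
        ),
        render=_render_greengenes,
    ),
    "silva": HeaderDialect(
        name="silva",
        extract_regex=r"(.+)$",
        spec=ClassSpec(sep=";"),
        render=_render_silva,
    ),
    "rdp": HeaderDialect(
        name="rdp",
        extract_regex=r"([^\t]+;[^\t]+)$",  # lineage = last tab-field with ';'
        spec=ClassSpec(
            sep=None,
            regex=r"([^;]+);([^;]+);?",
            key=(("taxon_name", "taxon_name"), ("taxon_rank", "taxon_rank")),
        ),
        render=_render_rdp,
    ),
    "generic": HeaderDialect(
        name="generic",
        extract_regex=r"(.+)$",
        spec=ClassSpec(sep=";"),
        render=_render_silva,
    ),
}


def read_fasta_classifications(path, dialect: HeaderDialect | str = "generic") -> ParseResult:
    """Parse a FASTA file whose headers embed classifications.

    One ``tax_data`` record per sequence (seq_id, description, sequence,
    linked to the most specific taxon); headers the dialect cannot parse
    are reported per record in the failures list.  Wrapped sequence lines
    and CRLF endings are tolerated.
    """
    if isinstance(dialect, str):
        if dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {dialect!r}; expected {sorted(DIALECTS)}")
        dialect = DIALECTS[dialect]
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    pattern = re.compile(dialect.extract_regex)
    failures: list[ParseFailure] = []
    lineages, parsed_infos, rows = [], [], []
    for i, rec in enumerate(records):
        header = rec.description
        m = pattern.search(header)
        if m is None:
            failures.append(
                ParseFailure(i, header, f"no lineage matching {dialect.extract_regex!r}")
            )
            continue
        try:
            parsed = parse_classification(m.group(1), dialect.spec)
        except ValueError as exc:
            failures.append(ParseFailure(i, header, str(exc)))
            continue
        lineages.append([t.to_taxon() for t in parsed])
        parsed_infos.append(parsed)
        rows.append(
            {"seq_id": rec.id, "description": header, "sequence": str(rec.seq)}
        )
    tax_rows = pd.DataFrame(rows, columns=["seq_id", "description", "sequence"])
    return _assemble(lineages, parsed_infos, tax_rows, dialect.spec, failures)


# ---------------------------------------------------------------------------
# delimited tables

_SEPS = {"csv": ",", "tsv": "\t"}


def read_delimited(path, dialect: str = "csv", header: bool = True) -> pd.DataFrame:
    """Read a CSV/TSV into a table of strings (caller types the columns).

    Quoted fields may contain the delimiter; a row with more fields than
    the header is rejected with its line number.
    """
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be one of {sorted(_SEPS)}")
    import csv

    with open(path, newline="") as handle:
        rows = [
            (line_no, row)
            for line_no, row in enumerate(csv.reader(handle, delimiter=_SEPS[dialect]), 1)
            if row
        ]
    if not rows:
        return pd.DataFrame()
    width = len(rows[0][1])
    for line_no, row in rows:
        if len(row) != width:
            raise ValueError(
                f"malformed delimited file {path}: line {line_no} has "
                f"{len(row)} fields, expected {width}"
            )
    if header:
        columns, data = rows[0][1], [r for _, r in rows[1:]]
    else:
        columns = [f"c{i}" for i in range(width)]
        data = [r for _, r in rows]
    return pd.DataFrame(data, columns=columns, dtype=str)


def write_delimited(table: pd.DataFrame, path, dialect: str = "csv") -> None:
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be one of {sorted(_SEPS)}")
    table.to_csv(path, sep=_SEPS[dialect], index=False)


# ---------------------------------------------------------------------------
# versioned JSON serialization


def _db_to_json(db):
    if db is None:
        return None
    if isinstance(db, str):
        return db
    return {
        "name": db.name,
        "url": db.url,
        "description": db.description,
        "id_regex": db.id_regex,
    }


def _db_from_json(doc):
    if doc is None or isinstance(doc, str):
        return doc
    return DatabaseInfo(**doc)


def _wrap_to_json(obj):
    if obj is None:
        return None
    return {"value": obj.value, "database": _db_to_json(obj.database)}


def _taxon_to_json(taxon: Taxon) -> dict:
    return {
        "name": _wrap_to_json(taxon.name),
        "rank": _wrap_to_json(taxon.rank),
        "id": _wrap_to_json(taxon.id),
    }


def _taxon_from_json(doc: dict) -> Taxon:
    def unwrap(part, cls):
        if part is None:
            return None
        return cls(part["value"], database=_db_from_json(part["database"]))

    return Taxon(
        name=unwrap(doc["name"], TaxonName),
        rank=unwrap(doc["rank"], TaxonRank),
        id=unwrap(doc["id"], TaxonId),
    )


def _clean(value):
    if value is None or (not isinstance(value, (str, list, dict)) and pd.isna(value)):
        return None
    if hasattr(value, "item"):
        return value.item()
    return value


def _dataset_to_json(payload):
    if isinstance(payload, pd.DataFrame):
        return {
            "kind": "table",
            "columns": [
                {
                    "name": str(col),
                    "dtype": str(payload[col].dtype),
                    "values": [_clean(v) for v in payload[col]],
                }
                for col in payload.columns
            ],
        }
    if isinstance(payload, pd.Series):
        return {
            "kind": "mapping",
            "dtype": str(payload.dtype),
            "keys": [_clean(k) for k in payload.index],
            "values": [_clean(v) for v in payload],
        }
    return {"kind": "sequence", "values": [_clean(v) for v in payload]}


def _series_from(values, dtype):
    s = pd.Series(values, dtype=object)
    try:
        return s.astype(dtype)
    except (TypeError, ValueError):
        return s


def _dataset_from_json(doc):
    kind = doc.get("kind")
    if kind == "table":
        data = {
            col["name"]: _series_from(col["values"], col["dtype"])
            for col in doc["columns"]
        }
        return pd.DataFrame(data, columns=[c["name"] for c in doc["columns"]])
    if kind == "mapping":
        return pd.Series(
            _series_from(doc["values"], doc["dtype"]).to_list(),
            index=doc["keys"],
            dtype=doc["dtype"] if doc["dtype"] == "object" else None,
        )
    if kind == "sequence":
        return list(doc["values"])
    raise ValueError(f"unknown dataset kind {kind!r} in document")


def serialize_taxmap(tm: Taxmap) -> str:
    """Serialize a taxmap (taxa, edges, datasets, links) to versioned JSON.

    Funcs are arbitrary callables and are not serialized; a warning is
    emitted when any are present.
    """
    if tm.funcs:
        warnings.warn(
            f"funcs {sorted(tm.funcs)} are not serializable and were dropped"
        )
    doc = {
        "schema_version": SCHEMA_VERSION,
        "taxa": {tid: _taxon_to_json(t) for tid, t in tm.graph.nodes.items()},
        "edges": [[parent, child] for parent, child in tm.graph.edges],
        "datasets": [
            {"name": name, **_dataset_to_json(payload)}
            for name, payload in tm.data.items()
        ],
    }
    return json.dumps(doc, indent=1)


def deserialize_taxmap(text: str) -> Taxmap:
    """Inverse of :func:`serialize_taxmap`; rejects unknown schema versions."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"not a valid taxmap document: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise ValueError("not a taxmap document: missing schema_version")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {doc['schema_version']!r}; "
            f"this reader supports version {SCHEMA_VERSION}"
        )
    for field in ("taxa", "edges", "datasets"):
        if field not in doc:
            raise ValueError(f"schema violation: missing field {field!r}")
    nodes = {tid: _taxon_from_json(t) for tid, t in doc["taxa"].items()}
    parents = {child: parent for parent, child in doc["edges"]}
    tm = Taxmap(TaxonomyGraph(nodes, parents))
    for ds in doc["datasets"]:
        tm.data[ds["name"]] = _dataset_from_json(ds)
    return tm


# ---------------------------------------------------------------------------
# newick export


def export_newick(graph: TaxonomyGraph) -> str:
    """Render the forest as newick, one tree per root (newline separated).

    Internal nodes keep their labels; names with spaces or newick
    metacharacters are quoted.  The leaf set of the parsed-back trees
    equals the taxonomy's leaves.
    """
    children = graph.children_map()

    def build(node_id: str, parent: dendropy.Node, tree: dendropy.Tree):
        node = dendropy.Node()
        node.label = graph.nodes[node_id].name_str
        parent.add_child(node)
        for child in children[node_id]:
            build(child, node, tree)

    out = []
    for root in tree_parts(graph, "roots"):
        tree = dendropy.Tree()
        tree.seed_node.label = graph.nodes[root].name_str
        for child in children[root]:
            build(child, tree.seed_node, tree)
        text = tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_leaf_node_labels=False,
            suppress_internal_node_labels=False,
            preserve_spaces=True,
        ).strip()
        out.append(text)
    return "\n".join(out)
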