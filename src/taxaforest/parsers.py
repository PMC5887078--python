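"""Parsers: classifications, taxon names/IDs and sequence IDs → taxmaps.

Taxonomic information reaches an analysis in three encodings — plain
vectors, table columns, or substrings of complex strings such as FASTA
headers — and carries one of four kinds of content: a full classification,
a taxon ID, a taxon name, or a sequence ID.  The functions here cover the
full grid: :func:`parse_tax_data` for classifications already in tables or
vectors, :func:`extract_tax_data` for information embedded in raw strings,
and :func:`lookup_tax_data` when only a name/ID is present and the lineage
must come from a resolver (an offline, file-backed lookup service here;
no network access is ever attempted).

All parsing is driven by a :class:`ClassSpec`: a separator, a regular
expression with capture groups, and a key assigning a role to each group
(taxon_name, taxon_rank, or info).  For example the classification string
``"Hominidae_f_2;Homo_g_3;sapiens_s_4"`` parses with separator ``";"``,
regex ``"(.+)_(.+)_(.+)"`` and key
``[("my_taxon", "taxon_name"), ("my_rank", "taxon_rank"), ("my_id", "info")]``;
the key's output names become column names of the per-taxon table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import Hierarchy, Taxon, TaxonomyBuilder
from .taxmap import LINK_COLUMN, Taxmap

__all__ = [
    "ClassSpec",
    "ParseKey",
    "ParsedTaxon",
    "ParseFailure",
    "ParseResult",
    "Resolver",
    "DictResolver",
    "FileResolver",
    "NcbiDumpResolver",
    "parse_classification",
    "parse_tax_data",
    "extract_tax_data",
    "lookup_tax_data",
]

CLASS_ROLES = ("taxon_name", "taxon_rank", "info")
EXTRACT_ROLES = ("taxon_name", "taxon_id", "class", "seq_id", "info")
LOOKUP_ROLES = ("taxon_name", "taxon_id", "seq_id")


def _normalise_key(key, allowed: tuple[str, ...]):
    if isinstance(key, Mapping):
        key = list(key.items())
    key = tuple((str(name), str(role)) for name, role in key)
    names = [name for name, _ in key]
    if len(set(names)) != len(names):
        raise ValueError(f"key output names must be unique, got {names}")
    for _, role in key:
        if role not in allowed:
            raise ValueError(f"unknown key role {role!r}; expected one of {allowed}")
    return key


@dataclass(frozen=True)
class ClassSpec:
    """How to split and interpret one classification string.

    sep: separator between taxa, or None for global-match mode in which
    ``regex`` is applied repeatedly along the string (needed for formats
    whose names and ranks alternate with a single separator).
    regex: pattern with capture groups, applied anchored to each separated
    segment; None means the whole segment is the taxon name.
    key: one (output_name, role) per capture group, roles among
    taxon_name / taxon_rank / info; exactly one taxon_name.
    """

    sep: str | None = ";"
    regex: str | None = None
    key: tuple = (("taxon_name", "taxon_name"),)

    def __post_init__(self) -> None:
        object.__setattr__(self, "key", _normalise_key(self.key, CLASS_ROLES))
        roles = [role for _, role in self.key]
        if self.regex is not None:
            n_groups = re.compile(self.regex).groups
            if n_groups != len(self.key):
                raise ValueError(
                    f"regex has {n_groups} capture groups but key has "
                    f"{len(self.key)} entries"
                )
            if roles.count("taxon_name") != 1:
                raise ValueError("key must contain exactly one taxon_name role")
        elif self.sep is None:
            raise ValueError("a regex is required when sep is None (global-match mode)")

    @property
    def name_column(self) -> str:
        for name, role in self.key:
            if role == "taxon_name":
                return name
        return "taxon_name"

    @property
    def rank_column(self) -> str | None:
        for name, role in self.key:
            if role == "taxon_rank":
                return name
        return None


@dataclass(frozen=True)
class ParsedTaxon:
    name: str
    rank: str | None = None
    info: Mapping[str, str] = field(default_factory=dict)

    def to_taxon(self, default_rank: str | None = None) -> Taxon:
        return Taxon(self.name, rank=self.rank if self.rank is not None else default_rank)


def _route_groups(groups: Sequence[str], key) -> ParsedTaxon:
    name, rank, info = "", None, {}
    for value, (out_name, role) in zip(groups, key):
        if role == "taxon_name":
            name = value or ""
        elif role == "taxon_rank":
            rank = value
        else:
            info[out_name] = value
    return ParsedTaxon(name, rank, info)


def parse_classification(
    text: str, spec: ClassSpec, allow_empty: bool = False
) -> list[ParsedTaxon]:
    """Split one classification string into taxa, most inclusive first.

    With a separator, segments are whitespace-trimmed and the regex (if
    any) must match each whole segment.  Without a separator the regex is
    applied repeatedly along the string; a final unpaired token left over
    after the last match becomes a rank-less taxon, which handles formats
    that alternate name and rank tokens and end on a name.  Trailing taxa
    with empty names are dropped unless ``allow_empty`` is set.
    """
    taxa: list[ParsedTaxon] = []
    if spec.sep is not None:
        for segment in (s.strip() for s in str(text).split(spec.sep)):
            if segment == "":
                taxa.append(ParsedTaxon(""))
            elif spec.regex is None:
                taxa.append(ParsedTaxon(segment))
            else:
                m = re.fullmatch(spec.regex, segment)
                if m is None:
                    raise ValueError(
                        f"segment {segment!r} does not match pattern {spec.regex!r}"
                    )
                taxa.append(_route_groups(m.groups(), spec.key))
    else:
        last_end = 0
        for m in re.finditer(spec.regex, str(text)):
            taxa.append(_route_groups(m.groups(), spec.key))
            last_end = m.end()
        tail = str(text)[last_end:].strip().strip(";").strip()
        if tail:
            if ";" in tail:
                raise ValueError(
                    f"unparsed trailing text {tail!r} for pattern {spec.regex!r}"
                )
            taxa.append(ParsedTaxon(tail))
        if not taxa:
            raise ValueError(
                f"string {text!r} contains no match for pattern {spec.regex!r}"
            )
    if not allow_empty:
        while taxa and taxa[-1].name == "":
            taxa.pop()
        if any(t.name == "" for t in taxa):
            raise ValueError(
                f"classification {text!r} has an empty taxon name mid-lineage "
                "(pass allow_empty=True to keep empty names)"
            )
    return taxa


@dataclass(frozen=True)
class ParseFailure:
    index: int
    query: str
    reason: str


@dataclass
class ParseResult:
    """A taxmap holding the parsed data, plus a report of failed inputs.

    The taxmap carries two datasets: ``tax_data`` (the source records with
    a ``taxon_id`` column prepended, linking each record to the most
    specific taxon of its lineage) and ``class_data`` (one row per taxon
    instance per record: taxon_id, source-record index, and the per-taxon
    key columns such as names, ranks and any info captures).
    """

    taxmap: Taxmap
    failures: list[ParseFailure] = field(default_factory=list)


# ---------------------------------------------------------------------------
# resolvers: offline name/ID/sequence-ID → classification lookup


class Resolver:
    """Contract: deterministic lookup of a classification.

    ``lookup(kind, query)`` with kind in {taxon_name, taxon_id, seq_id}
    returns a :class:`Hierarchy` or None when the query is unknown.
    """

    def lookup(self, kind: str, query: str) -> Hierarchy | None:
        raise NotImplementedError


class DictResolver(Resolver):
    """In-memory resolver backed by {kind: {query: lineage}} mappings.

    Lineages may be :class:`Hierarchy` objects or strings parsed with the
    given :class:`ClassSpec`.  A flat {query: lineage} mapping is accepted
    and then serves every kind.
    """

    def __init__(self, entries: Mapping, spec: ClassSpec | None = None):
        self.spec = spec
        if entries and all(isinstance(v, Mapping) for v in entries.values()):
            self.entries = {k: dict(v) for k, v in entries.items()}
        else:
            self.entries = {kind: dict(entries) for kind in LOOKUP_ROLES}

    def lookup(self, kind: str, query: str) -> Hierarchy | None:
        if kind not in LOOKUP_ROLES:
            raise ValueError(f"unknown lookup kind {kind!r}; expected {LOOKUP_ROLES}")
        lineage = self.entries.get(kind, {}).get(str(query))
        if lineage is None:
            return None
        if isinstance(lineage, Hierarchy):
            return lineage
        if self.spec is None:
            raise ValueError(
                "resolver holds lineage strings but no ClassSpec to parse them"
            )
        parsed = parse_classification(str(lineage), self.spec)
        return Hierarchy([t.to_taxon() for t in parsed])


class FileResolver(DictResolver):
    """Resolver backed by two-column (query, lineage-string) TSV files.

    ``paths`` is either one path (serving every kind) or a {kind: path}
    mapping; lineage strings are parsed with ``spec``.
    """

    def __init__(self, paths, spec: ClassSpec):
        if isinstance(paths, (str, Path)):
            paths = {kind: paths for kind in LOOKUP_ROLES}
        entries: dict[str, dict[str, str]] = {}
        for kind, path in paths.items():
            table: dict[str, str] = {}
            for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}: line {line_no} has {len(parts)} fields, expected 2"
                    )
                table[parts[0]] = parts[1]
            entries[kind] = table
        super().__init__(entries, spec=spec)


class NcbiDumpResolver(Resolver):
    """Resolver backed by taxonomy-dump style nodes/names tables.

    ``nodes_path``: lines "taxid | parent_taxid | rank | ..." and
    ``names_path``: lines "taxid | name | ... | name class" (scientific
    names are preferred).  An optional ``accessions_path`` (two-column TSV
    mapping sequence accession → taxid) enables seq_id lookups.
    """

    def __init__(self, nodes_path, names_path, accessions_path=None):
        self.parents: dict[str, str] = {}
        self.ranks: dict[str, str] = {}
        for line in Path(nodes_path).read_text().splitlines():
            if not line.strip():
                continue
            parts = [p.strip() for p in line.rstrip("\t|").split("\t|\t")]
            taxid, parent, rank = parts[0], parts[1], parts[2]
            self.parents[taxid] = parent
            self.ranks[taxid] = rank
        self.names: dict[str, str] = {}
        self.by_name: dict[str, str] = {}
        for line in Path(names_path).read_text().splitlines():
            if not line.strip():
                continue
            parts = [p.strip() for p in line.rstrip("\t|").split("\t|\t")]
            taxid, name = parts[0], parts[1]
            name_class = parts[3] if len(parts) > 3 else "scientific name"
            if taxid not in self.names or name_class == "scientific name":
                self.names[taxid] = name
            self.by_name.setdefault(name, taxid)
        self.accessions: dict[str, str] = {}
        if accessions_path is not None:
            for line in Path(accessions_path).read_text().splitlines():
                if line.strip():
                    acc, taxid = line.split("\t")[:2]
                    self.accessions[acc] = taxid

    def _hierarchy_for(self, taxid: str) -> Hierarchy | None:
        if taxid not in self.parents:
            return None
        chain = [taxid]
        while True:
            parent = self.parents.get(chain[-1])
            if parent is None or parent == chain[-1]:  # dump roots self-point
                break
            chain.append(parent)
        chain.reverse()
        return Hierarchy(
            [
                Taxon(self.names.get(t, t), rank=self.ranks.get(t), id=t)
                for t in chain
            ]
        )

    def lookup(self, kind: str, query: str) -> Hierarchy | None:
        query = str(query)
        if kind == "taxon_id":
            return self._hierarchy_for(query)
        if kind == "taxon_name":
            taxid = self.by_name.get(query)
            return None if taxid is None else self._hierarchy_for(taxid)
        if kind == "seq_id":
            taxid = self.accessions.get(query)
            return None if taxid is None else self._hierarchy_for(taxid)
        raise ValueError(f"unknown lookup kind {kind!r}; expected {LOOKUP_ROLES}")


# ---------------------------------------------------------------------------
# assembling parse results


def _class_data_columns(spec: ClassSpec | None) -> list[str]:
    if spec is None:
        return ["taxon_name", "taxon_rank"]
    cols = [name for name, _ in spec.key]
    if spec.rank_column is None:
        cols.append("taxon_rank")
    return cols


def _assemble(
    lineages: list[list[Taxon] | None],
    parsed_infos: list[list[ParsedTaxon] | None],
    tax_rows: pd.DataFrame,
    spec: ClassSpec | None,
    failures: list[ParseFailure],
) -> ParseResult:
    """Merge per-record lineages into a taxmap with tax_data/class_data."""
    builder = TaxonomyBuilder()
    links: list[str | None] = []
    class_rows: list[dict] = []
    columns = _class_data_columns(spec)
    for idx, lineage in enumerate(lineages):
        if lineage is None or not lineage:
            links.append(None)
            continue
        ids = builder.add_lineage_ids(lineage)
        links.append(ids[-1])
        parsed = parsed_infos[idx]
        for j, (node_id, taxon) in enumerate(zip(ids, lineage)):
            row = {LINK_COLUMN: node_id, "input_index": idx}
            if parsed is not None:
                pt = parsed[j]
                if spec is not None:
                    row[spec.name_column] = pt.name
                    rank_col = spec.rank_column or "taxon_rank"
                    row[rank_col] = taxon.rank_str
                    row.update(pt.info)
            else:
                row["taxon_name"] = taxon.name_str
                row["taxon_rank"] = taxon.rank_str
            class_rows.append(row)
    tax_data = tax_rows.copy().reset_index(drop=True)
    tax_data.insert(0, LINK_COLUMN, pd.array(links, dtype=object))
    class_data = pd.DataFrame(
        class_rows, columns=[LINK_COLUMN, "input_index", *columns]
    )
    tm = Taxmap(builder.graph)
    tm.attach_dataset("tax_data", tax_data)
    tm.attach_dataset("class_data", class_data)
    return ParseResult(tm, failures)


def _as_table(source) -> tuple[pd.DataFrame, list | None]:
    if isinstance(source, pd.DataFrame):
        return source, None
    values = list(source)
    return pd.DataFrame({"input": values}), values


def _resolve_columns(table: pd.DataFrame, cols) -> list[str]:
    out = []
    for c in cols:
        if isinstance(c, int):
            out.append(table.columns[c])
        elif c in table.columns:
            out.append(c)
        else:
            raise KeyError(f"classification column {c!r} not in table")
    return out


def parse_tax_data(
    source,
    class_cols=None,
    spec: ClassSpec | None = None,
    named_by_rank: bool = False,
    extra_datasets: Mapping[str, object] | None = None,
    mappings: Mapping[str, object] | None = None,
) -> ParseResult:
    """Parse classifications already held in a table or vector.

    The classification may be spread over several columns, packed into one
    separator-delimited column, or both: per record, ``class_cols`` are
    concatenated in order and each cell is further split by ``spec``.
    Other columns are preserved; each row of the output ``tax_data`` gains
    a ``taxon_id`` link to the most specific taxon of its lineage.  With
    ``named_by_rank`` the column names become rank labels for taxa that
    the spec itself left unranked.

    ``extra_datasets`` are additional payloads linked to the same taxa via
    ``mappings``: either ``{"extra_name": ("source_col", "extra_col")}``
    shared-key equality or the positional token ``"index"``.
    """
    table, _ = _as_table(source)
    if class_cols is None:
        class_cols = ["input"] if "input" in table.columns else list(table.columns)
    cols = _resolve_columns(table, class_cols)
    if spec is None:
        spec = ClassSpec()
    lineages: list[list[Taxon] | None] = []
    parsed_infos: list[list[ParsedTaxon] | None] = []
    for _, row in table.iterrows():
        taxa: list[Taxon] = []
        parsed_all: list[ParsedTaxon] = []
        for col in cols:
            cell = row[col]
            if cell is None or (not isinstance(cell, str) and pd.isna(cell)) or str(cell).strip() == "":
                continue
            parsed = parse_classification(str(cell), spec)
            default_rank = col if named_by_rank else None
            taxa.extend(t.to_taxon(default_rank=default_rank) for t in parsed)
            parsed_all.extend(parsed)
        lineages.append(taxa or None)
        parsed_infos.append(parsed_all or None)
    result = _assemble(lineages, parsed_infos, table, spec, [])
    _link_extras(result.taxmap, table, extra_datasets or {}, mappings or {})
    return result


def _link_extras(tm: Taxmap, source: pd.DataFrame, extra_datasets, mappings) -> None:
    source_links = tm.data["tax_data"][LINK_COLUMN]
    for name, payload in extra_datasets.items():
        rule = mappings.get(name)
        if rule is None:
            tm.attach_dataset(name, payload)
            continue
        if not isinstance(payload, pd.DataFrame):
            raise TypeError(
                f"extra dataset {name!r} must be a table to be taxon-linked"
            )
        payload = payload.copy().reset_index(drop=True)
        if rule == "index":
            if len(payload) != len(source):
                raise ValueError(
                    f"positional mapping requires equal lengths; dataset {name!r} "
                    f"has {len(payload)} records for {len(source)} source rows"
                )
            links = list(source_links)
        else:
            src_col, ds_col = rule
            if src_col not in source.columns:
                raise KeyError(f"mapping key {src_col!r} not in source table")
            if ds_col not in payload.columns:
                raise KeyError(f"mapping key {ds_col!r} not in dataset {name!r}")
            by_key: dict = {}
            for key, link in zip(source[src_col], source_links):
                by_key.setdefault(key, link)
            missing = [k for k in payload[ds_col] if k not in by_key]
            if missing:
                raise ValueError(
                    f"dataset {name!r} keys absent from source: {missing[:5]}"
                )
            links = [by_key[k] for k in payload[ds_col]]
        payload.insert(0, LINK_COLUMN, pd.array(links, dtype=object))
        tm.attach_dataset(name, payload)


class ParseKey:
    """Key for :func:`extract_tax_data`: one (output_name, role) per
    capture group, with exactly one primary role among
    taxon_name / taxon_id / class / seq_id; other groups are info."""

    PRIMARY = ("taxon_name", "taxon_id", "class", "seq_id")

    def __init__(self, entries):
        self.entries = _normalise_key(entries, EXTRACT_ROLES)
        primaries = [(n, r) for n, r in self.entries if r in self.PRIMARY]
        if len(primaries) != 1:
            raise ValueError(
                f"key must contain exactly one of {self.PRIMARY}, got {primaries}"
            )
        self.primary_name, self.primary_role = primaries[0]

    def __len__(self) -> int:
        return len(self.entries)


def extract_tax_data(
    strings: Iterable[str],
    regex: str,
    key,
    spec: ClassSpec | None = None,
    resolver: Resolver | None = None,
    strict: bool = False,
) -> ParseResult:
    """Extract taxonomic information embedded in raw strings.

    ``regex`` captures are routed by ``key`` roles: a ``class`` capture is
    parsed with ``spec``; ``taxon_name``/``taxon_id``/``seq_id`` captures
    are resolved to classifications through ``resolver``; ``info``
    captures become tax_data columns.  Strings the regex does not match
    are excluded from tax_data and reported as failures (or raise, with
    ``strict``); unresolved lookups keep their record with a missing link.
    """
    if not isinstance(key, ParseKey):
        key = ParseKey(key)
    pattern = re.compile(regex)
    if pattern.groups != len(key):
        raise ValueError(
            f"regex has {pattern.groups} capture groups but key has {len(key)} entries"
        )
    if key.primary_role == "class":
        if spec is None:
            raise ValueError("a ClassSpec is required when the key has a class role")
    elif resolver is None:
        raise ValueError(
            f"a resolver is required when the key has a {key.primary_role!r} role"
        )
    strings = [str(s) for s in strings]
    failures: list[ParseFailure] = []
    lineages: list[list[Taxon] | None] = []
    parsed_infos: list[list[ParsedTaxon] | None] = []
    rows: list[dict] = []
    kept_indices: list[int] = []
    for i, s in enumerate(strings):
        m = pattern.search(s)
        if m is None:
            failures.append(ParseFailure(i, s, f"no match for pattern {regex!r}"))
            if strict:
                raise ValueError(f"string {s!r} does not match pattern {regex!r}")
            continue
        row = {
            out_name: value for value, (out_name, _) in zip(m.groups(), key.entries)
        }
        primary = row[key.primary_name]
        if key.primary_role == "class":
            parsed = parse_classification(primary, spec)
            lineages.append([t.to_taxon() for t in parsed])
            parsed_infos.append(parsed)
        else:
            hierarchy = resolver.lookup(key.primary_role, primary)
            if hierarchy is None:
                failures.append(
                    ParseFailure(i, primary, f"unresolved {key.primary_role}")
                )
                lineages.append(None)
                parsed_infos.append(None)
            else:
                lineages.append(list(hierarchy.taxa))
                parsed_infos.append(None)
        rows.append(row)
        kept_indices.append(i)
    if strings and not rows:
        raise ValueError(f"no input string matches pattern {regex!r}")
    tax_rows = pd.DataFrame(rows, columns=[n for n, _ in key.entries])
    result = _assemble(
        lineages, parsed_infos, tax_rows,
        spec if key.primary_role == "class" else None, failures,
    )
    return result


def lookup_tax_data(
    source,
    kind: str,
    resolver: Resolver,
    column: str | None = None,
) -> ParseResult:
    """Resolve taxon names, taxon IDs or sequence IDs to classifications.

    Queries come from a vector or from ``column`` of a table; each is
    resolved through the (offline) resolver and merged into one taxonomy.
    Unresolved queries keep their record with a missing taxon link and are
    listed in the failures report.
    """
    if resolver is None:
        raise ValueError("lookup_tax_data requires a resolver")
    if kind not in LOOKUP_ROLES:
        raise ValueError(f"unknown lookup kind {kind!r}; expected {LOOKUP_ROLES}")
    table, _ = _as_table(source)
    if column is None:
        column = "input" if "input" in table.columns else table.columns[0]
    if column not in table.columns:
        raise KeyError(f"query column {column!r} not in table")
    failures: list[ParseFailure] = []
    lineages: list[list[Taxon] | None] = []
    for i, query in enumerate(table[column]):
        if query is None or pd.isna(query) or str(query) == "":
            failures.append(ParseFailure(i, str(query), "empty query"))
            lineages.append(None)
            continue
        hierarchy = resolver.lookup(kind, str(query))
        if hierarchy is None:
            failures.append(ParseFailure(i, str(query), f"unresolved {kind}"))
            lineages.append(None)
        else:
            lineages.append(list(hierarchy.taxa))
    parsed_infos: list = [None] * len(lineages)
    return _assemble(lineages, parsed_infos, table, None, failures)
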