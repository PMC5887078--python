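"""Synthetic taxonomies and taxmaps for testing and demonstration.

The generator emulates the shape of real classification data — a forest of
a few roots, ranked levels named after the usual kingdom→species ladder
(single-letter codes k/p/c/o/f/g/s, so rank-coded header dialects can
express them), and an observation table whose records land on taxa at any
rank, the way occurrence records or sequence classifications do.  Sibling
taxa always receive distinct names so every generated forest is exactly
recoverable from its leaf classifications; real data can violate that only
by containing genuinely indistinguishable records.

Everything is driven by a :class:`FixtureSpec` plus a seed: identical
spec and seed give identical output, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import DIALECTS, HeaderDialect
from .model import TaxonomyGraph, Taxon, id_generator, supertaxa
from .taxmap import LINK_COLUMN, Taxmap

__all__ = ["FixtureSpec", "random_taxonomy", "random_taxmap", "render_fasta"]

# rank ladder: single-letter codes usable by every header dialect
RANKS = ("k", "p", "c", "o", "f", "g", "s")

_SYLLABLES = (
    "ba", "co", "di", "fu", "ge", "hy", "lo", "mi", "ne", "or",
    "pa", "qui", "ro", "sa", "tu", "ve", "xy", "zo",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic taxonomy/taxmap.

    n_roots: trees in the forest.  depth_range: (min, max) levels per
    tree, inclusive; capped at the rank ladder length.  branching_mean:
    mean child count of internal nodes (Poisson, at least one child while
    below the target depth).  max_taxa: hard cap on forest size.
    name_syllables: syllables per generated name.  n_records: rows of the
    observation table, each linked to a uniformly chosen taxon.
    seed: RNG seed; same spec+seed ⇒ identical fixture.
    """

    n_roots: int = 2
    depth_range: tuple[int, int] = (2, 5)
    branching_mean: float = 1.8
    max_taxa: int = 60
    name_syllables: int = 3
    n_records: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.depth_range
        if lo > hi:
            raise ValueError(f"depth_range min {lo} exceeds max {hi}")
        if not (1 <= lo and hi <= len(RANKS)):
            raise ValueError(f"depth_range must lie within [1, {len(RANKS)}]")
        if self.n_roots < 1 or self.max_taxa < self.n_roots:
            raise ValueError("need at least one root and max_taxa >= n_roots")
        if self.n_records < 0 or self.branching_mean < 0:
            raise ValueError("counts must be non-negative")


def _name(rng: np.random.Generator, n_syllables: int) -> str:
    parts = rng.choice(len(_SYLLABLES), size=n_syllables)
    word = "".join(_SYLLABLES[i] for i in parts)
    return word.capitalize()


def _distinct_names(rng, count: int, n_syllables: int) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < count:
        nm = _name(rng, n_syllables)
        if nm not in seen:
            seen.add(nm)
            names.append(nm)
    return names


def random_taxonomy(spec: FixtureSpec | None = None, **overrides) -> TaxonomyGraph:
    """Generate a validate-clean random forest within the spec's bounds."""
    if spec is None:
        spec = FixtureSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a FixtureSpec or keyword overrides, not both")
    rng = np.random.default_rng(spec.seed)
    ids = id_generator()
    graph = TaxonomyGraph()
    lo, hi = spec.depth_range
    root_names = _distinct_names(rng, spec.n_roots, spec.name_syllables)
    # (node_id, depth, target_depth) frontier, breadth-first per root
    frontier: list[tuple[str, int, int]] = []
    for root_name in root_names:
        node_id = next(ids)
        graph.nodes[node_id] = Taxon(root_name, rank=RANKS[0])
        graph.parents[node_id] = None
        target = int(rng.integers(lo, hi + 1))
        frontier.append((node_id, 1, target))
    while frontier:
        node_id, depth, target = frontier.pop(0)
        if depth >= target or len(graph) >= spec.max_taxa:
            continue
        n_children = int(rng.poisson(spec.branching_mean))
        if depth < target:
            n_children = max(1, n_children)
        n_children = min(n_children, spec.max_taxa - len(graph))
        for child_name in _distinct_names(rng, n_children, spec.name_syllables):
            child_id = next(ids)
            graph.nodes[child_id] = Taxon(child_name, rank=RANKS[depth])
            graph.parents[child_id] = node_id
            frontier.append((child_id, depth + 1, target))
    return graph


def random_taxmap(spec: FixtureSpec | None = None, **overrides) -> Taxmap:
    """A random taxonomy plus an observation table ("info": taxon_id,
    value, site) with records linked uniformly to taxa."""
    if spec is None:
        spec = FixtureSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a FixtureSpec or keyword overrides, not both")
    graph = random_taxonomy(spec)
    rng = np.random.default_rng(spec.seed + 1)
    ids = graph.ids()
    links = [ids[i] for i in rng.integers(0, len(ids), size=spec.n_records)]
    table = pd.DataFrame(
        {
            LINK_COLUMN: pd.array(links, dtype=object),
            "value": np.round(rng.normal(10.0, 3.0, size=spec.n_records), 3),
            "site": [f"site_{i}" for i in rng.integers(0, 4, size=spec.n_records)],
        }
    )
    tm = Taxmap(graph)
    tm.attach_dataset("info", table)
    return tm


def render_fasta(
    tm: Taxmap,
    dialect: HeaderDialect | str,
    path,
    dataset: str | None = None,
    seed: int = 0,
    line_width: int = 60,
) -> Path:
    """Write one FASTA record per linked record of ``dataset``.

    Headers carry each record's full lineage in the dialect's encoding;
    reading the file back with the same dialect reproduces the lineage
    multiset.  Sequences come from a ``sequence`` column when present,
    otherwise random nucleotides (deterministic under ``seed``).  Records
    with a missing taxon link have no lineage and are skipped; a dialect
    that cannot express a lineage (e.g. missing ranks for a rank-coded
    dialect) raises ValueError.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    if dialect.render is None:
        raise ValueError(f"dialect {dialect.name!r} has no renderer")
    if dataset is None:
        dataset = tm._first_linked_table()
        if dataset is None:
            raise ValueError("taxmap has no taxon-linked dataset to render")
    payload = tm.data[dataset]
    if not isinstance(payload, pd.DataFrame):
        raise TypeError(f"render_fasta needs a table dataset, got {dataset!r}")
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    ancestry = supertaxa(tm.graph, recursive=True, include_self=True)
    for i, link in enumerate(payload[LINK_COLUMN]):
        if link is None or pd.isna(link):
            continue
        lineage = [
            (tm.graph.nodes[a].name_str, tm.graph.nodes[a].rank_str)
            for a in reversed(ancestry[link])
        ]
        header = dialect.render(lineage)
        if "sequence" in payload.columns:
            seq = str(payload["sequence"].iloc[i])
        else:
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=line_width))
        lines.append(f">{header}")
        lines.extend(seq[k: k + line_width] for k in range(0, len(seq), line_width))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
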