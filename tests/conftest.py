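"""Shared fixtures and independent oracles for the test suite.

The naive_* functions re-derive tree relations straight from the edge
list by repeated scanning/recursion, with none of the package's traversal
machinery, so they can serve as an independent check of the edge-list
implementation.
"""

from __future__ import annotations

import collections

import pandas as pd
import pytest

from taxaforest import FixtureSpec, random_taxmap, random_taxonomy, supertaxa


# ---------------------------------------------------------------------------
# naive oracles (edge-list scanning only)


def naive_parent(graph, tid):
    for parent, child in graph.edges:
        if child == tid:
            return parent
    return None


def naive_children(graph, tid):
    return [child for parent, child in graph.edges if parent == tid]


def naive_supertaxa(graph, tid):
    out = []
    current = naive_parent(graph, tid)
    while current is not None:
        out.append(current)
        current = naive_parent(graph, current)
    return out


def naive_subtaxa(graph, tid):
    out = []
    for child in naive_children(graph, tid):
        out.append(child)
        out.extend(naive_subtaxa(graph, child))
    return out


def naive_roots(graph):
    return [tid for tid in graph.nodes if naive_parent(graph, tid) is None]


def naive_leaves(graph):
    return [tid for tid in graph.nodes if not naive_children(graph, tid)]


def naive_branches(graph):
    return [
        tid
        for tid in graph.nodes
        if naive_parent(graph, tid) is not None and len(naive_children(graph, tid)) == 1
    ]


def naive_stems(graph):
    out = set()
    for root in naive_roots(graph):
        current = root
        out.add(current)
        while len(naive_children(graph, current)) == 1:
            current = naive_children(graph, current)[0]
            out.add(current)
    return out


def naive_is_ancestor(graph, a, b):
    return a in naive_supertaxa(graph, b)


# ---------------------------------------------------------------------------
# shared helpers


def lineage_names(tm, dataset):
    """Multiset of root-first name tuples, one per linked record."""
    anc = supertaxa(tm.graph, recursive=True, include_self=True)
    out = collections.Counter()
    for link in tm.data[dataset]["taxon_id"]:
        if link is not None and not pd.isna(link):
            out[tuple(tm.graph.nodes[a].name_str for a in reversed(anc[link]))] += 1
    return out


@pytest.fixture
def chain_taxmap():
    """A→B→C with one record on each taxon."""
    from taxaforest import Taxmap, build_taxonomy

    graph = build_taxonomy([["A", "B", "C"]])
    tm = Taxmap(graph)
    tm.attach_dataset(
        "d",
        pd.DataFrame(
            {"taxon_id": ["aaa", "aab", "aac"], "x": [1.0, 2.0, 3.0]}
        ),
    )
    return tm


@pytest.fixture
def small_forest():
    """Forest {A→(B→D, C), X} for tree-part queries."""
    from taxaforest import build_taxonomy

    return build_taxonomy([["A", "B", "D"], ["A", "C"], ["X"]])


def make_taxmap(seed, **overrides):
    defaults = dict(n_roots=2, depth_range=(2, 5), max_taxa=25, n_records=30)
    defaults.update(overrides)
    return random_taxmap(FixtureSpec(seed=seed, **defaults))


def make_forest(seed, **overrides):
    defaults = dict(n_roots=2, depth_range=(2, 5), max_taxa=50)
    defaults.update(overrides)
    return random_taxonomy(FixtureSpec(seed=seed, **defaults))
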