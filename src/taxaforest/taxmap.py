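"""The taxmap container: a taxonomy plus user datasets kept in sync.

A :class:`Taxmap` couples a :class:`~taxaforest.model.TaxonomyGraph` with
any number of named datasets — tables (pandas DataFrames with a
``taxon_id`` column), keyed mappings (pandas Series indexed by taxon IDs,
duplicate keys allowed) or plain sequences (no taxon link) — and with named
computed variables ("funcs", pure functions of the taxmap).  The verbs
(filter, mutate, arrange, sample) manipulate taxonomy and data
simultaneously so the two never drift apart: every non-missing taxon link
refers to an existing taxon after every verb.

Variables: verbs accept string expressions such as
``"taxon_names == 'Fungi'"`` or ``"n_subtaxa > 10"``.  Names are resolved
at call time against the current object — built-in per-taxon quantities
(taxon_names, n_obs, is_leaf, ...), user funcs, then dataset contents in
attachment order — so a name referenced after a filter reflects the
filtered state, never a stale cache.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import model
from .expr import evaluate

__all__ = [
    "Taxmap",
    "FilterOptions",
    "attach_dataset",
    "resolve_variable",
    "obs",
    "n_obs",
    "filter_taxa",
    "filter_obs",
    "mutate_obs",
    "arrange",
    "sample_n_taxa",
    "sample_frac_taxa",
    "sample_n_obs",
    "sample_frac_obs",
]

LINK_COLUMN = "taxon_id"

_BUILTIN_NAMES = (
    "taxon_ids",
    "taxon_names",
    "taxon_ranks",
    "n_obs",
    "n_subtaxa",
    "n_supertaxa",
    "is_root",
    "is_leaf",
    "is_stem",
    "is_branch",
)


@dataclass(frozen=True)
class FilterOptions:
    """Options controlling how removed taxa affect survivors and records.

    subtaxa / supertaxa: also keep descendants / ancestors of taxa that
    pass (True = unbounded, integer = depth).  reassign_taxa: re-edge
    surviving subtaxa of removed taxa to their nearest surviving supertaxon
    (else they become roots).  reassign_obs: re-link records of removed
    taxa to the closest surviving supertaxon when one exists.  drop_obs:
    delete records of removed taxa that were not re-linked (else they keep
    a missing-value link).  invert: swap kept and removed sets (the
    reassignment options still behave the same way).
    """

    subtaxa: bool | int = False
    supertaxa: bool | int = False
    reassign_taxa: bool = True
    reassign_obs: bool = True
    drop_obs: bool = True
    invert: bool = False


def _is_table(payload) -> bool:
    return isinstance(payload, pd.DataFrame)


def _is_mapping(payload) -> bool:
    return isinstance(payload, pd.Series)


def _is_linked(payload) -> bool:
    if _is_table(payload):
        return LINK_COLUMN in payload.columns
    return _is_mapping(payload)


class Taxmap:
    """A taxonomy with linked datasets and computed variables."""

    def __init__(
        self,
        graph: model.TaxonomyGraph | None = None,
        data: Mapping[str, object] | None = None,
        funcs: Mapping[str, Callable[["Taxmap"], Sequence]] | None = None,
    ):
        self.graph = graph if graph is not None else model.TaxonomyGraph()
        self.data: dict[str, object] = {}
        self.funcs: dict[str, Callable] = dict(funcs or {})
        for name, payload in (data or {}).items():
            self.attach_dataset(name, payload)

    # -- bookkeeping -------------------------------------------------------

    def copy(self) -> "Taxmap":
        out = Taxmap(self.graph.copy())
        for name, payload in self.data.items():
            if _is_table(payload) or _is_mapping(payload):
                out.data[name] = payload.copy()
            else:
                out.data[name] = list(payload)
        out.funcs = dict(self.funcs)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, Taxmap):
            return NotImplemented
        if self.graph != other.graph or set(self.data) != set(other.data):
            return False
        for name, payload in self.data.items():
            theirs = other.data[name]
            if _is_table(payload):
                if not (_is_table(theirs) and payload.equals(theirs)):
                    return False
            elif _is_mapping(payload):
                if not (_is_mapping(theirs) and payload.equals(theirs)):
                    return False
            elif list(payload) != list(theirs):
                return False
        return set(self.funcs) == set(other.funcs)

    def __repr__(self) -> str:
        n_records = {
            name: len(p) for name, p in self.data.items()
        }
        return (
            f"<Taxmap with {len(self.graph)} taxa, "
            f"{len(self.graph)} edges, datasets {n_records}>"
        )

    def validate(self) -> list[str]:
        """Graph diagnostics plus dataset-link checks; empty means clean."""
        problems = model.validate(self.graph)
        for name, payload in self.data.items():
            for i, link in enumerate(self._links(payload)):
                if link is not None and not pd.isna(link) and link not in self.graph.nodes:
                    problems.append(
                        f"dataset {name!r} record {i} links to unknown taxon {link!r}"
                    )
        return problems

    @staticmethod
    def _links(payload) -> list:
        if _is_table(payload) and LINK_COLUMN in payload.columns:
            return list(payload[LINK_COLUMN])
        if _is_mapping(payload):
            return list(payload.index)
        return []

    # -- datasets ----------------------------------------------------------

    def attach_dataset(self, name: str, payload, link=None) -> "Taxmap":
        """Register a dataset (in place; returns self for chaining).

        ``payload`` may be a DataFrame (taxon-linked iff it has a
        ``taxon_id`` column, or if ``link`` names the column to rename to
        ``taxon_id``), a dict or Series keyed by taxon IDs, or a plain
        sequence (no link).  Links to unknown taxa are rejected, naming
        the offending record; missing-value links are allowed.
        """
        if name in self.data:
            raise ValueError(f"a dataset named {name!r} is already attached")
        if isinstance(payload, Mapping) and not isinstance(payload, pd.Series):
            payload = pd.Series(payload, dtype=object)
        if _is_table(payload):
            payload = payload.copy().reset_index(drop=True)
            if link is not None and link != LINK_COLUMN:
                payload = payload.rename(columns={link: LINK_COLUMN})
        elif not _is_mapping(payload):
            payload = list(payload)
        for i, lk in enumerate(self._links(payload)):
            if lk is not None and not pd.isna(lk) and lk not in self.graph.nodes:
                raise ValueError(
                    f"dataset {name!r} record {i} links to nonexistent taxon {lk!r}"
                )
        self._warn_shadowing(name, payload)
        self.data[name] = payload
        return self

    def _warn_shadowing(self, name: str, payload) -> None:
        existing = set(self.all_names())
        incoming = set(
            payload.columns.drop(LINK_COLUMN, errors="ignore")
        ) if _is_table(payload) else {name}
        shadowed = existing & incoming
        if shadowed:
            warnings.warn(
                f"dataset {name!r} shadows existing variable name(s) "
                f"{sorted(shadowed)}; earlier bindings take precedence",
                stacklevel=3,
            )

    def add_func(self, name: str, fn: Callable[["Taxmap"], Sequence]) -> "Taxmap":
        if name in self.funcs:
            raise ValueError(f"a func named {name!r} is already defined")
        self.funcs[name] = fn
        return self

    def _first_linked_table(self) -> str | None:
        for name, payload in self.data.items():
            if _is_linked(payload):
                return name
        return None

    # -- the variable namespace -------------------------------------------

    def all_names(self) -> dict[str, str]:
        """Every resolvable variable name → its source, in precedence order."""
        out: dict[str, str] = {}
        for b in _BUILTIN_NAMES:
            if b == "n_obs" and self._first_linked_table() is None:
                continue
            out.setdefault(b, "built-in")
        for f in self.funcs:
            out.setdefault(f, "func")
        for name, payload in self.data.items():
            if _is_table(payload):
                for col in payload.columns:
                    if col != LINK_COLUMN:
                        out.setdefault(col, f"column of dataset {name!r}")
            else:
                out.setdefault(name, f"dataset {name!r}")
        return out

    def _builtin(self, name: str) -> pd.Series:
        g = self.graph
        ids = g.ids()
        idx = pd.Index(ids, name=LINK_COLUMN)
        if name == "taxon_ids":
            return pd.Series(ids, index=idx)
        if name == "taxon_names":
            return pd.Series([g.nodes[i].name_str for i in ids], index=idx)
        if name == "taxon_ranks":
            return pd.Series([g.nodes[i].rank_str for i in ids], index=idx)
        if name == "n_obs":
            target = self._first_linked_table()
            if target is None:
                raise KeyError("n_obs requires at least one taxon-linked dataset")
            counts = self.n_obs(target)
            return pd.Series([counts[i] for i in ids], index=idx)
        if name == "n_subtaxa":
            sub = model.subtaxa(g, recursive=True)
            return pd.Series([len(sub[i]) for i in ids], index=idx)
        if name == "n_supertaxa":
            sup = model.supertaxa(g, recursive=True)
            return pd.Series([len(sup[i]) for i in ids], index=idx)
        part_kind = {
            "is_root": "roots", "is_leaf": "leaves",
            "is_stem": "stems", "is_branch": "branches",
        }.get(name)
        if part_kind is not None:
            members = set(model.tree_parts(g, part_kind))
            return pd.Series([i in members for i in ids], index=idx)
        raise KeyError(name)

    def _sources_of(self, name: str) -> list[str]:
        sources = []
        if name in _BUILTIN_NAMES and not (name == "n_obs" and self._first_linked_table() is None):
            sources.append("built-in")
        if name in self.funcs:
            sources.append("func")
        for ds_name, payload in self.data.items():
            if _is_table(payload):
                if name in payload.columns and name != LINK_COLUMN:
                    sources.append(f"column of dataset {ds_name!r}")
            elif name == ds_name:
                sources.append(f"dataset {ds_name!r}")
        return sources

    def resolve_variable(self, name: str, scope: str = "taxa", strict: bool = False) -> pd.Series:
        """Resolve ``name`` to a value sequence, recomputed at call time.

        ``scope="taxa"`` yields one value per taxon (a Series indexed by
        internal taxon ID, in storage order); ``scope=<dataset name>``
        yields one value per record of that dataset, broadcasting
        per-taxon variables through each record's taxon link.
        """
        if strict and len(self._sources_of(name)) > 1:
            raise KeyError(
                f"variable name {name!r} is ambiguous under strict resolution: "
                f"defined by {self._sources_of(name)}"
            )
        if scope == "taxa":
            return self._resolve_taxa(name)
        if scope not in self.data:
            raise KeyError(f"unknown scope {scope!r}; not a dataset name")
        return self._resolve_records(name, scope)

    def _unknown(self, name: str) -> KeyError:
        return KeyError(
            f"unknown variable {name!r}; available names: {sorted(self.all_names())}"
        )

    def _resolve_taxa(self, name: str) -> pd.Series:
        ids = self.graph.ids()
        idx = pd.Index(ids, name=LINK_COLUMN)
        if name in _BUILTIN_NAMES:
            return self._builtin(name)
        if name in self.funcs:
            result = self.funcs[name](self)
            if isinstance(result, Mapping):
                return pd.Series([result[i] for i in ids], index=idx)
            result = list(result)
            if len(result) != len(ids):
                raise ValueError(
                    f"func {name!r} returned {len(result)} values for {len(ids)} taxa"
                )
            return pd.Series(result, index=idx)
        for ds_name, payload in self.data.items():
            if _is_mapping(payload) and name == ds_name:
                first = payload[~payload.index.duplicated()]
                return pd.Series([first.get(i) for i in ids], index=idx)
            if isinstance(payload, list) and name == ds_name and len(payload) == len(ids):
                return pd.Series(list(payload), index=idx)
        raise self._unknown(name)

    def _resolve_records(self, name: str, dataset: str) -> pd.Series:
        payload = self.data[dataset]
        if _is_table(payload) and name in payload.columns and name != LINK_COLUMN:
            return payload[name].reset_index(drop=True)
        if not _is_table(payload) and name == dataset:
            values = payload.to_list() if _is_mapping(payload) else list(payload)
            return pd.Series(values)
        # fall back to per-taxon values broadcast through the record links
        per_taxon = self._resolve_taxa(name)
        links = self._links(payload)
        if not links:
            raise KeyError(
                f"cannot broadcast per-taxon variable {name!r} over unlinked "
                f"dataset {dataset!r}"
            )
        values = [
            per_taxon.get(lk) if (lk is not None and not pd.isna(lk)) else None
            for lk in links
        ]
        return pd.Series(values)

    def _eval_predicate(self, predicate, scope: str):
        """Normalise one predicate to a boolean mask over taxa or records."""
        n = len(self.graph) if scope == "taxa" else len(self.data[scope])
        if callable(predicate) and not isinstance(predicate, str):
            predicate = predicate(self)
        if isinstance(predicate, str):
            predicate = evaluate(
                predicate, lambda name: self.resolve_variable(name, scope=scope)
            )
        if isinstance(predicate, pd.Series):
            predicate = predicate.to_numpy()
        if isinstance(predicate, np.ndarray) and predicate.dtype == bool:
            if len(predicate) != n:
                raise ValueError(
                    f"boolean mask has length {len(predicate)}, expected {n}"
                )
            return predicate
        if isinstance(predicate, (set, frozenset, list, tuple, np.ndarray)):
            items = list(predicate)
            if not items:  # empty selection keeps nothing
                return np.zeros(n, dtype=bool)
            if all(isinstance(x, (bool, np.bool_)) for x in items):
                return self._eval_predicate(np.asarray(items, dtype=bool), scope)
            if all(isinstance(x, (int, np.integer)) for x in items):
                mask = np.zeros(n, dtype=bool)
                for i in items:
                    if not 0 <= i < n:
                        raise IndexError(f"index {i} out of range for size {n}")
                    mask[i] = True
                return mask
            if scope == "taxa" and all(isinstance(x, str) for x in items):
                unknown = [x for x in items if x not in self.graph.nodes]
                if unknown:
                    raise KeyError(f"unknown taxon IDs in predicate: {unknown}")
                wanted = set(items)
                return np.array([tid in wanted for tid in self.graph.ids()])
        raise TypeError(f"cannot interpret predicate {predicate!r}")

    def _combined_mask(self, predicates, scope: str) -> np.ndarray:
        n = len(self.graph) if scope == "taxa" else len(self.data[scope])
        mask = np.ones(n, dtype=bool)
        for p in predicates:
            mask &= self._eval_predicate(p, scope)
        return mask

    # -- observation mapping ----------------------------------------------

    def obs(
        self,
        dataset: str,
        subset: Iterable[str] | None = None,
        recursive: bool | int = True,
        value: str | None = None,
    ) -> dict[str, list]:
        """Record indices (or values) of each taxon and, recursively, its
        subtaxa.  ``recursive=False`` counts only the taxon's own records;
        an integer bounds the subtree depth.  With a single root,
        ``obs(root)`` covers every linked record.
        """
        if dataset not in self.data:
            raise KeyError(f"unknown dataset {dataset!r}")
        payload = self.data[dataset]
        if not _is_linked(payload):
            raise ValueError(f"dataset {dataset!r} has no taxon link")
        links = self._links(payload)
        by_taxon: dict[str, list[int]] = {}
        for i, lk in enumerate(links):
            if lk is not None and not pd.isna(lk):
                by_taxon.setdefault(lk, []).append(i)
        ids = model._check_subset(self.graph, subset)
        if recursive is False:
            groups = {tid: [tid] for tid in ids}
        else:
            depth = True if recursive is True else int(recursive)
            groups = model.subtaxa(
                self.graph, subset=ids, recursive=depth, include_self=True
            )
        values = None
        if value is not None:
            values = self.resolve_variable(value, scope=dataset)
        out: dict[str, list] = {}
        for tid in ids:
            indices = sorted(
                i for member in groups[tid] for i in by_taxon.get(member, [])
            )
            out[tid] = indices if values is None else [values.iloc[i] for i in indices]
        return out

    def n_obs(self, dataset: str | None = None, recursive: bool | int = True) -> dict[str, int]:
        """Per-taxon record count (recursive over subtaxa by default)."""
        if dataset is None:
            dataset = self._first_linked_table()
            if dataset is None:
                raise ValueError("no taxon-linked dataset to count")
        return {tid: len(v) for tid, v in self.obs(dataset, recursive=recursive).items()}

    # -- verbs -------------------------------------------------------------

    def filter_taxa(self, *predicates, **options) -> "Taxmap":
        """Subset taxa, keeping taxonomy and data in sync.

        Predicates (boolean masks, taxon-ID sets, index sets, expression
        strings or callables) are AND-combined.  See :class:`FilterOptions`
        for the keyword options (``subtaxa``, ``supertaxa``,
        ``reassign_taxa``, ``reassign_obs``, ``drop_obs``, ``invert``).
        """
        opts = FilterOptions(**options)
        mask = self._combined_mask(predicates, "taxa")
        ids = self.graph.ids()
        kept = {tid for tid, keep in zip(ids, mask) if keep}
        if opts.subtaxa:
            depth = True if opts.subtaxa is True else int(opts.subtaxa)
            desc = model.subtaxa(self.graph, subset=list(kept), recursive=depth)
            kept |= {d for lst in desc.values() for d in lst}
        if opts.supertaxa:
            depth = True if opts.supertaxa is True else int(opts.supertaxa)
            anc = model.supertaxa(self.graph, subset=list(kept), recursive=depth)
            kept |= {a for lst in anc.values() for a in lst}
        if opts.invert:
            kept = set(ids) - kept
        return self._apply_kept(kept, opts)

    def _nearest_kept_ancestor(self, tid: str, kept: set[str]) -> str | None:
        current = self.graph.parents.get(tid)
        while current is not None:
            if current in kept:
                return current
            current = self.graph.parents.get(current)
        return None

    def _apply_kept(self, kept: set[str], opts: FilterOptions) -> "Taxmap":
        ids = self.graph.ids()
        # new graph: re-edge survivors on the original topology
        new_nodes = {tid: self.graph.nodes[tid] for tid in ids if tid in kept}
        new_parents: dict[str, str | None] = {}
        for tid in new_nodes:
            parent = self.graph.parents.get(tid)
            if parent in kept:
                new_parents[tid] = parent
            elif opts.reassign_taxa:
                new_parents[tid] = self._nearest_kept_ancestor(tid, kept)
            else:
                new_parents[tid] = None
        out = Taxmap(model.TaxonomyGraph(new_nodes, new_parents))
        out.funcs = dict(self.funcs)
        removed = set(ids) - kept
        for name, payload in self.data.items():
            out.data[name] = self._refit_payload(payload, kept, removed, opts)
        return out

    def _record_fate(self, link, kept: set[str], removed: set[str], opts: FilterOptions):
        """Return ("keep", new_link) or ("drop", None) for one record."""
        if link is None or pd.isna(link):
            return "keep", link
        if link in kept:
            return "keep", link
        if link not in removed:  # link to taxon unknown before the filter
            return "keep", link
        if opts.reassign_obs:
            anc = self._nearest_kept_ancestor(link, kept)
            if anc is not None:
                return "keep", anc
        if opts.drop_obs:
            return "drop", None
        return "keep", None  # missing-value placeholder, record retained

    def _refit_payload(self, payload, kept, removed, opts: FilterOptions):
        if _is_table(payload) and LINK_COLUMN in payload.columns:
            table = payload.copy().reset_index(drop=True)
            fates = [
                self._record_fate(lk, kept, removed, opts)
                for lk in table[LINK_COLUMN]
            ]
            new_links = [lk for fate, lk in fates if fate == "keep"]
            keep_rows = [i for i, (fate, _) in enumerate(fates) if fate == "keep"]
            table = table.iloc[keep_rows].reset_index(drop=True)
            table[LINK_COLUMN] = pd.array(new_links, dtype=object)
            return table
        if _is_mapping(payload):
            fates = [
                self._record_fate(lk, kept, removed, opts) for lk in payload.index
            ]
            keep_rows = [i for i, (fate, _) in enumerate(fates) if fate == "keep"]
            new_keys = [fates[i][1] for i in keep_rows]
            return pd.Series(
                [payload.iloc[i] for i in keep_rows], index=new_keys, dtype=payload.dtype
            )
        if _is_table(payload):
            return payload.copy()
        return list(payload)

    def filter_obs(
        self,
        dataset: str,
        *predicates,
        drop_taxa: bool = False,
        **taxa_options,
    ) -> "Taxmap":
        """Subset the records of one dataset; optionally drop taxa whose
        subtree no longer holds any record of that dataset.

        With ``drop_taxa=True`` a taxon survives iff it or any of its
        subtaxa retains at least one record after the row filter; removed
        taxa are handled by the :meth:`filter_taxa` machinery, so
        ``taxa_options`` control how other datasets' records are treated.
        """
        if dataset not in self.data:
            raise KeyError(f"unknown dataset {dataset!r}")
        mask = self._combined_mask(predicates, dataset)
        out = self.copy()
        payload = out.data[dataset]
        if _is_table(payload):
            out.data[dataset] = payload.iloc[np.flatnonzero(mask)].reset_index(drop=True)
        elif _is_mapping(payload):
            out.data[dataset] = payload.iloc[np.flatnonzero(mask)]
        else:
            out.data[dataset] = [v for v, keep in zip(payload, mask) if keep]
        if not drop_taxa:
            return out
        if not _is_linked(out.data[dataset]):
            raise ValueError(f"drop_taxa requires a taxon-linked dataset, got {dataset!r}")
        linked = {
            lk for lk in out._links(out.data[dataset])
            if lk is not None and not pd.isna(lk)
        }
        survivors: set[str] = set()
        for tid in linked:
            survivors.update(out.graph.lineage(tid))
        return out.filter_taxa(survivors, **taxa_options)

    def mutate_obs(
        self, dataset: str, name: str, expression, overwrite: bool = False
    ) -> "Taxmap":
        """Append a column to a table dataset, evaluated per record."""
        if dataset not in self.data:
            raise KeyError(f"unknown dataset {dataset!r}")
        if not _is_table(self.data[dataset]):
            raise TypeError(f"mutate_obs requires a table dataset, got {dataset!r}")
        out = self.copy()
        table = out.data[dataset]
        if name in table.columns and not overwrite:
            raise ValueError(
                f"column {name!r} already exists in dataset {dataset!r}; "
                "pass overwrite=True to replace it"
            )
        if isinstance(expression, str):
            values = evaluate(
                expression, lambda nm: out.resolve_variable(nm, scope=dataset)
            )
        else:
            values = expression
        values = np.asarray(values, dtype=object) if np.ndim(values) else np.repeat(values, len(table))
        if len(values) != len(table):
            raise ValueError(
                f"new column has {len(values)} values for {len(table)} rows"
            )
        table[name] = list(values)
        return out

    def arrange(self, target: str, *keys, descending: bool | Sequence[bool] = False) -> "Taxmap":
        """Reorder taxon storage order or a dataset's records, stably.

        Reordering taxa changes only the storage (and hence reporting)
        order — topology, links and every tree query are unaffected.
        """
        if not keys:
            raise ValueError("arrange requires at least one key")
        if isinstance(descending, bool):
            descending = [descending] * len(keys)
        scope = "taxa" if target == "taxa" else target
        if scope != "taxa" and scope not in self.data:
            raise KeyError(f"unknown arrange target {target!r}")
        resolved = []
        for key in keys:
            if isinstance(key, str) and key in self.all_names():
                values = self.resolve_variable(key, scope=scope)
            elif isinstance(key, str):
                values = pd.Series(
                    evaluate(key, lambda nm: self.resolve_variable(nm, scope=scope))
                )
            else:
                values = pd.Series(list(key))
            resolved.append(values.reset_index(drop=True))
        n = len(self.graph) if scope == "taxa" else len(self.data[scope])
        order = np.arange(n)
        for values, desc in reversed(list(zip(resolved, descending))):
            ranks = values.rank(method="dense").to_numpy()
            if desc:
                ranks = -ranks
            order = order[np.argsort(ranks[order], kind="stable")]
        out = self.copy()
        if scope == "taxa":
            ids = self.graph.ids()
            new_ids = [ids[i] for i in order]
            out.graph = model.TaxonomyGraph(
                {tid: self.graph.nodes[tid] for tid in new_ids},
                {tid: self.graph.parents[tid] for tid in new_ids},
            )
        else:
            payload = out.data[scope]
            if _is_table(payload):
                out.data[scope] = payload.iloc[order].reset_index(drop=True)
            elif _is_mapping(payload):
                out.data[scope] = payload.iloc[order]
            else:
                out.data[scope] = [payload[i] for i in order]
        return out

    # -- random sampling ---------------------------------------------------

    def _weights(self, weight, scope: str, n: int) -> np.ndarray | None:
        if weight is None:
            return None
        if isinstance(weight, str):
            w = np.asarray(
                evaluate(weight, lambda nm: self.resolve_variable(nm, scope=scope)),
                dtype=float,
            )
        else:
            w = np.asarray(list(weight), dtype=float)
        if len(w) != n:
            raise ValueError(f"weights have length {len(w)}, expected {n}")
        if (w < 0).any():
            raise ValueError("sampling weights must be non-negative")
        if w.sum() == 0:
            raise ValueError("sampling weights must not all be zero")
        return w / w.sum()

    def sample_n_taxa(self, n: int, weight=None, seed=None, **options) -> "Taxmap":
        """Randomly keep ``n`` taxa (without replacement, optionally
        weighted), then apply the full :meth:`filter_taxa` machinery."""
        total = len(self.graph)
        if not 0 <= n <= total:
            raise ValueError(f"cannot sample {n} of {total} taxa")
        rng = np.random.default_rng(seed)
        p = self._weights(weight, "taxa", total)
        chosen = rng.choice(self.graph.ids(), size=n, replace=False, p=p)
        return self.filter_taxa(set(chosen), **options)

    def sample_frac_taxa(self, frac: float, weight=None, seed=None, **options) -> "Taxmap":
        if not 0 <= frac <= 1:
            raise ValueError("frac must be in [0, 1]")
        return self.sample_n_taxa(
            int(round(frac * len(self.graph))), weight=weight, seed=seed, **options
        )

    def sample_n_obs(
        self, dataset: str, n: int, weight=None, seed=None,
        drop_taxa: bool = False, **taxa_options,
    ) -> "Taxmap":
        """Randomly keep ``n`` records of a dataset via :meth:`filter_obs`."""
        if dataset not in self.data:
            raise KeyError(f"unknown dataset {dataset!r}")
        total = len(self.data[dataset])
        if not 0 <= n <= total:
            raise ValueError(f"cannot sample {n} of {total} records")
        rng = np.random.default_rng(seed)
        p = self._weights(weight, dataset, total)
        chosen = rng.choice(total, size=n, replace=False, p=p)
        mask = np.zeros(total, dtype=bool)
        mask[chosen] = True
        return self.filter_obs(dataset, mask, drop_taxa=drop_taxa, **taxa_options)

    def sample_frac_obs(
        self, dataset: str, frac: float, weight=None, seed=None,
        drop_taxa: bool = False, **taxa_options,
    ) -> "Taxmap":
        if not 0 <= frac <= 1:
            raise ValueError("frac must be in [0, 1]")
        n = int(round(frac * len(self.data.get(dataset, []))))
        return self.sample_n_obs(
            dataset, n, weight=weight, seed=seed, drop_taxa=drop_taxa, **taxa_options
        )


# ---------------------------------------------------------------------------
# thin functional wrappers (the verb surface as module-level functions)


def attach_dataset(tm: Taxmap, name: str, payload, link=None) -> Taxmap:
    out = tm.copy()
    out.attach_dataset(name, payload, link=link)
    return out


def resolve_variable(tm: Taxmap, name: str, scope: str = "taxa", strict: bool = False):
    return tm.resolve_variable(name, scope=scope, strict=strict)


def obs(tm: Taxmap, dataset: str, subset=None, recursive: bool | int = True, value=None):
    return tm.obs(dataset, subset=subset, recursive=recursive, value=value)


def n_obs(tm: Taxmap, dataset: str | None = None, recursive: bool | int = True):
    return tm.n_obs(dataset, recursive=recursive)


def filter_taxa(tm: Taxmap, *predicates, **options) -> Taxmap:
    return tm.filter_taxa(*predicates, **options)


def filter_obs(tm: Taxmap, dataset: str, *predicates, drop_taxa: bool = False, **opts) -> Taxmap:
    return tm.filter_obs(dataset, *predicates, drop_taxa=drop_taxa, **opts)


def mutate_obs(tm: Taxmap, dataset: str, name: str, expression, overwrite: bool = False) -> Taxmap:
    return tm.mutate_obs(dataset, name, expression, overwrite=overwrite)


def arrange(tm: Taxmap, target: str, *keys, descending=False) -> Taxmap:
    return tm.arrange(target, *keys, descending=descending)


def sample_n_taxa(tm: Taxmap, n: int, weight=None, seed=None, **options) -> Taxmap:
    return tm.sample_n_taxa(n, weight=weight, seed=seed, **options)


def sample_frac_taxa(tm: Taxmap, frac: float, weight=None, seed=None, **options) -> Taxmap:
    return tm.sample_frac_taxa(frac, weight=weight, seed=seed, **options)


def sample_n_obs(tm: Taxmap, dataset: str, n: int, **kwargs) -> Taxmap:
    return tm.sample_n_obs(dataset, n, **kwargs)


def sample_frac_obs(tm: Taxmap, dataset: str, frac: float, **kwargs) -> Taxmap:
    return tm.sample_frac_obs(dataset, frac, **kwargs)
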