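# Methods notes

This note records the model underlying `taxaforest`, the choices made
where the design was genuinely open, and what the synthetic fixtures do
and do not demonstrate.

## The data model and its assumptions

A classification is an ordered chain of taxa from most inclusive to most
specific. Many classifications are merged into a **forest** stored as an
edge list: one (supertaxon, subtaxon) pair per taxon, with roots paired
with a null supertaxon. Merging deduplicates on the *full lineage* of
(name, rank) pairs from the root down to the taxon itself, never on the
name alone (homonyms across kingdoms are common) and never on
source-database IDs (the same numeric ID denotes different taxa in
different databases). Ranks are opaque labels: no ordering or vocabulary
is imposed, and taxa may be unranked.

Internal IDs are sequential lowercase base-26 strings ("aaa", "aab", ...,
widening beyond three letters only past 17 576 taxa), assigned in
first-encounter order during a root-first, input-order traversal. The same
input sequence therefore always yields the same IDs. IDs carry no meaning
beyond identity; any contract about "the same forest" regardless of IDs is
stated through the canonical form (node and edge sets keyed by lineage),
which is also how the round-trip identities are asserted.

### Traversal semantics

`recursive=True` walks without bound, `False` means depth 1 (immediate
relatives only), an integer `n` bounds the depth at `n`, and `0` yields an
empty result. `obs` differs in one deliberate way: its `recursive=False`
returns only a taxon's *own* records (depth 0 over subtaxa), because "the
records of this exact taxon" is the quantity users want when switching off
aggregation, whereas "immediate children's records but not the taxon's
own" is not a meaningful query.

`stems` includes each root and then each successive taxon while the
current one has exactly one immediate subtaxon, stopping at the first
taxon with any other child count — a literal reading of "everything before
the first split". Consequently a pure chain is entirely stem, and a root
with two children is a one-taxon stem. `n_subtaxa`/`n_supertaxa` count all
descendants/ancestors; `n_obs` aggregates over subtaxa by default, with
`recursive=False` available for direct counts.

## Filtering and the sync invariant

`filter_taxa` combines multiple predicates with AND (the convention of the
table-verb family it imitates), then optionally widens the kept set with
descendants (`subtaxa`) and/or ancestors (`supertaxa`), then applies
`invert`. Reconnection and record handling both consult the **original**
topology: a surviving taxon whose supertaxon was removed is re-edged to
its nearest surviving ancestor (`reassign_taxa=True`) or becomes a root;
a record of a removed taxon is re-linked to the nearest surviving ancestor
when one exists (`reassign_obs=True`), otherwise deleted
(`drop_obs=True`) or kept with a missing link (both false). Evaluating
"nearest surviving supertaxon" on the pre-filter topology makes the
outcome independent of the order in which taxa are processed.

`filter_obs(..., drop_taxa=True)` keeps a taxon iff it or any descendant
retains at least one record of the filtered dataset — equivalently, the
ancestors-or-self of every still-linked taxon. Records of *other* datasets
attached to dropped taxa then follow the standard removed-taxon policy,
so one knob set governs every dataset.

Missing (NA) links are legal at rest: they mark records whose taxon was
removed under the keep-records regime or whose lookup failed. They are
excluded from `obs`/`n_obs` aggregation and from link validation.

## The variable namespace

Verbs accept expression strings over named variables, resolved at call
time — never cached — so the same name re-resolves to the filtered state
after each step of a chain. Resolution precedence is fixed and documented:
built-ins (`taxon_names`, `taxon_ranks`, `taxon_ids`, `n_obs`,
`n_subtaxa`, `n_supertaxa`, `is_root`, `is_leaf`, `is_stem`,
`is_branch`), then user funcs, then dataset contents in attachment order.
Attaching a dataset that shadows an existing name emits a warning;
`strict=True` resolution turns ambiguity into an error. In a dataset
scope, per-taxon variables broadcast through each record's taxon link.
The expression language is a restricted subset of Python syntax
(comparisons, boolean operators, arithmetic, `isna`/`notna`) evaluated
over a node whitelist; no attribute access, subscripting or other calls,
so no arbitrary code can run from a CLI argument.

`n_obs` as a bare variable counts the first taxon-linked dataset; the
explicit `n_obs(dataset)` form disambiguates when several are attached.

## Parsing

All parsers are driven by a separator + regex + key triple. In separator
mode the regex is anchored against each whitespace-trimmed segment, so
`"; "` and `";"` variants of the same format both parse. In global-match
mode (no separator) the regex is applied repeatedly along the string,
which expresses formats whose names and ranks alternate with a single
separator; a final unpaired token left after the last match becomes a
rank-less taxon, since truncated lineages of such formats end on a name.
Trailing empty-name taxa (e.g. a rank prefix with nothing after it) are
dropped unless `allow_empty` is set; an empty name mid-lineage is an
error, because silently bridging it would fabricate ancestry.

Dialect presets: the rank-prefixed preset uses segment regex
`^\s*([a-z])__(.*)$` (rank letter, name); the bare-names preset treats
each segment as a name with no rank; the interleaved preset uses
global-match `([^;]+);([^;]+);?`. Header isolation regexes are permissive
(`[a-z]__...` onward for rank-prefixed headers; the last tab-field
containing a separator for interleaved ones) so that both bare-lineage
headers and `ID<tab>lineage` variants parse. Trailing per-taxon
confidence values some databases append are not modeled by the presets;
a custom spec covers them.

Lookup of names/IDs/sequence IDs goes through a resolver contract with
two offline implementations (two-column TSV; taxonomy-dump nodes/names
tables plus an optional accession map). Partial failure is not fatal:
unresolved queries keep their record with a missing link and are listed
in the failures report, with a `strict` mode for error-on-any-failure.
Resolution against multiple, possibly conflicting databases is out of
scope — one resolver per call.

Linked *extra* datasets in `parse_tax_data` must be tables (they gain a
`taxon_id` column via a shared-key or positional mapping). Vectors named
by duplicate taxon IDs, legal in some host languages, cannot be a Python
dict; a vector to be linked is passed as a single-column table instead.

## Serialization and interop

The taxmap JSON document (schema version 1) covers taxa (with their
wrapped name/rank/ID and database descriptors), edges, and datasets with
column dtypes; `deserialize(serialize(tm)) == tm` including dataset
dtypes. User funcs are arbitrary callables and are dropped with a warning.
Newick export writes one tree per root through dendropy, quoting labels
with spaces or metacharacters; the parsed-back leaf label multiset equals
the taxonomy's leaves.

## Synthetic fixtures

The generator emulates the shape of classified survey data: a forest of
`n_roots` trees (default 2), per-tree depth drawn uniformly from
`depth_range` (default 2–5, capped at the 7-level k/p/c/o/f/g/s rank
ladder so rank-coded header dialects can express every lineage),
Poisson-distributed child counts (`branching_mean` 1.8, at least one
child while below the target depth), a hard `max_taxa` cap (default 60),
and an observation table (default 50 records) whose rows land on
uniformly chosen taxa at any rank — as occurrence records do. Identical
spec+seed reproduces fixtures exactly; all sampling verbs likewise take
an explicit seed and touch no global RNG state.

Deliberately *not* emulated: homonym collisions between siblings (sibling
names are forced distinct so every generated forest is exactly recoverable
from its leaf classifications), missing or inconsistent ranks, malformed
header strings, and the long-tailed abundance distributions of real
surveys. Passing round-trip and filtering contracts on these fixtures
therefore demonstrates the algebra of the operations, not robustness to
dirty real-world inputs — the parser error paths and failure reports are
tested separately on hand-written malformed cases.

Test and acceptance problem sizes (forests of ≤ 50 taxa, 100–200 seeded
replicates, tables of 10–80 records) were chosen as the smallest scales at
which every contract is exercised across varied topologies; all operations
are linear or near-linear in taxa + records, and the 500-taxon generator
check covers the larger-graph path.

## Known limitations

- No rank-order validation or nomenclature/synonym resolution; ranks are
  labels.
- Sampling weights are direct per-taxon/per-record expressions; pooled
  ancestor/descendant weighting schemes are not implemented.
- Keyed-mapping datasets resolve to per-taxon values by first occurrence
  when duplicate keys exist.
- `arrange` sorts stably on dense ranks of the key values; mixed-type key
  columns must be comparable within themselves.
- Live database queries are intentionally absent; resolvers are
  file-backed and offline.
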