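# taxaforest

Tools for storing and manipulating taxonomic data: a forest-structured
taxonomy with attached user datasets, hierarchy-aware manipulation verbs
that keep taxonomy and data in sync, and flexible parsers that read
classifications, taxon names/IDs and sequence-header encodings into one
model.

## Who this is for

Community-composition studies (metabarcoding, microbiome surveys,
biodiversity occurrence data) produce tables and sequence files whose
records carry taxonomic classifications — encoded a different way in every
source. Greengenes headers look like `k__Bacteria; p__Cyanobacteria; ...`,
SILVA uses bare `Bacteria;Proteobacteria;...`, RDP interleaves names and
ranks (`Root;rootrank;Fungi;domain;...`), and GenBank headers carry only a
sequence ID whose lineage must be looked up. Once parsed, the data are
hierarchical: subsetting "everything in Tracheophyta" or "drop species-level
taxa but keep their occurrences at the genus level" requires tree-aware
operations that ordinary table verbs do not provide. `taxaforest` gives
both halves: uniform parsing into one model, and dplyr-style verbs that
operate on the tree and the data simultaneously.

## The model

- **Taxon** — a name, optionally a rank and a database ID (bare strings are
  accepted everywhere and promoted).
- **Hierarchy** — one classification, ordered most inclusive → most
  specific (`Animalia > Chordata > ... > sapiens`).
- **TaxonomyGraph** — many classifications merged into a deduplicated
  forest: nodes keyed by generated internal IDs (`aaa`, `aab`, ...), tree
  structure as an edge list of (supertaxon, subtaxon) pairs, roots paired
  with `None`. Node identity is the *full lineage* of (name, rank) pairs,
  so a genus name shared by an oomycete and a moth yields two nodes.
- **Taxmap** — a TaxonomyGraph plus named datasets. A table is linked by
  its `taxon_id` column; a keyed mapping by its taxon-ID keys; plain
  sequences are unlinked. Every verb maintains the invariant that each
  non-missing link points at an existing taxon.

The verbs mirror the dplyr family: `filter_taxa`, `filter_obs`,
`mutate_obs`, `arrange`, `sample_n_taxa` / `sample_n_obs` (and `_frac_`
variants), plus the mapping functions `supertaxa`, `subtaxa`, `roots` /
`stems` / `branches` / `leaves` (via `tree_parts`), `obs` and `n_obs`.
Filters accept expression strings over a live variable namespace
(`"taxon_names == 'Fungi'"`, `"n_subtaxa > 10"`): names re-resolve against
the current object on every call, so a variable referenced after a filter
reflects the filtered state. When taxa are removed, surviving subtaxa are
re-edged to their nearest surviving supertaxon (`reassign_taxa`), and each
record of a removed taxon is exactly one of re-linked to its closest
surviving supertaxon (`reassign_obs`), deleted (`drop_obs`), or kept with a
missing link.

## Worked example

```python
import pandas as pd
from taxaforest import parse_tax_data, export_newick

occurrences = pd.DataFrame({
    "classification": [
        "Plantae;Tracheophyta;Pinus",
        "Plantae;Tracheophyta;Poa",
        "Plantae;Bryophyta",
        "Plantae;Tracheophyta;Poa",
    ],
    "basis": ["SPECIMEN", "SPECIMEN", "OBSERVATION", "SPECIMEN"],
})
tm = parse_tax_data(occurrences, class_cols=["classification"]).taxmap
print(tm.data["tax_data"])
```

```
  taxon_id              classification        basis
0      aac  Plantae;Tracheophyta;Pinus     SPECIMEN
1      aad    Plantae;Tracheophyta;Poa     SPECIMEN
2      aae           Plantae;Bryophyta  OBSERVATION
3      aad    Plantae;Tracheophyta;Poa     SPECIMEN
```

The source table is preserved with a prepended `taxon_id` column linking
each row to the most specific taxon of its lineage; the five parsed taxa
(`Plantae`, `Tracheophyta`, `Pinus`, `Poa`, `Bryophyta`) are deduplicated
across rows. Chaining filters keeps tree and table in sync:

```python
kept = tm.filter_obs("tax_data", "basis == 'SPECIMEN'", drop_taxa=True)
sub = kept.filter_taxa("taxon_names == 'Tracheophyta'",
                       subtaxa=True, supertaxa=True)
print(len(sub.data["tax_data"]), "records")
print(export_newick(sub.graph))
```

```
3 records
((Pinus,Poa)Tracheophyta)Plantae;
```

The observation filter removed the one non-specimen record and with it
`Bryophyta`, whose subtree held no remaining records; the taxon filter then
kept the named clade plus its ancestors. `n_obs` at any point gives
per-taxon record counts aggregated over subtaxa — summed over roots it
always equals the number of linked records.

FASTA with lineage-bearing headers goes through
`read_fasta_classifications(path, dialect)` with presets `"greengenes"`,
`"silva"`, `"rdp"` and `"generic"`; names/IDs without classifications go
through `lookup_tax_data` backed by an offline resolver (two-column TSV or
taxonomy-dump tables). The same operations are available from the shell via
`taxa-parse`, `taxa-filter`, `taxa-stats`, `taxa-export` and
`taxa-fixture`, with taxmaps carried between commands as versioned JSON.

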