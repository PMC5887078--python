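"""Taxmap container: datasets, the variable namespace, and the verb set."""

import numpy as np
import pandas as pd
import pytest

from taxaforest import Taxmap, build_taxonomy, validate
from conftest import make_taxmap, naive_is_ancestor


@pytest.fixture
def fungi_taxmap():
    g = build_taxonomy(
        [["Fungi", "Ascomycota", "Morchella"], ["Fungi", "Basidiomycota"],
         ["Plantae", "Rosa"]]
    )
    tm = Taxmap(g)
    tm.attach_dataset(
        "occ",
        pd.DataFrame(
            {
                "taxon_id": ["aac", "aad", "aaf", "aaf"],
                "basis": ["SPECIMEN", "OBSERVATION", "SPECIMEN", "OBSERVATION"],
                "count": [3, 1, 2, 5],
            }
        ),
    )
    return tm


class TestAttach:
    def test_table_with_valid_links(self, chain_taxmap):
        assert "d" in chain_taxmap.data
        assert chain_taxmap.validate() == []

    def test_mapping_keyed_by_taxon_ids(self, chain_taxmap):
        tm = chain_taxmap.copy()
        tm.attach_dataset("notes", {"aaa": "root note", "aac": "leaf note"})
        assert tm.resolve_variable("notes")["aaa"] == "root note"
        assert pd.isna(tm.resolve_variable("notes")["aab"])

    def test_bogus_link_rejected_naming_record(self, chain_taxmap):
        tm = chain_taxmap.copy()
        bad = pd.DataFrame({"taxon_id": ["aaa", "zzz"], "x": [1, 2]})
        with pytest.raises(ValueError, match="record 1"):
            tm.attach_dataset("bad", bad)

    def test_duplicate_name_rejected(self, chain_taxmap):
        with pytest.raises(ValueError, match="already attached"):
            chain_taxmap.attach_dataset("d", [1, 2, 3])

    def test_na_links_permitted(self, chain_taxmap):
        tm = chain_taxmap.copy()
        tm.attach_dataset(
            "partial", pd.DataFrame({"taxon_id": ["aaa", None], "y": [1, 2]})
        )
        assert tm.validate() == []

    def test_shadowing_warns(self, chain_taxmap):
        tm = chain_taxmap.copy()
        with pytest.warns(UserWarning, match="shadows"):
            tm.attach_dataset(
                "clash", pd.DataFrame({"taxon_id": ["aaa"], "x": [9]})
            )


class TestNamespace:
    def test_builtins(self, chain_taxmap):
        tm = chain_taxmap
        assert list(tm.resolve_variable("taxon_names")) == ["A", "B", "C"]
        assert list(tm.resolve_variable("n_subtaxa")) == [2, 1, 0]
        assert list(tm.resolve_variable("n_supertaxa")) == [0, 1, 2]
        assert list(tm.resolve_variable("is_root")) == [True, False, False]
        assert list(tm.resolve_variable("is_leaf")) == [False, False, True]

    def test_n_subtaxa_fan(self):
        tm = Taxmap(build_taxonomy([["A", "B"], ["A", "C"]]))
        assert tm.resolve_variable("n_subtaxa").to_dict() == {
            "aaa": 2, "aab": 0, "aac": 0,
        }

    def test_table_column_in_dataset_scope(self, chain_taxmap):
        assert list(chain_taxmap.resolve_variable("x", scope="d")) == [1.0, 2.0, 3.0]

    def test_per_taxon_broadcast_into_records(self, chain_taxmap):
        assert list(chain_taxmap.resolve_variable("taxon_names", scope="d")) == [
            "A", "B", "C",
        ]

    def test_unknown_name_lists_available(self, chain_taxmap):
        with pytest.raises(KeyError, match="taxon_names"):
            chain_taxmap.resolve_variable("nope")

    def test_user_func_and_strict_ambiguity(self, chain_taxmap):
        tm = chain_taxmap.copy()
        tm.add_func("doubled", lambda t: [2 * n for n in t.n_obs().values()])
        assert list(tm.resolve_variable("doubled")) == [6, 4, 2]
        tm.add_func("x", lambda t: [0, 0, 0])  # collides with column of "d"
        with pytest.raises(KeyError, match="ambiguous"):
            tm.resolve_variable("x", scope="d", strict=True)

    def test_resolution_is_call_time(self, fungi_taxmap):
        before = fungi_taxmap.resolve_variable("taxon_ranks")
        filtered = fungi_taxmap.filter_taxa("taxon_names == 'Fungi'", subtaxa=True)
        after = filtered.resolve_variable("taxon_ranks")
        assert set(after.index) < set(before.index)
        kept = after.index
        assert list(before[kept]) == list(after)


class TestObs:
    def test_recursive_aggregation(self, chain_taxmap):
        tm = chain_taxmap
        assert tm.obs("d")["aaa"] == [0, 1, 2]
        assert tm.obs("d", recursive=False)["aaa"] == [0]
        assert tm.obs("d", recursive=1)["aaa"] == [0, 1]

    def test_value_returns_column(self, chain_taxmap):
        assert chain_taxmap.obs("d", value="x")["aab"] == [2.0, 3.0]

    def test_single_root_covers_all_records(self, chain_taxmap):
        root_obs = chain_taxmap.obs("d")["aaa"]
        assert root_obs == list(range(len(chain_taxmap.data["d"])))

    def test_unlinked_dataset_rejected(self, chain_taxmap):
        tm = chain_taxmap.copy()
        tm.attach_dataset("plain", ["u", "v"])
        with pytest.raises(ValueError, match="no taxon link"):
            tm.obs("plain")
        with pytest.raises(KeyError):
            tm.obs("missing")

    def test_n_obs_conservation(self):
        for seed in range(8):
            tm = make_taxmap(seed)
            counts = tm.n_obs("info")
            roots = [t for t in tm.graph.nodes if tm.graph.parents[t] is None]
            assert sum(counts[r] for r in roots) == len(tm.data["info"])

    def test_n_obs_zero_for_unobserved(self):
        tm = make_taxmap(1, n_records=0)
        assert set(tm.n_obs("info").values()) == {0}


class TestFilterTaxa:
    def test_all_true_is_identity(self, fungi_taxmap):
        out = fungi_taxmap.filter_taxa([True] * len(fungi_taxmap.graph))
        assert out == fungi_taxmap

    def test_name_with_subtaxa(self, fungi_taxmap):
        out = fungi_taxmap.filter_taxa("taxon_names == 'Fungi'", subtaxa=True)
        kept = {t.name_str for t in out.graph.nodes.values()}
        assert kept == {"Fungi", "Ascomycota", "Morchella", "Basidiomycota"}
        assert out.validate() == []

    def test_reassign_taxa_bridges_removed_middle(self, chain_taxmap):
        out = chain_taxmap.filter_taxa({"aaa", "aac"})
        assert out.graph.parents["aac"] == "aaa"
        assert list(out.data["d"]["taxon_id"]) == ["aaa", "aaa", "aac"]

    def test_no_reassign_taxa_makes_new_roots(self, chain_taxmap):
        out = chain_taxmap.filter_taxa({"aaa", "aac"}, reassign_taxa=False)
        assert out.graph.parents["aac"] is None

    def test_record_fate_trichotomy(self, chain_taxmap):
        # reassign: record of B re-linked to A
        relink = chain_taxmap.filter_taxa({"aaa", "aac"})
        assert list(relink.data["d"]["taxon_id"]) == ["aaa", "aaa", "aac"]
        # drop: record of B deleted
        drop = chain_taxmap.filter_taxa({"aaa", "aac"}, reassign_obs=False)
        assert list(drop.data["d"]["taxon_id"]) == ["aaa", "aac"]
        # keep with missing link
        keep = chain_taxmap.filter_taxa(
            {"aaa", "aac"}, reassign_obs=False, drop_obs=False
        )
        links = list(keep.data["d"]["taxon_id"])
        assert links[0] == "aaa" and links[2] == "aac" and pd.isna(links[1])

    def test_invert(self, fungi_taxmap):
        out = fungi_taxmap.filter_taxa("taxon_names == 'Plantae'", invert=True)
        assert "Plantae" not in {t.name_str for t in out.graph.nodes.values()}

    def test_supertaxa_option_keeps_ancestors(self, fungi_taxmap):
        out = fungi_taxmap.filter_taxa("taxon_names == 'Morchella'", supertaxa=True)
        kept = {t.name_str for t in out.graph.nodes.values()}
        assert kept == {"Fungi", "Ascomycota", "Morchella"}

    def test_predicates_and_combined(self, fungi_taxmap):
        out = fungi_taxmap.filter_taxa("n_supertaxa > 0", "taxon_names != 'Rosa'")
        kept = {t.name_str for t in out.graph.nodes.values()}
        assert kept == {"Ascomycota", "Morchella", "Basidiomycota"}

    def test_mask_length_mismatch(self, fungi_taxmap):
        with pytest.raises(ValueError, match="length"):
            fungi_taxmap.filter_taxa([True, False])

    @pytest.mark.parametrize("seed", range(10))
    def test_ancestry_preserved_on_random_kept_sets(self, seed):
        tm = make_taxmap(seed)
        rng = np.random.default_rng(seed)
        ids = tm.graph.ids()
        kept = {tid for tid in ids if rng.random() < 0.6}
        out = tm.filter_taxa(kept or {ids[0]})
        assert out.validate() == []
        for a in out.graph.nodes:
            for b in out.graph.nodes:
                if naive_is_ancestor(tm.graph, a, b):
                    assert naive_is_ancestor(out.graph, a, b)

    @pytest.mark.parametrize("seed", range(6))
    def test_conservation_when_ancestors_survive(self, seed):
        tm = make_taxmap(seed)
        roots = {t for t in tm.graph.nodes if tm.graph.parents[t] is None}
        rng = np.random.default_rng(seed + 100)
        kept = roots | {
            tid for tid in tm.graph.nodes if rng.random() < 0.5
        }
        out = tm.filter_taxa(kept)
        assert len(out.data["info"]) == len(tm.data["info"])

    def test_removing_branches_preserves_relations(self):
        from taxaforest import tree_parts

        tm = make_taxmap(4)
        branches = set(tree_parts(tm.graph, "branches"))
        out = tm.filter_taxa(set(tm.graph.ids()) - branches)
        for a in out.graph.nodes:
            for b in out.graph.nodes:
                assert naive_is_ancestor(tm.graph, a, b) == naive_is_ancestor(
                    out.graph, a, b
                )


class TestFilterObs:
    def test_column_predicate_with_drop_taxa(self, fungi_taxmap):
        out = fungi_taxmap.filter_obs("occ", "basis == 'SPECIMEN'", drop_taxa=True)
        assert list(out.data["occ"]["basis"].unique()) == ["SPECIMEN"]
        kept = {t.name_str for t in out.graph.nodes.values()}
        # Basidiomycota had no specimen records and is removed; ancestors stay
        assert "Basidiomycota" not in kept
        assert {"Fungi", "Ascomycota", "Morchella", "Plantae", "Rosa"} <= kept
        assert out.validate() == []

    def test_all_true_identity(self, fungi_taxmap):
        assert fungi_taxmap.filter_obs("occ", [True] * 4) == fungi_taxmap

    def test_sole_leaf_record_removed_drops_leaf(self, chain_taxmap):
        out = chain_taxmap.filter_obs("d", "x != 3", drop_taxa=True)
        assert "aac" not in out.graph.nodes
        assert {"aaa", "aab"} == set(out.graph.nodes)

    def test_drop_all_records(self, chain_taxmap):
        out = chain_taxmap.filter_obs("d", [False] * 3, drop_taxa=True)
        assert len(out.data["d"]) == 0
        assert len(out.graph) == 0


class TestMutateArrangeSample:
    def test_mutate_constant_and_expression(self, chain_taxmap):
        out = chain_taxmap.mutate_obs("d", "flag", "x > 1")
        assert list(out.data["d"]["flag"]) == [False, True, True]
        out2 = out.mutate_obs("d", "per_taxon", "n_obs")
        assert list(out2.data["d"]["per_taxon"]) == [3, 2, 1]

    def test_mutate_rejects_collision_and_unknown_name(self, chain_taxmap):
        with pytest.raises(ValueError, match="already exists"):
            chain_taxmap.mutate_obs("d", "x", "x")
        with pytest.raises(KeyError):
            chain_taxmap.mutate_obs("d", "y", "mystery + 1")
        tm = chain_taxmap.copy()
        tm.attach_dataset("plain", ["u"])
        with pytest.raises(TypeError, match="table"):
            tm.mutate_obs("plain", "y", "1")

    def test_arrange_taxa_sorts_and_preserves_queries(self):
        from taxaforest import subtaxa

        tm = Taxmap(build_taxonomy([["B"], ["A"], ["C"]]))
        out = tm.arrange("taxa", "taxon_names")
        assert [t.name_str for t in out.graph.nodes.values()] == ["A", "B", "C"]
        assert subtaxa(out.graph, recursive=True) == {
            k: v for k, v in subtaxa(tm.graph, recursive=True).items()
        }

    def test_arrange_descending_reverses(self, chain_taxmap):
        asc = chain_taxmap.arrange("d", "x")
        desc = chain_taxmap.arrange("d", "x", descending=True)
        assert list(desc.data["d"]["x"]) == list(asc.data["d"]["x"])[::-1]

    def test_sample_all_is_identity_topology(self, fungi_taxmap):
        out = fungi_taxmap.sample_n_taxa(len(fungi_taxmap.graph), seed=0)
        assert set(out.graph.nodes) == set(fungi_taxmap.graph.nodes)

    def test_sample_weight_concentration(self, fungi_taxmap):
        w = [1.0 if t.name_str == "Plantae" else 0.0
             for t in fungi_taxmap.graph.nodes.values()]
        out = fungi_taxmap.sample_n_taxa(1, weight=w, seed=1)
        assert [t.name_str for t in out.graph.nodes.values()] == ["Plantae"]

    def test_sample_seed_reproducible(self):
        tm = make_taxmap(7)
        assert tm.sample_n_taxa(5, seed=42) == tm.sample_n_taxa(5, seed=42)
        assert tm.sample_n_obs("info", 10, seed=9) == tm.sample_n_obs("info", 10, seed=9)

    def test_sample_obs_none_with_drop_taxa_empties(self, chain_taxmap):
        out = chain_taxmap.sample_n_obs("d", 0, seed=0, drop_taxa=True)
        assert len(out.data["d"]) == 0 and len(out.graph) == 0

    def test_sample_bounds_and_weights_validated(self, chain_taxmap):
        with pytest.raises(ValueError):
            chain_taxmap.sample_n_taxa(99)
        with pytest.raises(ValueError, match="non-negative"):
            chain_taxmap.sample_n_taxa(1, weight=[-1, 1, 1])
        with pytest.raises(ValueError, match="zero"):
            chain_taxmap.sample_n_taxa(1, weight=[0, 0, 0])


class TestSyncInvariant:
    @pytest.mark.parametrize("seed", range(6))
    def test_verbs_stay_validate_clean(self, seed):
        tm = make_taxmap(seed)
        rng = np.random.default_rng(seed)
        kept = {t for t in tm.graph.ids() if rng.random() < 0.5}
        for opts in (
            {},
            {"reassign_taxa": False},
            {"reassign_obs": False},
            {"reassign_obs": False, "drop_obs": False},
            {"invert": True},
        ):
            out = tm.filter_taxa(kept, **opts)
            assert out.validate() == []
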