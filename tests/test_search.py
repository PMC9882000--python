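import numpy as np
import pytest

import hetpath as hp
from hetpath.fixtures import FixtureSpec, MetaedgeSpec, MetanodeSpec
from hetpath.metapaths import enumerate_metapaths


class TestPathDegreeProduct:
    def test_w_zero_is_one(self, triangle):
        mp = triangle.metagraph.metapath_from_abbreviation("GiGiG")
        assert hp.path_degree_product(triangle, ["g1", "g2", "g3"], mp, 0.0) == 1.0

    def test_triangle_value(self, triangle):
        mp = triangle.metagraph.metapath_from_abbreviation("GiGiG")
        pdp = hp.path_degree_product(triangle, ["g1", "g2", "g3"], mp, 0.5)
        assert pdp == pytest.approx(0.25)

    def test_overlapping_toy_value(self, compound_disease):
        mp = compound_disease.metagraph.metapath_from_abbreviation("CtDtCtD")
        pdp = hp.path_degree_product(
            compound_disease, ["c2", "d1", "c1", "d2"], mp, 0.5
        )
        assert pdp == pytest.approx(0.25)

    def test_duplicate_node_rejected(self, triangle):
        mp = triangle.metagraph.metapath_from_abbreviation("GiGiG")
        with pytest.raises(ValueError, match="duplicate"):
            hp.path_degree_product(triangle, ["g1", "g2", "g1"], mp, 0.5)

    def test_nonedge_rejected(self, compound_gene):
        mp = compound_gene.metagraph.metapath_from_abbreviation("CbG")
        with pytest.raises(ValueError):
            hp.path_degree_product(compound_gene, ["c2", "g1"], mp, 0.5)


class TestEnumeratePaths:
    def test_no_paths_empty_list(self, compound_gene):
        mp = compound_gene.metagraph.metapath_from_abbreviation("CbGbC")
        store = hp.toy_T2()
        store.set_adjacency("CbG", np.zeros((2, 3), dtype=int))
        assert hp.enumerate_paths(store, "c1", "c2", mp, 0.5) == []

    def test_unique_triangle_path(self, triangle):
        mp = triangle.metagraph.metapath_from_abbreviation("GiGiG")
        rows = hp.enumerate_paths(triangle, "g1", "g3", mp, 0.5)
        assert len(rows) == 1
        assert rows[0].nodes == ("g1", "g2", "g3")
        assert rows[0].percent_of_dwpc == pytest.approx(1.0)

    def test_pdp_sum_equals_dwpc_entry(self, random_store):
        """DWPC decomposition: summed path degree products reproduce the
        matrix entry for every pair, metapath length <= 3."""
        for seed in range(4):
            store = random_store(seed, max_nodes=6)
            for mp in enumerate_metapaths(store.metagraph, 3)[:25]:
                matrix = hp.dwpc_matrix(store, mp, 0.5).matrix
                src_ids = store.nodes(mp.source)["identifier"]
                tgt_ids = store.nodes(mp.target)["identifier"]
                for i in range(0, len(src_ids), 3):
                    for j in range(0, len(tgt_ids), 3):
                        rows = hp.enumerate_paths(
                            store, src_ids[i], tgt_ids[j], mp, 0.5
                        )
                        total = sum(r.pdp for r in rows)
                        assert total == pytest.approx(
                            matrix[i, j], abs=1e-10
                        )

    def test_percentages_sum_to_one(self, compound_disease):
        mp = compound_disease.metagraph.metapath_from_abbreviation("CtDtC")
        rows = hp.enumerate_paths(compound_disease, "c1", "c2", mp, 0.5)
        assert rows
        assert sum(r.percent_of_dwpc for r in rows) == pytest.approx(1.0)


class TestPathScore:
    def test_arithmetic(self):
        assert hp.path_score(1.0, 0.01) == pytest.approx(2.0)
        assert hp.path_score(0.5, 1e-4) == pytest.approx(2.0)
        assert hp.path_score(0.7, 1.0) == 0.0

    def test_zero_p_is_capped(self):
        assert hp.path_score(0.5, 0.0) == pytest.approx(0.5 * 320.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hp.path_score(1.5, 0.5)
        with pytest.raises(ValueError):
            hp.path_score(0.5, 2.0)


class TestStorageThreshold:
    def test_length_one_stores_all_nonzero(self):
        assert hp.storage_threshold(100, 100, 1) is None

    def test_unit_base(self):
        assert hp.storage_threshold(1, 1, 2) == pytest.approx(5.0)

    def test_hetionet_scale_values(self):
        counts = hp.hetionet_node_counts()
        genes = counts["Gene"]
        assert hp.storage_threshold(genes, genes, 2) == pytest.approx(
            0.01277, abs=2e-5
        )
        assert hp.storage_threshold(counts["Disease"], counts["Pathway"], 3) == (
            pytest.approx(0.1202, abs=2e-4)
        )


def build_planted_store(seed: int):
    """Random C/G/PW hetnet with extra Compound-binds-Gene and
    Gene-participates-Pathway edges concentrating paths of CbGpPW between
    c000 and pw000."""
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        metanodes=(
            MetanodeSpec("Compound", "C", 12),
            MetanodeSpec("Gene", "G", 25),
            MetanodeSpec("Pathway", "PW", 10),
        ),
        metaedges=(
            MetaedgeSpec("C", "G", "binds", "b", density=0.12),
            MetaedgeSpec("G", "PW", "participates", "p", density=0.12),
            MetaedgeSpec("G", "G", "interacts", "i", density=0.1),
        ),
        seed=int(rng.integers(2**31)),
    )
    store = hp.make_fixture(spec)
    cbg = np.array(store.adjacency("CbG"))
    gpw = np.array(store.adjacency("GpPW"))
    boosted = set(np.nonzero(gpw[:, 0])[0]) | set(rng.choice(25, 8, replace=False))
    for g in boosted:
        cbg[0, g] = 1
        gpw[g, 0] = 1
    store.set_adjacency("CbG", cbg)
    store.set_adjacency("GpPW", gpw)
    return store


@pytest.fixture(scope="module")
def searched():
    store = build_planted_store(0)
    mps = [
        mp
        for mp in enumerate_metapaths(store.metagraph, 3)
        if {mp.source.abbreviation, mp.target.abbreviation} == {"C", "PW"}
    ]
    nulls = hp.compute_null_catalog(store, mps, n_permutations=25, base_seed=1, w=0.5)
    frames = hp.connectivity_search(store, nulls, "c000", "pw000", max_length=3)
    return store, nulls, frames


class TestConnectivitySearch:
    def test_planted_metapath_ranks_first(self, searched):
        _, _, (metapath_frame, _) = searched
        assert metapath_frame.iloc[0]["metapath"] == "CbGpPW"

    def test_rows_cover_all_metapaths_between_metanodes(self, searched):
        store, _, (metapath_frame, _) = searched
        expected = {
            mp.abbreviation
            for mp in enumerate_metapaths(store.metagraph, 3)
            if {mp.source.abbreviation, mp.target.abbreviation} == {"C", "PW"}
        }
        got = set(metapath_frame["metapath"])
        assert len(got) == len(expected)
        for abbrev in got:
            mp = store.metagraph.metapath_from_abbreviation(abbrev)
            assert mp.canonical().abbreviation in expected

    def test_zero_dwpc_implies_unit_pvalue(self, searched):
        _, _, (metapath_frame, _) = searched
        zero = metapath_frame[metapath_frame["dwpc"] == 0]
        assert (zero["path_count"] == 0).all()
        assert (zero["p_value"] == 1.0).all()
        nonzero = metapath_frame[metapath_frame["dwpc"] > 0]
        assert (nonzero["path_count"] > 0).all()

    def test_adjusted_p_consistent_with_bonferroni(self, searched):
        store, _, (metapath_frame, _) = searched
        mg = store.metagraph
        for row in metapath_frame.itertuples():
            mp = mg.metapath_from_abbreviation(row.metapath)
            expected = hp.bonferroni_adjust(
                row.p_value, mg, mp.source, mp.target, mp.length
            )
            assert row.adjusted_p_value == pytest.approx(expected)

    def test_paths_sorted_by_score(self, searched):
        _, _, (_, path_frame) = searched
        scores = path_frame["path_score"].to_numpy()
        assert (scores[:-1] >= scores[1:] - 1e-12).all()

    def test_symmetric_under_query_swap(self, searched):
        store, nulls, (metapath_frame, _) = searched
        swapped, _ = hp.connectivity_search(store, nulls, "pw000", "c000", max_length=3)
        fwd = {
            row.metapath: row.dwpc for row in metapath_frame.itertuples()
        }
        for row in swapped.itertuples():
            mp = store.metagraph.metapath_from_abbreviation(row.metapath)
            assert fwd[mp.reverse().abbreviation] == pytest.approx(row.dwpc)

    def test_unknown_node_lists_near_matches(self, searched):
        store, nulls, _ = searched
        with pytest.raises(LookupError, match="c00"):
            hp.connectivity_search(store, nulls, "c00x", "pw000")

    def test_edgeless_store_all_null(self):
        store = hp.make_fixture(
            FixtureSpec(
                metanodes=(
                    MetanodeSpec("TypeA", "A", 4),
                    MetanodeSpec("TypeB", "B", 4),
                ),
                metaedges=(MetaedgeSpec("A", "B", "kind_x", "x", density=0.0),),
                seed=0,
            )
        )
        nulls = hp.NullCatalog(w=0.5)
        metapath_frame, path_frame = hp.connectivity_search(
            store, nulls, "a000", "b000", max_length=2
        )
        assert (metapath_frame["path_count"] == 0).all()
        assert (metapath_frame["p_value"] == 1.0).all()
        assert path_frame.empty
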