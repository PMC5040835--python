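import numpy as np
import pytest

from conftest import build_network
from oracles import dfs_path_count_matrix, random_binary_network

from rmlm.hetnet import (
    HeteroNetwork,
    MetaPath,
    NodeCatalog,
    RelationMatrix,
    compose_metapath,
    enumerate_metapaths,
    path_count_matrix,
    register_relation,
    reverse_metapath,
)


@pytest.fixture
def small_net():
    sim = np.array([[0.0, 0.5], [0.5, 0.0]])
    mg = np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
    ppi = np.zeros((3, 3))
    return build_network(sim, mg, ppi)


class TestRegisterRelation:
    def test_inverse_is_transpose(self, small_net):
        rel = small_net.relation("regulate")
        inv = small_net.relation("regulate^-1")
        assert inv.source_type == "gene" and inv.target_type == "mirna"
        np.testing.assert_array_equal(inv.weights, rel.weights.T)

    def test_symmetric_relation_keeps_inverse_alias(self, small_net):
        np.testing.assert_array_equal(
            small_net.relation("ppi^-1").weights,
            small_net.relation("ppi").weights,
        )

    def test_out_of_range_weights_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            RelationMatrix("bad", "mirna", "gene", np.array([[1.2]]))

    def test_duplicate_name_rejected(self, small_net):
        dup = RelationMatrix("sim", "mirna", "mirna", np.zeros((2, 2)))
        with pytest.raises(ValueError, match="already registered"):
            register_relation(small_net, dup)

    def test_shape_mismatch_rejected(self, small_net):
        bad = RelationMatrix("extra", "mirna", "gene", np.zeros((3, 3)))
        with pytest.raises(ValueError, match="shape"):
            register_relation(small_net, bad)


class TestEnumerateMetapaths:
    def test_max_len_zero_gives_identity_only(self, small_net):
        paths = enumerate_metapaths(small_net, "mirna", 0)
        assert [p.relation_names for p in paths] == [()]

    def test_mirna_side_exhaustive_at_len3(self, small_net):
        # independently derived by listing all type-consistent sequences
        expected = {
            (),
            ("sim",),
            ("sim", "sim"),
            ("regulate", "regulate^-1"),
            ("sim", "sim", "sim"),
            ("sim", "regulate", "regulate^-1"),
            ("regulate", "regulate^-1", "sim"),
            ("regulate", "ppi", "regulate^-1"),
        }
        paths = enumerate_metapaths(small_net, "mirna", 3)
        assert {p.relation_names for p in paths} == expected
        assert len(paths) == 8

    def test_gene_side_exhaustive_at_len3(self, small_net):
        paths = enumerate_metapaths(small_net, "gene", 3)
        assert len(paths) == 8
        assert ("regulate^-1", "sim", "regulate") in {
            p.relation_names for p in paths}

    def test_canonical_order_and_no_duplicates(self, small_net):
        paths = enumerate_metapaths(small_net, "mirna", 3)
        keys = [(p.length, p.relation_names) for p in paths]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)
        for p in paths:
            small_net.validate_metapath(p)

    def test_unknown_type_rejected(self, small_net):
        with pytest.raises(KeyError):
            enumerate_metapaths(small_net, "protein", 2)


class TestComposeMetapath:
    def test_identity_sides(self, small_net):
        empty_m = MetaPath((), "mirna", "mirna")
        empty_g = MetaPath((), "gene", "gene")
        mp = compose_metapath(empty_m, "regulate", empty_g, net=small_net)
        assert mp.relation_names == ("regulate",)
        assert mp.length == 1

    def test_concatenation(self, small_net):
        mp = compose_metapath(
            MetaPath(("sim",), "mirna", "mirna"),
            "regulate",
            MetaPath(("ppi",), "gene", "gene"),
            net=small_net,
        )
        assert mp.relation_names == ("sim", "regulate", "ppi")
        assert mp.length == 3

    def test_type_chain_violation_rejected(self, small_net):
        with pytest.raises(ValueError):
            compose_metapath(
                MetaPath(("ppi",), "gene", "gene"),
                "regulate",
                MetaPath((), "gene", "gene"),
                net=small_net,
            )


class TestPathCountMatrix:
    def test_empty_path_is_identity(self, small_net):
        mp = MetaPath((), "gene", "gene")
        np.testing.assert_array_equal(path_count_matrix(small_net, mp), np.eye(3))

    def test_regulate_roundtrip_counts(self):
        mg = np.array([[1.0, 1.0], [0.0, 1.0]])
        net = build_network(np.zeros((2, 2)), mg, np.zeros((2, 2)))
        mp = MetaPath(("regulate", "regulate^-1"), "mirna", "mirna")
        np.testing.assert_array_equal(
            path_count_matrix(net, mp), np.array([[2.0, 1.0], [1.0, 1.0]]))

    def test_regulate_then_ppi(self):
        mg = np.array([[1.0, 0.0]])
        ppi = np.array([[0.0, 1.0], [1.0, 0.0]])
        net = build_network(np.zeros((1, 1)), mg, ppi)
        mp = MetaPath(("regulate", "ppi"), "mirna", "gene")
        np.testing.assert_array_equal(
            path_count_matrix(net, mp), np.array([[0.0, 1.0]]))

    def test_unknown_relation_rejected(self, small_net):
        with pytest.raises(KeyError):
            path_count_matrix(
                small_net, MetaPath(("bind",), "mirna", "mirna"))

    @pytest.mark.parametrize("seed", range(5))
    def test_reverse_path_transposes_counts(self, seed):
        rng = np.random.default_rng(seed)
        sim, mg, ppi = random_binary_network(rng, 4, 5)
        net = build_network(sim, mg, ppi)
        for mp in enumerate_metapaths(net, "mirna", 3):
            fwd = path_count_matrix(net, mp)
            rev = path_count_matrix(net, reverse_metapath(net, mp))
            np.testing.assert_allclose(rev, fwd.T)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dfs_oracle_on_small_networks(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_m, n_g = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        sim, mg, ppi = random_binary_network(rng, n_m, n_g)
        net = build_network(sim, mg, ppi)
        for mp in enumerate_metapaths(net, "mirna", 4):
            mats = [net.relations[r].weights for r in mp.relation_names]
            np.testing.assert_allclose(
                path_count_matrix(net, mp),
                dfs_path_count_matrix(mats, n_m, n_m),
            )


def test_empty_metapath_requires_same_endpoint_types():
    with pytest.raises(ValueError):
        MetaPath((), "mirna", "gene")


def test_catalog_rejects_duplicate_ids():
    with pytest.raises(ValueError):
        NodeCatalog("mirna", ("a", "a"))
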