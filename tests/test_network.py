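"""Network realization: exact in-degrees, NMDA rule, intercolumnar coupling
and structural manipulations."""

import numpy as np
import pandas as pd
import pytest

from betacol.config import POPULATIONS
from betacol.network import (
    apply_manipulation,
    build_two_column_network,
    in_degree_table,
    single_cell_network,
)


def in_deg(net, pre, post, column=0, receptor=None, scope="intra"):
    e = net.edges
    post_ids = net.cells_of(column, post)
    sel = (e["pre_pop"] == pre) & (e["post_pop"] == post) & e["post_id"].isin(post_ids) & (e["scope"] == scope)
    if receptor is None:
        sel &= e["receptor"] != "nmda"
    else:
        sel &= e["receptor"] == receptor
    counts = e[sel].groupby("post_id").size()
    counts = counts.reindex(post_ids, fill_value=0)
    return counts


class TestEdgeCountAudit:
    def test_every_rule_realized_exactly(self, net, model):
        """For every connectivity-map entry, every postsynaptic cell of both
        columns has exactly the specified number of presynaptic partners."""
        for pre_pop, rules in model.connectivity.items():
            for post_pop, k, _g in rules:
                for col in (0, 1):
                    counts = in_deg(net, pre_pop, post_pop, column=col)
                    assert (counts == k).all(), (pre_pop, post_pop, col)

    def test_unlisted_pairs_have_no_edges(self, net, model):
        listed = {(pre, post) for pre, rules in model.connectivity.items() for post, _, _ in rules}
        chem = net.edges[(net.edges["scope"] == "intra") & (net.edges["receptor"] != "nmda")]
        realized = set(zip(chem["pre_pop"], chem["post_pop"]))
        assert realized == listed

    def test_l23_fs_receives_two_l5_ib(self, net):
        assert (in_deg(net, "l5_ib", "l23_fs") == 2).all()

    def test_l4_fs_receives_ten_l5_si_at_g04(self, net):
        e = net.edges
        sel = (e["pre_pop"] == "l5_si") & (e["post_pop"] == "l4_fs")
        assert (e[sel].groupby("post_id").size() == 10).all()
        assert (e[sel]["g_max"] == 0.4).all()
        assert (e[sel]["receptor"] == "gaba_si").all()

    def test_within_population_full_count_is_all_to_all_with_self(self, net):
        # L5 SI -> L5 SI demands 20 partners from a 20-cell population
        counts = in_deg(net, "l5_si", "l5_si")
        assert (counts == 20).all()
        e = net.edges
        sel = (e["pre_pop"] == "l5_si") & (e["post_pop"] == "l5_si")
        autapses = (e[sel]["pre_id"] == e[sel]["post_id"]).sum()
        assert autapses == 40  # one per cell per column

    def test_no_self_partner_when_pool_allows(self, net):
        e = net.edges
        sel = (e["pre_pop"] == "l4_e") & (e["post_pop"] == "l4_e")
        assert (e[sel]["pre_id"] != e[sel]["post_id"]).all()

    def test_overfull_rule_raises(self, model):
        bad = model.with_overrides({"connectivity": {"l23_rs": [["l23_rs", 21, 0.1]]}})
        with pytest.raises(ValueError, match="exceeds"):
            build_two_column_network(bad, seed=0)

    def test_mean_in_degree_table_matches_rules(self, net, model):
        table = in_degree_table(net).set_index(["pre_pop", "post_pop"])["mean_in_degree"]
        for pre_pop, rules in model.connectivity.items():
            for post_pop, k, _g in rules:
                assert table[(pre_pop, post_pop)] == k


class TestNMDAAssignment:
    @pytest.mark.parametrize("pop,g", [("l23_fs", 0.04), ("l23_si", 0.03)])
    def test_quarter_of_cells_selected_with_indegree_ten(self, net, pop, g):
        e = net.edges[net.edges["receptor"] == "nmda"]
        for col in (0, 1):
            sub = e[e["post_id"].isin(net.cells_of(col, pop))]
            per_cell = sub.groupby("post_id").size()
            assert len(per_cell) == 5
            assert (per_cell == 10).all()
            assert (sub["g_max"] == g).all()
            assert (sub["pre_pop"] == "l23_rs").all()

    def test_nmda_is_additional_to_ampa(self, net):
        """NMDA-bearing FS cells keep their full AMPA in-degree."""
        counts = in_deg(net, "l23_rs", "l23_fs", receptor="ampa")
        assert (counts == 10).all()


class TestIntercolumnarCoupling:
    def test_si_boost_factor(self, net):
        e = net.edges
        intra = e[(e["scope"] == "intra") & (e["pre_pop"] == "l5_ib") & (e["post_pop"] == "l23_si")]["g_max"].iloc[0]
        inter = e[(e["scope"] == "inter") & (e["pre_pop"] == "l5_ib") & (e["post_pop"] == "l23_si")]["g_max"].iloc[0]
        assert inter / intra == pytest.approx(1.5)

    def test_fs_projection_not_boosted_and_fast(self, net):
        e = net.edges[(net.edges["scope"] == "inter") & (net.edges["post_pop"] == "l23_fs")]
        assert (e["g_max"] == 0.2).all()
        assert (e["receptor"] == "ampa").all()

    def test_only_l23_interneurons_receive_intercolumnar(self, net):
        inter = net.edges[net.edges["scope"] == "inter"]
        assert set(inter["post_pop"]) == {"l23_fs", "l23_si"}
        assert set(inter["pre_pop"]) == {"l5_ib", "l5_rs"}

    def test_symmetric_between_columns(self, net):
        inter = net.edges[net.edges["scope"] == "inter"]
        for col in (0, 1):
            onto = inter[inter["post_id"].isin(
                np.concatenate([net.cells_of(col, "l23_fs"), net.cells_of(col, "l23_si")])
            )]
            assert len(onto) == (2 + 2) * 40  # 2 IB + 2 RS partners per cell, 40 cells

    def test_slow_kinetics_on_si_projection(self, net):
        e = net.edges[(net.edges["scope"] == "inter") & (net.edges["post_pop"] == "l23_si")]
        assert (e["receptor"] == "slow_exc_l5_to_l23si").all()


class TestManipulations:
    def test_remove_l23_si(self, net):
        ablated = apply_manipulation(net, "remove_l23_si")
        for col in (0, 1):
            assert ablated.cells_of(col, "l23_si").size == 0
        assert not (ablated.edges["pre_pop"] == "l23_si").any()
        assert not (ablated.edges["post_pop"] == "l23_si").any()
        # base network untouched
        assert net.cells_of(0, "l23_si").size == 20

    def test_remove_ascending_inhibition(self, net):
        ablated = apply_manipulation(net, "remove_ascending_inhibition")
        sel = (ablated.edges["pre_pop"] == "l5_si") & (ablated.edges["post_pop"] == "l4_fs")
        assert sel.sum() == 0
        # all other L5 SI projections intact
        assert (ablated.edges["pre_pop"] == "l5_si").sum() == (net.edges["pre_pop"] == "l5_si").sum() - 2 * 20 * 10

    def test_scale_lateral(self, net):
        scaled = apply_manipulation(net, "scale_lateral", factor=0.8)
        assert np.allclose(
            scaled.edges.loc[scaled.edges["scope"] == "inter", "g_max"],
            net.edges.loc[net.edges["scope"] == "inter", "g_max"] * 0.8,
        )
        intra_cols = ["pre_id", "post_id", "g_max"]
        pd.testing.assert_frame_equal(
            scaled.edges.loc[scaled.edges["scope"] == "intra", intra_cols].reset_index(drop=True),
            net.edges.loc[net.edges["scope"] == "intra", intra_cols].reset_index(drop=True),
        )

    def test_scale_lateral_zero_removes_edges(self, net):
        cut = apply_manipulation(net, "scale_lateral", factor=0.0)
        assert (cut.edges["scope"] == "inter").sum() == 0

    def test_set_fs_tonic(self, net):
        mod = apply_manipulation(net, "set_fs_tonic", l23=2.0, l4=1.0, l5=-2.5)
        assert mod.tonic_overrides == {"l23_fs": 2.0, "l4_fs": 1.0, "l5_fs": -2.5}
        assert net.tonic_overrides == {}

    def test_unknown_manipulation_lists_registry(self, net):
        with pytest.raises(KeyError, match="remove_l23_si"):
            apply_manipulation(net, "definitely_not_a_thing")


class TestDeterminismAndStructure:
    def test_seed_determinism_byte_identical(self, model):
        a = build_two_column_network(model, seed=42)
        b = build_two_column_network(model, seed=42)
        assert a.edges.to_csv(index=False) == b.edges.to_csv(index=False)

    def test_different_seeds_differ(self, model):
        a = build_two_column_network(model, seed=1)
        b = build_two_column_network(model, seed=2)
        assert a.edges.to_csv(index=False) != b.edges.to_csv(index=False)

    def test_columns_statistically_exchangeable(self, net):
        """Before stimuli, the two columns have identical population sizes
        and identical per-pair edge counts."""
        for pop in POPULATIONS:
            assert net.cells_of(0, pop).size == net.cells_of(1, pop).size
        e = net.edges[net.edges["scope"] == "intra"]
        col_of = dict(zip(range(net.n_cells), net.cell_column))
        counts = e.groupby([e["post_id"].map(col_of), "pre_pop", "post_pop"]).size()
        assert (counts.xs(0, level=0) == counts.xs(1, level=0)).all()

    def test_export_import_roundtrip(self, net, tmp_path):
        path = tmp_path / "edges.tsv"
        net.export_edges(path)
        loaded = type(net).import_edges(path)
        pd.testing.assert_frame_equal(loaded, net.edges)

    def test_single_cell_network(self, model):
        sc = single_cell_network(model, "l5_ib")
        assert sc.n_cells == 1
        assert len(sc.edges) == 0
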