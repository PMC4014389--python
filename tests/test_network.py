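"""Network construction: quotas, sprouting, newborn substitution, spine loss."""

import numpy as np
import pytest
from scipy import stats

from dgnet import config, network
from dgnet.network import (
    SpineLossInfeasibleError,
    add_mossy_fiber_sprouting,
    apply_spine_loss_wiring,
    build_base_network,
    build_family_network,
    degree_audit,
    insert_newborn,
)


@pytest.fixture(scope="module")
def desk_net(pools, desk_cfg):
    return build_base_network(pools, desk_cfg, seed=3)


class TestBaseNetwork:
    def test_full_scale_quotas_exact(self, pools):
        net = build_base_network(pools, config.full_scale(), seed=0)
        out = degree_audit(net)["out"]
        per = out.pivot_table(index="kind", values="degree", aggfunc=["min", "max"])
        for kind, quota in (("MC->GC", 200), ("HC->GC", 160), ("BC->GC", 100),
                            ("GC->HC", 2), ("GC->MC", 1), ("GC->BC", 1),
                            ("MC->BC", 1), ("MC->HC", 2), ("MC->MC", 3),
                            ("HC->BC", 4), ("HC->MC", 4), ("BC->MC", 3),
                            ("BC->BC", 2)):
            assert per.loc[kind, ("min", "degree")] == quota, kind
            assert per.loc[kind, ("max", "degree")] == quota, kind

    def test_full_scale_composition(self, pools):
        net = build_base_network(pools, config.full_scale(), seed=0)
        assert net.counts() == {"GC": 500, "BC": 6, "MC": 15, "HC": 6}

    def test_total_mc_gc_endpoints(self, pools):
        net = build_base_network(pools, config.full_scale(), seed=0)
        n = sum(1 for e in net.edges if e.kind == "MC->GC")
        assert n == 15 * 200

    def test_same_seed_identical_edge_lists(self, pools, desk_cfg):
        a = build_base_network(pools, desk_cfg, seed=5)
        b = build_base_network(pools, desk_cfg, seed=5)
        assert a.edges == b.edges

    def test_handshake_identity(self, desk_net):
        aud = degree_audit(desk_net)
        out_tot = aud["out"].groupby("kind").degree.sum()
        in_tot = aud["in"].groupby("kind").degree.sum()
        for kind in out_tot.index:
            assert out_tot[kind] == in_tot[kind]

    def test_empty_network_audit(self, desk_net):
        empty = desk_net.copy()
        empty.edges = []
        aud = degree_audit(empty)
        assert aud["out"].empty and aud["in"].empty and aud["multiplicity"].empty

    def test_pair_uniqueness_except_mc(self, desk_net):
        mult = degree_audit(desk_net)["multiplicity"]
        multi_kinds = set(mult[mult.contacts > 1].kind)
        assert multi_kinds <= {"MC->GC"}


class TestMossyFiberSprouting:
    def test_zero_percent_adds_nothing(self, desk_net):
        out = add_mossy_fiber_sprouting(desk_net, 0.0)
        assert sum(1 for e in out.edges if e.kind == "MFS") == 0

    def test_ten_percent_gives_ten_contacts_per_gc(self, desk_net):
        out = add_mossy_fiber_sprouting(desk_net, 10.0)
        # max_sprout=100 at the pilocarpine level -> 10 contacts per GC
        counts = {}
        for e in out.edges:
            if e.kind == "MFS":
                counts[e.pre] = counts.get(e.pre, 0) + 1
        assert set(counts.values()) == {10}
        assert len(counts) == len(out.gc_slots())

    def test_all_sprouted_synapses_in_iml(self, desk_net):
        out = add_mossy_fiber_sprouting(desk_net, 20.0)
        assert all(e.layer == "IML" for e in out.edges if e.kind == "MFS")

    def test_invalid_percent_rejected(self, desk_net):
        with pytest.raises(ValueError):
            add_mossy_fiber_sprouting(desk_net, 150.0)


class TestInsertNewborn:
    def test_zero_fraction_unchanged(self, desk_net, pools):
        out = insert_newborn(desk_net, 0.0, "young_control", pools)
        assert [c.population for c in out.gc_slots()] == \
               [c.population for c in desk_net.gc_slots()]

    def test_full_replacement(self, desk_net, pools):
        out = insert_newborn(desk_net, 1.0, "young_pilo", pools)
        assert all(c.population == "young_pilo" for c in out.gc_slots())

    def test_half_replacement_count_and_uniformity(self, pools, desk_cfg):
        # exactly half the GCs replaced; positions uniform over ring deciles
        decile_counts = np.zeros(10)
        n_seeds = 30
        for seed in range(n_seeds):
            net = build_base_network(pools, desk_cfg, seed=seed)
            out = insert_newborn(net, 0.5, "young_control", pools, seed=seed)
            idx = [c.index for c in out.gc_slots() if c.population == "young_control"]
            assert len(idx) == 50
            decile_counts += np.histogram(idx, bins=10, range=(0, 100))[0]
        chi2 = ((decile_counts - decile_counts.mean()) ** 2 / decile_counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=9) > 0.01

    def test_rounding_half_up(self, pools, desk_cfg):
        net = build_base_network(pools, desk_cfg, seed=1)
        out = insert_newborn(net, 0.005, "young_control", pools)  # 0.5 cells
        n_new = sum(1 for c in out.gc_slots() if c.population == "young_control")
        assert n_new == 1


class TestSpineLossWiring:
    def _pilo_net(self, pools, desk_cfg, seed=2, fraction=0.5):
        net = build_base_network(pools, desk_cfg, seed=seed)
        net = add_mossy_fiber_sprouting(net, 10.0)
        return insert_newborn(net, fraction, "young_pilo", pools)

    def test_sl1_preserves_out_degrees_and_edge_count(self, pools, desk_cfg):
        net = self._pilo_net(pools, desk_cfg)
        out = apply_spine_loss_wiring(net, "SL1", 0.5)
        assert len(out.edges) == len(net.edges)
        for aud0, aud1 in [(degree_audit(net)["out"], degree_audit(out)["out"])]:
            a = aud0.set_index(["cell", "kind"]).degree
            b = aud1.set_index(["cell", "kind"]).degree
            assert a.equals(b)

    def test_sl2_strictly_reduces_edges(self, pools, desk_cfg):
        net = self._pilo_net(pools, desk_cfg)
        out = apply_spine_loss_wiring(net, "SL2", 0.5)
        assert len(out.edges) < len(net.edges)

    def test_sl2_thinning_matches_binomial_expectation(self, pools, desk_cfg):
        # over 50 seeds the kept fraction of PILO afferents ~ Binomial(n, 1-r)
        r = 0.75
        kept, total = 0, 0
        for seed in range(50):
            net = self._pilo_net(pools, desk_cfg, seed=seed, fraction=0.3)
            pilo = {c.index for c in net.gc_slots() if c.population == "young_pilo"}
            before = sum(1 for e in net.edges if e.post in pilo and e.pre >= 0)
            out = apply_spine_loss_wiring(net, "SL2", r, seed=seed)
            after = sum(1 for e in out.edges if e.post in pilo and e.pre >= 0)
            kept += after
            total += before
        p_hat = kept / total
        se = np.sqrt((1 - r) * r / total)
        assert abs(p_hat - (1 - r)) < 4 * se

    def test_sl1_redirected_targets_are_mature(self, pools, desk_cfg):
        net = self._pilo_net(pools, desk_cfg)
        out = apply_spine_loss_wiring(net, "SL1", 0.5)
        pilo = {c.index for c in out.gc_slots() if c.population == "young_pilo"}
        pilo_in_before = sum(1 for e in net.edges if e.post in pilo and e.pre >= 0)
        pilo_in_after = sum(1 for e in out.edges if e.post in pilo and e.pre >= 0)
        assert pilo_in_after < pilo_in_before

    def test_requires_pilo_cells(self, desk_net):
        with pytest.raises(network.ConstructionError):
            apply_spine_loss_wiring(desk_net, "SL2", 0.5)

    def test_sl1_infeasible_at_high_fraction(self, pools, desk_cfg):
        net = self._pilo_net(pools, desk_cfg, seed=4, fraction=0.95)
        with pytest.raises(SpineLossInfeasibleError):
            apply_spine_loss_wiring(net, "SL1", 0.5)


class TestFamilies:
    def test_family_validation(self):
        with pytest.raises(ValueError):
            network.FamilySpec(family="MZ")
        spec = network.FamilySpec(family="MPSL1c", newborn_fraction=0.4)
        assert spec.spine_mode == "SL1"
        assert spec.membrane_correction
        assert spec.newborn_tag == "young_pilo"

    def test_build_family_network_chains_operations(self, pools, desk_cfg):
        spec = network.FamilySpec(family="MPSL2", newborn_fraction=0.3, seed=6)
        net = build_family_network(spec, pools, desk_cfg)
        assert net.spine_loss == "SL2"
        assert net.mfs_percent == 10.0
        tags = {c.population for c in net.gc_slots()}
        assert "young_pilo" in tags

    def test_membrane_corrected_family_uses_corrected_cells(self, pools, desk_cfg):
        spec = network.FamilySpec(family="MPSL2c", newborn_fraction=0.3, seed=6)
        net = build_family_network(spec, pools, desk_cfg)
        pilo_cells = [c for c in net.gc_slots() if c.population == "young_pilo"]
        assert all(c.spec.spine_corrected for c in pilo_cells)


class TestGlobalSiteInvariants:
    def test_mfs_iml_after_full_construction_chain(self, pools, desk_cfg):
        spec = network.FamilySpec(family="MPSL1", newborn_fraction=0.4, seed=8)
        net = build_family_network(spec, pools, desk_cfg)
        assert all(e.layer == "IML" for e in net.edges if e.kind == "MFS")
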