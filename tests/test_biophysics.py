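"""Cell construction, membrane corrections, and single-cell protocols."""

import math
import warnings

import numpy as np
import pytest

from dgnet import biophysics as bp
from dgnet import layers, morphology as m
from dgnet.synthetic import generate_population


@pytest.fixture(scope="module")
def mature_cell(pools):
    return pools.specs["mature"][0]


def passive_table(rm=40000.0, cm=1.0):
    entry = dict(rm=rm, cm=cm, ra=200.0, e_leak=-75.0)
    return bp.ChannelDensityTable({r: dict(entry) for r in
                                   ("soma", "GCLD", "PD", "MD", "DD", "basal")})


def toy_cell(rm=30000.0, soma_r=8.0):
    """Single passive spherical compartment with a stub dendrite."""
    tree = m.MorphTree(
        structure=np.array([1, 4]),
        xyz=np.array([[0.0, 0.0, 0.0], [0.0, 5.0, 0.0]]),
        radius=np.array([soma_r, 0.5]),
        parent=np.array([-1, 0]), name="toy",
    )
    cm_map = layers.classify_dendrites(tree, (10.0, 20.0), gcl_depth=1.0)
    return bp.build_cell(tree, cm_map, passive_table(rm=rm))


class TestBuildCell:
    def test_passive_cell_never_spikes(self):
        cell = toy_cell()
        spikes, _, _ = bp.simulate_cell(cell, 300.0)
        assert len(spikes) == 0

    def test_construction_is_deterministic(self, pools):
        tree = pools.trees["mature"][0]
        cm_map = layers.classify_dendrites(tree, pools.thresholds["mature"])
        a = bp.build_cell(tree, cm_map, bp.default_gc_table())
        b = bp.build_cell(tree, cm_map, bp.default_gc_table())
        np.testing.assert_array_equal(a.area_cm2, b.area_cm2)
        np.testing.assert_array_equal(a.density["na"], b.density["na"])

    def test_resting_potential_stable(self, mature_cell):
        _, rec, _ = bp.simulate_cell(mature_cell, 500.0, record=np.array([0]))
        assert abs(rec[-1, 0] - rec[0, 0]) < 1.0  # < 1 mV drift over 500 ms

    def test_large_step_evokes_spike(self, mature_cell):
        comp = bp.proximal_injection_comp(mature_cell)
        spikes, _, _ = bp.simulate_cell(
            mature_cell, 550.0, injections=[(comp, 0.5, 10.0, 510.0)]
        )
        assert len(spikes) >= 1

    def test_missing_region_is_config_error(self, pools):
        tree = pools.trees["mature"][0]
        cm_map = layers.classify_dendrites(tree, pools.thresholds["mature"])
        table = bp.ChannelDensityTable(
            {"soma": dict(rm=40000.0, cm=1.0, ra=200.0, e_leak=-75.0)}
        )
        with pytest.raises(KeyError):
            bp.build_cell(tree, cm_map, table)


class TestSpineLossMembraneCorrection:
    def test_dendritic_rm_cm_become_somatic(self, pools):
        cell = pools.specs["young_pilo"][0]
        assert not np.allclose(cell.rm[1:], cell.rm[0])
        out = bp.apply_spine_loss_membrane_correction(cell)
        dend = out.region != "soma"
        assert np.allclose(out.rm[dend], out.rm[0])
        assert np.allclose(out.cm[dend], out.cm[0])

    def test_soma_untouched(self, pools):
        cell = pools.specs["young_pilo"][1]
        out = bp.apply_spine_loss_membrane_correction(cell)
        assert out.rm[0] == cell.rm[0]
        assert out.cm[0] == cell.cm[0]

    def test_double_application_is_warned_noop(self, pools):
        cell = pools.specs["young_pilo"][2]
        once = bp.apply_spine_loss_membrane_correction(cell)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            twice = bp.apply_spine_loss_membrane_correction(once)
        assert any("already applied" in str(w.message) for w in caught)
        np.testing.assert_array_equal(twice.rm, once.rm)


class TestRheobase:
    def test_matches_closed_form_on_passive_toy_cell(self):
        # single-compartment RC cell: a 500 ms step settles essentially at
        # V = E_L + I * R_in, and a "spike" is a 0 mV upward crossing, so
        # rheobase ~ (V_thresh - E_L) / R_in
        cell = toy_cell(rm=30000.0, soma_r=8.0)
        area = cell.area_cm2.sum()
        r_in_mohm = 30000.0 / area * 1e-6     # MΩ
        tau = 30000.0 * 1.0 * 1e-3            # ms
        # I(nA) = ΔV(mV) / R(MΩ), corrected for the finite 500 ms charge-up
        expected = (0.0 - (-75.0)) / r_in_mohm / (1.0 - math.exp(-500.0 / tau))
        measured = bp.rheobase(cell, comp=0, upper_nA=2.0 * expected)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_search_failure_reports_bound(self):
        cell = toy_cell()
        with pytest.raises(bp.RheobaseSearchError, match="0.001"):
            bp.rheobase(cell, comp=0, upper_nA=0.001)

    def test_smaller_amplitude_at_tolerance_gives_no_spike(self, pools):
        cell = pools.specs["young_control"][0]
        rheo = bp.rheobase(cell, tol_nA=0.002)
        comp = bp.proximal_injection_comp(cell)
        spk, _, _ = bp.simulate_cell(cell, 550.0,
                                     injections=[(comp, rheo - 0.004, 10.0, 510.0)])
        assert len(spk) == 0


class TestSynapticTrain:
    def test_zero_amplitude_gives_zero_spikes(self, pools):
        cell = pools.specs["mature"][0]
        assert bp.synaptic_train_response(cell, g_syn_uS=0.0) == 0

    def test_suprathreshold_toy_cell_fires_once_per_pulse(self):
        # weakly active soma: each pulse triggers exactly one spike and the
        # 100 ms interval far exceeds the refractory period
        tree = m.MorphTree(
            structure=np.array([1, 4, 4]),
            xyz=np.array([[0, 0, 0], [0, 40, 0], [0, 80, 0]], dtype=float),
            radius=np.array([7.0, 1.0, 0.8]), parent=np.array([-1, 0, 1]),
            name="toy_active",
        )
        cm_map = layers.classify_dendrites(tree, (30.0, 60.0), gcl_depth=5.0)
        table = passive_table()
        table.regions["soma"].update(na=0.15, kdr=0.08)
        cell = bp.build_cell(tree, cm_map, table)
        # at the smallest suprathreshold amplitude each pulse evokes exactly
        # one spike; the 100 ms interval far exceeds any refractory effect
        times = [5.0 + 100.0 * k for k in range(10)]
        for g in np.geomspace(0.001, 0.1, 16):
            spk, _, _ = bp.simulate_cell(
                cell, 1000.0, stim_synapses=[(2, float(g), 0.5, 3.0, 0.0, times)]
            )
            if len(spk) > 0:
                assert len(spk) == 10
                break
        else:
            pytest.fail("no pulse amplitude in the scanned range evoked spikes")

    def test_protocol_inapplicable_without_oml_reach(self, pools):
        short = [c for c, t in zip(pools.specs["young_pilo"], pools.trees["young_pilo"])
                 if m.max_dendritic_extent(t) < pools.partition.oml[0]]
        assert short, "expected at least one short PILO cell"
        with pytest.raises(ValueError, match="outer molecular layer"):
            bp.synaptic_train_response(short[0], partition=pools.partition)


class TestNumerics:
    def test_spike_count_stable_under_dt_halving(self, pools):
        cell = pools.specs["mature"][3]
        comp = bp.proximal_injection_comp(cell)
        counts = []
        for dt in (0.1, 0.05):
            spk, _, _ = bp.simulate_cell(
                cell, 200.0, dt=dt, injections=[(comp, 0.12, 10.0, 190.0)]
            )
            counts.append(len(spk))
        assert counts[0] > 0
        assert abs(counts[0] - counts[1]) <= 1
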