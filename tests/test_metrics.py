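"""Response readouts: totals, activities, peak detection, classification."""

import numpy as np
import pytest

from p53mdmx import DamageProtocol, build_network, run_damage
from p53mdmx.metrics import (
    delta_A,
    detect_peaks,
    early_activity,
    period,
    reservoir_log_ratio,
    total_protein,
)
from p53mdmx.network import MassActionSystem
from p53mdmx.parameters import ALL_SYMBOLS, ParameterSet
from p53mdmx.simulate import Trajectory, default_initial_state, integrate


def _snap(network, species_values=None):
    x = np.zeros(network.n_species)
    for idx, v in (species_values or {}).items():
        x[network.species_position(idx)] = v
    return Trajectory(np.array([0.0]), x[None, :], network)


class TestTotalProtein:
    def test_tetramer_counts_four(self, full_net):
        assert total_protein(_snap(full_net, {12: 1.0}), "p53")[0] == 4.0

    def test_heterodimer_counts_in_both_moieties(self, full_net):
        snap = _snap(full_net, {8: 1.0})
        assert total_protein(snap, "Mdm2")[0] == 1.0
        assert total_protein(snap, "MdmX")[0] == 1.0

    def test_unknown_moiety(self, full_net):
        with pytest.raises(KeyError):
            total_protein(_snap(full_net), "p21")

    def test_binding_only_dynamics_conserve_totals(self, simple_net, rng):
        # only association/dissociation active: all three totals constant
        vals = {s: 0.0 for s in ALL_SYMBOLS}
        vals.update(k11=1.0, k12=0.1, k23=0.5, k24=0.2, k25=0.8, k26=0.3,
                    k27=0.4, k28=0.1, k29=0.2, k30=0.1)
        p = ParameterSet(vals)
        x0 = rng.uniform(0.1, 1.0, 14)
        sys_ = MassActionSystem(simple_net, p)
        sol = integrate(sys_, x0, (0.0, 200.0))
        traj = Trajectory(sol.t, sol.y.T, simple_net)
        for moiety in ("p53", "Mdm2", "MdmX"):
            tot = total_protein(traj, moiety)
            assert np.allclose(tot, tot[0], atol=1e-8)


class TestEarlyActivity:
    def test_constant_series(self, full_net):
        t = np.arange(0.0, 200.0)
        states = np.zeros((t.size, 16))
        states[:, full_net.species_position(15)] = 0.37
        assert early_activity(Trajectory(t, states, full_net)) == 0.37

    def test_simple_variant_reads_t55(self, simple_net):
        t = np.arange(0.0, 100.0)
        states = np.zeros((t.size, 14))
        states[:, simple_net.species_position(14)] = t / 100.0
        assert early_activity(Trajectory(t, states, simple_net)) == pytest.approx(0.55)

    def test_window_not_covered(self, full_net):
        t = np.arange(0.0, 50.0)
        with pytest.raises(ValueError):
            early_activity(Trajectory(t, np.zeros((t.size, 16)), full_net))

    def test_grid_refinement_invariance(self, full_net, col8):
        proto = DamageProtocol(t_end=180.0)
        coarse = early_activity(run_damage(col8, proto, full_net, dt=1.0))
        fine = early_activity(run_damage(col8, proto, full_net, dt=0.1))
        assert coarse > 0
        assert abs(fine - coarse) / coarse < 5e-3


class TestDeltaA:
    def test_identical_arms_give_zero(self, col4):
        assert delta_A(col4, 0.0, phospho_rate=0.1) == 0.0

    def test_sign_structure_of_reservoir_switch(self, col4):
        # p53:MdmX reservoir dominant (low Mdm2, tight p53-MdmX binding)
        up = delta_A(col4, 5.0, phospho_rate=0.1, k6=0.001, k25=1.0)
        # Mdm2:MdmX reservoir dominant (high Mdm2, tight Mdm2-MdmX binding)
        down = delta_A(col4, 5.0, phospho_rate=0.1, k6=1.0, k23=1.0)
        assert up > 1e-3
        assert down < -1e-5

    def test_numerically_stable_across_tolerances(self, simple_net, col4):
        # same protocol at two solver tolerances: tiny relative shift
        from p53mdmx.metrics import early_activity as ea

        proto = DamageProtocol(phospho_rate=0.1, t_end=60.0, feedback_off=True)
        p = col4.with_rates(k6=0.001, k25=1.0, k15=5.0)
        a = ea(run_damage(p, proto, simple_net, rtol=1e-8, atol=1e-12))
        b = ea(run_damage(p, proto, simple_net, rtol=1e-9, atol=1e-13))
        assert abs(a - b) <= 1e-6 * max(1.0, abs(a))


class TestPeaks:
    def test_known_sinusoid(self):
        t = np.arange(0.0, 4000.0, 1.0)
        y = np.sin(2 * np.pi * t / 360.0)
        assert period(t, y) == pytest.approx(360.0, abs=1.0)

    def test_monotone_series_flags_no_oscillation(self):
        t = np.arange(0.0, 100.0)
        res = detect_peaks(t, t * 0.1)
        assert not res.oscillating and res.period is None
        with pytest.raises(ValueError):
            period(t, t * 0.1)

    def test_programmed_spacing_recovered(self):
        from p53mdmx.targets import make_oscillation_target

        tgt = make_oscillation_target(period=360.0, n_peaks=6, dt=5.0, seed=7,
                                      noise_sd=0.02)
        res = detect_peaks(tgt["time"].to_numpy(), tgt["value"].to_numpy(),
                           discard_frac=0.0)
        assert res.oscillating
        assert res.period == pytest.approx(360.0, abs=5.0)

    def test_small_ripple_does_not_distort_the_period(self):
        t = np.arange(0.0, 4000.0)
        y = np.sin(2 * np.pi * t / 360.0) + 0.02 * np.sin(2 * np.pi * t / 30.0)
        res = detect_peaks(t, y)
        assert res.oscillating
        assert res.period == pytest.approx(360.0, abs=2.0)


class TestReservoirLogRatio:
    def test_equal_reservoirs_give_zero(self):
        # fully symmetric p53/Mdm2 sides: the two reservoirs coincide
        vals = {s: 0.0 for s in ALL_SYMBOLS}
        vals.update(k1=0.01, k2=0.01, k6=0.01, k7=0.01, k15=0.01, k16=0.01,
                    k23=0.5, k24=0.05, k25=0.5, k26=0.05)
        field = reservoir_log_ratio(ParameterSet(vals), phospho_rate=0.0,
                                    scan={"k6": np.array([0.01])})
        assert field["log_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_sign_flips_with_mdm2_production(self, col4):
        field = reservoir_log_ratio(col4.with_rates(k15=5.0, k25=1.0),
                                    phospho_rate=0.1,
                                    scan={"k6": np.array([1e-3, 1.0])})
        low = field.loc[field.k6 == 1e-3, "log_ratio"].iloc[0]
        high = field.loc[field.k6 == 1.0, "log_ratio"].iloc[0]
        assert low > 0    # p53:MdmX dominates at low Mdm2
        assert high < 0   # Mdm2:MdmX dominates at high Mdm2
        assert low > high

    def test_symmetric_binding_constants_give_antisymmetric_field(self):
        # a constructed set where p53 and Mdm2 sides are mirror images:
        # swapping the two association constants flips the ratio's sign
        vals = {s: 0.0 for s in ALL_SYMBOLS}
        vals.update(k1=0.01, k2=0.01, k6=0.01, k7=0.01, k15=0.01, k16=0.01,
                    k24=0.05, k26=0.05)
        rows = {}
        for name, (k23, k25) in {"a": (0.1, 0.9), "b": (0.9, 0.1)}.items():
            p = ParameterSet({**vals, "k23": k23, "k25": k25})
            field = reservoir_log_ratio(p, phospho_rate=0.0,
                                        scan={"k6": np.array([0.01])})
            rows[name] = field["log_ratio"].iloc[0]
        assert rows["a"] == pytest.approx(-rows["b"], rel=1e-6)
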