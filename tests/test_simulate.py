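"""Simulation protocols: equilibration, damage, delay, Nutlin, pulse."""

import numpy as np
import pytest

from p53mdmx import (
    DamageProtocol,
    PulseSchedule,
    build_network,
    pre_equilibrate,
    run_damage,
    run_delay,
    run_nutlin,
    run_pulse,
)
from p53mdmx.network import MassActionSystem
from p53mdmx.parameters import ALL_SYMBOLS, ParameterSet
from p53mdmx.simulate import default_initial_state, integrate


class TestPreEquilibrate:
    def test_empty_system_is_trivial(self, simple_net):
        p = ParameterSet({s: 0.0 for s in ALL_SYMBOLS})
        x = pre_equilibrate(p, simple_net)
        expect = np.zeros(14)
        expect[simple_net.species_position(13)] = 1.0
        assert np.allclose(x, expect)

    def test_two_method_oracle_long_integration(self, simple_net, col4):
        # closed-form equilibrium vs brute long integration of the ODEs
        p = col4.with_rates(k6=0.05, k15=0.0, k3=0.0, k8=0.0, k17=0.0)
        x_fast = pre_equilibrate(p, simple_net)
        sys_ = MassActionSystem(simple_net, p)
        sol = integrate(sys_, default_initial_state(simple_net), (0.0, 2e6),
                        t_grid=np.array([0.0, 2e6]))
        assert np.allclose(x_fast, sol.y[:, -1], rtol=1e-8, atol=1e-10)

    def test_full_model_residual(self, full_net, col8):
        x = pre_equilibrate(col8, full_net)
        sys_ = MassActionSystem(full_net, col8.for_phase(damage=False).with_rates(
            k3=0.0, k8=0.0, k17=0.0))
        resid = np.max(np.abs(sys_.rhs(0.0, x)))
        assert resid < 1e-9 * (1.0 + np.max(np.abs(x)))
        assert col8.k1_predamage == 0.003  # pre-damage basal p53 production

    def test_reservoirs_fill_at_rest(self, full_net, col8):
        # the Mdm2:MdmX pool at rest dwarfs free MdmX when Mdm2 is high
        x = pre_equilibrate(col8.with_rates(k6=1e-2), full_net)
        assert x[full_net.species_position(9)] > 100 * x[full_net.species_position(5)]


class TestRunDamage:
    def test_no_perturbation_keeps_steady_state(self, simple_net, col4):
        proto = DamageProtocol(phospho_rate=0.0, t_end=100.0, feedback_off=True)
        traj = run_damage(col4.with_rates(k15=0.05), proto, simple_net)
        x14 = traj.series(14)
        assert np.allclose(x14, x14[0], atol=1e-9)

    def test_activity_rises_from_zero_after_damage(self, simple_net, col4):
        proto = DamageProtocol(phospho_rate=0.1, t_end=60.0, feedback_off=True)
        traj = run_damage(col4.with_rates(k6=1e-3, k15=5.0), proto, simple_net)
        x14 = traj.series(14)
        assert x14[0] == pytest.approx(0.0, abs=1e-12)
        assert x14[-1] > 1e-4

    def test_promoter_moiety_conserved_along_trajectory(self, full_net, col8):
        proto = DamageProtocol(t_end=300.0, pre_equilibrate=False)
        traj = run_damage(col8, proto, full_net)
        tot = traj.states[:, full_net.promoter_rows].sum(axis=1)
        assert np.allclose(tot, tot[0], atol=1e-8)

    def test_nonnegativity(self, full_net, col9):
        proto = DamageProtocol(t_end=500.0, pre_equilibrate=False)
        traj = run_damage(col9, proto, full_net)
        assert traj.states.min() > -1e-9

    def test_tolerance_refinement_stability(self, full_net, col8):
        # a 10x tighter solver tolerance moves the readout by <0.1%
        proto = DamageProtocol(t_end=180.0)
        a = run_damage(col8, proto, full_net, rtol=1e-8, atol=1e-12).series(15).max()
        b = run_damage(col8, proto, full_net, rtol=1e-9, atol=1e-13).series(15).max()
        assert abs(a - b) / a < 1e-3

    def test_full_model_switches_k1_on_damage(self, full_net, col8):
        proto = DamageProtocol(t_end=5.0, pre_equilibrate=True)
        traj = run_damage(col8, proto, full_net)
        x = traj.states[0]
        sys_damage = MassActionSystem(full_net, col8.for_phase(damage=True))
        d_obs = (traj.states[1] - traj.states[0])[full_net.species_position(1)]
        d_pred = sys_damage.rhs(0.0, x)[full_net.species_position(1)]
        assert d_obs == pytest.approx(d_pred, rel=0.1)


class TestRunDelay:
    def test_zero_delay_reproduces_ode(self, simple_net, col6):
        proto = DamageProtocol(t_end=200.0, pre_equilibrate=True)
        a = run_delay(col6, proto, simple_net, tau=0.0)
        b = run_damage(col6, proto, simple_net)
        assert np.abs(a.states - b.states).max() < 1e-6

    def test_matches_piecewise_closed_form(self, simple_net):
        # only Mdm2 production (delayed, catalysed by x14) and x14 decay
        # are active, so x3 has an explicit piecewise solution
        vals = {s: 0.0 for s in ALL_SYMBOLS}
        vals.update(k33=2.0, k32=0.3)
        p = ParameterSet(vals, label="delay-toy")
        x0 = default_initial_state(simple_net, 0.3)
        c = 0.7
        x0[simple_net.species_position(14)] = c
        tau, k32, k33 = 5.0, 0.3, 2.0
        traj = run_delay(p, DamageProtocol(t_end=20.0, pre_equilibrate=False),
                         simple_net, tau=tau, x0=x0, dt=0.25)

        def exact(t):
            if t <= tau:
                return k33 * c * t
            return k33 * c * (tau + (1 - np.exp(-k32 * (t - tau))) / k32)

        got = traj.series(3)
        want = np.array([exact(t) for t in traj.times])
        assert np.abs(got - want).max() < 1e-5

    def test_mdmx_reduces_delay_oscillation_amplitude(self, simple_net, col6):
        proto = DamageProtocol(t_end=1500.0, pre_equilibrate=True)
        amps = {}
        for k15 in (0.0, 0.1):
            traj = run_delay(col6.with_rates(k15=k15), proto, simple_net, tau=50.0)
            tail = traj.series(14)[traj.times > 500]
            amps[k15] = tail.max() - tail.min()
        assert amps[0.0] > 0.1          # sustained oscillation without MdmX
        assert amps[0.1] < 0.9 * amps[0.0]

    def test_negative_delay_rejected(self, simple_net, col6):
        with pytest.raises(ValueError):
            run_delay(col6, DamageProtocol(t_end=10.0), simple_net, tau=-1.0)


class TestRunNutlin:
    def test_fold_changes_normalised_at_t0(self, full_net, col8):
        folds, _ = run_nutlin(col8, full_net, t_end=60.0)
        assert np.allclose(folds.iloc[0], 1.0)

    def test_total_p53_rises_after_blockade(self, full_net, col8):
        folds, _ = run_nutlin(col8, full_net, t_end=720.0)
        assert folds["p53"].iloc[-1] > 1.05
        assert folds["p53"].is_monotonic_increasing

    def test_isolated_complex_decays_exponentially(self, full_net, col8):
        # with k11 = 0, the p53:Mdm2 balance is linear:
        # x7(t) = x7(0) * exp(-(k12+k13+k14) t)
        folds, traj = run_nutlin(col8, full_net, t_end=120.0)
        x7 = traj.series(7)
        lam = col8["k12"] + col8["k13"] + col8["k14"]
        want = x7[0] * np.exp(-lam * traj.times)
        mask = want > 1e-10  # above the solver's absolute-error floor
        assert mask.sum() > 5
        assert np.allclose(x7[mask], want[mask], rtol=1e-6)

    def test_requires_binding_before_treatment(self, full_net, col8):
        with pytest.raises(ValueError):
            run_nutlin(col8.with_rates(k11=0.0), full_net)


class TestRunPulse:
    def test_single_phase_equals_plain_damage(self, full_net, col8):
        x0 = default_initial_state(full_net)
        a = run_pulse(col8, PulseSchedule(((500.0, 1.0),)), full_net, x0=x0)
        b = run_damage(col8, DamageProtocol(t_end=500.0, pre_equilibrate=False),
                       full_net)
        assert np.abs(a.states - b.states).max() < 1e-9

    def test_state_continuous_across_phases(self, full_net, col8):
        traj = run_pulse(col8, PulseSchedule(((300.0, 1.0), (300.0, 100.0))),
                         full_net)
        i = np.searchsorted(traj.times, 300.0)
        assert traj.times[i] == 300.0
        jump = np.abs(traj.states[i] - traj.states[i - 1]).max()
        assert jump < np.abs(traj.states[i - 1]).max() * 0.05  # one dt step apart

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            PulseSchedule(())


class TestSteadyStateMdmXIndependence:
    def test_non_mdmx_species_independent_of_k15(self, simple_net, fig7_params):
        # verified steady states at three MdmX production rates: the
        # non-MdmX block must coincide exactly
        from p53mdmx.bifurcation import steady_state_reduction

        base = fig7_params.with_rates(k1=5.0)
        states = {}
        for k15 in (0.0, 0.2, 0.6):
            p = base.with_rates(k15=k15)
            x = steady_state_reduction(p, simple_net)
            sys_ = MassActionSystem(simple_net, p)
            resid = np.max(np.abs(sys_.rhs(0.0, x)))
            assert resid < 1e-9 * (1 + np.max(x))  # genuinely steady
            states[k15] = x
        non_mdmx = [i for i in (1, 2, 3, 4, 7, 11, 12, 13, 14)]
        for k15 in (0.2, 0.6):
            for idx in non_mdmx:
                a = states[0.0][simple_net.species_position(idx)]
                b = states[k15][simple_net.species_position(idx)]
                assert b == pytest.approx(a, rel=1e-6, abs=1e-12)
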