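"""Network construction, mass-action derivatives and parameter registry."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p53mdmx import build_network, load_parameter_set, rhs
from p53mdmx.network import MassActionSystem, reaction_table
from p53mdmx.parameters import (
    ALL_SYMBOLS,
    PARAMETER_LABELS,
    ParameterSet,
    apply_search_constraints,
)


class TestBuildNetwork:
    def test_simple_variant_shape(self, simple_net):
        assert simple_net.n_species == 14
        assert simple_net.n_reactions == 33
        assert [rx.id for rx in simple_net.reactions] == list(range(1, 34))

    def test_full_variant_shape(self, full_net):
        assert full_net.n_species == 16
        assert full_net.n_reactions == 38
        ids = [rx.id for rx in full_net.reactions]
        assert 33 not in ids  # direct Mdm2 production replaced by the mRNA route
        assert ids == list(range(1, 33)) + list(range(34, 40))

    def test_delay_variant(self):
        net = build_network("simple", delay_on=True)
        delays = {rx.id: rx.delay for rx in net.reactions}
        assert delays[33] == 50.0
        assert all(d == 0 for i, d in delays.items() if i != 33)

    def test_errors(self):
        with pytest.raises(ValueError):
            build_network("reduced")
        with pytest.raises(ValueError):
            build_network("full", delay_on=True)

    def test_promoter_rows_conserved_by_stoichiometry(self, simple_net, full_net):
        for net in (simple_net, full_net):
            rows = net.promoter_rows
            assert np.all(net.stoichiometry[rows].sum(axis=0) == 0)

    def test_moiety_conservation_in_binding_reactions(self, full_net):
        # pure association/dissociation rows conserve all three subunit counts
        binding = {11, 12, 20, 21, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 37, 38}
        S = full_net.stoichiometry
        for moiety in ("p53", "Mdm2", "MdmX"):
            w = full_net.moiety_weights(moiety)
            for j, rx in enumerate(full_net.reactions):
                if rx.id in binding:
                    assert w @ S[:, j] == 0, (moiety, rx.id)

    def test_reaction_table_audit(self, full_net):
        tab = reaction_table(full_net)
        assert len(tab) == 38
        assert (tab.loc[tab.id == 36, "products"] == "x3 + x15").all()


from oracles import brute_force_rhs  # independent flux-accumulation oracle


class TestRhs:
    @pytest.mark.parametrize("variant,label", [("simple", "col4"), ("simple", "col5"),
                                               ("full", "col8"), ("full", "col9")])
    def test_matches_bruteforce_on_random_states(self, variant, label, rng):
        net = build_network(variant)
        p = load_parameter_set(label)
        for _ in range(100):
            x = rng.uniform(0.0, 5.0, net.n_species)
            got = rhs(x, p, net)
            want = brute_force_rhs(x, p, net)
            assert np.allclose(got, want, rtol=1e-12, atol=1e-14)

    def test_zero_state_only_production(self, simple_net, col4):
        dx = rhs(np.zeros(14), col4, simple_net)
        assert dx[simple_net.species_position(1)] == pytest.approx(0.05)
        # complexes cannot form from the empty state
        for idx in (7, 8, 9, 10, 11, 12, 14):
            assert dx[simple_net.species_position(idx)] == 0.0

    def test_promoter_derivative_sums_to_zero(self, full_net, col8, rng):
        for _ in range(10):
            x = rng.uniform(0, 3, 16)
            dx = rhs(x, col8, full_net)
            assert abs(dx[full_net.promoter_rows].sum()) < 1e-14

    def test_length_mismatch(self, simple_net, col4):
        with pytest.raises(ValueError):
            rhs(np.zeros(16), col4, simple_net)

    def test_analytic_jacobian_matches_finite_differences(self, full_net, col9, rng):
        sys_ = MassActionSystem(full_net, col9)
        x = rng.uniform(0.1, 2.0, 16)
        J = sys_.jacobian(0.0, x)
        h = 1e-7
        for j in range(16):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fd = (sys_.rhs(0, xp) - sys_.rhs(0, xm)) / (2 * h)
            assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_homodimerisation_flux_is_k_x_squared(self, seed):
        net = build_network("simple")
        p = load_parameter_set("col4")
        x = np.random.default_rng(seed).uniform(0, 4, 14)
        sys_ = MassActionSystem(net, p)
        f = sys_.fluxes(x)
        j27 = [j for j, rx in enumerate(net.reactions) if rx.id == 27][0]
        assert f[j27] == pytest.approx(p["k27"] * x[net.species_position(2)] ** 2)


class TestParameterSets:
    def test_printed_values(self):
        c4 = load_parameter_set("col4")
        assert c4["k13"] == 5.0 and c4["k20"] == 11.0
        c5 = load_parameter_set("col5")
        assert c5["k15"] == 0.0 and c5["k14"] == 0.1 and c5["k33"] == 0.1
        c8 = load_parameter_set("col8")
        assert c8["k38"] == 3.708 and c8["k37"] == 5.551e-2 and c8["k3"] == 1.578e-2

    def test_variant_flags(self):
        for lbl in PARAMETER_LABELS:
            p = load_parameter_set(lbl)
            if p.variant == "simple":
                assert all(p[s] == 0 for s in ("k34", "k35", "k36", "k37", "k38"))
            else:
                assert p.k1_predamage == 0.003 and p.k1_postdamage == 0.01

    def test_scan_axes_are_recorded(self):
        c4 = load_parameter_set("col4")
        assert set(c4.scan_axes) == {"k3", "k8", "k17", "k6", "k15"}
        assert c4.scan_axes["k3"].grid().size == 50
        assert c4["k15"] == 0.05  # middle element of the printed list
        c5 = load_parameter_set("col5")
        g = c5.scan_axes["k1"].grid()
        assert g.size == 26 and g[0] == pytest.approx(0.028118) and g[-1] == pytest.approx(10.0)

    def test_unknown_label(self):
        with pytest.raises(KeyError):
            load_parameter_set("col3")

    def test_negative_rate_rejected(self):
        vals = {s: 0.0 for s in ALL_SYMBOLS}
        vals["k2"] = -1.0
        with pytest.raises(ValueError):
            ParameterSet(vals)

    def test_with_rates_unknown_symbol(self, col4):
        with pytest.raises(KeyError):
            col4.with_rates(k99=1.0)


class TestSearchConstraints:
    def test_stage1_ties(self, col8):
        p = apply_search_constraints(1, col8.with_rates(k2=0.004, k13=2.5, k3=1.0))
        assert p["k5"] == p["k7"] == 0.004
        assert p["k14"] == pytest.approx(0.5)
        assert p["k8"] == 1.0
        assert p["k4"] == p["k9"] == pytest.approx(0.02)

    def test_stage2_ties(self, col8):
        p = apply_search_constraints(2, col8.with_rates(k3=1.0))
        assert p["k10"] == p["k17"] == 1.0
        assert p["k4"] == p["k9"] == p["k18"] == pytest.approx(0.02)

    def test_unknown_stage(self, col8):
        with pytest.raises(ValueError):
            apply_search_constraints(3, col8)
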