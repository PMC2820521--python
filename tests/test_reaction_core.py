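"""Mass-action core: rate conversions, RHS assembly, conservation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spinesim.io import generate_fixture
from spinesim.reaction_core import (
    BindingReaction,
    EnzymaticReaction,
    NetworkError,
    ReactionNetwork,
    Species,
    assemble_rhs,
    conserved_moieties,
    law_value,
    rate_constants_from_kd_tau,
    rate_constants_from_km_kcat,
)


class TestRateConversions:
    def test_kd_tau_identity_case(self):
        assert rate_constants_from_kd_tau(1.0, 1.0) == (1.0, 1.0)

    def test_kd_tau_derived_case(self):
        kf, kb = rate_constants_from_kd_tau(2.0, 0.5)
        assert kb == pytest.approx(2.0)
        assert kf == pytest.approx(1.0)

    @pytest.mark.parametrize("kd,tau", [(0.3, 2.0), (7.5, 0.01), (1e-3, 40.0)])
    def test_kd_tau_detailed_balance(self, kd, tau):
        kf, kb = rate_constants_from_kd_tau(kd, tau)
        assert kb / kf == pytest.approx(kd, rel=1e-14)
        assert kb == pytest.approx(1.0 / tau, rel=1e-14)

    def test_km_kcat_genesis_convention(self):
        assert rate_constants_from_km_kcat(1.0, 1.0) == (5.0, 4.0, 1.0)
        kf, kb, kcat = rate_constants_from_km_kcat(10.0, 2.0)
        assert (kf, kb, kcat) == (1.0, 8.0, 2.0)

    @pytest.mark.parametrize("km,kcat", [(0.5, 3.0), (60.0, 0.05), (2.0, 2.0)])
    def test_km_kcat_consistency(self, km, kcat):
        kf, kb, kc = rate_constants_from_km_kcat(km, kcat)
        assert (kb + kc) / kf == pytest.approx(km, rel=1e-14)
        assert kb == pytest.approx(4.0 * kcat, rel=1e-14)

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            rate_constants_from_kd_tau(*bad)
        with pytest.raises(ValueError):
            rate_constants_from_km_kcat(*bad)


def _binding_net(a0=1.0, b0=1.0, kf=1.0, kb=1.0):
    return ReactionNetwork(
        [Species("A", a0), Species("B", b0),
         Species("AB", 0.0, moieties={"A": 1, "B": 1})],
        [BindingReaction("A", "B", "AB", kf=kf, kb=kb)],
    )


class TestAssembleRhs:
    def test_single_binding_direct_substitution(self):
        net = _binding_net()
        rhs, _ = assemble_rhs(net)
        dy = rhs(0.0, np.array([1.0, 1.0, 0.0]))
        # d[AB]/dt = kf[A][B] - kb[AB] = 1
        assert dy[net.index["AB"]] == pytest.approx(1.0)
        assert dy[net.index["A"]] == pytest.approx(-1.0)

    def test_conservation_weighted_derivative_sum_is_zero(self):
        net = _binding_net(kf=2.3, kb=0.7)
        rhs, _ = assemble_rhs(net)
        laws = conserved_moieties(net)
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = rng.uniform(0.0, 3.0, 3)
            dy = rhs(0.0, y)
            for law in laws:
                s = sum(w * dy[net.index[n]] for n, w in law.items())
                assert s == pytest.approx(0.0, abs=1e-12)

    def test_clamped_species_has_zero_derivative_but_drives(self):
        net = ReactionNetwork(
            [Species("A", 2.0, clamped=True), Species("B", 1.0),
             Species("AB", 0.0, moieties={"A": 1, "B": 1})],
            [BindingReaction("A", "B", "AB", kf=1.0, kb=0.5)],
        )
        dy = net.rhs(0.0, net.initial_state())
        assert dy[net.index["A"]] == 0.0
        assert dy[net.index["AB"]] == pytest.approx(2.0)  # kf*[A]*[B]

    def test_time_dependent_clamp_waveform(self):
        net = ReactionNetwork(
            [Species("A", 0.0, clamped=True, clamp_value=lambda t: 1.0 + t),
             Species("B", 1.0), Species("AB", 0.0, moieties={"A": 1, "B": 1})],
            [BindingReaction("A", "B", "AB", kf=1.0, kb=0.0)],
        )
        dy0 = net.rhs(0.0, net.initial_state())
        dy3 = net.rhs(3.0, net.initial_state())
        assert dy0[net.index["AB"]] == pytest.approx(1.0)
        assert dy3[net.index["AB"]] == pytest.approx(4.0)

    def test_dangling_species_reference_rejected(self):
        with pytest.raises(NetworkError):
            ReactionNetwork([Species("A", 1.0)],
                            [BindingReaction("A", "B", "AB", kf=1.0, kb=0.0)])

    def test_jacobian_matches_finite_differences(self):
        net, _ = generate_fixture("random_small_network", seed=7)
        rng = np.random.default_rng(7)
        y = rng.uniform(0.1, 2.0, net.n_species)
        J = net.jacobian(0.0, y)
        eps = 1e-7
        for j in range(net.n_species):
            yp = y.copy(); yp[j] += eps
            ym = y.copy(); ym[j] -= eps
            col = (net.rhs(0.0, yp) - net.rhs(0.0, ym)) / (2 * eps)
            assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_per_reaction_sum(self, seed):
        """Assembled derivative equals a naive per-reaction summation."""
        net, _ = generate_fixture("random_small_network", seed=seed)
        rng = np.random.default_rng(seed + 100)
        y = rng.uniform(0.0, 2.0, net.n_species)
        expected = np.zeros_like(y)
        ix = net.index
        for r in net.reactions:
            flux = r.kf * y[ix[r.a]] * y[ix[r.b]] - r.kb * y[ix[r.ab]]
            expected[ix[r.a]] -= flux
            expected[ix[r.b]] -= flux
            expected[ix[r.ab]] += flux
        assert np.allclose(net.rhs(0.0, y), expected, rtol=1e-12, atol=1e-12)


class TestConservedMoieties:
    def test_binding_textbook_laws(self):
        net = _binding_net()
        laws = conserved_moieties(net)
        supports = sorted(tuple(sorted(law)) for law in laws)
        assert supports == [("A", "AB"), ("AB", "B")]

    def test_enzymatic_textbook_laws(self):
        net = ReactionNetwork(
            [Species("E", 1.0), Species("S", 5.0),
             Species("ES", 0.0, moieties={"E": 1, "S": 1}),
             Species("P", 0.0, moieties={"S": 1})],
            [EnzymaticReaction("E", "S", "ES", "P", kf=1.0, kb=1.0, kcat=1.0)],
        )
        laws = conserved_moieties(net)
        supports = sorted(tuple(sorted(law)) for law in laws)
        assert supports == [("E", "ES"), ("ES", "P", "S")]

    def test_laws_exclude_clamped_bath_species(self):
        net = ReactionNetwork(
            [Species("A", 1.0, clamped=True), Species("B", 1.0),
             Species("AB", 0.0, moieties={"A": 1, "B": 1})],
            [BindingReaction("A", "B", "AB", kf=1.0, kb=1.0)],
        )
        laws = conserved_moieties(net)
        assert all("A" not in law for law in laws)
        assert any(set(law) == {"B", "AB"} for law in laws)


class TestDynamicsInvariants:
    def test_binding_equilibrium_matches_quadratic(self):
        net, ref = generate_fixture("binding_equilibrium", seed=3)
        sol = solve_ivp(net.rhs, (0, 2000.0), net.initial_state(),
                        method="LSODA", jac=net.jacobian,
                        rtol=1e-10, atol=1e-13)
        y = sol.y[:, -1]
        ix = net.index
        assert y[ix["AB"]] == pytest.approx(ref["AB"], rel=1e-3)
        # [A][B]/[AB] == Kd within 0.1%
        assert y[ix["A"]] * y[ix["B"]] / y[ix["AB"]] == pytest.approx(
            ref["kd"], rel=1e-3)

    def test_michaelis_menten_initial_velocity_limit(self):
        net, ref = generate_fixture("enzymatic_mm_limit", seed=11)
        # integrate briefly past the complex-formation transient
        sol = solve_ivp(net.rhs, (0, 2.0), net.initial_state(),
                        method="LSODA", jac=net.jacobian,
                        rtol=1e-10, atol=1e-13, t_eval=[1.0, 2.0])
        p = sol.y[net.index["P"], :]
        v = (p[1] - p[0]) / 1.0
        assert v == pytest.approx(ref["v0"], rel=0.02)

    def test_nonnegativity_along_trajectory(self):
        net, _ = generate_fixture("random_small_network", seed=2)
        sol = solve_ivp(net.rhs, (0, 100.0), net.initial_state(),
                        method="LSODA", jac=net.jacobian,
                        rtol=1e-8, atol=1e-12)
        assert sol.y.min() >= -10 * 1e-12

    def test_conservation_drift_along_trajectory(self):
        net, _ = generate_fixture("random_small_network", seed=4)
        laws = conserved_moieties(net)
        y0 = net.initial_state()
        sol = solve_ivp(net.rhs, (0, 50.0), y0, method="LSODA",
                        jac=net.jacobian, rtol=1e-10, atol=1e-13)
        for law in laws:
            v0 = law_value(net, law, y0)
            vT = law_value(net, law, sol.y[:, -1])
            assert vT == pytest.approx(v0, rel=1e-6, abs=1e-9)


class TestValidation:
    def test_binding_species_must_be_distinct(self):
        with pytest.raises(NetworkError):
            BindingReaction("A", "A", "AA", kf=1.0, kb=0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(NetworkError):
            BindingReaction("A", "B", "AB", kf=-1.0, kb=0.0)
        with pytest.raises(NetworkError):
            EnzymaticReaction("E", "S", "ES", "P", kf=1.0, kb=1.0, kcat=0.0)

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(NetworkError):
            Species("A", -0.1)

    def test_duplicate_species_rejected(self):
        with pytest.raises(NetworkError):
            ReactionNetwork([Species("A", 1.0), Species("A", 2.0)], [])


class TestConversionProperties:
    """Property-based checks of the rate-constant conversion contracts."""

    def test_kd_tau_contract_holds_for_any_positive_inputs(self):
        from hypothesis import given, settings, strategies as st

        @given(kd=st.floats(1e-6, 1e4), tau=st.floats(1e-6, 1e4))
        @settings(max_examples=200, deadline=None, derandomize=True)
        def check(kd, tau):
            kf, kb = rate_constants_from_kd_tau(kd, tau)
            assert kb / kf == pytest.approx(kd, rel=1e-12)
        check()

    def test_km_kcat_contract_holds_for_any_positive_inputs(self):
        from hypothesis import given, settings, strategies as st

        @given(km=st.floats(1e-6, 1e4), kcat=st.floats(1e-6, 1e4))
        @settings(max_examples=200, deadline=None, derandomize=True)
        def check(km, kcat):
            kf, kb, kc = rate_constants_from_km_kcat(km, kcat)
            assert (kb + kc) / kf == pytest.approx(km, rel=1e-12)
            assert kb == 4.0 * kc
        check()
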