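"""Steady-state machinery: Newton, stability, subsystem extraction."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spinesim.io import generate_fixture
from spinesim.steady_state import (
    extract_subsystem,
    find_steady_states,
    pka_pp2a_thr75_subsystem,
)
from spinesim.reaction_core import ReactionNetwork, Species, BindingReaction


class TestToyNetworks:
    def test_binding_toy_unique_stable_state(self):
        net, ref = generate_fixture("binding_equilibrium", seed=9)
        sub = extract_subsystem(net, retained=None, clamps={})
        states = find_steady_states(sub)
        assert len(states) == 1
        st = states[0]
        assert st.stability == "stable"
        assert st.residual < 1e-10
        assert st.y[net.index["AB"]] == pytest.approx(ref["AB"], rel=1e-6)

    def test_bistable_toy_two_stable_states(self):
        net, ref = generate_fixture("bistable_toy", seed=0)
        sub = extract_subsystem(net, retained=None, clamps={})
        ix = net.index
        lo = net.initial_state()
        hi = net.initial_state()
        hi[ix["Ep"]] = ref["high_start"]["Ep"]
        hi[ix["E"]] = ref["high_start"]["E"]
        states = find_steady_states(sub, seeds=[lo, hi])
        stable = [s for s in states if s.stability == "stable"]
        assert len(stable) >= 2
        eps = sorted(s.y[ix["Ep"]] for s in stable)
        assert eps[-1] > 5 * max(eps[0], 1e-3)

    def test_residuals_below_tolerance(self):
        net, _ = generate_fixture("bistable_toy", seed=0)
        sub = extract_subsystem(net, retained=None, clamps={})
        for st in find_steady_states(sub):
            assert st.residual < 1e-10


class TestStabilityLabels:
    def test_labels_verified_by_perturbation_integration(self):
        """Stable states attract a 1% perturbation; unstable ones repel."""
        net, ref = generate_fixture("bistable_toy", seed=0)
        sub = extract_subsystem(net, retained=None, clamps={})
        ix = net.index
        hi = net.initial_state()
        hi[ix["Ep"]] = ref["high_start"]["Ep"]; hi[ix["E"]] = ref["high_start"]["E"]
        states = find_steady_states(sub, seeds=[net.initial_state(), hi])
        rng = np.random.default_rng(0)
        S = net.stoichiometric_matrix
        checked = 0
        for st in states:
            # perturb within the stoichiometric subspace so conservation
            # totals (which define the steady-state family) are untouched
            dy = S @ rng.normal(size=S.shape[1])
            dy *= 1e-3 / max(np.max(np.abs(dy)), 1e-12)
            while (st.y + dy < 0).any():
                dy *= 0.5
            d0 = np.max(np.abs(dy))
            sol = solve_ivp(net.rhs, (0, 3000.0), st.y + dy,
                            method="LSODA", jac=net.jacobian,
                            rtol=1e-10, atol=1e-14)
            dist = np.max(np.abs(sol.y[:, -1] - st.y))
            if st.stability == "stable":
                assert dist < 0.5 * d0      # perturbation decays
            else:
                assert dist > 5.0 * d0      # trajectory departs
            checked += 1
        assert checked >= 2

    def test_conservation_zero_modes_do_not_misclassify(self):
        # a pure binding equilibrium has conservation laws (zero modes of
        # the raw Jacobian) but must still classify as stable
        net, _ = generate_fixture("binding_equilibrium", seed=1)
        sub = extract_subsystem(net, retained=None, clamps={})
        st = find_steady_states(sub)[0]
        assert st.stability == "stable"
        assert np.max(st.eigenvalues.real) < -1e-8


class TestSubsystemExtraction:
    def test_retaining_everything_is_identity(self, network):
        all_names = [s.name for s in network.species]
        sub = extract_subsystem(network, retained=all_names, clamps={})
        assert len(sub.network.reactions) == len(network.reactions)

    def test_loop_subsystem_contains_the_three_loop_arms(self, network):
        sub = pka_pp2a_thr75_subsystem(network, camp=0.8, cdk5=0.5)
        labels = {r.label for r in sub.network.reactions}
        assert "PKAc_phos_PP2A" in labels            # PKA activates PP2A
        assert "PP2Ap_T75_D32_75" in labels          # PP2A dephosphorylates Thr75
        assert "T75_inhibits_PKA_D32_75" in labels   # pThr75 sequesters PKA

    def test_loop_subsystem_conserves_its_darpp32(self, network):
        sub = pka_pp2a_thr75_subsystem(network, camp=0.8, cdk5=0.5)
        from spinesim.reaction_core import conserved_moieties
        laws = conserved_moieties(sub.network)
        d32 = set(sub.network.species_by_moiety("D32"))
        assert any(set(law) <= d32 for law in laws)

    def test_orphan_retained_species_warns(self, network):
        with pytest.warns(UserWarning, match="without reactions"):
            extract_subsystem(network, retained=["PKA", "CaM"], clamps={})


class TestMonostableSweep:
    def test_monostable_toy_sweep_branches_identical(self):
        from spinesim.steady_state import hysteresis_sweep
        net, _ = generate_fixture("binding_equilibrium", seed=6)

        def factory(kb_scale):
            reactions = [BindingReaction(r.a, r.b, r.ab, kf=r.kf,
                                         kb=r.kb * kb_scale)
                         for r in net.reactions]
            return extract_subsystem(net.copy_with(reactions=reactions),
                                     retained=None, clamps={})

        vals = np.linspace(0.5, 2.0, 5)
        res = hysteresis_sweep(factory, vals, "kb_scale",
                               net.initial_state(), settle_time=100.0,
                               readout="AB")
        assert np.allclose(res["up"], res["down"], rtol=1e-5)
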