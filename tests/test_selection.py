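import numpy as np
import pytest

from evolvex.basis import FluxBasis
from evolvex.fixtures import brute_force_b_min, fca_oracle, toy_network
from evolvex.lp import FluxState, minimal_uptake_state
from evolvex.model import Environment, EvolveXConfig, StoichiometricModel
from evolvex.selection import (BigMError, ReferenceInfeasibleError,
                               min_stronger_subset, per_flux_coupling,
                               reference_couplings, relative_response,
                               response_to_selection)


@pytest.fixture(scope="module")
def evolved_b(toy1, env_b, config):
    return minimal_uptake_state(toy1, env_b, config)


@pytest.fixture(scope="module")
def evolved_a(toy1, env_a, config):
    return minimal_uptake_state(toy1, env_a, config)


class TestPerFluxCoupling:
    @pytest.mark.parametrize("rxn,direction,expected", [
        ("EX_P", "up", 10.0),   # growth on B forces product secretion
        ("R4", "up", 0.0),      # R4 can stay silent
        ("R3", "down", 10.0),   # growth fixes the biomass branch
    ])
    def test_env_b(self, toy1, env_b, config, evolved_b, rxn, direction, expected):
        c = per_flux_coupling(toy1, env_b, evolved_b, rxn, direction, config)
        assert c == pytest.approx(expected, abs=1e-6)

    def test_trait_uncoupled_on_a(self, toy1, env_a, config, evolved_a):
        c = per_flux_coupling(toy1, env_a, evolved_a, "EX_P", "up", config)
        assert c == pytest.approx(0.0, abs=1e-6)

    def test_classification_matches_fca_oracle(self, toy1, env_a, env_b, config):
        for env in (env_a, env_b):
            oracle = fca_oracle(toy1, env, config)
            evolved = minimal_uptake_state(toy1, env, config)
            for rxn in toy1.reaction_ids:
                c = per_flux_coupling(toy1, env, evolved, rxn, "up", config)
                assert (c > config.coupling_tol) == oracle[rxn], rxn


class TestResponseToSelection:
    def test_env_b_worst_case_total(self, toy1, env_b, config, basis_a, evolved_b):
        resp = response_to_selection(toy1, env_b, basis_a, evolved_b, config)
        assert resp.per_flux == pytest.approx(
            {"EX_P": 10.0, "R4": 0.0, "R3": 10.0}, abs=1e-6)
        assert resp.s_min == pytest.approx(0.0, abs=1e-6)
        assert resp.tacking == frozenset({"EX_P", "R3"})

    def test_env_a_negative_total(self, toy1, env_a, config, basis_a, evolved_a):
        resp = response_to_selection(toy1, env_a, basis_a, evolved_a, config)
        assert resp.s_min == pytest.approx(-10.0, abs=1e-6)
        assert resp.tacking == frozenset({"R3"})

    def test_empty_basis(self, toy1, env_b, config, evolved_b):
        empty = FluxBasis(frozenset(), frozenset(), "EX_P", 0.5,
                          FluxState({}, None, "optimal"))
        resp = response_to_selection(toy1, env_b, empty, evolved_b, config)
        assert resp.s_min == 0.0 and resp.tacking == frozenset()

    def test_linearization_exact(self, toy1, env_a, env_b, config, basis_a):
        for env in (env_a, env_b):
            evolved = minimal_uptake_state(toy1, env, config)
            resp = response_to_selection(toy1, env, basis_a, evolved, config)
            assert resp.linearization_gap <= 1e-6

    def test_s_min_invariant_to_duplicating_non_basis_reaction(
            self, toy1, env_b, config, basis_a, evolved_b):
        S = np.hstack([toy1.S, toy1.S[:, [toy1.index("R1")]]])
        m2 = StoichiometricModel(toy1.metabolite_ids,
                                 toy1.reaction_ids + ["R1b"], S,
                                 np.append(toy1.v_lb, 0.0),
                                 np.append(toy1.v_ub, 1000.0), "GROWTH")
        ev2 = minimal_uptake_state(m2, env_b, config)
        resp = response_to_selection(m2, env_b, basis_a, ev2, config)
        base = response_to_selection(toy1, env_b, basis_a, evolved_b, config)
        assert resp.s_min == pytest.approx(base.s_min, abs=1e-6)

    def test_series_network_sum_of_independent_minima(self, config):
        # single path: every member's coupling is forced, s_min = sum
        m = toy_network("SERIES")
        env = Environment(frozenset({"EX_S"}), label="S")
        basis = FluxBasis(frozenset({"R1", "R2"}), frozenset(), "GROWTH", 1.0,
                          FluxState({}, None, "optimal"))
        evolved = minimal_uptake_state(m, env, config)
        resp = response_to_selection(m, env, basis, evolved, config)
        expected = sum(
            per_flux_coupling(m, env, evolved, r, "up", config)
            for r in ("R1", "R2"))
        assert resp.s_min == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(20.0, abs=1e-6)

    def test_big_m_guard(self, toy1, env_b, config, basis_a, evolved_b):
        cfg = EvolveXConfig(big_M=20_000.0)
        object.__setattr__(cfg, "big_M", 100.0)  # bypass ctor check
        with pytest.raises(BigMError):
            response_to_selection(toy1, env_b, basis_a, evolved_b, cfg)


class TestRelativeResponse:
    def test_componentwise_division(self):
        fs = FluxState({"a": 10.0, "b": 0.0, "c": 5.0}, None, "optimal")
        assert relative_response(fs, 10.0) == {"a": 1.0, "b": 0.0, "c": 0.5}

    def test_zero_growth_errors(self):
        with pytest.raises(ValueError, match="zero growth"):
            relative_response(FluxState({}, None, "optimal"), 0.0)


class TestReferenceCouplings:
    def test_reference_on_a(self, toy1, env_a, config, basis_a):
        ref = reference_couplings(toy1, env_a, basis_a, config)
        assert ref == pytest.approx({"EX_P": 0.0, "R4": 0.0, "R3": 10.0},
                                    abs=1e-6)

    def test_self_reference_equals_per_flux(self, toy1, env_b, config,
                                            basis_a, evolved_b):
        ref = reference_couplings(toy1, env_b, basis_a, config)
        resp = response_to_selection(toy1, env_b, basis_a, evolved_b, config)
        assert ref == pytest.approx(resp.per_flux, abs=1e-6)

    def test_infeasible_reference_raises(self, toy1, config, basis_a):
        env = Environment(frozenset({"EX_P"}), label="P")
        with pytest.raises(ReferenceInfeasibleError, match="infeasible"):
            reference_couplings(toy1, env, basis_a, config)


class TestMinStrongerSubset:
    def test_env_b_vs_reference_a(self, toy1, env_a, env_b, config,
                                  basis_a, evolved_b):
        ref = reference_couplings(toy1, env_a, basis_a, config)
        resp = response_to_selection(toy1, env_b, basis_a, evolved_b, config)
        cov = min_stronger_subset(toy1, env_b, basis_a, evolved_b,
                                  resp.s_min, ref, config)
        assert cov.b_min == 1
        assert cov.stronger_flags["EX_P"]

    def test_large_gamma_zero_coverage(self, toy1, env_a, env_b, basis_a,
                                       evolved_b):
        cfg = EvolveXConfig(alpha=0.5, delta=0.0, epsilon=1e-6, gamma=1e6,
                            exclude_from_basis=frozenset({"GROWTH"}))
        ref = {r: 1.0 for r in basis_a.members}  # any positive reference
        resp = response_to_selection(toy1, env_b, basis_a, evolved_b, cfg)
        cov = min_stronger_subset(toy1, env_b, basis_a, evolved_b,
                                  resp.s_min, ref, cfg)
        assert cov.b_min == 0

    def test_empty_basis_zero(self, toy1, env_b, config, evolved_b):
        empty = FluxBasis(frozenset(), frozenset(), "EX_P", 0.5,
                          FluxState({}, None, "optimal"))
        cov = min_stronger_subset(toy1, env_b, empty, evolved_b, 0.0, {},
                                  config)
        assert cov.b_min == 0

    def test_matches_brute_force(self, toy1, env_a, env_b, config, basis_a):
        ref = reference_couplings(toy1, env_a, basis_a, config)
        for env in (env_a, env_b):
            evolved = minimal_uptake_state(toy1, env, config)
            resp = response_to_selection(toy1, env, basis_a, evolved, config)
            cov = min_stronger_subset(toy1, env, basis_a, evolved,
                                      resp.s_min, ref, config)
            oracle = brute_force_b_min(toy1, env, basis_a.up_set,
                                       basis_a.down_set, resp.s_min, ref,
                                       config)
            assert cov.b_min == oracle

    def test_b_min_non_increasing_in_gamma(self, toy1, env_a, env_b,
                                           basis_a, evolved_b):
        ref = None
        values = []
        for gamma in (0.0, 0.5, 2.0, 10.0):
            cfg = EvolveXConfig(alpha=0.5, delta=0.0, epsilon=1e-6,
                                gamma=gamma,
                                exclude_from_basis=frozenset({"GROWTH"}))
            if ref is None:
                ref = reference_couplings(toy1, env_a, basis_a, cfg)
            resp = response_to_selection(toy1, env_b, basis_a, evolved_b, cfg)
            cov = min_stronger_subset(toy1, env_b, basis_a, evolved_b,
                                      resp.s_min, ref, cfg)
            values.append(cov.b_min)
        assert values == sorted(values, reverse=True)
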