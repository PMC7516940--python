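"""Regime-switching models: kernels, stationarity, closed forms, simulation."""

import numpy as np
import pytest

import rsdarma as rd
from rsdarma.exceptions import InvalidModelError, ReducibleChainError
from rsdarma.regime import (
    RsDarmaSpec,
    boundary_marginal_kappa,
    boundary_marginal_spec,
    boundary_marginal_stationary,
    per_state_bivariate,
    per_state_dependence_spec,
    per_state_stationary,
    rs_darp_transition_prob,
)


def random_spec(gen, n_states=4, K=2, variant="general"):
    rng = rd.CategoricalRange([f"s{i}" for i in range(n_states)])
    regime_of = gen.integers(0, K, n_states)
    regime_of[:K] = np.arange(K)  # every regime non-empty
    part = rd.RangePartition(rng, regime_of)
    phi = gen.uniform(0.1, 0.9, K)
    pe = np.clip(gen.dirichlet(np.ones(n_states), K), 0.02, None)
    pe = pe / pe.sum(axis=1, keepdims=True)
    if variant == "marginal_regimes":
        phi[:] = phi[0]
    if variant == "dependence_regimes":
        pe[:] = pe[0]
    return rd.RsDar1Spec(rng, part, variant, phi, pe)


class TestKernel:
    @pytest.mark.parametrize("variant",
                             ["general", "marginal_regimes", "dependence_regimes"])
    def test_columns_sum_to_one_and_invariance(self, variant):
        gen = np.random.default_rng(42)
        for _ in range(20):
            spec = random_spec(gen, variant=variant)
            tm = rd.rs_dar1_transition_matrix(spec)
            np.testing.assert_allclose(tm.P.sum(axis=0), 1.0, atol=1e-12)
            p = rd.stationary_distribution(tm)
            assert np.max(np.abs(tm.P @ p - p)) < 1e-10

    def test_single_regime_reduces_to_dar1(self, range4):
        part = rd.RangePartition.trivial(range4)
        pe = [0.4, 0.3, 0.2, 0.1]
        spec = rd.RsDar1Spec.marginal(range4, part, 0.35, [pe])
        tm = rd.rs_dar1_transition_matrix(spec)
        np.testing.assert_allclose(tm.P, rd.dar1_transition_matrix(0.35, pe).P)

    def test_dna_fit_reproduces_printed_kernel(self, dna_model):
        tm = rd.rs_dar1_transition_matrix(dna_model)
        assert tm.P[0, 0] == pytest.approx(0.291, abs=0.002)
        assert tm.P[0, 1] == pytest.approx(0.203, abs=0.002)
        assert tm.P[1, 1] == pytest.approx(0.392, abs=0.002)
        assert tm.P[0, 3] == pytest.approx(0.170, abs=0.002)

    def test_marginal_variant_identifiability_bound(self, range4):
        sing = rd.RangePartition.singletons(range4)
        with pytest.raises(InvalidModelError):
            rd.RsDar1Spec.marginal(range4, sing, 0.5, np.full((4, 4), 0.25))


class TestHigherOrderTransitions:
    def test_p1_agrees_with_kernel(self):
        gen = np.random.default_rng(3)
        spec = random_spec(gen)
        rs = spec.to_rs_darma()
        tm = rd.rs_dar1_transition_matrix(spec)
        for j in range(4):
            for i in range(4):
                assert rs_darp_transition_prob(rs, i, [j]) == pytest.approx(
                    tm.P[i, j], abs=1e-12)

    def test_sums_to_one_over_outcomes(self):
        rng = rd.CategoricalRange(("lo", "hi"))
        part = rd.RangePartition(rng, (0, 1))
        spec = RsDarmaSpec(rng, part, 2, 0,
                           [[0.3, 0.25, 0.45], [0.2, 0.4, 0.4]],
                           [[0.7, 0.3], [0.2, 0.8]])
        for past in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            total = sum(rs_darp_transition_prob(spec, i, past) for i in (0, 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_p2_matches_empirical_conditional_frequencies(self):
        rng = rd.CategoricalRange(("lo", "hi"))
        part = rd.RangePartition(rng, (0, 1))
        spec = RsDarmaSpec(rng, part, 2, 0,
                           [[0.3, 0.25, 0.45], [0.2, 0.4, 0.4]],
                           [[0.7, 0.3], [0.2, 0.8]])
        x = rd.simulate_rs_darma(spec, 1_000_000, seed=314)
        for j1 in (0, 1):
            for j2 in (0, 1):
                sel = (x[1:-1] == j1) & (x[:-2] == j2)
                emp = np.mean(x[2:][sel] == 1)
                model = rs_darp_transition_prob(spec, 1, [j1, j2])
                assert emp == pytest.approx(model, abs=0.005)

    def test_requires_pure_ar(self):
        rng = rd.CategoricalRange(("lo", "hi"))
        part = rd.RangePartition(rng, (0, 1))
        spec = RsDarmaSpec(rng, part, 0, 1,
                           [[0.6, 0.4], [0.5, 0.5]], [[0.7, 0.3], [0.2, 0.8]])
        with pytest.raises(InvalidModelError):
            rs_darp_transition_prob(spec, 0, [0])


class TestStationaryDistribution:
    def test_iid_columns_return_that_vector(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        P = np.tile(v[:, None], (1, 4))
        np.testing.assert_allclose(rd.stationary_distribution(P), v, atol=1e-12)

    def test_reducible_matrix_rejected(self):
        P = np.eye(3)
        with pytest.raises(ReducibleChainError):
            rd.stationary_distribution(P)
        P2 = np.array([[1.0, 0.5], [0.0, 0.5]])  # absorbing state
        with pytest.raises(ReducibleChainError):
            rd.stationary_distribution(P2)

    def test_model_bivariate_long_lag_approaches_independence(self, dna_model):
        tm = rd.rs_dar1_transition_matrix(dna_model)
        p = rd.stationary_distribution(tm)
        tab = rd.model_bivariate(tm, 50)
        np.testing.assert_allclose(tab.joint, np.outer(p, p), atol=1e-12)
        assert rd.kappa(tab) == pytest.approx(0.0, abs=1e-10)


class TestBoundaryTwoRegimeClosedForms:
    """The 4-state cross-feeding construction with analytic kappa."""

    def test_stationary_vector(self):
        p = boundary_marginal_stationary(0.3, 0.8)
        np.testing.assert_allclose(p, [0.4, 0.1, 0.15, 0.35])
        spec = boundary_marginal_spec(0.2, 0.3, 0.8)
        tm = rd.rs_dar1_transition_matrix(spec)
        np.testing.assert_allclose(rd.stationary_distribution(tm), p, atol=1e-12)

    def test_full_persistence_limit(self):
        k1, kord = boundary_marginal_kappa(1.0 - 1e-12, 0.4, 0.6)
        assert k1 == pytest.approx(1.0)
        assert kord == pytest.approx(1.0)

    def test_kappa_root_at_quarter_phi(self):
        # with p1 = p2 = 0.5: kappa(1) = 1 - 2(1-phi)/1.5 = 0 at phi = 0.25
        k1, _ = boundary_marginal_kappa(0.25, 0.5, 0.5)
        assert k1 == pytest.approx(0.0, abs=1e-12)

    def test_negative_dependence_for_small_phi(self):
        spec = boundary_marginal_spec(0.05, 0.5, 0.5)
        tab = rd.model_bivariate(rd.rs_dar1_transition_matrix(spec), 1)
        assert rd.kappa(tab) < 0
        assert rd.kappa_ord(tab) < 0

    def test_closed_forms_match_matrix_route(self):
        gen = np.random.default_rng(7)
        for _ in range(50):
            phi, p1, p2 = gen.uniform(0.05, 0.95, 3)
            tab = rd.model_bivariate(
                rd.rs_dar1_transition_matrix(boundary_marginal_spec(phi, p1, p2)), 1)
            k1, kord = boundary_marginal_kappa(phi, p1, p2)
            assert rd.kappa(tab) == pytest.approx(k1, abs=1e-10)
            assert rd.kappa_ord(tab) == pytest.approx(kord, abs=1e-10)


class TestPerStateDependenceClosedForms:
    def test_equal_phis_reduce_to_shared_marginal(self):
        pe = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(per_state_stationary([0.4] * 3, pe), pe, atol=1e-14)

    def test_hand_evaluated_two_state_case(self):
        # phi = (0.5, 0.9), pe = (0.5, 0.5): weights (1, 5)/sum -> (1/6, 5/6)
        np.testing.assert_allclose(
            per_state_stationary([0.5, 0.9], [0.5, 0.5]), [1 / 6, 5 / 6], atol=1e-14)

    def test_closed_forms_match_matrix_route(self):
        gen = np.random.default_rng(12)
        for _ in range(50):
            n = int(gen.integers(3, 6))
            phi = gen.uniform(0.05, 0.95, n)
            pe = np.clip(gen.dirichlet(np.ones(n)), 0.02, None)
            pe = pe / pe.sum()
            spec = per_state_dependence_spec(phi, pe)
            tm = rd.rs_dar1_transition_matrix(spec)
            np.testing.assert_allclose(
                rd.stationary_distribution(tm), per_state_stationary(phi, pe),
                atol=1e-10)
            np.testing.assert_allclose(
                rd.model_bivariate(tm, 1).joint, per_state_bivariate(phi, pe).joint,
                atol=1e-10)


class TestSimulation:
    def test_k1_paths_bitwise_equal_to_darma(self, range4):
        part = rd.RangePartition.trivial(range4)
        pe = [0.4, 0.3, 0.2, 0.1]
        rs = rd.RsDar1Spec.marginal(range4, part, 0.6, [pe])
        plain = rd.dar1(range4, 0.6, pe)
        for seed in (0, 7, 123):
            assert np.array_equal(rd.simulate_rs_darma(rs, 2000, seed=seed),
                                  rd.simulate_darma(plain, 2000, seed=seed))

    def test_long_run_marginal_matches_stationary(self, cloud2_model):
        tm = rd.rs_dar1_transition_matrix(cloud2_model)
        p = rd.stationary_distribution(tm)
        x = rd.simulate_rs_darma(cloud2_model, 400_000, seed=55)
        np.testing.assert_allclose(rd.sample_marginal(x, 5), p, atol=0.01)

    def test_simulated_ordinal_kappa_matches_model(self, cloud2_model):
        tab = rd.model_bivariate(rd.rs_dar1_transition_matrix(cloud2_model), 1)
        target = rd.kappa_ord(tab)
        x = rd.simulate_rs_darma(cloud2_model, 400_000, seed=56)
        khat = rd.kappa_ord(rd.sample_bivariate(x, 1, 5))
        assert khat == pytest.approx(target, abs=0.01)

    def test_delayed_regime_selection_changes_law(self, two_regime_truth):
        d2 = rd.RsDar1Spec.marginal(
            two_regime_truth.range, two_regime_truth.partition,
            float(two_regime_truth.phi_by_regime[0]),
            two_regime_truth.p_eps_by_regime, delay=2)
        a = rd.simulate_rs_darma(two_regime_truth, 2000, seed=3)
        b = rd.simulate_rs_darma(d2, 2000, seed=3)
        assert not np.array_equal(a, b)
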