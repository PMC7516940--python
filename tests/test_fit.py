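"""Conditional ML estimation, information criteria, selection, forecasting."""

import numpy as np
import pytest

import rsdarma as rd
from rsdarma.exceptions import InvalidModelError, ZeroLikelihoodError
from rsdarma.fit import ModelFamily, information_criteria


class TestLogLikelihood:
    def test_hand_evaluated_dar1(self):
        # series (a, a, b), phi = 0.5, p_eps = (1/2, 1/2):
        # p(a|a) = 0.5*0.5 + 0.5 = 0.75, p(b|a) = 0.25
        rng = rd.CategoricalRange(("a", "b"))
        spec = rd.dar1(rng, 0.5, [0.5, 0.5])
        ll = rd.log_likelihood(spec, np.array([0, 0, 1]))
        assert ll == pytest.approx(np.log(0.75) + np.log(0.25), abs=1e-12)

    def test_zero_phi_is_conditioned_iid_product(self):
        rng = rd.CategoricalRange(("a", "b", "c"))
        pe = np.array([0.5, 0.3, 0.2])
        spec = rd.dar1(rng, 1e-14, pe)
        x = np.array([2, 0, 1, 1, 2, 0])
        expected = np.sum(np.log(pe[x[1:]]))
        assert rd.log_likelihood(spec, x) == pytest.approx(expected, abs=1e-9)

    def test_zero_probability_transition_is_named(self, cloud2_model):
        # the fitted cloudiness model forbids SKC after a regime-2 state
        x = np.array([3, 0, 0])  # BKN -> SKC has probability 0
        with pytest.raises(ZeroLikelihoodError) as err:
            rd.log_likelihood(cloud2_model, x)
        assert err.value.prev == "BKN" and err.value.cur == "SKC"
        assert err.value.t == 2


class TestInformationCriteria:
    def test_zero_case(self):
        assert information_criteria(0.0, 0, 100) == (0.0, 0.0)

    def test_ln_t_arithmetic(self):
        aic, bic = information_criteria(-100.0, 5, int(round(np.exp(2))))
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(200.0 + 5 * np.log(round(np.exp(2))))

    def test_penalty_monotone_in_n_model(self):
        a1, b1 = information_criteria(-50.0, 3, 500)
        a2, b2 = information_criteria(-50.0, 7, 500)
        assert a2 > a1 and b2 > b1

    def test_fit_result_identities(self, two_regime_truth, range4):
        x = rd.simulate_rs_darma(two_regime_truth, 3000, seed=21)
        fit = rd.fit_ml(ModelFamily("rs_dar1_marginal", two_regime_truth.partition),
                        x, range4, restarts=3, seed=0)
        assert fit.loglik_max == pytest.approx(
            fit.T / (fit.T - 1) * fit.loglik_conditional, abs=1e-9)
        assert fit.aic == pytest.approx(-2 * fit.loglik_max + 2 * fit.n_model)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik_max + fit.n_model * np.log(fit.T))


class TestFitMl:
    def test_parameter_recovery_two_regime_marginal(self, two_regime_truth, range4):
        x = rd.simulate_rs_darma(two_regime_truth, 5000, seed=11)
        fit = rd.fit_ml(ModelFamily("rs_dar1_marginal", two_regime_truth.partition),
                        x, range4, restarts=5, seed=1)
        assert fit.converged
        assert fit.spec.phi_by_regime[0] == pytest.approx(0.5, abs=0.05)
        np.testing.assert_allclose(fit.spec.p_eps_by_regime,
                                   two_regime_truth.p_eps_by_regime, atol=0.05)

    def test_optimum_at_least_truth(self, two_regime_truth, range4):
        x = rd.simulate_rs_darma(two_regime_truth, 4000, seed=13)
        fit = rd.fit_ml(ModelFamily("rs_dar1_marginal", two_regime_truth.partition),
                        x, range4, restarts=3, seed=5)
        assert fit.loglik_conditional >= rd.log_likelihood(two_regime_truth, x) - 1e-6

    def test_trivial_partition_equals_direct_dar1(self, range4):
        spec = rd.dar1(range4, 0.4, [0.4, 0.3, 0.2, 0.1])
        x = rd.simulate_darma(spec, 3000, seed=2)
        f_dar = rd.fit_ml(ModelFamily("dar1"), x, range4, restarts=4, seed=3)
        f_rs = rd.fit_ml(
            ModelFamily("rs_dar1_marginal", rd.RangePartition.trivial(range4)),
            x, range4, restarts=4, seed=3)
        assert f_dar.loglik_max == pytest.approx(f_rs.loglik_max, abs=1e-6)
        assert f_dar.n_model == f_rs.n_model == 4

    def test_full_mc_closed_form_is_the_count_mle(self, range4):
        gen = np.random.default_rng(9)
        x = gen.integers(0, 4, 2000)
        fit = rd.fit_ml(ModelFamily("full_mc"), x, range4)
        counts = np.zeros((4, 4))
        np.add.at(counts, (x[1:], x[:-1]), 1.0)
        P_hat = counts / counts.sum(axis=0, keepdims=True)
        np.testing.assert_allclose(fit.spec.P, P_hat, atol=1e-12)
        # no parametric model can beat the count MLE's conditional likelihood
        dar = rd.fit_ml(ModelFamily("dar1"), x, range4, restarts=3, seed=0)
        assert fit.loglik_conditional >= dar.loglik_conditional - 1e-8

    def test_rmse_of_phi_shrinks_with_t(self, two_regime_truth, range4):
        fam = ModelFamily("rs_dar1_marginal", two_regime_truth.partition)
        rmse = []
        for T in (500, 2000, 8000):
            errs = []
            for rep in range(8):
                x = rd.simulate_rs_darma(two_regime_truth, T, seed=1000 + 17 * rep + T)
                fit = rd.fit_ml(fam, x, range4, restarts=3, seed=rep)
                errs.append(fit.spec.phi_by_regime[0] - 0.5)
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmse[0] > rmse[2], f"RMSE did not shrink: {rmse}"


class TestSelectModel:
    def test_single_candidate_wins(self, range4):
        x = rd.simulate_darma(rd.dar1(range4, 0.3, [0.25] * 4), 1500, seed=4)
        report = rd.select_model(x, [ModelFamily("dar1")], range4, restarts=2, seed=0)
        assert report.winner == 0
        assert report.best().family.kind == "dar1"

    def test_iid_data_prefers_parsimony(self, range4):
        gen = np.random.default_rng(31)
        wins = 0
        part = rd.RangePartition.from_blocks(range4, [("s0", "s1"), ("s2", "s3")])
        for rep in range(10):
            x = gen.integers(0, 4, 2000)
            report = rd.select_model(
                x, [ModelFamily("dar1"), ModelFamily("rs_dar1_marginal", part),
                    ModelFamily("full_mc")], range4,
                criterion="bic", restarts=2, seed=rep)
            if report.best().family.kind == "dar1":
                wins += 1
        assert wins >= 8

    def test_failed_candidates_reported_not_dropped(self, range4, two_regime_truth):
        x = rd.simulate_rs_darma(two_regime_truth, 800, seed=6)
        bad = ModelFamily("rs_dar1_marginal", rd.RangePartition.singletons(range4))
        report = rd.select_model(x, [bad, ModelFamily("dar1")], range4,
                                 restarts=2, seed=0)
        fam, fit, err = report.candidates[0]
        assert fit is None and "K <= m" in err
        assert report.winner == 1

    def test_invalid_criterion_rejected(self, range4):
        with pytest.raises(InvalidModelError):
            rd.select_model(np.zeros(10, dtype=int), [ModelFamily("dar1")],
                            range4, criterion="dic")


class TestRegularity:
    def test_interior_dar1_passes(self, range4):
        rep = rd.check_regularity(rd.dar1(range4, 0.4, [0.25] * 4))
        assert rep.ok and rep.irreducible and rep.full_rank

    def test_saturated_marginal_model_is_rank_deficient(self, range4):
        sing = rd.RangePartition.singletons(range4)
        spec = rd.RsDar1Spec(range4, sing, "general", [0.3] * 4,
                             np.full((4, 4), 0.25))
        rep = rd.check_regularity(spec)
        assert not rep.full_rank
        assert rep.jacobian_rank == 12  # m(m+1) free transition probabilities

    def test_boundary_innovation_flagged(self, cloud2_model):
        rep = rd.check_regularity(cloud2_model)
        assert any("SKC" in name for name in rep.boundary_params)


class TestForecasting:
    def test_chapman_kolmogorov(self, cloud2_model):
        tm = rd.rs_dar1_transition_matrix(cloud2_model)
        two_step = rd.forecast_distribution(cloud2_model, "FEW", 2)
        np.testing.assert_allclose(two_step, tm.P @ tm.P[:, 1], atol=1e-12)

    def test_long_horizon_reaches_stationarity(self, cloud2_model):
        tm = rd.rs_dar1_transition_matrix(cloud2_model)
        p = rd.stationary_distribution(tm)
        np.testing.assert_allclose(
            rd.forecast_distribution(cloud2_model, "OVC", 200), p, atol=1e-10)

    def test_point_forecast_is_current_state(self, cloud2_model):
        for s in ("SKC", "FEW", "SCT", "BKN", "OVC"):
            dist = rd.forecast_distribution(cloud2_model, s, 1)
            assert cloud2_model.range.states[int(np.argmax(dist))] == s


class TestPredictionSets:
    def test_printed_cloudiness_rules(self, cloud2_model):
        assert set(rd.prediction_set(cloud2_model, "SKC", 0.95)) == {
            "SKC", "FEW", "SCT", "BKN"}
        for s in ("FEW", "SCT"):
            assert set(rd.prediction_set(cloud2_model, s, 0.95)) == {
                "FEW", "SCT", "BKN"}
        for s in ("BKN", "OVC"):
            assert set(rd.prediction_set(cloud2_model, s, 0.95)) == {
                "SCT", "BKN", "OVC"}

    def test_mass_reaches_level_and_is_minimal(self, cloud3_model):
        tm = rd.rs_dar1_transition_matrix(cloud3_model)
        for j, s in enumerate(cloud3_model.range.states):
            for level in (0.5, 0.8, 0.95):
                ps = rd.prediction_set(cloud3_model, s, level)
                idx = [cloud3_model.range.index(lbl) for lbl in ps]
                mass = tm.P[idx, j].sum()
                assert mass >= level - 1e-12
                smallest = tm.P[idx, j].min()
                assert mass - smallest < level, "a member could be removed"

    def test_level_near_one_returns_support(self, dna_model):
        ps = rd.prediction_set(dna_model, "a", 0.999999)
        assert set(ps) == {"a", "c", "g", "t"}

    def test_contiguous_mode_returns_interval(self, cloud2_model):
        ps = rd.prediction_set(cloud2_model, "SKC", 0.95, contiguous=True)
        idx = [cloud2_model.range.index(s) for s in ps]
        assert idx == list(range(min(idx), max(idx) + 1))
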