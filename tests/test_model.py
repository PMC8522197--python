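import numpy as np
import pandas as pd
import pytest

from lncpair import (
    ClinicalTable,
    PairFeatureMatrix,
    PipelineError,
    aic_optimal_cutoff,
    compute_risk_scores,
    forward_model_scan,
    repeated_lasso_selection,
    univariate_cox_screen,
)
from lncpair._cox import breslow_loglik, fit_binary_cox
from lncpair.model import RiskModel
from oracles import aic_cutoff_oracle, breslow_beta_grid, breslow_loglik_slow


def _pm(rows, ids=None, samples=None):
    rows = np.asarray(rows)
    ids = ids or [f"A{i}|B{i}" for i in range(rows.shape[0])]
    samples = samples or [f"S{i}" for i in range(rows.shape[1])]
    return PairFeatureMatrix(pd.DataFrame(rows, index=ids, columns=samples))


def _clin(time, event, samples=None):
    samples = samples or [f"S{i}" for i in range(len(time))]
    return ClinicalTable(pd.DataFrame({"time": time, "event": event},
                                      index=pd.Index(samples, name="sample_id")))


class TestBinaryCoxAgainstGridOracle:
    def test_toy_early_deaths_positive_beta(self):
        # indicator marks the three earliest of six uncensored deaths:
        # the partial likelihood is monotone in beta (perfect separation)
        x = [1, 1, 1, 0, 0, 0]
        time = [1, 2, 3, 4, 5, 6]
        event = [1] * 6
        fit = fit_binary_cox(np.array([x]), np.array(time), np.array(event))
        assert fit.beta[0] > 0
        assert fit.separated[0]

    def test_toy_interleaved_deaths_match_oracle(self):
        x = [1, 0, 1, 0, 1, 0]
        time = [1, 2, 3, 4, 5, 6]
        event = [1] * 6
        fit = fit_binary_cox(np.array([x]), np.array(time), np.array(event))
        oracle = breslow_beta_grid(x, time, event)
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", range(12))
    def test_random_small_datasets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        x = rng.integers(0, 2, n)
        while x.std() == 0:
            x = rng.integers(0, 2, n)
        time = rng.exponential(5, n)
        event = (rng.random(n) > 0.3).astype(int)
        if event.sum() < 2:
            event[:2] = 1
        fit = fit_binary_cox(x[None, :], time, event)
        if fit.separated[0]:
            return  # capped; oracle grid would run to its boundary too
        oracle = breslow_beta_grid(x, time, event)
        assert fit.beta[0] == pytest.approx(oracle, abs=1e-4)
        ll = breslow_loglik_slow(fit.beta[0], x, time, event)
        assert fit.loglik[0] == pytest.approx(ll, abs=1e-8)

    def test_vectorised_loglik_matches_general_helper(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, (4, 30)).astype(float)
        time = rng.exponential(5, 30)
        event = (rng.random(30) > 0.3).astype(int)
        fit = fit_binary_cox(X, time, event)
        for i in range(4):
            ll = breslow_loglik(np.array([fit.beta[i]]), X[i][:, None], time, event)
            assert fit.loglik[i] == pytest.approx(ll, abs=1e-8)

    def test_separation_flagged_not_crashed(self):
        # all x=1 subjects die before any x=0 subject is censored/dies
        x = np.array([1, 1, 1, 0, 0, 0])
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.array([1, 1, 1, 0, 0, 0])
        fit = fit_binary_cox(x[None, :], time, event)
        assert fit.separated[0]

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_binary_cox(np.ones((1, 6)), np.arange(1.0, 7.0), np.ones(6, dtype=int))


class TestUnivariateScreen:
    def test_constant_pair_named(self):
        pm = _pm(np.vstack([np.ones(20), np.random.default_rng(0).integers(0, 2, 20)]))
        clin = _clin(np.arange(1.0, 21.0), [1] * 20)
        with pytest.raises(PipelineError, match="A0|frequency"):
            univariate_cox_screen(pm, clin)

    def test_requires_ten_events(self):
        pm = _pm([[1, 0, 1, 0, 1, 0]])
        clin = _clin([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0])
        with pytest.raises(PipelineError, match="events"):
            univariate_cox_screen(pm, clin)

    def test_passed_iff_p_below_alpha(self):
        rng = np.random.default_rng(1)
        pm = _pm(rng.integers(0, 2, (20, 40)))
        clin = _clin(rng.exponential(5, 40), (rng.random(40) > 0.2).astype(int))
        res = univariate_cox_screen(pm, clin, alpha=0.1)
        assert ((res["p"] < 0.1) == res["passed"]).all()
        assert (res["hr"] > 0).all()


class TestRepeatedLasso:
    def _planted(self, seed=0, n=200, beta=1.5, n_noise=8):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, (1 + n_noise, n))
        eta = beta * x[0]
        time = rng.exponential(1.0 / (0.1 * np.exp(eta)))
        cens = rng.exponential(8.0, n)
        obs = np.minimum(time, cens)
        event = (time <= cens).astype(int)
        return _pm(x, ids=[f"P{i}|Q{i}" for i in range(1 + n_noise)]), _clin(obs, event)

    def test_deterministic_given_seed(self):
        pm, clin = self._planted()
        a = repeated_lasso_selection(pm, clin, n_cycles=8, count_threshold=2, seed=5)
        b = repeated_lasso_selection(pm, clin, n_cycles=8, count_threshold=2, seed=5)
        pd.testing.assert_series_equal(a.counts, b.counts)

    def test_planted_pair_dominates_counts(self):
        # strong effect (log HR 1.5, n = 200): selected in nearly every cycle
        pm, clin = self._planted()
        rep = repeated_lasso_selection(pm, clin, n_cycles=50, count_threshold=5, seed=1)
        assert rep.counts["P0|Q0"] >= 45
        assert rep.ranked_pairs()[0] == "P0|Q0"

    def test_threshold_monotonicity_and_empty_warning(self, caplog):
        pm, clin = self._planted()
        rep = repeated_lasso_selection(pm, clin, n_cycles=6, count_threshold=6, seed=2)
        assert rep.selected.sum() == 0  # count can never exceed n_cycles
        assert any("empty" in r.message for r in caplog.records)
        rep0 = repeated_lasso_selection(pm, clin, n_cycles=6, count_threshold=0, seed=2)
        assert set(rep0.counts[rep0.selected].index) == set(
            rep0.counts[rep0.counts > 0].index
        )


class TestForwardScan:
    def test_single_candidate_equals_univariate(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 60)
        eta = 1.2 * x
        time = rng.exponential(1.0 / (0.2 * np.exp(eta)))
        pm = _pm(x[None, :], ids=["A|B"])
        clin = _clin(time, [1] * 60)
        model = forward_model_scan(["A|B"], pm, clin, eval_time=np.median(time))
        assert model.chosen_size == 1
        uni = univariate_cox_screen(pm, clin)
        assert model.betas["A|B"] == pytest.approx(uni.loc["A|B", "beta"], abs=5e-2)
        assert all(0 <= a <= 1 for a in model.auc_trajectory)

    def test_noise_pair_adds_little_and_strong_pair_dominates(self):
        gains = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 250
            strong = rng.integers(0, 2, n)
            noise = rng.integers(0, 2, n)
            eta = 1.8 * strong
            time = rng.exponential(1.0 / (0.3 * np.exp(eta)))
            pm = _pm(np.vstack([strong, noise]), ids=["A|B", "C|D"])
            clin = _clin(time, [1] * n)
            model = forward_model_scan(["A|B", "C|D"], pm, clin,
                                       eval_time=float(np.median(time)))
            assert "A|B" in model.pairs  # the informative pair is always kept
            if model.chosen_size == 2:
                assert abs(model.betas["C|D"]) < abs(model.betas["A|B"])
            gains.append(model.auc_trajectory[1] - model.auc_trajectory[0])
        # a pure-noise pair buys at most a sliver of in-sample AUC
        assert np.mean(gains) < 0.03


class TestRiskScoresAndCutoff:
    def test_zero_betas_zero_scores(self):
        pm = _pm([[1, 0, 1]], ids=["A|B"])
        model = RiskModel(pairs=["A|B"], betas=pd.Series({"A|B": 0.0}),
                          auc_trajectory=[0.5], chosen_size=1, eval_time=1.0)
        assert (compute_risk_scores(model, pm)["risk_score"] == 0).all()

    def test_single_pair_scores_binary(self):
        pm = _pm([[1, 0, 1, 0]], ids=["A|B"])
        model = RiskModel(pairs=["A|B"], betas=pd.Series({"A|B": 0.7}),
                          auc_trajectory=[0.6], chosen_size=1, eval_time=1.0)
        assert set(compute_risk_scores(model, pm)["risk_score"]) == {0.0, 0.7}

    def test_missing_pair_named(self):
        pm = _pm([[1, 0, 1]], ids=["A|B"])
        model = RiskModel(pairs=["X|Y"], betas=pd.Series({"X|Y": 1.0}),
                          auc_trajectory=[0.6], chosen_size=1, eval_time=1.0)
        with pytest.raises(PipelineError, match="X|Y"):
            compute_risk_scores(model, pm)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        ind = rng.integers(0, 2, (2, 10))
        pm = _pm(ind, ids=["A|B", "C|D"])
        model = RiskModel(pairs=["A|B", "C|D"],
                          betas=pd.Series({"A|B": 0.5, "C|D": -0.3}),
                          auc_trajectory=[0.6], chosen_size=2, eval_time=1.0)
        base = compute_risk_scores(model, pm)["risk_score"]
        perm = list(reversed(list(pm.sample_ids)))
        permuted = compute_risk_scores(
            model, PairFeatureMatrix(pm.indicators[perm]))["risk_score"]
        np.testing.assert_allclose(base.loc[perm].to_numpy(), permuted.to_numpy())

    def test_two_cluster_cutoff_between_clusters(self):
        scores = pd.Series([1, 1, 1, 10, 10, 10.0],
                           index=[f"S{i}" for i in range(6)])
        clin = _clin([5, 6, 7, 1, 2, 3.0], [1] * 6)
        cut = aic_optimal_cutoff(scores, clin, min_group_frac=0.1)
        assert 1 < cut < 10

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 31))
        scores = pd.Series(rng.normal(0, 1, n).round(2),
                           index=[f"S{i}" for i in range(n)])
        if scores.nunique() < 2:
            return
        time = rng.exponential(5, n)
        event = (rng.random(n) > 0.3).astype(int)
        clin = _clin(time, event)
        cut = aic_optimal_cutoff(scores, clin)
        oracle = aic_cutoff_oracle(scores.to_numpy(), time, event)
        assert cut == pytest.approx(oracle, abs=1e-9)

    def test_null_scores_contract(self):
        rng = np.random.default_rng(7)
        n = 50
        scores = pd.Series(rng.normal(0, 1, n), index=[f"S{i}" for i in range(n)])
        clin = _clin(rng.exponential(5, n), (rng.random(n) > 0.3).astype(int))
        cut = aic_optimal_cutoff(scores, clin)
        assert (scores > cut).sum() >= 5 and (scores <= cut).sum() >= 5

    def test_identical_scores_rejected(self):
        scores = pd.Series(np.ones(20), index=[f"S{i}" for i in range(20)])
        clin = _clin(np.arange(1.0, 21.0), [1] * 20)
        with pytest.raises(PipelineError):
            aic_optimal_cutoff(scores, clin)
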