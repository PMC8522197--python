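import numpy as np
import pandas as pd
import pytest

from lncpair import ClinicalTable, PipelineError
from lncpair.evaluate import (
    clinical_association_tests,
    clinical_cox_models,
    ipcw_auc,
    kaplan_meier_logrank,
    time_dependent_roc,
)
from oracles import breslow_beta_grid, fisher_2x2_oracle, logrank_chi2_oracle, mann_whitney_auc


def _clin(time, event, extra=None, ids=None):
    ids = ids or [f"S{i}" for i in range(len(time))]
    df = pd.DataFrame({"time": time, "event": event}, index=pd.Index(ids, name="sample_id"))
    for k, v in (extra or {}).items():
        df[k] = v
    return ClinicalTable(df)


def _scores(values, groups=None, ids=None):
    ids = ids or [f"S{i}" for i in range(len(values))]
    df = pd.DataFrame({"risk_score": values}, index=ids)
    if groups is not None:
        df["group"] = groups
    return df


class TestKaplanMeierLogrank:
    def test_identical_groups_give_null_test(self):
        time = [1, 2, 3, 4, 5.0] * 2
        event = [1, 0, 1, 1, 0] * 2
        scores = _scores(np.zeros(10), ["high"] * 5 + ["low"] * 5)
        res = kaplan_meier_logrank(scores, _clin(time, event))
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.logrank_p == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_summed_oracle(self):
        t_a, t_b = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        scores = _scores([1] * 3 + [0] * 3, ["high"] * 3 + ["low"] * 3)
        res = kaplan_meier_logrank(scores, _clin(t_a + t_b, [1] * 6))
        oracle = logrank_chi2_oracle(t_a, [1] * 3, t_b, [1] * 3)
        assert res.logrank_chi2 == pytest.approx(oracle, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_on_random_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        time = rng.exponential(5, n)
        event = (rng.random(n) > 0.3).astype(int)
        grp = np.where(rng.random(n) > 0.5, "high", "low")
        if len(set(grp)) < 2 or event.sum() == 0:
            return
        scores = _scores(np.zeros(n), grp)
        res = kaplan_meier_logrank(scores, _clin(time, event))
        hi, lo = grp == "high", grp == "low"
        oracle = logrank_chi2_oracle(time[hi], event[hi], time[lo], event[lo])
        assert res.logrank_chi2 == pytest.approx(oracle, rel=1e-8, abs=1e-10)

    def test_km_reaches_zero_without_censoring(self):
        scores = _scores([1, 1, 0, 0.0], ["high"] * 2 + ["low"] * 2)
        res = kaplan_meier_logrank(scores, _clin([1, 2, 3, 4.0], [1] * 4))
        assert res.survival["high"]["survival"].iloc[-1] == pytest.approx(0.0)

    def test_empty_group_rejected(self):
        scores = _scores([1, 2, 3.0], ["high"] * 3)
        with pytest.raises(PipelineError):
            kaplan_meier_logrank(scores, _clin([1, 2, 3.0], [1, 1, 1]))


class TestTimeDependentRoc:
    def test_perfect_ranking_auc_one(self):
        time = np.arange(1.0, 21.0)
        scores = _scores(-time)  # earlier death -> higher score
        res = time_dependent_roc(scores, _clin(time, [1] * 20), eval_times=[5, 10, 15])
        assert all(r.auc == pytest.approx(1.0) for r in res)

    def test_negation_maps_auc_to_complement(self):
        rng = np.random.default_rng(1)
        n = 40
        time = rng.exponential(5, n)
        s = rng.normal(0, 1, n)
        a = ipcw_auc(s, time, np.ones(n, dtype=int), 3.0)
        b = ipcw_auc(-s, time, np.ones(n, dtype=int), 3.0)
        assert a == pytest.approx(1 - b, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_no_censoring_reduces_to_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 21))
        time = rng.exponential(5, n)
        s = rng.normal(0, 1, n).round(1)  # rounding makes score ties possible
        t = float(np.median(time))
        case, control = time <= t, time > t
        if case.sum() == 0 or control.sum() == 0:
            return
        auc = ipcw_auc(s, time, np.ones(n, dtype=int), t)
        assert auc == pytest.approx(mann_whitney_auc(s[case], s[control]), abs=1e-12)

    def test_matches_sksurv_under_censoring(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(2)
        n = 150
        x = rng.normal(0, 1, n)
        time = rng.exponential(5, n) * np.exp(-0.8 * x)
        cens = rng.exponential(8, n)
        obs = np.minimum(time, cens)
        event = (time <= cens).astype(int)
        t = 2.0
        ours = ipcw_auc(x, obs, event, t)
        y = Surv.from_arrays(event.astype(bool), obs)
        theirs = float(cumulative_dynamic_auc(y, y, x, [t])[0][0])
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_roc_points_consistent_with_auc(self):
        rng = np.random.default_rng(3)
        n = 60
        time = rng.exponential(5, n)
        cens = rng.exponential(8, n)
        obs = np.minimum(time, cens)
        event = (time <= cens).astype(int)
        s = rng.normal(0, 1, n)
        res = time_dependent_roc(_scores(s), _clin(obs, event), eval_times=[3.0])
        r = res[0]
        fpr, tpr = r.roc_points["fpr"].to_numpy(), r.roc_points["tpr"].to_numpy()
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert (np.diff(fpr) >= -1e-12).all() and (np.diff(tpr) >= -1e-12).all()
        assert np.trapezoid(tpr, fpr) == pytest.approx(r.auc, abs=1e-10)

    def test_horizon_without_cases_skipped(self):
        time = [5.0, 6.0, 7.0, 8.0]
        res = time_dependent_roc(_scores([1, 2, 3, 4.0]), _clin(time, [1] * 4),
                                 eval_times=[1.0, 6.5])
        assert [r.eval_time for r in res] == [6.5]


class TestClinicalAssociations:
    def test_fisher_exact_diagonal_table(self):
        # 2x2 table [[10,0],[0,10]] -> two-sided p = 2 / C(20,10)
        groups = ["high"] * 10 + ["low"] * 10
        cov = ["a"] * 10 + ["b"] * 10
        scores = _scores(np.zeros(20), groups)
        clin = _clin(np.ones(20), [1] * 20, extra={"marker": cov})
        res = clinical_association_tests(scores, clin, ["marker"])
        assert res.loc["marker", "test"] == "fisher"
        expected = fisher_2x2_oracle(10, 0, 0, 10)
        assert res.loc["marker", "p"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.082e-5, rel=1e-3)

    def test_mirrored_ages_give_p_one(self):
        ages = [50, 60, 70, 80.0]
        scores = _scores(np.zeros(8), ["high"] * 4 + ["low"] * 4)
        clin = _clin(np.ones(8), [1] * 8, extra={"age": ages + ages})
        res = clinical_association_tests(scores, clin, ["age"])
        assert res.loc["age", "test"] == "wilcoxon"
        assert res.loc["age", "p"] == pytest.approx(1.0)

    def test_large_table_uses_chi2(self):
        rng = np.random.default_rng(0)
        n = 200
        groups = np.where(rng.random(n) > 0.5, "high", "low")
        stage = rng.choice(["I", "II", "III", "IV"], n)
        scores = _scores(np.zeros(n), groups)
        clin = _clin(np.ones(n), [1] * n, extra={"stage": stage})
        res = clinical_association_tests(scores, clin, ["stage"])
        assert res.loc["stage", "test"] == "chi2"

    def test_missing_covariate_named(self):
        scores = _scores(np.zeros(4), ["high", "high", "low", "low"])
        clin = _clin(np.ones(4), [1] * 4)
        with pytest.raises(PipelineError, match="nope"):
            clinical_association_tests(scores, clin, ["nope"])


class TestClinicalCox:
    def _data(self, seed=0, n=80):
        rng = np.random.default_rng(seed)
        score = rng.normal(0, 1, n)
        time = rng.exponential(1.0 / (0.2 * np.exp(0.8 * score)))
        cens = rng.exponential(10, n)
        obs = np.minimum(time, cens)
        event = (time <= cens).astype(int)
        extra = {
            "age": rng.normal(65, 8, n).round(1),
            "grade": rng.choice(["low", "high"], n),
            "stage": rng.choice(["I", "II", "III", "IV"], n),
        }
        return _scores(score, np.where(score > 0, "high", "low")), _clin(obs, event, extra)

    def test_tables_well_formed_and_risk_score_detected(self):
        scores, clin = self._data()
        uni, multi = clinical_cox_models(scores, clin, ["age", "grade", "stage"])
        for tab in (uni, multi):
            assert ((tab["ci_low"] <= tab["hr"]) & (tab["hr"] <= tab["ci_high"])).all()
            assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()
            assert (tab["hr"] > 0).all()
        assert uni.loc["risk_score", "p"] < 0.001

    def test_null_covariates_cover_one(self):
        covered = 0
        for seed in range(10):
            scores, clin = self._data(seed)
            _, multi = clinical_cox_models(scores, clin, ["age", "grade", "stage"])
            row = multi.loc["grade"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 8  # hazard depends only on the risk score

    def test_binary_covariate_matches_grid_oracle(self):
        rng = np.random.default_rng(4)
        n = 18
        x = rng.integers(0, 2, n)
        time = rng.exponential(5, n)  # tie-free: Efron == Breslow
        event = (rng.random(n) > 0.2).astype(int)
        scores = _scores(x.astype(float), np.where(x > 0, "high", "low"))
        clin = _clin(time, np.maximum(event, 1))  # all events, >= 10
        uni, _ = clinical_cox_models(scores, clin, [])
        oracle = breslow_beta_grid(x, time, np.ones(n, dtype=int))
        assert np.log(uni.loc["risk_score", "hr"]) == pytest.approx(oracle, abs=1e-4)

    def test_zero_variance_covariate_rejected(self):
        scores, clin = self._data()
        clin.table["flat"] = 0.0
        with pytest.raises(PipelineError, match="flat"):
            clinical_cox_models(scores, clin, ["flat"])

    def test_collinear_covariates_named(self):
        scores, clin = self._data()
        clin.table["age2"] = clin.table["age"] * 2.0
        with pytest.raises(PipelineError, match="age"):
            clinical_cox_models(scores, clin, ["age", "age2"])
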