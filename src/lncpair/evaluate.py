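"""Validation of a fitted risk model against survival and clinical data.

Covers Kaplan-Meier curves with the two-group log-rank test, time-dependent
ROC/AUC at 1/3/5 years (cumulative-case / dynamic-control with inverse
probability of censoring weights), risk-group vs clinical-characteristic
association tests, and univariate/multivariate clinical Cox models.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .containers import ClinicalTable
from .errors import PipelineError

logger = logging.getLogger(__name__)

STAGE_CODES = {"I": 1, "II": 2, "III": 3, "IV": 4}
GRADE_CODES = {"low": 0, "high": 1}


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass
class KMResult:
    """Per-group product-limit estimates and the two-group log-rank test."""

    survival: dict  # group -> DataFrame(timeline, survival, at_risk)
    logrank_chi2: float
    logrank_p: float


def kaplan_meier_logrank(scores: pd.DataFrame, clin: ClinicalTable) -> KMResult:
    """Kaplan-Meier estimates per risk group plus the log-rank chi-square (1 df)."""
    if "group" not in scores.columns:
        raise PipelineError("risk scores carry no group assignment; set a cutoff first")
    clin = clin.subset(scores.index)
    groups = scores["group"]
    curves = {}
    for g in ("high", "low"):
        ids = groups.index[groups == g]
        if len(ids) == 0:
            raise PipelineError(f"risk group {g!r} is empty")
        kmf = KaplanMeierFitter()
        sub = clin.subset(ids)
        kmf.fit(sub.time, sub.event, label=g)
        timeline = kmf.survival_function_.index.to_numpy()
        curves[g] = pd.DataFrame(
            {
                "timeline": timeline,
                "survival": kmf.survival_function_[g].to_numpy(),
                "at_risk": kmf.event_table["at_risk"].reindex(timeline).to_numpy(),
            }
        )
    hi = clin.subset(groups.index[groups == "high"])
    lo = clin.subset(groups.index[groups == "low"])
    if int(hi.event.sum() + lo.event.sum()) < 1:
        raise PipelineError("log-rank test requires at least one event")
    res = logrank_test(hi.time, lo.time, event_observed_A=hi.event, event_observed_B=lo.event)
    return KMResult(
        survival=curves,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


# ---------------------------------------------------------------------------
# time-dependent ROC


def _censoring_survival(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimate of the censoring survival G(t) = P(C > t).

    Returns a lookup(t, left) giving the right-continuous estimate, or the
    left limit G(t-) when ``left`` is true.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - np.asarray(event))
    sf = kmf.survival_function_.iloc[:, 0]
    knots = sf.index.to_numpy(dtype=float)
    vals = sf.to_numpy(dtype=float)

    def lookup(t, left=False):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        side = "left" if left else "right"
        idx = np.searchsorted(knots, t, side=side) - 1
        out = np.where(idx < 0, 1.0, vals[np.clip(idx, 0, len(vals) - 1)])
        return out

    return lookup


def ipcw_auc(scores: np.ndarray, time: np.ndarray, event: np.ndarray,
             eval_time: float) -> float:
    """Uno-type cumulative/dynamic time-dependent AUC at ``eval_time``.

    Cases are subjects with an event by ``eval_time``; controls are still at
    risk beyond it. Case weights are 1/G(Ti-), with G the censoring KM
    estimate; ties in the score count one half.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    case = (time <= eval_time) & (event == 1)
    control = time > eval_time
    if case.sum() == 0 or control.sum() == 0:
        raise PipelineError(f"no cases or no controls at t={eval_time}")
    G = _censoring_survival(time, event)
    w = 1.0 / np.clip(G(time[case], left=True), 1e-12, None)
    sc, st = scores[case], scores[control]
    gt = (sc[:, None] > st[None, :]).sum(axis=1)
    eq = (sc[:, None] == st[None, :]).sum(axis=1)
    num = (w * (gt + 0.5 * eq)).sum()
    return float(num / (w.sum() * len(st)))


@dataclass
class TdRocResult:
    """Time-dependent ROC curve and its AUC at one evaluation time."""

    eval_time: float
    auc: float
    roc_points: pd.DataFrame = field(repr=False)  # columns fpr, tpr


def time_dependent_roc(
    scores: pd.DataFrame | pd.Series,
    clin: ClinicalTable,
    eval_times: Sequence[float] = (1.0, 3.0, 5.0),
) -> list[TdRocResult]:
    """IPCW time-dependent ROC curves of the risk score at each horizon.

    Horizons with no cases or no controls are skipped with a warning.
    """
    s = scores["risk_score"] if isinstance(scores, pd.DataFrame) else scores
    clin = clin.subset(s.index)
    sv = s.to_numpy(dtype=float)
    time = clin.time.to_numpy()
    event = clin.event.to_numpy()
    out: list[TdRocResult] = []
    for t in eval_times:
        case = (time <= t) & (event == 1)
        control = time > t
        if case.sum() == 0 or control.sum() == 0:
            logger.warning("time_dependent_roc: no cases or controls at t=%g; skipped", t)
            continue
        G = _censoring_survival(time, event)
        w = 1.0 / np.clip(G(time[case], left=True), 1e-12, None)
        sc, st = sv[case], sv[control]
        thresholds = np.concatenate([[np.inf], np.sort(np.unique(sv))[::-1], [-np.inf]])
        tpr = [(w * (sc > c)).sum() / w.sum() for c in thresholds]
        fpr = [(st > c).mean() for c in thresholds]
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
        auc = ipcw_auc(sv, time, event, t)
        out.append(TdRocResult(eval_time=float(t), auc=auc, roc_points=roc))
    return out


# ---------------------------------------------------------------------------
# clinical characteristic tests


def _is_continuous(series: pd.Series) -> bool:
    if pd.api.types.is_float_dtype(series):
        return True
    return pd.api.types.is_numeric_dtype(series) and series.nunique() > 6


def clinical_association_tests(
    scores: pd.DataFrame,
    clin: ClinicalTable,
    covariates: Sequence[str],
) -> pd.DataFrame:
    """Association between the risk grouping and each clinical characteristic.

    Categorical covariates: risk-group x level contingency table, chi-squared
    test, switching to Fisher's exact (two-sided) for sparse 2x2 tables (an
    expected cell below 5 or an observed zero). Continuous covariates: Wilcoxon rank-sum
    between the high- and low-risk groups.
    """
    if "group" not in scores.columns:
        raise PipelineError("risk scores carry no group assignment")
    clin = clin.subset(scores.index)
    groups = scores["group"]
    rows = []
    for cov in covariates:
        if cov not in clin.table.columns:
            raise PipelineError(f"covariate {cov!r} absent from the clinical table")
        x = clin.table[cov]
        if _is_continuous(x):
            hi = x[groups == "high"].to_numpy(dtype=float)
            lo = x[groups == "low"].to_numpy(dtype=float)
            stat, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
            rows.append((cov, "wilcoxon", float(stat), float(p), ""))
            continue
        table = pd.crosstab(groups, x)
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows.append((cov, "chi2", np.nan, 1.0, "degenerate table"))
            continue
        chi2, p, _, expected = stats.chi2_contingency(table.to_numpy())
        note = ""
        sparse = (expected < 5).any() or (table.to_numpy() == 0).any()
        if sparse:
            if table.shape == (2, 2):
                _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
                rows.append((cov, "fisher", np.nan, float(p), "sparse 2x2 table"))
                continue
            note = "sparse cells; chi-squared retained (table larger than 2x2)"
            logger.warning("clinical_association_tests[%s]: %s", cov, note)
        rows.append((cov, "chi2", float(chi2), float(p), note))
    return pd.DataFrame(rows, columns=["covariate", "test", "statistic", "p", "note"]
                        ).set_index("covariate")


def encode_ordinal(series: pd.Series) -> pd.Series:
    """Encode stage (I-IV -> 1-4) / grade (low/high -> 0/1) labels as numbers."""
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float)
    mapping = {**STAGE_CODES, **GRADE_CODES}
    out = series.map(mapping)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise PipelineError(f"cannot ordinal-encode value {bad!r} in {series.name!r}")
    return out.astype(float)


def clinical_cox_models(
    scores: pd.DataFrame,
    clin: ClinicalTable,
    covariates: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Univariate and multivariate Cox models over clinical covariates + risk score.

    The risk score enters as a continuous covariate; stage and grade are
    ordinal-encoded. Returns (univariate, multivariate) tables with columns
    ``hr, ci_low, ci_high, p``.
    """
    clin = clin.subset(scores.index)
    df = clin.table[["time", "event"]].copy()
    df["risk_score"] = scores["risk_score"].to_numpy(dtype=float)
    for cov in covariates:
        if cov not in clin.table.columns:
            raise PipelineError(f"covariate {cov!r} absent from the clinical table")
        df[cov] = encode_ordinal(clin.table[cov]).to_numpy()
    all_cov = ["risk_score", *covariates]
    for cov in all_cov:
        if df[cov].std() == 0:
            raise PipelineError(f"covariate {cov!r} has no variance")
    if int(df["event"].sum()) < 10:
        raise PipelineError("clinical Cox models require at least 10 events")
    corr = df[all_cov].corr().abs()
    np.fill_diagonal(corr.to_numpy(), 0.0)
    if (corr.to_numpy() > 0.999).any():
        i, j = np.argwhere(corr.to_numpy() > 0.999)[0]
        raise PipelineError(f"collinear covariates: {all_cov[i]!r} and {all_cov[j]!r}")

    def _row(cph: CoxPHFitter, cov: str, kind: str):
        s = cph.summary.loc[cov]
        return {
            "covariate": cov,
            "hr": float(s["exp(coef)"]),
            "ci_low": float(s["exp(coef) lower 95%"]),
            "ci_high": float(s["exp(coef) upper 95%"]),
            "p": float(s["p"]),
            "model_kind": kind,
        }

    uni_rows = []
    for cov in all_cov:
        cph = CoxPHFitter()
        cph.fit(df[["time", "event", cov]], duration_col="time", event_col="event")
        uni_rows.append(_row(cph, cov, "univariate"))
    cph = CoxPHFitter()
    cph.fit(df[["time", "event", *all_cov]], duration_col="time", event_col="event")
    multi_rows = [_row(cph, cov, "multivariate") for cov in all_cov]
    uni = pd.DataFrame(uni_rows).set_index("covariate")
    multi = pd.DataFrame(multi_rows).set_index("covariate")
    return uni, multi
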