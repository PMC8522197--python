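"""Prognostic pair selection and the rank-based risk model.

Selection proceeds in three stages, mirroring how pair signatures are built
in practice:

1. univariate Cox screen over all pair indicators (Wald P < alpha);
2. repeated lasso-Cox: many cycles of L1-penalised Cox on random subsamples,
   penalty chosen per cycle by cross-validated partial-likelihood deviance;
   pairs kept if selected in more than ``count_threshold`` cycles;
3. forward scan: nested multivariate Cox models adding pairs in order of
   lasso selection count, stopping at the model whose linear predictor
   maximises the time-dependent AUC at ``eval_time``.

The per-sample risk score is the linear predictor sum(beta_i * indicator_i);
patients are dichotomised at the cutoff minimising the AIC of a Cox model on
the binary split.

The public surface follows the statsmodels convention: build a
:class:`PairRiskCox` model from data, call :meth:`~PairRiskCox.fit`, and work
with the returned :class:`PairRiskCoxResults`.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._cox import breslow_loglik, fit_binary_cox
from .containers import ClinicalTable, ExpressionMatrix, PairFeatureMatrix
from .errors import ConfigurationError, PipelineError
from .evaluate import ipcw_auc
from .pairs import build_pair_matrix, filter_pairs_by_frequency

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stage operations


def _align(pm: PairFeatureMatrix, clin: ClinicalTable) -> ClinicalTable:
    missing = [s for s in pm.sample_ids if s not in set(clin.sample_ids)]
    if missing:
        raise PipelineError(f"sample {missing[0]!r} has no clinical record")
    return clin.subset(pm.sample_ids)


def univariate_cox_screen(
    pm: PairFeatureMatrix, clin: ClinicalTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Single-covariate Breslow Cox fit and Wald test for every pair.

    Returns a DataFrame indexed by pair id with columns
    ``beta, hr, se, p, passed, separated``. Monotone-likelihood (perfect
    separation) fits are flagged with the coefficient capped, not crashed.
    """
    clin = _align(pm, clin)
    if int(clin.event.sum()) < 10:
        raise PipelineError("univariate screen requires at least 10 events")
    X = pm.indicators.to_numpy(dtype=float)
    const = X.std(axis=1) == 0
    if const.any():
        pid = pm.pair_ids[np.flatnonzero(const)[0]]
        raise PipelineError(f"constant indicator for pair {pid!r}; apply the frequency filter first")
    fit = fit_binary_cox(X, clin.time.to_numpy(), clin.event.to_numpy())
    out = pd.DataFrame(
        {
            "beta": fit.beta,
            "hr": np.exp(fit.beta),
            "se": fit.se,
            "p": fit.p,
            "passed": fit.p < alpha,
            "separated": fit.separated,
        },
        index=pm.pair_ids,
    )
    if fit.separated.any():
        logger.warning("univariate screen: %d pair(s) flagged for monotone likelihood",
                       int(fit.separated.sum()))
    return out


@dataclass
class LassoSelectionReport:
    """Selection counts over the repeated lasso-Cox cycles."""

    counts: pd.Series  # pair_id -> number of cycles with nonzero coefficient
    n_cycles: int
    count_threshold: int
    seed: int
    n_failed_cycles: int = 0

    @property
    def selected(self) -> pd.Series:
        return self.counts > self.count_threshold

    def ranked_pairs(self) -> list[str]:
        """Selected pairs ordered by count (desc), pair id as tie-break."""
        sel = self.counts[self.selected]
        order = sorted(sel.index, key=lambda pid: (-sel[pid], pid))
        return order


def _one_lasso_cycle(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    rng: np.random.Generator,
    subsample_frac: float,
    cv_folds: int,
) -> np.ndarray:
    """One cycle: subsample, CV the penalty, return the nonzero-coefficient mask."""
    n = len(time)
    m = max(int(np.floor(subsample_frac * n)), cv_folds + 1)
    idx = rng.choice(n, size=m, replace=False)
    idx.sort()
    Xs, ts, es = X[idx], time[idx], event[idx]
    if es.sum() < max(3, cv_folds):
        raise ArithmeticError("too few events in subsample")
    y = Surv.from_arrays(es.astype(bool), ts)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=25, alpha_min_ratio=0.05,
                                  max_iter=100000)
    path.fit(Xs, y)
    alphas = path.alphas_

    folds = KFold(n_splits=cv_folds, shuffle=True,
                  random_state=int(rng.integers(2**31 - 1)))
    dev = np.zeros(len(alphas))
    for train, test in folds.split(Xs):
        if es[train].sum() < 2 or es[test].sum() < 1:
            continue
        fold_fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                          max_iter=100000)
        fold_fit.fit(Xs[train], Surv.from_arrays(es[train].astype(bool), ts[train]))
        for j in range(len(alphas)):
            beta = fold_fit.coef_[:, min(j, fold_fit.coef_.shape[1] - 1)]
            dev[j] += -2.0 * breslow_loglik(beta, Xs[test], ts[test], es[test])
    best = int(np.argmin(dev))
    beta = path.coef_[:, min(best, path.coef_.shape[1] - 1)]
    return beta != 0.0


def repeated_lasso_selection(
    pm: PairFeatureMatrix,
    clin: ClinicalTable,
    n_cycles: int = 1000,
    count_threshold: int = 100,
    seed: int = 0,
    subsample_frac: float = 0.8,
    cv_folds: int = 5,
    max_retries: int = 3,
) -> LassoSelectionReport:
    """Repeated lasso-Cox selection over random subsamples.

    Each cycle draws ``subsample_frac`` of the samples without replacement
    (cycle-specific RNG stream derived from ``seed``), fits an L1-penalised
    Cox path, picks the penalty by ``cv_folds``-fold cross-validated
    partial-likelihood deviance, and records the pairs with nonzero
    coefficients. Pairs selected in more than ``count_threshold`` cycles are
    retained.
    """
    if len(pm.pair_ids) < 2:
        raise PipelineError("repeated lasso requires at least 2 candidate pairs")
    clin = _align(pm, clin)
    if int(clin.event.sum()) < 10:
        raise PipelineError("repeated lasso requires at least 10 events")
    if count_threshold >= n_cycles:
        logger.warning(
            "count_threshold (%d) >= n_cycles (%d): the selected set will be empty",
            count_threshold, n_cycles,
        )
    X = pm.indicators.to_numpy(dtype=float).T  # samples x pairs
    time = clin.time.to_numpy()
    event = clin.event.to_numpy()

    counts = np.zeros(len(pm.pair_ids), dtype=int)
    failed = 0
    for cycle in range(n_cycles):
        ok = False
        for retry in range(max_retries + 1):
            rng = np.random.default_rng([seed, cycle, retry])
            try:
                mask = _one_lasso_cycle(X, time, event, rng, subsample_frac, cv_folds)
            except (ArithmeticError, ValueError) as exc:
                logger.debug("lasso cycle %d attempt %d failed: %s", cycle, retry, exc)
                continue
            counts += mask
            ok = True
            break
        if not ok:
            failed += 1
    if failed > 0.10 * n_cycles:
        raise PipelineError(f"{failed}/{n_cycles} lasso cycles failed to converge")
    return LassoSelectionReport(
        counts=pd.Series(counts, index=pm.pair_ids, name="selection_count"),
        n_cycles=n_cycles,
        count_threshold=count_threshold,
        seed=seed,
        n_failed_cycles=failed,
    )


@dataclass
class RiskModel:
    """Selected pairs with Cox coefficients, AUC trajectory and risk cutoff."""

    pairs: list[str]
    betas: pd.Series
    auc_trajectory: list[float]
    chosen_size: int
    eval_time: float
    cutoff: float | None = None
    cutoff_method: str = "aic"
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pairs": list(self.pairs),
            "betas": {k: float(v) for k, v in self.betas.items()},
            "auc_trajectory": [float(a) for a in self.auc_trajectory],
            "chosen_size": int(self.chosen_size),
            "eval_time": float(self.eval_time),
            "cutoff": None if self.cutoff is None else float(self.cutoff),
            "cutoff_method": self.cutoff_method,
            "meta": self.meta,
        }


def _fit_multivariate(df: pd.DataFrame, covariates: Sequence[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    try:
        cph.fit(df[["time", "event", *covariates]], duration_col="time", event_col="event")
    except Exception:
        # ridge fallback for near-separated small models
        cph = CoxPHFitter(penalizer=0.01)
        cph.fit(df[["time", "event", *covariates]], duration_col="time", event_col="event")
    return cph


def forward_model_scan(
    ranked_pairs: Sequence[str],
    pm: PairFeatureMatrix,
    clin: ClinicalTable,
    eval_time: float = 1.0,
) -> RiskModel:
    """AUC-guided forward scan over nested Cox models.

    Models M1 c M2 c ... add pairs in the given rank order; each is refit by
    multivariate Cox and scored by the IPCW time-dependent AUC of its linear
    predictor at ``eval_time``. The chosen size is the first index attaining
    the maximal AUC; coefficients come from that refit.
    """
    ranked_pairs = list(ranked_pairs)
    if not ranked_pairs:
        raise PipelineError("forward scan requires at least one selected pair")
    clin = _align(pm, clin)
    ind = pm.indicators.loc[ranked_pairs]
    df = clin.table[["time", "event"]].copy()
    safe = {pid: f"x{i}" for i, pid in enumerate(ranked_pairs)}
    for pid in ranked_pairs:
        df[safe[pid]] = ind.loc[pid].to_numpy(dtype=float)

    time = clin.time.to_numpy()
    event = clin.event.to_numpy()
    aucs: list[float] = []
    fits: list[CoxPHFitter | None] = []
    sizes: list[int] = []
    for k in range(1, len(ranked_pairs) + 1):
        cov = [safe[p] for p in ranked_pairs[:k]]
        try:
            cph = _fit_multivariate(df, cov)
        except Exception as exc:
            logger.warning("forward scan: size-%d Cox fit failed (%s); skipped", k, exc)
            continue
        eta = (df[cov].to_numpy() @ cph.params_[cov].to_numpy()).astype(float)
        auc = ipcw_auc(eta, time, event, eval_time)
        aucs.append(float(auc))
        fits.append(cph)
        sizes.append(k)
    if not aucs:
        raise PipelineError("forward scan: every candidate model failed to fit")
    best = int(np.argmax(aucs))  # first index attaining the maximum
    chosen = fits[best]
    cov = [safe[p] for p in ranked_pairs[: sizes[best]]]
    betas = pd.Series(
        {pid: float(chosen.params_[safe[pid]]) for pid in ranked_pairs[: sizes[best]]},
        name="beta",
    )
    return RiskModel(
        pairs=ranked_pairs[: sizes[best]],
        betas=betas,
        auc_trajectory=aucs,
        chosen_size=sizes[best],
        eval_time=eval_time,
    )


def compute_risk_scores(model: RiskModel, pm: PairFeatureMatrix) -> pd.DataFrame:
    """Per-sample risk score sum(beta_i * indicator_i); group once a cutoff exists."""
    missing = [p for p in model.pairs if p not in set(pm.pair_ids)]
    if missing:
        raise PipelineError(f"pair {missing[0]!r} missing from the pair matrix")
    ind = pm.indicators.loc[model.pairs].to_numpy(dtype=float)
    scores = model.betas.loc[model.pairs].to_numpy() @ ind
    out = pd.DataFrame({"risk_score": scores}, index=pm.sample_ids)
    if model.cutoff is not None:
        out["group"] = np.where(out["risk_score"] > model.cutoff, "high", "low")
    return out


def aic_optimal_cutoff(
    scores: pd.Series, clin: ClinicalTable, min_group_frac: float = 0.1
) -> float:
    """Risk-score cutoff minimising the AIC of a Cox fit on the binary split.

    Candidates are midpoints between consecutive distinct sorted scores,
    restricted so each side keeps at least ``min_group_frac`` of the samples;
    AIC = 2*1 - 2*logPL at the fitted coefficient; ties go to the smaller
    cutoff.
    """
    clin = clin.subset(scores.index)
    s = scores.to_numpy(dtype=float)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise PipelineError("all risk scores identical; no admissible cutoff")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = len(s)
    floor = max(1, int(np.ceil(min_group_frac * n)))
    admissible = [c for c in mids
                  if (s > c).sum() >= floor and (s <= c).sum() >= floor]
    if not admissible:
        raise PipelineError("no admissible cutoff keeps both groups above the size floor")
    X = np.stack([(s > c).astype(float) for c in admissible])
    fit = fit_binary_cox(X, clin.time.to_numpy(), clin.event.to_numpy())
    aic = 2.0 - 2.0 * fit.loglik
    best = int(np.argmin(aic))  # np.argmin takes the first (smallest cutoff) on ties
    return float(admissible[best])


# ---------------------------------------------------------------------------
# model / results objects


class PairRiskCox:
    """Rank-based lncRNA-pair Cox risk model.

    Parameters
    ----------
    pair_matrix : PairFeatureMatrix
        Binary pair indicators (typically frequency-filtered, tumor samples).
    clinical : ClinicalTable
        Survival times and event flags covering the pair-matrix samples.
    alpha : float
        Wald significance threshold of the univariate screen.
    n_cycles, count_threshold : int
        Repeated-lasso cycle count and selection-count threshold.
    eval_time : float
        Horizon (years) of the time-dependent AUC used by the forward scan.
    """

    def __init__(
        self,
        pair_matrix: PairFeatureMatrix,
        clinical: ClinicalTable,
        *,
        alpha: float = 0.05,
        n_cycles: int = 1000,
        count_threshold: int = 100,
        subsample_frac: float = 0.8,
        cv_folds: int = 5,
        eval_time: float = 1.0,
        min_group_frac: float = 0.1,
    ) -> None:
        if not (0 < subsample_frac <= 1):
            raise ConfigurationError("subsample_frac must be in (0, 1]")
        self.pair_matrix = pair_matrix
        self.clinical = _align(pair_matrix, clinical)
        self.alpha = alpha
        self.n_cycles = n_cycles
        self.count_threshold = count_threshold
        self.subsample_frac = subsample_frac
        self.cv_folds = cv_folds
        self.eval_time = eval_time
        self.min_group_frac = min_group_frac

    @classmethod
    def from_expression(
        cls,
        expr: ExpressionMatrix,
        clinical: ClinicalTable,
        *,
        freq_lo: float = 0.2,
        freq_hi: float = 0.8,
        **kwargs,
    ) -> "PairRiskCox":
        """Build the model straight from a DE-ir-lncRNA expression submatrix."""
        pm = filter_pairs_by_frequency(build_pair_matrix(expr), freq_lo, freq_hi)
        return cls(pm, clinical, **kwargs)

    def fit(self, seed: int = 0) -> "PairRiskCoxResults":
        """Run screen -> repeated lasso -> forward scan -> AIC cutoff."""
        uni = univariate_cox_screen(self.pair_matrix, self.clinical, self.alpha)
        passed = uni.index[uni["passed"]]
        if len(passed) < 2:
            raise PipelineError(
                f"only {len(passed)} pair(s) passed the univariate screen; need >= 2"
            )
        pm_uni = self.pair_matrix.subset_pairs(passed)
        report = repeated_lasso_selection(
            pm_uni,
            self.clinical,
            n_cycles=self.n_cycles,
            count_threshold=self.count_threshold,
            seed=seed,
            subsample_frac=self.subsample_frac,
            cv_folds=self.cv_folds,
        )
        ranked = report.ranked_pairs()
        if not ranked:
            raise PipelineError("repeated lasso selected no pairs above the count threshold")
        model = forward_model_scan(ranked, pm_uni, self.clinical, self.eval_time)
        scores = compute_risk_scores(model, self.pair_matrix)
        model.cutoff = aic_optimal_cutoff(
            scores["risk_score"], self.clinical, self.min_group_frac
        )
        model.meta = {"seed": int(seed), "n_cycles": int(self.n_cycles),
                      "count_threshold": int(self.count_threshold)}
        scores = compute_risk_scores(model, self.pair_matrix)
        return PairRiskCoxResults(self, model, uni, report, scores)


class PairRiskCoxResults:
    """Fitted pair risk model: coefficients, trajectory, cutoff and scores."""

    def __init__(
        self,
        model_spec: PairRiskCox,
        risk_model: RiskModel,
        univariate: pd.DataFrame,
        lasso_report: LassoSelectionReport,
        risk_scores: pd.DataFrame,
    ) -> None:
        self.model = model_spec
        self.risk_model = risk_model
        self.univariate = univariate
        self.lasso_report = lasso_report
        self.risk_scores = risk_scores

    # -- predictions -------------------------------------------------------
    def predict_risk(self, pm: PairFeatureMatrix) -> pd.DataFrame:
        """Risk scores and high/low groups for new samples' pair indicators."""
        return compute_risk_scores(self.risk_model, pm)

    def predict_risk_from_expression(self, expr: ExpressionMatrix) -> pd.DataFrame:
        """Score new samples from raw expression of the model's pair genes."""
        genes = sorted({g for pid in self.risk_model.pairs for g in pid.split("|", 1)})
        pm = build_pair_matrix(expr.subset_genes(genes))
        return self.predict_risk(pm.subset_pairs(self.risk_model.pairs))

    # -- evaluation shortcuts (thin wrappers over lncpair.evaluate) --------
    def km_logrank(self, clinical: ClinicalTable | None = None):
        from .evaluate import kaplan_meier_logrank

        return kaplan_meier_logrank(self.risk_scores, clinical or self.model.clinical)

    def time_dependent_roc(self, clinical: ClinicalTable | None = None,
                           eval_times: Sequence[float] = (1.0, 3.0, 5.0)):
        from .evaluate import time_dependent_roc

        return time_dependent_roc(self.risk_scores, clinical or self.model.clinical,
                                  eval_times)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        rm = self.risk_model
        lines = [
            "Pair risk Cox model",
            "===================",
            f"candidate pairs:      {len(self.univariate)}",
            f"univariate passed:    {int(self.univariate['passed'].sum())}",
            f"lasso selected:       {int(self.lasso_report.selected.sum())}"
            f"  (> {self.lasso_report.count_threshold}/{self.lasso_report.n_cycles} cycles)",
            f"chosen model size:    {rm.chosen_size}",
            f"AUC at {rm.eval_time:g}y:          {max(rm.auc_trajectory):.3f}",
            f"risk-score cutoff:    {rm.cutoff:.4f} ({rm.cutoff_method})",
            "",
            f"{'pair':<24}{'beta':>10}{'HR':>10}",
        ]
        for pid in rm.pairs:
            b = rm.betas[pid]
            lines.append(f"{pid:<24}{b:>10.4f}{np.exp(b):>10.4f}")
        if "group" in self.risk_scores:
            vc = self.risk_scores["group"].value_counts()
            lines += ["", f"high-risk: {vc.get('high', 0)}   low-risk: {vc.get('low', 0)}"]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.risk_model.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
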