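"""Associations between the risk model and immune / chemosensitivity panels.

All tests are rank-based: two-sample Wilcoxon rank-sum between the high- and
low-risk groups, and Spearman correlation against the continuous risk score.
Panels are consumed as-is — the upstream deconvolution (TIMER, CIBERSORT,
XCELL, QUANTISEQ, MCPcounter, EPIC) or IC50 prediction method is recorded in
the panel's source label, never recomputed here. For drug panels the scores
are predicted IC50s, so "higher in the low-risk group" means the high-risk
group is the more sensitive one.

A raw P < 0.05 significance flag is reported (no correction across panel
features); a BH-adjusted column is emitted alongside for transparency.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClinicalTable, ExpressionMatrix, ScorePanel
from .errors import PipelineError
from .screen import benjamini_hochberg

logger = logging.getLogger(__name__)

#: Immune-checkpoint-related genes examined by default.
DEFAULT_CHECKPOINT_GENES = ("DDR2", "HAVCR2", "LAG3", "CTLA4")


def _require_groups(scores: pd.DataFrame) -> pd.Series:
    if "group" not in scores.columns:
        raise PipelineError("risk scores carry no group assignment")
    return scores["group"]


def panel_group_test(
    panel: ScorePanel, scores: pd.DataFrame, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Wilcoxon rank-sum of every panel feature between risk groups.

    Direction is read off the group medians. Features constant across all
    samples get p = 1 and direction "none".
    """
    groups = _require_groups(scores)
    shared = [s for s in panel.sample_ids if s in set(groups.index)]
    hi_ids = [s for s in shared if groups[s] == "high"]
    lo_ids = [s for s in shared if groups[s] == "low"]
    if len(hi_ids) < 3 or len(lo_ids) < 3:
        raise PipelineError("panel test requires >= 3 samples per risk group")
    rows = []
    for fid in panel.feature_ids:
        hi = panel.values.loc[fid, hi_ids].to_numpy(dtype=float)
        lo = panel.values.loc[fid, lo_ids].to_numpy(dtype=float)
        if np.concatenate([hi, lo]).std() == 0:
            rows.append((fid, "wilcoxon", np.nan, 1.0, "none"))
            continue
        stat, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
        mh, ml = np.median(hi), np.median(lo)
        if mh > ml:
            direction = "higher_in_high_risk"
        elif mh < ml:
            direction = "higher_in_low_risk"
        else:
            direction = "none"
        rows.append((fid, "wilcoxon", float(stat), float(p), direction))
    out = pd.DataFrame(
        rows, columns=["feature_id", "test", "statistic", "p", "direction"]
    ).set_index("feature_id")
    out["significant"] = out["p"] < p_threshold
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy()) if len(out) else []
    return out


def score_correlation(
    panel: ScorePanel, scores: pd.DataFrame, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Spearman correlation of each panel feature with the continuous risk score."""
    shared = [s for s in panel.sample_ids if s in set(scores.index)]
    if len(shared) < 4:
        raise PipelineError("score correlation requires >= 4 shared samples")
    rs = scores.loc[shared, "risk_score"].to_numpy(dtype=float)
    rows = []
    for fid in panel.feature_ids:
        x = panel.values.loc[fid, shared].to_numpy(dtype=float)
        if x.std() == 0:
            rows.append((fid, "spearman", np.nan, 1.0, np.nan, "constant feature"))
            continue
        rho, p = stats.spearmanr(rs, x)
        rows.append((fid, "spearman", float(rho), float(p), float(rho), ""))
    out = pd.DataFrame(
        rows, columns=["feature_id", "test", "statistic", "p", "rho", "reason"]
    ).set_index("feature_id")
    out["significant"] = out["p"] < p_threshold
    out["fdr"] = benjamini_hochberg(out["p"].fillna(1.0).to_numpy()) if len(out) else []
    return out


def checkpoint_gene_association(
    expr: ExpressionMatrix,
    gene_ids: Sequence[str],
    scores: pd.DataFrame,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Risk-group Wilcoxon test on log2(x + 1) expression of checkpoint genes."""
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        raise PipelineError("duplicate gene ids in checkpoint request")
    missing = [g for g in gene_ids if g not in set(expr.gene_ids)]
    if missing:
        raise PipelineError(f"checkpoint gene {missing[0]!r} absent from expression matrix")
    logx = expr.log2p1().loc[gene_ids]
    panel = ScorePanel(logx, source_label="checkpoint log2(x+1) expression")
    return panel_group_test(panel, scores, p_threshold)


def drug_sensitivity_group_test(
    drug_panel: ScorePanel, scores: pd.DataFrame, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Risk-group Wilcoxon test on predicted IC50 per drug.

    Direction semantics: lower IC50 = more sensitive, so
    ``higher_in_low_risk`` means the high-risk group is predicted more
    sensitive to the drug.
    """
    if len(drug_panel.feature_ids) == 0:
        logger.warning("drug panel is empty; no tests run")
        return pd.DataFrame(
            columns=["test", "statistic", "p", "direction", "significant", "fdr"]
        )
    return panel_group_test(drug_panel, scores, p_threshold)
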