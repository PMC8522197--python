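"""Immune-related lncRNA screening.

Two filters are applied to the lncRNA compartment:

1. Co-expression screen: a lncRNA is called immune-related (ir-lncRNA) if it
   correlates with at least one curated immune mRNA with |r| > 0.5 (strict)
   and P < 0.05.
2. Differential expression: Welch two-sample t-test on log2(FPKM + 1)
   between tumor and normal samples; a gene passes with |log2FC| > 2 and
   Benjamini-Hochberg FDR < 0.05.

The DE-ir-lncRNA set is the intersection of the two pass sets.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NORMAL, TUMOR, ExpressionMatrix
from .errors import ConfigurationError, PipelineError


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _corr_matrix(A: np.ndarray, B: np.ndarray, method: str) -> np.ndarray:
    """Row-by-row correlation between two matrices sharing their sample axis."""
    if method == "spearman":
        A = stats.rankdata(A, axis=1)
        B = stats.rankdata(B, axis=1)
    elif method != "pearson":
        raise ConfigurationError(f"unknown correlation method {method!r}")
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A**2).sum(axis=1))
    sb = np.sqrt((B**2).sum(axis=1))
    num = A @ B.T
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / np.outer(sa, sb)
    return np.clip(r, -1.0, 1.0)


def immune_correlation_screen(
    lnc: ExpressionMatrix,
    immune_mrna: ExpressionMatrix,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
    method: str = "pearson",
    transform: str = "log2",
) -> pd.DataFrame:
    """Screen every lncRNA for co-expression with the immune mRNA panel.

    A lncRNA passes if ANY immune mRNA satisfies |r| > r_threshold (strict)
    and P < p_threshold; ``best_partner`` is the immune mRNA of maximal |r|.
    Correlation is computed on log2(x + 1) by default (``transform="none"``
    uses the values as given) — FPKM-scale Pearson is dominated by the
    heaviest samples. Zero-variance lncRNAs are reported failed with a
    reason rather than as NaN.

    Returns a DataFrame indexed by lncRNA id with columns
    ``best_partner, r, p, passed, reason``.
    """
    if list(lnc.sample_ids) != list(immune_mrna.sample_ids):
        raise PipelineError("lncRNA and immune mRNA matrices must share sample ordering")
    n = len(lnc.sample_ids)
    if n < 3:
        raise PipelineError("correlation screen requires at least 3 samples")
    if transform not in ("log2", "none"):
        raise ConfigurationError(f"unknown correlation transform {transform!r}")

    if transform == "log2":
        L = lnc.log2p1().to_numpy(dtype=float)
        M = immune_mrna.log2p1().to_numpy(dtype=float)
    else:
        L = lnc.values.to_numpy(dtype=float)
        M = immune_mrna.values.to_numpy(dtype=float)
    lnc_const = L.std(axis=1) == 0
    m_const = M.std(axis=1) == 0

    r = _corr_matrix(L, M, method)
    r[:, m_const] = 0.0  # undefined against constant partners -> never a hit
    r[lnc_const, :] = 0.0
    # t-test on the correlation coefficient, n - 2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0

    hit = (np.abs(r) > r_threshold) & (p < p_threshold)
    best = np.abs(r).argmax(axis=1)
    rows = []
    for i, gid in enumerate(lnc.gene_ids):
        if lnc_const[i]:
            rows.append((gid, "", np.nan, np.nan, False, "zero variance"))
            continue
        j = best[i]
        rows.append(
            (gid, immune_mrna.gene_ids[j], r[i, j], p[i, j], bool(hit[i].any()), "")
        )
    out = pd.DataFrame(
        rows, columns=["lncrna_id", "best_partner", "r", "p", "passed", "reason"]
    ).set_index("lncrna_id")
    return out


def differential_expression(
    expr: ExpressionMatrix,
    logfc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Tumor-vs-normal Welch t-test per gene on the log2(x + 1) scale.

    log2fc = mean(tumor) - mean(normal); BH correction across all tested
    genes; a gene passes with |log2fc| > logfc_threshold and fdr < fdr_threshold.
    Zero-variance genes with equal group means get p = 1 by convention.
    """
    tumor_ids = expr.samples_in_group(TUMOR)
    normal_ids = expr.samples_in_group(NORMAL)
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise PipelineError("differential expression requires >= 2 samples per group")

    logx = expr.log2p1()
    T = logx[tumor_ids].to_numpy(dtype=float)
    N = logx[normal_ids].to_numpy(dtype=float)
    log2fc = T.mean(axis=1) - N.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, p = stats.ttest_ind(T, N, axis=1, equal_var=False)
    degenerate = np.isnan(p)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance, any mean difference handled below
    # zero variance in both groups but different means: the difference is exact
    both_const = (T.std(axis=1) == 0) & (N.std(axis=1) == 0)
    p = np.where(both_const & (log2fc != 0), 0.0, p)

    fdr = benjamini_hochberg(p)
    passed = (np.abs(log2fc) > logfc_threshold) & (fdr < fdr_threshold)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "direction": np.where(log2fc > 0, "up", "down"),
            "passed": passed,
        },
        index=expr.gene_ids,
    )


def de_ir_lncrnas(corr_result: pd.DataFrame, de_result: pd.DataFrame) -> list[str]:
    """DE-ir-lncRNA set: intersection of the two pass sets, sorted for determinism."""
    ir = set(corr_result.index[corr_result["passed"]])
    de = set(de_result.index[de_result["passed"]])
    return sorted(ir & de)
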