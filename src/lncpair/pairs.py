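"""Rank-based lncRNA pair features.

For every unordered pair of DE-ir-lncRNAs (B, C), the pair feature in sample
s is 1 iff expr(B, s) > expr(C, s), else 0 (ties count as 0). Because the
indicator depends only on the within-sample ordering of the two genes, the
resulting signature is invariant to any per-sample monotone transform of
expression — no cross-sample normalisation is needed.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PairFeatureMatrix
from .errors import ConfigurationError, PipelineError


def build_pair_matrix(expr: ExpressionMatrix) -> PairFeatureMatrix:
    """Build the 0/1 indicator matrix over all unordered gene pairs.

    Pairs are stored in canonical orientation (B lexicographically < C) under
    row ids ``"B|C"``; for k genes the matrix has k*(k-1)/2 rows.
    """
    genes = sorted(expr.gene_ids)
    if len(genes) < 2:
        raise PipelineError("pair matrix requires at least 2 genes")
    V = expr.values.loc[genes].to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(genes)}
    pairs = list(itertools.combinations(genes, 2))
    bi = np.fromiter((idx[b] for b, _ in pairs), dtype=int)
    ci = np.fromiter((idx[c] for _, c in pairs), dtype=int)
    indicators = (V[bi] > V[ci]).astype(np.int8)
    frame = pd.DataFrame(
        indicators,
        index=pd.Index([f"{b}|{c}" for b, c in pairs], name="pair_id"),
        columns=expr.sample_ids,
    )
    return PairFeatureMatrix(frame, pairs)


def filter_pairs_by_frequency(
    pm: PairFeatureMatrix, lo: float = 0.2, hi: float = 0.8
) -> PairFeatureMatrix:
    """Keep pairs whose indicator frequency lies strictly inside (lo, hi).

    A pair that is 0 or 1 in (almost) every sample carries no prognostic
    contrast; the bounds are strict, so frequency == lo is removed.
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise ConfigurationError(f"invalid frequency bounds ({lo}, {hi})")
    freq = pm.frequency
    keep = freq.index[(freq > lo) & (freq < hi)]
    return pm.subset_pairs(keep)
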