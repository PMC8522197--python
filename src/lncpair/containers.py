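"""In-memory containers shared across the pipeline.

All tabular containers are thin, validated wrappers around pandas objects:
an expression matrix (genes x samples, FPKM-like), a per-sample clinical
table, a generic per-sample score panel (immune-infiltration cell types or
predicted drug IC50s) and a gene annotation map.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative abundance matrix with per-sample group labels.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene id, columns by sample id; FPKM-like units.
    sample_group : Series
        Label per sample, ``"tumor"`` or ``"normal"``, indexed like the columns.
    """

    values: pd.DataFrame
    sample_group: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[1] == 0:
            raise FormatError("expression matrix has no samples")
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = v.columns[v.dtypes.map(lambda d: not np.issubdtype(d, np.number))][0]
            raise FormatError(f"non-numeric expression values in column {bad!r}")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(f"non-finite expression at gene {v.index[g]!r}, sample {v.columns[s]!r}")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(f"negative expression at gene {v.index[g]!r}, sample {v.columns[s]!r}")
        self.sample_group = self.sample_group.reindex(v.columns)
        if self.sample_group.isna().any():
            missing = self.sample_group.index[self.sample_group.isna()][0]
            raise FormatError(f"sample {missing!r} has no group label")
        bad = set(self.sample_group.unique()) - {TUMOR, NORMAL}
        if bad:
            raise FormatError(f"unknown sample group label(s): {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> pd.Index:
        return self.sample_group.index[self.sample_group == group]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.sample_group)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.sample_group.loc[ids])

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1) transform of the matrix; used by DE and checkpoint tests."""
        return np.log2(self.values + 1.0)


@dataclass
class GeneAnnotation:
    """gene_id -> {biotype, gene_name} map derived from a GTF annotation."""

    table: pd.DataFrame  # index gene_id, columns: biotype, gene_name

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate gene id in annotation: {dup!r}")

    def biotype_of(self, gene_id: str) -> str | None:
        if gene_id in self.table.index:
            return self.table.at[gene_id, "biotype"]
        return None

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ClinicalTable:
    """Per-sample survival and clinical covariates.

    ``table`` is indexed by sample id with columns ``time`` (years, > 0),
    ``event`` (0/1) and optional covariates (age, grade, stage).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate sample id in clinical table: {dup!r}")
        for col in ("time", "event"):
            if col not in t.columns:
                raise FormatError(f"clinical table missing required column {col!r}")
        time = t["time"].to_numpy(dtype=float)
        if not np.isfinite(time).all() or (time <= 0).any():
            raise FormatError("clinical 'time' must be finite and > 0")
        ev = t["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise FormatError("clinical 'event' must be 0 or 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def time(self) -> pd.Series:
        return self.table["time"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.table["event"].astype(int)

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)])


@dataclass
class ScorePanel:
    """Generic per-sample score matrix (immune cell types or drugs) plus provenance.

    ``source_label`` records which upstream method produced the scores
    (e.g. "TIMER", "CIBERSORT", "pRRophetic"); the pipeline only consumes them.
    """

    values: pd.DataFrame  # features x samples
    source_label: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise FormatError("duplicate feature id in score panel")
        if v.columns.duplicated().any():
            raise FormatError("duplicate sample id in score panel")
        if len(v) and not np.isfinite(v.to_numpy(dtype=float)).all():
            raise FormatError("non-finite value in score panel")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class PairFeatureMatrix:
    """Binary pair-indicator matrix: one row per ordered lncRNA pair (B, C).

    The indicator for pair (B, C) in sample s is 1 iff expr(B, s) > expr(C, s).
    Pairs are stored in canonical orientation (B lexicographically < C) under
    the row id ``"B|C"``. ``frequency`` is the row mean of the indicator.
    """

    indicators: pd.DataFrame  # pairs x samples, entries in {0, 1}
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.indicators.to_numpy()
        if len(arr) and not np.isin(arr, [0, 1]).all():
            raise FormatError("pair indicators must be 0 or 1")
        if not self.pairs:
            self.pairs = [tuple(pid.split("|", 1)) for pid in self.indicators.index]
        seen = set()
        for b, c in self.pairs:
            if b == c:
                raise FormatError(f"self-pair {b!r}")
            if (c, b) in seen:
                raise FormatError(f"pair ({b}, {c}) present in both orientations")
            seen.add((b, c))

    @property
    def pair_ids(self) -> pd.Index:
        return self.indicators.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.indicators.columns

    @property
    def frequency(self) -> pd.Series:
        return self.indicators.mean(axis=1)

    def subset_pairs(self, pair_ids) -> "PairFeatureMatrix":
        ids = list(pair_ids)
        sub = self.indicators.loc[ids]
        pairs = [tuple(pid.split("|", 1)) for pid in ids]
        return PairFeatureMatrix(sub, pairs)
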