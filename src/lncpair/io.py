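"""Readers, writers and validation for the standard-format pipeline inputs.

Formats: expression / clinical / score-panel tables are UTF-8 TSV with a
header row; the annotation is standard 9-column GTF (``gene_biotype`` and
``gene_type`` attribute spellings both accepted); gene lists are plain text,
one identifier per line, ``#`` comments allowed.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pyranges

from .containers import ClinicalTable, ExpressionMatrix, GeneAnnotation, ScorePanel
from .errors import FormatError, PipelineError

logger = logging.getLogger(__name__)

#: Ensembl biotypes treated as lncRNA by default; the annotation source only
#: partitions into "lncRNA vs protein_coding", so the set is configurable.
DEFAULT_LNC_BIOTYPES = frozenset(
    {
        "lncRNA",
        "lincRNA",
        "antisense",
        "processed_transcript",
        "sense_intronic",
        "sense_overlapping",
    }
)


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty matrix")
    return df


def read_expression_matrix(path: str | Path, group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a genes x samples TSV and validate it into an :class:`ExpressionMatrix`.

    ``group_map`` assigns each sample id a "tumor"/"normal" label. Rows with
    negative or non-numeric entries are rejected with a located error.
    """
    df = _read_tsv_matrix(path)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} at gene "
                f"{df.index[bad][0]!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value in row for gene {gene!r} (ragged row?)")
    missing = [s for s in df.columns if s not in group_map]
    if missing:
        raise FormatError(f"{path}: sample {missing[0]!r} has no entry in the group map")
    groups = pd.Series({s: group_map[s] for s in df.columns})
    return ExpressionMatrix(df.astype(float), groups)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read gene records from a GTF file into a gene_id -> biotype/name map."""
    gr = pyranges.read_gtf(str(path))
    df = gr.df
    df = df[df["Feature"] == "gene"] if "Feature" in df.columns else df
    if "gene_id" not in df.columns or df.empty:
        raise FormatError(f"{path}: no gene records with a gene_id attribute")
    if "gene_biotype" in df.columns and "gene_type" in df.columns:
        biotype = df["gene_biotype"].fillna(df["gene_type"])
    elif "gene_biotype" in df.columns:
        biotype = df["gene_biotype"]
    elif "gene_type" in df.columns:
        biotype = df["gene_type"]
    else:
        raise FormatError(f"{path}: neither gene_biotype nor gene_type attribute present")
    name = df["gene_name"] if "gene_name" in df.columns else df["gene_id"]
    table = pd.DataFrame(
        {"biotype": biotype.to_numpy(), "gene_name": name.to_numpy()},
        index=pd.Index(df["gene_id"].to_numpy(), name="gene_id"),
    )
    table = table[~table.index.duplicated(keep="first")]
    return GeneAnnotation(table)


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    """Emit one GTF gene line per annotated gene (synthetic coordinates)."""
    with open(path, "w") as fh:
        for i, (gid, row) in enumerate(ann.table.iterrows()):
            start = 1000 * i + 1
            attrs = (
                f'gene_id "{gid}"; gene_name "{row.gene_name}"; '
                f'gene_biotype "{row.biotype}";'
            )
            fh.write(
                f"chr1\tlncpair\tgene\t{start}\t{start + 500}\t.\t+\t.\t{attrs}\n"
            )


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list (one id per line, '#' comments) into a set."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    if not ids:
        raise FormatError(f"{path}: gene list is empty")
    return ids


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(set(ids)):
            fh.write(f"{gid}\n")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = _read_tsv_matrix(path)
    return ClinicalTable(df)


def write_clinical_table(clin: ClinicalTable, path: str | Path) -> None:
    clin.table.to_csv(path, sep="\t", index_label="sample_id")


def read_score_panel(path: str | Path, source_label: str = "") -> ScorePanel:
    df = _read_tsv_matrix(path)
    return ScorePanel(df.astype(float), source_label=source_label)


def write_score_panel(panel: ScorePanel, path: str | Path) -> None:
    panel.values.to_csv(path, sep="\t", index_label="feature_id")


def partition_by_biotype(
    expr: ExpressionMatrix,
    ann: GeneAnnotation,
    lnc_biotypes: frozenset[str] | set[str] = DEFAULT_LNC_BIOTYPES,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split an expression matrix into (lncRNA, mRNA) submatrices by biotype.

    Genes with a biotype in ``lnc_biotypes`` go to the lncRNA partition,
    ``protein_coding`` genes to the mRNA partition; everything else (including
    unannotated genes) is dropped with a logged count.
    """
    lnc_ids, mrna_ids, dropped = [], [], 0
    for gid in expr.gene_ids:
        bt = ann.biotype_of(gid)
        if bt is None:
            logger.warning("gene %s absent from annotation; excluded", gid)
            dropped += 1
        elif bt in lnc_biotypes:
            lnc_ids.append(gid)
        elif bt == "protein_coding":
            mrna_ids.append(gid)
        else:
            dropped += 1
    if dropped:
        logger.info("partition_by_biotype: %d gene(s) dropped (unannotated or other biotype)", dropped)
    if not lnc_ids:
        raise PipelineError("biotype partition produced an empty lncRNA set; nothing to screen")
    return expr.subset_genes(lnc_ids), expr.subset_genes(mrna_ids)


def match_samples(
    expr: ExpressionMatrix, clin: ClinicalTable, strict: bool = False
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Align expression and clinical tables on their shared sample ids.

    In strict mode any expression sample missing clinical data is an error;
    in tolerant mode the intersection is taken with a logged count.
    """
    shared = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    n_lost = len(expr.sample_ids) - len(shared)
    if strict and n_lost:
        missing = [s for s in expr.sample_ids if s not in set(clin.sample_ids)]
        raise FormatError(f"{n_lost} expression sample(s) missing clinical data, e.g. {missing[0]!r}")
    if n_lost:
        logger.info("match_samples: dropped %d expression sample(s) without clinical data", n_lost)
    if not shared:
        raise PipelineError("no samples shared between expression and clinical tables")
    return expr.subset_samples(shared), clin.subset(shared)


def check_finite_scores(values: np.ndarray, where: str) -> None:
    if not np.isfinite(values).all():
        raise FormatError(f"non-finite value in {where}")
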