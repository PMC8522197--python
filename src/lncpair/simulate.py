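"""Synthetic TCGA-like cohort generator.

Emits everything the pipeline consumes — an FPKM-like expression matrix over
mRNAs and lncRNAs with tumor/normal labels, a GTF annotation, an immune gene
list, a clinical/survival table, and immune-infiltration / drug-IC50 score
panels — with known planted structure so every downstream stage can be
tested without external data:

* immune-linked lncRNAs are generated on the log2 scale as their parent
  immune mRNA's deviation plus noise, so their correlation clears the
  co-expression screen in expectation;
* planted DE lncRNAs carry a configured tumor-vs-normal log2 shift;
* planted prognostic pairs are pairs of DE, immune-linked lncRNAs whose
  members share a parent and a mean, so the pair indicator is an
  informative coin flip per tumor sample; survival times follow a Weibull
  (default exponential) proportional-hazards model whose linear predictor
  is the sum of those indicators times the planted log hazard ratios, with
  independent exponential censoring truncated at ``max_followup``;
* score panels get a configurable mean shift between samples above and
  below the median of the true linear predictor.

Which genes are DE / immune-linked and which pairs are prognostic is a
deterministic function of the configuration (a first-index convention); the
seed drives only the random draws. Two cohorts simulated from the same
configuration with different seeds therefore share the planted pairs, which
is what makes held-out validation of a recovered model possible.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    NORMAL,
    TUMOR,
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotation,
    ScorePanel,
)
from .errors import ConfigurationError
from . import io as lio

CHECKPOINT_GENES = ("DDR2", "HAVCR2", "LAG3", "CTLA4")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults are a reduced-scale cohort (60 tumor + 15 normal; 300 mRNA of
    which 50 immune; 150 lncRNA) that keeps the full pipeline fast while
    preserving the statistical structure of the real design.
    """

    n_tumor: int = 60
    n_normal: int = 15
    n_mrna: int = 300
    n_lncrna: int = 150
    n_immune_mrna: int = 50
    n_immune_linked_lncrna: int = 40
    n_de_lncrna: int = 20
    n_prognostic_pairs: int = 3
    planted_log_hazard_ratios: tuple[float, ...] = (1.0, 1.25, 1.5)
    planted_log2fc: float = 3.0
    de_fraction_up: float = 0.8
    baseline_hazard: float = 0.10  # events per year at linear predictor 0
    censoring_rate: float = 0.08  # exponential censoring, per year
    max_followup: float = 10.0  # years; administrative truncation
    weibull_shape: float = 1.0  # 1.0 = exponential baseline
    noise_sd: float = 0.5  # log2-scale residual noise of linked lncRNAs
    gene_sd: float = 1.0  # log2-scale between-sample spread per gene
    link_slope: float = 1.3  # log2-scale loading of a linked lncRNA on its parent
    n_infiltration_features: int = 12
    n_shifted_infiltration: int = 4
    infiltration_shift: float = 1.5  # in panel SD units, high- minus low-risk
    n_drugs: int = 8
    n_shifted_drugs: int = 4
    drug_shift: float = 1.5  # IC50 shift; half the shifted drugs go each way
    checkpoint_shift: float = 1.5  # log2 shift of DDR2/HAVCR2 in high-risk
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
            "n_mrna": self.n_mrna,
            "n_lncrna": self.n_lncrna,
            "n_immune_mrna": self.n_immune_mrna,
            "n_immune_linked_lncrna": self.n_immune_linked_lncrna,
            "n_de_lncrna": self.n_de_lncrna,
            "n_prognostic_pairs": self.n_prognostic_pairs,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v}")
        if self.n_immune_mrna > self.n_mrna:
            raise ConfigurationError("n_immune_mrna cannot exceed n_mrna")
        if self.n_immune_linked_lncrna > self.n_lncrna:
            raise ConfigurationError("n_immune_linked_lncrna cannot exceed n_lncrna")
        if self.n_de_lncrna > self.n_lncrna:
            raise ConfigurationError("n_de_lncrna cannot exceed n_lncrna")
        if len(self.planted_log_hazard_ratios) != self.n_prognostic_pairs:
            raise ConfigurationError(
                "planted_log_hazard_ratios length must equal n_prognostic_pairs"
            )
        n_up = self.n_de_lncrna - int(np.floor((1 - self.de_fraction_up) * self.n_de_lncrna))
        if 2 * self.n_prognostic_pairs > min(self.n_de_lncrna,
                                             self.n_immune_linked_lncrna, n_up):
            raise ConfigurationError(
                "prognostic pairs need 2*n_prognostic_pairs up-regulated, "
                "immune-linked, DE lncRNAs"
            )
        for name in ("baseline_hazard", "censoring_rate", "max_followup",
                     "weibull_shape", "noise_sd", "gene_sd", "link_slope"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    # -- structural truth: deterministic in the config ----------------------
    def lnc_ids(self) -> list[str]:
        return [f"LNC{i + 1:04d}" for i in range(self.n_lncrna)]

    def mrna_ids(self) -> list[str]:
        base = [f"MRNA{i + 1:04d}" for i in range(self.n_mrna)]
        return base + list(CHECKPOINT_GENES)

    def immune_gene_ids(self) -> list[str]:
        return [f"MRNA{i + 1:04d}" for i in range(self.n_immune_mrna)]

    def immune_linked_lncrnas(self) -> dict[str, str]:
        """lncRNA id -> parent immune mRNA id."""
        immune = self.immune_gene_ids()
        out: dict[str, str] = {}
        for j in range(self.n_immune_linked_lncrna):
            out[f"LNC{j + 1:04d}"] = immune[(j // 2) % len(immune)]
        return out

    def de_lncrnas(self) -> dict[str, float]:
        """lncRNA id -> planted log2 fold change (tumor minus normal)."""
        n_down = int(np.floor((1 - self.de_fraction_up) * self.n_de_lncrna))
        out: dict[str, float] = {}
        for j in range(self.n_de_lncrna):
            sign = -1.0 if j >= self.n_de_lncrna - n_down else 1.0
            out[f"LNC{j + 1:04d}"] = sign * self.planted_log2fc
        return out

    def planted_pairs(self) -> list[tuple[str, str]]:
        """Prognostic pairs: consecutive DE, immune-linked lncRNAs sharing a parent."""
        return [
            (f"LNC{2 * k + 1:04d}", f"LNC{2 * k + 2:04d}")
            for k in range(self.n_prognostic_pairs)
        ]


@dataclass
class SyntheticCohort:
    """A generated cohort plus the record of everything that was planted."""

    expression: ExpressionMatrix
    annotation: GeneAnnotation
    immune_genes: set[str]
    clinical: ClinicalTable
    infiltration: ScorePanel
    drug_scores: ScorePanel
    truth: dict
    config: SimulationConfig = field(repr=False, default=None)


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a fully synthetic cohort under the configured study conditions."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_t, n_n = config.n_tumor, config.n_normal
    tumor_ids = [f"TUM{i + 1:04d}" for i in range(n_t)]
    normal_ids = [f"NOR{i + 1:04d}" for i in range(n_n)]
    samples = tumor_ids + normal_ids
    n = n_t + n_n
    is_tumor = np.array([True] * n_t + [False] * n_n)

    mrna_ids = config.mrna_ids()
    lnc_ids = config.lnc_ids()
    immune_ids = config.immune_gene_ids()
    linked = config.immune_linked_lncrnas()
    de = config.de_lncrnas()
    pairs = config.planted_pairs()
    betas = np.asarray(config.planted_log_hazard_ratios, dtype=float)

    # --- mRNA compartment (log2 scale) ---
    mu_m = rng.uniform(3.0, 7.0, size=len(mrna_ids))
    log_m = mu_m[:, None] + config.gene_sd * rng.standard_normal((len(mrna_ids), n))
    m_index = {g: i for i, g in enumerate(mrna_ids)}
    # centred deviations of the immune parents, reused by linked lncRNAs
    dev_m = log_m - mu_m[:, None]

    # --- lncRNA compartment ---
    mu_l = rng.uniform(3.0, 7.0, size=len(lnc_ids))
    pair_members = {g for bc in pairs for g in bc}
    # pair members share a mean so the pair indicator is balanced across samples
    for b, c in pairs:
        mu_l[lnc_ids.index(c)] = mu_l[lnc_ids.index(b)]
    log_l = np.empty((len(lnc_ids), n))
    for i, g in enumerate(lnc_ids):
        if g in linked:
            parent = dev_m[m_index[linked[g]]]
            eps = config.noise_sd * rng.standard_normal(n)
            log_l[i] = mu_l[i] + config.link_slope * parent + eps
        else:
            log_l[i] = mu_l[i] + config.gene_sd * rng.standard_normal(n)
        if g in de:
            log_l[i, is_tumor] += de[g]

    # --- true pair indicators and hazard linear predictor (tumor samples) ---
    def _lnc(g):
        return log_l[lnc_ids.index(g)]

    indicators = np.stack([( _lnc(b) > _lnc(c)).astype(float) for b, c in pairs])
    eta = (betas @ indicators[:, :n_t]) if len(pairs) else np.zeros(n_t)

    # --- checkpoint genes: group-shifted protein-coding expression ---
    truth_high = eta > np.median(eta) if eta.std() > 0 else np.zeros(n_t, dtype=bool)
    for g, shift in zip(CHECKPOINT_GENES[:2], [config.checkpoint_shift] * 2):
        row = m_index[g]
        log_m[row, :n_t][truth_high] += shift

    # --- survival with exponential censoring, truncated at max_followup ---
    rate = config.baseline_hazard * np.exp(eta)
    u = rng.exponential(1.0, size=n_t)
    t_event = (u / rate) ** (1.0 / config.weibull_shape)
    t_cens = rng.exponential(1.0 / config.censoring_rate, size=n_t)
    t_obs = np.minimum(np.minimum(t_event, t_cens), config.max_followup)
    event = (t_event <= t_cens) & (t_event <= config.max_followup)
    t_obs = np.maximum(t_obs, 1e-6)

    age = np.clip(rng.normal(68.0, 10.0, size=n_t), 30, 95).round(1)
    grade = rng.choice(["low", "high"], size=n_t, p=[0.35, 0.65])
    stage = rng.choice(["I", "II", "III", "IV"], size=n_t, p=[0.1, 0.3, 0.35, 0.25])
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time": t_obs,
                "event": event.astype(int),
                "age": age,
                "grade": grade,
                "stage": stage,
            },
            index=pd.Index(tumor_ids, name="sample_id"),
        )
    )

    # --- expression matrix, annotation, immune list ---
    values = pd.DataFrame(
        np.vstack([2.0 ** log_m, 2.0 ** log_l]),
        index=pd.Index(mrna_ids + lnc_ids, name="gene_id"),
        columns=samples,
    )
    groups = pd.Series(np.where(is_tumor, TUMOR, NORMAL), index=values.columns)
    expression = ExpressionMatrix(values, groups)
    ann = GeneAnnotation(
        pd.DataFrame(
            {
                "biotype": ["protein_coding"] * len(mrna_ids) + ["lncRNA"] * len(lnc_ids),
                "gene_name": mrna_ids + lnc_ids,
            },
            index=pd.Index(mrna_ids + lnc_ids, name="gene_id"),
        )
    )

    # --- score panels with group shifts on the truth split ---
    def _panel(prefix, n_feat, n_shifted, shift, two_sided):
        feats = [f"{prefix}{i + 1:02d}" for i in range(n_feat)]
        vals = rng.standard_normal((n_feat, n_t))
        directions = {}
        for i in range(min(n_shifted, n_feat)):
            sgn = -1.0 if (two_sided and i % 2 == 1) else 1.0
            if truth_high.any():
                vals[i, truth_high] += sgn * shift
            directions[feats[i]] = "up_in_high" if sgn > 0 else "down_in_high"
        df = pd.DataFrame(vals, index=pd.Index(feats, name="feature_id"),
                          columns=tumor_ids)
        return df, directions

    inf_df, inf_truth = _panel("CELL", config.n_infiltration_features,
                               config.n_shifted_infiltration,
                               config.infiltration_shift, two_sided=False)
    drug_df, drug_truth = _panel("DRUG", config.n_drugs, config.n_shifted_drugs,
                                 config.drug_shift, two_sided=True)

    truth = {
        "de_lncrnas": de,
        "immune_linked": linked,
        "planted_pairs": [f"{b}|{c}" for b, c in pairs],
        "planted_log_hazard_ratios": list(map(float, betas)),
        "pair_indicators": {
            f"{b}|{c}": indicators[k, :n_t].astype(int).tolist()
            for k, (b, c) in enumerate(pairs)
        },
        "linear_predictor": eta.tolist(),
        "truth_high": truth_high.astype(bool).tolist(),
        "shifted_infiltration": inf_truth,
        "shifted_drugs": drug_truth,
        "shifted_checkpoint_genes": {g: config.checkpoint_shift
                                     for g in CHECKPOINT_GENES[:2]},
    }
    return SyntheticCohort(
        expression=expression,
        annotation=ann,
        immune_genes=set(immune_ids),
        clinical=clinical,
        infiltration=ScorePanel(inf_df, source_label="synthetic-infiltration"),
        drug_scores=ScorePanel(drug_df, source_label="synthetic-IC50"),
        truth=truth,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, str]:
    """Write the cohort in the same on-disk formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "sample_groups": outdir / "sample_groups.tsv",
        "annotation": outdir / "annotation.gtf",
        "immune_genes": outdir / "immune_genes.txt",
        "clinical": outdir / "clinical.tsv",
        "infiltration": outdir / "infiltration.tsv",
        "drug_scores": outdir / "drug_scores.tsv",
        "truth": outdir / "truth.json",
    }
    lio.write_expression_matrix(cohort.expression, paths["expression"])
    cohort.expression.sample_group.rename("group").to_csv(
        paths["sample_groups"], sep="\t", index_label="sample_id"
    )
    lio.write_gene_annotation(cohort.annotation, paths["annotation"])
    lio.write_gene_list(cohort.immune_genes, paths["immune_genes"])
    lio.write_clinical_table(cohort.clinical, paths["clinical"])
    lio.write_score_panel(cohort.infiltration, paths["infiltration"])
    lio.write_score_panel(cohort.drug_scores, paths["drug_scores"])
    payload = dict(cohort.truth)
    payload["config"] = dataclasses.asdict(cohort.config)
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
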