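"""Config-driven orchestration of the full analysis.

A single YAML config (or :class:`PipelineConfig`) drives: synthetic cohort
generation (or reading of on-disk inputs) -> immune/DE screening -> pair
construction -> model selection -> survival evaluation -> immune and drug
association, writing every stage table plus a machine-readable run manifest.
Reruns with the same config and seed produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as lio
from .associate import (
    DEFAULT_CHECKPOINT_GENES,
    checkpoint_gene_association,
    drug_sensitivity_group_test,
    panel_group_test,
    score_correlation,
)
from .containers import TUMOR
from .errors import ConfigurationError, PipelineError
from .evaluate import clinical_association_tests, clinical_cox_models
from .model import PairRiskCox
from .pairs import build_pair_matrix, filter_pairs_by_frequency
from .screen import de_ir_lncrnas, differential_expression, immune_correlation_screen
from .simulate import SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger("lncpair.pipeline")

STAGES = ("simulate", "screen", "pairing", "fit", "evaluate", "associate")


@dataclass
class PipelineConfig:
    """All pipeline thresholds (printed defaults) plus input locations."""

    seed: int = 0
    outdir: str = "lncpair_out"
    simulate: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)  # paths, if not simulating
    r_threshold: float = 0.5
    corr_p_threshold: float = 0.05
    corr_method: str = "pearson"
    corr_transform: str = "log2"
    logfc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    freq_lo: float = 0.2
    freq_hi: float = 0.8
    alpha: float = 0.05
    n_cycles: int = 1000
    count_threshold: int = 100
    subsample_frac: float = 0.8
    cv_folds: int = 5
    eval_time: float = 1.0
    eval_times: tuple[float, ...] = (1.0, 3.0, 5.0)
    covariates: tuple[str, ...] = ("age", "grade", "stage")
    checkpoint_genes: tuple[str, ...] = DEFAULT_CHECKPOINT_GENES
    pair_sample_set: str = "tumor"  # pairs built on tumor samples only

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("r_threshold", 0.0, 1.0),
            ("corr_p_threshold", 0.0, 1.0),
            ("fdr_threshold", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
            ("subsample_frac", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ConfigurationError(f"{name}={v} outside ({lo}, {hi}]")
        if not (0.0 <= self.freq_lo < self.freq_hi <= 1.0):
            raise ConfigurationError("frequency bounds must satisfy 0 <= lo < hi <= 1")
        if self.logfc_threshold < 0:
            raise ConfigurationError("logfc_threshold must be >= 0")
        if self.n_cycles <= 0 or self.count_threshold < 0:
            raise ConfigurationError("n_cycles must be > 0 and count_threshold >= 0")
        if self.pair_sample_set not in ("tumor", "all"):
            raise ConfigurationError("pair_sample_set must be 'tumor' or 'all'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        for tup in ("eval_times", "covariates", "checkpoint_genes"):
            if tup in raw and raw[tup] is not None:
                raw[tup] = tuple(raw[tup])
        cfg = cls(**raw)
        if sim is not None:
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            bad = set(sim) - sim_known
            if bad:
                raise ConfigurationError(f"unknown simulate key(s): {sorted(bad)}")
            if "planted_log_hazard_ratios" in sim:
                sim["planted_log_hazard_ratios"] = tuple(sim["planted_log_hazard_ratios"])
            cfg.simulate = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where outputs land does not change what they are
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_cohort(cfg: PipelineConfig):
    """Simulate the cohort or read all inputs named in the config."""
    if cfg.simulate is not None:
        sim = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        return simulate_cohort(sim), None
    required = ("expression", "sample_groups", "annotation", "immune_genes", "clinical")
    missing = [k for k in required if k not in cfg.inputs]
    if missing:
        raise ConfigurationError(f"config missing input path(s): {missing}")
    for key, path in cfg.inputs.items():
        if not Path(path).exists():
            raise ConfigurationError(f"input {key!r} does not exist: {path}")
    groups = pd.read_csv(cfg.inputs["sample_groups"], sep="\t", index_col=0)["group"]
    expr = lio.read_expression_matrix(cfg.inputs["expression"], groups.to_dict())
    ann = lio.read_gene_annotation(cfg.inputs["annotation"])
    immune = lio.read_gene_list(cfg.inputs["immune_genes"])
    clin = lio.read_clinical_table(cfg.inputs["clinical"])
    inf = (lio.read_score_panel(cfg.inputs["infiltration"], "infiltration")
           if "infiltration" in cfg.inputs else None)
    drugs = (lio.read_score_panel(cfg.inputs["drug_scores"], "drug-IC50")
             if "drug_scores" in cfg.inputs else None)
    from .simulate import SyntheticCohort  # reuse the bundle type for loaded data

    cohort = SyntheticCohort(
        expression=expr, annotation=ann, immune_genes=immune, clinical=clin,
        infiltration=inf, drug_scores=drugs, truth={}, config=None,
    )
    return cohort, cfg.inputs


def validate_config(cfg: PipelineConfig) -> dict:
    """Check all inputs and return a manifest of what was found."""
    cohort, _ = _load_cohort(cfg)
    lnc, mrna = lio.partition_by_biotype(cohort.expression, cohort.annotation)
    return {
        "config_hash": cfg.config_hash(),
        "n_samples": len(cohort.expression.sample_ids),
        "n_tumor": len(cohort.expression.samples_in_group(TUMOR)),
        "n_genes": len(cohort.expression.gene_ids),
        "n_lncrna": len(lnc.gene_ids),
        "n_mrna": len(mrna.gene_ids),
        "n_immune_genes": len(cohort.immune_genes),
        "n_clinical": len(cohort.clinical.sample_ids),
    }


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig,
                 index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# lncpair v{__version__} config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def run_pipeline(cfg: PipelineConfig, stop_after: str = "associate") -> dict:
    """Execute the pipeline through ``stop_after`` and write stage outputs.

    Returns the run manifest (also written to ``manifest.json``).
    """
    if stop_after not in STAGES:
        raise ConfigurationError(f"unknown stage {stop_after!r}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("lncpair").addHandler(fh)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "seed": int(cfg.seed),
        "counts": {},
        "outputs": [],
    }
    counts = manifest["counts"]

    def _done(stage: str) -> bool:
        return STAGES.index(stop_after) <= STAGES.index(stage)

    try:
        # -- simulate / load ------------------------------------------------
        cohort, _ = _load_cohort(cfg)
        if cfg.simulate is not None:
            paths = write_cohort(cohort, outdir / "inputs")
            manifest["outputs"] += sorted(paths.values())
        counts["samples"] = len(cohort.expression.sample_ids)
        counts["genes"] = len(cohort.expression.gene_ids)
        if _done("simulate"):
            return _finish(manifest, outdir, cfg)

        # -- screen ---------------------------------------------------------
        lnc, mrna = lio.partition_by_biotype(cohort.expression, cohort.annotation)
        immune_present = sorted(cohort.immune_genes & set(mrna.gene_ids))
        if not immune_present:
            raise PipelineError("no immune genes present in the mRNA compartment")
        immune_mrna = mrna.subset_genes(immune_present)
        counts["lncrnas"] = len(lnc.gene_ids)
        counts["mrnas"] = len(mrna.gene_ids)
        counts["immune_mrnas"] = len(immune_mrna.gene_ids)

        corr = immune_correlation_screen(
            lnc, immune_mrna, cfg.r_threshold, cfg.corr_p_threshold,
            cfg.corr_method, cfg.corr_transform,
        )
        de = differential_expression(lnc, cfg.logfc_threshold, cfg.fdr_threshold)
        de_ir = de_ir_lncrnas(corr, de)
        counts["ir_lncrnas"] = int(corr["passed"].sum())
        counts["de_lncrnas"] = int(de["passed"].sum())
        counts["de_ir_lncrnas"] = len(de_ir)
        _write_table(corr, outdir / "ir_lncrna.tsv", cfg, "lncrna_id")
        _write_table(de, outdir / "de_ir_lncrna.tsv", cfg, "gene_id")
        manifest["outputs"] += [str(outdir / "ir_lncrna.tsv"), str(outdir / "de_ir_lncrna.tsv")]
        logger.info("screen: %d ir-lncRNAs, %d DE, %d DE-ir", counts["ir_lncrnas"],
                    counts["de_lncrnas"], counts["de_ir_lncrnas"])
        if _done("screen"):
            return _finish(manifest, outdir, cfg)

        # -- pairing ----------------------------------------------------------
        if len(de_ir) < 2:
            raise PipelineError(f"only {len(de_ir)} DE-ir-lncRNA(s); cannot build pairs")
        expr_pairs = cohort.expression.subset_genes(de_ir)
        if cfg.pair_sample_set == "tumor":
            expr_pairs = expr_pairs.subset_samples(expr_pairs.samples_in_group(TUMOR))
        pm_all = build_pair_matrix(expr_pairs)
        pm = filter_pairs_by_frequency(pm_all, cfg.freq_lo, cfg.freq_hi)
        counts["pairs_built"] = len(pm_all.pair_ids)
        counts["pairs_after_filter"] = len(pm.pair_ids)
        out = pm.indicators.copy()
        out["frequency"] = pm.frequency
        _write_table(out, outdir / "pairs.tsv", cfg, "pair_id")
        manifest["outputs"].append(str(outdir / "pairs.tsv"))
        if _done("pairing"):
            return _finish(manifest, outdir, cfg)

        # -- model selection --------------------------------------------------
        clin = cohort.clinical.subset(
            [s for s in pm.sample_ids if s in set(cohort.clinical.sample_ids)]
        )
        model = PairRiskCox(
            pm, clin, alpha=cfg.alpha, n_cycles=cfg.n_cycles,
            count_threshold=cfg.count_threshold, subsample_frac=cfg.subsample_frac,
            cv_folds=cfg.cv_folds, eval_time=cfg.eval_time,
        )
        res = model.fit(seed=cfg.seed)
        counts["univariate_passed"] = int(res.univariate["passed"].sum())
        counts["lasso_selected"] = int(res.lasso_report.selected.sum())
        counts["model_size"] = res.risk_model.chosen_size
        groups = res.risk_scores["group"]
        counts["high_risk"] = int((groups == "high").sum())
        counts["low_risk"] = int((groups == "low").sum())
        _write_table(res.univariate, outdir / "univariate_cox.tsv", cfg, "pair_id")
        _write_table(res.lasso_report.counts.to_frame(), outdir / "lasso_counts.tsv",
                     cfg, "pair_id")
        _write_table(res.risk_scores, outdir / "risk_scores.tsv", cfg, "sample_id")
        res.to_json(outdir / "model.json")
        manifest["outputs"] += [
            str(outdir / n)
            for n in ("univariate_cox.tsv", "lasso_counts.tsv", "risk_scores.tsv", "model.json")
        ]
        logger.info("fit: %d univariate, %d lasso-selected, model size %d",
                    counts["univariate_passed"], counts["lasso_selected"],
                    counts["model_size"])
        if _done("fit"):
            return _finish(manifest, outdir, cfg)

        # -- evaluation -------------------------------------------------------
        km = res.km_logrank()
        km_rows = []
        for g, curve in km.survival.items():
            c = curve.copy()
            c.insert(0, "group", g)
            km_rows.append(c)
        _write_table(pd.concat(km_rows, ignore_index=True), outdir / "km.tsv", cfg, "row")
        manifest["outputs"].append(str(outdir / "km.tsv"))
        counts["logrank_chi2"] = round(km.logrank_chi2, 6)
        rocs = res.time_dependent_roc(eval_times=cfg.eval_times)
        for r in rocs:
            name = f"roc_{r.eval_time:g}.tsv"
            _write_table(r.roc_points, outdir / name, cfg, "point")
            manifest["outputs"].append(str(outdir / name))
            counts[f"auc_{r.eval_time:g}y"] = round(r.auc, 6)
        tests = clinical_association_tests(res.risk_scores, clin, cfg.covariates)
        _write_table(tests, outdir / "clinical_tests.tsv", cfg, "covariate")
        uni, multi = clinical_cox_models(res.risk_scores, clin, cfg.covariates)
        _write_table(uni, outdir / "cox_uni.tsv", cfg, "covariate")
        _write_table(multi, outdir / "cox_multi.tsv", cfg, "covariate")
        manifest["outputs"] += [str(outdir / n)
                                for n in ("clinical_tests.tsv", "cox_uni.tsv", "cox_multi.tsv")]
        if _done("evaluate"):
            return _finish(manifest, outdir, cfg)

        # -- immune / chemo associations --------------------------------------
        if cohort.infiltration is not None:
            assoc = panel_group_test(cohort.infiltration, res.risk_scores)
            rho = score_correlation(cohort.infiltration, res.risk_scores)
            assoc["rho"] = rho["rho"]
            _write_table(assoc, outdir / "immune_assoc.tsv", cfg, "feature_id")
            manifest["outputs"].append(str(outdir / "immune_assoc.tsv"))
            counts["immune_significant"] = int(assoc["significant"].sum())
        chk = [g for g in cfg.checkpoint_genes if g in set(cohort.expression.gene_ids)]
        if chk:
            tum = cohort.expression.subset_samples(
                cohort.expression.samples_in_group(TUMOR))
            chk_assoc = checkpoint_gene_association(tum, chk, res.risk_scores)
            _write_table(chk_assoc, outdir / "checkpoint_assoc.tsv", cfg, "gene_id")
            manifest["outputs"].append(str(outdir / "checkpoint_assoc.tsv"))
        if cohort.drug_scores is not None:
            drug = drug_sensitivity_group_test(cohort.drug_scores, res.risk_scores)
            _write_table(drug, outdir / "drug_assoc.tsv", cfg, "drug_id")
            manifest["outputs"].append(str(outdir / "drug_assoc.tsv"))
            counts["drugs_significant"] = int(drug["significant"].sum())
        return _finish(manifest, outdir, cfg)
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logging.getLogger("lncpair").removeHandler(fh)
        fh.close()


def _finish(manifest: dict, outdir: Path, cfg: PipelineConfig) -> dict:
    manifest["outputs"] = sorted(set(manifest["outputs"]))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline finished: %s", json.dumps(manifest["counts"], sort_keys=True))
    return manifest
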