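# lncpair

Prognostic modelling of tumor cohorts from **immune-related lncRNA pairs**.

Many published RNA-seq signatures depend on absolute expression values and
therefore on the platform, the units and the normalisation. `lncpair`
implements the alternative: for each pair of immune-related, differentially
expressed lncRNAs (B, C) the feature is the within-sample indicator

&nbsp;&nbsp;&nbsp;&nbsp;*A(B,C,s) = 1 if expr(B,s) > expr(C,s), else 0*

so the signature uses only the relative ordering of two genes inside one
sample and survives any per-sample monotone transform of expression. On top
of this encoding the package builds a Cox proportional-hazards risk score

&nbsp;&nbsp;&nbsp;&nbsp;*score(s) = Σᵢ βᵢ · Aᵢ(s)*

by a three-stage selection — univariate Cox screen (Wald P < 0.05),
repeated lasso-Cox over random subsamples (pairs kept when selected in
more than a threshold number of cycles), and a forward scan of nested Cox
models stopped at the maximal time-dependent AUC — then dichotomises
patients at the cutoff minimising the AIC of the binary-split Cox model.
The fitted model is validated by Kaplan–Meier/log-rank, IPCW time-dependent
ROC at 1/3/5 years and clinical Cox models, and associated with
immune-infiltration, checkpoint-gene and drug-sensitivity (predicted IC50)
panels through rank-based tests.

The package is aimed at computational oncology / biomarker researchers. A
fully synthetic TCGA-like cohort generator with planted ground truth
(`lncpair.simulate`) makes every stage testable without any data download.

## Worked example

```python
from lncpair import SimulationConfig, simulate_cohort, PairRiskCox
from lncpair import io as lio
from lncpair.screen import (immune_correlation_screen,
                            differential_expression, de_ir_lncrnas)

# synthetic cohort: 60 tumor + 15 normal, 3 planted prognostic pairs
co = simulate_cohort(SimulationConfig(seed=1))

# screen: immune-related (co-expression) AND differentially expressed lncRNAs
lnc, mrna = lio.partition_by_biotype(co.expression, co.annotation)
imm = mrna.subset_genes(sorted(co.immune_genes))
deir = de_ir_lncrnas(immune_correlation_screen(lnc, imm),
                     differential_expression(lnc))

# pair features on tumor samples, then the selection chain
tum = co.expression.subset_genes(deir)
tum = tum.subset_samples(tum.samples_in_group("tumor"))
model = PairRiskCox.from_expression(tum, co.clinical,
                                    n_cycles=50, count_threshold=5)
res = model.fit(seed=1)
print(res.summary())
```

prints

```
Pair risk Cox model
===================
candidate pairs:      91
univariate passed:    10
lasso selected:       10  (> 5/50 cycles)
chosen model size:    9
AUC at 1y:          0.914
risk-score cutoff:    2.6451 (aic)

pair                          beta        HR
LNC0005|LNC0006             1.2752    3.5794
LNC0005|LNC0017             0.3701    1.4479
LNC0003|LNC0004             0.8584    2.3595
LNC0001|LNC0002             0.8186    2.2672
...
high-risk: 25   low-risk: 35
```

91 frequency-filtered pairs were screened down to a 9-pair model whose
1-year IPCW AUC is 0.914; the three planted pairs (`LNC0001|LNC0002`,
`LNC0003|LNC0004`, `LNC0005|LNC0006`) are all recovered with positive
coefficients, and the AIC cutoff 2.645 splits the cohort 25/35. Validation
hangs off the results object:

```python
km = res.km_logrank()            # log-rank chi2 = 46.41, p = 9.6e-12
for r in res.time_dependent_roc():
    print(r.eval_time, r.auc)    # 1y 0.914, 3y 0.889, 5y 0.874
```

## Command line

The same pipeline runs from a YAML config:

```bash
lncpair run-all --config config.yaml --seed 1 --outdir out/
```

with subcommands `simulate | validate | screen | fit | evaluate |
associate` for individual stages. A minimal config for a synthetic run is

```yaml
seed: 1
outdir: out
simulate: {}          # or an `inputs:` block with file paths
n_cycles: 50
count_threshold: 5
```

Every stage writes a TSV stamped with the config hash and seed, plus a
deterministic `manifest.json`; two runs with the same config and seed are
byte-identical.

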