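# gcsubtype

Molecular subtyping of gastric cancer into a **mesenchymal phenotype (MP)**
and an **epithelial phenotype (EP)**, as a tested, reusable Python pipeline.
It is aimed at computational biologists who work with bulk expression
cohorts and need the full chain from unsupervised subtype discovery to a
portable classifier and treatment-interaction survival analysis — together
with a ground-truthed synthetic multi-cohort generator for validating every
stage.

## What it computes

Gastric adenocarcinomas that have undergone epithelial-to-mesenchymal
transition form a clinically distinct group: poorer survival, resistance to
adjuvant chemotherapy, lower somatic mutation rates, and higher stromal
content. The pipeline identifies and exploits this dichotomy:

1. **Discovery** — genes with ≥ 2-fold deviation from their median in ≥ 15
   samples are clustered (centered Pearson distance, average linkage); the
   smaller of the two sample clusters is the MP group. GIST-like mesenchymal
   outgroup samples co-cluster with MP.
2. **Signature** — two independent two-sample *t*-test lists (MP vs EP, and
   MP vs non-tumor mucosa), each at raw *P* < 0.001, are intersected and
   restricted to ≥ 2-fold MP−EP differences. Gene weights are the MP-vs-EP
   *t* statistics.
3. **Classification** — the Bayesian compound covariate predictor (BCCP).
   Each sample gets a scalar score
   `c = Σ_g t_g · z_g` over signature genes (z-scored expression), modeled
   per class as Gaussian with pooled SD σ, giving

   `P(MP | c) = π_MP N(c; μ_MP, σ) / Σ_k π_k N(c; μ_k, σ)`

   Robustness is estimated by leave-one-out cross-validation with honest
   in-fold re-derivation of the signature, and by concordance (Cohen's κ)
   with an independent linear SVM.
4. **Survival** — Kaplan–Meier / log-rank comparisons per cohort and per
   AJCC stage, multivariate Cox proportional-hazards regression (Efron or
   Breslow ties, likelihood-ratio tests), and the subtype × chemotherapy
   interaction model `h(t | x) = h₀(t) exp(β₁·MP + β₂·CTX + β₃·MP·CTX +
   β₄·sex + β₅·age + β₆·stage)` on the stage II–IV, non-metastatic subset.
5. **Stromal adjustment** — two-reference constrained least-squares tumor
   fractions (`y ≈ p·tumor_ref + (1−p)·normal_ref`) and removal of the
   stromal contribution, in both the published multiply-by-purity form and
   a model-based mixture inversion.
6. **Cross-cohort analysis** — genes significant with a consistent MP−EP
   direction in *every* cohort, ratio ranking, promoter-methylation vs
   expression Pearson correlation, and hypermutation calls at the strict
   \> 11.4 mutations/Mb threshold.

The `simulate` module generates multi-cohort expression (with batch shifts
and Beta-distributed stromal contamination), clinical tables with
exponential proportional-hazards survival and a planted subtype × chemo
interaction, methylation β-values and mutation rates — all with a recorded
ground truth, so recovery is testable.

## Worked example

```python
from gcsubtype import PipelineConfig, run_end_to_end

report = run_end_to_end(PipelineConfig(
    simulation={"n_cohorts": 2, "samples_per_cohort": 80,
                "n_genes": 1000, "n_signature_genes": 80},
    seed=7))
s = report["stages"]
print("signature genes:", s["signature"]["n_genes"])
print("LOOCV misclassification:", s["loocv"]["misclassification_rate"])
print("validation RFS log-rank p:", s["validation"]["cohort_1"]["logrank_p_rfs"])
print("pooled MP hazard ratio:", round(s["multivariate_cox"]["hr_mp"], 2))
print("chemo HR in EP:", round(s["interaction"]["hr_chemo_ep"], 2),
      " in MP:", round(s["interaction"]["hr_chemo_mp"], 2))
```

prints

```
signature genes: 80
LOOCV misclassification: 0.0
validation RFS log-rank p: 0.00606815741683083
pooled MP hazard ratio: 3.28
chemo HR in EP: 0.46  in MP: 1.01
```

Read: all 80 planted signature genes were recovered, the classifier
transfers to the held-out cohort (predicted subtypes split recurrence-free
survival at p ≈ 0.006), and chemotherapy halves the recurrence hazard in EP
tumors while doing nothing in MP tumors — the planted treatment
interaction. The pooled marginal MP hazard ratio (3.3) exceeds the planted
conditional value (2.0) because MP tumors additionally forgo the
EP-specific chemotherapy benefit.

The same workflow is available from the shell:

```sh
gcsubtype simulate --seed 7 --outdir study/
gcsubtype discover --expression study/cohort0_expression.tsv \
    --clinical study/cohort0_clinical.tsv --out labels.tsv --newick tree.nwk
gcsubtype report --seed 7 --outdir out/
```

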