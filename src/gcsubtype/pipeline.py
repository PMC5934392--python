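"""End-to-end orchestration: simulate/load -> preprocess -> discover ->
signature -> BCCP train/LOOCV -> validation prediction -> survival ->
interaction -> conserved genes -> stromal adjustment.

The first cohort is the training (exploration) cohort; subtypes there come
from unsupervised clustering, and every other cohort is labeled by the
trained BCCP classifier.  The report is a JSON-serializable dictionary
embedding the exact configuration and a content hash of every input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, crosscohort, discovery, preprocess, simulate, stromal, survival
from .containers import (
    EP,
    MP,
    ExpressionMatrix,
    SubtypeLabels,
    ValidationError,
    annotations_from_clinical,
    read_clinical,
    read_expression,
)

log = logging.getLogger("gcsubtype")


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and mode switches of the end-to-end workflow."""

    simulation: dict | None = None       # SimulationConfig fields; None => file inputs
    cohort_files: list | None = None     # [{"expression": ..., "clinical": ...}, ...]
    p_cutoff: float = 0.001
    fold: float = 2.0
    min_samples: int = 15
    hypermutation_threshold: float = 11.4
    posterior_cutoff: float = 0.5
    priors: str = "equal"
    ties: str = "efron"
    adjustment_mode: str = "as_published"
    in_fold_selection: bool = True
    stage_coding: str = "numeric"
    quantile_normalization: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.p_cutoff < 1:
            raise ValidationError("p_cutoff must lie in (0, 1)")
        if self.fold <= 1:
            raise ValidationError("fold must be > 1")
        if self.min_samples < 0:
            raise ValidationError("min_samples must be >= 0")
        if not 0 < self.posterior_cutoff < 1:
            raise ValidationError("posterior_cutoff must lie in (0, 1)")
        if self.hypermutation_threshold < 0:
            raise ValidationError("hypermutation_threshold must be >= 0")
        if self.priors not in ("equal", "empirical"):
            raise ValidationError("priors must be 'equal' or 'empirical'")
        if self.ties not in ("efron", "breslow"):
            raise ValidationError("ties must be 'efron' or 'breslow'")
        if self.adjustment_mode not in ("as_published", "model_based"):
            raise ValidationError("adjustment_mode must be 'as_published' or 'model_based'")
        if self.simulation is None and not self.cohort_files:
            raise ValidationError("either simulation settings or cohort_files required")

    def to_json(self, path=None):
        payload = asdict(self)
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, payload) -> "PipelineConfig":
        if not isinstance(payload, dict):
            payload = json.loads(Path(payload).read_text())
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def simulation_config(self) -> simulate.SimulationConfig:
        sim = dict(self.simulation or {})
        sim.setdefault("seed", self.seed)
        return simulate.SimulationConfig.from_json(sim)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_cohorts(config: PipelineConfig):
    """Returns (cohorts, truths, input_hashes); truths entries may be None."""
    if config.simulation is not None:
        sim_config = config.simulation_config()
        study = simulate.simulate_study(sim_config)
        cohorts = [(m, c) for m, c, _ in study]
        truths = [t for _, _, t in study]
        hashes = {"simulation_config": hashlib.sha256(
            json.dumps(sim_config.to_json(), sort_keys=True).encode()
        ).hexdigest()}
        return cohorts, truths, hashes
    cohorts, hashes = [], {}
    for entry in config.cohort_files:
        clinical = read_clinical(entry["clinical"])
        matrix = read_expression(
            entry["expression"], annotations_from_clinical(clinical)
        )
        cohorts.append((matrix, clinical))
        hashes[str(entry["expression"])] = _sha256(entry["expression"])
        hashes[str(entry["clinical"])] = _sha256(entry["clinical"])
    return cohorts, [None] * len(cohorts), hashes


def _preprocessed(matrix: ExpressionMatrix, config: PipelineConfig) -> ExpressionMatrix:
    out = preprocess.drop_missing_genes(matrix)
    if config.quantile_normalization:
        out = preprocess.quantile_normalize(out)
    return out


def run_end_to_end(config: PipelineConfig, outdir=None) -> dict:
    """Execute the full workflow; returns the machine-readable report."""
    config.validate()
    report: dict = {"config": config.to_json(), "stages": {}}
    cohorts, truths, hashes = _load_cohorts(config)
    report["input_hashes"] = hashes
    if len(cohorts) < 1:
        raise ValidationError("need at least a training cohort")

    norm = [ _preprocessed(m, config) for m, _ in cohorts ]
    clinicals = [c for _, c in cohorts]
    log.info("loaded %d cohorts", len(cohorts))

    # --- discovery on the training cohort -------------------------------
    train_matrix = norm[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = preprocess.filter_variable_genes(
            train_matrix, fold=config.fold, min_samples=config.min_samples
        )
    centered = preprocess.median_center_genes(filtered)
    clusters = discovery.hierarchical_cluster(centered, k=2)
    report["stages"]["discovery"] = {
        "n_genes_after_filter": int(filtered.n_genes),
        "n_mp": len(clusters.samples(MP)),
        "n_ep": len(clusters.samples(EP)),
    }

    normals = train_matrix.samples_of_type("normal")
    signature = discovery.derive_signature(
        train_matrix, clusters, normals,
        p_cutoff=config.p_cutoff, fold=config.fold,
    )
    report["stages"]["signature"] = {"n_genes": len(signature)}
    log.info("signature: %d genes", len(signature))

    # --- classifier ------------------------------------------------------
    labels_per_cohort = [clusters]
    model = None
    if len(signature) == 0:
        # valid under a null configuration: no classifier can be built, so
        # downstream cohorts stay unlabeled and only the training cohort's
        # discovered labels feed the survival stages
        report["stages"]["classifier_skipped"] = "empty signature"
        labels_per_cohort += [None] * (len(norm) - 1)
    else:
        train_tumor = train_matrix.subset_samples(list(clusters.sample_ids))
        model = classify.train_bccp(
            train_tumor, clusters, signature, priors=config.priors
        )
        cv = classify.loocv(
            train_matrix, clusters, normal_samples=normals,
            signature=signature, in_fold_selection=config.in_fold_selection,
            p_cutoff=config.p_cutoff, fold=config.fold, priors=config.priors,
        )
        svm_ref = classify.train_reference_classifier(
            train_tumor, clusters, signature
        )
        report["stages"]["loocv"] = {
            "misclassification_rate": cv.misclassification_rate,
            "sensitivity_mp": cv.sensitivity_mp,
            "specificity_mp": cv.specificity_mp,
            "n_empty_signature_folds": cv.n_empty_signature_folds,
            "n_skipped_folds": cv.n_skipped_folds,
        }

        # --- validation cohorts ------------------------------------------
        validation = {}
        for i, matrix in enumerate(norm[1:], start=1):
            pred = classify.predict_bccp(
                model, matrix, restandardize=True,
                posterior_cutoff=config.posterior_cutoff,
            )
            labels_per_cohort.append(pred)
            svm_pred = svm_ref.predict(matrix, restandardize=True)
            kappa, kappa_p = classify.cohens_kappa(pred, svm_pred)
            clinical = clinicals[i].set_index("sample_id", drop=False)
            entry = {"n_mp": len(pred.samples(MP)), "n_ep": len(pred.samples(EP)),
                     "kappa_vs_svm": kappa, "kappa_p": kappa_p}
            for endpoint in ("OS", "RFS"):
                tcol, ecol = f"{endpoint.lower()}_time", f"{endpoint.lower()}_event"
                sub = clinical.loc[list(pred.sample_ids)]
                try:
                    res = survival.logrank_test(
                        sub[tcol], sub[ecol], pred.labels.loc[sub.index]
                    )
                    entry[f"logrank_p_{endpoint.lower()}"] = res.p
                except ValidationError as exc:
                    entry[f"logrank_p_{endpoint.lower()}"] = None
                    entry[f"logrank_note_{endpoint.lower()}"] = str(exc)
            validation[f"cohort_{i}"] = entry
        report["stages"]["validation"] = validation

    # --- pooled survival: multivariate Cox, stage strata, interaction ----
    pooled_clinical = pd.concat(clinicals, ignore_index=True)
    pooled_labels = SubtypeLabels(
        pd.concat([l.labels for l in labels_per_cohort if l is not None])
    )
    try:
        merged = pooled_clinical.set_index("sample_id", drop=False).join(
            pooled_labels.labels.rename("subtype"), how="inner"
        )
        multi = survival.cox_fit(
            merged, ["subtype", "sex", "age", "stage"], endpoint="RFS",
            ties=config.ties, stage_coding=config.stage_coding,
        )
        report["stages"]["multivariate_cox"] = {
            "hr_mp": float(multi.hazard_ratios["subtype_mp"]),
            "ci_mp": [float(multi.ci_lower["subtype_mp"]),
                      float(multi.ci_upper["subtype_mp"])],
            "lrt_p": multi.lrt_p,
        }
        by_stage = survival.km_by_stage(pooled_clinical, pooled_labels)
        report["stages"]["km_by_stage"] = json.loads(
            by_stage.to_json(orient="index")
        )
        adjuvant = survival.subset_for_adjuvant_analysis(pooled_clinical)
        inter = survival.interaction_test(
            adjuvant, pooled_labels, ties=config.ties,
            stage_coding=config.stage_coding,
        )
        report["stages"]["interaction"] = {
            "n_adjuvant_subset": int(len(adjuvant)),
            "hr_chemo_ep": inter.hr_chemo_ep,
            "ci_chemo_ep": list(inter.ci_chemo_ep),
            "hr_chemo_mp": inter.hr_chemo_mp,
            "ci_chemo_mp": list(inter.ci_chemo_mp),
            "interaction_p": inter.interaction_p,
        }
    except (ValidationError, survival.ConvergenceError) as exc:
        report["stages"]["interaction_error"] = str(exc)

    # --- conserved genes across cohorts ----------------------------------
    labeled = {f"cohort_{i}": (m, l)
               for i, (m, l) in enumerate(zip(norm, labels_per_cohort))
               if l is not None}
    if len(labeled) >= 2:
        try:
            cohort_set = crosscohort.CohortSet(labeled)
            conserved = crosscohort.conserved_genes(
                cohort_set, p_cutoff=config.p_cutoff
            )
            report["stages"]["conserved_genes"] = {
                "n_conserved": int(conserved["conserved"].sum()),
                "n_universe": int(len(conserved)),
            }
        except ValidationError as exc:
            report["stages"]["conserved_genes_error"] = str(exc)

    # --- stromal adjustment on the training cohort -----------------------
    try:
        tumor_ref, normal_ref = stromal.reference_profiles(train_matrix)
        decon = stromal.estimate_tumor_fraction(train_matrix, tumor_ref, normal_ref)
        entry = {
            "mean_tumor_fraction": float(
                decon.tumor_fraction.loc[train_matrix.tumor_samples].mean()
            )
        }
        if truths[0] is not None:
            true_frac = truths[0].tumor_fraction.loc[train_matrix.tumor_samples]
            est = decon.tumor_fraction.loc[train_matrix.tumor_samples]
            entry["fraction_mae_vs_truth"] = float((est - true_frac).abs().mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adjusted = stromal.adjust_expression(
                train_matrix, decon, mode=config.adjustment_mode,
                normal_ref=normal_ref,
            )
        before = discovery.two_sample_ttest(
            train_matrix, clusters.samples(MP), clusters.samples(EP)
        )
        after = discovery.two_sample_ttest(
            adjusted, clusters.samples(MP), clusters.samples(EP)
        )
        sig_genes = signature.gene_ids
        if len(sig_genes):
            same_sign = (
                np.sign(before.loc[sig_genes, "t"]) == np.sign(after.loc[sig_genes, "t"])
            ).mean()
            entry["signature_sign_agreement_after_adjustment"] = float(same_sign)
        report["stages"]["stromal"] = entry
    except ValidationError as exc:
        report["stages"]["stromal_error"] = str(exc)

    # --- simulated-only companions: methylation and mutation rates -------
    if truths[0] is not None:
        sim_config = config.simulation_config()
        truth = truths[0]
        if sim_config.n_methylation_genes:
            meth = simulate.generate_methylation(truth, train_matrix, sim_config)
            corr = crosscohort.methylation_expression_correlation(train_matrix, meth)
            report["stages"]["methylation"] = {
                "mean_pearson_r": float(corr["r"].mean()),
                "n_genes": int(len(corr)),
            }
        rates = simulate.generate_mutation_rates(truth, sim_config)
        t, p = crosscohort.compare_mutation_rates(rates, truth.labels)
        calls = crosscohort.classify_hypermutated(
            rates, threshold=config.hypermutation_threshold
        )
        frac_hyper = {
            s: float((calls.loc[truth.labels.samples(s)] == "hypermutated").mean())
            for s in (MP, EP)
        }
        report["stages"]["mutation"] = {
            "t": t, "p": p, "fraction_hypermutated": frac_hyper,
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        signature.to_tsv(outdir / "signature.tsv")
        model.to_json(outdir / "bccp_model.json")
        pooled_labels.labels.rename_axis("sample_id").to_csv(
            outdir / "subtype_labels.tsv", sep="\t"
        )
    return report
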