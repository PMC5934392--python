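"""Bayesian compound covariate prediction and cross-validation.

The compound covariate of a sample is the t-statistic-weighted sum of its
standardized signature-gene expression, ``c = sum_g t_g * z_g``.  Class
posteriors come from per-class Gaussian models of ``c`` with a pooled
within-class standard deviation and configurable priors:

    P(MP | c) = pi_MP N(c; mu_MP, sigma) / sum_k pi_k N(c; mu_k, sigma)

A linear SVM on the same signature genes serves as an independent
reference classifier for concordance (Cohen's kappa) checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import svm

from .containers import (
    EP,
    MP,
    ExpressionMatrix,
    GeneSignature,
    SubtypeLabels,
    ValidationError,
)
from .discovery import derive_signature

MAX_MISSING_FRACTION = 0.2


@dataclass
class BCCPModel:
    signature: GeneSignature
    class_means: dict           # {MP: float, EP: float}
    pooled_sd: float
    priors: dict                # {MP: float, EP: float}
    standardization: pd.DataFrame   # index gene, columns 'mean', 'sd' (training set)

    def __post_init__(self) -> None:
        if len(self.signature) == 0:
            raise ValidationError("BCCP model requires a non-empty signature")
        if self.pooled_sd <= 0:
            raise ValidationError("pooled sd must be > 0")
        if abs(sum(self.priors.values()) - 1.0) > 1e-9:
            raise ValidationError("priors must sum to 1")

    def to_json(self, path=None):
        payload = {
            "signature": self.signature.to_json(),
            "class_means": {k: float(v) for k, v in self.class_means.items()},
            "pooled_sd": float(self.pooled_sd),
            "priors": {k: float(v) for k, v in self.priors.items()},
            "standardization": {
                g: {"mean": float(r["mean"]), "sd": float(r["sd"])}
                for g, r in self.standardization.iterrows()
            },
        }
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, payload) -> "BCCPModel":
        if not isinstance(payload, dict):
            payload = json.loads(Path(payload).read_text())
        std = pd.DataFrame.from_dict(payload["standardization"], orient="index")
        std.index.name = "gene_id"
        return cls(
            signature=GeneSignature.from_json(payload["signature"]),
            class_means=payload["class_means"],
            pooled_sd=payload["pooled_sd"],
            priors=payload["priors"],
            standardization=std,
        )


@dataclass
class CVReport:
    misclassification_rate: float
    sensitivity_mp: float
    specificity_mp: float
    posterior: pd.Series        # left-out P(MP) per sample
    predicted: pd.Series
    confusion: pd.DataFrame     # rows true, columns predicted
    n_skipped_folds: int = 0
    n_empty_signature_folds: int = 0


def compound_covariate(model: BCCPModel, sample_expression: pd.Series) -> float:
    """Weighted sum of standardized signature-gene expression for one sample.

    Up to 20% missing signature genes are mean-imputed (z=0) with a
    warning; more is an error.
    """
    genes = model.signature.gene_ids
    present = genes.intersection(sample_expression.dropna().index)
    missing_frac = 1.0 - len(present) / len(genes)
    if missing_frac > MAX_MISSING_FRACTION:
        raise ValidationError(
            f"{missing_frac:.0%} of signature genes missing (> {MAX_MISSING_FRACTION:.0%})"
        )
    if missing_frac > 0:
        warnings.warn(f"mean-imputing {missing_frac:.1%} missing signature genes")
    std = model.standardization.loc[present]
    z = (sample_expression.loc[present] - std["mean"]) / std["sd"]
    return float((model.signature.weights.loc[present] * z).sum())


def _scores(model: BCCPModel, matrix: ExpressionMatrix,
            restandardize: bool) -> pd.Series:
    """Compound covariates for every sample of a matrix.

    Missing signature genes (<=20%) are dropped and the remaining weights
    rescaled so the score keeps its scale; ``restandardize`` z-scores each
    gene with the target matrix's own mean/sd (cross-cohort harmonization)
    instead of the stored training standardization.
    """
    genes = model.signature.gene_ids
    present = genes.intersection(matrix.gene_ids)
    if len(present) / len(genes) < 1.0 - MAX_MISSING_FRACTION:
        raise ValidationError(
            f"only {len(present)}/{len(genes)} signature genes present "
            f"(need >= {1.0 - MAX_MISSING_FRACTION:.0%})"
        )
    w = model.signature.weights.loc[present]
    if len(present) < len(genes):
        warnings.warn(f"dropping {len(genes) - len(present)} absent signature genes")
        w = w * (model.signature.weights.abs().sum() / w.abs().sum())
    x = matrix.values.loc[present]
    if restandardize:
        mean, sd = x.mean(axis=1), x.std(axis=1, ddof=1)
    else:
        std = model.standardization.loc[present]
        mean, sd = std["mean"], std["sd"]
    if (sd <= 0).any():
        raise ValidationError("zero-variance signature gene; cannot standardize")
    z = x.sub(mean, axis=0).div(sd, axis=0)
    return z.mul(w, axis=0).sum(axis=0)


def train_bccp(matrix: ExpressionMatrix, labels: SubtypeLabels,
               signature: GeneSignature, priors: str = "equal") -> BCCPModel:
    """Fit the compound-covariate Gaussian class model on a training cohort.

    ``priors`` is "equal" (0.5/0.5, the default — keeps validation-cohort
    prevalence assumptions out of the classifier) or "empirical" (training
    class frequencies).
    """
    if len(signature) == 0:
        raise ValidationError("cannot train on an empty signature")
    mp, ep = labels.samples(MP), labels.samples(EP)
    if len(mp) < 2 or len(ep) < 2:
        raise ValidationError("each class needs >= 2 training samples")
    train = matrix.subset_samples(list(labels.sample_ids))
    genes = signature.gene_ids.intersection(train.gene_ids)
    if len(genes) < len(signature):
        raise ValidationError("training matrix lacks signature genes")
    x = train.values.loc[signature.gene_ids]
    std = pd.DataFrame({"mean": x.mean(axis=1), "sd": x.std(axis=1, ddof=1)})
    if (std["sd"] <= 0).any():
        raise ValidationError("zero-variance signature gene in training data")
    model = BCCPModel(
        signature=signature,
        class_means={MP: 0.0, EP: 0.0},
        pooled_sd=1.0,
        priors={MP: 0.5, EP: 0.5},
        standardization=std,
    )
    c = _scores(model, train, restandardize=False)
    c_mp, c_ep = c.loc[mp], c.loc[ep]
    pooled_var = (
        ((len(mp) - 1) * c_mp.var(ddof=1) + (len(ep) - 1) * c_ep.var(ddof=1))
        / (len(mp) + len(ep) - 2)
    )
    if pooled_var <= 0:
        raise ValidationError("zero pooled within-class variance of compound covariate")
    if priors == "equal":
        pri = {MP: 0.5, EP: 0.5}
    elif priors == "empirical":
        n = len(mp) + len(ep)
        pri = {MP: len(mp) / n, EP: len(ep) / n}
    else:
        raise ValidationError("priors must be 'equal' or 'empirical'")
    model.class_means = {MP: float(c_mp.mean()), EP: float(c_ep.mean())}
    model.pooled_sd = float(np.sqrt(pooled_var))
    model.priors = pri
    return model


def posterior_mp(model: BCCPModel, c) -> np.ndarray:
    """P(MP | c) under the two-class Gaussian model (numerically stable)."""
    c = np.asarray(c, dtype=float)
    log_mp = np.log(model.priors[MP]) + stats.norm.logpdf(
        c, model.class_means[MP], model.pooled_sd
    )
    log_ep = np.log(model.priors[EP]) + stats.norm.logpdf(
        c, model.class_means[EP], model.pooled_sd
    )
    m = np.maximum(log_mp, log_ep)
    return np.exp(log_mp - m) / (np.exp(log_mp - m) + np.exp(log_ep - m))


def predict_bccp(model: BCCPModel, matrix: ExpressionMatrix,
                 restandardize: bool = False,
                 posterior_cutoff: float = 0.5) -> SubtypeLabels:
    """Label tumor samples; posterior >= cutoff -> MP (tie goes to MP)."""
    if matrix.scale != "log2":
        raise ValidationError("prediction expects log2-scale expression")
    tumors = matrix.tumor_samples
    c = _scores(model, matrix.subset_samples(tumors), restandardize=restandardize)
    post = pd.Series(posterior_mp(model, c.to_numpy()), index=c.index)
    labels = pd.Series(
        np.where(post >= posterior_cutoff, MP, EP), index=c.index, name="subtype"
    )
    return SubtypeLabels(labels, posterior=post)


def loocv(matrix: ExpressionMatrix, labels: SubtypeLabels, normal_samples=None,
          signature: GeneSignature | None = None, in_fold_selection: bool = True,
          p_cutoff: float = 0.001, fold: float = 2.0,
          priors: str = "equal") -> CVReport:
    """Leave-one-out cross-validation of the BCCP pipeline.

    With ``in_fold_selection`` (the honest default) the signature is
    re-derived from the remaining n-1 samples in every fold, so the
    left-out sample never influences feature selection; the fixed
    ``signature`` mode reproduces the optimistic variant.  A fold whose
    in-fold signature is empty predicts from the priors alone (counted in
    ``n_empty_signature_folds``); a fold that would lose an entire class
    is skipped and reported.
    """
    sample_ids = list(labels.sample_ids)
    if len(sample_ids) < 4:
        raise ValidationError("LOOCV needs n >= 4")
    if len(labels.samples(MP)) < 2 or len(labels.samples(EP)) < 2:
        raise ValidationError("LOOCV needs >= 2 samples per class")
    if in_fold_selection and normal_samples is None:
        raise ValidationError("in-fold selection requires normal_samples")
    if not in_fold_selection and signature is None:
        raise ValidationError("fixed-signature mode requires a signature")
    normal_samples = list(normal_samples or [])

    post, pred, truth = {}, {}, {}
    n_skipped = n_empty = 0
    for left_out in sample_ids:
        rest_ids = [s for s in sample_ids if s != left_out]
        rest_labels = SubtypeLabels(labels.labels.loc[rest_ids])
        if len(rest_labels.samples(MP)) < 2 or len(rest_labels.samples(EP)) < 2:
            n_skipped += 1
            continue
        fold_matrix = matrix.subset_samples(rest_ids + normal_samples)
        if in_fold_selection:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sig = derive_signature(
                    fold_matrix, rest_labels, normal_samples,
                    p_cutoff=p_cutoff, fold=fold,
                )
        else:
            sig = signature
        if len(sig) == 0:
            n_empty += 1
            pri_mp = (len(rest_labels.samples(MP)) / len(rest_ids)
                      if priors == "empirical" else 0.5)
            p_mp = pri_mp
        else:
            model = train_bccp(
                matrix.subset_samples(rest_ids), rest_labels, sig, priors=priors
            )
            c = compound_covariate(model, matrix.values.loc[:, left_out])
            p_mp = float(posterior_mp(model, c))
        post[left_out] = p_mp
        pred[left_out] = MP if p_mp >= 0.5 else EP
        truth[left_out] = labels.labels.loc[left_out]

    post = pd.Series(post, name="posterior_mp")
    pred = pd.Series(pred, name="predicted")
    truth = pd.Series(truth, name="true")
    confusion = pd.crosstab(truth, pred).reindex(
        index=[MP, EP], columns=[MP, EP], fill_value=0
    )
    n = confusion.to_numpy().sum()
    correct = confusion.loc[MP, MP] + confusion.loc[EP, EP]
    n_mp = confusion.loc[MP].sum()
    n_ep = confusion.loc[EP].sum()
    return CVReport(
        misclassification_rate=float(1 - correct / n),
        sensitivity_mp=float(confusion.loc[MP, MP] / n_mp) if n_mp else float("nan"),
        specificity_mp=float(confusion.loc[EP, EP] / n_ep) if n_ep else float("nan"),
        posterior=post,
        predicted=pred,
        confusion=confusion,
        n_skipped_folds=n_skipped,
        n_empty_signature_folds=n_empty,
    )


def cohens_kappa(labels_a: SubtypeLabels, labels_b: SubtypeLabels):
    """Cohen's kappa between two labelings with a large-sample test of kappa=0.

    Returns ``(kappa, p)``; both are NaN when chance agreement is 1 (both
    raters constant with the same label), where kappa is undefined.
    """
    a = labels_a.labels
    b = labels_b.labels.reindex(a.index)
    if b.isna().any():
        raise ValidationError("label sets cover different samples")
    n = len(a)
    table = pd.crosstab(a, b).reindex(index=[MP, EP], columns=[MP, EP], fill_value=0)
    obs = table.to_numpy(float) / n
    p_o = np.trace(obs)
    row, col = obs.sum(axis=1), obs.sum(axis=0)
    p_e = float(row @ col)
    if abs(1.0 - p_e) < 1e-12:
        return float("nan"), float("nan")
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss large-sample variance under H0: kappa = 0
    var0 = (p_e + p_e**2 - float(np.sum(row * col * (row + col)))) / (n * (1 - p_e) ** 2)
    if var0 <= 0:
        return float(kappa), float("nan")
    z = kappa / np.sqrt(var0)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(kappa), float(p)


@dataclass
class ReferenceClassifier:
    """Linear maximum-margin classifier on signature genes (concordance only)."""

    signature: GeneSignature
    standardization: pd.DataFrame
    _svm: svm.SVC

    def predict(self, matrix: ExpressionMatrix,
                restandardize: bool = False) -> SubtypeLabels:
        tumors = matrix.tumor_samples
        x = matrix.values.loc[self.signature.gene_ids, tumors]
        if restandardize:
            mean, sd = x.mean(axis=1), x.std(axis=1, ddof=1)
        else:
            mean = self.standardization["mean"]
            sd = self.standardization["sd"]
        z = x.sub(mean, axis=0).div(sd, axis=0).to_numpy(float).T
        labels = pd.Series(self._svm.predict(z), index=tumors, name="subtype")
        return SubtypeLabels(labels)


def train_reference_classifier(matrix: ExpressionMatrix, labels: SubtypeLabels,
                               signature: GeneSignature) -> ReferenceClassifier:
    if len(signature) == 0:
        raise ValidationError("cannot train on an empty signature")
    if len(labels.samples(MP)) < 2 or len(labels.samples(EP)) < 2:
        raise ValidationError("each class needs >= 2 training samples")
    x = matrix.values.loc[signature.gene_ids, list(labels.sample_ids)]
    std = pd.DataFrame({"mean": x.mean(axis=1), "sd": x.std(axis=1, ddof=1)})
    if (std["sd"] <= 0).any():
        raise ValidationError("zero-variance signature gene in training data")
    z = x.sub(std["mean"], axis=0).div(std["sd"], axis=0).to_numpy(float).T
    clf = svm.SVC(kernel="linear", C=1.0, random_state=0)
    clf.fit(z, labels.labels.to_numpy())
    return ReferenceClassifier(signature=signature, standardization=std, _svm=clf)
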