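"""Compound-covariate classifier, LOOCV, kappa, and SVM concordance."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from conftest import make_matrix
from gcsubtype import (
    EP,
    MP,
    GeneSignature,
    SimulationConfig,
    SubtypeLabels,
    ValidationError,
    generate_cohort,
)
from gcsubtype.classify import (
    BCCPModel,
    cohens_kappa,
    compound_covariate,
    loocv,
    posterior_mp,
    predict_bccp,
    train_bccp,
    train_reference_classifier,
)


def _signature(weights):
    table = pd.DataFrame(
        {
            "weight": weights,
            "log2_fold_change": np.sign(weights),
            "p_value": 1e-5,
        },
        index=[f"g{i}" for i in range(len(weights))],
    )
    table.index.name = "gene_id"
    return GeneSignature(table)


def _model(weights, mu_mp=2.0, mu_ep=-2.0, sd=1.0, priors=(0.5, 0.5)):
    sig = _signature(weights)
    std = pd.DataFrame({"mean": 0.0, "sd": 1.0}, index=sig.gene_ids)
    return BCCPModel(
        signature=sig,
        class_means={MP: mu_mp, EP: mu_ep},
        pooled_sd=sd,
        priors={MP: priors[0], EP: priors[1]},
        standardization=std,
    )


class TestCompoundCovariate:
    def test_zero_z_scores_give_zero(self):
        model = _model([1.0, -2.0, 0.5])
        x = pd.Series(0.0, index=model.signature.gene_ids)
        assert compound_covariate(model, x) == 0.0

    def test_single_gene_closed_form(self):
        model = _model([2.0])
        assert compound_covariate(model, pd.Series({"g0": 1.5})) == pytest.approx(3.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=10)
        model = _model(list(w))
        x = pd.Series(rng.normal(size=10), index=model.signature.gene_ids)
        expected = 0.0
        for g in model.signature.gene_ids:          # independent sum loop
            expected += model.signature.weights[g] * x[g]
        assert compound_covariate(model, x) == pytest.approx(expected, abs=1e-12)

    def test_missing_gene_policy(self):
        model = _model(list(np.ones(10)))
        x = pd.Series(1.0, index=model.signature.gene_ids)
        with pytest.warns(UserWarning, match="imputing"):
            c = compound_covariate(model, x.drop(["g0"]))
        assert c == pytest.approx(9.0)
        with pytest.raises(ValidationError, match="missing"):
            compound_covariate(model, x.iloc[:7])


class TestPosterior:
    def test_midpoint_with_equal_priors_is_half(self):
        model = _model([1.0])
        assert posterior_mp(model, 0.0) == pytest.approx(0.5)

    def test_six_sigma_separation_is_confident(self):
        model = _model([1.0], mu_mp=3.0, mu_ep=-3.0, sd=1.0)
        assert posterior_mp(model, 3.0) > 0.99

    def test_posteriors_normalize_and_are_monotone(self):
        model = _model([1.0])
        grid = np.linspace(-10, 10, 201)
        post = posterior_mp(model, grid)
        assert np.all((post >= 0) & (post <= 1))
        assert np.all(np.diff(post) >= 0)          # mu_MP > mu_EP
        # swapping the class means turns P(MP|c) into P(EP|c) = 1 - P(MP|c)
        flipped = _model([1.0], mu_mp=-2.0, mu_ep=2.0)
        assert np.allclose(posterior_mp(flipped, grid), 1.0 - post, atol=1e-12)

    def test_prior_shift_matches_closed_form(self):
        """Decision boundary: mid + sd^2 log((1-q)/q) / (mu_MP - mu_EP)."""
        q = 0.2
        model = _model([1.0], mu_mp=1.0, mu_ep=-3.0, sd=1.5, priors=(q, 1 - q))
        mid = (1.0 + -3.0) / 2
        boundary = mid + 1.5**2 * np.log((1 - q) / q) / (1.0 - (-3.0))
        assert posterior_mp(model, boundary) == pytest.approx(0.5, abs=1e-10)


def _labeled_cohort(rng, n_mp=20, n_ep=30, n_genes=60, n_sig=20, delta=3.0, sd=1.0):
    direction = np.where(np.arange(n_sig) % 2 == 0, 1.0, -1.0)
    values = rng.normal(0, sd, (n_genes, n_mp + n_ep))
    values[:n_sig, :n_mp] += direction[:, None] * delta / 2
    values[:n_sig, n_mp:] -= direction[:, None] * delta / 2
    ids = [f"m{i}" for i in range(n_mp)] + [f"e{i}" for i in range(n_ep)]
    m = make_matrix(values, sample_ids=ids)
    labels = SubtypeLabels(pd.Series([MP] * n_mp + [EP] * n_ep, index=ids))
    weights = direction * 5.0
    return m, labels, _signature(list(weights))


class TestTrainPredict:
    def test_separated_classes_classified_confidently(self):
        rng = np.random.default_rng(1)
        m, labels, sig = _labeled_cohort(rng)
        model = train_bccp(m, labels, sig)
        assert model.class_means[MP] > model.class_means[EP]
        pred = predict_bccp(model, m)
        for s in labels.sample_ids:
            own = pred.posterior[s] if labels.labels[s] == MP else 1 - pred.posterior[s]
            assert own > 0.5
        assert (pred.labels == labels.labels).all()

    def test_permuted_labels_remove_separation(self):
        rng = np.random.default_rng(2)
        m, labels, sig = _labeled_cohort(rng, delta=0.0)
        model = train_bccp(m, labels, sig)
        gap = abs(model.class_means[MP] - model.class_means[EP])
        assert gap < model.pooled_sd

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(3)
        m, labels, sig = _labeled_cohort(rng)
        a = train_bccp(m, labels, sig)
        b = train_bccp(m, labels, sig)
        assert a.to_json() == b.to_json()

    def test_affine_gene_rescaling_is_absorbed_by_restandardization(self):
        rng = np.random.default_rng(4)
        m, labels, sig = _labeled_cohort(rng)
        model = train_bccp(m, labels, sig)
        scaled_values = m.values.copy()
        scaled_values.iloc[0] = scaled_values.iloc[0] * 7.0 + 3.0
        scaled = m.with_values(scaled_values)
        rescaled_model = train_bccp(scaled, labels, sig)
        a = predict_bccp(model, m)
        b = predict_bccp(rescaled_model, scaled)
        assert np.allclose(a.posterior, b.posterior, atol=1e-9)

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        m, labels, sig = _labeled_cohort(rng)
        model = train_bccp(m, labels, sig)
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = BCCPModel.from_json(path)
        pred_a = predict_bccp(model, m)
        pred_b = predict_bccp(restored, m)
        assert (pred_a.labels == pred_b.labels).all()

    def test_small_class_rejected(self):
        rng = np.random.default_rng(6)
        m, labels, sig = _labeled_cohort(rng, n_mp=1, n_ep=10)
        with pytest.raises(ValidationError, match=">= 2"):
            train_bccp(m, labels, sig)


class TestLOOCV:
    def test_strong_signal_low_error_and_matches_holdout(self):
        """LOOCV error is small and within 3 points of independent hold-out."""
        config = SimulationConfig(
            n_cohorts=2, samples_per_cohort=100, n_genes=2000,
            n_signature_genes=50, effect_size=3.0, gene_noise_sd=1.0,
            n_methylation_genes=10, seed=31,
        )
        train_m, _, train_truth = generate_cohort(config, 0)
        hold_m, _, hold_truth = generate_cohort(config, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = loocv(train_m, train_truth.labels,
                       normal_samples=train_m.samples_of_type("normal"))
        assert cv.misclassification_rate <= 0.05
        from gcsubtype.discovery import derive_signature
        sig = derive_signature(train_m, train_truth.labels,
                               train_m.samples_of_type("normal"))
        model = train_bccp(
            train_m.subset_samples(list(train_truth.subtype.index)),
            train_truth.labels, sig,
        )
        pred = predict_bccp(model, hold_m, restandardize=True)
        holdout_err = (pred.labels.loc[hold_truth.subtype.index]
                       != hold_truth.subtype).mean()
        assert abs(cv.misclassification_rate - holdout_err) <= 0.03

    def test_null_labels_approach_majority_class_error(self):
        """Random labels on null data: the in-fold signature is empty, so
        empirical-prior prediction degenerates to the majority class."""
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, (300, 70))
        ids = [f"t{i}" for i in range(60)] + [f"n{i}" for i in range(10)]
        m = make_matrix(values, sample_ids=ids,
                        tissue_types=["tumor"] * 60 + ["normal"] * 10)
        lab = rng.permutation([MP] * 24 + [EP] * 36)
        labels = SubtypeLabels(pd.Series(lab, index=ids[:60]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = loocv(m, labels, normal_samples=ids[60:], priors="empirical")
        minority_rate = 24 / 60
        assert abs(cv.misclassification_rate - minority_rate) <= 0.15

    def test_confusion_counts_sum_to_n(self, strong_cohort):
        _, matrix, _, truth = strong_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = loocv(matrix, truth.labels,
                       normal_samples=matrix.samples_of_type("normal"))
        assert cv.confusion.to_numpy().sum() + cv.n_skipped_folds == len(truth.subtype)
        assert 0 <= cv.misclassification_rate <= 1


class TestCohensKappa:
    def test_identical_labelings_give_one(self):
        labels = SubtypeLabels(pd.Series([MP, MP, EP, EP, EP], dtype=object,
                                         index=list("abcde")))
        kappa, p = cohens_kappa(labels, labels)
        assert kappa == pytest.approx(1.0)
        assert p < 0.05

    def test_independent_labelings_near_zero(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(2000)]
        a = SubtypeLabels(pd.Series(rng.choice([MP, EP], 2000), index=idx))
        b = SubtypeLabels(pd.Series(rng.choice([MP, EP], 2000), index=idx))
        kappa, p = cohens_kappa(a, b)
        assert abs(kappa) < 0.05

    def test_matches_hand_computed_table_and_sklearn(self):
        # agreement table rows MP/EP of rater A: (20, 5; 10, 65)
        a_vec = [MP] * 25 + [EP] * 75
        b_vec = [MP] * 20 + [EP] * 5 + [MP] * 10 + [EP] * 65
        idx = [f"s{i}" for i in range(100)]
        a = SubtypeLabels(pd.Series(a_vec, index=idx))
        b = SubtypeLabels(pd.Series(b_vec, index=idx))
        kappa, p = cohens_kappa(a, b)
        # p_o = 0.85, p_e = 0.25*0.30 + 0.75*0.70 = 0.6 -> kappa = 0.625
        assert kappa == pytest.approx(0.625, abs=1e-12)
        assert kappa == pytest.approx(cohen_kappa_score(a_vec, b_vec), abs=1e-12)
        assert p < 1e-6

    def test_constant_raters_undefined(self):
        labels = SubtypeLabels(pd.Series([MP, MP, MP], dtype=object,
                                         index=list("abc")))
        kappa, p = cohens_kappa(labels, labels)
        assert np.isnan(kappa) and np.isnan(p)


class TestReferenceClassifier:
    def test_concordant_with_bccp_on_separated_data(self):
        rng = np.random.default_rng(9)
        m, labels, sig = _labeled_cohort(rng, n_mp=25, n_ep=35)
        bccp = predict_bccp(train_bccp(m, labels, sig), m)
        ref = train_reference_classifier(m, labels, sig)
        kappa, _ = cohens_kappa(bccp, ref.predict(m))
        assert kappa >= 0.8

    def test_deterministic_predictions(self):
        rng = np.random.default_rng(10)
        m, labels, sig = _labeled_cohort(rng)
        a = train_reference_classifier(m, labels, sig).predict(m)
        b = train_reference_classifier(m, labels, sig).predict(m)
        assert (a.labels == b.labels).all()

    def test_null_data_concordance_near_zero_on_fresh_samples(self):
        """Classifiers trained on pure noise disagree on new noise draws."""
        rng = np.random.default_rng(11)
        kappas = []
        for rep in range(8):
            m, labels, sig = _labeled_cohort(rng, n_mp=30, n_ep=30, delta=0.0)
            test_m, _, _ = _labeled_cohort(rng, n_mp=30, n_ep=30, delta=0.0)
            bccp = predict_bccp(train_bccp(m, labels, sig), test_m)
            ref = train_reference_classifier(m, labels, sig)
            k, _ = cohens_kappa(bccp, ref.predict(test_m))
            if not np.isnan(k):
                kappas.append(k)
        assert abs(np.mean(kappas)) < 0.4
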