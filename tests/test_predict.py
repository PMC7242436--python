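"""Fold-in, predictive likelihood, kNN prediction and imputation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mixehr import (
    ModelHyperparameters,
    MultiModalCorpus,
    ParameterEstimates,
    PatientRecord,
    TrainConfig,
    cross_validate_K,
    evaluate_binary_predictions,
    fit_jcvb,
    impute_lab_result,
    infer_patient_mixture,
    knn_neighbors,
    predict_code,
    predictive_log_likelihood,
    sample_corpus,
    sample_truth,
    split_record,
)


def _model_from_truth(truth, alpha=0.5):
    """Treat ground-truth parameters as a frozen fitted model."""
    K = truth.n_topics
    est = ParameterEstimates(
        theta=truth.theta, phi=truth.phi, eta=truth.eta, psi=truth.psi
    )
    hyper = ModelHyperparameters.symmetric(
        K,
        [p.shape[0] for p in truth.phi],
        [e.shape[1] for e in truth.eta],
        alpha=alpha,
    )
    return est, hyper


class TestFoldIn:
    def test_empty_record_returns_prior_mean(self):
        hyper = ModelHyperparameters.symmetric(3, (4,), (2,), alpha=2.0)
        truth = sample_truth(hyper, 1, seed=0)
        est, hyper = _model_from_truth(truth, alpha=2.0)
        theta = infer_patient_mixture(est, hyper, PatientRecord())
        np.testing.assert_allclose(theta, 1 / 3, atol=1e-12)

    def test_single_topic_is_degenerate(self):
        hyper = ModelHyperparameters.symmetric(1, (4,), ())
        truth = sample_truth(hyper, 1, seed=0)
        est, hyper = _model_from_truth(truth)
        rec = PatientRecord(tok_type=np.array([0]), tok_feat=np.array([1]), tok_cnt=np.array([3]))
        assert infer_patient_mixture(est, hyper, rec) == pytest.approx([1.0])

    def test_unknown_features_skipped_with_warning(self):
        hyper = ModelHyperparameters.symmetric(2, (4,), ())
        est, hyper = _model_from_truth(sample_truth(hyper, 1, seed=0))
        rec = PatientRecord(
            tok_type=np.array([0, 0]), tok_feat=np.array([1, 99]), tok_cnt=np.array([1, 1])
        )
        with pytest.warns(UserWarning, match="skipped 1"):
            infer_patient_mixture(est, hyper, rec)

    def test_recovers_dominant_topic_of_pure_patients(self):
        # patients drawn purely from topic 0 under a well-separated model
        gen = ModelHyperparameters.symmetric(3, (30, 20), (2, 2), alpha=0.5, beta=0.1)
        truth = sample_truth(gen, 200, seed=5)
        truth.theta[:] = np.array([1.0, 0.0, 0.0])
        corpus = sample_corpus(truth, 20, seed=6)
        est, hyper = _model_from_truth(truth)
        hits = sum(
            np.argmax(infer_patient_mixture(est, hyper, corpus.patient(j))) == 0
            for j in range(200)
        )
        assert hits >= 190

    def test_fold_in_reproduces_training_mixture(self, fixture_corpus):
        # at realistic corpus size the patient's own share of the global
        # statistics is negligible and fold-in matches training closely
        gen = ModelHyperparameters.symmetric(2, (20, 15), (2, 2), alpha=0.5, beta=0.1)
        truth = sample_truth(gen, 100, seed=0)
        corpus = sample_corpus(truth, 20, seed=1)
        est, state, _ = fit_jcvb(
            corpus, 2, config=TrainConfig(max_sweeps=40, update_hyper=False), seed=0
        )
        for j in range(corpus.n_patients):
            theta = infer_patient_mixture(
                est, state.hyper, corpus.patient(j), include_missing_labs=True
            )
            assert 0.5 * np.abs(theta - est.theta[j]).sum() < 0.02
        # on the tiny fixture the self-inclusion bias of the posterior-mean
        # topics dominates; only a coarser agreement is attainable
        est, state, _ = fit_jcvb(
            fixture_corpus, 2, config=TrainConfig(max_sweeps=40, update_hyper=False), seed=0
        )
        for j in range(fixture_corpus.n_patients):
            theta = infer_patient_mixture(
                est, state.hyper, fixture_corpus.patient(j), include_missing_labs=True
            )
            assert 0.5 * np.abs(theta - est.theta[j]).sum() < 0.08


class TestPredictiveLogLikelihood:
    def test_uniform_single_topic_closed_form(self):
        est = ParameterEstimates(
            theta=np.array([[1.0]]),
            phi=[np.full((4, 1), 0.25)],
            eta=[],
            psi=np.zeros((0, 1)),
        )
        test = MultiModalCorpus(1, (4,), (), tokens=([0, 0], [0, 0], [0, 2], [1, 1]))
        ll = predictive_log_likelihood(est, test, np.array([[1.0]]))
        assert ll == pytest.approx(2 * np.log(0.25), abs=1e-12)

    def test_empty_corpus_scores_zero(self):
        est = ParameterEstimates(
            theta=np.zeros((0, 2)), phi=[np.full((3, 2), 1 / 3)], eta=[], psi=np.zeros((0, 2))
        )
        empty = MultiModalCorpus(0, (3,), ())
        assert predictive_log_likelihood(est, empty, np.zeros((0, 2))) == 0.0

    def test_matches_explicit_loop(self, fixture_corpus):
        gen = ModelHyperparameters.symmetric(2, (5, 4), (2, 2))
        truth = sample_truth(gen, 6, seed=1)
        est, _ = _model_from_truth(truth)
        theta = truth.theta
        ll = predictive_log_likelihood(est, fixture_corpus, theta)
        ref = 0.0
        c = fixture_corpus
        for r in range(len(c.tok_pat)):
            j, t, w = c.tok_pat[r], c.tok_type[r], c.tok_feat[r]
            ref += c.tok_cnt[r] * np.log(sum(theta[j, k] * est.phi[t][w, k] for k in range(2)))
        for r in range(len(c.lab_pat)):
            j, l, v = c.lab_pat[r], c.lab_lab[r], c.lab_state[r]
            ref += c.lab_freq[r] * np.log(
                sum(theta[j, k] * est.psi[l, k] * est.eta[l][k, v] for k in range(2))
            )
        assert ll == pytest.approx(ref, abs=1e-10)

    def test_invariant_under_joint_topic_permutation(self, fixture_corpus):
        gen = ModelHyperparameters.symmetric(3, (5, 4), (2, 2))
        truth = sample_truth(gen, 6, seed=2)
        est, _ = _model_from_truth(truth)
        ll = predictive_log_likelihood(est, fixture_corpus, truth.theta)
        perm = [2, 0, 1]
        est_p = ParameterEstimates(
            theta=truth.theta[:, perm],
            phi=[p[:, perm] for p in truth.phi],
            eta=[e[perm] for e in truth.eta],
            psi=truth.psi[:, perm],
        )
        ll_p = predictive_log_likelihood(est_p, fixture_corpus, truth.theta[:, perm])
        assert ll == pytest.approx(ll_p, abs=1e-10)

    def test_as_printed_sum_mode_differs(self, fixture_corpus):
        gen = ModelHyperparameters.symmetric(2, (5, 4), (2, 2))
        truth = sample_truth(gen, 6, seed=3)
        est, _ = _model_from_truth(truth)
        a = predictive_log_likelihood(est, fixture_corpus, truth.theta, lab_term="product")
        b = predictive_log_likelihood(est, fixture_corpus, truth.theta, lab_term="sum")
        assert b > a  # sum mode inflates each lab factor


class TestSplitAndCrossValidation:
    def test_split_partitions_record(self, fixture_corpus):
        rec = fixture_corpus.patient(0)
        a, b = split_record(rec, seed=0)
        assert len(a.tok_type) + len(b.tok_type) == len(rec.tok_type)
        assert a.tok_cnt.sum() + b.tok_cnt.sum() == rec.tok_cnt.sum()
        assert set(a.lab_lab) | set(b.lab_lab) == set(rec.lab_lab)
        assert set(a.lab_lab) & set(b.lab_lab) == set()

    def test_every_patient_in_exactly_one_fold(self):
        rng = np.random.default_rng(4)
        assignment = rng.permutation(50) % 5
        assert np.bincount(assignment, minlength=5).sum() == 50
        gen = ModelHyperparameters.symmetric(2, (10,), (), alpha=0.5)
        truth = sample_truth(gen, 50, seed=4)
        corpus = sample_corpus(truth, 6, seed=5)
        table = cross_validate_K(
            corpus, [2], folds=5, seed=4,
            train_config=TrainConfig(max_sweeps=3, update_hyper=False),
        )
        assert len(table) == 1 and np.isfinite(table["mean_log_likelihood"]).all()

    def test_deterministic_table(self):
        gen = ModelHyperparameters.symmetric(2, (10,), (2,), alpha=0.5)
        truth = sample_truth(gen, 30, seed=6)
        corpus = sample_corpus(truth, 6, seed=7)
        cfg = TrainConfig(max_sweeps=5, update_hyper=False)
        t1 = cross_validate_K(corpus, [1, 2], folds=2, seed=9, train_config=cfg)
        t2 = cross_validate_K(corpus, [1, 2], folds=2, seed=9, train_config=cfg)
        assert t1.equals(t2)

    def test_empty_grid_rejected(self, fixture_corpus):
        with pytest.raises(ValueError, match="K_grid"):
            cross_validate_K(fixture_corpus, [], folds=2, seed=0)


class TestKNN:
    def test_analytic_distances(self):
        idx, dist = knn_neighbors(np.array([1.0, 0.0]), np.array([[1.0, 0.0], [0.0, 1.0]]), 2)
        np.testing.assert_array_equal(idx, [0, 1])
        np.testing.assert_allclose(dist, [0.0, np.sqrt(2)], atol=1e-12)

    def test_ties_broken_by_index(self):
        train = np.array([[0.5, 0.5], [0.5, 0.5], [0.0, 1.0]])
        idx, _ = knn_neighbors(np.array([0.5, 0.5]), train, 3)
        np.testing.assert_array_equal(idx, [0, 1, 2])

    def test_matches_full_sort_brute_force(self, rng):
        train = rng.random((100, 4))
        query = rng.random(4)
        idx, dist = knn_neighbors(query, train, 100)
        ref = np.sqrt(((train - query) ** 2).sum(axis=1))
        order = np.lexsort((np.arange(100), ref))
        np.testing.assert_array_equal(idx, order)
        assert (np.diff(dist) >= -1e-15).all()

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError, match="k"):
            knn_neighbors(np.zeros(2), rng.random((5, 2)), 6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hits=st.integers(0, 5))
    def test_predict_code_lies_on_grid(self, hits):
        indicator = np.array([1] * hits + [0] * (5 - hits))
        score = predict_code(np.arange(5), indicator, 5)
        assert score == pytest.approx(hits / 5)


class TestImputation:
    def _setup(self, freqs):
        """Training corpus whose lab-0 records are given per patient."""
        D = len(freqs)
        lab = [[], [], [], []]
        for j, per_state in enumerate(freqs):
            for v, y in enumerate(per_state):
                if y:
                    lab[0].append(j)
                    lab[1].append(0)
                    lab[2].append(v)
                    lab[3].append(y)
        corpus = MultiModalCorpus(D, (4,), (2, 2), lab_records=lab)
        gen = ModelHyperparameters.symmetric(2, (4,), (2, 2))
        truth = sample_truth(gen, D, seed=0)
        est, hyper = _model_from_truth(truth)
        est.theta = np.tile([0.5, 0.5], (D, 1))
        return corpus, est, hyper

    def test_unanimous_neighbors(self):
        corpus, est, hyper = self._setup([(0, 2)] * 5)
        with pytest.warns(UserWarning, match="eligible"):
            dist = impute_lab_result(est, hyper, corpus, est.theta, PatientRecord(), 0, k=25)
        np.testing.assert_allclose(dist, [0.0, 1.0], atol=1e-12)

    def test_even_split_neighbors(self):
        corpus, est, hyper = self._setup([(1, 0), (0, 1)] * 3)
        with pytest.warns(UserWarning):
            dist = impute_lab_result(est, hyper, corpus, est.theta, PatientRecord(), 0, k=25)
        np.testing.assert_allclose(dist, [0.5, 0.5], atol=1e-12)

    def test_unimputable_lab(self):
        corpus, est, hyper = self._setup([(1, 0)] * 3)
        with pytest.raises(ValueError, match="unimputable"):
            impute_lab_result(est, hyper, corpus, est.theta, PatientRecord(), 1, k=2)


class TestBinaryMetrics:
    def test_perfect_separation(self):
        m = evaluate_binary_predictions([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], threshold=0.5)
        assert m.auroc == 1.0 and m.accuracy == 1.0

    def test_random_scores_near_chance(self, rng):
        n = 4000
        labels = rng.integers(0, 2, size=n)
        scores = rng.random(n)
        m = evaluate_binary_predictions(scores, labels, threshold=0.5)
        se = 1.0 / np.sqrt(n)  # conservative AUROC SE bound
        assert abs(m.auroc - 0.5) < 3 * se

    def test_single_class_labels(self):
        m = evaluate_binary_predictions([0.9, 0.2], [1, 1], threshold=0.5)
        assert np.isnan(m.auroc)
        assert m.accuracy == 0.5
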