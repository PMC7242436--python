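"""Corpus containers, validation, and on-disk round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mixehr import (
    CorpusParseError,
    CorpusValidationError,
    ModelHyperparameters,
    MultiModalCorpus,
    ParameterEstimates,
    read_corpus,
    read_model,
    validate_corpus,
    write_corpus,
    write_model,
)


def _write(tmp_path, meta, counts, labs):
    (tmp_path / "meta.tsv").write_text(meta)
    (tmp_path / "counts.tsv").write_text(counts)
    (tmp_path / "labs.tsv").write_text(labs)
    return tmp_path / "counts.tsv", tmp_path / "labs.tsv", tmp_path / "meta.tsv"


META_SMALL = "D\t2\nT\t1\nW\t3\nL\t1\nV\t2\n"


class TestReadCorpus:
    def test_small_corpus_with_derived_missingness(self, tmp_path):
        paths = _write(tmp_path, META_SMALL, "1\t1\t2\t5\n2\t1\t1\t1\n", "1\t1\t1\t2\n")
        corpus = read_corpus(*paths)
        assert corpus.n_patients == 2
        assert corpus.lab_observed[0, 0] and not corpus.lab_observed[0, 1]
        assert corpus.tok_cnt.sum() == 6

    def test_empty_files_give_empty_corpus(self, tmp_path):
        paths = _write(tmp_path, "D\t0\nT\t1\nW\t3\nL\t1\nV\t2\n", "", "")
        corpus = read_corpus(*paths)
        assert corpus.n_patients == 0
        assert len(corpus.tok_pat) == 0

    def test_out_of_range_feature_names_the_feature(self, tmp_path):
        paths = _write(tmp_path, META_SMALL, "1\t1\t4\t1\n", "")
        with pytest.raises(CorpusValidationError, match="feature 4"):
            read_corpus(*paths)

    def test_malformed_line_reports_line_number(self, tmp_path):
        paths = _write(tmp_path, META_SMALL, "1\t1\t2\n", "")
        with pytest.raises(CorpusParseError, match=":1:"):
            read_corpus(*paths)

    def test_duplicate_rows_rejected(self, tmp_path):
        paths = _write(tmp_path, META_SMALL, "1\t1\t2\t5\n1\t1\t2\t3\n", "")
        with pytest.raises(CorpusValidationError, match="duplicate"):
            read_corpus(*paths)


class TestValidateCorpus:
    def test_valid_corpus_has_no_violations(self, fixture_corpus):
        assert validate_corpus(fixture_corpus) == []

    def test_record_for_unobserved_lab_flagged(self, fixture_corpus):
        broken = MultiModalCorpus(
            fixture_corpus.n_patients,
            fixture_corpus.types,
            fixture_corpus.labs,
            tokens=(fixture_corpus.tok_pat, fixture_corpus.tok_type, fixture_corpus.tok_feat, fixture_corpus.tok_cnt),
            lab_records=(fixture_corpus.lab_pat, fixture_corpus.lab_lab, fixture_corpus.lab_state, fixture_corpus.lab_freq),
            lab_observed=np.zeros_like(fixture_corpus.lab_observed),
        )
        assert any("unobserved lab" in v for v in validate_corpus(broken))

    def test_non_positive_count_flagged(self, fixture_corpus):
        cnt = fixture_corpus.tok_cnt.copy()
        cnt[0] = 0
        broken = MultiModalCorpus(
            fixture_corpus.n_patients, fixture_corpus.types, fixture_corpus.labs,
            tokens=(fixture_corpus.tok_pat, fixture_corpus.tok_type, fixture_corpus.tok_feat, cnt),
            lab_records=(fixture_corpus.lab_pat, fixture_corpus.lab_lab, fixture_corpus.lab_state, fixture_corpus.lab_freq),
        )
        assert sum("non-positive count" in v for v in validate_corpus(broken)) == 1


class TestCorpusRoundTrip:
    def test_fixture_round_trips(self, fixture_corpus, tmp_path):
        paths = (tmp_path / "c.tsv", tmp_path / "l.tsv", tmp_path / "m.tsv")
        write_corpus(fixture_corpus, *paths)
        assert read_corpus(*paths) == fixture_corpus

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), D=st.integers(1, 8))
    def test_random_synthetic_corpora_round_trip(self, seed, D, tmp_path_factory):
        from mixehr import sample_corpus, sample_truth

        hyper = ModelHyperparameters.symmetric(2, (4, 3), (2, 3))
        truth = sample_truth(hyper, D, seed)
        corpus = sample_corpus(truth, 5, seed + 1)
        assert validate_corpus(corpus) == []
        tmp = tmp_path_factory.mktemp("rt")
        paths = (tmp / "c.tsv", tmp / "l.tsv", tmp / "m.tsv")
        write_corpus(corpus, *paths)
        assert read_corpus(*paths) == corpus


class TestModelIO:
    def _toy(self):
        est = ParameterEstimates(
            theta=np.array([[0.25, 0.75], [0.5, 0.5]]),
            phi=[np.array([[0.2, 0.6], [0.8, 0.4]])],
            eta=[np.array([[0.3, 0.7], [0.9, 0.1]])],
            psi=np.array([[0.4, 0.6]]),
        )
        hyper = ModelHyperparameters.symmetric(2, (2,), (2,))
        return est, hyper

    def test_round_trip_exact(self, tmp_path):
        est, hyper = self._toy()
        path = tmp_path / "model.json"
        write_model(est, hyper, path)
        est2, hyper2 = read_model(path)
        for a, b in [
            (est.theta, est2.theta), (est.phi[0], est2.phi[0]),
            (est.eta[0], est2.eta[0]), (est.psi, est2.psi),
            (hyper.alpha, hyper2.alpha), (hyper.beta[0], hyper2.beta[0]),
        ]:
            assert np.max(np.abs(a - b)) <= 1e-12 * np.max(np.abs(a))

    def test_invalid_theta_rejected(self, tmp_path):
        est, hyper = self._toy()
        est.theta = np.array([[0.5, 0.4]])
        with pytest.raises(CorpusValidationError, match="theta"):
            write_model(est, hyper, tmp_path / "model.json")

    def test_model_without_labs(self, tmp_path):
        est = ParameterEstimates(
            theta=np.array([[1.0]]),
            phi=[np.array([[0.5], [0.5]])],
            eta=[],
            psi=np.zeros((0, 1)),
        )
        hyper = ModelHyperparameters.symmetric(1, (2,), ())
        path = tmp_path / "model.json"
        write_model(est, hyper, path)
        est2, _ = read_model(path)
        assert est2.eta == [] and est2.psi.shape[0] == 0
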