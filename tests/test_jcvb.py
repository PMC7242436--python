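"""Batch collapsed variational inference: updates, statistics, EM loop."""

import numpy as np
import pytest

from mixehr import (
    ModelHyperparameters,
    MultiModalCorpus,
    TrainConfig,
    estimate_parameters,
    fit_jcvb,
    initialize_state,
    refresh_statistics,
    sweep,
    update_gamma,
    update_hyperparameters,
    update_lambda,
    update_pi,
)
from mixehr.jcvb import update_hyperparameters_from_counts
from mixehr.oracles import oracle_update
from mixehr.synthetic import GammaPrior


def _assignments(state, corpus):
    return (
        [list(g) for g in state.gamma],
        [list(l) for l in state.lam],
        [
            [list(row[: corpus.lab_sizes[state.mis_lab[u]]]) for row in state.pi[u]]
            for u in range(len(state.mis_pat))
        ],
        list(state.mis_pat),
        list(state.mis_lab),
    )


class TestInitialization:
    def test_same_seed_identical(self, fixture_corpus):
        a = initialize_state(fixture_corpus, 3, seed=1)
        b = initialize_state(fixture_corpus, 3, seed=1)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(a.pi, b.pi)

    def test_token_conservation_at_init(self, fixture_corpus):
        state = initialize_state(fixture_corpus, 2, seed=0)
        M = fixture_corpus.tokens_per_patient().sum(axis=0)
        assert np.allclose(state.n_jk.sum(axis=1), M, atol=1e-9)

    def test_single_topic_statistics_are_raw_counts(self, fixture_corpus):
        state = initialize_state(fixture_corpus, 1, seed=0)
        assert np.allclose(state.gamma, 1.0)
        np.testing.assert_allclose(
            state.n_jk[:, 0],
            fixture_corpus.tokens_per_patient().sum(axis=0),
            atol=1e-12,
        )

    def test_invalid_K_rejected(self, fixture_corpus):
        with pytest.raises(ValueError, match="K"):
            initialize_state(fixture_corpus, 0, seed=0)


class TestRecordUpdates:
    def test_single_topic_updates_are_degenerate(self, fixture_corpus, state2):
        state = initialize_state(fixture_corpus, 1, seed=0)
        hyper = ModelHyperparameters.symmetric(1, fixture_corpus.type_sizes, fixture_corpus.lab_sizes)
        assert update_gamma(state, hyper, 0) == pytest.approx([1.0])
        assert update_lambda(state, hyper, 0) == pytest.approx([1.0])

    def test_symmetric_state_gives_uniform_updates(self, state2, hyper2):
        # a perfectly symmetric configuration cannot prefer either topic
        state2.gamma[:] = 0.5
        state2.lam[:] = 0.5
        state2.pi[:] = 0.25
        refresh_statistics(state2)
        np.testing.assert_allclose(update_gamma(state2, hyper2, 3), [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(update_lambda(state2, hyper2, 2), [0.5, 0.5], atol=1e-12)
        # topic symmetry: observed state frequencies may differ over v, but
        # nothing distinguishes the two topics
        pi = update_pi(state2, hyper2, 5, 0)
        np.testing.assert_allclose(pi[0], pi[1], atol=1e-12)
        np.testing.assert_allclose(pi.sum(axis=1), 0.5, atol=1e-12)

    def test_pi_uniform_when_states_symmetric(self):
        # no observed labs at all: zero m, symmetric zeta -> uniform pi
        corpus = MultiModalCorpus(2, (3,), (2,), tokens=([0, 1], [0, 0], [0, 1], [2, 2]))
        state = initialize_state(corpus, 2, seed=0)
        hyper = ModelHyperparameters.symmetric(2, (3,), (2,))
        state.gamma[:] = 0.5
        state.pi[:] = 0.25
        refresh_statistics(state)
        np.testing.assert_allclose(update_pi(state, hyper, 0, 0), 0.25, atol=1e-12)

    def test_pi_normalizes_jointly(self, state2, hyper2, fixture_corpus):
        u = 0
        j, l = state2.mis_pat[u], state2.mis_lab[u]
        pi = update_pi(state2, hyper2, j, l)
        assert pi.shape == (2, fixture_corpus.lab_sizes[l])
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_contract_violations(self, state2, hyper2, fixture_corpus):
        j_obs, l_obs = fixture_corpus.lab_pat[0], fixture_corpus.lab_lab[0]
        with pytest.raises(ValueError, match="observed"):
            update_pi(state2, hyper2, j_obs, l_obs)

    @pytest.mark.parametrize("which,n_records", [("gamma", 19), ("lambda", 7), ("pi", 5)])
    def test_updates_match_term_by_term_oracle(self, fixture_corpus, state2, hyper2, which, n_records):
        assignments = _assignments(state2, fixture_corpus)
        for r in range(n_records):
            ref = oracle_update(fixture_corpus, assignments, hyper2, r, which)
            if which == "gamma":
                got = update_gamma(state2, hyper2, r)
            elif which == "lambda":
                got = update_lambda(state2, hyper2, r)
            else:
                j, l = state2.mis_pat[r], state2.mis_lab[r]
                got = update_pi(state2, hyper2, j, l)
            np.testing.assert_allclose(got, ref, atol=1e-12)


class TestRefreshStatistics:
    def test_no_lab_corpus_has_zero_lab_statistics(self):
        corpus = MultiModalCorpus(3, (4,), (), tokens=([0, 1, 2], [0, 0, 0], [0, 1, 2], [2, 1, 3]))
        state = initialize_state(corpus, 2, seed=0)
        assert state.m_jk.sum() == 0 and state.p.size == 0

    def test_conservation_after_sweep_and_refresh(self, fixture_corpus, hyper2, state2):
        sweep(state2, hyper2)
        refresh_statistics(state2)
        M = fixture_corpus.tokens_per_patient().sum(axis=0)
        assert np.allclose(state2.n_jk.sum(axis=1), M, atol=1e-9)
        # per-(lab, patient) mass: y total when observed, 1 when unobserved
        for l in range(fixture_corpus.n_labs):
            for j in range(fixture_corpus.n_patients):
                m = (fixture_corpus.lab_pat == j) & (fixture_corpus.lab_lab == l)
                expect = fixture_corpus.lab_freq[m].sum() if fixture_corpus.lab_observed[l, j] else 1.0
                u = (state2.mis_pat == j) & (state2.mis_lab == l)
                mass = (state2.lam[m] * fixture_corpus.lab_freq[m, None]).sum() + state2.pi[u].sum()
                assert mass == pytest.approx(expect, abs=1e-9)


class TestHyperparameterUpdates:
    def test_zero_counts_return_prior_mode_exactly(self):
        # digamma terms cancel at zero counts: beta* = (a_beta - 1)/b_beta
        hyper = ModelHyperparameters.symmetric(2, (3,), (2,))
        hyper.priors["beta"] = GammaPrior(shape=2.0, rate=1.0)
        new = update_hyperparameters_from_counts(
            hyper,
            np.zeros((4, 2)),
            [np.zeros((3, 2))],
            [np.zeros((2, 2))],
            np.zeros((1, 2)),
            np.zeros((1, 2)),
        )
        assert new.beta[0] == pytest.approx([1.0, 1.0, 1.0], abs=0)

    def test_positivity_on_fixture_state(self, state2, hyper2):
        new = update_hyperparameters(state2, hyper2)
        assert (new.alpha > 0).all()
        assert all((b > 0).all() for b in new.beta)
        assert all((z > 0).all() for z in new.zeta)
        assert (new.a > 0).all() and (new.b > 0).all()


class TestEstimates:
    def test_zero_statistics_give_prior_means(self, fixture_corpus, hyper2):
        from mixehr import VariationalState

        state = VariationalState(fixture_corpus, 2)  # all-zero caches
        est = estimate_parameters(state, hyper2)
        np.testing.assert_allclose(est.theta, 0.5)
        np.testing.assert_allclose(est.eta[0], 0.5)
        np.testing.assert_allclose(est.psi, 0.5)

    def test_stochasticity_and_formula(self, state2, hyper2):
        est = estimate_parameters(state2, hyper2)
        est.validate()
        expect = hyper2.alpha + state2.n_jk[0] + state2.m_jk[0]
        np.testing.assert_allclose(est.theta[0], expect / expect.sum(), atol=1e-12)
        t = 0
        num = hyper2.beta[t][:, None] + state2.n_wk[state2.phi_slice(t)]
        np.testing.assert_allclose(est.phi[t], num / num.sum(axis=0), atol=1e-12)

    def test_lab_mass_flag_changes_theta_only(self, state2, hyper2):
        a = estimate_parameters(state2, hyper2, include_lab_mass=True)
        b = estimate_parameters(state2, hyper2, include_lab_mass=False)
        assert not np.allclose(a.theta, b.theta)
        np.testing.assert_array_equal(a.phi[0], b.phi[0])


class TestFit:
    def test_single_topic_closed_form(self, fixture_corpus):
        est, state, trace = fit_jcvb(
            fixture_corpus, 1, config=TrainConfig(max_sweeps=5, update_hyper=False), seed=0
        )
        for t in range(fixture_corpus.n_types):
            counts = np.zeros(fixture_corpus.type_sizes[t])
            m = fixture_corpus.tok_type == t
            np.add.at(counts, fixture_corpus.tok_feat[m], fixture_corpus.tok_cnt[m])
            beta = 0.1
            expect = (beta + counts) / (beta * len(counts) + counts.sum())
            np.testing.assert_allclose(est.phi[t][:, 0], expect, atol=1e-12)

    def test_monitored_likelihood_finite_and_improves(self, fixture_corpus):
        _, _, trace = fit_jcvb(
            fixture_corpus, 2, config=TrainConfig(max_sweeps=30, update_hyper=False), seed=1
        )
        lls = [row["log_likelihood"] for row in trace]
        assert all(np.isfinite(lls))
        assert lls[-1] >= lls[0]

    def test_determinism(self, fixture_corpus):
        a = fit_jcvb(fixture_corpus, 2, config=TrainConfig(max_sweeps=10), seed=3)
        b = fit_jcvb(fixture_corpus, 2, config=TrainConfig(max_sweeps=10), seed=3)
        np.testing.assert_array_equal(a[0].theta, b[0].theta)
        np.testing.assert_array_equal(a[0].phi[0], b[0].phi[0])

    def test_normalization_after_every_sweep(self, fixture_corpus, hyper2):
        state = initialize_state(fixture_corpus, 2, seed=2)
        for _ in range(5):
            sweep(state, hyper2)
            assert state.normalization_errors() < 1e-9
            refresh_statistics(state)
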