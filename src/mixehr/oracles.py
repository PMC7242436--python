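"""Loop-literal reference implementations used to validate the fast code.

These functions re-derive every quantity by explicit scalar loops over
records, with no caching, no vectorization, and no code shared with the
optimized inference modules.  They exist so the test suite can check the
incremental Gauss-Seidel bookkeeping of the compiled sweep against a
transparent transcription of the update equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .corpus import MultiModalCorpus
from .synthetic import ModelHyperparameters

__all__ = [
    "OracleReport",
    "oracle_soft_suffstats",
    "oracle_hard_suffstats",
    "oracle_update",
    "oracle_estep",
    "oracle_collapsed_loglik",
    "run_selftest",
]


@dataclass
class OracleReport:
    op: str
    max_abs_deviation: float
    instance: str
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.max_abs_deviation < self.tolerance


# ---------------------------------------------------------------------------
# Sufficient statistics.
# ---------------------------------------------------------------------------

def oracle_soft_suffstats(corpus: MultiModalCorpus, gamma, lam, pi, mis_pat, mis_lab, K: int):
    """Expected sufficient statistics by quadruple loops.

    gamma: (R, K) aligned with the corpus token records; lam: (Ro, K)
    aligned with the observed lab records; pi: (Ru, K, Vmax) aligned with
    (mis_pat, mis_lab).  Returns dict of n_jk, n_wk (per type), m_jk,
    m_vk (per lab), p, q.
    """
    D, T, L = corpus.n_patients, corpus.n_types, corpus.n_labs
    n_jk = np.zeros((D, K))
    n_wk = [np.zeros((int(w), K)) for w in corpus.type_sizes]
    m_jk = np.zeros((D, K))
    m_vk = [np.zeros((int(v), K)) for v in corpus.lab_sizes]
    p = np.zeros((L, K))
    q = np.zeros((L, K))
    for r in range(len(corpus.tok_pat)):
        j, t, w, c = corpus.tok_pat[r], corpus.tok_type[r], corpus.tok_feat[r], corpus.tok_cnt[r]
        for k in range(K):
            n_jk[j, k] += c * gamma[r][k]
            n_wk[t][w, k] += c * gamma[r][k]
    for r in range(len(corpus.lab_pat)):
        j, l, v, y = corpus.lab_pat[r], corpus.lab_lab[r], corpus.lab_state[r], corpus.lab_freq[r]
        for k in range(K):
            m_jk[j, k] += y * lam[r][k]
            m_vk[l][v, k] += y * lam[r][k]
            p[l, k] += y * lam[r][k]
    for u in range(len(mis_pat)):
        j, l = mis_pat[u], mis_lab[u]
        for k in range(K):
            for v in range(int(corpus.lab_sizes[l])):
                m_jk[j, k] += pi[u][k][v]
                m_vk[l][v, k] += pi[u][k][v]
                q[l, k] += pi[u][k][v]
    return {"n_jk": n_jk, "n_wk": n_wk, "m_jk": m_jk, "m_vk": m_vk, "p": p, "q": q}


def oracle_hard_suffstats(corpus: MultiModalCorpus, z, h, y_miss=None, K=None):
    """Hard-assignment counts: n, m, p, q from sampled topic assignments.

    z: per token record, one topic shared by all identical tokens of the
    record; h: (L, D) topic per (lab, patient); y_miss: optional (L, D)
    imputed state for unobserved pairs (needed for q's state breakdown).
    """
    K_data = int(max(np.max(z) if len(z) else 0, h.max() if h.size else 0)) + 1
    if K is None:
        K = K_data
    D, L = corpus.n_patients, corpus.n_labs
    n_jk = np.zeros((D, K))
    n_wk = [np.zeros((int(w), K)) for w in corpus.type_sizes]
    m_jk = np.zeros((D, K))
    m_vk = [np.zeros((int(v), K)) for v in corpus.lab_sizes]
    p = np.zeros((L, K))
    q = np.zeros((L, K))
    for r in range(len(corpus.tok_pat)):
        j, t, w, c = corpus.tok_pat[r], corpus.tok_type[r], corpus.tok_feat[r], corpus.tok_cnt[r]
        n_jk[j, z[r]] += c
        n_wk[t][w, z[r]] += c
    for r in range(len(corpus.lab_pat)):
        j, l, v, y = corpus.lab_pat[r], corpus.lab_lab[r], corpus.lab_state[r], corpus.lab_freq[r]
        m_jk[j, h[l, j]] += y
        m_vk[l][v, h[l, j]] += y
        p[l, h[l, j]] += y
    for l in range(L):
        for j in range(D):
            if not corpus.lab_observed[l, j]:
                q[l, h[l, j]] += 1
                if y_miss is not None:
                    m_jk[j, h[l, j]] += 1
                    m_vk[l][y_miss[l, j], h[l, j]] += 1
    return {"n_jk": n_jk, "n_wk": n_wk, "m_jk": m_jk, "m_vk": m_vk, "p": p, "q": q, "K": K_data}


# ---------------------------------------------------------------------------
# Single-record updates, term by term.
# ---------------------------------------------------------------------------

def _token_stats_excluding(corpus, gamma, K, record):
    """n_jk^-(i,j) and n_wk^(t)-/n_.k^(t)- with the record's own mass removed."""
    j0, t0, w0 = corpus.tok_pat[record], corpus.tok_type[record], corpus.tok_feat[record]
    nj = [0.0] * K
    nw = [0.0] * K
    nt = [0.0] * K
    for r in range(len(corpus.tok_pat)):
        if r == record:
            continue
        j, t, w, c = corpus.tok_pat[r], corpus.tok_type[r], corpus.tok_feat[r], corpus.tok_cnt[r]
        for k in range(K):
            if j == j0:
                nj[k] += c * gamma[r][k]
            if t == t0:
                nt[k] += c * gamma[r][k]
                if w == w0:
                    nw[k] += c * gamma[r][k]
    return nj, nw, nt


def _lab_mass_of_patient(corpus, lam, pi, mis_pat, mis_lab, K, j0, exclude_lab=None):
    """m_jk for patient j0, optionally excluding one lab entirely."""
    m = [0.0] * K
    for r in range(len(corpus.lab_pat)):
        if corpus.lab_pat[r] != j0 or corpus.lab_lab[r] == exclude_lab:
            continue
        for k in range(K):
            m[k] += corpus.lab_freq[r] * lam[r][k]
    for u in range(len(mis_pat)):
        if mis_pat[u] != j0 or mis_lab[u] == exclude_lab:
            continue
        for k in range(K):
            for v in range(int(corpus.lab_sizes[mis_lab[u]])):
                m[k] += pi[u][k][v]
    return m


def _lab_state_stats(corpus, lam, pi, mis_pat, mis_lab, K, l0, exclude_record=None, exclude_pair=None):
    """m_vk, p, q for lab l0 with optional own-record / own-pair exclusion."""
    V = int(corpus.lab_sizes[l0])
    m = [[0.0] * V for _ in range(K)]
    p = [0.0] * K
    q = [0.0] * K
    for r in range(len(corpus.lab_pat)):
        if corpus.lab_lab[r] != l0:
            continue
        j, v, y = corpus.lab_pat[r], corpus.lab_state[r], corpus.lab_freq[r]
        for k in range(K):
            if r != exclude_record:
                m[k][v] += y * lam[r][k]
            if j != exclude_pair:
                p[k] += y * lam[r][k]
    for u in range(len(mis_pat)):
        if mis_lab[u] != l0:
            continue
        j = mis_pat[u]
        for k in range(K):
            for v in range(V):
                if (u, v) != exclude_record:
                    m[k][v] += pi[u][k][v]
                if j != exclude_pair:
                    q[k] += pi[u][k][v]
    return m, p, q


def oracle_update(corpus, assignments, hyper: ModelHyperparameters, record, which: str):
    """Term-by-term evaluation of one collapsed update.

    ``assignments`` is (gamma, lam, pi, mis_pat, mis_lab); ``record`` is a
    token record index for ``gamma``, an observed lab record index for
    ``lambda``, or an unobserved-pair index for ``pi``.
    """
    gamma, lam, pi, mis_pat, mis_lab = assignments
    K = hyper.n_topics
    alpha = hyper.alpha
    if which == "gamma":
        j, t, w = corpus.tok_pat[record], corpus.tok_type[record], corpus.tok_feat[record]
        nj, nw, nt = _token_stats_excluding(corpus, gamma, K, record)
        mj = _lab_mass_of_patient(corpus, lam, pi, mis_pat, mis_lab, K, j)
        beta_sum = float(hyper.beta[t].sum())
        out = [
            (alpha[k] + nj[k] + mj[k]) * (hyper.beta[t][w] + nw[k]) / (beta_sum + nt[k])
            for k in range(K)
        ]
        tot = sum(out)
        return np.array([o / tot for o in out])

    if which == "lambda":
        j, l, v = corpus.lab_pat[record], corpus.lab_lab[record], corpus.lab_state[record]
        stats_all = oracle_soft_suffstats(corpus, gamma, lam, pi, mis_pat, mis_lab, K)
        nj = stats_all["n_jk"][j]
        mj = _lab_mass_of_patient(corpus, lam, pi, mis_pat, mis_lab, K, j, exclude_lab=l)
        m_ex, p_ex, _ = _lab_state_stats(
            corpus, lam, pi, mis_pat, mis_lab, K, l, exclude_record=record, exclude_pair=j
        )
        q_all = stats_all["q"][l]
        zeta_sum = float(hyper.zeta[l].sum())
        out = []
        for k in range(K):
            msum = sum(m_ex[k][vv] for vv in range(int(corpus.lab_sizes[l])))
            out.append(
                (alpha[k] + nj[k] + mj[k])
                * (hyper.zeta[l][v] + m_ex[k][v]) / (zeta_sum + msum)
                * (hyper.a[l] + p_ex[k]) / (hyper.a[l] + p_ex[k] + hyper.b[l] + q_all[k])
            )
        tot = sum(out)
        return np.array([o / tot for o in out])

    if which == "pi":
        u = record
        j, l = mis_pat[u], mis_lab[u]
        V = int(corpus.lab_sizes[l])
        stats_all = oracle_soft_suffstats(corpus, gamma, lam, pi, mis_pat, mis_lab, K)
        nj = stats_all["n_jk"][j]
        mj = _lab_mass_of_patient(corpus, lam, pi, mis_pat, mis_lab, K, j, exclude_lab=l)
        p_all = stats_all["p"][l]
        zeta_sum = float(hyper.zeta[l].sum())
        out = np.zeros((K, V))
        for k in range(K):
            q_ex = 0.0
            for uu in range(len(mis_pat)):
                if mis_lab[uu] == l and mis_pat[uu] != j:
                    for vv in range(V):
                        q_ex += pi[uu][k][vv]
            for v in range(V):
                m_ex, _, _ = _lab_state_stats(
                    corpus, lam, pi, mis_pat, mis_lab, K, l, exclude_record=(u, v)
                )
                msum = sum(m_ex[k][vv] for vv in range(V))
                out[k, v] = (
                    (alpha[k] + nj[k] + mj[k])
                    * (hyper.zeta[l][v] + m_ex[k][v]) / (zeta_sum + msum)
                    * (hyper.b[l] + q_ex) / (hyper.a[l] + p_all[k] + hyper.b[l] + q_ex)
                )
        return out / out.sum()

    raise ValueError("which must be 'gamma', 'lambda' or 'pi'")


def oracle_estep(corpus, assignments, hyper: ModelHyperparameters):
    """One full Gauss-Seidel E-step by repeated term-by-term evaluation.

    Visits patients in index order; per patient: token records, then
    observed lab records, then unobserved labs — the same discipline as the
    optimized sweep, but every exclusion sum recomputed from scratch.
    Mutates and returns the assignment lists.
    """
    gamma, lam, pi, mis_pat, mis_lab = assignments
    for j in range(corpus.n_patients):
        for r in range(len(corpus.tok_pat)):
            if corpus.tok_pat[r] == j:
                gamma[r] = list(oracle_update(corpus, assignments, hyper, r, "gamma"))
        for r in range(len(corpus.lab_pat)):
            if corpus.lab_pat[r] == j:
                lam[r] = list(oracle_update(corpus, assignments, hyper, r, "lambda"))
        for u in range(len(mis_pat)):
            if mis_pat[u] == j:
                pi[u] = [list(row) for row in oracle_update(corpus, assignments, hyper, u, "pi")]
    return assignments


# ---------------------------------------------------------------------------
# Collapsed marginal likelihood (hard assignments).
# ---------------------------------------------------------------------------

def oracle_collapsed_loglik(corpus, z, h, hyper: ModelHyperparameters, y_miss=None) -> float:
    """Closed-form collapsed joint log-likelihood of data + hard assignments.

    The product of Dirichlet-multinomial and Beta-Bernoulli Gamma-function
    ratios, evaluated in log space.  Used to verify the hyperparameter
    fixed point and to check that better assignments score higher.
    """
    hyper.validate()
    K = hyper.n_topics
    s = oracle_hard_suffstats(corpus, z, h, y_miss, K=K)
    if s["K"] > K:
        raise ValueError("assignments use more topics than hyper declares")
    total = 0.0
    alpha = hyper.alpha
    for j in range(corpus.n_patients):
        total += gammaln(alpha.sum()) - gammaln(alpha).sum()
        cj = s["n_jk"][j] + s["m_jk"][j]
        total += gammaln(alpha + cj).sum() - gammaln(alpha.sum() + cj.sum())
    for t in range(corpus.n_types):
        beta = hyper.beta[t]
        for k in range(K):
            nk = s["n_wk"][t][:, k]
            total += gammaln(beta.sum()) - gammaln(beta).sum()
            total += gammaln(beta + nk).sum() - gammaln(beta.sum() + nk.sum())
    for l in range(corpus.n_labs):
        zeta = hyper.zeta[l]
        a, b = hyper.a[l], hyper.b[l]
        for k in range(K):
            mk = s["m_vk"][l][:, k]
            total += gammaln(zeta.sum()) - gammaln(zeta).sum()
            total += gammaln(zeta + mk).sum() - gammaln(zeta.sum() + mk.sum())
            total += gammaln(a + b) - gammaln(a) - gammaln(b)
            total += gammaln(a + s["p"][l, k]) + gammaln(b + s["q"][l, k])
            total -= gammaln(a + s["p"][l, k] + b + s["q"][l, k])
    if not math.isfinite(total):
        raise FloatingPointError("non-finite collapsed log-likelihood")
    return float(total)


# ---------------------------------------------------------------------------
# Self-test harness (also behind `mixehr selftest`).
# ---------------------------------------------------------------------------

def run_selftest() -> list[OracleReport]:
    """Compare the optimized sweep and statistics against all oracles."""
    from .jcvb import initialize_state, refresh_statistics, sweep
    from .synthetic import ModelHyperparameters, make_fixture

    corpus, _ = make_fixture()
    K = 2
    hyper = ModelHyperparameters.symmetric(K, corpus.type_sizes, corpus.lab_sizes)
    state = initialize_state(corpus, K, seed=7)
    assignments = (
        [list(g) for g in state.gamma],
        [list(l) for l in state.lam],
        [[list(row[: corpus.lab_sizes[state.mis_lab[u]]]) for row in state.pi[u]] for u in range(len(state.mis_pat))],
        list(state.mis_pat),
        list(state.mis_lab),
    )
    reports = []

    ref = oracle_soft_suffstats(corpus, *assignments, K)
    dev = max(
        np.abs(ref["n_jk"] - state.n_jk).max(),
        max(np.abs(ref["n_wk"][t] - state.n_wk[state.phi_slice(t)]).max() for t in range(corpus.n_types)),
        np.abs(ref["m_jk"] - state.m_jk).max(),
        max(np.abs(ref["m_vk"][l].T - state.m_vk[state.lab_slice(l)].T).max() for l in range(corpus.n_labs)),
        np.abs(ref["p"] - state.p).max(),
        np.abs(ref["q"] - state.q).max(),
    )
    reports.append(OracleReport("refresh_statistics", float(dev), "fixture K=2", 1e-10))

    oracle_estep(corpus, assignments, hyper)
    sweep(state, hyper)
    dev = max(
        np.abs(np.array(assignments[0]) - state.gamma).max() if len(state.gamma) else 0.0,
        np.abs(np.array(assignments[1]) - state.lam).max() if len(state.lam) else 0.0,
        max(
            (
                np.abs(
                    np.array(assignments[2][u])
                    - state.pi[u, :, : corpus.lab_sizes[state.mis_lab[u]]]
                ).max()
                for u in range(len(state.mis_pat))
            ),
            default=0.0,
        ),
    )
    reports.append(OracleReport("full_e_step", float(dev), "fixture K=2", 1e-10))

    refresh_statistics(state)
    ref = oracle_soft_suffstats(corpus, *assignments, K)
    dev = max(
        np.abs(ref["n_jk"] - state.n_jk).max(),
        np.abs(ref["m_jk"] - state.m_jk).max(),
        np.abs(ref["p"] - state.p).max(),
        np.abs(ref["q"] - state.q).max(),
    )
    reports.append(OracleReport("post_sweep_refresh", float(dev), "fixture K=2", 1e-10))
    return reports
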