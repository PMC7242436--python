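"""Batch joint collapsed variational Bayesian inference (JCVB0).

The patient mixtures theta, topic matrices phi, lab-result distributions
eta, and observation probabilities psi are integrated out analytically;
inference maintains only the per-record topic assignment distributions
(gamma for tokens, lambda for observed lab records, pi jointly over topic
and result state for unobserved labs) and their cached expected sufficient
statistics.  Updates are zero-order collapsed variational (CVB0): products
of ratios of smoothed expected counts with the record's own contribution
excluded, renormalized in linear space.

Sufficient-statistic caches (all expectations under q):

==========  =========  ====================================================
name        shape      meaning
==========  =========  ====================================================
n_jk        (D, K)     token mass of patient j on topic k
n_wk        (SumW, K)  feature-by-topic mass, types stacked via type_off
n_tk        (T, K)     per-type totals (denominators of the phi ratio)
m_jk        (D, K)     lab mass of patient j (observed y-weighted lambda
                       plus unobserved pi mass)
m_vk        (SumV, K)  lab-state-by-topic mass, labs stacked via lab_off
p, q        (L, K)     observed / unobserved Beta exposure masses
==========  =========  ====================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import psi as digamma

from ._kernels import sweep_kernel
from .corpus import MultiModalCorpus, ParameterEstimates
from .synthetic import ModelHyperparameters

__all__ = [
    "VariationalState",
    "TrainConfig",
    "TrainingDivergedError",
    "initialize_state",
    "refresh_statistics",
    "update_gamma",
    "update_lambda",
    "update_pi",
    "update_hyperparameters",
    "estimate_parameters",
    "sweep",
    "fit_jcvb",
]

HYPER_FLOOR = 1e-6


class TrainingDivergedError(RuntimeError):
    def __init__(self, iteration: int, message: str = "non-finite monitored likelihood"):
        self.iteration = iteration
        super().__init__(f"{message} at iteration {iteration}")


class VariationalState:
    """Assignment distributions plus cached sufficient statistics.

    Construction packs the corpus into flat patient-major arrays consumed
    by the compiled sweep kernel; :func:`initialize_state` is the public
    entry point.
    """

    def __init__(self, corpus: MultiModalCorpus, K: int):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.corpus = corpus
        self.K = int(K)
        D = corpus.n_patients
        W = corpus.type_sizes
        V = corpus.lab_sizes
        self.type_off = np.concatenate(([0], np.cumsum(W))).astype(np.int64)
        self.lab_off = np.concatenate(([0], np.cumsum(V))).astype(np.int64) if len(V) else np.zeros(1, dtype=np.int64)
        self.Vmax = int(V.max()) if len(V) else 1

        # token records (already patient-major in the corpus)
        self.tok_col = self.type_off[corpus.tok_type] + corpus.tok_feat
        self.tok_start = np.searchsorted(corpus.tok_pat, np.arange(D + 1)).astype(np.int64)
        # observed lab records
        self.obs_row = (self.lab_off[corpus.lab_lab] + corpus.lab_state if len(V) else np.zeros(0, dtype=np.int64))
        self.obs_start = np.searchsorted(corpus.lab_pat, np.arange(D + 1)).astype(np.int64)
        # unobserved (lab, patient) pairs, patient-major then lab order
        if corpus.n_labs:
            mis_pat, mis_lab = np.nonzero(~corpus.lab_observed.T)
        else:
            mis_pat = mis_lab = np.zeros(0, dtype=np.int64)
        self.mis_pat = mis_pat.astype(np.int64)
        self.mis_lab = mis_lab.astype(np.int64)
        self.mis_start = np.searchsorted(self.mis_pat, np.arange(D + 1)).astype(np.int64)

        R, Ro, Ru = len(corpus.tok_pat), len(corpus.lab_pat), len(self.mis_pat)
        self.gamma = np.full((R, K), 1.0 / K)
        self.lam = np.full((Ro, K), 1.0 / K)
        self.pi = np.zeros((Ru, K, self.Vmax))
        for l in range(corpus.n_labs):
            rows = self.mis_lab == l
            self.pi[rows, :, : V[l]] = 1.0 / (K * V[l])

        T, L = corpus.n_types, corpus.n_labs
        self.n_jk = np.zeros((D, K))
        self.m_jk = np.zeros((D, K))
        self.n_wk = np.zeros((int(W.sum()), K))
        self.n_tk = np.zeros((T, K))
        self.m_vk = np.zeros((int(V.sum()), K))
        self.p = np.zeros((L, K))
        self.q = np.zeros((L, K))

    # -------------------------------------------------------------- helpers
    def copy(self) -> "VariationalState":
        new = object.__new__(VariationalState)
        new.__dict__.update(self.__dict__)
        for name in ("gamma", "lam", "pi", "n_jk", "m_jk", "n_wk", "n_tk", "m_vk", "p", "q"):
            setattr(new, name, getattr(self, name).copy())
        return new

    def phi_slice(self, t: int) -> slice:
        return slice(self.type_off[t], self.type_off[t + 1])

    def lab_slice(self, l: int) -> slice:
        return slice(self.lab_off[l], self.lab_off[l + 1])

    def normalization_errors(self) -> float:
        """Worst deviation of any gamma/lambda/pi from summing to one."""
        errs = [0.0]
        if len(self.gamma):
            errs.append(np.abs(self.gamma.sum(axis=1) - 1).max())
        if len(self.lam):
            errs.append(np.abs(self.lam.sum(axis=1) - 1).max())
        if len(self.pi):
            errs.append(np.abs(self.pi.sum(axis=(1, 2)) - 1).max())
        return max(errs)


def _hyper_flat(hyper: ModelHyperparameters):
    beta_flat = np.concatenate(hyper.beta) if hyper.beta else np.zeros(0)
    beta_sum = np.array([b.sum() for b in hyper.beta])
    zeta_flat = np.concatenate(hyper.zeta) if hyper.zeta else np.zeros(0)
    zeta_sum = np.array([z.sum() for z in hyper.zeta]) if hyper.zeta else np.zeros(0)
    return beta_flat, beta_sum, zeta_flat, zeta_sum


def initialize_state(corpus: MultiModalCorpus, K: int, seed: int) -> VariationalState:
    """Seeded perturbed-uniform assignments with consistent statistics.

    Each gamma/lambda entry is drawn uniformly in [1/K - eps, 1/K + eps]
    (eps = 0.1/K) and normalized; pi is uniform over (topic, state).
    """
    state = VariationalState(corpus, K)
    rng = np.random.default_rng(seed)
    eps = 0.1 / K
    for arr in (state.gamma, state.lam):
        if arr.size:
            raw = 1.0 / K + rng.uniform(-eps, eps, size=arr.shape)
            arr[:] = raw / raw.sum(axis=1, keepdims=True)
    refresh_statistics(state)
    return state


def refresh_statistics(state: VariationalState, corpus: MultiModalCorpus | None = None) -> VariationalState:
    """Recompute every cached statistic from the assignments, from scratch.

    Replaces the incrementally maintained caches, cancelling floating-point
    drift; run once per sweep.
    """
    c = corpus if corpus is not None else state.corpus
    K = state.K
    state.n_jk[:] = 0
    state.n_wk[:] = 0
    state.m_jk[:] = 0
    state.m_vk[:] = 0
    state.p[:] = 0
    state.q[:] = 0
    if len(c.tok_pat):
        wgamma = state.gamma * c.tok_cnt[:, None]
        np.add.at(state.n_jk, c.tok_pat, wgamma)
        np.add.at(state.n_wk, state.tok_col, wgamma)
    for t in range(c.n_types):
        state.n_tk[t] = state.n_wk[state.phi_slice(t)].sum(axis=0)
    if len(c.lab_pat):
        wlam = state.lam * c.lab_freq[:, None]
        np.add.at(state.m_jk, c.lab_pat, wlam)
        np.add.at(state.m_vk, state.obs_row, wlam)
        np.add.at(state.p, c.lab_lab, wlam)
    if len(state.mis_pat):
        mass = state.pi.sum(axis=2)  # (Ru, K)
        np.add.at(state.m_jk, state.mis_pat, mass)
        np.add.at(state.q, state.mis_lab, mass)
        for v in range(state.Vmax):
            rows = state.lab_off[state.mis_lab] + v
            ok = v < c.lab_sizes[state.mis_lab]
            np.add.at(state.m_vk, rows[ok], state.pi[ok, :, v])
    return state


# ---------------------------------------------------------------------------
# Single-record updates (reference-grade Python; the kernel is equivalent).
# ---------------------------------------------------------------------------

def _clip0(x):
    return np.maximum(x, 0.0)


def update_gamma(state: VariationalState, hyper: ModelHyperparameters, record: int) -> np.ndarray:
    """Collapsed update for one token record; returns the normalized K-vector."""
    c = state.corpus
    j, t, col = c.tok_pat[record], c.tok_type[record], state.tok_col[record]
    own = state.gamma[record] * c.tok_cnt[record]
    nj = _clip0(state.n_jk[j] - own)
    nw = _clip0(state.n_wk[col] - own)
    nt = _clip0(state.n_tk[t] - own)
    beta_wt = hyper.beta[t][c.tok_feat[record]]
    val = (hyper.alpha + nj + state.m_jk[j]) * (beta_wt + nw) / (hyper.beta[t].sum() + nt)
    return val / val.sum()


def _obs_group(state: VariationalState, record: int):
    """Indices of all observed records sharing this record's (patient, lab)."""
    c = state.corpus
    j, l = c.lab_pat[record], c.lab_lab[record]
    grp = np.nonzero((c.lab_pat == j) & (c.lab_lab == l))[0]
    return j, l, grp


def update_lambda(state: VariationalState, hyper: ModelHyperparameters, record: int) -> np.ndarray:
    """Collapsed update for one observed lab record (j, l, v)."""
    c = state.corpus
    j, l, grp = _obs_group(state, record)
    if not c.lab_observed[l, j]:
        raise ValueError(f"lab {l} is not observed for patient {j}")
    sl = state.lab_slice(l)
    own = state.lam[record] * c.lab_freq[record]
    mass = (state.lam[grp] * c.lab_freq[grp, None]).sum(axis=0)
    mj = _clip0(state.m_jk[j] - mass)
    row = state.obs_row[record]
    mv = _clip0(state.m_vk[row] - own)
    msum = _clip0(state.m_vk[sl].sum(axis=0) - own)
    pe = _clip0(state.p[l] - mass)
    zeta_lv = hyper.zeta[l][c.lab_state[record]]
    val = (
        (hyper.alpha + state.n_jk[j] + mj)
        * (zeta_lv + mv) / (hyper.zeta[l].sum() + msum)
        * (hyper.a[l] + pe) / (hyper.a[l] + pe + hyper.b[l] + state.q[l])
    )
    return val / val.sum()


def update_pi(state: VariationalState, hyper: ModelHyperparameters, j: int, l: int) -> np.ndarray:
    """Collapsed joint (topic, state) update for one unobserved (l, j) pair."""
    c = state.corpus
    if c.lab_observed[l, j]:
        raise ValueError(f"lab {l} is observed for patient {j}; use update_lambda")
    u = np.nonzero((state.mis_pat == j) & (state.mis_lab == l))[0][0]
    V = c.lab_sizes[l]
    sl = state.lab_slice(l)
    mass = state.pi[u, :, :V].sum(axis=1)
    mj = _clip0(state.m_jk[j] - mass)
    qe = _clip0(state.q[l] - mass)
    base = (hyper.alpha + state.n_jk[j] + mj) * (hyper.b[l] + qe) / (hyper.a[l] + state.p[l] + hyper.b[l] + qe)
    msum = state.m_vk[sl].sum(axis=0)  # (K,)
    out = np.empty((state.K, V))
    for v in range(V):
        own = state.pi[u, :, v]
        mv = _clip0(state.m_vk[sl.start + v] - own)
        ms = _clip0(msum - own)
        out[:, v] = base * (hyper.zeta[l][v] + mv) / (hyper.zeta[l].sum() + ms)
    return out / out.sum()


# ---------------------------------------------------------------------------
# Full E-step sweep (compiled) and EM driver.
# ---------------------------------------------------------------------------

def sweep(state: VariationalState, hyper: ModelHyperparameters, patients: np.ndarray | None = None) -> None:
    """One Gauss-Seidel E-step over ``patients`` (default: all, in order)."""
    c = state.corpus
    if patients is None:
        patients = np.arange(c.n_patients, dtype=np.int64)
    beta_flat, beta_sum, zeta_flat, zeta_sum = _hyper_flat(hyper)
    sweep_kernel(
        np.asarray(patients, dtype=np.int64),
        state.tok_start, c.tok_type, state.tok_col, c.tok_cnt, state.gamma,
        state.obs_start, c.lab_lab, state.obs_row, c.lab_freq, state.lam,
        state.mis_start, state.mis_lab, state.pi,
        state.n_jk, state.m_jk, state.n_wk, state.n_tk, state.m_vk, state.p, state.q,
        hyper.alpha, beta_flat, beta_sum, zeta_flat, zeta_sum,
        state.lab_off, c.lab_sizes, hyper.a, hyper.b,
    )


def estimate_parameters(
    state: VariationalState,
    hyper: ModelHyperparameters,
    include_lab_mass: bool = True,
) -> ParameterEstimates:
    """Posterior-mean estimates from the cached statistics.

    theta_jk = (alpha_k + n_jk [+ m_jk]) / row sum; the lab mass m_jk is
    included by default since the collapsed likelihood couples token and
    lab assignments in the same Dirichlet posterior.
    """
    c = state.corpus
    njk = state.n_jk + (state.m_jk if include_lab_mass else 0.0)
    theta = hyper.alpha + njk
    theta /= theta.sum(axis=1, keepdims=True)
    phi = []
    for t in range(c.n_types):
        num = hyper.beta[t][:, None] + state.n_wk[state.phi_slice(t)]
        phi.append(num / num.sum(axis=0, keepdims=True))
    eta = []
    for l in range(c.n_labs):
        num = hyper.zeta[l][None, :] + state.m_vk[state.lab_slice(l)].T  # (K, V_l)
        eta.append(num / num.sum(axis=1, keepdims=True))
    ap = hyper.a[:, None] + state.p
    bq = hyper.b[:, None] + state.q
    psi = ap / (ap + bq)
    return ParameterEstimates(theta=theta, phi=phi, eta=eta, psi=psi)


# ---------------------------------------------------------------------------
# Empirical-Bayes hyperparameter fixed points.
# ---------------------------------------------------------------------------

def _dirichlet_fixed_point(conc: np.ndarray, counts: np.ndarray, prior) -> np.ndarray:
    """One Minka fixed-point step for a Dirichlet concentration vector.

    ``counts`` has shape (n_groups, dim); ``conc`` shape (dim,).  With a
    Gamma(shape, rate) prior the update is

        conc_i <- (shape - 1 + conc_i * [sum_g Psi(conc_i + counts_gi)
                                         - G Psi(conc_i)])
                  / (rate + sum_g Psi(sum_i conc + counts_g.) - G Psi(sum_i conc))

    whose fixed point is a stationary point of the collapsed log-likelihood
    plus the log Gamma prior.  At zero counts the digamma terms cancel
    exactly and the update returns (shape - 1) / rate.
    """
    G = counts.shape[0]
    num = prior.shape - 1.0 + conc * (digamma(conc[None, :] + counts).sum(axis=0) - G * digamma(conc))
    total = conc.sum()
    den = prior.rate + digamma(total + counts.sum(axis=1)).sum() - G * digamma(total)
    if not (np.isfinite(num).all() and math.isfinite(den)):
        raise FloatingPointError("non-finite digamma argument in hyperparameter update")
    return np.maximum(num / den, HYPER_FLOOR)


def _beta_shape_fixed_point(a, b, pos, neg, prior_a, prior_b):
    """Paired Minka step for Beta shapes given per-group (pos, neg) masses."""
    G = pos.shape[0]
    den_common = digamma(a + b + pos + neg).sum() - G * digamma(a + b)
    num_a = prior_a.shape - 1.0 + a * (digamma(a + pos).sum() - G * digamma(a))
    num_b = prior_b.shape - 1.0 + b * (digamma(b + neg).sum() - G * digamma(b))
    new_a = max(num_a / (prior_a.rate + den_common), HYPER_FLOOR)
    new_b = max(num_b / (prior_b.rate + den_common), HYPER_FLOOR)
    return new_a, new_b


def update_hyperparameters_from_counts(
    hyper: ModelHyperparameters,
    n_jk: np.ndarray,
    n_wk_per_type: list[np.ndarray],
    m_vk_per_lab: list[np.ndarray],
    p: np.ndarray,
    q: np.ndarray,
) -> ModelHyperparameters:
    """Fixed-point step given explicit (expected or hard) counts.

    ``n_jk`` is the (D, K) patient-topic mass entering the theta posterior
    (tokens plus lab mass); ``n_wk_per_type[t]`` is (W_t, K);
    ``m_vk_per_lab[l]`` is (V_l, K); p, q are (L, K).
    """
    new_alpha = _dirichlet_fixed_point(hyper.alpha, n_jk, hyper.priors["alpha"])
    new_beta = [
        _dirichlet_fixed_point(hyper.beta[t], n_wk_per_type[t].T, hyper.priors["beta"])
        for t in range(hyper.n_types)
    ]
    new_zeta = [
        _dirichlet_fixed_point(hyper.zeta[l], m_vk_per_lab[l].T, hyper.priors["zeta"])
        for l in range(hyper.n_labs)
    ]
    new_a = hyper.a.copy()
    new_b = hyper.b.copy()
    for l in range(hyper.n_labs):
        new_a[l], new_b[l] = _beta_shape_fixed_point(
            hyper.a[l], hyper.b[l], p[l], q[l], hyper.priors["a"], hyper.priors["b"]
        )
    return ModelHyperparameters(new_alpha, new_beta, new_zeta, new_a, new_b, dict(hyper.priors))


def update_hyperparameters(state: VariationalState, hyper: ModelHyperparameters) -> ModelHyperparameters:
    """Empirical-Bayes fixed-point step using the state's expected counts."""
    c = state.corpus
    return update_hyperparameters_from_counts(
        hyper,
        state.n_jk + state.m_jk,
        [state.n_wk[state.phi_slice(t)] for t in range(c.n_types)],
        [state.m_vk[state.lab_slice(l)] for l in range(c.n_labs)],
        state.p,
        state.q,
    )


# ---------------------------------------------------------------------------
# Training loop.
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """JCVB training settings.

    max_sweeps:     hard cap on EM iterations.
    min_sweeps:     sweeps always run before the tolerance is consulted
                    (guards against spurious early stops: the relative
                    change of a large-magnitude log-likelihood can dip
                    below tol while the optimizer is still climbing).
    tol:            relative change of the monitored log-likelihood below
                    which training stops.
    update_hyper:   whether to run empirical-Bayes hyperparameter updates.
    hyper_every:    run them every this many sweeps ...
    hyper_burnin:   ... after this many initial sweeps.
    include_lab_mass: lab mass in the theta estimator (see
                    :func:`estimate_parameters`).
    """

    max_sweeps: int = 500
    min_sweeps: int = 10
    tol: float = 1e-4
    update_hyper: bool = True
    hyper_every: int = 5
    hyper_burnin: int = 10
    include_lab_mass: bool = True


def training_log_likelihood(
    state: VariationalState, hyper: ModelHyperparameters, include_lab_mass: bool = True
) -> float:
    """Predictive log-likelihood of the training data under current estimates."""
    from .predict import predictive_log_likelihood

    est = estimate_parameters(state, hyper, include_lab_mass=include_lab_mass)
    return predictive_log_likelihood(est, state.corpus, est.theta)


def fit_jcvb(
    corpus: MultiModalCorpus,
    K: int,
    config: TrainConfig | None = None,
    seed: int = 0,
    hyper: ModelHyperparameters | None = None,
):
    """Batch EM: E-step sweeps + statistic refresh + hyperparameter updates.

    Returns ``(estimates, state, trace)`` where ``trace`` is a list of
    per-sweep dicts (iteration, monitored log-likelihood, hyperparameter
    norms).  Deterministic given the seed.
    """
    config = config or TrainConfig()
    if hyper is None:
        hyper = ModelHyperparameters.symmetric(K, corpus.type_sizes, corpus.lab_sizes)
    hyper.validate()
    state = initialize_state(corpus, K, seed)
    trace = []
    prev = None
    for it in range(config.max_sweeps):
        sweep(state, hyper)
        refresh_statistics(state)
        if config.update_hyper and it >= config.hyper_burnin and (it - config.hyper_burnin) % config.hyper_every == 0:
            hyper = update_hyperparameters(state, hyper)
        ll = training_log_likelihood(state, hyper, config.include_lab_mass)
        if not math.isfinite(ll):
            raise TrainingDivergedError(it)
        trace.append(
            {
                "iteration": it,
                "log_likelihood": ll,
                "alpha_norm": float(np.linalg.norm(hyper.alpha)),
                "beta_norm": float(np.linalg.norm(np.concatenate(hyper.beta))) if hyper.beta else 0.0,
            }
        )
        if (
            prev is not None
            and it + 1 >= config.min_sweeps
            and abs(ll - prev) < config.tol * abs(prev)
        ):
            break
        prev = ll
    estimates = estimate_parameters(state, hyper, config.include_lab_mass)
    state.hyper = hyper  # final (possibly EB-updated) hyperparameters
    return estimates, state, trace
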