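"""Stochastic collapsed variational inference (SCVB0).

Global topic statistics are maintained as an interpolation between their
previous value and a scaled minibatch estimate (a natural-gradient step):

    n_wk <- (1 - rho) n_wk + rho * (D / D') * sum over batch of c * gamma
    m_vk <- (1 - rho) m_vk + rho * (D / D') * batch lambda/pi mass

Per-patient assignments are never materialized outside the current batch;
each batch patient's gamma/lambda/pi are re-initialized and refined with a
few local sweeps against a working copy of the global statistics (own
current contributions subtracted, clipped at zero — the same Gauss-Seidel
record update as batch inference).  The Beta exposure masses p, q are
interpolated with the same learning rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import sweep_kernel
from .corpus import MultiModalCorpus
from .jcvb import (
    VariationalState,
    TrainingDivergedError,
    _hyper_flat,
    estimate_parameters,
    initialize_state,
)
from .synthetic import ModelHyperparameters

__all__ = ["SCVBConfig", "minibatch_statistics", "scvb_step", "fit_scvb"]


@dataclass
class SCVBConfig:
    """Minibatch training settings.

    batch_size: D', number of patients per minibatch.
    rho:        fixed learning rate in [0, 1]; ignored when a
                Robbins-Monro schedule (tau, kappa) is given, in which
                case rho_s = (s + tau) ** (-kappa) at step s.
    epochs:     passes over the corpus.
    local_sweeps: local E-step refinements per batch.
    scale_minibatch: multiply batch sums by D/D' so the interpolation
                mixes same-scale quantities (configurable because the
                unscaled batch-sum form is also defensible).
    seed:       randomness source for batching and initialization.
    """

    batch_size: int
    rho: float = 0.5
    rho_schedule: tuple[float, float] | None = None
    epochs: int = 50
    local_sweeps: int = 3
    scale_minibatch: bool = True
    monitor_patients: int = 50
    seed: int = 0


def minibatch_statistics(
    corpus: MultiModalCorpus,
    batch: np.ndarray,
    state: VariationalState,
    hyper: ModelHyperparameters,
    scale: bool = True,
):
    """Scaled batch estimates of the global feature/lab statistics.

    Sums the batch patients' current assignments (count-weighted gamma for
    tokens; y-weighted lambda plus pi mass for labs) and scales by D/D' to
    estimate the full-corpus statistic.  Returns ``(n_hat, m_hat)`` shaped
    like ``state.n_wk`` and ``state.m_vk``.
    """
    batch = np.asarray(batch, dtype=np.int64)
    if batch.size == 0:
        raise ValueError("minibatch must be non-empty")
    factor = corpus.n_patients / batch.size if scale else 1.0
    in_batch = np.zeros(corpus.n_patients, dtype=bool)
    in_batch[batch] = True

    n_hat = np.zeros_like(state.n_wk)
    tm = in_batch[corpus.tok_pat]
    if tm.any():
        np.add.at(n_hat, state.tok_col[tm], state.gamma[tm] * corpus.tok_cnt[tm, None])
    m_hat = np.zeros_like(state.m_vk)
    lm = in_batch[corpus.lab_pat]
    if lm.any():
        np.add.at(m_hat, state.obs_row[lm], state.lam[lm] * corpus.lab_freq[lm, None])
    um = np.nonzero(in_batch[state.mis_pat])[0]
    if len(um):
        labs_u = state.mis_lab[um]
        for v in range(state.Vmax):
            ok = v < corpus.lab_sizes[labs_u]
            np.add.at(m_hat, state.lab_off[labs_u[ok]] + v, state.pi[um[ok], :, v])
    return n_hat * factor, m_hat * factor


def scvb_step(state: VariationalState, n_hat, m_hat, rho: float, p_hat=None, q_hat=None) -> VariationalState:
    """Natural-gradient interpolation of the global statistics, in place."""
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    state.n_wk *= 1.0 - rho
    state.n_wk += rho * n_hat
    state.m_vk *= 1.0 - rho
    state.m_vk += rho * m_hat
    for t in range(state.corpus.n_types):
        state.n_tk[t] = state.n_wk[state.phi_slice(t)].sum(axis=0)
    if p_hat is not None:
        state.p *= 1.0 - rho
        state.p += rho * p_hat
    if q_hat is not None:
        state.q *= 1.0 - rho
        state.q += rho * q_hat
    return state


def _gather(starts: np.ndarray, batch: np.ndarray):
    """Record indices for ``batch`` patients plus compact start offsets."""
    lengths = starts[batch + 1] - starts[batch]
    new_start = np.concatenate(([0], np.cumsum(lengths))).astype(np.int64)
    if lengths.sum() == 0:
        return np.zeros(0, dtype=np.int64), new_start
    idx = np.concatenate([np.arange(starts[j], starts[j + 1]) for j in batch])
    return idx.astype(np.int64), new_start


class _Batch:
    """Compact assignment arrays for one minibatch (memory O(batch))."""

    __slots__ = (
        "patients", "tok_idx", "tok_start", "obs_idx", "obs_start",
        "mis_idx", "mis_start", "gamma", "lam", "pi", "n_jk", "m_jk",
    )


def _run_batch(
    corpus: MultiModalCorpus,
    packing: VariationalState,
    globals_state: VariationalState,
    batch: np.ndarray,
    hyper: ModelHyperparameters,
    rng: np.random.Generator,
    local_sweeps: int,
) -> _Batch:
    """Fresh local assignments for the batch, refined by local sweeps.

    Operates on a working copy of the global statistics so the persistent
    state is only changed through the interpolation step.
    """
    K = globals_state.K
    b = _Batch()
    b.patients = batch
    b.tok_idx, b.tok_start = _gather(packing.tok_start, batch)
    b.obs_idx, b.obs_start = _gather(packing.obs_start, batch)
    b.mis_idx, b.mis_start = _gather(packing.mis_start, batch)

    eps = 0.1 / K
    Vmax = packing.Vmax
    mis_lab = packing.mis_lab[b.mis_idx]
    raw = 1.0 / K + rng.uniform(-eps, eps, size=(len(b.tok_idx), K))
    b.gamma = raw / raw.sum(axis=1, keepdims=True) if len(b.tok_idx) else np.zeros((0, K))
    raw = 1.0 / K + rng.uniform(-eps, eps, size=(len(b.obs_idx), K))
    b.lam = raw / raw.sum(axis=1, keepdims=True) if len(b.obs_idx) else np.zeros((0, K))
    b.pi = np.zeros((len(b.mis_idx), K, Vmax))
    for l in range(corpus.n_labs):
        rows = np.nonzero(mis_lab == l)[0]
        b.pi[rows, :, : corpus.lab_sizes[l]] = 1.0 / (K * corpus.lab_sizes[l])

    B = len(batch)
    b.n_jk = np.zeros((B, K))
    b.m_jk = np.zeros((B, K))
    local_tok_pat = np.repeat(np.arange(B), b.tok_start[1:] - b.tok_start[:-1])
    local_obs_pat = np.repeat(np.arange(B), b.obs_start[1:] - b.obs_start[:-1])
    local_mis_pat = np.repeat(np.arange(B), b.mis_start[1:] - b.mis_start[:-1])
    tok_cnt = corpus.tok_cnt[b.tok_idx]
    obs_y = corpus.lab_freq[b.obs_idx]
    if len(b.tok_idx):
        np.add.at(b.n_jk, local_tok_pat, b.gamma * tok_cnt[:, None])
    if len(b.obs_idx):
        np.add.at(b.m_jk, local_obs_pat, b.lam * obs_y[:, None])
    if len(b.mis_idx):
        np.add.at(b.m_jk, local_mis_pat, b.pi.sum(axis=2))

    n_wk = globals_state.n_wk.copy()
    n_tk = globals_state.n_tk.copy()
    m_vk = globals_state.m_vk.copy()
    p = globals_state.p.copy()
    q = globals_state.q.copy()
    beta_flat, beta_sum, zeta_flat, zeta_sum = _hyper_flat(hyper)
    for _ in range(local_sweeps):
        sweep_kernel(
            np.arange(B, dtype=np.int64),
            b.tok_start, corpus.tok_type[b.tok_idx], packing.tok_col[b.tok_idx], tok_cnt, b.gamma,
            b.obs_start, corpus.lab_lab[b.obs_idx], packing.obs_row[b.obs_idx], obs_y, b.lam,
            b.mis_start, mis_lab, b.pi,
            b.n_jk, b.m_jk, n_wk, n_tk, m_vk, p, q,
            hyper.alpha, beta_flat, beta_sum, zeta_flat, zeta_sum,
            packing.lab_off, corpus.lab_sizes, hyper.a, hyper.b,
        )
    return b


def _batch_stats(corpus, packing, b: _Batch, scale_factor: float):
    """(n_hat, m_hat, p_hat, q_hat) from one batch's final assignments."""
    n_hat = np.zeros_like(packing.n_wk)
    m_hat = np.zeros_like(packing.m_vk)
    p_hat = np.zeros_like(packing.p)
    q_hat = np.zeros_like(packing.q)
    if len(b.tok_idx):
        np.add.at(n_hat, packing.tok_col[b.tok_idx], b.gamma * corpus.tok_cnt[b.tok_idx, None])
    if len(b.obs_idx):
        wlam = b.lam * corpus.lab_freq[b.obs_idx, None]
        np.add.at(m_hat, packing.obs_row[b.obs_idx], wlam)
        np.add.at(p_hat, corpus.lab_lab[b.obs_idx], wlam)
    if len(b.mis_idx):
        labs_u = packing.mis_lab[b.mis_idx]
        np.add.at(q_hat, labs_u, b.pi.sum(axis=2))
        for v in range(packing.Vmax):
            ok = v < corpus.lab_sizes[labs_u]
            np.add.at(m_hat, packing.lab_off[labs_u[ok]] + v, b.pi[ok, :, v])
    return n_hat * scale_factor, m_hat * scale_factor, p_hat * scale_factor, q_hat * scale_factor


def _rho_at(config: SCVBConfig, step: int) -> float:
    if config.rho_schedule is not None:
        tau, kappa = config.rho_schedule
        return float((step + tau) ** (-kappa))
    return config.rho


def fit_scvb(
    corpus: MultiModalCorpus,
    K: int,
    config: SCVBConfig,
    hyper: ModelHyperparameters | None = None,
):
    """Constant-memory minibatch training.

    Returns ``(estimates, trace, info)``: the trace monitors the predictive
    log-likelihood of a fixed seeded subset of patients under a 50/50
    feature split (mixture inferred from one half, likelihood of the
    other); ``info`` reports structural diagnostics, notably
    ``max_batch_rows``, the largest per-batch assignment allocation (the
    memory bound).
    """
    from .predict import infer_patient_mixture, predictive_log_likelihood, split_record

    if hyper is None:
        hyper = ModelHyperparameters.symmetric(K, corpus.type_sizes, corpus.lab_sizes)
    hyper.validate()
    if not (1 <= config.batch_size <= corpus.n_patients):
        raise ValueError("batch_size must lie in [1, D]")

    rng = np.random.default_rng(config.seed)
    # global statistics seeded from a streaming perturbed-uniform pass;
    # assignments themselves are immediately dropped
    state = initialize_state(corpus, K, config.seed)
    state.gamma = np.zeros((0, K))
    state.lam = np.zeros((0, K))
    state.pi = np.zeros((0, K, state.Vmax))
    packing = state  # index arrays live here

    n_mon = min(config.monitor_patients, corpus.n_patients)
    monitor = rng.choice(corpus.n_patients, size=n_mon, replace=False)
    monitor_splits = [split_record(corpus.patient(j), seed=int(rng.integers(2**31))) for j in monitor]

    def monitored_ll() -> float:
        est = estimate_parameters(state, hyper)
        if not n_mon:
            return 0.0
        thetas = np.stack([infer_patient_mixture(est, hyper, half) for half, _ in monitor_splits])
        sub = _record_corpus([ev for _, ev in monitor_splits], corpus)
        return predictive_log_likelihood(est, sub, thetas)

    trace = [{"epoch": -1, "log_likelihood": monitored_ll()}]
    info = {"max_batch_rows": 0}
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(corpus.n_patients)
        for start in range(0, corpus.n_patients, config.batch_size):
            batch = np.asarray(order[start : start + config.batch_size], dtype=np.int64)
            if batch.size == 0:
                continue
            b = _run_batch(corpus, packing, state, batch, hyper, rng, config.local_sweeps)
            info["max_batch_rows"] = max(info["max_batch_rows"], len(b.tok_idx))
            factor = (corpus.n_patients / batch.size) if config.scale_minibatch else 1.0
            n_hat, m_hat, p_hat, q_hat = _batch_stats(corpus, packing, b, factor)
            scvb_step(state, n_hat, m_hat, _rho_at(config, step), p_hat, q_hat)
            step += 1
        ll = monitored_ll()
        if not math.isfinite(ll):
            raise TrainingDivergedError(epoch)
        trace.append({"epoch": epoch, "log_likelihood": ll})

    est = estimate_parameters(state, hyper)
    if corpus.n_patients:
        est.theta = np.stack(
            [infer_patient_mixture(est, hyper, corpus.patient(j)) for j in range(corpus.n_patients)]
        )
    return est, trace, info


def _record_corpus(records, like: MultiModalCorpus) -> MultiModalCorpus:
    """Assemble patient records into a corpus with ``like``'s schema."""
    tok = [[], [], [], []]
    lab = [[], [], [], []]
    for j, rec in enumerate(records):
        tok[0].extend([j] * len(rec.tok_type))
        tok[1].extend(rec.tok_type.tolist())
        tok[2].extend(rec.tok_feat.tolist())
        tok[3].extend(rec.tok_cnt.tolist())
        lab[0].extend([j] * len(rec.lab_lab))
        lab[1].extend(rec.lab_lab.tolist())
        lab[2].extend(rec.lab_state.tolist())
        lab[3].extend(rec.lab_freq.tolist())
    return MultiModalCorpus(len(records), like.type_sizes, like.lab_sizes, tokens=tok, lab_records=lab)
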