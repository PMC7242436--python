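"""Fold-in inference, held-out predictive likelihood, kNN prediction.

New patients are "folded in": their topic mixture theta is inferred by
patient-local collapsed updates against the frozen global topic matrices
(phi, eta, psi).  The held-out predictive log-likelihood scores one half of
a patient's features under a mixture inferred from the other half.  Code
prediction and lab imputation average over the k nearest training patients
in the topic-mixture embedding (Euclidean distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .corpus import MultiModalCorpus, ParameterEstimates, PatientRecord
from .jcvb import TrainConfig, fit_jcvb
from .synthetic import ModelHyperparameters

def _record_corpus(records, like):
    from .scvb import _record_corpus as impl

    return impl(records, like)

__all__ = [
    "infer_patient_mixture",
    "split_record",
    "predictive_log_likelihood",
    "cross_validate_K",
    "knn_neighbors",
    "predict_code",
    "impute_lab_result",
    "evaluate_binary_predictions",
    "BinaryMetrics",
]


def infer_patient_mixture(
    model: ParameterEstimates,
    hyper: ModelHyperparameters,
    record: PatientRecord,
    sweeps: int = 10,
    include_lab_mass: bool = True,
    include_missing_labs: bool = False,
) -> np.ndarray:
    """Fold-in: infer theta for one patient against frozen topics.

    By default only the patient's observed tokens and lab records enter,
    so an empty record returns the prior mean alpha / sum(alpha).  With
    ``include_missing_labs=True`` the labs absent from the record are
    treated as genuinely not taken (r = 0) and contribute their own
    evidence through 1 - psi — the non-random-missingness reading, which
    makes fold-in of a training patient match their training mixture.
    Unknown features (outside the model vocabularies) are skipped with a
    warning.
    """
    K = model.n_topics
    alpha = hyper.alpha
    T = len(model.phi)
    L = model.psi.shape[0]

    tok_rows = []  # (phi_row (K,), count)
    skipped = 0
    for t, w, c in zip(record.tok_type, record.tok_feat, record.tok_cnt):
        if t < 0 or t >= T or w < 0 or w >= model.phi[t].shape[0]:
            skipped += 1
            continue
        tok_rows.append((model.phi[t][w], float(c)))
    lab_groups: dict[int, list[tuple[np.ndarray, float]]] = {}
    for l, v, y in zip(record.lab_lab, record.lab_state, record.lab_freq):
        if l < 0 or l >= L or v < 0 or v >= model.eta[l].shape[1]:
            skipped += 1
            continue
        lab_groups.setdefault(int(l), []).append((model.eta[l][:, v] * model.psi[l], float(y)))
    if skipped:
        warnings.warn(f"fold-in skipped {skipped} record(s) outside the model vocabularies")

    missing_labs = (
        [l for l in range(L) if l not in lab_groups] if include_missing_labs else []
    )
    gamma = [np.full(K, 1.0 / K) for _ in tok_rows]
    lam = {l: [np.full(K, 1.0 / K) for _ in recs] for l, recs in lab_groups.items()}
    pi_mass = {l: np.full(K, 1.0 / K) for l in missing_labs}  # topic marginal of pi
    n_loc = sum((g * c for g, (_, c) in zip(gamma, tok_rows)), np.zeros(K))
    m_loc = np.zeros(K)
    for l, recs in lab_groups.items():
        for lv, (_, y) in zip(lam[l], recs):
            m_loc += y * lv
    for l in missing_labs:
        m_loc += pi_mass[l]

    for _ in range(max(1, sweeps)):
        for i, (phi_row, c) in enumerate(tok_rows):
            excl = np.maximum(n_loc - c * gamma[i], 0.0)
            val = (alpha + excl + m_loc) * phi_row
            val /= val.sum()
            n_loc = excl + c * val
            gamma[i] = val
        for l, recs in lab_groups.items():
            mass = np.zeros(K)
            for lv, (_, y) in zip(lam[l], recs):
                mass += y * lv
            for i, (lik_row, y) in enumerate(recs):
                m_excl = np.maximum(m_loc - mass, 0.0)
                val = (alpha + n_loc + m_excl) * lik_row
                val /= val.sum()
                d = y * (val - lam[l][i])
                m_loc += d
                mass += d
                lam[l][i] = val
        for l in missing_labs:
            m_excl = np.maximum(m_loc - pi_mass[l], 0.0)
            # eta rows sum to one over states, so the joint (topic, state)
            # update marginalizes to a single per-topic factor 1 - psi
            val = (alpha + n_loc + m_excl) * (1.0 - model.psi[l])
            val /= val.sum()
            m_loc = m_excl + val
            pi_mass[l] = val

    theta = alpha + n_loc + (m_loc if include_lab_mass else 0.0)
    return theta / theta.sum()


def split_record(record: PatientRecord, seed: int) -> tuple[PatientRecord, PatientRecord]:
    """Random 50/50 split of a patient's features, stratified per data type.

    Token records are split within each type; observed labs are split at
    the lab level (all result states of a lab stay together).  Returns
    (inference half, evaluation half).
    """
    rng = np.random.default_rng(seed)
    tok_half = np.zeros(len(record.tok_type), dtype=bool)
    for t in np.unique(record.tok_type):
        idx = np.nonzero(record.tok_type == t)[0]
        perm = rng.permutation(len(idx))
        tok_half[idx[perm[: (len(idx) + 1) // 2]]] = True
    labs = np.unique(record.lab_lab)
    perm = rng.permutation(len(labs))
    labs_a = set(labs[perm[: (len(labs) + 1) // 2]].tolist())
    lab_half = np.array([l in labs_a for l in record.lab_lab], dtype=bool)

    def pick(tm, lm):
        return PatientRecord(
            record.tok_type[tm], record.tok_feat[tm], record.tok_cnt[tm],
            record.lab_lab[lm], record.lab_state[lm], record.lab_freq[lm],
        )

    return pick(tok_half, lab_half), pick(~tok_half, ~lab_half)


def predictive_log_likelihood(
    model: ParameterEstimates,
    test: MultiModalCorpus,
    theta: np.ndarray,
    lab_term: str = "product",
) -> float:
    """Held-out predictive log-likelihood of a test corpus.

    Token term: sum over records of c * log sum_k theta_jk phi_wk^(t).
    Observed-lab term, per record (j, l, v) with frequency y:
    ``product`` (default) scores y * log sum_k theta_jk psi_lk eta_lkv —
    the probability the generative process assigns to an observed result;
    ``sum`` uses psi_lk + eta_lkv in place of the product.  Returns 0.0 on
    an empty corpus and -inf (with a diagnostic) if any record has zero
    probability.
    """
    if lab_term not in ("product", "sum"):
        raise ValueError("lab_term must be 'product' or 'sum'")
    total = 0.0
    if len(test.tok_pat):
        for t in range(test.n_types):
            m = test.tok_type == t
            if not m.any():
                continue
            probs = np.einsum(
                "jk,jk->j", theta[test.tok_pat[m]], model.phi[t][test.tok_feat[m]]
            )
            if (probs <= 0).any():
                bad = np.nonzero(probs <= 0)[0][0]
                warnings.warn(
                    f"zero predictive probability: type {t}, record index {bad}"
                )
                return -np.inf
            total += float(np.sum(test.tok_cnt[m] * np.log(probs)))
    if len(test.lab_pat):
        for l in range(test.n_labs):
            m = test.lab_lab == l
            if not m.any():
                continue
            et = model.eta[l][:, test.lab_state[m]].T  # (n, K)
            inner = model.psi[l] * et if lab_term == "product" else model.psi[l] + et
            probs = np.einsum("jk,jk->j", theta[test.lab_pat[m]], inner)
            if (probs <= 0).any():
                bad = np.nonzero(probs <= 0)[0][0]
                warnings.warn(f"zero predictive probability: lab {l}, record index {bad}")
                return -np.inf
            total += float(np.sum(test.lab_freq[m] * np.log(probs)))
    return total


def cross_validate_K(
    corpus: MultiModalCorpus,
    K_grid: list[int],
    folds: int,
    seed: int,
    train_config: TrainConfig | None = None,
    fold_in_sweeps: int = 10,
) -> pd.DataFrame:
    """Cross-validated held-out predictive likelihood over a grid of K.

    For each fold, models are trained on the remaining folds; each held-out
    patient's features are split 50/50 (seeded), the mixture inferred from
    one half, and the other half scored.  Returns a table of
    (K, mean predictive log-likelihood per held-out patient).
    """
    if not K_grid:
        raise ValueError("K_grid must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    D = corpus.n_patients
    assignment = rng.permutation(D) % folds
    split_seeds = rng.integers(2**31, size=D)

    totals = {K: [] for K in K_grid}
    for fold in range(folds):
        val = np.nonzero(assignment == fold)[0]
        train = np.nonzero(assignment != fold)[0]
        train_corpus = corpus.subset(train)
        for K in K_grid:
            est, tr_state, _ = fit_jcvb(
                train_corpus, K, config=train_config, seed=int(rng.integers(2**31))
            )
            hyper = tr_state.hyper
            ll = 0.0
            for j in val:
                half_a, half_b = split_record(corpus.patient(j), int(split_seeds[j]))
                theta = infer_patient_mixture(est, hyper, half_a, sweeps=fold_in_sweeps)
                sub = _record_corpus([half_b], corpus)
                ll += predictive_log_likelihood(est, sub, theta[None, :])
            totals[K].append(ll / max(len(val), 1))
    return pd.DataFrame(
        {
            "K": K_grid,
            "mean_log_likelihood": [float(np.mean(totals[K])) for K in K_grid],
        }
    )


def knn_neighbors(theta_test: np.ndarray, theta_train: np.ndarray, k: int):
    """The k training patients nearest in topic-mixture space.

    Euclidean distance; ties broken by ascending patient index.  Returns
    (indices, distances), distances non-decreasing.
    """
    D = theta_train.shape[0]
    if not (1 <= k <= D):
        raise ValueError(f"k must lie in [1, {D}]")
    d = np.sqrt(((theta_train - theta_test[None, :]) ** 2).sum(axis=1))
    order = np.lexsort((np.arange(D), d))[:k]
    return order, d[order]


def predict_code(neighbors: np.ndarray, code_indicator: np.ndarray, k: int) -> float:
    """Average binarized presence of a code over the k nearest neighbors."""
    neighbors = np.asarray(neighbors)
    if len(neighbors) != k:
        raise ValueError(f"expected {k} neighbors, got {len(neighbors)}")
    return float(np.mean(np.asarray(code_indicator, dtype=float)[neighbors] > 0))


def impute_lab_result(
    model: ParameterEstimates,
    hyper: ModelHyperparameters,
    train_corpus: MultiModalCorpus,
    train_theta: np.ndarray,
    record: PatientRecord,
    lab: int,
    k: int = 25,
    fold_in_sweeps: int = 10,
) -> np.ndarray:
    """Impute a masked lab's result-state distribution for a test patient.

    (1) fold in the test patient without the target lab; (2) among training
    patients with the lab observed, take the k nearest in mixture space;
    (3) average their normalized result-state frequencies.  Fewer than k
    eligible neighbors are used with a warning; none raises ValueError.
    """
    eligible = np.nonzero(train_corpus.lab_observed[lab])[0]
    if len(eligible) == 0:
        raise ValueError(f"no training patient has lab {lab} observed; unimputable")
    if len(eligible) < k:
        warnings.warn(f"only {len(eligible)} eligible neighbors for lab {lab} (k={k})")
        k = len(eligible)
    theta = infer_patient_mixture(model, hyper, record.without_lab(lab), sweeps=fold_in_sweeps)
    local_idx, _ = knn_neighbors(theta, train_theta[eligible], k)
    neighbors = eligible[local_idx]

    V = train_corpus.lab_sizes[lab]
    freq = np.zeros((train_corpus.n_patients, V))
    m = train_corpus.lab_lab == lab
    freq[train_corpus.lab_pat[m], train_corpus.lab_state[m]] = train_corpus.lab_freq[m]
    dist = freq[neighbors]
    dist = dist / dist.sum(axis=1, keepdims=True)
    return dist.mean(axis=0)


@dataclass(frozen=True)
class BinaryMetrics:
    accuracy: float
    auroc: float
    auprc: float


def evaluate_binary_predictions(scores, labels, threshold: float) -> BinaryMetrics:
    """Accuracy at a threshold plus AUROC/AUPRC (NaN when undefined)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    acc = float(np.mean((scores >= threshold).astype(int) == labels))
    if len(np.unique(labels)) < 2:
        return BinaryMetrics(acc, float("nan"), float("nan"))
    return BinaryMetrics(
        acc,
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )
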