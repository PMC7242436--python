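"""Sampling model parameters and corpora from the generative process.

The model: each of K latent disease topics carries, per data type t, a
multinomial distribution phi_k^(t) over that type's vocabulary
(phi_k^(t) ~ Dir(beta_t)); per lab l, a multinomial eta_lk over V_l result
states (eta_lk ~ Dir(zeta_l)) and an observation probability
psi_lk ~ Beta(a_l, b_l).  Each patient draws a topic mixture
theta_j ~ Dir(alpha).  Tokens: z ~ Mul(theta_j), then x ~ Mul(phi_z^(t)).
Labs: h_lj ~ Mul(theta_j), r_lj ~ Bernoulli(psi_{l,h}), and if r_lj = 1 a
result state y ~ Mul(eta_{l,h}) is recorded.  Missingness is therefore
non-random: it depends on the latent topic h, never directly on y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import MultiModalCorpus

__all__ = [
    "GammaPrior",
    "ModelHyperparameters",
    "SyntheticTruth",
    "sample_truth",
    "sample_corpus",
    "make_fixture",
]


@dataclass(frozen=True)
class GammaPrior:
    """Gamma hyper-prior (shape, rate) on one hyperparameter family."""

    shape: float = 1.0
    rate: float = 1.0


def _default_priors() -> dict:
    return {name: GammaPrior() for name in ("alpha", "beta", "zeta", "a", "b")}


@dataclass
class ModelHyperparameters:
    """Dirichlet/Beta hyperparameters of the model, with their Gamma priors.

    alpha : (K,) Dirichlet concentration over topics per patient.
    beta  : per type t, (W^(t),) Dirichlet concentration over features.
    zeta  : per lab l, (V_l,) Dirichlet concentration over result states.
    a, b  : (L,) Beta shapes of the per-topic lab observation probability.
    priors: Gamma (shape, rate) for each family, used by the empirical-Bayes
            fixed-point updates.  Defaults are weakly informative (1, 1).
    """

    alpha: np.ndarray
    beta: list[np.ndarray]
    zeta: list[np.ndarray]
    a: np.ndarray
    b: np.ndarray
    priors: dict = field(default_factory=_default_priors)

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = [np.asarray(b, dtype=float) for b in self.beta]
        self.zeta = [np.asarray(z, dtype=float) for z in self.zeta]
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)

    @property
    def n_topics(self) -> int:
        return len(self.alpha)

    @property
    def n_types(self) -> int:
        return len(self.beta)

    @property
    def n_labs(self) -> int:
        return len(self.zeta)

    def validate(self) -> None:
        arrays = [self.alpha, *self.beta, *self.zeta, self.a, self.b]
        if any(a.size and (a <= 0).any() for a in arrays):
            raise ValueError("all hyperparameters must be strictly positive")
        if len(self.a) != len(self.zeta) or len(self.b) != len(self.zeta):
            raise ValueError("a, b must have one entry per lab")

    @classmethod
    def symmetric(
        cls,
        K: int,
        type_sizes,
        lab_sizes,
        alpha: float = 1.0,
        beta: float = 0.1,
        zeta: float = 0.5,
        a: float = 1.0,
        b: float = 1.0,
    ) -> "ModelHyperparameters":
        """Symmetric hyperparameters for given dimensions."""
        return cls(
            alpha=np.full(K, alpha, dtype=float),
            beta=[np.full(int(w), beta, dtype=float) for w in type_sizes],
            zeta=[np.full(int(v), zeta, dtype=float) for v in lab_sizes],
            a=np.full(len(list(lab_sizes)), a, dtype=float),
            b=np.full(len(list(lab_sizes)), b, dtype=float),
        )


@dataclass
class SyntheticTruth:
    """Ground-truth parameters a simulated corpus was drawn from."""

    theta: np.ndarray          # (D, K) row-stochastic
    phi: list[np.ndarray]      # per type (W_t, K) column-stochastic
    eta: list[np.ndarray]      # per lab (K, V_l) row-stochastic
    psi: np.ndarray            # (L, K) in (0, 1)
    z: list | None = None      # optional retained hard topic assignments
    h: np.ndarray | None = None

    @property
    def n_topics(self) -> int:
        return self.theta.shape[1]


def sample_truth(hyper: ModelHyperparameters, D: int, seed: int) -> SyntheticTruth:
    """Draw global and per-patient parameters from their priors.

    phi columns ~ Dir(beta_t), eta rows ~ Dir(zeta_l), psi ~ Beta(a_l, b_l),
    theta rows ~ Dir(alpha).  Deterministic given ``seed``.
    """
    hyper.validate()
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = np.random.default_rng(seed)
    K = hyper.n_topics
    phi = [rng.dirichlet(beta_t, size=K).T for beta_t in hyper.beta]  # (W_t, K)
    eta = [rng.dirichlet(zeta_l, size=K) for zeta_l in hyper.zeta]    # (K, V_l)
    L = hyper.n_labs
    psi = (
        rng.beta(hyper.a[:, None], hyper.b[:, None], size=(L, K))
        if L
        else np.zeros((0, K))
    )
    theta = rng.dirichlet(hyper.alpha, size=D) if D else np.zeros((0, K))
    return SyntheticTruth(theta=theta, phi=phi, eta=eta, psi=psi)


def sample_corpus(
    truth: SyntheticTruth,
    tokens_per_patient,
    seed: int,
    result_draws: float | None = None,
) -> MultiModalCorpus:
    """Sample a corpus from ground-truth parameters.

    ``tokens_per_patient`` is an int (same budget M for every type) or a
    per-type sequence.  ``result_draws``: by default each observed (lab,
    patient) pair records a single result draw; if a positive float
    ``lam`` is given, ``1 + Poisson(lam)`` draws emulate repeated
    measurements within an admission.
    """
    rng = np.random.default_rng(seed)
    D, K = truth.theta.shape
    T = len(truth.phi)
    L = truth.psi.shape[0]
    if np.isscalar(tokens_per_patient):
        budgets = [int(tokens_per_patient)] * T
    else:
        budgets = [int(m) for m in tokens_per_patient]
    if any(m < 0 for m in budgets):
        raise ValueError("token budgets must be non-negative")

    tok_pat, tok_type, tok_feat, tok_cnt = [], [], [], []
    for t in range(T):
        W = truth.phi[t].shape[0]
        for j in range(D):
            if budgets[t] == 0:
                continue
            zcounts = rng.multinomial(budgets[t], truth.theta[j])
            wcounts = np.zeros(W, dtype=np.int64)
            for k in np.nonzero(zcounts)[0]:
                wcounts += rng.multinomial(zcounts[k], truth.phi[t][:, k])
            feats = np.nonzero(wcounts)[0]
            tok_pat.extend([j] * len(feats))
            tok_type.extend([t] * len(feats))
            tok_feat.extend(feats.tolist())
            tok_cnt.extend(wcounts[feats].tolist())

    lab_pat, lab_lab, lab_state, lab_freq = [], [], [], []
    h_all = np.zeros((L, D), dtype=np.int64)
    for l in range(L):
        V = truth.eta[l].shape[1]
        for j in range(D):
            h = rng.choice(K, p=truth.theta[j])
            h_all[l, j] = h
            if rng.random() < truth.psi[l, h]:
                n_draws = 1 if result_draws is None else 1 + rng.poisson(result_draws)
                ycounts = rng.multinomial(n_draws, truth.eta[l][h])
                for v in np.nonzero(ycounts)[0]:
                    lab_pat.append(j)
                    lab_lab.append(l)
                    lab_state.append(int(v))
                    lab_freq.append(int(ycounts[v]))

    truth.h = h_all
    return MultiModalCorpus(
        D,
        [p.shape[0] for p in truth.phi],
        [e.shape[1] for e in truth.eta],
        tokens=(tok_pat, tok_type, tok_feat, tok_cnt),
        lab_records=(lab_pat, lab_lab, lab_state, lab_freq),
    )


# ---------------------------------------------------------------------------
# Fixed tiny instance shared across the test suite.
# ---------------------------------------------------------------------------

#: Total token count of the fixture (sum of its count column).
FIXTURE_TOKEN_TOTAL = 38


def make_fixture() -> tuple[MultiModalCorpus, SyntheticTruth]:
    """A fixed tiny instance: D=6, K=2, T=2, W=(5,4), L=2, V=(2,2).

    Counts are hard-coded constants (identical on every call), chosen to
    exercise every code path: multiple data types, a lab observed at both
    result states for the same patient, unobserved (lab, patient) pairs,
    and one patient (index 5) with tokens but no lab observations.
    """
    # (patient, type, feature, count), 0-based
    tokens = np.array(
        [
            [0, 0, 0, 3], [0, 0, 2, 1], [0, 1, 1, 2],
            [1, 0, 1, 2], [1, 0, 3, 2], [1, 1, 0, 1], [1, 1, 3, 1],
            [2, 0, 0, 1], [2, 0, 4, 4], [2, 1, 2, 2],
            [3, 0, 2, 2], [3, 1, 1, 1], [3, 1, 2, 1],
            [4, 0, 1, 3], [4, 0, 4, 1], [4, 1, 0, 2], [4, 1, 3, 2],
            [5, 0, 3, 4], [5, 1, 2, 3],
        ],
        dtype=np.int64,
    )
    # (patient, lab, state, frequency); patient 0 has lab 0 at both states.
    labs = np.array(
        [
            [0, 0, 0, 2], [0, 0, 1, 1],
            [1, 0, 1, 1],
            [2, 1, 0, 3],
            [3, 0, 0, 1], [3, 1, 1, 2],
            [4, 1, 0, 1],
        ],
        dtype=np.int64,
    )
    corpus = MultiModalCorpus(
        6, (5, 4), (2, 2),
        tokens=tuple(tokens[:, i] for i in range(4)),
        lab_records=tuple(labs[:, i] for i in range(4)),
    )
    theta = np.array(
        [
            [0.8, 0.2], [0.3, 0.7], [0.6, 0.4],
            [0.1, 0.9], [0.5, 0.5], [0.9, 0.1],
        ]
    )
    phi = [
        np.array([[0.4, 0.05], [0.2, 0.25], [0.1, 0.3], [0.1, 0.2], [0.2, 0.2]]),
        np.array([[0.5, 0.1], [0.2, 0.3], [0.1, 0.4], [0.2, 0.2]]),
    ]
    eta = [
        np.array([[0.7, 0.3], [0.2, 0.8]]),
        np.array([[0.1, 0.9], [0.6, 0.4]]),
    ]
    psi = np.array([[0.9, 0.3], [0.4, 0.7]])
    return corpus, SyntheticTruth(theta=theta, phi=phi, eta=eta, psi=psi)
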