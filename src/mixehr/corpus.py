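"""Multi-type EHR corpus containers, validation, and on-disk formats.

A corpus holds, per patient, sparse counts of categorical clinical features
over ``T`` data types (notes words, diagnosis codes, prescriptions, ...),
plus lab records ``(patient, lab, result state, frequency)`` together with an
observed/missing indicator per (lab, patient) pair.  Missingness is implicit
on disk: a (lab, patient) pair is observed iff it has at least one lab
record.  Files are tab-separated with 1-based indices; everything in memory
is 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DataTypeSpec",
    "LabSpec",
    "MultiModalCorpus",
    "PatientRecord",
    "ParameterEstimates",
    "CorpusParseError",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "validate_corpus",
    "read_model",
    "write_model",
]


class CorpusParseError(ValueError):
    """A corpus file line could not be parsed."""


class CorpusValidationError(ValueError):
    """A corpus or model violates a structural invariant."""


@dataclass(frozen=True)
class DataTypeSpec:
    """One data modality: a vocabulary of ``n_features`` discrete features."""

    n_features: int


@dataclass(frozen=True)
class LabSpec:
    """One lab test with ``n_states`` discrete result states."""

    n_states: int


def _as_int_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


class MultiModalCorpus:
    """Sparse per-patient counts over typed vocabularies plus lab records.

    Parameters
    ----------
    n_patients:
        Number of patients ``D``.
    types:
        Vocabulary size per data type (``W^(t)``), as ints or DataTypeSpec.
    labs:
        Number of result states per lab (``V_l``), as ints or LabSpec.
    tokens:
        Four aligned integer arrays ``(patient, type, feature, count)`` with
        0-based indices; one row per distinct (patient, type, feature).
    lab_records:
        Four aligned integer arrays ``(patient, lab, state, frequency)``.
    lab_observed:
        Optional (L, D) boolean indicator matrix.  By default it is derived
        from ``lab_records`` (observed iff at least one record exists); it
        may be overridden, e.g. to construct deliberately invalid corpora
        for :func:`validate_corpus`.
    """

    def __init__(
        self,
        n_patients: int,
        types: Sequence,
        labs: Sequence,
        tokens=((), (), (), ()),
        lab_records=((), (), (), ()),
        lab_observed: np.ndarray | None = None,
    ):
        self.n_patients = int(n_patients)
        self.types = [t if isinstance(t, DataTypeSpec) else DataTypeSpec(int(t)) for t in types]
        self.labs = [l if isinstance(l, LabSpec) else LabSpec(int(l)) for l in labs]

        tp, tt, tw, tc = (_as_int_array(a, n) for a, n in zip(tokens, ("tok_pat", "tok_type", "tok_feat", "tok_cnt")))
        order = np.lexsort((tw, tt, tp))
        self.tok_pat, self.tok_type, self.tok_feat, self.tok_cnt = tp[order], tt[order], tw[order], tc[order]

        lp, ll, lv, ly = (_as_int_array(a, n) for a, n in zip(lab_records, ("lab_pat", "lab_lab", "lab_state", "lab_freq")))
        order = np.lexsort((lv, ll, lp))
        self.lab_pat, self.lab_lab, self.lab_state, self.lab_freq = lp[order], ll[order], lv[order], ly[order]

        if lab_observed is None:
            obs = np.zeros((self.n_labs, self.n_patients), dtype=bool)
            valid = (
                (self.lab_lab >= 0)
                & (self.lab_lab < self.n_labs)
                & (self.lab_pat >= 0)
                & (self.lab_pat < self.n_patients)
            )
            obs[self.lab_lab[valid], self.lab_pat[valid]] = True
            self.lab_observed = obs
        else:
            self.lab_observed = np.asarray(lab_observed, dtype=bool)

    # ------------------------------------------------------------------ sizes
    @property
    def n_types(self) -> int:
        return len(self.types)

    @property
    def n_labs(self) -> int:
        return len(self.labs)

    @property
    def type_sizes(self) -> np.ndarray:
        return np.array([t.n_features for t in self.types], dtype=np.int64)

    @property
    def lab_sizes(self) -> np.ndarray:
        return np.array([l.n_states for l in self.labs], dtype=np.int64)

    def tokens_per_patient(self) -> np.ndarray:
        """(T, D) matrix of token totals M_j^(t)."""
        M = np.zeros((self.n_types, self.n_patients), dtype=np.int64)
        np.add.at(M, (self.tok_type, self.tok_pat), self.tok_cnt)
        return M

    # ----------------------------------------------------------------- access
    def patient(self, j: int) -> "PatientRecord":
        """Extract one patient's observations as a standalone record."""
        tm = self.tok_pat == j
        lm = self.lab_pat == j
        return PatientRecord(
            tok_type=self.tok_type[tm].copy(),
            tok_feat=self.tok_feat[tm].copy(),
            tok_cnt=self.tok_cnt[tm].copy(),
            lab_lab=self.lab_lab[lm].copy(),
            lab_state=self.lab_state[lm].copy(),
            lab_freq=self.lab_freq[lm].copy(),
        )

    def subset(self, patients: Sequence[int]) -> "MultiModalCorpus":
        """Corpus restricted to ``patients``, re-indexed 0..len(patients)-1."""
        patients = np.asarray(patients, dtype=np.int64)
        remap = -np.ones(self.n_patients, dtype=np.int64)
        remap[patients] = np.arange(len(patients))
        tm = remap[self.tok_pat] >= 0
        lm = remap[self.lab_pat] >= 0
        return MultiModalCorpus(
            len(patients),
            self.types,
            self.labs,
            tokens=(remap[self.tok_pat[tm]], self.tok_type[tm], self.tok_feat[tm], self.tok_cnt[tm]),
            lab_records=(remap[self.lab_pat[lm]], self.lab_lab[lm], self.lab_state[lm], self.lab_freq[lm]),
        )

    # ------------------------------------------------------------- validation
    def validate(self) -> list[str]:
        return validate_corpus(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MultiModalCorpus):
            return NotImplemented
        return (
            self.n_patients == other.n_patients
            and self.types == other.types
            and self.labs == other.labs
            and all(
                np.array_equal(getattr(self, a), getattr(other, a))
                for a in ("tok_pat", "tok_type", "tok_feat", "tok_cnt", "lab_pat", "lab_lab", "lab_state", "lab_freq")
            )
            and np.array_equal(self.lab_observed, other.lab_observed)
        )


@dataclass
class PatientRecord:
    """One patient's observations, detached from any corpus."""

    tok_type: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    tok_feat: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    tok_cnt: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    lab_lab: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    lab_state: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    lab_freq: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def without_lab(self, lab: int) -> "PatientRecord":
        m = self.lab_lab != lab
        return PatientRecord(
            self.tok_type, self.tok_feat, self.tok_cnt,
            self.lab_lab[m], self.lab_state[m], self.lab_freq[m],
        )

    def without_feature(self, data_type: int, feature: int) -> "PatientRecord":
        m = ~((self.tok_type == data_type) & (self.tok_feat == feature))
        return PatientRecord(
            self.tok_type[m], self.tok_feat[m], self.tok_cnt[m],
            self.lab_lab, self.lab_state, self.lab_freq,
        )


def validate_corpus(corpus: MultiModalCorpus) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the corpus is valid.  Violations are returned, not
    raised, so deliberately broken corpora can be inspected.
    """
    v: list[str] = []
    D, T, L = corpus.n_patients, corpus.n_types, corpus.n_labs
    W = corpus.type_sizes
    V = corpus.lab_sizes

    for i in range(len(corpus.tok_pat)):
        j, t, w, c = corpus.tok_pat[i], corpus.tok_type[i], corpus.tok_feat[i], corpus.tok_cnt[i]
        if not (0 <= j < D):
            v.append(f"count record {i}: patient {j + 1} outside 1..{D}")
        if not (0 <= t < T):
            v.append(f"count record {i}: type {t + 1} outside 1..{T}")
            continue
        if not (0 <= w < W[t]):
            v.append(f"count record {i}: feature {w + 1} outside 1..{W[t]} for type {t + 1}")
        if c < 1:
            v.append(f"count record {i}: non-positive count {c}")
    keys = set()
    for i in range(len(corpus.tok_pat)):
        key = (int(corpus.tok_pat[i]), int(corpus.tok_type[i]), int(corpus.tok_feat[i]))
        if key in keys:
            v.append(f"count record {i}: duplicate (patient,type,feature) {tuple(x + 1 for x in key)}")
        keys.add(key)

    for i in range(len(corpus.lab_pat)):
        j, l, s, y = corpus.lab_pat[i], corpus.lab_lab[i], corpus.lab_state[i], corpus.lab_freq[i]
        if not (0 <= j < D):
            v.append(f"lab record {i}: patient {j + 1} outside 1..{D}")
        if not (0 <= l < L):
            v.append(f"lab record {i}: lab {l + 1} outside 1..{L}")
            continue
        if not (0 <= s < V[l]):
            v.append(f"lab record {i}: state {s + 1} outside 1..{V[l]} for lab {l + 1}")
        if y < 1:
            v.append(f"lab record {i}: non-positive frequency {y}")
        if 0 <= j < D and not corpus.lab_observed[l, j]:
            v.append(f"lab record {i}: record for unobserved lab (lab {l + 1}, patient {j + 1})")
    lab_keys = set()
    for i in range(len(corpus.lab_pat)):
        key = (int(corpus.lab_pat[i]), int(corpus.lab_lab[i]), int(corpus.lab_state[i]))
        if key in lab_keys:
            v.append(f"lab record {i}: duplicate (patient,lab,state) {tuple(x + 1 for x in key)}")
        lab_keys.add(key)

    if corpus.lab_observed.shape != (L, D):
        v.append(f"lab_observed has shape {corpus.lab_observed.shape}, expected {(L, D)}")
    else:
        has_rec = np.zeros((L, D), dtype=bool)
        ok = (corpus.lab_lab >= 0) & (corpus.lab_lab < L) & (corpus.lab_pat >= 0) & (corpus.lab_pat < D)
        has_rec[corpus.lab_lab[ok], corpus.lab_pat[ok]] = True
        missing = corpus.lab_observed & ~has_rec
        for l, j in zip(*np.nonzero(missing)):
            v.append(f"lab {l + 1}, patient {j + 1}: marked observed but has no lab record")
    return v


# ---------------------------------------------------------------------------
# On-disk corpus format: three tab-separated files.
# ---------------------------------------------------------------------------

def _parse_int_fields(path: Path, n_fields: int):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != n_fields:
                raise CorpusParseError(f"{path}:{ln}: expected {n_fields} tab-separated fields, got {len(parts)}")
            try:
                rows.append([int(p) for p in parts])
            except ValueError as e:
                raise CorpusParseError(f"{path}:{ln}: non-integer field ({e})") from None
    if not rows:
        return [np.zeros(0, dtype=np.int64)] * n_fields
    arr = np.array(rows, dtype=np.int64)
    return [arr[:, i] for i in range(n_fields)]


def _parse_meta(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusParseError(f"{path}:{ln}: expected 'key<TAB>value'")
            key, value = parts
            try:
                if key in ("D", "T", "L"):
                    meta[key] = int(value)
                elif key in ("W", "V"):
                    meta[key] = [int(x) for x in value.split(",")] if value else []
                else:
                    raise CorpusParseError(f"{path}:{ln}: unknown meta key {key!r}")
            except ValueError:
                raise CorpusParseError(f"{path}:{ln}: bad value {value!r} for {key}") from None
    for key in ("D", "T", "W", "L", "V"):
        if key not in meta:
            raise CorpusParseError(f"{path}: meta file missing key {key!r}")
    if len(meta["W"]) != meta["T"]:
        raise CorpusParseError(f"{path}: W lists {len(meta['W'])} sizes but T={meta['T']}")
    if len(meta["V"]) != meta["L"]:
        raise CorpusParseError(f"{path}: V lists {len(meta['V'])} sizes but L={meta['L']}")
    return meta


def read_corpus(counts_path, labs_path, meta_path) -> MultiModalCorpus:
    """Read and validate a corpus from its three tab-separated files.

    Raises :class:`CorpusParseError` on malformed lines (with line numbers)
    and :class:`CorpusValidationError` when the declared dimensions are
    violated (out-of-range feature indices, duplicates, ...).
    """
    meta = _parse_meta(Path(meta_path))
    tp, tt, tw, tc = _parse_int_fields(Path(counts_path), 4)
    lp, ll, lv, ly = _parse_int_fields(Path(labs_path), 4)
    corpus = MultiModalCorpus(
        meta["D"], meta["W"], meta["V"],
        tokens=(tp - 1, tt - 1, tw - 1, tc),
        lab_records=(lp - 1, ll - 1, lv - 1, ly),
    )
    violations = validate_corpus(corpus)
    if violations:
        raise CorpusValidationError("; ".join(violations))
    return corpus


def write_corpus(corpus: MultiModalCorpus, counts_path, labs_path, meta_path) -> None:
    """Write the three tab-separated corpus files (1-based indices)."""
    with open(meta_path, "w") as fh:
        fh.write(f"D\t{corpus.n_patients}\n")
        fh.write(f"T\t{corpus.n_types}\n")
        fh.write("W\t" + ",".join(str(w) for w in corpus.type_sizes) + "\n")
        fh.write(f"L\t{corpus.n_labs}\n")
        fh.write("V\t" + ",".join(str(v) for v in corpus.lab_sizes) + "\n")
    with open(counts_path, "w") as fh:
        for j, t, w, c in zip(corpus.tok_pat, corpus.tok_type, corpus.tok_feat, corpus.tok_cnt):
            fh.write(f"{j + 1}\t{t + 1}\t{w + 1}\t{c}\n")
    with open(labs_path, "w") as fh:
        for j, l, v, y in zip(corpus.lab_pat, corpus.lab_lab, corpus.lab_state, corpus.lab_freq):
            fh.write(f"{j + 1}\t{l + 1}\t{v + 1}\t{y}\n")


# ---------------------------------------------------------------------------
# Fitted-model artifacts.
# ---------------------------------------------------------------------------

@dataclass
class ParameterEstimates:
    """Posterior-mean parameter estimates of a fitted model.

    theta: (D, K) patient-by-topic mixtures, rows sum to 1.
    phi:   per type t a (W^(t), K) matrix, columns sum to 1.
    eta:   per lab l a (K, V_l) matrix of result-state probabilities,
           rows sum to 1.
    psi:   (L, K) probabilities in (0, 1) that a lab is observed under
           each topic (the non-random missingness mechanism).
    """

    theta: np.ndarray
    phi: list[np.ndarray]
    eta: list[np.ndarray]
    psi: np.ndarray

    @property
    def n_topics(self) -> int:
        return self.theta.shape[1] if self.theta.ndim == 2 else self.phi[0].shape[1]

    def validate(self, atol: float = 1e-6) -> None:
        if self.theta.size and not np.allclose(self.theta.sum(axis=1), 1.0, atol=atol):
            raise CorpusValidationError("theta rows must sum to 1")
        for t, ph in enumerate(self.phi):
            if not np.allclose(ph.sum(axis=0), 1.0, atol=atol):
                raise CorpusValidationError(f"phi[{t}] columns must sum to 1")
        for l, et in enumerate(self.eta):
            if not np.allclose(et.sum(axis=1), 1.0, atol=atol):
                raise CorpusValidationError(f"eta[{l}] rows must sum to 1")
        if self.psi.size and not ((self.psi > 0) & (self.psi < 1)).all():
            raise CorpusValidationError("psi entries must lie strictly in (0, 1)")


def write_model(estimates: ParameterEstimates, hyper, path) -> None:
    """Serialize estimates + hyperparameters as JSON (exact float round-trip)."""
    estimates.validate()
    hyper.validate()
    payload = {
        "theta": estimates.theta.tolist(),
        "phi": [p.tolist() for p in estimates.phi],
        "eta": [e.tolist() for e in estimates.eta],
        "psi": estimates.psi.tolist(),
        "alpha": hyper.alpha.tolist(),
        "beta": [b.tolist() for b in hyper.beta],
        "zeta": [z.tolist() for z in hyper.zeta],
        "a": hyper.a.tolist(),
        "b": hyper.b.tolist(),
        "priors": {k: [p.shape, p.rate] for k, p in hyper.priors.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_model(path):
    """Inverse of :func:`write_model`; returns (estimates, hyperparameters)."""
    from .synthetic import GammaPrior, ModelHyperparameters

    with open(path) as fh:
        payload = json.load(fh)
    K = len(payload["alpha"])
    estimates = ParameterEstimates(
        theta=np.array(payload["theta"], dtype=float).reshape(-1, K),
        phi=[np.array(p, dtype=float) for p in payload["phi"]],
        eta=[np.array(e, dtype=float).reshape(K, -1) for e in payload["eta"]],
        psi=np.array(payload["psi"], dtype=float).reshape(-1, K),
    )
    hyper = ModelHyperparameters(
        alpha=np.array(payload["alpha"], dtype=float),
        beta=[np.array(b, dtype=float) for b in payload["beta"]],
        zeta=[np.array(z, dtype=float) for z in payload["zeta"]],
        a=np.array(payload["a"], dtype=float),
        b=np.array(payload["b"], dtype=float),
        priors={k: GammaPrior(*v) for k, v in payload["priors"].items()},
    )
    return estimates, hyper
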