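"""Topic-embedding comorbidity analysis.

Each code's embedding is its row of the fitted topic matrix phi (its
probability under each of the K topics).  Codes whose embeddings correlate
across topics tend to co-occur in the same meta-phenotypes; significance is
assessed by shuffling the target code's embedding entries to build a
permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .corpus import ParameterEstimates

__all__ = [
    "CodeEmbedding",
    "embedding_from_model",
    "code_correlation_matrix",
    "permutation_significance",
]


@dataclass
class CodeEmbedding:
    """Per-code K-vectors from one data type's topic matrix."""

    codes: list
    vectors: np.ndarray  # (n_codes, K)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.codes):
            raise ValueError("vectors must be (n_codes, K) aligned with codes")


def embedding_from_model(
    model: ParameterEstimates,
    data_type: int,
    codes: list | None = None,
    renormalize: bool = False,
) -> CodeEmbedding:
    """Rows of phi for one data type, optionally renormalized over topics."""
    vectors = model.phi[data_type].copy()
    if renormalize:
        vectors = vectors / vectors.sum(axis=1, keepdims=True)
    if codes is None:
        codes = list(range(vectors.shape[0]))
    else:
        vectors = vectors[np.asarray(codes)]
    return CodeEmbedding(codes=list(codes), vectors=vectors)


def _drop_zero_variance(embedding: CodeEmbedding) -> CodeEmbedding:
    sd = embedding.vectors.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance code(s)")
    return CodeEmbedding(
        [c for c, k in zip(embedding.codes, keep) if k], embedding.vectors[keep]
    )


def code_correlation_matrix(embedding: CodeEmbedding) -> tuple[CodeEmbedding, np.ndarray]:
    """Pairwise Pearson correlations between code embeddings.

    Zero-variance codes are dropped with a warning.  Returns the (possibly
    reduced) embedding and the symmetric correlation matrix with unit
    diagonal.
    """
    if embedding.vectors.shape[1] < 2:
        raise ValueError("correlation over topics requires K >= 2")
    emb = _drop_zero_variance(embedding)
    if len(emb.codes) < 2:
        raise ValueError("need at least 2 codes with nonzero variance")
    R = np.corrcoef(emb.vectors)
    np.fill_diagonal(R, 1.0)
    return emb, R


def permutation_significance(
    embedding: CodeEmbedding,
    target_code,
    n_perm: int,
    seed: int,
    two_sided: bool = True,
    threshold: float = 0.01,
):
    """Permutation p-values for the target code's correlations.

    The target's K-vector entries are shuffled ``n_perm`` times; each
    permutation's correlations with all other codes form the null.  The
    per-code p-value uses the add-one estimator
    (1 + #{|null r| >= |observed r|}) / (1 + n_perm), so the minimum
    attainable p is 1 / (1 + n_perm).  Returns a dict
    code -> (observed r, p-value, flagged at ``threshold``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    idx = embedding.codes.index(target_code)
    target = embedding.vectors[idx]
    if target.std() == 0:
        raise ValueError("target code has zero variance across topics")
    others_keep = [i for i in range(len(embedding.codes)) if i != idx]
    others = embedding.vectors[others_keep]
    sd = others.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"dropped {int((sd == 0).sum())} zero-variance code(s)")
        others_keep = [i for i, s in zip(others_keep, sd) if s > 0]
        others = embedding.vectors[others_keep]

    oc = others - others.mean(axis=1, keepdims=True)
    oc_norm = np.sqrt((oc**2).sum(axis=1))

    def corr_with(vec):
        vc = vec - vec.mean()
        return (oc @ vc) / (oc_norm * np.sqrt((vc**2).sum()))

    observed = corr_with(target)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(others_keep), dtype=np.int64)
    for _ in range(n_perm):
        null_r = corr_with(rng.permutation(target))
        if two_sided:
            exceed += np.abs(null_r) >= np.abs(observed)
        else:
            exceed += null_r >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return {
        embedding.codes[i]: (float(r), float(p), bool(p < threshold))
        for i, r, p in zip(others_keep, observed, pvals)
    }
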