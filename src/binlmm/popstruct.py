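"""Population structure: principal components and the additive kinship matrix.

PCs of the column-centered call matrix serve as fixed-effect covariates; the
kinship matrix K estimates additive relatedness between lines (VanRaden
method 1).  The factor 2 in the model's line-effect covariance 2*K*sigma_G^2
is applied inside the association models, not folded into K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix


@dataclass
class CovariateSet:
    """Fixed-effect design: intercept plus principal-component scores.

    ``design`` is n x (1+k) with an all-ones first column; ``varexp`` holds
    the fraction of genotypic variance explained by each retained PC.
    """

    samples: list[str]
    design: np.ndarray
    varexp: np.ndarray

    @property
    def names(self) -> list[str]:
        return ["intercept"] + [f"PC{i+1}" for i in range(self.design.shape[1] - 1)]


@dataclass
class KinshipMatrix:
    """Symmetric, numerically PSD additive relatedness matrix aligned to samples."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample IDs")
        if np.max(np.abs(self.values - self.values.T)) > 1e-8:
            raise ValueError("kinship matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)


def compute_pcs(G: GenotypeMatrix, k: int, scale: bool = False) -> CovariateSet:
    """Top-k principal components of the centered (optionally scaled) calls.

    Scores are the top-k left singular directions of the column-centered call
    matrix, with a deterministic sign convention (largest-magnitude loading of
    each score vector is positive).  ``scale=True`` divides each marker column
    by its standard deviation (unit-variance scaling); the default matches the
    VanRaden-consistent centering-only convention.
    """
    if G.has_missing():
        raise ValueError("impute missing calls before computing PCs")
    n, m = G.calls.shape
    if not (0 < k < min(n, m)):
        raise ValueError(f"k must be in (0, min(n,m)={min(n, m)})")
    S = G.calls.astype(float)
    S -= S.mean(axis=0, keepdims=True)
    if scale:
        sd = S.std(axis=0)
        keep = sd > 0
        S = S[:, keep] / sd[keep]
    if not np.any(S):
        raise ValueError("zero-variance genotype matrix")
    U, s, _ = np.linalg.svd(S, full_matrices=False)
    scores = U[:, :k] * s[:k]
    # deterministic sign: largest-|.| element of each score column positive
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    varexp = (s[:k] ** 2) / np.sum(s**2)
    design = np.column_stack([np.ones(n), scores])
    return CovariateSet(list(G.samples), design, varexp)


def compute_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden method-1 additive kinship.

    K = S S^T / (2 * sum_j p_j (1 - p_j)) with S the call matrix centered by
    twice the counted-allele frequency.  Monomorphic markers contribute a zero
    column to S and are excluded from the denominator.
    """
    if G.has_missing():
        raise ValueError("impute missing calls before computing kinship")
    calls = G.calls.astype(float)
    p = calls.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic markers for kinship")
    S = calls - 2.0 * p[None, :]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = (S @ S.T) / denom
    return KinshipMatrix(list(G.samples), 0.5 * (K + K.T))


def write_kinship(K: KinshipMatrix, path: str) -> None:
    pd.DataFrame(K.values, index=K.samples, columns=K.samples).to_csv(path, sep="\t")


def read_kinship(path: str) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix([str(s) for s in df.index], df.to_numpy(dtype=float))


def write_covariates(C: CovariateSet, path: str) -> None:
    df = pd.DataFrame(C.design[:, 1:], index=C.samples,
                      columns=[f"PC{i+1}" for i in range(C.design.shape[1] - 1)])
    df.to_csv(path, sep="\t", index_label="sample")


def read_covariates(path: str) -> CovariateSet:
    """Read a covariate TSV (sample ID + score columns); adds the intercept."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    design = np.column_stack([np.ones(len(df)), df.to_numpy(dtype=float)])
    return CovariateSet([str(s) for s in df.index], design, np.full(df.shape[1], np.nan))
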