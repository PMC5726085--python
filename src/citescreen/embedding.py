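"""Spectral embedding of a citation corpus.

Each citation's TF-IDF row is renormalised so that pairwise inner products
give the Bhattacharyya coefficient between the two term-share
distributions: with shares ``s_{d,w} = X[d,w] / sum_w' X[d,w']`` the row is
``r_{d,w} = sqrt(s_{d,w})``, so ``<r_d, r_d'> = sum_w sqrt(s_d s_d')`` lies
in [0, 1], equals 1 on the diagonal, and the Gram matrix C = R R^T is
positive semidefinite.  The symmetrically normalised operator

    C~ = D^{-1/2} C D^{-1/2},    D = diag(row sums of C)

has its spectrum in [0, 1] with top eigenvalue exactly 1 (eigenvector
proportional to D^{1/2} 1).  The p-dimensional embedding scales the leading
eigenvectors by the square roots of their eigenvalues:

    Z = [u_1 sqrt(lambda_1), ..., u_p sqrt(lambda_p)]

so that Z Z^T converges to C~ as p grows.  C~ is dense in general, but
matrix-vector products factor through the sparse R:
``C~ x = D^{-1/2} (R (R^T (D^{-1/2} x)))``, which is what the iterative
eigensolver uses; the operator is never densified above a size threshold.

A plain L1 variant (rows are the raw term shares, no square root) is kept
behind ``sqrt_dialect=False`` for comparison; its Gram matrix no longer has
a unit diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "NormalisedMatrix",
    "Embedding",
    "EigensolverError",
    "DegenerateRowError",
    "row_normalize",
    "pairwise_similarity",
    "degree_vector",
    "similarity_matrix",
    "normalised_similarity_dense",
    "spectral_embed",
]

DENSE_THRESHOLD = 500  # below this many valid rows, use an exact dense solve


class EigensolverError(RuntimeError):
    """Iterative eigensolver failed to converge."""


class DegenerateRowError(ValueError):
    """Similarity requested for an all-zero (degenerate) citation row."""


@dataclass(frozen=True)
class NormalisedMatrix:
    """Row-normalised TF-IDF matrix R with a validity flag per citation.

    Rows whose TF-IDF entries are all zero (every token appears in every
    citation) cannot be normalised; they are stored as zero vectors and
    flagged invalid.  Valid rows satisfy <r_d, r_d> = 1 in the square-root
    dialect.
    """

    R: sp.csr_matrix
    valid: np.ndarray  # bool, shape (n,)
    sqrt_dialect: bool = True

    @property
    def n(self) -> int:
        return self.R.shape[0]


@dataclass(frozen=True)
class Embedding:
    """Spectral coordinates Z (n x p) and the retained eigenvalues.

    Row ``Z[d]`` holds the coordinates of citation d; degenerate citations
    get zero rows and ``valid[d] = False``.  Eigenvalues are sorted
    non-increasing with ``eigenvalues[0] ~= 1``.
    """

    Z: np.ndarray
    eigenvalues: np.ndarray
    valid: np.ndarray = field(repr=False)

    @property
    def p(self) -> int:
        return self.Z.shape[1]


def row_normalize(X: sp.spmatrix, sqrt_dialect: bool = True) -> NormalisedMatrix:
    """Normalise each TF-IDF row to a term-share distribution.

    Square-root dialect (default): ``r_{d,w} = sqrt(X[d,w] / sum_w' X[d,w'])``.
    Plain dialect: the L1 shares themselves.  All-zero rows become zero
    vectors flagged invalid.
    """
    X = sp.csr_matrix(X, dtype=np.float64)
    if X.nnz and X.data.min() < 0:
        raise ValueError("TF-IDF matrix must be non-negative")
    row_sums = np.asarray(X.sum(axis=1)).ravel()
    valid = row_sums > 0
    scale = np.where(valid, row_sums, 1.0)
    R = sp.csr_matrix(X, copy=True)
    R = sp.diags(1.0 / scale) @ R
    if sqrt_dialect:
        R.data = np.sqrt(R.data)
    R = sp.csr_matrix(R)
    R.sort_indices()
    return NormalisedMatrix(R=R, valid=valid, sqrt_dialect=sqrt_dialect)


def pairwise_similarity(norm: NormalisedMatrix, d: int, d_prime: int) -> float:
    """Bhattacharyya coefficient between two citations' term-share distributions."""
    if not (norm.valid[d] and norm.valid[d_prime]):
        bad = d if not norm.valid[d] else d_prime
        raise DegenerateRowError(f"citation {bad} has a degenerate (all-zero) row")
    value = float(norm.R[d].multiply(norm.R[d_prime]).sum())
    return min(max(value, 0.0), 1.0)


def degree_vector(norm: NormalisedMatrix) -> np.ndarray:
    """Row sums of the similarity matrix C, computed as R (R^T 1).

    Never materialises C.  Valid rows have degree >= 1 (the diagonal
    contributes C[d,d] = 1); degenerate rows have degree 0.
    """
    ones = np.ones(norm.n)
    return np.asarray(norm.R @ (norm.R.T @ ones)).ravel()


def similarity_matrix(norm: NormalisedMatrix) -> np.ndarray:
    """Dense Gram matrix C = R R^T (small-n oracle; O(n^2) memory)."""
    return np.asarray((norm.R @ norm.R.T).todense())


def _inv_sqrt_degree(norm: NormalisedMatrix) -> np.ndarray:
    deg = degree_vector(norm)
    inv = np.zeros(norm.n)
    inv[norm.valid] = 1.0 / np.sqrt(deg[norm.valid])
    return inv


def normalised_similarity_dense(norm: NormalisedMatrix) -> np.ndarray:
    """Dense C~ = D^{-1/2} C D^{-1/2} (small-n oracle).

    Degenerate rows give zero rows/columns.
    """
    C = similarity_matrix(norm)
    inv = _inv_sqrt_degree(norm)
    return inv[:, None] * C * inv[None, :]


def spectral_embed(
    norm: NormalisedMatrix,
    p: int = 50,
    seed: int = 0,
    tol: float = 1e-10,
    maxiter: int = 5000,
    dense_threshold: int = DENSE_THRESHOLD,
) -> Embedding:
    """Top-p eigenpairs of the normalised similarity operator as coordinates.

    For corpora with at most ``dense_threshold`` valid rows the operator is
    densified and solved exactly (this path doubles as the internal oracle);
    larger corpora use an implicitly restarted Lanczos iteration on the
    composed sparse operator with a seeded start vector, so results are
    deterministic given ``seed``.  Eigenvector sign is arbitrary; only
    distances between rows of Z matter downstream.

    If p exceeds the number of available eigenpairs the trailing columns of
    Z are zero-filled with a warning.
    """
    n = norm.n
    if p < 1:
        raise ValueError("embedding dimension p must be >= 1")
    if p > n:
        raise ValueError(f"embedding dimension p={p} exceeds corpus size n={n}")
    n_valid = int(norm.valid.sum())
    if n_valid == 0:
        raise ValueError("no non-degenerate citation rows to embed")

    inv = _inv_sqrt_degree(norm)
    k = min(p, n_valid)

    # ARPACK needs k strictly below the operator size; fall back to the
    # dense path when the corpus is small or p is nearly full-rank.
    if n_valid <= max(dense_threshold, k + 1):
        C_tilde = normalised_similarity_dense(norm)
        vals, vecs = np.linalg.eigh(C_tilde)
        order = np.argsort(vals)[::-1][:k]
        vals, vecs = vals[order], vecs[:, order]
    else:
        R, inv_vec = norm.R, inv

        def matvec(x: np.ndarray) -> np.ndarray:
            y = inv_vec * x
            y = R.T @ y
            y = R @ y
            return inv_vec * y

        op = spla.LinearOperator((n, n), matvec=matvec, dtype=np.float64)
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        try:
            vals, vecs = spla.eigsh(
                op, k=k, which="LA", v0=v0, tol=tol, maxiter=maxiter
            )
        except spla.ArpackNoConvergence as exc:
            raise EigensolverError(
                f"eigensolver did not converge within {maxiter} iterations "
                f"at tolerance {tol} ({len(exc.eigenvalues)} of {k} eigenvalues "
                "converged)"
            ) from exc
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    Z = vecs * np.sqrt(np.clip(vals, 0.0, None))[None, :]
    Z[~norm.valid, :] = 0.0
    if k < p:
        warnings.warn(
            f"requested p={p} exceeds the {k} available eigenpairs; "
            "trailing embedding columns are zero-filled",
            RuntimeWarning,
            stacklevel=2,
        )
        Z = np.hstack([Z, np.zeros((n, p - k))])
        vals = np.concatenate([vals, np.zeros(p - k)])
    return Embedding(Z=np.ascontiguousarray(Z), eigenvalues=vals, valid=norm.valid.copy())
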