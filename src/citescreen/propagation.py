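"""k-NN label propagation from manually labelled to unlabelled citations.

Under the cluster assumption — nearby citations in feature space tend to
share an eligibility label — each manually labelled citation copies its
label to its k nearest unlabelled neighbours (cosine distance, in either
the bag-of-words or the spectral space).  An unlabelled citation claimed by
several labelled sources takes the label of the closest one; exact distance
ties break on the lower source corpus index so results are reproducible.
Manual labels are never overwritten.

Neighbourhoods are found by exact search: corpora in this problem class are
small enough (tens of thousands of citations, 50-dimensional spectral
coordinates) that approximate indices buy nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from sklearn.metrics.pairwise import cosine_distances

__all__ = [
    "PseudoLabel",
    "ZeroVectorError",
    "cosine_distance",
    "nearest_neighbours",
    "propagate",
    "valid_rows",
]

logger = logging.getLogger(__name__)


class ZeroVectorError(ValueError):
    """Cosine distance is undefined for a zero-norm vector."""


@dataclass(frozen=True)
class PseudoLabel:
    """A propagated label: the class, the manual source it came from, and
    the cosine distance to that source."""

    label: int
    source: int
    distance: float


def cosine_distance(v: np.ndarray, u: np.ndarray) -> float:
    """1 - cos(angle) between two vectors; in [0, 2]."""
    v = np.asarray(v, dtype=np.float64).ravel()
    u = np.asarray(u, dtype=np.float64).ravel()
    nv, nu = np.linalg.norm(v), np.linalg.norm(u)
    if nv == 0.0 or nu == 0.0:
        raise ZeroVectorError("cosine distance undefined for a zero vector")
    return float(1.0 - np.dot(v, u) / (nv * nu))


def valid_rows(vectors: np.ndarray | sp.spmatrix) -> np.ndarray:
    """Boolean mask of rows with positive Euclidean norm."""
    if sp.issparse(vectors):
        sq = np.asarray(vectors.multiply(vectors).sum(axis=1)).ravel()
    else:
        sq = np.einsum("ij,ij->i", vectors, vectors)
    return sq > 0


def _row_distances(
    vectors: np.ndarray | sp.spmatrix, rows: np.ndarray
) -> np.ndarray:
    """Cosine distances from the given rows to every row, clipped to [0, 2]."""
    D = cosine_distances(vectors[rows], vectors)
    return np.clip(D, 0.0, 2.0)


def nearest_neighbours(
    d: int,
    vectors: np.ndarray | sp.spmatrix,
    k: int,
    valid: np.ndarray | None = None,
) -> list[int]:
    """The k other citations closest to d by cosine distance.

    Ordered ascending by distance, ties broken by ascending corpus index.
    Degenerate (zero-vector) citations are never candidates; if fewer than
    k candidates exist, all of them are returned and a message is logged.
    """
    if valid is None:
        valid = valid_rows(vectors)
    if not valid[d]:
        raise ZeroVectorError(f"citation {d} has a zero feature vector")
    n = vectors.shape[0]
    dist = _row_distances(vectors, np.array([d]))[0]
    dist[d] = np.inf
    dist[~valid] = np.inf
    order = np.lexsort((np.arange(n), dist))
    available = int(np.isfinite(dist).sum())
    if available < k:
        logger.info(
            "citation %d has only %d candidates for k=%d neighbours", d, available, k
        )
    return [int(i) for i in order[: min(k, available)]]


def propagate(
    manual: Mapping[int, int],
    vectors: np.ndarray | sp.spmatrix,
    k: int = 3,
    valid: np.ndarray | None = None,
) -> dict[int, PseudoLabel]:
    """Copy each manual label to its k nearest unlabelled neighbours.

    Neighbourhoods are taken over all citations (labelled neighbours are
    simply skipped, not re-labelled).  Conflicting claims resolve to the
    closest source, ties to the lower source index; the output is
    independent of the order in which sources are processed.

    Parameters
    ----------
    manual
        Corpus index -> label (0/1) for the manually screened citations.
    vectors
        Feature rows, one per citation (TF-IDF rows or spectral coordinates).
    k
        Neighbourhood size; the method's default is 3.
    valid
        Optional precomputed mask of non-degenerate rows.

    Returns
    -------
    dict mapping each pseudo-labelled corpus index to its
    :class:`PseudoLabel` (label, source, distance).
    """
    if not manual:
        raise ValueError("label propagation needs at least one manual label")
    for idx, y in manual.items():
        if y not in (0, 1):
            raise ValueError(f"manual label for citation {idx} must be 0 or 1")
    if valid is None:
        valid = valid_rows(vectors)
    n = vectors.shape[0]
    labelled = np.zeros(n, dtype=bool)
    labelled[list(manual)] = True

    sources = np.array(sorted(i for i in manual if valid[i]), dtype=np.int64)
    if sources.size == 0:
        return {}
    D = _row_distances(vectors, sources)

    best: dict[int, PseudoLabel] = {}
    index_order = np.arange(n)
    for row, src in enumerate(sources):
        dist = D[row].copy()
        dist[src] = np.inf
        dist[~valid] = np.inf
        order = np.lexsort((index_order, dist))
        neighbours = order[: min(k, int(np.isfinite(dist).sum()))]
        for t in neighbours:
            if labelled[t]:
                continue  # neighbourhood includes labelled citations; skip them
            t = int(t)
            cand = PseudoLabel(
                label=int(manual[int(src)]), source=int(src), distance=float(dist[t])
            )
            cur = best.get(t)
            if cur is None or (cand.distance, cand.source) < (cur.distance, cur.source):
                best[t] = cand
    return best
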