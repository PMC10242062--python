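"""PCA clustering and the two-stage IF-PCA / IF-PCA(X) procedures.

PCA clustering embeds the n subjects as rows of the leading left singular
vectors of the data matrix — K vectors for the raw matrix X (whose signal
part has rank K) and K-1 for the column-standardized W (standardization
removes one rank) — and partitions the rows with k-means.  IF-PCA first
runs the IF selection step on W and then clusters on the post-selection
columns of W (orthodox variant) or of X (the "(X)" variant); both use K-1
singular vectors of the post-selection matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .io import ExpressionMatrix, NormalizedMatrix, normalize_columns
from .selection import SelectionResult, select_features


@dataclass
class Embedding:
    """Rows of the top-r left singular vectors embedding the n subjects."""

    vectors: np.ndarray
    singular_values: np.ndarray
    source: str = "W"


@dataclass
class ClusterResult:
    labels: np.ndarray
    method: str
    variant: str | None
    embedding: Embedding
    seed: int
    selection: SelectionResult | None = None
    repeats: int = 1


def pca_embed(M: np.ndarray, r: int) -> Embedding:
    """Top-r left singular vectors of M, by decreasing singular value.

    Deterministic for a fixed input: each column's sign is fixed so that
    its largest-magnitude entry is positive.  If r exceeds the numerical
    rank, the available vectors are returned with a warning.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if r > min(M.shape):
        raise ValueError(f"r={r} exceeds min(n, p)={min(M.shape)}")
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    tol = s[0] * max(M.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if r > rank:
        warnings.warn(
            f"requested {r} singular vectors but numerical rank is {rank}",
            stacklevel=2,
        )
        r = max(rank, 1)
    U = U[:, :r].copy()
    for k in range(U.shape[1]):  # sign convention for determinism
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    return Embedding(vectors=U, singular_values=s[:r].copy())


def kmeans_cluster(
    E: Embedding | np.ndarray, K: int, restarts: int = 30, seed: int = 0
) -> np.ndarray:
    """Best-of-``restarts`` k-means on the embedding rows; labels in 1..K."""
    V = E.vectors if isinstance(E, Embedding) else np.asarray(E, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    n = V.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds n={n}")
    distinct = np.unique(V, axis=0).shape[0]
    if K > distinct:
        warnings.warn(
            f"K={K} exceeds the {distinct} distinct embedding rows",
            stacklevel=2,
        )
        K = distinct
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed)
    return km.fit_predict(V) + 1


def pca_cluster(
    data: ExpressionMatrix | NormalizedMatrix,
    K: int,
    seed: int = 0,
    restarts: int = 30,
) -> ClusterResult:
    """Classical PCA clustering: r = K components on a raw matrix,
    r = K - 1 on a normalized one."""
    if K < 2:
        raise ValueError("K must be >= 2")
    normalized = isinstance(data, NormalizedMatrix)
    r = K - 1 if normalized else K
    emb = pca_embed(data.values, r)
    emb.source = "W" if normalized else "X"
    labels = kmeans_cluster(emb, K, restarts=restarts, seed=seed)
    return ClusterResult(
        labels=labels,
        method="pca",
        variant="W" if normalized else "X",
        embedding=emb,
        seed=seed,
    )


def _if_step(
    X: ExpressionMatrix, K: int, min_retained: int | None = None
) -> tuple[NormalizedMatrix, SelectionResult]:
    W = normalize_columns(X)
    floor = max(K - 1, 1) if min_retained is None else min_retained
    sel = select_features(W, min_retained=floor)
    return W, sel

def post_selection_matrix(
    X: ExpressionMatrix,
    W: NormalizedMatrix,
    sel: SelectionResult,
    variant: str,
) -> np.ndarray:
    """Columns retained by the IF step, taken from W or from the raw X.

    Selection indices refer to W's columns; for variant "X" they are
    mapped back through any zero-variance columns W dropped.
    """
    if variant == "W":
        return W.values[:, sel.retained]
    if variant == "X":
        kept = np.delete(np.arange(X.n_features), W.dropped_features)
        return X.values[:, kept[sel.retained]]
    raise ValueError(f"unknown variant {variant!r}")


def if_pca(
    X: ExpressionMatrix,
    K: int,
    variant: str = "W",
    seed: int = 0,
    restarts: int = 30,
    n_components: int | None = None,
) -> ClusterResult:
    """IF-PCA: IF step on W, then k-means on the leading left singular
    vectors of the post-selection matrix (W^IF or X^IF).

    Both variants use K-1 singular vectors of the post-selection matrix by
    default (``n_components`` overrides, e.g. K for the raw-matrix variant).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    W, sel = _if_step(X, K)
    sub = post_selection_matrix(X, W, sel, variant)
    r = min(K - 1 if n_components is None else n_components, min(sub.shape))
    emb = pca_embed(sub, r)
    emb.source = f"{variant}_IF"
    labels = kmeans_cluster(emb, K, restarts=restarts, seed=seed)
    return ClusterResult(
        labels=labels,
        method="if_pca",
        variant=variant,
        embedding=emb,
        seed=seed,
        selection=sel,
    )
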