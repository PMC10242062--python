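"""Expression-matrix I/O, column normalization, low-expression filtering,
and the planted-mean synthetic data generator.

The in-memory convention throughout the package is rows = subjects (samples,
cells), columns = features (genes).  Single-cell matrices shipped gene-by-cell
are handled with an explicit ``orientation`` flag; there is no auto-detection.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class MatrixFormatError(ValueError):
    """Malformed input file (header, triplet indices, sidecars...)."""


class MatrixValidationError(ValueError):
    """Structurally valid file with invalid content (NaN/inf, dup ids...)."""


class DimensionError(ValueError):
    """Id counts or declared dimensions do not match the data."""


class DegenerateColumnError(ValueError):
    """A constant column where the caller demanded an error."""


@dataclass
class ExpressionMatrix:
    """An n x p expression matrix with subject and feature identifiers.

    ``values`` holds raw expression or log-counts, one row per subject.
    All entries must be finite; identifiers must be unique along each axis.
    """

    values: np.ndarray
    subject_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, p = self.shape
        if len(self.subject_ids) != n:
            raise DimensionError(
                f"{len(self.subject_ids)} subject ids for {n} rows"
            )
        if len(self.feature_ids) != p:
            raise DimensionError(
                f"{len(self.feature_ids)} feature ids for {p} columns"
            )
        if len(set(self.subject_ids)) != n:
            raise MatrixValidationError("duplicate subject ids")
        if len(set(self.feature_ids)) != p:
            raise MatrixValidationError("duplicate feature ids")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixValidationError(
                f"non-finite entry at row {bad[0]}, column {bad[1]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.subject_ids),
            [self.feature_ids[j] for j in idx],
        )


@dataclass
class NormalizedMatrix:
    """Column-standardized matrix W: each retained column has mean 0, sd 1.

    ``dropped_features`` records indices (into the source matrix) of
    zero-variance columns removed during normalization; ``feature_ids``
    are those of the retained columns, ``source`` the provenance matrix.
    """

    values: np.ndarray
    feature_ids: list[str]
    subject_ids: list[str]
    dropped_features: list[int] = field(default_factory=list)
    source: ExpressionMatrix | None = None
    ddof: int = 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PlantedDesign:
    """Ground truth of a planted K-class mean model.

    ``membership`` is the n x K one-hot matrix Pi, ``class_means`` the p x K
    matrix M = [mu_1, ..., mu_K]; the signal matrix is E[X] = Pi M'.
    Class-mean contrasts mu_k - mu_bar are supported on ``support`` only.
    """

    K: int
    membership: np.ndarray
    class_means: np.ndarray
    noise_sd: float
    support: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.membership)
        if not (
            np.all((pi == 0) | (pi == 1)) and np.all(pi.sum(axis=1) == 1)
        ):
            raise MatrixValidationError("membership rows must be one-hot")


def _read_dense(path: str) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise MatrixFormatError(f"{path}: empty header line 1")
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MatrixFormatError(f"{path}: {exc}") from exc
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric entry ({exc})") from exc
    return ExpressionMatrix(
        values, [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def _read_sidecar(path: str) -> list[str]:
    with open(path) as fh:
        # 10x-style sidecars may carry extra tab-separated columns; the
        # first column is the identifier.
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _read_mtx(path: str, orientation: str) -> ExpressionMatrix:
    base = os.path.dirname(os.path.abspath(path))
    feat_path = os.path.join(base, "features.tsv")
    if not os.path.exists(feat_path):
        feat_path = os.path.join(base, "genes.tsv")
    bc_path = os.path.join(base, "barcodes.tsv")
    for req in (feat_path, bc_path):
        if not os.path.exists(req):
            raise MatrixFormatError(
                f"missing sidecar {os.path.basename(req)} next to {path}"
            )
    try:
        m = spio.mmread(path)
    except ValueError as exc:
        msg = str(exc).lower()
        if "exceed" in msg or "dimension" in msg or "out of range" in msg:
            raise DimensionError(f"{path}: {exc}") from exc
        raise MatrixFormatError(f"{path}: {exc}") from exc
    except Exception as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc
    arr = sparse.coo_matrix(m).toarray()
    features = _read_sidecar(feat_path)
    barcodes = _read_sidecar(bc_path)
    # The orientation flag describes the on-disk grid; features.tsv always
    # lists features and barcodes.tsv subjects, on whichever axis each lies.
    if orientation == "features_by_subjects":
        row_ids, col_ids = features, barcodes
    else:
        row_ids, col_ids = barcodes, features
    if arr.shape[0] != len(row_ids):
        raise DimensionError(
            f"{arr.shape[0]} matrix rows but {len(row_ids)} sidecar entries"
        )
    if arr.shape[1] != len(col_ids):
        raise DimensionError(
            f"{arr.shape[1]} matrix columns but {len(col_ids)} sidecar entries"
        )
    if orientation == "features_by_subjects":
        return ExpressionMatrix(arr.T, barcodes, features)
    return ExpressionMatrix(arr, barcodes, features)


def read_matrix(
    path: str,
    format: str = "dense",
    orientation: str = "subjects_by_features",
) -> ExpressionMatrix:
    """Read an expression matrix from ``dense`` delimited text or ``mtx``.

    Dense text: first row feature ids, first column subject ids, tab or
    comma separated (auto-detected from the header line).  MatrixMarket
    input expects ``features.tsv`` (or ``genes.tsv``) and ``barcodes.tsv``
    sidecars next to the ``.mtx`` file; raw 10x-style gene-by-cell deposits
    should be read with ``orientation="features_by_subjects"``.

    ``orientation`` states how the file on disk is laid out; the returned
    matrix is always subjects-by-features.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if orientation not in ("subjects_by_features", "features_by_subjects"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if format == "dense":
        mat = _read_dense(path)
        if orientation == "features_by_subjects":
            mat = ExpressionMatrix(
                mat.values.T, mat.feature_ids, mat.subject_ids
            )
        return mat
    if format == "mtx":
        return _read_mtx(path, orientation)
    raise ValueError(f"unknown format {format!r}")


def write_matrix(X: ExpressionMatrix, path: str, format: str = "dense") -> str:
    """Write a matrix so that :func:`read_matrix` round-trips it.

    Dense output is TSV with feature ids as header and subject ids as the
    first column.  ``mtx`` output writes the matrix features-by-subjects
    with ``features.tsv``/``barcodes.tsv`` sidecars (read back with
    ``orientation="features_by_subjects"``).
    """
    if X.n_subjects == 0 or X.n_features == 0:
        raise MatrixValidationError("refusing to write an empty matrix")
    if format == "dense":
        df = pd.DataFrame(X.values, index=X.subject_ids, columns=X.feature_ids)
        df.to_csv(path, sep="\t", float_format="%.12g")
    elif format == "mtx":
        base = os.path.dirname(os.path.abspath(path))
        spio.mmwrite(path, sparse.coo_matrix(X.values.T))
        with open(os.path.join(base, "features.tsv"), "w") as fh:
            fh.write("\n".join(X.feature_ids) + "\n")
        with open(os.path.join(base, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(X.subject_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def normalize_columns(
    X: ExpressionMatrix, zero_variance: str = "drop", ddof: int = 1
) -> NormalizedMatrix:
    """Standardize every column to empirical mean 0 and sd 1.

    ``ddof=1`` (sample sd) is the default; ``ddof=0`` gives the population
    convention — the choice only rescales columns uniformly.  Zero-variance
    columns are dropped and recorded, or raise, per ``zero_variance``.
    """
    n = X.n_subjects
    if n < 2:
        raise MatrixValidationError("need at least 2 subjects to normalize")
    vals = X.values
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=ddof)
    constant = sd == 0
    if np.any(constant):
        if zero_variance == "error":
            j = int(np.argmax(constant))
            raise DegenerateColumnError(
                f"feature {X.feature_ids[j]!r} (column {j}) is constant"
            )
        if zero_variance != "drop":
            raise ValueError(f"unknown zero_variance policy {zero_variance!r}")
    keep = ~constant
    W = (vals[:, keep] - mean[keep]) / sd[keep]
    return NormalizedMatrix(
        values=W,
        feature_ids=[f for f, k in zip(X.feature_ids, keep) if k],
        subject_ids=list(X.subject_ids),
        dropped_features=list(np.flatnonzero(constant)),
        source=X,
        ddof=ddof,
    )


def filter_low_nonzero(
    X: ExpressionMatrix, min_frac: float = 0.05
) -> ExpressionMatrix:
    """Drop features whose fraction of nonzero entries is strictly below
    ``min_frac`` (the single-cell low-expression gene filter)."""
    if not 0 <= min_frac <= 1:
        raise ValueError("min_frac must lie in [0, 1]")
    frac = (X.values != 0).mean(axis=0)
    keep = np.flatnonzero(frac >= min_frac)
    if keep.size == 0:
        raise MatrixValidationError(
            "low-expression filter removed every feature; lower min_frac"
        )
    return X.subset_features(keep)


def _planted_class_means(
    p: int, K: int, n_useful: int, effect_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Class-mean matrix M (p x K) for the planted model.

    Support features share a common baseline of ``effect_size`` (so the
    signal matrix has rank K, not K-1) and carry class contrasts assigned
    round-robin: feature j in group g has contrast +effect_size for class g
    and -effect_size/(K-1) for the others.  Contrast patterns of distinct
    groups are linearly independent, hence so are mu_1..mu_K.
    """
    support = np.arange(n_useful)
    M = np.zeros((p, K))
    base = effect_size
    for rank, j in enumerate(support):
        g = rank % K
        M[j, :] = base - effect_size / (K - 1)
        M[j, g] = base + effect_size
    return M, support


def generate_planted_data(
    n: int,
    p: int,
    K: int,
    n_useful: int,
    effect_size: float,
    noise_sd: float,
    balance: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray, PlantedDesign]:
    """Simulate the K-class planted-mean model X = Pi M' + noise.

    Class labels are drawn i.i.d. from ``balance`` (uniform by default);
    only ``n_useful`` shared features carry class-mean contrasts, of
    magnitude ``effect_size``; the noise is i.i.d. Gaussian with sd
    ``noise_sd``.  Returns the matrix, 1-based true labels, and the design.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise DimensionError(f"cannot plant {K} classes among {n} subjects")
    if n_useful > p:
        raise DimensionError("n_useful exceeds p")
    if n_useful < K:
        raise DimensionError("need n_useful >= K for independent class means")
    if balance is None:
        balance = np.full(K, 1.0 / K)
    balance = np.asarray(balance, dtype=float)
    if balance.shape != (K,) or not np.isclose(balance.sum(), 1.0):
        raise ValueError("balance must be a length-K probability vector")
    rng = np.random.default_rng(seed)
    labels = rng.choice(K, size=n, p=balance) + 1
    Pi = np.zeros((n, K))
    Pi[np.arange(n), labels - 1] = 1.0
    M, support = _planted_class_means(p, K, n_useful, effect_size)
    X = Pi @ M.T
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=(n, p))
    mat = ExpressionMatrix(
        X,
        [f"subject_{i}" for i in range(n)],
        [f"feature_{j}" for j in range(p)],
    )
    design = PlantedDesign(
        K=K, membership=Pi, class_means=M, noise_sd=noise_sd, support=support
    )
    return mat, labels, design


def read_labels(path: str) -> np.ndarray:
    """Read a label file: one label per line, aligned to subject order."""
    with open(path) as fh:
        raw = [line.strip() for line in fh if line.strip()]
    try:
        return np.array([int(x) for x in raw])
    except ValueError:
        # non-integer labels: map to 1..K in order of first appearance
        seen: dict[str, int] = {}
        return np.array([seen.setdefault(x, len(seen) + 1) for x in raw])


def write_labels(labels: np.ndarray, subject_ids: list[str], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("subject_id\tlabel\n")
        for sid, lab in zip(subject_ids, labels):
            fh.write(f"{sid}\t{int(lab)}\n")
    return path
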