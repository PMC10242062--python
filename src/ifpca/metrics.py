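"""Clustering evaluation: permutation-minimized errors, accuracy, ARI, and
rank/regret aggregation across data sets.

A predicted partition is only defined up to relabeling of the clusters, so
the clustering error counts mismatches minimized over all permutations of
cluster identities (solved exactly by optimal assignment).  To compare
methods across data sets, each data set's method errors are converted to
midranks (ties share the average rank, so every row's ranks sum to
m(m+1)/2) and to regrets r = (e - e_min) / (e_max - e_min); the per-method
means of these summarize overall performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score


@dataclass
class ErrorTable:
    """Data sets x methods table of clustering errors or accuracies."""

    values: pd.DataFrame
    value_kind: str = "errors"  # or "accuracy"

    def __post_init__(self) -> None:
        if self.value_kind not in ("errors", "accuracy"):
            raise ValueError("value_kind must be 'errors' or 'accuracy'")


def _check_labels(Y_hat, Y) -> tuple[np.ndarray, np.ndarray]:
    Y_hat = np.asarray(Y_hat, dtype=int)
    Y = np.asarray(Y, dtype=int)
    if Y_hat.shape != Y.shape or Y_hat.ndim != 1:
        raise ValueError("label vectors must be 1-d and of equal length")
    if Y_hat.min() < 1 or Y.min() < 1:
        raise ValueError("labels must be positive integers 1..K")
    return Y_hat, Y


def clustering_error(Y_hat, Y) -> int:
    """Minimum mismatch count over permutations of cluster identities."""
    Y_hat, Y = _check_labels(Y_hat, Y)
    K = int(max(Y_hat.max(), Y.max()))
    cont = np.zeros((K, K), dtype=int)
    np.add.at(cont, (Y_hat - 1, Y - 1), 1)
    row, col = linear_sum_assignment(-cont)
    return int(len(Y) - cont[row, col].sum())


def accuracy(Y_hat, Y) -> float:
    """Fraction of correctly clustered subjects: 1 - error / n."""
    Y_hat, Y = _check_labels(Y_hat, Y)
    return 1.0 - clustering_error(Y_hat, Y) / len(Y)


def adjusted_rand_index(Y_hat, Y) -> float:
    """Chance-corrected Rand index of the two partitions."""
    Y_hat = np.asarray(Y_hat)
    Y = np.asarray(Y)
    if Y_hat.shape != Y.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(Y, Y_hat))


def rank_with_ties(values, direction: str = "lower_better") -> np.ndarray:
    """Midranks of m method scores; tied values share the average rank, so
    the ranks always sum to m(m+1)/2."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 methods to rank")
    if direction == "lower_better":
        return rankdata(values, method="average")
    if direction == "higher_better":
        return rankdata(-values, method="average")
    raise ValueError(f"unknown direction {direction!r}")


def regret(values, direction: str = "lower_better") -> np.ndarray:
    """(e - e_min)/(e_max - e_min) per method: 0 for the best, 1 for the
    worst; an all-equal row gives all zeros by convention."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 methods")
    if direction == "higher_better":
        values = -values
    elif direction != "lower_better":
        raise ValueError(f"unknown direction {direction!r}")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def summarize(
    table: ErrorTable,
    exclude: list[str] | None = None,
    ddof: int = 1,
) -> pd.DataFrame:
    """Per-method mean/SD of midranks and regrets over the table rows.

    Methods in ``exclude`` are dropped before ranking.  A missing (NaN)
    cell for an included method raises — partially observed methods must be
    excluded explicitly, mirroring how a method with an NA result is left
    out of a published comparison.
    """
    df = table.values.copy()
    if exclude:
        df = df.drop(columns=list(exclude))
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(
            f"missing cells for included methods {bad}; exclude them"
        )
    direction = "lower_better" if table.value_kind == "errors" else "higher_better"
    ranks = df.apply(
        lambda row: pd.Series(
            rank_with_ties(row.to_numpy(), direction), index=row.index
        ),
        axis=1,
    )
    regrets = df.apply(
        lambda row: pd.Series(
            regret(row.to_numpy(), direction), index=row.index
        ),
        axis=1,
    )
    return pd.DataFrame(
        {
            "rank_mean": ranks.mean(),
            "rank_sd": ranks.std(ddof=ddof),
            "regret_mean": regrets.mean(),
            "regret_sd": regrets.std(ddof=ddof),
        }
    )
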