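"""Rare/weak two-class simulation lab and phase-transition diagnostics.

The model: labels Y_i i.i.d. uniform on {-1, +1}; a contrast mean vector mu
whose entries are 0 with probability 1 - eps and +-tau with probability
eps/2 each; data X = Y mu' + Z with standard-normal noise.  The asymptotic
calibration ties everything to a single dimension p:

    n = round(p^theta),  eps = p^(-beta),  tau = p^(-alpha),  s_p = p * eps,

so beta indexes signal rarity and alpha signal weakness.  The simplified
clustering procedures studied on this model skip normalization, Efron's
correction and the HC threshold: features are screened by the chi-square
score psi_j = (||x_j||^2 - n) / sqrt(2n) against the fixed threshold
sqrt(2 log p), and subjects are clustered by the sign of the first left
singular vector.  The critical signal strength tau_p* and its exponent
alpha*(beta, theta) delimit where polynomial-time clustering can succeed;
the phase grid renders the transition empirically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RareWeakParams:
    """Calibration (p, theta, beta, alpha) with derived (n, eps, tau, s_p)."""

    p: int
    theta: float
    beta: float
    alpha: float

    def __post_init__(self) -> None:
        if not (0 < self.theta < 1 and 0 < self.beta < 1):
            raise ValueError("theta and beta must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def n(self) -> int:
        return int(round(self.p ** self.theta))

    @property
    def eps(self) -> float:
        return self.p ** (-self.beta)

    @property
    def tau(self) -> float:
        return self.p ** (-self.alpha)

    @property
    def s_p(self) -> float:
        return self.p * self.eps


@dataclass
class RareWeakInstance:
    params: RareWeakParams
    Y: np.ndarray
    mu: np.ndarray
    support: np.ndarray = field(default=None)
    X: np.ndarray = field(default=None)
    seed: int = 0


def simulate(params: RareWeakParams, seed: int = 0) -> RareWeakInstance:
    """Draw one instance of the rare/weak model, reproducibly per seed."""
    n = params.n
    if n < 2:
        raise ValueError(f"p^theta rounds to n={n} < 2; infeasible design")
    rng = np.random.default_rng(seed)
    Y = rng.choice([-1.0, 1.0], size=n)
    u = rng.random(params.p)
    mu = np.zeros(params.p)
    signal = u < params.eps
    signs = rng.choice([-1.0, 1.0], size=int(signal.sum()))
    mu[signal] = signs * params.tau
    X = np.outer(Y, mu) + rng.standard_normal((n, params.p))
    return RareWeakInstance(
        params=params,
        Y=Y,
        mu=mu,
        support=np.flatnonzero(signal),
        X=X,
        seed=seed,
    )


def chi2_scores(X: np.ndarray) -> np.ndarray:
    """Normalized chi-square screening scores (||x_j||^2 - n) / sqrt(2n);
    approximately N(0,1) for a null feature, mean sqrt(n/2) tau^2 for a
    useful one."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    return ((X**2).sum(axis=0) - n) / np.sqrt(2.0 * n)


def _first_left_singular_vector(X: np.ndarray) -> np.ndarray:
    n, m = X.shape
    if min(n, m) < 10:
        u = np.linalg.svd(X, full_matrices=False)[0][:, 0]
    elif n <= m:  # leading eigenvector of the smaller Gram matrix
        u = np.linalg.eigh(X @ X.T)[1][:, -1]
    else:
        v = np.linalg.eigh(X.T @ X)[1][:, -1]
        u = X @ v
        u /= np.linalg.norm(u)
    if u[np.argmax(np.abs(u))] < 0:  # deterministic sign convention
        u = -u
    return u


def simple_pca_cluster(X: np.ndarray) -> np.ndarray:
    """Cluster by the sign of the first left singular vector (sign(0) -> +1)."""
    xi = _first_left_singular_vector(np.asarray(X, dtype=float))
    labels = np.where(xi >= 0, 1.0, -1.0)
    return labels


def simple_ifpca_cluster(
    X: np.ndarray, threshold: float | None = None
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Chi-square screening at ``sqrt(2 log p)`` then sign clustering on the
    selected columns.

    Returns (selected indices, labels, fallback flag); an empty selection
    falls back to full-matrix PCA clustering.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need p >= 2 features")
    if threshold is None:
        threshold = np.sqrt(2.0 * np.log(p))
    psi = chi2_scores(X)
    S_hat = np.flatnonzero(psi >= threshold)
    if S_hat.size == 0:
        return S_hat, simple_pca_cluster(X), True
    return S_hat, simple_pca_cluster(X[:, S_hat]), False


def hamming_error(Y_hat: np.ndarray, Y: np.ndarray) -> float:
    """Empirical two-class Hamming error rate: the mismatch fraction
    minimized over the global sign flip; lies in [0, 1/2]."""
    Y_hat = np.asarray(Y_hat)
    Y = np.asarray(Y)
    if Y_hat.shape != Y.shape:
        raise ValueError("label vectors must have equal length")
    if not (set(np.unique(Y_hat)) <= {-1, 1} and set(np.unique(Y)) <= {-1, 1}):
        raise ValueError("labels must be in {-1, +1}")
    mis = float(np.mean(Y_hat != Y))
    return min(mis, 1.0 - mis)


def critical_tau(params: RareWeakParams) -> float:
    """Critical signal strength tau_p*: below it (in order of magnitude) no
    polynomial-time procedure can cluster better than chance.

        (p / (n s_p^2))^(1/4)   if beta < 1/2        (s_p >> sqrt(p))
        n^(-1/4)                if 1/2 < beta < 1 - theta/2
        s_p^(-1/2)              if beta > 1 - theta/2 (s_p << sqrt(n))

    Boundary betas take the shared limiting value (the pieces are
    continuous there).
    """
    n, s_p, p = params.n, params.s_p, params.p
    if params.beta <= 0.5:
        return float((p / (n * s_p**2)) ** 0.25)
    if params.beta <= 1.0 - params.theta / 2.0:
        return float(n ** -0.25)
    return float(s_p ** -0.5)


def alpha_star(beta: float, theta: float) -> float:
    """Exponent of the critical strength: tau_p* = p^(-alpha*(beta, theta)).

    Piecewise in beta: (1 + theta - 2 beta)/4 below 1/2, theta/4 in the
    middle band, (1 - beta)/2 above 1 - theta/2; continuous at both joins.
    """
    if not (0 < beta < 1 and 0 < theta < 1):
        raise ValueError("beta and theta must lie in (0, 1)")
    if beta <= 0.5:
        return (1.0 + theta - 2.0 * beta) / 4.0
    if beta <= 1.0 - theta / 2.0:
        return theta / 4.0
    return (1.0 - beta) / 2.0


def eigvec_deviation(instance: RareWeakInstance) -> float:
    """Entrywise deviation of the scaled first left singular vector from the
    label vector: min over the sign flip of ||sqrt(n) xi -+ Y||_inf.

    Small values certify that sign clustering recovers Y exactly.
    """
    xi = _first_left_singular_vector(instance.X)
    scaled = np.sqrt(len(instance.Y)) * xi
    return float(
        min(
            np.max(np.abs(scaled - instance.Y)),
            np.max(np.abs(scaled + instance.Y)),
        )
    )


def phase_grid(
    theta: float,
    p: int,
    beta_grid,
    alpha_grid,
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean (+- SE) Hamming error of simple PCA and simple IF-PCA over a
    (beta, alpha) grid; one substream per cell so results are reproducible
    under any execution order."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    for ci, beta in enumerate(beta_grid):
        for cj, alpha in enumerate(alpha_grid):
            params = RareWeakParams(p=p, theta=theta, beta=beta, alpha=alpha)
            cell_seed = np.random.SeedSequence(
                entropy=seed, spawn_key=(ci, cj)
            )
            child_seeds = cell_seed.generate_state(reps)
            errs = {"simple_pca": [], "simple_ifpca": []}
            for r in range(reps):
                inst = simulate(params, seed=int(child_seeds[r] % 2**31))
                errs["simple_pca"].append(
                    hamming_error(simple_pca_cluster(inst.X), inst.Y)
                )
                _, labels, _ = simple_ifpca_cluster(inst.X)
                errs["simple_ifpca"].append(hamming_error(labels, inst.Y))
            for method, e in errs.items():
                e = np.asarray(e)
                rows.append(
                    {
                        "beta": beta,
                        "alpha": alpha,
                        "method": method,
                        "mean_error": float(e.mean()),
                        "se": float(e.std(ddof=1) / np.sqrt(reps))
                        if reps > 1
                        else float("nan"),
                        "reps": reps,
                    }
                )
    return pd.DataFrame(rows)
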