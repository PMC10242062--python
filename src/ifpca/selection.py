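"""The influential-feature (IF) selection step.

For each standardized feature w_j the Kolmogorov-Smirnov statistic
``phi_n(w_j) = sqrt(n) * sup_t |F_n(t) - F(t)|`` measures departure of the
studentized within-column empirical distribution from the null reference F.
Because genomic columns are correlated and the theoretical null is only
approximate, the scores are re-standardized by their own empirical mean and
sd (Efron's empirical-null correction) before conversion to p-values
``pi_j = 1 - F(psi*_j)``.  A higher-criticism threshold (HCT) turns the
sorted p-values into a data-driven selection threshold:

    HC_{p,j} = sqrt(p) (j/p - pi_(j)) / sqrt(max(sqrt(n)(j/p - pi_(j)), 0) + j/p)

maximized over { j : pi_(j) > log(p)/p, j < p/2 }; features with
pi_j <= pi_(j_hat) are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class DegenerateInputError(ValueError):
    pass


_EPS = 1e-15  # clamp for p-values so the HC functional stays finite


@dataclass
class KSScores:
    """Per-feature KS scores with their Efron standardization."""

    phi: np.ndarray
    mu_star: float
    sigma_star: float
    psi_star: np.ndarray
    pvalues: np.ndarray


@dataclass
class SelectionResult:
    """Outcome of the HCT selection step.

    ``retained`` lists (sorted) indices j with pi_j <= t_hc; if a
    ``min_retained`` floor forced extra features in, ``augmented`` flags it
    and ``retained`` includes them.  ``fallback_used`` marks an empty
    admissible set in the HC maximization.
    """

    hc_curve: np.ndarray
    j_hat: int
    t_hc: float
    retained: np.ndarray
    fallback_used: bool = False
    augmented: bool = False
    scores: KSScores | None = None
    feature_ids: list[str] | None = None

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_tsv(self, path: str) -> str:
        """feature_id, phi, psi_star, pvalue, retained — plus JSON sidecar."""
        ids = self.feature_ids or [
            f"feature_{j}" for j in range(len(self.scores.phi))
        ]
        keep = np.zeros(len(ids), dtype=int)
        keep[self.retained] = 1
        with open(path, "w") as fh:
            fh.write("feature_id\tphi\tpsi_star\tpvalue\tretained\n")
            for j, fid in enumerate(ids):
                fh.write(
                    f"{fid}\t{self.scores.phi[j]:.10g}"
                    f"\t{self.scores.psi_star[j]:.10g}"
                    f"\t{self.scores.pvalues[j]:.10g}\t{keep[j]}\n"
                )
        with open(path + ".json", "w") as fh:
            json.dump(
                {
                    "j_hat": int(self.j_hat),
                    "t_hc": float(self.t_hc),
                    "n_retained": int(self.n_retained),
                    "fallback_used": bool(self.fallback_used),
                    "augmented": bool(self.augmented),
                },
                fh,
                indent=2,
            )
        return path


def ks_statistic(z: np.ndarray, cdf=None) -> float:
    """sqrt(n) times the sup-distance between the empirical CDF of the
    studentized values (z_i - mean)/sd and the reference CDF.

    The supremum over t is attained at an order statistic, so it equals
    ``max_i max(i/n - F(u_(i)), F(u_(i)) - (i-1)/n)`` exactly.  The
    reference F defaults to the standard normal CDF (the studentization
    effect is absorbed downstream by Efron's correction).
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < 3:
        raise DegenerateInputError("need n >= 3 observations")
    sd = z.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant input has no KS score")
    u = np.sort((z - z.mean()) / sd)
    F = stats.norm.cdf(u) if cdf is None else cdf(u)
    i = np.arange(1, n + 1)
    gaps = np.maximum(i / n - F, F - (i - 1) / n)
    return float(np.sqrt(n) * gaps.max())


def efron_standardize(phi: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize scores by their own empirical mean and sd (sample sd)."""
    phi = np.asarray(phi, dtype=float)
    if phi.size < 2:
        raise DegenerateInputError("need at least 2 scores")
    mu = float(phi.mean())
    sigma = float(phi.std(ddof=1))
    if sigma == 0:
        raise DegenerateInputError("scores have zero spread")
    return (phi - mu) / sigma, mu, sigma


def ks_pvalues(psi_star: np.ndarray) -> np.ndarray:
    """Upper-tail standard-normal p-values, clamped into (0, 1)."""
    psi_star = np.asarray(psi_star, dtype=float)
    if not np.all(np.isfinite(psi_star)):
        raise DegenerateInputError("non-finite standardized scores")
    return np.clip(stats.norm.sf(psi_star), _EPS, 1 - _EPS)


def ks_null_scores(
    n: int, reps: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo null distribution of the studentized-normal KS score.

    Simulates ``reps`` i.i.d. N(0,1) samples of size n and returns their
    KS scores; used to validate the standard-normal reference-CDF
    approximation (not in the default pipeline).
    """
    rng = np.random.default_rng(seed)
    return np.array(
        [ks_statistic(rng.standard_normal(n)) for _ in range(reps)]
    )


def hc_curve(sorted_pvalues: np.ndarray, n: int) -> np.ndarray:
    """HC_{p,j} over the ascending p-values."""
    p = sorted_pvalues.size
    j = np.arange(1, p + 1)
    gap = j / p - sorted_pvalues
    denom = np.sqrt(np.maximum(np.sqrt(n) * gap, 0.0) + j / p)
    return np.sqrt(p) * gap / denom


def hc_threshold(pvalues: np.ndarray, n: int) -> SelectionResult:
    """Higher-criticism threshold over marginal p-values.

    The maximizer j_hat is searched over { j : pi_(j) > log(p)/p, j < p/2 }
    (ties to the smallest j); if that set is empty the search falls back to
    { j : j < p/2 } and ``fallback_used`` is set.  ``retained`` holds the
    original indices with pi_j <= t_hc.
    """
    pvalues = np.clip(np.asarray(pvalues, dtype=float), _EPS, 1 - _EPS)
    p = pvalues.size
    if p < 4:
        raise DegenerateInputError("need at least 4 p-values for HCT")
    order = np.argsort(pvalues, kind="stable")
    srt = pvalues[order]
    curve = hc_curve(srt, n)
    j = np.arange(1, p + 1)
    below_half = j < p / 2
    admissible = below_half & (srt > np.log(p) / p)
    fallback = not admissible.any()
    search = below_half if fallback else admissible
    cand = np.flatnonzero(search)
    j_hat = int(cand[np.argmax(curve[cand])]) + 1  # argmax ties -> smallest j
    t_hc = float(srt[j_hat - 1])
    retained = np.flatnonzero(pvalues <= t_hc)
    return SelectionResult(
        hc_curve=curve,
        j_hat=j_hat,
        t_hc=t_hc,
        retained=retained,
        fallback_used=fallback,
    )


def select_features(W, min_retained: int = 1) -> SelectionResult:
    """Full IF step on a normalized matrix: KS scores per column, Efron
    standardization, normal p-values, HCT selection.

    If fewer than ``min_retained`` features survive, the smallest-p-value
    features are added up to the floor and ``augmented`` is flagged (the
    floor keeps the downstream K-1-dimensional SVD well-posed).
    """
    values = W.values if hasattr(W, "values") else np.asarray(W, dtype=float)
    n, p = values.shape
    if min_retained < 1:
        raise ValueError("min_retained must be >= 1")
    phi = np.array([ks_statistic(values[:, j]) for j in range(p)])
    psi_star, mu_star, sigma_star = efron_standardize(phi)
    pvals = ks_pvalues(psi_star)
    result = hc_threshold(pvals, n)
    result.scores = KSScores(
        phi=phi,
        mu_star=mu_star,
        sigma_star=sigma_star,
        psi_star=psi_star,
        pvalues=pvals,
    )
    result.feature_ids = list(getattr(W, "feature_ids", [])) or None
    if result.n_retained < min_retained:
        best = np.argsort(pvals, kind="stable")[:min_retained]
        result.retained = np.union1d(result.retained, best)
        result.augmented = True
    return result
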