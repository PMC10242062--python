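"""Variational-autoencoder embedding clustering, and IF-VAE / IF-VAE(X).

The VAE here is deliberately minimal, matching the architecture used for
the expression-data experiments: a one-hidden-layer ReLU encoder producing
a Gaussian latent mean/log-variance (latent dimension d, default 25), a
one-hidden-layer decoder with sigmoid output, inputs min-max scaled to
[0, 1] per feature, and a Bernoulli (binary cross-entropy) reconstruction
term plus the KL divergence to a standard-normal prior.  Training is plain
minibatch SGD (50 minibatches per epoch, 100 epochs, learning rate 5e-4 by
default).  It is implemented directly in numpy with manual backpropagation,
which keeps it dependency-free, bitwise reproducible for a fixed seed, and
fast enough at the matrix sizes this package targets.

Clustering applies k-means to the rows of the encoder-mean matrix Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix
from .spectral import ClusterResult, Embedding, _if_step, kmeans_cluster, \
    post_selection_matrix


class TrainingDivergedError(RuntimeError):
    def __init__(self, msg: str, trace: list[float]):
        super().__init__(msg)
        self.trace = trace


@dataclass
class VAEConfig:
    """Training settings; defaults follow the reference experimental setup."""

    latent_dim: int = 25
    hidden_width: int = 128
    epochs: int = 100
    n_batches: int = 50
    learning_rate: float = 5e-4
    optimizer: str = "sgd"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.epochs < 1:
            raise ValueError("latent_dim and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


@dataclass
class LatentEmbedding:
    """Encoder means Z (n x d) with the per-epoch training-loss trace."""

    Z: np.ndarray
    training_loss_trace: list[float] = field(default_factory=list)
    config: VAEConfig | None = None


def _minmax_scale(M: np.ndarray) -> np.ndarray:
    lo = M.min(axis=0)
    rng = M.max(axis=0) - lo
    rng[rng == 0] = 1.0  # constant features map to 0
    return (M - lo) / rng


def _softplus(a: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, a)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


class _VAENet:
    """Weights and manual forward/backward pass."""

    def __init__(self, p: int, cfg: VAEConfig, rng: np.random.Generator):
        h, d = cfg.hidden_width, cfg.latent_dim

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        self.W1, self.b1 = glorot(p, h), np.zeros(h)
        self.Wm, self.bm = glorot(h, d), np.zeros(d)
        self.Wv, self.bv = glorot(h, d), np.zeros(d)
        self.W2, self.b2 = glorot(d, h), np.zeros(h)
        self.W3, self.b3 = glorot(h, p), np.zeros(p)
        self._adam_state = None

    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        return h1, h1 @ self.Wm + self.bm, h1 @ self.Wv + self.bv

    def step(self, X: np.ndarray, lr: float, rng: np.random.Generator) -> float:
        """One SGD step on a minibatch; returns the minibatch loss
        (mean per-sample negative ELBO)."""
        B = X.shape[0]
        h1, mu, logvar = self.encode(X)
        logvar = np.clip(logvar, -15.0, 15.0)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * logvar)
        z = mu + std * eps
        h2 = np.maximum(z @ self.W2 + self.b2, 0.0)
        a3 = h2 @ self.W3 + self.b3
        bce = float(np.sum(_softplus(a3) - X * a3) / B)
        kl = float(
            -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar)) / B
        )
        loss = bce + kl

        # backward
        dA3 = (_sigmoid(a3) - X) / B
        dW3 = h2.T @ dA3
        db3 = dA3.sum(axis=0)
        dh2 = dA3 @ self.W3.T
        dh2[h2 <= 0] = 0.0
        dW2 = z.T @ dh2
        db2 = dh2.sum(axis=0)
        dz = dh2 @ self.W2.T
        dmu = dz + mu / B
        dlv = dz * eps * 0.5 * std + 0.5 * (np.exp(logvar) - 1.0) / B
        dWm = h1.T @ dmu
        dbm = dmu.sum(axis=0)
        dWv = h1.T @ dlv
        dbv = dlv.sum(axis=0)
        dh1 = dmu @ self.Wm.T + dlv @ self.Wv.T
        dh1[h1 <= 0] = 0.0
        dW1 = X.T @ dh1
        db1 = dh1.sum(axis=0)

        for w, g in (
            (self.W1, dW1), (self.b1, db1), (self.Wm, dWm), (self.bm, dbm),
            (self.Wv, dWv), (self.bv, dbv), (self.W2, dW2), (self.b2, db2),
            (self.W3, dW3), (self.b3, db3),
        ):
            w -= lr * g
        return loss


def train_vae(M: np.ndarray, config: VAEConfig | None = None) -> LatentEmbedding:
    """Train the VAE on an n x p matrix and return the encoder means.

    Inputs are min-max scaled to [0, 1] per feature.  Each epoch draws
    ``n_batches`` shuffled minibatches of size ceil(n / n_batches).
    Reproducible bitwise for a fixed config seed.
    """
    cfg = config or VAEConfig()
    values = M.values if hasattr(M, "values") else np.asarray(M, dtype=float)
    X = _minmax_scale(values)
    n, p = X.shape
    rng = np.random.default_rng(cfg.seed)
    net = _VAENet(p, cfg, rng)
    batch = max(1, int(np.ceil(n / cfg.n_batches)))
    trace: list[float] = []
    if cfg.optimizer == "adam":  # pragma: no cover - optional path
        raise NotImplementedError(
            "adam is reserved; the reference setup uses plain SGD"
        )
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = perm[start:start + batch]
            losses.append(net.step(X[idx], cfg.learning_rate, rng))
        epoch_loss = float(np.mean(losses))
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {len(trace) + 1}", trace
            )
        trace.append(epoch_loss)
    _, Z, _ = net.encode(X)
    return LatentEmbedding(Z=Z, training_loss_trace=trace, config=cfg)


def vae_cluster(
    M, K: int, config: VAEConfig | None = None
) -> ClusterResult:
    """VAE embedding then k-means on the rows of Z; labels in 1..K."""
    cfg = config or VAEConfig()
    emb = train_vae(M, cfg)
    labels = kmeans_cluster(emb.Z, K, seed=cfg.seed)
    return ClusterResult(
        labels=labels,
        method="vae",
        variant=None,
        embedding=Embedding(
            vectors=emb.Z, singular_values=np.array([]), source="Z"
        ),
        seed=cfg.seed,
    )


def if_vae(
    X: ExpressionMatrix,
    K: int,
    variant: str = "W",
    config: VAEConfig | None = None,
) -> ClusterResult:
    """IF-VAE: the same IF step as IF-PCA, then VAE + k-means on the
    post-selection matrix (W^IF for variant "W", X^IF for "X")."""
    if K < 2:
        raise ValueError("K must be >= 2")
    cfg = config or VAEConfig()
    W, sel = _if_step(X, K)
    sub = post_selection_matrix(X, W, sel, variant)
    emb = train_vae(sub, cfg)
    labels = kmeans_cluster(emb.Z, K, seed=cfg.seed)
    return ClusterResult(
        labels=labels,
        method="if_vae",
        variant=variant,
        embedding=Embedding(
            vectors=emb.Z, singular_values=np.array([]), source=f"Z_{variant}_IF"
        ),
        seed=cfg.seed,
        selection=sel,
    )
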