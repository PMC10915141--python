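"""Encoding models: how well do model features predict neural responses?

Two pipelines. The first, for trial-averaged population data, standardizes
and PCA-reduces the feature space (reference 300 components), fits linear
partial least squares from features to responses on a train split, and
scores the test-set Pearson correlation per neuron; the median over neurons
of a visual area is the area's predictivity. The second, for single-unit
spike counts with spatially laid-out features, fits a linear/nonlinear map
rate = softplus(w.x + b) by minimizing Poisson negative log-likelihood
(Adam) under three penalties on the weight map: L1 sparsity, squared
spatial-gradient smoothness, and channel-wise group sparsity (l2 within a
channel, l1 across channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA

__all__ = [
    "EncodingConfig",
    "RegularizationConfig",
    "PredictivityResult",
    "pls_predictivity",
    "poisson_regression_fit",
]


@dataclass(frozen=True)
class EncodingConfig:
    """Split and dimensionality settings for the encoding fits."""

    n_components: int = 300
    train_fraction: float = 0.8
    n_splits: int = 1
    seed: int = 0
    pls_components: int = 25  # latent dimension, capped at n_components
    max_iter: int = 2000  # Poisson optimizer iteration cap
    tol: float = 1e-6  # Poisson optimizer loss-change tolerance
    lr: float = 0.05  # Poisson optimizer Adam step size

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_components < 1:
            raise ValueError("n_components must be at least 1")


@dataclass(frozen=True)
class RegularizationConfig:
    """Penalty rates for the Poisson map fit (all nonnegative)."""

    l1_rate: float = 0.01
    smoothness_rate: float = 0.1
    group_rate: float = 0.001

    def __post_init__(self):
        if min(self.l1_rate, self.smoothness_rate, self.group_rate) < 0:
            raise ValueError("regularization rates must be nonnegative")


@dataclass
class PredictivityResult:
    """Per-neuron test-set Pearson correlations and their median."""

    per_neuron_r: np.ndarray
    median_r: float
    converged: bool = True
    notes: list = field(default_factory=list)


def _split_indices(n: int, train_fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return perm[:n_train], perm[n_train:]


def _per_neuron_pearson(pred: np.ndarray, actual: np.ndarray) -> np.ndarray:
    p = pred - pred.mean(axis=0)
    a = actual - actual.mean(axis=0)
    num = (p * a).sum(axis=0)
    den = np.sqrt((p**2).sum(axis=0) * (a**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.clip(r, -1.0, 1.0)


def pls_predictivity(activations, neural, cfg: EncodingConfig | None = None) -> PredictivityResult:
    """PCA + partial-least-squares encoding predictivity.

    `activations` (n_stimuli, n_features) and `neural` (n_stimuli,
    n_neurons) must share the stimulus axis. Features are standardized on
    the train split; n_components is capped at min(rank, train size) - 1
    with a logged note when the cap binds.
    """
    cfg = cfg or EncodingConfig()
    x = np.asarray(activations, dtype=float)
    x = x.reshape(x.shape[0], -1)
    y = np.atleast_2d(np.asarray(neural, dtype=float))
    if y.shape[0] != x.shape[0]:
        raise ValueError("activations and neural responses must share the stimulus axis")
    if x.shape[0] < 10:
        raise ValueError("fewer than 10 stimuli: encoding fit would be unstable")
    rng = np.random.default_rng(cfg.seed)
    notes: list[str] = []
    rs = []
    for _ in range(cfg.n_splits):
        tr, te = _split_indices(x.shape[0], cfg.train_fraction, rng)
        mu, sd = x[tr].mean(axis=0), x[tr].std(axis=0)
        sd[sd == 0] = 1.0
        xtr, xte = (x[tr] - mu) / sd, (x[te] - mu) / sd
        n_comp = min(cfg.n_components, len(tr) - 1, xtr.shape[1])
        if n_comp < cfg.n_components:
            notes.append(f"n_components capped at {n_comp}")
        pca = PCA(n_components=n_comp, random_state=int(rng.integers(2**31)))
        ztr = pca.fit_transform(xtr)
        zte = pca.transform(xte)
        pls = PLSRegression(n_components=min(cfg.pls_components, n_comp), scale=False)
        pls.fit(ztr, y[tr])
        rs.append(_per_neuron_pearson(np.asarray(pls.predict(zte)), y[te]))
    per_r = np.mean(rs, axis=0)
    return PredictivityResult(per_r, float(np.median(per_r)), notes=notes)


def _softplus(z):
    return np.logaddexp(0.0, z)


def _spatial_gradient_penalty(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Sum of squared first differences over the last two (spatial) axes."""
    dy = np.diff(w, axis=-2)
    dx = np.diff(w, axis=-1)
    pen = float((dy**2).sum() + (dx**2).sum())
    g = np.zeros_like(w)
    g[..., :-1, :] += -2 * dy
    g[..., 1:, :] += 2 * dy
    g[..., :, :-1] += -2 * dx
    g[..., :, 1:] += 2 * dx
    return pen, g


def poisson_regression_fit(
    features: np.ndarray,
    spikes: np.ndarray,
    reg: RegularizationConfig | None = None,
    cfg: EncodingConfig | None = None,
):
    """Regularized Poisson encoding fit with spatially laid-out weights.

    features : (n_stimuli, n_channels, h, w) feature maps (batch-normalized
        internally: z-scored per feature over the training split).
    spikes : (n_stimuli, n_neurons) nonnegative counts.

    Minimizes mean Poisson NLL of rate = softplus(w.x + b) plus
    l1_rate*||w||_1 + smoothness_rate*(squared spatial gradient) +
    group_rate*(channel-wise l2,1 norm), by Adam. Returns
    (PredictivityResult, weight maps (n_neurons, n_channels, h, w)).
    """
    reg = reg or RegularizationConfig()
    cfg = cfg or EncodingConfig()
    x = np.asarray(features, dtype=float)
    if x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4:
        raise ValueError("features must be (n_stimuli, n_channels, h, w)")
    y = np.atleast_2d(np.asarray(spikes, dtype=float))
    if np.any(y < 0):
        raise ValueError("spike counts must be nonnegative")
    n, c, h, wdt = x.shape
    n_neurons = y.shape[1]
    rng = np.random.default_rng(cfg.seed)
    tr, te = _split_indices(n, cfg.train_fraction, rng)

    mu = x[tr].mean(axis=0)
    sd = x[tr].std(axis=0)
    sd[sd == 0] = 1.0
    xn = (x - mu) / sd
    xf = xn.reshape(n, -1)

    w = np.zeros((n_neurons, c, h, wdt))
    b = np.log(np.expm1(np.maximum(y[tr].mean(axis=0), 1e-3)))  # softplus^-1 of mean rate

    m_w, v_w = np.zeros_like(w), np.zeros_like(w)
    m_b, v_b = np.zeros_like(b), np.zeros_like(b)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    prev_loss, converged = np.inf, False
    xtr = xf[tr]
    ytr = y[tr]
    for t in range(1, cfg.max_iter + 1):
        z = xtr @ w.reshape(n_neurons, -1).T + b  # (n_train, n_neurons)
        rate = _softplus(z) + 1e-9
        sig = 1.0 / (1.0 + np.exp(-z))  # d softplus / dz
        nll = float((rate - ytr * np.log(rate)).mean())
        dz = (1.0 - ytr / rate) * sig / ytr.shape[0]
        gw = (dz.T @ xtr).reshape(w.shape)
        gb = dz.sum(axis=0)

        sm_pen, sm_grad = _spatial_gradient_penalty(w)
        group = np.sqrt((w**2).sum(axis=(2, 3)) + 1e-12)  # (n_neurons, c)
        loss = (
            nll
            + reg.l1_rate * float(np.abs(w).sum())
            + reg.smoothness_rate * sm_pen
            + reg.group_rate * float(group.sum())
        )
        gw += reg.l1_rate * np.sign(w)
        gw += reg.smoothness_rate * sm_grad
        gw += reg.group_rate * w / group[:, :, None, None]

        for p, g, m, v in ((w, gw, m_w, v_w), (b, gb, m_b, v_b)):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            p -= cfg.lr * (m / (1 - beta1**t)) / (np.sqrt(v / (1 - beta2**t)) + eps)

        if abs(prev_loss - loss) < cfg.tol:
            converged = True
            break
        prev_loss = loss

    pred = _softplus(xf[te] @ w.reshape(n_neurons, -1).T + b)
    per_r = _per_neuron_pearson(pred, y[te])
    result = PredictivityResult(
        per_r,
        float(np.median(per_r)),
        converged=converged,
        notes=[] if converged else ["optimizer hit max_iter before loss tolerance"],
    )
    return result, w
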