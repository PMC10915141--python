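"""Behavioral evaluation: shape bias, corruption robustness, PGD, consistency.

Shape bias is scored on cue-conflict hybrids: of the classification
decisions that match either the hybrid's shape class or its texture class,
the fraction matching shape. Robustness is clean accuracy plus accuracy
under parametric image corruptions at severities 1..5. Adversarial
robustness uses projected gradient descent: ascend the loss with steps of
size alpha (sign of the gradient for the L-inf norm, the L2-normalized
gradient for the L2 norm), projecting after every step onto the epsilon
ball around the original image and clipping to [0, 1]. Human/model (or
model/model) agreement is summarized by observed consistency — the fraction
of items both got right or both got wrong — and error consistency, a
kappa-style excess of observed over the level two independent responders of
the same accuracies would show.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .blur import apply_gaussian_blur

__all__ = [
    "CueConflictTrial",
    "ShapeBiasScore",
    "AdversarialConfig",
    "ConsistencyScores",
    "shape_bias",
    "classify_cue_conflict",
    "corrupt",
    "CORRUPTION_KINDS",
    "robustness_curve",
    "pgd_attack",
    "consistency",
]


@dataclass(frozen=True)
class CueConflictTrial:
    """One hybrid-image classification outcome (restricted argmax)."""

    shape_label: int
    texture_label: int
    predicted: int

    def __post_init__(self):
        if self.shape_label == self.texture_label:
            raise ValueError("cue-conflict trials require shape_label != texture_label")


@dataclass(frozen=True)
class ShapeBiasScore:
    """Shape-consistent / (shape- + texture-consistent) decisions.

    Decisions matching neither cue are counted in n_other and excluded from
    the denominator. `defined` is False when the denominator is zero.
    """

    n_shape: int
    n_texture: int
    n_other: int
    score: float
    defined: bool = True


@dataclass(frozen=True)
class AdversarialConfig:
    """PGD settings: norm ('inf' or 'two'), ball radius epsilon, step size
    alpha (reference 0.001), iteration count (reference 15), random init."""

    norm: str = "inf"
    epsilon: float = 0.001
    alpha: float = 0.001
    steps: int = 15
    random_init: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.norm not in ("inf", "two"):
            raise ValueError("norm must be 'inf' or 'two'")
        if self.epsilon < 0 or self.alpha <= 0 or self.steps < 1:
            raise ValueError("need epsilon >= 0, alpha > 0, steps >= 1")


@dataclass(frozen=True)
class ConsistencyScores:
    """Observed and chance-expected agreement of two responders.

    kappa = (observed - expected) / (1 - expected); undefined (flagged) when
    expected = 1, i.e. both responders are at accuracy 0 or 1.
    """

    acc_a: float
    acc_b: float
    observed: float
    expected: float
    kappa: float
    defined: bool = True


def shape_bias(trials) -> ShapeBiasScore:
    """Count shape-, texture- and other-consistent decisions; score = shape
    fraction of the cue-consistent decisions."""
    trials = list(trials)
    n_shape = sum(t.predicted == t.shape_label for t in trials)
    n_texture = sum(t.predicted == t.texture_label for t in trials)
    n_other = len(trials) - n_shape - n_texture
    denom = n_shape + n_texture
    if denom == 0:
        return ShapeBiasScore(n_shape, n_texture, n_other, np.nan, defined=False)
    return ShapeBiasScore(n_shape, n_texture, n_other, n_shape / denom)


def classify_cue_conflict(model, stimuli, class_set=None) -> list[CueConflictTrial]:
    """Classify hybrids with the argmax restricted to `class_set`.

    `stimuli` is a list of LabeledImage-like objects with pixels,
    shape_label and texture_label. The model may emit scores for more
    classes than class_set; the argmax ignores the rest.
    """
    stimuli = list(stimuli)
    logits = model.scores(np.stack([s.pixels for s in stimuli]))
    if class_set is None:
        class_set = sorted({s.shape_label for s in stimuli} | {s.texture_label for s in stimuli})
    class_set = list(class_set)
    restricted = logits[:, class_set]
    pred = [class_set[i] for i in restricted.argmax(axis=1)]
    return [
        CueConflictTrial(s.shape_label, s.texture_label, p)
        for s, p in zip(stimuli, pred)
    ]


# --------------------------------------------------------------------------
# image corruptions (severity schedules are this package's own, monotone by
# construction; severity 0 is an identity passthrough exposed for testing)

_SCHEDULES = {
    "gaussian_noise": [0.08, 0.12, 0.18, 0.26, 0.38],  # additive noise sd
    "shot_noise": [60, 25, 12, 5, 3],  # photons at full scale
    "impulse_noise": [0.03, 0.06, 0.09, 0.17, 0.27],  # salt/pepper prob
    "speckle_noise": [0.10, 0.20, 0.35, 0.50, 0.70],  # multiplicative sd
    "defocus_blur": [0.6, 1.0, 1.6, 2.5, 4.0],  # gaussian sigma px
    "motion_blur": [3, 5, 7, 9, 13],  # kernel length px
    "zoom_blur": [1.04, 1.08, 1.14, 1.22, 1.32],  # max zoom factor
    "contrast": [0.70, 0.55, 0.40, 0.28, 0.18],  # contrast multiplier
    "brightness": [0.08, 0.16, 0.24, 0.32, 0.40],  # additive offset
    "pixelate": [2, 3, 4, 6, 8],  # block size px
    "jpeg_like": [12, 20, 32, 48, 64],  # DCT quantization step /255
}
CORRUPTION_KINDS = tuple(_SCHEDULES)


def _block_mean(x: np.ndarray, b: int) -> np.ndarray:
    h, w = x.shape
    out = x.copy()
    for i in range(0, h, b):
        for j in range(0, w, b):
            out[i : i + b, j : j + b] = x[i : i + b, j : j + b].mean()
    return out


def _jpeg_like(x: np.ndarray, q: float) -> np.ndarray:
    from scipy.fft import dctn, idctn

    step = q / 255.0
    h, w = x.shape
    out = np.empty_like(x)
    for i in range(0, h, 8):
        for j in range(0, w, 8):
            blk = x[i : i + 8, j : j + 8]
            coef = dctn(blk, norm="ortho")
            out[i : i + 8, j : j + 8] = idctn(np.round(coef / step) * step, norm="ortho")
    return out


def corrupt(image: np.ndarray, kind: str, severity: int, rng=None) -> np.ndarray:
    """Apply one corruption at integer severity 0..5 (0 = identity).

    Stochastic kinds draw from `rng` (seed or Generator); the schedules are
    monotone in severity, and output is clipped to [0, 1].
    """
    if kind not in _SCHEDULES:
        raise ValueError(f"unknown corruption {kind!r}; kinds: {CORRUPTION_KINDS}")
    if severity not in range(0, 6):
        raise ValueError("severity must be an integer in 0..5")
    x = np.asarray(image, dtype=float)
    if severity == 0:
        return x.copy()
    p = _SCHEDULES[kind][severity - 1]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    if kind == "gaussian_noise":
        x = x + rng.normal(0, p, x.shape)
    elif kind == "shot_noise":
        x = rng.poisson(np.clip(x, 0, 1) * p) / p
    elif kind == "impulse_noise":
        u = rng.random(x.shape)
        x = np.where(u < p / 2, 0.0, np.where(u > 1 - p / 2, 1.0, x))
    elif kind == "speckle_noise":
        x = x + x * rng.normal(0, p, x.shape)
    elif kind == "defocus_blur":
        x = apply_gaussian_blur(x, p)
    elif kind == "motion_blur":
        # soft-profile horizontal smear (Gaussian-weighted line kernel):
        # monotone frequency attenuation, unlike a hard box kernel
        r = int(p)
        t = np.arange(-r, r + 1)
        k = np.exp(-0.5 * (t / (p / 3.0)) ** 2)
        x = ndimage.convolve1d(x, k / k.sum(), axis=-1, mode="reflect")
    elif kind == "zoom_blur":
        acc = x.copy()
        factors = np.arange(1.0, p + 1e-9, 0.02)[1:]  # prefix-nested across severities
        h, w = x.shape
        for f in factors:
            z = ndimage.zoom(x, f, order=1)
            dy, dx = (z.shape[0] - h) // 2, (z.shape[1] - w) // 2
            acc += z[dy : dy + h, dx : dx + w]
        x = acc / (len(factors) + 1)
    elif kind == "contrast":
        x = (x - 0.5) * p + 0.5
    elif kind == "brightness":
        x = x + p
    elif kind == "pixelate":
        x = _block_mean(x, int(p))
    elif kind == "jpeg_like":
        x = _jpeg_like(x, p)
    return np.clip(x, 0.0, 1.0)


def robustness_curve(
    model, images, labels, kinds=CORRUPTION_KINDS, severities=(1, 2, 3, 4, 5), seed: int = 0
) -> pd.DataFrame:
    """Accuracy per (corruption kind, severity), plus a 'clean' row.

    Returns a DataFrame indexed by kind with one column per severity; the
    clean row repeats the uncorrupted accuracy at every severity.
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels)
    clean_acc = float((model.predict(images) == labels).mean())
    rows = {"clean": {s: clean_acc for s in severities}}
    for kind in kinds:
        row = {}
        for s in severities:
            rng = np.random.default_rng(seed + 1000 * s)
            xs = np.stack([corrupt(im, kind, s, rng) for im in images])
            row[s] = float((model.predict(xs) == labels).mean())
        rows[kind] = row
    df = pd.DataFrame(rows).T
    df.index.name = "kind"
    df.columns.name = "severity"
    return df


def _project(delta: np.ndarray, cfg: AdversarialConfig) -> np.ndarray:
    if cfg.norm == "inf":
        return np.clip(delta, -cfg.epsilon, cfg.epsilon)
    flat = delta.reshape(delta.shape[0], -1)
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    scale = np.minimum(1.0, cfg.epsilon / np.maximum(norms, 1e-12))
    return (flat * scale).reshape(delta.shape)


def pgd_attack(model, images, labels, cfg: AdversarialConfig | None = None) -> np.ndarray:
    """Projected-gradient-descent attack on [0,1] images.

    Iterates x <- P(x + alpha * dir(grad_x L)) for `steps` iterations, where
    dir is the elementwise sign for the L-inf norm and the L2-normalized
    gradient for the L2 norm, P projects onto the epsilon ball around the
    original image, and every iterate is clipped to [0, 1]. epsilon = 0
    returns the input unchanged.
    """
    cfg = cfg or AdversarialConfig()
    x0 = np.asarray(images, dtype=float)
    squeeze = x0.ndim == 2
    if squeeze:
        x0 = x0[None]
    labels = np.atleast_1d(labels)
    if cfg.epsilon == 0:
        return x0[0].copy() if squeeze else x0.copy()
    rng = np.random.default_rng(cfg.seed)
    if cfg.random_init:
        if cfg.norm == "inf":
            delta = rng.uniform(-cfg.epsilon, cfg.epsilon, x0.shape)
        else:
            d = rng.standard_normal(x0.shape)
            flat = d.reshape(d.shape[0], -1)
            u = rng.random(d.shape[0]) ** (1.0 / flat.shape[1])
            flat *= (cfg.epsilon * u / np.linalg.norm(flat, axis=1))[:, None]
            delta = flat.reshape(x0.shape)
    else:
        delta = np.zeros_like(x0)
    x = np.clip(x0 + delta, 0.0, 1.0)
    for _ in range(cfg.steps):
        g = model.input_gradient(x, labels)
        g = g.reshape(x.shape)
        if cfg.norm == "inf":
            step = np.sign(g)
        else:
            flat = g.reshape(g.shape[0], -1)
            norms = np.linalg.norm(flat, axis=1, keepdims=True)
            step = (flat / np.maximum(norms, 1e-12)).reshape(g.shape)
        x = x + cfg.alpha * step
        x = x0 + _project(x - x0, cfg)
        x = np.clip(x, 0.0, 1.0)
    return x[0] if squeeze else x


def consistency(flags_a, flags_b) -> ConsistencyScores:
    """Observed and error consistency of two per-item correctness vectors."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("flags must be matching nonempty 1-D boolean vectors")
    acc_a, acc_b = float(a.mean()), float(b.mean())
    observed = float((a == b).mean())
    expected = acc_a * acc_b + (1 - acc_a) * (1 - acc_b)
    if expected >= 1.0 - 1e-15:
        return ConsistencyScores(acc_a, acc_b, observed, expected, np.nan, defined=False)
    kappa = (observed - expected) / (1.0 - expected)
    return ConsistencyScores(acc_a, acc_b, observed, expected, kappa)
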