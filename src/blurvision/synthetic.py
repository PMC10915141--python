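"""Procedural shape x texture corpus, simulated neural areas, tiny CNNs.

Every downstream probe in this package needs three kinds of input that at
full scale come from large external resources: a labeled image corpus (with
cue-conflict hybrids pairing one class's silhouette with another's texture),
condition-wise neural response patterns, and a trained classifier exposing
named-layer activations. This module generates desk-scale versions of all
three with known ground truth.

Images are grayscale in [0, 1] on a mid-gray (0.5) background. A class is a
silhouette template (regular polygon, star, or smoothed blob) plus a texture
(oriented grating, checkerboard, band-passed noise, or dots) rendered only
inside the silhouette, so shape information lives at low spatial frequencies
and texture information at high ones — the same cue separation the
cue-conflict paradigm exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as _draw_polygon

from . import nn
from .blur import (
    PeripheralBlurProfile,
    apply_gaussian_blur,
    apply_peripheral_blur,
    sample_sigma,
    strong_blur_reference,
    weak_blur_reference,
)

__all__ = [
    "ShapeTexSpec",
    "LabeledImage",
    "SimulatedArea",
    "TrainingConfig",
    "TrainingError",
    "ModelHandle",
    "generate_shapetex",
    "generate_cue_conflict",
    "gabor_filter",
    "gabor_teacher_bank",
    "simulate_neural_responses",
    "build_tiny_cnn",
    "train_reference_models",
    "REGIMES",
]

REGIMES = ("clear", "weak_blur", "strong_blur", "peripheral_blur")

# silhouette templates: ("poly", n) regular n-gon; ("star", n, inner/outer
# radius ratio); ("blob", k) smoothed random blob with class-fixed harmonics
_SHAPE_TEMPLATES = [
    ("poly", 4),
    ("poly", 3),
    ("star", 5, 0.55),
    ("poly", 6),
    ("star", 4, 0.5),
    ("blob", 0),
    ("star", 6, 0.6),
    ("poly", 8),
    ("blob", 1),
    ("poly", 5),
    ("star", 7, 0.65),
    ("blob", 2),
    ("poly", 7),
    ("blob", 3),
    ("star", 3, 0.5),
    ("blob", 4),
]


@dataclass(frozen=True)
class ShapeTexSpec:
    """Corpus recipe; the same seed reproduces the corpus bit for bit."""

    n_shape_classes: int = 4
    n_texture_classes: int = 4
    image_size: int = 64
    samples_per_class: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_shape_classes < 2 or self.n_texture_classes < 2:
            raise ValueError("need at least 2 shape and 2 texture classes")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32 px")
        if self.n_shape_classes > len(_SHAPE_TEMPLATES):
            raise ValueError(
                f"at most {len(_SHAPE_TEMPLATES)} distinct silhouette classes supported"
            )


@dataclass
class LabeledImage:
    """Grayscale image with shape and texture class labels.

    Ordinary corpus samples have shape_label == texture_label; cue-conflict
    hybrids have shape_label != texture_label. The generator's silhouette
    mask is retained for verification.
    """

    pixels: np.ndarray
    shape_label: int
    texture_label: int
    mask: np.ndarray | None = None


def _boundary_radii(template, phis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-scale boundary radius r(phi) for a silhouette template."""
    kind = template[0]
    if kind == "poly":
        n = template[1]
        # radius of a regular n-gon of circumradius 1 at angle phi
        a = np.mod(phis, 2 * np.pi / n) - np.pi / n
        return np.cos(np.pi / n) / np.cos(a)
    if kind == "star":
        n, ratio = template[1], template[2]
        # linear interpolation of radius between outer and inner vertices
        a = np.abs(np.mod(phis, 2 * np.pi / n) - np.pi / n) / (np.pi / n)
        return ratio + (1.0 - ratio) * a
    if kind == "blob":
        tpl_rng = np.random.default_rng(10_000 + template[1])
        amps = tpl_rng.uniform(0.08, 0.22, size=3)
        ks = tpl_rng.integers(2, 6, size=3)
        phases = tpl_rng.uniform(0, 2 * np.pi, size=3)
        r = np.ones_like(phis)
        for a, k, p in zip(amps, ks, phases):
            r += a * np.cos(k * phis + p)
        return r
    raise ValueError(f"unknown template kind {kind!r}")


def _render_mask(shape_class: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one silhouette with jittered rotation/area/position."""
    template = _SHAPE_TEMPLATES[shape_class]
    # pose jitter is limited (as natural object photographs have broadly
    # canonical poses); full rotation would demand rotation-invariant shape
    # reading, which this corpus scale cannot support
    rot = rng.uniform(-0.35, 0.35)
    area_frac = rng.uniform(0.28, 0.45)
    phis = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    r = _boundary_radii(template, phis + rot, rng)
    # shoelace area of the unit-scale boundary, then scale to the target area
    x, y = r * np.cos(phis), r * np.sin(phis)
    unit_area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    scale = np.sqrt(area_frac * size * size / unit_area)
    cx = size / 2 + rng.uniform(-0.04, 0.04) * size
    cy = size / 2 + rng.uniform(-0.04, 0.04) * size
    rr, cc = _draw_polygon(cy + scale * y, cx + scale * x, shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


def _texture_field(texture_class: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Full-frame texture in [0,1], mean ~0.5, dominated by high frequencies."""
    kind = texture_class % 4
    tier = texture_class // 4
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    amp = 0.35
    if kind == 0:  # oriented grating
        theta = np.deg2rad(30 + 60 * tier)
        period = 3.0 + 0.5 * tier
        phase = rng.uniform(0, 2 * np.pi)
        u = xx * np.cos(theta) + yy * np.sin(theta)
        return 0.5 + amp * np.cos(2 * np.pi * u / period + phase)
    if kind == 1:  # checkerboard
        period = 3 + tier
        off = rng.integers(0, period, size=2)
        return 0.5 + amp * (((xx + off[0]) // period + (yy + off[1]) // period) % 2 * 2 - 1)
    if kind == 2:  # band-passed (high-frequency) noise
        noise = rng.standard_normal((size, size))
        spec = np.fft.fft2(noise)
        fy = np.fft.fftfreq(size)[:, None]
        fx = np.fft.fftfreq(size)[None, :]
        f = np.hypot(fy, fx)
        band = (f > 0.22) & (f < 0.46)
        tex = np.fft.ifft2(spec * band).real
        tex = tex / (np.abs(tex).max() + 1e-12)
        return 0.5 + amp * tex
    # kind == 3: random dots
    density = 0.06 + 0.03 * tier
    dots = rng.random((size, size)) < density
    tex = np.full((size, size), 0.5 - amp * 0.5)
    tex[dots] = 0.5 + amp
    return tex


def _render_image(
    shape_class: int, texture_class: int, size: int, rng: np.random.Generator
) -> LabeledImage:
    mask = _render_mask(shape_class, size, rng)
    tex = _texture_field(texture_class, size, rng)
    pixels = np.full((size, size), 0.5)
    # equalize first- and second-order statistics inside the silhouette so
    # texture identity carries no mean-luminance or contrast cue, then give
    # the whole fill a per-sample random mean offset from the background:
    # the offset is uninformative about either class but keeps the
    # silhouette visible as a luminance edge once blur removes the texture
    # (as real objects differ from their background in mean luminance)
    vals = tex[mask]
    offset = rng.uniform(0.12, 0.28) * rng.choice([-1.0, 1.0])
    vals = (vals - vals.mean()) / (vals.std() + 1e-9) * 0.15 + 0.5 + offset
    pixels[mask] = np.clip(vals, 0.02, 0.98)
    return LabeledImage(pixels, shape_class, texture_class, mask)


def generate_shapetex(spec: ShapeTexSpec) -> list[LabeledImage]:
    """Generate a balanced corpus of ordinary (shape == texture) samples.

    Classes are shared between the shape and texture factors (class k is
    silhouette template k filled with texture k), so the corpus requires
    n_shape_classes == n_texture_classes.
    """
    if spec.n_shape_classes != spec.n_texture_classes:
        raise ValueError("corpus generation assumes a shared shape/texture class set")
    rng = np.random.default_rng(spec.seed)
    images = []
    for c in range(spec.n_shape_classes):
        for _ in range(spec.samples_per_class):
            images.append(_render_image(c, c, spec.image_size, rng))
    return images


def generate_cue_conflict(spec: ShapeTexSpec, n_per_pair: int = 1) -> list[LabeledImage]:
    """Hybrids: silhouette of one class filled with another class's texture.

    Every ordered pair (shape a, texture b), a != b, appears exactly
    n_per_pair times; 16 classes at ~5-6 per pair reproduce the scale of the
    standard 1280-image cue-conflict stimulus set.
    """
    if spec.n_shape_classes != spec.n_texture_classes:
        raise ValueError("cue-conflict hybrids assume a shared class set")
    rng = np.random.default_rng(spec.seed + 1)
    images = []
    for a in range(spec.n_shape_classes):
        for b in range(spec.n_texture_classes):
            if a == b:
                continue
            for _ in range(n_per_pair):
                images.append(_render_image(a, b, spec.image_size, rng))
    return images


# --------------------------------------------------------------------------
# simulated neural areas


def gabor_filter(
    size: int,
    frequency: float,
    orientation_deg: float,
    phase_deg: float = 0.0,
    envelope_frac: float = 0.25,
) -> np.ndarray:
    """Zero-mean, unit-norm Gabor; `frequency` in cycles per image."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    theta = np.deg2rad(orientation_deg)
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    env = np.exp(-0.5 * (((xx - cx) ** 2 + (yy - cy) ** 2) / (envelope_frac * size) ** 2))
    g = env * np.cos(2 * np.pi * frequency * u / size + np.deg2rad(phase_deg))
    g -= g.mean()
    return g / (np.linalg.norm(g) + 1e-12)


def gabor_teacher_bank(
    size: int, frequencies, orientations_deg=(0.0, 45.0, 90.0, 135.0)
) -> np.ndarray:
    """Bank of Gabor receptive fields, shape (n_filters, size, size)."""
    return np.stack(
        [gabor_filter(size, f, o) for f in frequencies for o in orientations_deg]
    )


@dataclass(frozen=True)
class SimulatedArea:
    """A bank of linear receptive fields standing in for a visual area.

    Responses are filter dot-products corrupted by i.i.d. Gaussian noise of
    sd `noise_sd` on each of `n_repeats` repeats, then repeat-averaged.
    """

    teacher_filters: np.ndarray
    noise_sd: float = 0.5
    n_repeats: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")


def simulate_neural_responses(stimuli, area: SimulatedArea):
    """Return (noisy, noiseless) condition x feature response tables.

    `stimuli` is an array (N, H, W) or a list of LabeledImage. The noiseless
    teacher table is returned alongside the noisy one for oracle tests.
    """
    if isinstance(stimuli, (list, tuple)):
        stimuli = np.stack([s.pixels if isinstance(s, LabeledImage) else s for s in stimuli])
    if stimuli.size == 0:
        raise ValueError("stimuli must be nonempty")
    x = stimuli.reshape(stimuli.shape[0], -1)
    filt = area.teacher_filters.reshape(area.teacher_filters.shape[0], -1)
    clean = x @ filt.T
    if area.noise_sd == 0:
        return clean.copy(), clean
    rng = np.random.default_rng(area.seed)
    noise = rng.normal(0.0, area.noise_sd, size=(area.n_repeats, *clean.shape))
    noisy = clean + noise.mean(axis=0)
    return noisy, clean


# --------------------------------------------------------------------------
# tiny trainable classifier


class TrainingError(RuntimeError):
    """Raised when a reference model fails to reach above-chance accuracy."""


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 80
    batch_size: int = 16
    lr: float = 4e-3
    seed: int = 0
    channels: tuple = (8, 16, 32)
    kernel: int = 3
    head: str = "flatten"
    min_margin: float = 0.15  # required train accuracy above chance


def build_tiny_cnn(
    n_classes: int,
    channels=(8, 16, 32),
    kernel: int = 3,
    image_size: int = 64,
    head: str = "flatten",
    rng=None,
) -> nn.Sequential:
    """Three conv blocks (conv-ReLU-maxpool) + classifier head.

    head='flatten' average-pools once more and reads the coarse spatial map
    with the linear head (retains global layout — needed for silhouette
    reading); head='gap' uses a global average pool instead.
    """
    rng = np.random.default_rng(rng)
    c1, c2, c3 = channels
    layers = [
        ("conv1", nn.Conv2d(1, c1, kernel + 2, rng=rng)),  # larger early RF
        ("relu1", nn.ReLU()),
        ("pool1", nn.MaxPool2()),
        ("conv2", nn.Conv2d(c1, c2, kernel, rng=rng)),
        ("relu2", nn.ReLU()),
        ("pool2", nn.MaxPool2()),
        ("conv3", nn.Conv2d(c2, c3, kernel, rng=rng)),
        ("relu3", nn.ReLU()),
        ("pool3", nn.MaxPool2()),
    ]
    if head == "gap":
        layers += [("gap", nn.GlobalAvgPool()), ("fc", nn.Linear(c3, n_classes, rng=rng))]
    elif head == "flatten":
        side = image_size // 16
        layers += [
            ("pool4", nn.AvgPool2()),
            ("flatten", nn.Flatten()),
            ("fc", nn.Linear(c3 * side * side, n_classes, rng=rng)),
        ]
    else:
        raise ValueError("head must be 'gap' or 'flatten'")
    return nn.Sequential(layers)


class ModelHandle:
    """A trained classifier exposing named-layer activations and gradients.

    The activation-extraction contract used by every probe module:
    ``scores`` returns class logits, ``activations`` a dict of named layer
    outputs, ``input_gradient`` the gradient of the classification loss with
    respect to the input pixels.
    """

    def __init__(self, net: nn.Sequential, n_classes: int, image_size: int,
                 regime: str = "clear", seed: int = 0, meta: dict | None = None):
        self.net = net
        self.n_classes = n_classes
        self.image_size = image_size
        self.regime = regime
        self.seed = seed
        self.meta = meta or {}

    @staticmethod
    def _batch(images) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        return x

    @property
    def layer_names(self) -> list[str]:
        return self.net.layer_names

    @property
    def probe_layers(self) -> list[str]:
        """Post-ReLU conv activations plus the head — the RSA/tuning surface."""
        return [n for n in self.net.layer_names if n.startswith("relu")] + ["fc"]

    @property
    def conv_probe_layers(self) -> list[str]:
        return [n for n in self.net.layer_names if n.startswith("relu")]

    def scores(self, images) -> np.ndarray:
        return self.net.forward(self._batch(images))

    def predict(self, images) -> np.ndarray:
        return self.scores(images).argmax(axis=1)

    def activations(self, images) -> dict[str, np.ndarray]:
        rec: dict[str, np.ndarray] = {}
        self.net.forward(self._batch(images), record=rec)
        return rec

    def input_gradient(self, images, labels) -> np.ndarray:
        x = self._batch(images)
        logits = self.net.forward(x)
        _, dlogits = nn.cross_entropy(logits, np.atleast_1d(labels))
        return self.net.backward(dlogits)

    def save(self, path) -> None:
        """Write weights as .npz plus a JSON metadata sidecar (.json)."""
        import json
        from pathlib import Path

        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.net.params())}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "n_classes": self.n_classes,
            "image_size": self.image_size,
            "regime": self.regime,
            "seed": self.seed,
            **{k: v for k, v in self.meta.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "ModelHandle":
        """Rebuild a tiny-CNN handle from save()'s .npz + .json pair."""
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = build_tiny_cnn(
            meta["n_classes"],
            tuple(meta.get("channels", (8, 16, 32))),
            image_size=meta["image_size"],
        )
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(net.params()):
                p[...] = data[f"p{i}"]
        return cls(
            net, meta["n_classes"], meta["image_size"],
            regime=meta.get("regime", "clear"), seed=meta.get("seed", 0), meta=meta,
        )


def _regime_augment(regime: str):
    """Per-presentation augmentation closure for a training regime.

    Blur levels are applied in pixel units exactly as the regime states
    them, at any image size; on small images the largest kernels degrade
    shape as well as texture, which impairs but does not abolish
    classification of those presentations.
    """
    if regime == "clear":
        return lambda img, rng: img
    if regime == "weak_blur":
        dist = weak_blur_reference()
    elif regime == "strong_blur":
        dist = strong_blur_reference()
    elif regime == "peripheral_blur":
        profile = PeripheralBlurProfile(0.0, 8.0, 112.0)

        def aug_periph(img, rng):
            if rng.random() < 0.5:
                return img
            return apply_peripheral_blur(img, profile)

        return aug_periph
    else:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")

    def aug(img, rng):
        s = float(sample_sigma(dist, rng))
        return apply_gaussian_blur(img, s) if s > 0 else img

    return aug


def train_reference_models(
    corpus: list[LabeledImage],
    regime: str = "clear",
    config: TrainingConfig | None = None,
) -> ModelHandle:
    """Train the tiny CNN on a corpus under a blur regime.

    The blur level is re-sampled independently for every presentation of
    every image (per image, per epoch). Raises TrainingError if the final
    accuracy on the clear training images is below chance + min_margin.
    """
    cfg = config or TrainingConfig()
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    rng = np.random.default_rng(cfg.seed)
    x = np.stack([im.pixels for im in corpus])
    y = np.array([im.shape_label for im in corpus])
    n_classes = int(y.max()) + 1
    size = x.shape[-1]
    aug = _regime_augment(regime)

    net = build_tiny_cnn(
        n_classes, cfg.channels, cfg.kernel, image_size=size, head=cfg.head, rng=rng
    )
    opt = nn.Adam(net.params(), net.grads(), lr=cfg.lr)
    n = len(corpus)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = np.stack([aug(x[i], rng) for i in idx])[:, None]
            logits = net.forward(xb)
            _, dlogits = nn.cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step()

    handle = ModelHandle(
        net, n_classes, size, regime=regime, seed=cfg.seed,
        meta={"epochs": cfg.epochs, "lr": cfg.lr, "channels": list(cfg.channels)},
    )
    acc = float((handle.predict(x) == y).mean())
    chance = 1.0 / n_classes
    if acc < chance + cfg.min_margin:
        raise TrainingError(
            f"regime {regime!r}: train accuracy {acc:.3f} below chance+margin "
            f"({chance + cfg.min_margin:.3f}); corpus size {n}, {cfg.epochs} epochs"
        )
    handle.meta["train_accuracy"] = acc
    return handle
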