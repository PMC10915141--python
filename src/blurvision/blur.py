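"""Defocus optics and Gaussian blur augmentation.

The augmentation law models the retinal blur a viewer accumulates during
natural behavior. An object at a depth offset of D diopters from fixation,
seen through a pupil of diameter p, spreads over a blur circle of angular
diameter ~ p * D radians (thin-lens small-angle geometry). Converting that
angle to pixels for a photograph of known field of view, and matching a
Gaussian kernel's FWHM to the blur-circle diameter, yields a distribution of
Gaussian sigma values over everyday viewing — the "weak" regime, dominated by
clear presentations. The "strong" regime instead samples five widely spaced
sigma levels uniformly, emulating the steady fall of resolution from fovea to
periphery; its largest kernel (sigma = 8 px on a 224-px image) passes less
than 50% amplitude beyond ~6 cycles/image. A spatially varying variant ramps
sigma linearly with eccentricity within a single image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "OpticalConfig",
    "BlurDistribution",
    "DefocusSample",
    "PeripheralBlurProfile",
    "blur_circle_diameter_px",
    "fwhm_to_sigma",
    "derive_weak_blur_distribution",
    "weak_blur_reference",
    "strong_blur_reference",
    "sample_sigma",
    "gaussian_kernel_1d",
    "apply_gaussian_blur",
    "gaussian_mtf",
    "gaussian_mtf_discrete",
    "apply_peripheral_blur",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.35482


@dataclass(frozen=True)
class OpticalConfig:
    """Viewing geometry linking diopters of defocus to pixels of blur.

    pupil_diameter_mm : entrance pupil, mm (mean human photopic ~5.8).
    horizontal_fov_deg : camera horizontal field of view, degrees.
    image_width_px : image width the field of view maps onto.
    """

    pupil_diameter_mm: float = 5.8
    horizontal_fov_deg: float = 54.0
    image_width_px: int = 224

    def __post_init__(self):
        if min(self.pupil_diameter_mm, self.horizontal_fov_deg, self.image_width_px) <= 0:
            raise ValueError("optical parameters must be strictly positive")


@dataclass(frozen=True)
class BlurDistribution:
    """Discrete augmentation law: P(sigma = sigma_levels[i]) = probabilities[i]."""

    sigma_levels: tuple
    probabilities: tuple

    def __post_init__(self):
        s = np.asarray(self.sigma_levels, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if s.shape != p.shape or s.ndim != 1 or s.size == 0:
            raise ValueError("sigma_levels and probabilities must be matching 1-D sequences")
        if np.any(s < 0) or np.any(np.diff(s) <= 0):
            raise ValueError("sigma_levels must be nonnegative and strictly increasing")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "sigma_levels", tuple(float(x) for x in s))
        object.__setattr__(self, "probabilities", tuple(float(x) for x in p))

    def to_dict(self) -> dict:
        return {"sigma": list(self.sigma_levels), "prob": list(self.probabilities)}

    @classmethod
    def from_dict(cls, d: dict) -> "BlurDistribution":
        return cls(tuple(d["sigma"]), tuple(d["prob"]))


@dataclass(frozen=True)
class DefocusSample:
    """One observation of relative defocus (diopters) with a task weight."""

    relative_defocus: float
    task_weight: float

    def __post_init__(self):
        if self.task_weight < 0:
            raise ValueError("task_weight must be nonnegative")


@dataclass(frozen=True)
class PeripheralBlurProfile:
    """Linear eccentricity ramp of Gaussian sigma, saturating at max_sigma.

    sigma(e) = min(max_sigma, center_sigma + (max_sigma - center_sigma)
               * e / saturation_eccentricity), e = Euclidean px from center.
    """

    center_sigma: float = 0.0
    max_sigma: float = 8.0
    saturation_eccentricity: float = 112.0

    def __post_init__(self):
        if not (0 <= self.center_sigma <= self.max_sigma):
            raise ValueError("need 0 <= center_sigma <= max_sigma")
        if self.saturation_eccentricity <= 0:
            raise ValueError("saturation_eccentricity must be positive")

    def sigma_at(self, ecc: np.ndarray) -> np.ndarray:
        ramp = self.center_sigma + (self.max_sigma - self.center_sigma) * (
            np.asarray(ecc, dtype=float) / self.saturation_eccentricity
        )
        return np.minimum(self.max_sigma, ramp)


def blur_circle_diameter_px(defocus_diopters: float, optics: OpticalConfig) -> float:
    """Blur-circle diameter in pixels for a given relative defocus.

    Small-angle geometry: angular diameter = pupil (m) x defocus (1/m)
    radians, converted to degrees, then to pixels at image_width/fov px/deg.
    Linear in both defocus and pupil diameter.
    """
    if defocus_diopters < 0:
        raise ValueError("defocus must be nonnegative")
    angle_rad = optics.pupil_diameter_mm * 1e-3 * defocus_diopters
    angle_deg = np.degrees(angle_rad)
    return angle_deg * optics.image_width_px / optics.horizontal_fov_deg


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma whose full width at half maximum equals `fwhm`."""
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    return fwhm / FWHM_PER_SIGMA


def derive_weak_blur_distribution(
    samples: list[DefocusSample],
    optics: OpticalConfig | None = None,
    sigma_grid: tuple = (0, 1, 2, 3, 4, 5),
) -> BlurDistribution:
    """Derive a weak-blur law from defocus observations.

    Each sample maps to a Gaussian sigma (blur-circle diameter -> FWHM ->
    sigma), sigma is binned to the nearest grid level (capped at the top
    level), and task-weighted frequencies are accumulated. The clear mass
    (sigma = 0 bin) is kept as the empirical point mass; the nonzero-sigma
    mass is smoothed by a least-squares exponential fit of log-frequency
    against sigma over the occupied nonzero bins, then renormalized so the
    total is 1.
    """
    if not samples:
        raise ValueError("need at least one defocus sample")
    optics = optics or OpticalConfig()
    grid = np.asarray(sigma_grid, dtype=float)
    w = np.array([s.task_weight for s in samples], dtype=float)
    if w.sum() <= 0:
        raise ValueError("task weights must have positive total")
    w = w / w.sum()
    sig = np.array(
        [fwhm_to_sigma(blur_circle_diameter_px(s.relative_defocus, optics)) for s in samples]
    )
    # nearest-grid binning, saturating at the largest level
    idx = np.abs(sig[:, None] - grid[None, :]).argmin(axis=1)
    freq = np.bincount(idx, weights=w, minlength=grid.size)

    p0 = freq[0] if grid[0] == 0 else 0.0
    nz = (grid > 0) & (freq > 0)
    if p0 >= 1.0 - 1e-12 or nz.sum() == 0:
        warnings.warn("all defocus mass at sigma=0: degenerate clear-only distribution")
        return BlurDistribution((0.0,), (1.0,))
    if nz.sum() == 1:
        smooth = np.where(nz, freq, 0.0)[grid > 0]
    else:
        a, b = np.polyfit(grid[nz], np.log(freq[nz]), 1)
        smooth = np.exp(a * grid[grid > 0] + b)
    smooth = smooth / smooth.sum() * (1.0 - p0)
    levels = grid if grid[0] == 0 else np.concatenate([[0.0], grid])
    probs = np.concatenate([[p0], smooth])
    return BlurDistribution(tuple(levels), tuple(probs))


def weak_blur_reference() -> BlurDistribution:
    """The published weak-blur law: clear 69.4%, then 21.3/6.5/2.0/0.6/0.2%
    at sigma = 1..5 px (derived from everyday-task defocus statistics)."""
    return BlurDistribution(
        (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
        (0.694, 0.213, 0.065, 0.020, 0.006, 0.002),
    )


def strong_blur_reference() -> BlurDistribution:
    """The strong-blur law: sigma in {0, 1, 2, 4, 8} px with equal probability."""
    return BlurDistribution((0.0, 1.0, 2.0, 4.0, 8.0), (0.2,) * 5)


def sample_sigma(dist: BlurDistribution, rng, size: int | None = None):
    """Draw i.i.d. sigma values; `rng` is a seed or a numpy Generator."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.choice(np.asarray(dist.sigma_levels), size=size, p=np.asarray(dist.probabilities))


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Unit-sum 1-D Gaussian truncated at radius ceil(4*sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return np.array([1.0])
    r = int(np.ceil(4.0 * sigma))
    x = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def apply_gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur with reflective borders; sigma=0 is identity."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    k = gaussian_kernel_1d(sigma)
    out = ndimage.convolve1d(image, k, axis=-2, mode="reflect")
    return ndimage.convolve1d(out, k, axis=-1, mode="reflect")


def gaussian_mtf(sigma: float, image_width: int, k) -> np.ndarray | float:
    """Amplitude transfer of a continuous Gaussian blur at k cycles/image:
    exp(-2 pi^2 sigma^2 (k / image_width)^2)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    k = np.asarray(k, dtype=float)
    out = np.exp(-2.0 * np.pi**2 * sigma**2 * (k / image_width) ** 2)
    return float(out) if out.ndim == 0 else out


def gaussian_mtf_discrete(sigma: float, image_width: int, k: int) -> float:
    """Fourier amplitude of the truncated unit-sum discrete kernel at k
    cycles/image (agrees with the closed form to ~1e-3 for sigma >= 1)."""
    kern = gaussian_kernel_1d(sigma)
    r = (kern.size - 1) // 2
    x = np.arange(-r, r + 1)
    return float(np.abs(np.sum(kern * np.exp(-2j * np.pi * k * x / image_width))))


def apply_peripheral_blur(
    image: np.ndarray,
    profile: PeripheralBlurProfile | None = None,
    step: float = 0.5,
) -> np.ndarray:
    """Eccentricity-ramped blur via a quantized blur stack.

    Copies of the image blurred at sigma levels spaced `step` px apart are
    blended per pixel with linear interpolation between the two levels
    bracketing that pixel's sigma(eccentricity).
    """
    profile = profile or PeripheralBlurProfile()
    image = np.asarray(image, dtype=float)
    h, w = image.shape[-2:]
    if h != w:
        raise ValueError("peripheral blur expects a square image")
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ecc = np.hypot(yy - cy, xx - cx)
    sig = profile.sigma_at(ecc)

    levels = np.arange(0.0, profile.max_sigma + step / 2, step)
    if levels[-1] < profile.max_sigma:
        levels = np.append(levels, profile.max_sigma)
    stack = np.stack([apply_gaussian_blur(image, s) for s in levels])

    pos = np.clip(sig / step, 0, len(levels) - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, len(levels) - 1)
    frac = pos - lo
    flat_lo = np.take_along_axis(stack.reshape(len(levels), -1), lo.reshape(1, -1), axis=0)
    flat_hi = np.take_along_axis(stack.reshape(len(levels), -1), hi.reshape(1, -1), axis=0)
    out = (1 - frac.reshape(-1)) * flat_lo[0] + frac.reshape(-1) * flat_hi[0]
    return out.reshape(image.shape)
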