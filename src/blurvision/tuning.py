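"""Spatial-frequency tuning of convolutional units via grating probes.

Each convolutional channel is probed with whole-field sinusoidal gratings on
a full factorial grid of spatial frequency, orientation and phase. Averaging
the channel's activation over orientations, phases and spatial positions at
each frequency gives its tuning curve; the argmax is its preferred spatial
frequency, and a Gaussian fit on a log2-frequency axis gives a
full-width-at-half-maximum bandwidth, also expressed relative to the center
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GratingSpec",
    "TuningCurve",
    "BandwidthResult",
    "generate_grating",
    "probe_bank",
    "grating_batch",
    "unit_tuning_curve",
    "all_channel_tuning_curves",
    "preferred_sf",
    "tuning_bandwidth",
    "layerwise_tuning_summary",
]

# probe grids stated at the 224-px reference scale
_BASE_SIZE = 224
_BASE_FREQ_STEP = 4.48  # cycles/image; 25 multiples reach 112 = Nyquist at 224
_N_FREQS = 25
_ORIENTATIONS = tuple(float(o) for o in range(0, 180, 12))
_PHASES = (0.0, 90.0, 180.0, 270.0)


@dataclass(frozen=True)
class GratingSpec:
    """One sinusoidal grating: frequency (cycles/image), orientation and
    phase in degrees, square size in px."""

    frequency: float
    orientation: float
    phase: float
    size: int

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not (0 <= self.orientation < 180):
            raise ValueError("orientation must lie in [0, 180)")
        if not (0 <= self.phase < 360):
            raise ValueError("phase must lie in [0, 360)")


@dataclass(frozen=True)
class TuningCurve:
    """Mean response per probed frequency (averaged over orientation, phase
    and spatial position)."""

    frequencies: tuple
    mean_response: tuple

    def __post_init__(self):
        f = np.asarray(self.frequencies, float)
        r = np.asarray(self.mean_response, float)
        if f.shape != r.shape or f.ndim != 1:
            raise ValueError("frequencies and mean_response must be matching 1-D sequences")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")


@dataclass(frozen=True)
class BandwidthResult:
    """Gaussian-fit tuning summary.

    fwhm_log is the full width at half maximum in log2-frequency (octaves);
    relative_bandwidth is the linear-frequency FWHM divided by the peak
    frequency. Fits with R^2 < 0.5, and flat curves, are flagged unreliable.
    """

    peak_frequency: float
    fwhm_log: float
    relative_bandwidth: float
    fit_quality: float
    reliable: bool = True


def generate_grating(spec: GratingSpec) -> np.ndarray:
    """Cosine grating rescaled to [0, 1] (mean ~0.5)."""
    yy, xx = np.mgrid[0 : spec.size, 0 : spec.size].astype(float)
    theta = np.deg2rad(spec.orientation)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    wave = np.cos(2 * np.pi * spec.frequency * u / spec.size + np.deg2rad(spec.phase))
    return 0.5 + 0.5 * wave


def probe_bank(size: int = _BASE_SIZE) -> list[GratingSpec]:
    """Full factorial probe grid: 25 frequencies x 15 orientations x 4 phases.

    Frequencies are an arithmetic ladder whose step equals the lowest
    frequency; the grid is stated at 224 px and scaled proportionally for
    other sizes so cycles-per-image coverage (up to Nyquist) is preserved.
    """
    step = _BASE_FREQ_STEP * size / _BASE_SIZE
    freqs = [step * i for i in range(1, _N_FREQS + 1)]
    return [
        GratingSpec(f, o, p, size)
        for f in freqs
        for o in _ORIENTATIONS
        for p in _PHASES
    ]


def grating_batch(bank: list[GratingSpec]) -> np.ndarray:
    """Render a bank into an (N, size, size) stack."""
    return np.stack([generate_grating(s) for s in bank])


def _frequency_groups(bank: list[GratingSpec]):
    freqs = sorted({s.frequency for s in bank})
    groups = {f: [i for i, s in enumerate(bank) if s.frequency == f] for f in freqs}
    return freqs, groups


def _bank_layer_means(model, bank: list[GratingSpec], layers, chunk: int = 128):
    """Spatially averaged activations of `layers` for every bank grating.

    The bank is pushed through the model in chunks (it can hold thousands of
    gratings) and only the (N, channels) spatial means are retained.
    """
    means = {layer: [] for layer in layers}
    for start in range(0, len(bank), chunk):
        batch = grating_batch(bank[start : start + chunk])
        acts = model.activations(batch)
        for layer in layers:
            if layer not in acts:
                raise KeyError(f"model has no layer named {layer!r}")
            a = acts[layer]
            if a.ndim == 4:
                a = a.mean(axis=(2, 3))
            elif a.ndim != 2:
                raise ValueError(f"layer {layer!r} activation has unsupported rank {a.ndim}")
            means[layer].append(a)
    return {layer: np.concatenate(v) for layer, v in means.items()}


def all_channel_tuning_curves(model, layer: str, bank: list[GratingSpec]) -> pd.DataFrame:
    """Tuning curves for every channel of a layer at once.

    Returns a DataFrame indexed by frequency with one column per channel:
    each channel's activation averaged over spatial positions, then over all
    orientations and phases at each frequency.
    """
    a = _bank_layer_means(model, bank, [layer])[layer]
    freqs, groups = _frequency_groups(bank)
    rows = [a[groups[f]].mean(axis=0) for f in freqs]
    return pd.DataFrame(rows, index=pd.Index(freqs, name="frequency"))


def unit_tuning_curve(model, layer: str, channel: int, bank: list[GratingSpec]) -> TuningCurve:
    """Tuning curve of one named channel."""
    df = all_channel_tuning_curves(model, layer, bank)
    if not 0 <= channel < df.shape[1]:
        raise IndexError(f"layer {layer!r} has {df.shape[1]} channels; got {channel}")
    return TuningCurve(tuple(df.index), tuple(df.iloc[:, channel]))


def preferred_sf(curve: TuningCurve) -> tuple[float, bool]:
    """Argmax frequency and a tie flag; ties break toward the lowest frequency."""
    r = np.asarray(curve.mean_response)
    f = np.asarray(curve.frequencies)
    i = int(np.argmax(r))  # first (lowest-frequency) maximum
    tie = bool(np.sum(np.isclose(r, r[i], rtol=0, atol=1e-12)) > 1)
    return float(f[i]), tie


def _gauss_with_floor(logf, amp, mu, sd, floor):
    return floor + amp * np.exp(-0.5 * ((logf - mu) / sd) ** 2)


def tuning_bandwidth(curve: TuningCurve) -> BandwidthResult:
    """Gaussian fit of the (baseline-subtracted) curve on a log2 axis.

    The minimum response is subtracted, a Gaussian-plus-offset is fitted in
    log2 frequency, and the FWHM of the fitted Gaussian is reported both in
    octaves and relative to the peak frequency. All outputs are invariant to
    positive rescaling of the responses.
    """
    f = np.asarray(curve.frequencies, float)
    r = np.asarray(curve.mean_response, float)
    if f.size < 5:
        raise ValueError("need at least 5 probed frequencies")
    rng_dyn = r.max() - r.min()
    if rng_dyn <= 0 or not np.isfinite(rng_dyn):
        return BandwidthResult(float(f[0]), np.nan, np.nan, np.nan, reliable=False)
    y = (r - r.min()) / rng_dyn  # scale-invariant by construction
    logf = np.log2(f)
    mu0 = float(logf[np.argmax(y)])
    try:
        popt, _ = curve_fit(
            _gauss_with_floor,
            logf,
            y,
            p0=[1.0, mu0, 0.7, 0.0],
            bounds=([1e-9, logf.min() - 2, 1e-3, -1.0], [10.0, logf.max() + 2, 10.0, 1.0]),
            maxfev=20000,
        )
    except RuntimeError:
        return BandwidthResult(float(f[np.argmax(y)]), np.nan, np.nan, -np.inf, reliable=False)
    amp, mu, sd, floor = popt
    resid = y - _gauss_with_floor(logf, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else -np.inf
    fwhm_log = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sd
    peak = float(np.clip(2.0**mu, f.min(), f.max()))
    rel = float(2.0 ** (fwhm_log / 2.0) - 2.0 ** (-fwhm_log / 2.0))
    return BandwidthResult(peak, float(fwhm_log), rel, r2, reliable=bool(r2 >= 0.5))


def layerwise_tuning_summary(model, bank: list[GratingSpec], layers=None) -> pd.DataFrame:
    """Per-layer mean preferred SF and mean bandwidth over channels.

    Unreliable bandwidth fits are excluded from the bandwidth means and the
    excluded count reported. Deterministic for a fixed model and bank.
    """
    layers = list(layers) if layers is not None else list(model.conv_probe_layers)
    layer_means = _bank_layer_means(model, bank, layers)
    freqs, groups = _frequency_groups(bank)
    rows = []
    for layer in layers:
        a = layer_means[layer]
        df = pd.DataFrame(
            [a[groups[f]].mean(axis=0) for f in freqs], index=pd.Index(freqs, name="frequency")
        )
        prefs, fwhms, rels, n_bad = [], [], [], 0
        for c in range(df.shape[1]):
            curve = TuningCurve(tuple(df.index), tuple(df.iloc[:, c]))
            pf, _ = preferred_sf(curve)
            prefs.append(pf)
            bw = tuning_bandwidth(curve)
            if bw.reliable:
                fwhms.append(bw.fwhm_log)
                rels.append(bw.relative_bandwidth)
            else:
                n_bad += 1
        rows.append(
            {
                "layer": layer,
                "n_channels": df.shape[1],
                "mean_pref_sf": float(np.mean(prefs)),
                "mean_fwhm_log": float(np.mean(fwhms)) if fwhms else np.nan,
                "mean_relative_bandwidth": float(np.mean(rels)) if rels else np.nan,
                "n_unreliable": n_bad,
            }
        )
    return pd.DataFrame(rows).set_index("layer")
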