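"""Layer-wise relevance propagation for feedforward conv classifiers.

The relevance of the target class unit is set to 1 at the output and
redistributed backward layer by layer with the epsilon rule: each input's
share of a unit's relevance is proportional to its contribution to that
unit's pre-activation, with a small epsilon stabilizing near-zero
denominators. ReLU passes relevance through unchanged, max pooling routes it
to the winning input, average pooling splits it in proportion to the pooled
activations. At the input, negative relevance is zeroed and the heatmap is
rescaled linearly to [0, 1]. The epsilon rule conserves total relevance
approximately (bias terms and the epsilon absorb a little per layer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import _col2im

__all__ = ["RelevanceMap", "lrp_relevance", "lrp_input_relevance"]

_SUPPORTED = (nn.Conv2d, nn.ReLU, nn.MaxPool2, nn.AvgPool2, nn.GlobalAvgPool, nn.Flatten, nn.Linear)


@dataclass(frozen=True)
class RelevanceMap:
    """Per-pixel relevance in [0, 1] (max = 1 when any relevance is positive)."""

    values: np.ndarray
    raw: np.ndarray  # signed pre-normalization input relevance
    target_class: int


def _stab(z: np.ndarray, eps: float) -> np.ndarray:
    return z + eps * np.where(z >= 0, 1.0, -1.0)


def _backprop_layer(layer, x: np.ndarray, r: np.ndarray, eps: float) -> np.ndarray:
    """Redistribute relevance `r` at the layer's output back to its input `x`."""
    if isinstance(layer, nn.Linear):
        z = x @ layer.w.T + layer.b
        s = r / _stab(z, eps)
        return x * (s @ layer.w)
    if isinstance(layer, nn.Conv2d):
        z = layer.forward(x)
        s = (r / _stab(z, eps)).reshape(r.shape[0], r.shape[1], -1)
        wmat = layer.w.reshape(layer.w.shape[0], -1)
        dcols = np.einsum("of,nop->nfp", wmat, s)
        return x * _col2im(dcols, x.shape, layer.k, layer.pad)
    if isinstance(layer, nn.ReLU):
        return r
    if isinstance(layer, nn.MaxPool2):
        layer.forward(x)  # refresh switches for this input
        return layer.backward(r)
    if isinstance(layer, nn.AvgPool2):
        n, c, h, w = x.shape
        wsum = x.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
        s = r / _stab(wsum, eps)
        return x * np.repeat(np.repeat(s, 2, axis=2), 2, axis=3)
    if isinstance(layer, nn.GlobalAvgPool):
        denom = x.sum(axis=(2, 3))
        s = r / _stab(denom, eps)
        return x * s[:, :, None, None]
    if isinstance(layer, nn.Flatten):
        return r.reshape(x.shape)
    raise TypeError(f"unsupported layer type {type(layer).__name__}")


def lrp_input_relevance(model, image, target_class: int, eps: float = 1e-9) -> np.ndarray:
    """Signed input-pixel relevance (pre-normalization), summed over channels.

    `model` is a ModelHandle or a Sequential of conv/linear/pool/ReLU/flatten
    layers; other architectures are rejected.
    """
    net = model.net if hasattr(model, "net") else model
    for name, layer in net.layers:
        if not isinstance(layer, _SUPPORTED):
            raise TypeError(
                f"layer {name!r} ({type(layer).__name__}) is not a supported "
                "feedforward conv/linear/pool/ReLU layer"
            )
    x = np.asarray(image, dtype=float)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]

    inputs = []
    h = x
    for _, layer in net.layers:
        inputs.append(h)
        h = layer.forward(h)
    logits = h
    if not 0 <= target_class < logits.shape[1]:
        raise IndexError(f"target_class {target_class} outside {logits.shape[1]} outputs")
    r = np.zeros_like(logits)
    r[:, target_class] = 1.0
    for (_, layer), xin in zip(reversed(net.layers), reversed(inputs)):
        r = _backprop_layer(layer, xin, r, eps)
    return r[0].sum(axis=0)  # (H, W), signed


def lrp_relevance(model, image, target_class: int, eps: float = 1e-9) -> RelevanceMap:
    """Heatmap of the target class's decision evidence over input pixels.

    Negative relevance is zeroed; the remaining map is linearly rescaled so
    its maximum is 1 (left all-zero when no pixel carries positive
    relevance).
    """
    raw = lrp_input_relevance(model, image, target_class, eps=eps)
    pos = np.maximum(raw, 0.0)
    top = pos.max()
    values = pos / top if top > 0 else pos
    return RelevanceMap(values=values, raw=raw, target_class=int(target_class))
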