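"""Representational similarity analysis.

Two systems (a model layer and a neural area, say) are compared not response
by response but through the geometry of their condition-wise response
patterns: each yields a condition x condition Pearson correlation matrix
(RDM), and the similarity of the two systems is the Pearson correlation of
those matrices with the main diagonal excluded. Correlations destined for
averaging or testing are variance-stabilized with Fisher's r-to-z. Across a
model's layers, the peak similarity and the layer attaining it summarize the
model-area correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResponseMatrix",
    "RDM",
    "RSAResult",
    "condition_matrix",
    "rdm_pearson",
    "rsa_similarity",
    "fisher_z",
    "model_area_correspondence",
]


@dataclass(frozen=True)
class ResponseMatrix:
    """Condition x feature response table with ordered condition ids."""

    condition_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.condition_ids):
            raise ValueError("values must be 2-D with one row per condition id")
        if v.shape[0] < 3:
            raise ValueError("need at least 3 conditions")
        if not np.all(np.isfinite(v)):
            raise ValueError("response table contains non-finite values")
        object.__setattr__(self, "condition_ids", tuple(self.condition_ids))
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class RDM:
    """Condition x condition Pearson similarity matrix (unit diagonal)."""

    condition_ids: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.condition_ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape must match the condition set")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("RDM diagonal must be 1")
        if m.min() < -1 - 1e-10 or m.max() > 1 + 1e-10:
            raise ValueError("RDM entries must lie in [-1, 1]")
        object.__setattr__(self, "condition_ids", tuple(self.condition_ids))
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class RSAResult:
    """Layer-wise model-area similarity with the peak layer singled out."""

    per_layer_r: dict
    per_layer_z: dict
    peak_layer: str
    peak_r: float


def condition_matrix(responses, grouping=None, condition_ids=None) -> ResponseMatrix:
    """Build a condition x feature table, averaging within groups.

    `responses` is (n_items, n_features); `grouping` assigns each item a
    condition label (None means one condition per item). Rows are ordered by
    first appearance of each condition unless `condition_ids` fixes an order.
    """
    r = np.asarray(responses, dtype=float)
    if r.ndim != 2:
        r = r.reshape(r.shape[0], -1)
    if grouping is None:
        ids = condition_ids if condition_ids is not None else list(range(r.shape[0]))
        return ResponseMatrix(tuple(ids), r)
    grouping = list(grouping)
    if len(grouping) != r.shape[0]:
        raise ValueError("grouping length must match the number of items")
    if condition_ids is None:
        condition_ids = list(dict.fromkeys(grouping))
    rows = [r[[i for i, g in enumerate(grouping) if g == cid]].mean(axis=0) for cid in condition_ids]
    return ResponseMatrix(tuple(condition_ids), np.stack(rows))


def rdm_pearson(m: ResponseMatrix) -> RDM:
    """Pairwise Pearson correlation of condition response vectors."""
    v = m.values
    sd = v.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(
            f"zero-variance response vector for condition(s) "
            f"{[m.condition_ids[i] for i in bad]}: correlation undefined"
        )
    c = np.corrcoef(v)
    np.fill_diagonal(c, 1.0)
    return RDM(m.condition_ids, np.clip((c + c.T) / 2.0, -1.0, 1.0))


def rsa_similarity(a: RDM, b: RDM) -> float:
    """Pearson correlation of two RDMs over the strict upper triangle.

    The diagonal is excluded and each unordered condition pair counted once;
    both RDMs must share the same condition set and order.
    """
    if a.condition_ids != b.condition_ids:
        raise ValueError("RDMs must share the same condition set and order")
    iu = np.triu_indices(len(a.condition_ids), k=1)
    x, y = a.matrix[iu], b.matrix[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate RDM: off-diagonal entries have zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r, clip: float = 1.0 - 1e-12):
    """Fisher r-to-z transform z = atanh(r); |r| >= 1 is clipped just inside."""
    r = np.asarray(r, dtype=float)
    out = np.arctanh(np.clip(r, -clip, clip))
    return float(out) if out.ndim == 0 else out


def model_area_correspondence(
    model,
    stimuli,
    target: RDM,
    grouping=None,
    layers=None,
) -> RSAResult:
    """Layer-wise RSA of a model against a target RDM.

    For each probed layer, activations to `stimuli` are flattened,
    condition-averaged under `grouping`, turned into an RDM and correlated
    with `target`; the peak layer and its r are recorded.
    """
    layers = list(layers) if layers is not None else list(model.probe_layers)
    acts = model.activations(np.asarray(stimuli))
    per_r: dict[str, float] = {}
    for layer in layers:
        if layer not in acts:
            raise KeyError(f"model has no layer named {layer!r}")
        cm = condition_matrix(
            acts[layer].reshape(acts[layer].shape[0], -1),
            grouping=grouping,
            condition_ids=target.condition_ids if grouping is not None else None,
        )
        if grouping is None:
            cm = ResponseMatrix(target.condition_ids, cm.values)
        per_r[layer] = rsa_similarity(rdm_pearson(cm), target)
    peak_layer = max(per_r, key=per_r.get)
    return RSAResult(
        per_layer_r=per_r,
        per_layer_z={k: fisher_z(v) for k, v in per_r.items()},
        peak_layer=peak_layer,
        peak_r=per_r[peak_layer],
    )
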