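"""Shared fixtures: small corpora, trained tiny models, the 5-seed regime battery.

The regime battery (5 seeds x {clear, strong_blur}) is the most expensive
object in the suite; it is built once per session and shared by every test
that compares training regimes.
"""

from __future__ import annotations

import numpy as np
import pytest

import blurvision as bv
from blurvision.behavior import corrupt

N_BATTERY_SEEDS = 5
BATTERY_REGIMES = ("clear", "strong_blur")


@pytest.fixture(scope="session")
def small_spec():
    return bv.ShapeTexSpec(n_shape_classes=4, n_texture_classes=4, image_size=64,
                           samples_per_class=20, seed=100)


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return bv.generate_shapetex(small_spec)


@pytest.fixture(scope="session")
def clear_model(small_corpus):
    """One clear-regime tiny CNN, shared by interface/probe tests."""
    return bv.train_reference_models(small_corpus, "clear", bv.TrainingConfig(seed=0))


@pytest.fixture(scope="session")
def heldout_set():
    corpus = bv.generate_shapetex(
        bv.ShapeTexSpec(4, 4, 64, samples_per_class=10, seed=900)
    )
    x = np.stack([im.pixels for im in corpus])
    y = np.array([im.shape_label for im in corpus])
    return x, y


@pytest.fixture(scope="session")
def regime_battery():
    """Per (seed, regime): trained model plus the evaluation battery outputs.

    For each of 5 seeds, a fresh corpus/conflict/held-out trio is generated
    and a clear and a strong-blur model trained; each model is probed for
    layer-wise preferred spatial frequency, shape bias on cue-conflict
    hybrids, and accuracy under Gaussian noise severities 3-5 and under
    sigma=4 blur.
    """
    bank = bv.probe_bank(64)
    out = {}
    for seed in range(N_BATTERY_SEEDS):
        spec = bv.ShapeTexSpec(4, 4, 64, samples_per_class=20, seed=100 + seed)
        corpus = bv.generate_shapetex(spec)
        conflict = bv.generate_cue_conflict(spec, n_per_pair=3)
        held = bv.generate_shapetex(bv.ShapeTexSpec(4, 4, 64, 10, seed=900 + seed))
        hx = np.stack([im.pixels for im in held])
        hy = np.array([im.shape_label for im in held])
        for regime in BATTERY_REGIMES:
            model = bv.train_reference_models(corpus, regime, bv.TrainingConfig(seed=seed))
            summary = bv.layerwise_tuning_summary(model, bank)
            sb = bv.shape_bias(bv.classify_cue_conflict(model, conflict))
            noise_acc = {}
            for sev in (3, 4, 5):
                xs = np.stack(
                    [corrupt(im, "gaussian_noise", sev, np.random.default_rng(55 + sev))
                     for im in hx]
                )
                noise_acc[sev] = float((model.predict(xs) == hy).mean())
            blurred = np.stack([bv.apply_gaussian_blur(im, 4.0) for im in hx])
            out[(seed, regime)] = {
                "model": model,
                "pref_sf": summary["mean_pref_sf"].to_dict(),
                "shape_bias": sb.score,
                "noise_acc": noise_acc,
                "blur4_acc": float((model.predict(blurred) == hy).mean()),
                "clean_acc": float((model.predict(hx) == hy).mean()),
            }
    return out
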