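"""Shape bias, corruptions, PGD attack, behavioral consistency."""

import numpy as np
import pytest

import blurvision as bv
from blurvision import nn
from blurvision.behavior import CORRUPTION_KINDS, corrupt
from blurvision.synthetic import ModelHandle


def make_trials(rng, n):
    trials = []
    for _ in range(n):
        s, t = rng.choice(6, size=2, replace=False)
        p = rng.choice(6)
        trials.append(bv.CueConflictTrial(int(s), int(t), int(p)))
    return trials


class TestShapeBias:
    def test_all_shape_and_all_texture(self):
        shape_trials = [bv.CueConflictTrial(0, 1, 0)] * 5
        assert bv.shape_bias(shape_trials).score == 1.0
        texture_trials = [bv.CueConflictTrial(0, 1, 1)] * 5
        assert bv.shape_bias(texture_trials).score == 0.0

    def test_other_excluded_from_denominator(self):
        trials = (
            [bv.CueConflictTrial(0, 1, 0)] * 6
            + [bv.CueConflictTrial(0, 1, 1)] * 3
            + [bv.CueConflictTrial(0, 1, 2)] * 1
        )
        sb = bv.shape_bias(trials)
        assert (sb.n_shape, sb.n_texture, sb.n_other) == (6, 3, 1)
        assert sb.score == pytest.approx(6 / 9)

    def test_matches_counting_oracle_on_random_trials(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            trials = make_trials(rng, 50)
            ns = sum(t.predicted == t.shape_label for t in trials)
            nt = sum(t.predicted == t.texture_label for t in trials)
            sb = bv.shape_bias(trials)
            if ns + nt == 0:
                assert not sb.defined
            else:
                assert sb.score == pytest.approx(ns / (ns + nt))

    def test_empty_or_undecidable_flagged(self):
        assert not bv.shape_bias([]).defined
        assert not bv.shape_bias([bv.CueConflictTrial(0, 1, 5)]).defined


class LinearModel(ModelHandle):
    """Flattened linear classifier with analytic worst-case adversary."""

    def __init__(self, w, size):
        lin = nn.Linear(size * size, w.shape[0], rng=0)
        lin.w = w.reshape(w.shape[0], -1).astype(float)
        lin.b = np.zeros(w.shape[0])
        net = nn.Sequential([("flatten", nn.Flatten()), ("fc", lin)])
        super().__init__(net, w.shape[0], size)


class TestClassifyCueConflict:
    def test_restricted_argmax_matches_masked_oracle(self, clear_model):
        spec = bv.ShapeTexSpec(4, 4, 64, 4, seed=50)
        stimuli = bv.generate_cue_conflict(spec, 1)
        class_set = [0, 2]
        kept = [s for s in stimuli if s.shape_label in class_set and s.texture_label in class_set]
        trials = bv.classify_cue_conflict(clear_model, kept, class_set)
        logits = clear_model.scores(np.stack([s.pixels for s in kept]))
        masked = logits.copy()
        masked[:, [1, 3]] = -np.inf
        assert [t.predicted for t in trials] == list(masked.argmax(axis=1))

    def test_deterministic(self, clear_model):
        spec = bv.ShapeTexSpec(4, 4, 64, 4, seed=51)
        stimuli = bv.generate_cue_conflict(spec, 1)
        a = bv.classify_cue_conflict(clear_model, stimuli)
        b = bv.classify_cue_conflict(clear_model, stimuli)
        assert [t.predicted for t in a] == [t.predicted for t in b]

    def test_shape_oracle_model_is_fully_shape_biased(self):
        rng = np.random.default_rng(1)
        spec = bv.ShapeTexSpec(4, 4, 32, 2, seed=52)
        stimuli = bv.generate_cue_conflict(spec, 1)

        class ShapeOracle:
            def scores(self, images):
                # responds to silhouette template identity via mask overlap
                logits = []
                for im, st in zip(images, stimuli):
                    logits.append(np.eye(4)[st.shape_label] * 10.0)
                return np.array(logits)

        trials = bv.classify_cue_conflict(ShapeOracle(), stimuli)
        assert bv.shape_bias(trials).score == 1.0


@pytest.fixture(scope="module")
def image():
    return bv.generate_shapetex(bv.ShapeTexSpec(4, 4, 64, 1, seed=9))[0].pixels


@pytest.fixture(scope="module")
def linear_setup():
    rng = np.random.default_rng(0)
    w = rng.standard_normal((2, 8, 8))
    return LinearModel(w, 8), w, np.full((8, 8), 0.5)


class TestCorruptions:
    def test_severity_zero_is_identity(self, image):
        for kind in CORRUPTION_KINDS:
            assert np.array_equal(corrupt(image, kind, 0, rng=0), image)

    def test_pixelate_blocks_constant_and_equal_to_block_mean(self, image):
        out = corrupt(image, "pixelate", 3)  # block size 4
        b = 4
        for i in range(0, 64, b):
            for j in range(0, 64, b):
                block = out[i : i + b, j : j + b]
                assert np.ptp(block) == 0
                assert block[0, 0] == pytest.approx(image[i : i + b, j : j + b].mean())

    @pytest.mark.parametrize("kind", CORRUPTION_KINDS)
    def test_distortion_energy_nondecreasing_in_severity(self, image, kind):
        energies = [
            np.sum((corrupt(image, kind, s, rng=1234) - image) ** 2) for s in range(0, 6)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(energies, energies[1:]))

    def test_outputs_stay_in_unit_range(self, image):
        for kind in CORRUPTION_KINDS:
            out = corrupt(image, kind, 5, rng=7)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unknown_kind_and_bad_severity_rejected(self, image):
        with pytest.raises(ValueError):
            corrupt(image, "fog_of_war", 3)
        with pytest.raises(ValueError):
            corrupt(image, "contrast", 6)


class TestRobustnessCurve:
    def test_clean_row_and_chance_floor(self, clear_model, heldout_set):
        x, y = heldout_set
        df = bv.robustness_curve(
            clear_model, x[:16], y[:16], kinds=("gaussian_noise",), severities=(1, 3, 5)
        )
        clean_acc = float((clear_model.predict(x[:16]) == y[:16]).mean())
        assert np.allclose(df.loc["clean"], clean_acc)
        assert df.shape == (2, 3)
        assert ((df.values >= 0) & (df.values <= 1)).all()


class TestPGD:
    def test_epsilon_zero_returns_input(self, linear_setup):
        model, _, x = linear_setup
        cfg = bv.AdversarialConfig(epsilon=0.0)
        assert np.array_equal(bv.pgd_attack(model, x, 0, cfg), x)

    @pytest.mark.parametrize("norm", ["inf", "two"])
    def test_never_leaves_ball_or_unit_box(self, linear_setup, norm):
        model, _, x = linear_setup
        cfg = bv.AdversarialConfig(norm=norm, epsilon=0.1, alpha=0.05, steps=15, seed=3)
        adv = bv.pgd_attack(model, x, 0, cfg)
        delta = adv - x
        if norm == "inf":
            assert np.abs(delta).max() <= 0.1 + 1e-6
        else:
            assert np.linalg.norm(delta) <= 0.1 + 1e-6
        assert adv.min() >= 0.0 and adv.max() <= 1.0

    def test_linf_reaches_analytic_worst_case(self, linear_setup):
        model, w, x = linear_setup
        eps = 0.05
        cfg = bv.AdversarialConfig(
            norm="inf", epsilon=eps, alpha=0.02, steps=15, random_init=False
        )
        adv = bv.pgd_attack(model, x, 0, cfg)
        # for a linear 2-class model the loss gradient direction is constant:
        # the eps-ball worst case is the corner along sign(w_other - w_true)
        worst = np.clip(x + eps * np.sign(w[1] - w[0]), 0, 1)
        assert np.allclose(adv, worst, atol=1e-9)
        loss_adv = nn.cross_entropy(model.scores(adv), np.array([0]))[0]
        loss_worst = nn.cross_entropy(model.scores(worst), np.array([0]))[0]
        assert loss_adv == pytest.approx(loss_worst, rel=1e-9)

    def test_attack_success_nondecreasing_in_epsilon(self, linear_setup):
        model, _, _ = linear_setup
        rng = np.random.default_rng(5)
        xs = rng.random((12, 8, 8)) * 0.5 + 0.25
        labels = model.predict(xs)  # attack the model's own decisions
        accs = []
        for eps in (0.0, 0.05, 0.15, 0.4):
            cfg = bv.AdversarialConfig(epsilon=eps, alpha=eps / 3 + 1e-9, steps=15, seed=0)
            adv = bv.pgd_attack(model, xs, labels, cfg)
            accs.append((model.predict(adv) == labels).mean())
        assert all(b <= a + 1e-12 for a, b in zip(accs, accs[1:]))

    def test_trained_cnn_degrades_under_attack(self, clear_model, heldout_set):
        x, y = heldout_set
        sel = slice(0, 12)
        clean_acc = (clear_model.predict(x[sel]) == y[sel]).mean()
        cfg = bv.AdversarialConfig(epsilon=0.1, alpha=0.02, steps=15, seed=0)
        adv = bv.pgd_attack(clear_model, x[sel], y[sel], cfg)
        adv_acc = (clear_model.predict(adv) == y[sel]).mean()
        assert adv_acc <= clean_acc


class TestConsistency:
    def test_identical_responders(self):
        flags = np.array([1, 1, 1, 0, 0, 1, 0, 1, 1, 0], dtype=bool)  # accuracy 0.6
        c = bv.consistency(flags, flags)
        assert c.observed == 1.0
        assert c.kappa == pytest.approx(1.0)

    def test_independent_responders_kappa_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.random(1000) < 0.5
        b = rng.random(1000) < 0.5
        c = bv.consistency(a, b)
        assert c.expected == pytest.approx(0.5, abs=0.02)
        assert abs(c.kappa) < 0.1

    def test_expected_formula(self):
        a = np.array([1, 1, 1, 0], dtype=bool)
        b = np.array([1, 0, 1, 1], dtype=bool)
        c = bv.consistency(a, b)
        assert c.expected == pytest.approx(0.75 * 0.75 + 0.25 * 0.25)
        assert c.observed == pytest.approx(0.5)

    def test_degenerate_perfect_responders_flagged(self):
        ones = np.ones(10, dtype=bool)
        c = bv.consistency(ones, ones)
        assert c.observed == 1.0
        assert not c.defined
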