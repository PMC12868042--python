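import math

import numpy as np
import pytest

from phantomforge.nn import (
    GanConfig,
    ImageBuffer,
    LossBreakdown,
    load_checkpoint,
    loss_adversarial,
    loss_cycle,
    loss_discriminator,
    loss_gdl,
    loss_generator_total,
    loss_intensity,
    predict_volume,
    save_checkpoint,
    train,
)
from phantomforge.nn.training import init_bundle


class TestLosses:
    def test_adversarial_closed_forms(self):
        assert loss_adversarial(np.ones((1, 4, 4))) == pytest.approx(0.0, abs=1e-6)
        assert loss_adversarial(np.full((1, 4, 4), 0.5)) == pytest.approx(math.log(2), abs=1e-9)
        assert loss_adversarial(np.full((1, 2, 2), 0.1)) > loss_adversarial(
            np.full((1, 2, 2), 0.9))

    def test_cycle_l1_closed_forms(self, rng):
        x = rng.normal(size=(1, 8, 8))
        assert loss_cycle(x, x) == 0.0
        assert loss_cycle(x, x + 0.25) == pytest.approx(0.25)
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        b = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert loss_cycle(a, b) == pytest.approx(0.5)

    def test_intensity_matches_brute_force(self, rng):
        x, g = rng.normal(size=(1, 6, 6)), rng.normal(size=(1, 6, 6))
        brute = np.mean([abs(a - b) for a, b in zip(x.ravel(), g.ravel())])
        assert loss_intensity(x, g) == pytest.approx(brute, abs=1e-12)

    def test_gdl_zero_for_identical_and_shifted(self, rng):
        x = rng.normal(size=(1, 8, 8))
        assert loss_gdl(x, x) == 0.0
        assert loss_gdl(x, x + 3.7) == pytest.approx(0.0, abs=1e-12)

    def test_gdl_two_by_two_hand_case(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0]])
        y = np.zeros((2, 2))
        # four gradient terms, summed penalty 2, mean over 4 valid positions
        assert loss_gdl(x, y) == pytest.approx(2.0 / 4.0)

    def test_generator_total_weighted_sum(self):
        parts = LossBreakdown(adv=1, cyc_fwd=1, cyc_bwd=1, intensity=1, gdl=1)
        cfg = GanConfig(lambda_cyc=10, lambda_int=0.5, lambda_gdl=0.5, seed=0)
        assert loss_generator_total(parts, cfg) == pytest.approx(22.0)
        cfg_ct = GanConfig(lambda_cyc=10, lambda_int=1, lambda_gdl=1, seed=0)
        assert loss_generator_total(parts, cfg_ct) == pytest.approx(23.0)
        assert loss_generator_total(LossBreakdown(), cfg) == 0.0

    def test_discriminator_closed_forms(self):
        ones, halves = np.ones((1, 3, 3)), np.full((1, 3, 3), 0.5)
        assert loss_discriminator(ones, 1 - ones) == pytest.approx(0.0, abs=1e-6)
        assert loss_discriminator(halves, halves) == pytest.approx(math.log(2), abs=1e-9)

    def test_discriminator_halving(self, rng):
        d_real = rng.uniform(0.1, 0.9, size=(1, 4, 4))
        d_fake = rng.uniform(0.1, 0.9, size=(1, 4, 4))
        unhalved = np.mean(-np.log(d_real)) + np.mean(-np.log(1 - d_fake))
        assert loss_discriminator(d_real, d_fake) == pytest.approx(unhalved / 2)


class TestBuffer:
    def test_first_push_returned_while_filling(self, rng):
        buf = ImageBuffer(1, rng)
        img = np.ones((1, 2, 2))
        np.testing.assert_array_equal(buf.push_sample(img), img)

    def test_capacity_bound(self, rng):
        buf = ImageBuffer(5, rng)
        for i in range(50):
            buf.push_sample(np.full((1, 2, 2), float(i)))
        assert len(buf) == 5

    def test_historical_return_fraction_is_half(self):
        buf = ImageBuffer(10, np.random.default_rng(7))
        for i in range(10):
            buf.push_sample(np.full((1,), float(i)))
        historical = 0
        n = 10_000
        for i in range(n):
            val = float(i + 100)
            out = buf.push_sample(np.full((1,), val))
            if out[0] != val:
                historical += 1
        assert historical / n == pytest.approx(0.5, abs=0.02)


def _toy_domains(n=4, size=32, seed=0):
    rng = np.random.default_rng(seed)
    xs = [np.clip(rng.normal(0, 0.3, size=(size, size)), -1, 1) for _ in range(n)]
    ys = [np.clip(x + rng.normal(0, 0.2, size=(size, size)), -1, 1) for x in xs]
    return xs, ys


class TestTraining:
    def test_zero_epochs_returns_initialized_bundle(self):
        xs, ys = _toy_domains()
        cfg = GanConfig(n_res_blocks=1, base_filters=4, input_size=32, epochs=0, seed=0)
        bundle, history = train(xs, ys, cfg)
        assert history == []
        assert bundle.G.forward(xs[0][None]).shape == (1, 32, 32)

    def test_empty_domain_rejected(self):
        cfg = GanConfig(epochs=1, seed=0)
        with pytest.raises(ValueError):
            train([], [np.zeros((32, 32))], cfg)

    def test_total_loss_recombines_from_parts(self):
        xs, ys = _toy_domains(n=2)
        cfg = GanConfig(n_res_blocks=1, base_filters=4, input_size=32, epochs=1,
                        lambda_int=0.5, lambda_gdl=0.5, seed=1)
        _, history = train(xs, ys, cfg)
        rec = history[0]
        for side in ("G", "F"):
            recombined = (
                cfg.lambda_adv * rec[f"{side}_adv"]
                + cfg.lambda_cyc * (rec[f"{side}_cyc_fwd"] + rec[f"{side}_cyc_bwd"])
                + cfg.lambda_int * rec[f"{side}_intensity"]
                + cfg.lambda_gdl * rec[f"{side}_gdl"]
            )
            assert rec[f"{side}_total"] == pytest.approx(recombined, abs=1e-6)

    def test_training_is_bit_reproducible(self):
        xs, ys = _toy_domains(n=2)
        cfg = GanConfig(n_res_blocks=1, base_filters=4, input_size=32, epochs=2, seed=3)
        b1, h1 = train(xs, ys, cfg)
        b2, h2 = train(xs, ys, cfg)
        assert h1 == h2
        for p1, p2 in zip(b1.G.params(), b2.G.params()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_checkpoint_round_trip(self, tmp_path):
        xs, ys = _toy_domains(n=2)
        cfg = GanConfig(n_res_blocks=1, base_filters=4, input_size=32, epochs=1, seed=4)
        bundle, _ = train(xs, ys, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(bundle, path)
        loaded = load_checkpoint(path)
        assert loaded.cfg == cfg
        x = xs[0][None]
        np.testing.assert_array_equal(loaded.G.forward(x), bundle.G.forward(x))


class _IdentityGenerator:
    """Test hook: a pass-through 'network' for plumbing checks."""

    def __init__(self):
        self.calls = 0

    def forward(self, x):
        self.calls += 1
        return x


class TestPredictVolume:
    def test_identity_generator_round_trips_volume(self, phantom_ct):
        gen = _IdentityGenerator()
        out = predict_volume(gen, phantom_ct, patch_size=64, stride=32, input_size=64)
        # no resize (patch==input size) so the plumbing is exact up to float32
        np.testing.assert_allclose(out.data, phantom_ct.data, atol=0.15)
        assert out.shape == phantom_ct.shape

    def test_output_within_ct_range(self, phantom_ct):
        cfg = GanConfig(n_res_blocks=1, base_filters=4, input_size=32, seed=5)
        bundle = init_bundle(cfg)
        out = predict_volume(bundle.G, phantom_ct, patch_size=48, stride=48, input_size=32)
        assert out.data.min() >= -1000.0 and out.data.max() <= 1047.0

    def test_patch_budget_nine_per_slice(self):
        from phantomforge.volumes import CT_RANGE, Modality, Volume

        vol = Volume(np.zeros((5, 348, 348), np.float32), (2, 1.0625, 1.0625),
                     modality=Modality.CT, intensity_range=CT_RANGE)
        gen = _IdentityGenerator()
        predict_volume(gen, vol, patch_size=220, stride=64, input_size=256)
        assert gen.calls == 45  # 9 patches x 5 slices
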