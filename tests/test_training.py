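import csv
import json

import numpy as np
import pytest

from desmoke import smoke_sim, training
from desmoke.losses import LossWeights, TranslationDirection
from desmoke.networks import DiscriminatorSpec, GeneratorSpec

TINY_GEN = GeneratorSpec(n_res_blocks=1, base_width=4)
TINY_DISC = DiscriminatorSpec(n_layers=1, base_width=4)


def tiny_config(**kw):
    defaults = dict(batch_size=2, crop=32, seed=5, gen_spec=TINY_GEN,
                    disc_spec=TINY_DISC, epochs_const=1, epochs_decay=1)
    defaults.update(kw)
    return training.TrainConfig(**defaults)


def random_batches(seed, n=2, size=32):
    rng = np.random.default_rng(seed)
    return (rng.random((n, size, size, 3)).astype(np.float32),
            rng.random((n, size, size, 3)).astype(np.float32))


class TestSchedule:
    def test_constant_then_linear_to_zero(self):
        cfg = training.TrainConfig(seed=0)
        assert training.lr_at_epoch(cfg, 10) == pytest.approx(0.002)
        assert training.lr_at_epoch(cfg, 49) == pytest.approx(0.002)
        assert training.lr_at_epoch(cfg, 75) == pytest.approx(0.001)
        assert training.lr_at_epoch(cfg, 100) == 0.0

    def test_continuous_at_boundary(self):
        cfg = training.TrainConfig(seed=0)
        assert training.lr_at_epoch(cfg, 50) == pytest.approx(0.002)

    def test_out_of_range_rejected(self):
        cfg = training.TrainConfig(seed=0)
        with pytest.raises(ValueError):
            training.lr_at_epoch(cfg, -1)
        with pytest.raises(ValueError):
            training.lr_at_epoch(cfg, 101)


class TestTrainStep:
    def test_first_step_deterministic_under_seed(self):
        bc, bh = random_batches(1)
        br1 = training.train_step(training.TrainState(tiny_config()), bc, bh)
        br2 = training.train_step(training.TrainState(tiny_config()), bc, bh)
        assert br1 == br2

    def test_breakdown_sums_to_total(self):
        bc, bh = random_batches(2)
        cfg = tiny_config()
        br = training.train_step(training.TrainState(cfg), bc, bh)
        w = cfg.weights
        assert br.total == pytest.approx(
            br.adversarial_g + br.adversarial_f + w.lambda_cyc * br.cycle
            + w.alpha * br.ic + w.beta * br.dc)
        assert all(v >= 0 for v in (br.adversarial_g, br.adversarial_f,
                                    br.cycle, br.ic, br.dc))

    def test_weighted_objective_differs_by_exactly_alpha_ic_beta_dc(self):
        bc, bh = random_batches(3)
        full = training.train_step(
            training.TrainState(tiny_config()), bc, bh)
        base = training.train_step(
            training.TrainState(tiny_config(weights=LossWeights(0.0, 0.0))),
            bc, bh)
        # identical seeds -> identical pre-update nets -> identical components
        assert full.cycle == pytest.approx(base.cycle, abs=1e-7)
        assert full.total - base.total == pytest.approx(
            3.0 * full.ic + 0.05 * full.dc, abs=1e-5)


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("data")
    smoke_sim.make_dataset(8, 48, {"medium": 1.0}, seed=3, out_dir=root)
    return root


class TestFit:
    def test_smoke_run_writes_checkpoint_and_log(self, dataset, tmp_path):
        cfg = tiny_config()
        paths = training.fit(cfg, dataset, tmp_path / "run")
        assert paths["checkpoint"].exists()
        with open(paths["log"]) as fh:
            rows = list(csv.reader(fh))
        assert rows[0][:2] == ["epoch", "lr"]
        assert len(rows) == 1 + 2  # header + 2 epochs
        assert float(rows[1][1]) == pytest.approx(
            training.lr_at_epoch(cfg, 0))
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["seed"] == cfg.seed

    def test_checkpoint_sidecar_records_scheduled_lr(self, dataset, tmp_path):
        cfg = tiny_config()
        paths = training.fit(cfg, dataset, tmp_path / "run2")
        sidecar = json.loads(
            paths["checkpoint"].with_suffix(".json").read_text())
        epoch = sidecar["extra"]["epoch"]
        assert sidecar["extra"]["lr"] == pytest.approx(
            training.lr_at_epoch(cfg, epoch))

    def test_empty_domain_rejected_before_training(self, tmp_path):
        (tmp_path / "trainA").mkdir()
        (tmp_path / "trainB").mkdir()
        with pytest.raises(ValueError, match="no images"):
            training.fit(tiny_config(), tmp_path, tmp_path / "out")

    def test_translate_shape_and_determinism(self, dataset, tmp_path, rng):
        paths = training.fit(tiny_config(), dataset, tmp_path / "run3")
        img = rng.random((48, 48, 3))
        a = training.translate(paths["checkpoint"], img,
                               TranslationDirection.HAZY_TO_CLEAR)
        b = training.translate(paths["checkpoint"], img,
                               TranslationDirection.HAZY_TO_CLEAR)
        assert a.shape == img.shape
        assert np.array_equal(a, b)
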