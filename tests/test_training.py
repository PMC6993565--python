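"""Balanced sampling, augmentation, losses, learning-rate schedule, and
short training runs."""

import numpy as np
import pytest

from tumorloc import nncore as nc
from tumorloc.networks import DeepMedicConfig, UNet3DConfig
from tumorloc.phantom import PhantomSpec, generate_phantom, subject_seed
from tumorloc.training import (TrainConfig, TrainingError, augment,
                               epochs_to_threshold, hard_negative_ce_loss,
                               lr_at_epoch, sample_balanced_centers,
                               subject_from_phantom, train_model)


# ------------------------------------------------------------ sampling


def test_balanced_sampler_fraction_within_binomial_ci():
    rng = np.random.default_rng(0)
    lab = np.zeros((40, 40, 40), dtype=np.int16)
    lab[10:20, 10:20, 10:20] = 2
    mask = np.ones_like(lab, dtype=bool)
    centers = sample_balanced_centers(lab, 10_000, rng, mask)
    frac = (lab[tuple(centers.T)] != 0).mean()
    assert frac == pytest.approx(0.5, abs=0.02)


def test_balanced_sampler_degenerate_cases():
    rng = np.random.default_rng(1)
    all_lesion = np.full((8, 8, 8), 2, dtype=np.int16)
    c = sample_balanced_centers(all_lesion, 50, rng)
    assert (all_lesion[tuple(c.T)] != 0).all()
    no_lesion = np.zeros((8, 8, 8), dtype=np.int16)
    c = sample_balanced_centers(no_lesion, 50, rng)
    assert (no_lesion[tuple(c.T)] == 0).all()


# ---------------------------------------------------------- augmentation


class _ForcedRng:
    """Wraps a Generator, forcing the flip draws."""

    def __init__(self, flips):
        self._flips = np.asarray(flips, dtype=float)

    def random(self, n):
        return np.where(self._flips, 0.0, 1.0)

    def normal(self, loc, scale, size):
        return np.zeros(size)


def test_augment_identity_when_no_flips_no_noise():
    x = np.random.default_rng(0).normal(size=(3, 5, 5, 5))
    t = np.random.default_rng(1).integers(0, 5, size=(5, 5, 5))
    out = augment([x, t], _ForcedRng([0, 0, 0]), image_channels=(3, 0),
                  noise_sd=0.0)
    np.testing.assert_array_equal(out[0], x)
    np.testing.assert_array_equal(out[1], t)


def test_augment_double_flip_is_identity():
    x = np.random.default_rng(2).normal(size=(2, 4, 4, 4))
    once = augment([x], _ForcedRng([1, 1, 0]), image_channels=(0,), noise_sd=0.0)[0]
    twice = augment([once], _ForcedRng([1, 1, 0]), image_channels=(0,), noise_sd=0.0)[0]
    np.testing.assert_array_equal(twice, x)


def test_augment_preserves_target_histogram_and_masks():
    rng = np.random.default_rng(3)
    img = rng.normal(size=(4, 6, 6, 6))
    atlas = (rng.random((2, 6, 6, 6)) < 0.5).astype(float)
    t = rng.integers(0, 5, size=(6, 6, 6))
    stack = np.concatenate([img, atlas])
    out_stack, out_t = augment([stack, t], rng, image_channels=(4, 0),
                               noise_sd=0.5)
    np.testing.assert_array_equal(np.bincount(out_t.ravel(), minlength=5),
                                  np.bincount(t.ravel(), minlength=5))
    # atlas channels (beyond the 4 image channels) stay exactly binary
    assert set(np.unique(out_stack[4:])) <= {0.0, 1.0}


# ---------------------------------------------------------------- losses


def test_hard_negative_loss_equals_plain_ce_when_all_positive():
    rng = np.random.default_rng(4)
    logits = rng.normal(size=(1, 5, 4, 4, 4))
    targets = np.full((1, 4, 4, 4), 2, dtype=np.int64)
    hn, _ = hard_negative_ce_loss(logits, targets)
    plain, _ = nc.softmax_cross_entropy(logits, targets)
    assert hn == pytest.approx(plain)


def test_hard_negative_selection_matches_sort_oracle():
    rng = np.random.default_rng(5)
    logits = rng.normal(size=(1, 5, 1010, 1, 1))
    targets = np.zeros((1, 1010, 1, 1), dtype=np.int64)
    targets[0, :10] = 2  # 10 positives, 1000 negatives -> select 30 negatives
    loss, _ = hard_negative_ce_loss(logits, targets, ratio=3)
    lsm = nc.log_softmax(logits, axis=1)
    nll = -np.take_along_axis(lsm, targets[:, None], axis=1)[:, 0].ravel()
    neg_sorted = np.sort(nll[10:])[::-1]
    expected = (nll[:10].sum() + neg_sorted[:30].sum()) / 40
    assert loss == pytest.approx(expected)


def test_hard_negative_loss_vanishes_for_perfect_predictions():
    targets = np.zeros((1, 4, 4, 4), dtype=np.int64)
    targets[0, 0, 0, 0] = 2
    logits = np.full((1, 5, 4, 4, 4), -50.0)
    np.put_along_axis(logits, targets[:, None], 50.0, axis=1)
    loss, _ = hard_negative_ce_loss(logits, targets)
    assert loss < 1e-8


def test_hard_negative_loss_approaches_plain_ce_for_large_ratio():
    rng = np.random.default_rng(6)
    logits = rng.normal(size=(1, 5, 6, 6, 6))
    targets = rng.integers(0, 3, size=(1, 6, 6, 6)).astype(np.int64)
    hn, _ = hard_negative_ce_loss(logits, targets, ratio=10**6)
    plain, _ = nc.softmax_cross_entropy(logits, targets)
    assert hn == pytest.approx(plain)


def test_hard_negative_fallback_without_positives():
    rng = np.random.default_rng(7)
    logits = rng.normal(size=(1, 5, 4, 4, 4))
    targets = np.zeros((1, 4, 4, 4), dtype=np.int64)
    loss, d = hard_negative_ce_loss(logits, targets)
    assert loss > 0
    assert np.isfinite(d).all() and np.abs(d).sum() > 0


# --------------------------------------------------------------- schedule


def test_lr_schedule_closed_forms():
    cfg = TrainConfig(epochs=100)
    assert lr_at_epoch(cfg, 0) == pytest.approx(1e-3)
    assert lr_at_epoch(cfg, 100) == pytest.approx(1e-4)
    lit = TrainConfig(epochs=100, lr_schedule_mode="literal")
    assert lr_at_epoch(lit, 0) == pytest.approx(1e-3)
    assert lr_at_epoch(lit, 3) == pytest.approx(1e-6)


# --------------------------------------------------------------- training


@pytest.fixture(scope="module")
def tiny_subjects():
    subs = []
    for i in range(3):
        spec = PhantomSpec(grid_shape=(32, 32, 32), n_parcels=4,
                           seed=subject_seed(77, i))
        mmv, atlas, lv = generate_phantom(spec)
        subs.append(subject_from_phantom(mmv, None, lv, f"s{i}"))
    return subs


def test_deepmedic_training_reduces_loss_and_is_deterministic(tiny_subjects):
    mcfg = DeepMedicConfig(in_channels=4, conv_widths=(3,) * 8, head_width=4)
    tcfg = TrainConfig(model_kind="deepmedic", epochs=4, batch_size=8,
                       patches_per_subject=8, seed=11)
    _, log1 = train_model(tiny_subjects, mcfg, tcfg)
    _, log2 = train_model(tiny_subjects, mcfg, tcfg)
    assert [r["loss"] for r in log1] == [r["loss"] for r in log2]
    assert log1[-1]["loss"] < log1[0]["loss"]


def test_unet_training_reduces_loss(tiny_subjects):
    ucfg = UNet3DConfig(in_channels=4, depth=3, base_width=4)
    tcfg = TrainConfig(model_kind="unet", epochs=10, batch_size=1,
                       crop_size=16, augmentation=False, seed=12)
    _, log = train_model(tiny_subjects, ucfg, tcfg)
    assert log[-1]["loss"] < log[0]["loss"]


def test_training_rejects_channel_mismatch(tiny_subjects):
    mcfg = DeepMedicConfig(in_channels=25, conv_widths=(3,) * 8, head_width=4)
    tcfg = TrainConfig(model_kind="deepmedic", epochs=1, batch_size=4,
                       patches_per_subject=4)
    with pytest.raises(TrainingError, match="channels"):
        train_model(tiny_subjects, mcfg, tcfg)


def test_epochs_to_threshold():
    log = [{"epoch": i, "loss": 1.0 / (i + 1)} for i in range(5)]
    assert epochs_to_threshold(log, 0.5) == 1
    assert epochs_to_threshold(log, 0.01) == 5
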