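"""Mixed loss, SSIM, cross-validation protocol, fit loop, reassembly."""

import numpy as np
import pytest

from amytrans.network import ModelConfig
from amytrans.phantom import PhantomConfig, generate_cohort
from amytrans.preprocess import apply_mask, to_suvr
from amytrans.training import (LossWeights, TrainConfig, make_folds,
                               mixed_loss, predict_volume, ssim,
                               subject_slice_pairs, train_fold)

COHORT_35 = [(f"{dx}{j}", dx) for dx, n in
             [("YHC", 10), ("EHC", 6), ("MCI", 9), ("AD", 8), ("FTD", 2)]
             for j in range(n)]


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((40, 40))
        assert ssim(x, x, data_range=1.0) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        x, y = rng.random((32, 32)), rng.random((32, 32))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)

    def test_constant_images_reduce_to_luminance_term(self):
        """For two constant images only the luminance term survives:
        SSIM = (2ab + C1) / (a^2 + b^2 + C1)."""
        a, b, R = 1.2, 1.7, 3.0
        c1 = (0.01 * R) ** 2
        expected = (2 * a * b + c1) / (a * a + b * b + c1)
        got = ssim(np.full((24, 24), a), np.full((24, 24), b), data_range=R)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_skimage_oracle(self, rng):
        from skimage.metrics import structural_similarity
        x = rng.random((48, 48))
        y = np.clip(x + 0.15 * rng.standard_normal((48, 48)), 0, 1)
        ref = structural_similarity(x, y, data_range=1.0, gaussian_weights=True,
                                    sigma=1.5, use_sample_covariance=False)
        assert ssim(x, y, data_range=1.0) == pytest.approx(ref, abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.random((16, 16)), rng.random((16, 17)))


class TestMixedLoss:
    def test_zero_iff_prediction_equals_target(self, rng):
        x = rng.random((32, 32))
        w = LossWeights(1.0, 0.0, 1.0)
        assert mixed_loss(x, x, w) == pytest.approx(0.0, abs=1e-12)
        assert mixed_loss(x + 0.01, x, w) > 0

    def test_pure_l1_of_constant_offset(self, rng):
        x = rng.random((32, 32))
        loss = mixed_loss(x + 0.5, x, LossWeights(1.0, 0.0, 0.0))
        assert loss == pytest.approx(0.5, abs=1e-9)

    def test_terms_sum_independently(self, rng):
        """Total (1,0,1) loss equals separately computed L1 and 1-SSIM."""
        x = rng.random((32, 32))
        y = rng.random((32, 32))
        l1 = float(np.abs(x - y).mean())
        dssim = 1.0 - ssim(x, y, data_range=3.0)
        total = mixed_loss(x, y, LossWeights(1.0, 0.0, 1.0), data_range=3.0)
        assert total == pytest.approx(l1 + dssim, abs=1e-9)
        l2 = float(((x - y) ** 2).mean())
        total2 = mixed_loss(x, y, LossWeights(0.5, 2.0, 0.0))
        assert total2 == pytest.approx(0.5 * l1 + 2.0 * l2, abs=1e-9)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0, 0.0)


class TestFolds:
    def test_35_subject_cohort_splits_into_five_folds_of_seven(self):
        split = make_folds(COHORT_35, seed=0)
        assert [len(f) for f in split.folds] == [7, 7, 7, 7, 7]

    def test_every_subject_in_exactly_one_fold(self):
        split = make_folds(COHORT_35, seed=1)
        all_ids = [sid for fold in split.folds for sid in fold]
        assert sorted(all_ids) == sorted(sid for sid, _ in COHORT_35)

    def test_stratification_within_one_after_ftd_regrouping(self):
        split = make_folds(COHORT_35, seed=2)
        for dx in ("YHC", "EHC", "MCI", "AD"):
            per_fold = [sum(1 for sid in fold
                            if ("EHC" if split.diagnosis[sid] == "FTD"
                                else split.diagnosis[sid]) == dx)
                        for fold in split.folds]
            assert max(per_fold) - min(per_fold) <= 1, (dx, per_fold)

    def test_step_roles_rotate_and_are_disjoint(self):
        split = make_folds(COHORT_35, seed=0)
        tested = []
        for step in range(5):
            test = set(split.test_ids(step))
            val = set(split.val_ids(step))
            train = set(split.train_ids(step))
            assert not (test & val) and not (test & train) and not (val & train)
            assert len(test | val | train) == 35
            tested.extend(test)
        assert sorted(tested) == sorted(sid for sid, _ in COHORT_35)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_folds(COHORT_35[:3], seed=0)

    def test_deterministic_given_seed(self):
        a = make_folds(COHORT_35, seed=7)
        b = make_folds(COHORT_35, seed=7)
        assert a.folds == b.folds


MICRO_MODEL = ModelConfig(c1=2, c_prime=2, l1=1, l3=1, in_channels=2)


@pytest.fixture(scope="module")
def micro_cohort():
    cfg = PhantomConfig(grid_shape=(48, 40, 40),
                        counts={"YHC": 2, "EHC": 1, "MCI": 2, "AD": 2, "FTD": 1},
                        psf_fwhm_mm=4.0, noise_sd=0.03, seed=21)
    return generate_cohort(cfg)


def _micro_train_config(**kw):
    base = dict(epochs=2, batch_size=8, lr=1e-3, keep_range=(12, 28),
                slice_step=4, downsample=4, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestTrainFold:
    @pytest.fixture(scope="class")
    def run(self, micro_cohort):
        split = make_folds(micro_cohort, seed=0)
        cfg = _micro_train_config()
        model, log, info = train_fold(micro_cohort, split, 0, cfg, MICRO_MODEL)
        return model, log, info, split, cfg

    def test_training_loss_decreases_from_first_epoch(self, run):
        _, log, _, _, _ = run
        assert log[-1]["train_loss"] <= log[0]["train_loss"]

    def test_test_fold_never_enters_training_batches(self, run):
        _, _, info, _, _ = run
        assert not (info["trained_subject_ids"] & info["test_ids"])
        assert info["trained_subject_ids"] <= info["train_ids"]

    def test_identical_seeds_reproduce_validation_loss(self, micro_cohort, run):
        _, log, _, split, cfg = run
        _, log2, _ = train_fold(micro_cohort, split, 0, cfg, MICRO_MODEL)
        assert log2[-1]["val_loss"] == log[-1]["val_loss"]

    def test_empty_training_set_rejected(self, micro_cohort):
        ids = [s.id for s in micro_cohort]
        split = make_folds(micro_cohort, seed=0)
        # all subjects in the test and validation folds -> nothing to train on
        split.folds = [ids[:4], ids[4:], [], [], []]
        with pytest.raises(ValueError):
            train_fold(micro_cohort, split, 0, _micro_train_config(), MICRO_MODEL)

    def test_best_validation_checkpoint_is_kept(self, run):
        model, log, info, _, cfg = run
        assert info["best_val_loss"] == pytest.approx(
            min(row["val_loss"] for row in log))


class TestPredictVolume:
    def test_identity_network_reassembles_input(self, micro_cohort):
        """Slicing -> forward -> unpad -> stack is lossless for an identity
        network on the kept slices (and zero outside them)."""
        s = micro_cohort[0]
        cfg = _micro_train_config(downsample=1, slice_step=1)
        vol = predict_volume(lambda x: x[..., :1], s, cfg)
        pib = to_suvr(apply_mask(s.pib, s.mask), s.atlas)
        lo, hi = cfg.keep_range
        np.testing.assert_allclose(vol.data[:, :, lo:hi + 1],
                                   pib.data[:, :, lo:hi + 1], atol=1e-12)
        assert vol.data[:, :, :lo].sum() == 0
        assert vol.data[:, :, hi + 1:].sum() == 0

    def test_output_shape_matches_subject_grid(self, micro_cohort):
        s = micro_cohort[0]
        vol = predict_volume(lambda x: x[..., :1], s, _micro_train_config())
        assert vol.data.shape == s.pib.data.shape

    def test_slice_pair_counts_respect_step(self, micro_cohort):
        cfg = _micro_train_config()  # keep (12, 28), step 4 -> 5 slices
        assert len(subject_slice_pairs(micro_cohort[0], cfg)) == 5


class TestCapacity:
    def test_can_overfit_a_single_slice_pair(self, micro_cohort):
        """Capacity check: driving the mixed loss under 0.05 on one repeated
        sample within 200 steps."""
        from amytrans.nn import Adam, Tensor
        from amytrans.network import build_model

        cfg = _micro_train_config(downsample=4)
        pair = subject_slice_pairs(micro_cohort[3], cfg)[2]
        model = build_model(ModelConfig(), seed=0)
        opt = Adam(model.parameters(), lr=5e-3)
        x = pair.input[None].astype(np.float32)
        y = pair.target[None].astype(np.float32)
        loss_val = np.inf
        for _ in range(200):
            loss = mixed_loss(model.forward(x), Tensor(y))
            loss_val = float(loss.data)
            if loss_val < 0.05:
                break
            loss.backward()
            opt.step()
            opt.zero_grad()
        assert loss_val < 0.05
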