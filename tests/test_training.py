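"""Patch extraction, leakage-free splitting, the training loop, and the
bootstrap / paired-t-test comparison machinery."""

import math

import numpy as np
import pytest
from scipy import stats

from tococonet import (
    PatchDataset,
    TrainConfig,
    bootstrap_evaluate,
    evaluate_corrector,
    extract_patches,
    mse_loss,
    paired_t_test,
    split_dataset,
    train,
)
from tococonet.nn import DccnConfig, NetworkConfig, TococoNet

from conftest import random_rgb

TINY = NetworkConfig(
    ublock_mid_filters=4,
    ublock_out_channels=6,
    mblock_filters=4,
    mblock_out_channels=6,
    head_filters=6,
)


def make_pairs(rng, n_sources=10, patches_per_source=4, size=8):
    pairs = []
    for src in range(n_sources):
        for _ in range(patches_per_source):
            img = random_rgb(rng, size, size)
            pairs.append((img, img.copy(), src))
    return pairs


class TestExtractPatches:
    def test_640_yields_49_patches(self, tongue_image):
        patches = extract_patches(tongue_image, size=160, step=80)
        assert len(patches) == 49
        assert all(p.shape == (160, 160, 3) for p in patches)

    def test_full_size_patch_is_the_image(self, small_scene):
        patches = extract_patches(small_scene, size=160, step=80)
        assert len(patches) == 1
        assert np.array_equal(patches[0], small_scene)

    def test_row_major_order_and_coverage(self, rng):
        img = random_rgb(rng, 32, 32)
        patches = extract_patches(img, size=16, step=8)
        assert len(patches) == 9
        assert np.array_equal(patches[0], img[:16, :16])
        assert np.array_equal(patches[1], img[:16, 8:24])
        # step ≤ size: every pixel covered by at least one patch
        cover = np.zeros((32, 32), dtype=int)
        k = 0
        for r in range(0, 17, 8):
            for c in range(0, 17, 8):
                cover[r : r + 16, c : c + 16] += 1
                k += 1
        assert cover.min() >= 1 and k == 9

    def test_oversized_patch_rejected(self, rng):
        with pytest.raises(ValueError, match="size"):
            extract_patches(random_rgb(rng, 8, 8), size=16, step=8)


class TestSplitDataset:
    def test_ratios_on_100_sources(self, rng):
        pairs = make_pairs(rng, n_sources=100, patches_per_source=1)
        ds = split_dataset(pairs, seed=0)
        counts = ds.counts()
        assert counts == {"train": 60, "val": 30, "test": 10}

    def test_same_seed_identical_assignment(self, rng):
        pairs = make_pairs(rng)
        a = split_dataset(pairs, seed=3)
        b = split_dataset(pairs, seed=3)
        assert a.split == b.split

    def test_no_source_straddles_splits_across_seeds(self, rng):
        pairs = make_pairs(rng, n_sources=10, patches_per_source=5)
        for seed in range(20):
            ds = split_dataset(pairs, seed=seed)  # PatchDataset validates leakage
            for tag in ("train", "val", "test"):
                assert any(s == tag for s in ds.split)

    def test_too_few_sources_rejected(self, rng):
        with pytest.raises(ValueError, match="source images"):
            split_dataset(make_pairs(rng, n_sources=2), seed=0)

    def test_leaky_dataset_rejected_on_construction(self, rng):
        img = random_rgb(rng, 8, 8)
        with pytest.raises(ValueError, match="splits"):
            PatchDataset(
                biased=[img, img],
                clean=[img, img],
                split=["train", "test"],
                source_id=[0, 0],
            )


class TestMseLoss:
    def test_identical_tensors_zero(self, rng):
        x = rng.random((3, 4, 4, 3))
        assert mse_loss(x, x) == 0.0

    def test_constant_difference_closed_form(self, rng):
        x = rng.random((2, 5, 5, 3))
        assert mse_loss(x + 0.3, x) == pytest.approx(0.09)

    def test_matches_elementwise_summation_oracle(self, rng):
        a, b = rng.random((2, 6, 6, 3)), rng.random((2, 6, 6, 3))
        total = 0.0
        for ai, bi in zip(a.ravel(), b.ravel()):
            total += (ai - bi) ** 2
        assert mse_loss(a, b) == pytest.approx(total / a.size, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            mse_loss(np.zeros((2, 2)), np.zeros((3, 2)))


def _identity_dataset(rng, n_sources=6, size=8):
    """Pairs where biased == clean: the easiest learnable task."""
    pairs = []
    for src in range(n_sources):
        for _ in range(3):
            img = random_rgb(rng, size, size)
            pairs.append((img, img.copy(), src))
    return split_dataset(pairs, seed=0)


class TestTrainLoop:
    def test_converges_on_identity_task(self, rng):
        ds = _identity_dataset(rng)
        model = TococoNet(TINY, seed=0)
        cfg = TrainConfig(batch_size=8, epochs=20, learning_rate=3e-3, seed=0)
        model, hist = train(model, ds, cfg)
        assert len(hist.train_loss) == 20
        assert hist.train_loss[-1] < hist.train_loss[0] / 10

    def test_history_and_lr_monotonicity(self, rng):
        ds = _identity_dataset(rng)
        model = TococoNet(TINY, seed=1)
        cfg = TrainConfig(batch_size=8, epochs=8, learning_rate=1e-3,
                          scheduler_patience=2, seed=0)
        _, hist = train(model, ds, cfg)
        assert len(hist.val_loss) == len(hist.lr) == 8
        assert all(b <= a for a, b in zip(hist.lr, hist.lr[1:]))
        frame = hist.to_frame()
        assert list(frame.columns) == [
            "epoch", "train_loss", "val_loss", "train_psnr", "val_psnr", "lr",
        ]

    def test_empty_split_rejected(self, rng):
        ds = _identity_dataset(rng)
        ds = PatchDataset(
            biased=[b for b, s in zip(ds.biased, ds.split) if s == "train"],
            clean=[c for c, s in zip(ds.clean, ds.split) if s == "train"],
            split=["train" for s in ds.split if s == "train"],
            source_id=[i for i, s in zip(ds.source_id, ds.split) if s == "train"],
        )
        with pytest.raises(ValueError, match="non-empty"):
            train(TococoNet(TINY, seed=0), ds, TrainConfig(epochs=2, scheduler_patience=1))


class TestEvaluateCorrector:
    def test_identity_corrector_on_clean_pairs(self, rng):
        pairs = [(p, p.copy()) for p in [random_rgb(rng, 16, 16) for _ in range(3)]]
        table = evaluate_corrector(lambda img: img, pairs)
        assert set(table["state"]) == {"Original", "Corrected"}
        assert np.allclose(table["SSIM"], 1.0)
        assert np.allclose(table["E_mean"], 0.0)

    def test_original_rows_score_the_bias(self, rng):
        clean = random_rgb(rng, 16, 16)
        biased = np.clip(clean.astype(int) + 40, 0, 255).astype(np.uint8)
        table = evaluate_corrector(lambda img: img, [(biased, clean)])
        orig = table[table["state"] == "Original"].iloc[0]
        assert orig["E_mean"] > 0 and orig["MAE"] > 0


class TestBootstrap:
    def test_constant_input_gives_zero_std(self):
        report = bootstrap_evaluate([4.2] * 25, n_boot=40, seed=0)
        assert report.std == 0.0 and report.mean == pytest.approx(4.2)

    def test_seeded_determinism(self, rng):
        vals = list(rng.normal(10, 2, size=50))
        a = bootstrap_evaluate(vals, seed=7)
        b = bootstrap_evaluate(vals, seed=7)
        assert a == b and a.n_boot == 40

    def test_bootstrap_mean_near_sample_mean(self, rng):
        vals = rng.normal(5.0, 1.0, size=400)
        report = bootstrap_evaluate(vals, n_boot=40, seed=1)
        se = vals.std(ddof=1) / math.sqrt(vals.size)
        assert abs(report.mean - vals.mean()) < 3 * se

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_evaluate([])


class TestPairedTTest:
    def test_identical_vectors_degenerate_case(self):
        r = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0 and r.p_value == 1.0 and not r.significant

    def test_textbook_hand_computation(self):
        # differences (2, 4, 6, 8, 10): mean 6, sd sqrt(10), n 5
        a = [12.0, 14.0, 16.0, 18.0, 20.0]
        b = [10.0, 10.0, 10.0, 10.0, 10.0]
        r = paired_t_test(a, b)
        expected_t = 6.0 / (math.sqrt(10.0) / math.sqrt(5.0))
        assert r.t_statistic == pytest.approx(expected_t, abs=1e-9)
        assert r.df == 4

    def test_matches_reference_implementation(self, rng):
        a = rng.normal(0, 1, size=30)
        b = rng.normal(0.3, 1, size=30)
        ours = paired_t_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert ours.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_shift_at_n40_significant(self, rng):
        b = rng.normal(0, 1, size=40)
        r = paired_t_test(b + 5.0, b)
        assert r.significant and r.p_value < 0.001

    def test_type_one_error_calibrated_under_null(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(0, 1, size=20)
            b = rng.normal(0, 1, size=20)
            if paired_t_test(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0])
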