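"""Patch datasets, the training loop, evaluation tables, and the
bootstrap + paired-t-test comparison protocol.

Training data are paired (biased, clean) patches cropped from full images
by a sliding window (160×160 with step 80 on the 640×640 reference size:
49 patches per image) and split 60/30/10 into train/validation/test **by
source image**, never by patch — overlapping patches from one image are
near-duplicates, and letting them straddle splits would leak.

The loss is plain MSE on [0, 1] tensors, minimized with Adam (lr 1e-4, L2
weight decay 1e-5, batch 32) under a reduce-on-plateau schedule (factor
0.5 after 15 epochs without validation improvement).  Model comparison
follows the published protocol: 40 bootstrap resamples of the per-image
test metrics (mean ± sd across resamples) and two-sided paired t-tests at
α = 0.001, reported without multiple-testing correction across the
5 scenarios × 2 metrics (raw p-values, as in the protocol being followed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .image import validate_rgb
from .metrics import quality_report
from .nn.layers import Module
from .nn.models import load_state_dict, state_dict
from .nn.optim import Adam, ReduceLROnPlateau

__all__ = [
    "PatchDataset",
    "TrainConfig",
    "TrainingHistory",
    "BootstrapReport",
    "TTestResult",
    "extract_patches",
    "split_dataset",
    "mse_loss",
    "train",
    "evaluate_corrector",
    "bootstrap_evaluate",
    "paired_t_test",
]


def extract_patches(img: np.ndarray, size: int = 160, step: int = 80) -> list[np.ndarray]:
    """Sliding-window square crops at offsets 0, step, 2·step, … (row-major).

    Only fully fitting windows are returned; a 640×640 image at size 160,
    step 80 yields ((640−160)/80 + 1)² = 49 patches.
    """
    img = validate_rgb(img)
    h, w = img.shape[:2]
    if size > min(h, w):
        raise ValueError(f"patch size {size} exceeds image dims {h}×{w}")
    if step < 1:
        raise ValueError("step must be ≥ 1")
    return [
        img[r : r + size, c : c + size].copy()
        for r in range(0, h - size + 1, step)
        for c in range(0, w - size + 1, step)
    ]


@dataclass
class PatchDataset:
    """Paired (biased, clean) patches with a train/val/test tag per pair."""

    biased: list[np.ndarray]
    clean: list[np.ndarray]
    split: list[str]  # per-pair tag: train | val | test
    source_id: list[int]

    def __post_init__(self) -> None:
        n = len(self.biased)
        if not (len(self.clean) == len(self.split) == len(self.source_id) == n):
            raise ValueError("biased/clean/split/source_id must have equal lengths")
        shapes = {p.shape for p in self.biased} | {p.shape for p in self.clean}
        if len(shapes) > 1:
            raise ValueError(f"patch dimensions must be uniform, got {shapes}")
        by_split: dict[str, set[int]] = {}
        for tag, src in zip(self.split, self.source_id):
            by_split.setdefault(tag, set()).add(src)
        tags = list(by_split)
        for i, a in enumerate(tags):
            for b in tags[i + 1 :]:
                common = by_split[a] & by_split[b]
                if common:
                    raise ValueError(
                        f"source images {sorted(common)} appear in both "
                        f"'{a}' and '{b}' splits"
                    )

    def subset(self, tag: str) -> list[tuple[np.ndarray, np.ndarray]]:
        return [
            (b, c)
            for b, c, s in zip(self.biased, self.clean, self.split)
            if s == tag
        ]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {"train": 0, "val": 0, "test": 0}
        for s in self.split:
            out[s] = out.get(s, 0) + 1
        return out


def split_dataset(
    patch_pairs: list[tuple[np.ndarray, np.ndarray, int]],
    ratios: tuple[float, float, float] = (0.6, 0.3, 0.1),
    seed: int = 0,
) -> PatchDataset:
    """Assign pairs to train/val/test by shuffled source image, 60/30/10.

    All patches sharing a source image land in the same split.  Image
    counts follow the cumulative ratios (largest-remainder-free rounding on
    the shuffled order), so proportions are met within one source image.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    sources = sorted({src for _, _, src in patch_pairs})
    if len(sources) < 3:
        raise ValueError(f"need at least 3 source images to form 3 splits, got {len(sources)}")
    rng = np.random.default_rng(seed)
    order = [sources[i] for i in rng.permutation(len(sources))]
    n = len(order)
    n_train = max(1, int(round(ratios[0] * n)))
    n_val = max(1, int(round(ratios[1] * n)))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    assignment: dict[int, str] = {}
    for i, src in enumerate(order):
        assignment[src] = "train" if i < n_train else "val" if i < n_train + n_val else "test"
    return PatchDataset(
        biased=[b for b, _, _ in patch_pairs],
        clean=[c for _, c, _ in patch_pairs],
        split=[assignment[src] for _, _, src in patch_pairs],
        source_id=[src for _, _, src in patch_pairs],
    )


def mse_loss(predicted: np.ndarray, target: np.ndarray) -> float:
    """Mean of squared elementwise differences over all positions."""
    predicted = np.asarray(predicted)
    target = np.asarray(target)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {target.shape}")
    diff = predicted.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(diff * diff))


@dataclass(frozen=True)
class TrainConfig:
    """Published training hyperparameters (defaults) for the correction nets."""

    batch_size: int = 32
    epochs: int = 200
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    scheduler_factor: float = 0.5
    scheduler_patience: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("batch size, epochs and learning rate must be positive")
        if self.scheduler_patience >= self.epochs:
            raise ValueError("scheduler patience must be smaller than the epoch budget")


@dataclass
class TrainingHistory:
    """Per-epoch records: losses, PSNR (255 convention) and learning rate."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_psnr: list[float] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_psnr": self.train_psnr,
                "val_psnr": self.val_psnr,
                "lr": self.lr,
            }
        )


def _to_tensor(patches: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """(biased, clean) uint8 pairs → [0, 1] float NHWC tensors."""
    from .nn.layers import get_default_dtype

    dtype = get_default_dtype()
    x = np.stack([b for b, _ in patches]).astype(dtype) / 255.0
    y = np.stack([c for _, c in patches]).astype(dtype) / 255.0
    return x, y


def _psnr_01(mse: float) -> float:
    """PSNR from an MSE on [0, 1] tensors, reported on the 255 convention."""
    return math.inf if mse <= 0 else 10.0 * math.log10(1.0 / mse)


def train(
    model: Module,
    data: PatchDataset,
    cfg: TrainConfig | None = None,
    stop_threshold: float | None = None,
) -> tuple[Module, TrainingHistory]:
    """Adam-optimize the MSE loss with a validation plateau schedule.

    Keeps the lowest-validation-loss parameters and restores them at the
    end.  ``stop_threshold`` optionally ends training early once the
    validation loss falls below it (used by CPU-scale experiments).
    Non-finite losses abort with a diagnostic.
    """
    cfg = cfg or TrainConfig()
    train_pairs = data.subset("train")
    val_pairs = data.subset("val")
    if not train_pairs or not val_pairs:
        raise ValueError("train and val splits must both be non-empty")
    x_train, y_train = _to_tensor(train_pairs)
    x_val, y_val = _to_tensor(val_pairs)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(
        model.parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    sched = ReduceLROnPlateau(
        opt, factor=cfg.scheduler_factor, patience=cfg.scheduler_patience
    )
    history = TrainingHistory()
    best_val = math.inf
    best_state = state_dict(model)

    n = x_train.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            pred = model.forward(xb, train=True)
            loss = mse_loss(pred, yb)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss {loss} at step {opt.t}"
                )
            opt.zero_grad()
            model.backward((2.0 / pred.size) * (pred - yb).astype(np.float32))
            opt.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= n

        val_loss = _batched_eval_loss(model, x_val, y_val, cfg.batch_size)
        if val_loss < best_val:
            best_val = val_loss
            best_state = state_dict(model)
        history.train_loss.append(epoch_loss)
        history.val_loss.append(val_loss)
        history.train_psnr.append(_psnr_01(epoch_loss))
        history.val_psnr.append(_psnr_01(val_loss))
        history.lr.append(opt.lr)
        sched.step(val_loss)
        if stop_threshold is not None and val_loss < stop_threshold:
            break

    load_state_dict(model, best_state)
    return model, history


def _batched_eval_loss(model: Module, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    total = 0.0
    for start in range(0, x.shape[0], batch):
        xb, yb = x[start : start + batch], y[start : start + batch]
        total += mse_loss(model.forward(xb, train=False), yb) * xb.shape[0]
    return total / x.shape[0]


def evaluate_corrector(
    correct_fn, test_pairs: list[tuple[np.ndarray, np.ndarray]], label: str = "Corrected"
) -> pd.DataFrame:
    """Per-pair metric table: an "Original" row (biased vs clean) and a
    corrected row per pair, in the standard report column order."""
    if not test_pairs:
        raise ValueError("test set must be non-empty")
    rows = []
    for i, (biased, clean) in enumerate(test_pairs):
        rows.append(
            {"pair": i, "state": "Original", **quality_report(clean, biased).to_row()}
        )
        rows.append(
            {"pair": i, "state": label, **quality_report(clean, correct_fn(biased)).to_row()}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BootstrapReport:
    """Mean and sd of a metric across bootstrap resamples of the test set."""

    n_boot: int
    mean: float
    std: float
    resample_means: tuple[float, ...] = field(repr=False, default=())


def bootstrap_evaluate(
    per_image_metric: list[float] | np.ndarray, n_boot: int = 40, seed: int = 0
) -> BootstrapReport:
    """Resample the per-image metric list with replacement ``n_boot`` times.

    Each resample has the size of the full list; the report carries the mean
    and standard deviation of the resample means.
    """
    values = np.asarray(per_image_metric, dtype=np.float64)
    if values.size == 0:
        raise ValueError("metric list must be non-empty")
    rng = np.random.default_rng(seed)
    means = np.array(
        [values[rng.integers(0, values.size, size=values.size)].mean() for _ in range(n_boot)]
    )
    return BootstrapReport(
        n_boot=n_boot,
        mean=float(means.mean()),
        std=float(means.std(ddof=1)) if n_boot > 1 else 0.0,
        resample_means=tuple(means),
    )


@dataclass(frozen=True)
class TTestResult:
    """Two-sided paired t-test outcome at significance level α = 0.001."""

    t_statistic: float
    p_value: float
    significant: bool
    df: int


def paired_t_test(a: list[float] | np.ndarray, b: list[float] | np.ndarray) -> TTestResult:
    """Classical paired t-test on the differences a − b.

    t = mean(d) / (sd(d)/√n) with n−1 degrees of freedom, two-sided p from
    the t distribution.  Identical vectors (all differences zero) are the
    defined degenerate case t = 0, p = 1; a nonzero constant difference
    gives t = ±inf, p = 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired samples must be equal-length vectors, got {a.shape}, {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            return TTestResult(t_statistic=0.0, p_value=1.0, significant=False, df=n - 1)
        t = math.copysign(math.inf, d[0])
        return TTestResult(t_statistic=t, p_value=0.0, significant=True, df=n - 1)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * _stats.t.sf(abs(t), df=n - 1)
    return TTestResult(t_statistic=float(t), p_value=float(p), significant=p < 0.001, df=n - 1)
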