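"""Seeded synthetic tongue-like imagery and paired benchmark datasets.

No deposited tongue-image dataset exists, so every experiment in this
package runs on procedurally generated scenes: an anti-aliased reddish
ellipse (the tongue body) with a radial lightness gradient, speckle
texture, and optional pale "coating" patches, on a neutral background at
640×640 by default.  Realism is deliberately minimal — color-cast
correction depends on color statistics, not anatomy — which keeps fixtures
fast and fully specified.

The benchmark builder renders scenes, applies the requested casts, crops
160×160 patches with step 80 (49 per 640×640 image) and splits 60/30/10 by
source image, returning a :class:`~tococonet.training.PatchDataset` plus a
manifest of every bias spec used, so any biased image can be replayed
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bias import BIAS_KINDS, DEFAULT_ADJUSTMENT, BiasSpec, apply_bias, sample_random_bias
from .classical import COLORCHECKER_CLASSIC
from .image import quantize
from .training import PatchDataset, extract_patches, split_dataset

__all__ = [
    "SyntheticSceneSpec",
    "generate_tongue_image",
    "generate_color_blocks",
    "make_benchmark_dataset",
]


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one rendered tongue scene.

    The base color is reddish by construction (R dominant); the ellipse must
    fit inside the canvas.  Amplitudes are in 8-bit levels.
    """

    canvas_size: tuple[int, int] = (640, 640)  # (height, width)
    center: tuple[float, float] = (320.0, 330.0)  # (row, col)
    axes: tuple[float, float] = (200.0, 260.0)  # (semi-axis cols, semi-axis rows)
    rotation_deg: float = 0.0
    base_color: tuple[int, int, int] = (180, 90, 95)
    gradient_amplitude: float = 25.0
    noise_amplitude: float = 6.0
    coating_probability: float = 0.3
    background_color: tuple[int, int, int] = (205, 205, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        r, g, b = self.base_color
        if not (r > g and r > b):
            raise ValueError("tongue base color must be reddish (R > G and R > B)")
        for color in (self.base_color, self.background_color):
            if min(color) < 0 or max(color) > 255:
                raise ValueError("colors must lie in [0, 255]")
        h, w = self.canvas_size
        cy, cx = self.center
        ax, ay = self.axes
        if not (ay <= cy <= h - ay and ax <= cx <= w - ax):
            raise ValueError("tongue ellipse must lie fully inside the canvas")


def generate_tongue_image(spec: SyntheticSceneSpec | None = None) -> np.ndarray:
    """Render one scene deterministically for its seed; returns H×W×3 uint8."""
    spec = spec or SyntheticSceneSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas_size
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = rows - spec.center[0], cols - spec.center[1]
    theta = np.deg2rad(spec.rotation_deg)
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    r2 = (u / spec.axes[0]) ** 2 + (v / spec.axes[1]) ** 2
    r = np.sqrt(r2)
    alpha = np.clip((1.0 - r) / 0.02, 0.0, 1.0)  # ~2%-of-radius anti-aliased rim

    tongue = np.empty((h, w, 3), dtype=np.float64)
    # radial lightness gradient: brightest at the center, darker at the rim
    lightness = spec.gradient_amplitude * (1.0 - np.minimum(r2, 1.0))
    for c in range(3):
        tongue[..., c] = spec.base_color[c] + lightness

    if rng.random() < spec.coating_probability:
        # a pale, slightly yellowish coating patch on the upper tongue body
        ccy = spec.center[0] - 0.35 * spec.axes[1]
        ccx = spec.center[1] + rng.uniform(-0.2, 0.2) * spec.axes[0]
        cr2 = ((cols - ccx) / (0.45 * spec.axes[0])) ** 2 + (
            (rows - ccy) / (0.3 * spec.axes[1])
        ) ** 2
        cmask = np.clip(1.0 - cr2, 0.0, 1.0)
        coat = np.array([225.0, 215.0, 185.0])
        tongue = tongue * (1 - 0.6 * cmask[..., None]) + coat * 0.6 * cmask[..., None]

    img = np.empty_like(tongue)
    bg = np.array(spec.background_color, dtype=np.float64)
    for c in range(3):
        img[..., c] = bg[c] * (1 - alpha) + tongue[..., c] * alpha

    img += rng.normal(0.0, spec.noise_amplitude, size=img.shape)
    return quantize(img)


def generate_color_blocks(
    n: int, seed: int = 0, size: int = 32, chart: bool = False
) -> list[np.ndarray]:
    """Uniform single-color patches from a tongue-plausible color distribution.

    With ``chart=True`` and ``n=24``, returns the embedded 24-patch reference
    chart colors instead (for calibration tests).  Colors are drawn from a
    truncated Gaussian around (180, 90, 95) with broad spread, with a 15%
    admixture of neutral grays, so both the saturating and non-saturating
    paths of the cast simulator are exercised.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if chart:
        if n != 24:
            raise ValueError("chart mode returns exactly the 24 reference patches")
        colors = np.array([v for _, v in COLORCHECKER_CLASSIC], dtype=np.float64)
    else:
        rng = np.random.default_rng(seed)
        base = np.array([180.0, 90.0, 95.0])
        colors = np.empty((n, 3))
        for i in range(n):
            if rng.random() < 0.15:  # neutral outlier
                colors[i] = rng.uniform(60, 250)
            else:
                colors[i] = np.clip(base + rng.normal(0, 40, size=3), 0, 255)
    return [
        np.full((size, size, 3), quantize(c), dtype=np.uint8) for c in colors
    ]


def _scene_variant(base_seed: int, index: int, canvas: int) -> SyntheticSceneSpec:
    """A per-image scene with jittered geometry and hue, seeded reproducibly."""
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, index]))
    scale = canvas / 640.0
    base = (
        int(np.clip(180 + rng.normal(0, 15), 150, 220)),
        int(np.clip(90 + rng.normal(0, 12), 50, 130)),
        int(np.clip(95 + rng.normal(0, 12), 50, 135)),
    )
    if not (base[0] > base[1] and base[0] > base[2]):
        base = (max(base) + 20, base[1], base[2])
    axes = (
        float(rng.uniform(0.28, 0.33) * canvas),
        float(rng.uniform(0.36, 0.42) * canvas),
    )
    center = (
        float(canvas / 2 + rng.uniform(-10, 10) * scale),
        float(canvas / 2 + rng.uniform(-10, 10) * scale),
    )
    spec = SyntheticSceneSpec(
        canvas_size=(canvas, canvas),
        center=center,
        axes=axes,
        base_color=base,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return spec


def make_benchmark_dataset(
    n_images: int,
    kinds: tuple[str, ...] = BIAS_KINDS,
    seed: int = 0,
    canvas: int = 640,
    patch_size: int = 160,
    step: int = 80,
    randomize_casts: bool = False,
    ratios: tuple[float, float, float] = (0.6, 0.3, 0.1),
) -> tuple[PatchDataset, list[dict]]:
    """Render scenes, bias them, patch them, and split by source image.

    For each scene and each requested kind a bias spec is drawn: brightness
    kinds sample contrast/offset from their stated ranges; channel casts use
    the canonical adjustment 50 unless ``randomize_casts`` samples 10–50.
    Returns the split dataset and a JSON-serializable manifest of every
    (source image, bias spec) pairing.
    """
    if n_images < 3:
        raise ValueError("need at least 3 source images for a 3-way split")
    for kind in kinds:
        if kind not in BIAS_KINDS:
            raise ValueError(f"unknown bias kind {kind!r}")
    pairs = []
    manifest = []
    for i in range(n_images):
        spec = _scene_variant(seed, i, canvas)
        clean = generate_tongue_image(spec)
        for k_idx, kind in enumerate(kinds):
            bias_seed = int(
                np.random.SeedSequence([seed, i, k_idx]).generate_state(1)[0] % (2**31)
            )
            if kind in ("reddish", "greenish", "bluish") and not randomize_casts:
                bspec = BiasSpec(kind=kind, adjustment=DEFAULT_ADJUSTMENT, seed=bias_seed)
            else:
                bspec = sample_random_bias(kind, bias_seed)
            biased = apply_bias(clean, bspec)
            for bp, cp in zip(
                extract_patches(biased, patch_size, step),
                extract_patches(clean, patch_size, step),
            ):
                pairs.append((bp, cp, i))
            manifest.append({"source_image": i, "scene_seed": spec.seed, **bspec.to_dict()})
    dataset = split_dataset(pairs, ratios=ratios, seed=seed)
    return dataset, manifest
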