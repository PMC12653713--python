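"""Simulation of the five canonical color casts on 8-bit RGB images.

Two degradation families produce paired (clean, biased) data:

* brightness casts (``lower_brightness`` / ``higher_brightness``)::

      v  →  v · contrast ∓ offset          contrast ∈ [0.8, 1],  offset ∈ [0, 30]

  computed in floating point on every channel; the result is quantized to
  8 bits only once at the end (with contrast ≤ 1 and offset ≤ 30 the raised
  value can reach at most 285 before that final clamp);

* channel casts (``reddish`` / ``greenish`` / ``bluish``)::

      v  →  min(255, v + adjustment)       canonical adjustment = 50

  applied to the single affected channel with saturation at 255.

Randomized-severity specs draw contrast and offset uniformly from the ranges
above, and the cast adjustment uniformly from the integers 10–50 (mild up to
the canonical severity), all from a seeded generator so that every spec can
be replayed bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .image import quantize, to_float, validate_rgb

__all__ = [
    "BIAS_KINDS",
    "BRIGHTNESS_KINDS",
    "CHANNEL_KINDS",
    "DEFAULT_ADJUSTMENT",
    "BiasSpec",
    "apply_brightness_bias",
    "apply_channel_cast",
    "sample_random_bias",
    "apply_bias",
]

BRIGHTNESS_KINDS = ("lower_brightness", "higher_brightness")
CHANNEL_KINDS = ("reddish", "greenish", "bluish")
BIAS_KINDS = BRIGHTNESS_KINDS + CHANNEL_KINDS

#: Channel index shifted by each channel-cast kind.
_CAST_CHANNEL = {"reddish": 0, "greenish": 1, "bluish": 2}
_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}

#: Canonical cast severity used for training data.
DEFAULT_ADJUSTMENT = 50


@dataclass(frozen=True)
class BiasSpec:
    """A fully parameterized color degradation, replayable from its fields.

    ``contrast`` / ``brightness_offset`` drive the brightness kinds;
    ``adjustment`` drives the channel-cast kinds.  ``seed`` records the
    generator state the spec was sampled from (informational for fixed specs).
    """

    kind: str
    contrast: float = 1.0
    brightness_offset: float = 0.0
    adjustment: int = DEFAULT_ADJUSTMENT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BIAS_KINDS:
            raise ValueError(f"unknown bias kind {self.kind!r}; expected one of {BIAS_KINDS}")
        if not 0.8 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must lie in [0.8, 1.0], got {self.contrast}")
        if not 0.0 <= self.brightness_offset <= 30.0:
            raise ValueError(f"brightness offset must lie in [0, 30], got {self.brightness_offset}")
        if self.adjustment < 0:
            raise ValueError(f"adjustment must be non-negative, got {self.adjustment}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BiasSpec":
        return cls(**d)


def apply_brightness_bias(
    img: np.ndarray, contrast: float, brightness_offset: float, direction: str
) -> np.ndarray:
    """Scale every channel by ``contrast`` and shift by ±``brightness_offset``.

    ``direction`` is ``"lower"`` (subtract the offset) or ``"higher"`` (add).
    The affine math runs unclipped in floating point; clamping to [0, 255]
    happens only at the final 8-bit quantization.
    """
    if not 0.8 <= contrast <= 1.0:
        raise ValueError(f"contrast must lie in [0.8, 1.0], got {contrast}")
    if not 0.0 <= brightness_offset <= 30.0:
        raise ValueError(f"brightness offset must lie in [0, 30], got {brightness_offset}")
    if direction not in ("lower", "higher"):
        raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")
    img = validate_rgb(img)
    sign = -1.0 if direction == "lower" else 1.0
    return quantize(to_float(img) * contrast + sign * brightness_offset)


def apply_channel_cast(img: np.ndarray, channel: str, adjustment: int) -> np.ndarray:
    """Add ``adjustment`` to one channel (``"R"``/``"G"``/``"B"``), saturating at 255."""
    if adjustment < 0:
        raise ValueError(f"adjustment must be non-negative, got {adjustment}")
    if channel not in _CHANNEL_INDEX:
        raise ValueError(f"channel must be one of R, G, B; got {channel!r}")
    img = validate_rgb(img)
    out = img.astype(np.int64)
    c = _CHANNEL_INDEX[channel]
    out[..., c] = np.minimum(255, out[..., c] + int(round(adjustment)))
    return out.astype(np.uint8)


def sample_random_bias(kind: str, seed: int) -> BiasSpec:
    """Draw a randomized-severity :class:`BiasSpec` for ``kind``.

    Brightness kinds: contrast ~ U[0.8, 1.0], offset ~ U[0, 30].
    Channel-cast kinds: adjustment ~ U{10, …, 50}.
    Identical (kind, seed) always yields an identical spec.
    """
    if kind not in BIAS_KINDS:
        raise ValueError(f"unknown bias kind {kind!r}; expected one of {BIAS_KINDS}")
    rng = np.random.default_rng(seed)
    if kind in BRIGHTNESS_KINDS:
        return BiasSpec(
            kind=kind,
            contrast=float(rng.uniform(0.8, 1.0)),
            brightness_offset=float(rng.uniform(0.0, 30.0)),
            seed=seed,
        )
    return BiasSpec(kind=kind, adjustment=int(rng.integers(10, 51)), seed=seed)


def apply_bias(img: np.ndarray, spec: BiasSpec) -> np.ndarray:
    """Apply a :class:`BiasSpec`: brightness affine or single-channel cast."""
    if spec.kind in BRIGHTNESS_KINDS:
        direction = "lower" if spec.kind == "lower_brightness" else "higher"
        return apply_brightness_bias(img, spec.contrast, spec.brightness_offset, direction)
    channel = "RGB"[_CAST_CHANNEL[spec.kind]]
    return apply_channel_cast(img, channel, spec.adjustment)
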