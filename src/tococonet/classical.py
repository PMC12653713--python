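"""Classical (non-neural) color-correction baselines.

Four methods, all operating on 8-bit RGB images with a single float → uint8
quantization at the output:

* **gray world** — assumes the scene average is achromatic: with channel
  means (R̄, Ḡ, B̄) and K = (R̄ + Ḡ + B̄)/3, each channel is scaled by K/mean.
* **perfect reflection** — assumes the brightest pixel (largest R+G+B) is
  white, and scales each channel by 255/that pixel's component.
* **SDW** — gray world with block-weighted means: the image is divided into
  16×16 blocks and each block's contribution to the channel means is
  weighted by its within-block standard deviation (pooled over channels),
  suppressing large flat single-color regions that would otherwise drag the
  mean.
* **polynomial regression** — a least-squares linear map from a polynomial
  expansion of observed chart-patch colors to the reference chart colors,
  fitted on a 24-patch ColorChecker-style chart and applied per pixel.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from .image import quantize, to_float, validate_rgb

__all__ = [
    "DegenerateInputError",
    "ChannelMeans",
    "ReferenceChart",
    "PolynomialMap",
    "COLORCHECKER_CLASSIC",
    "DEFAULT_TERMS",
    "gray_world",
    "perfect_reflection",
    "sdw_correct",
    "expand_terms",
    "fit_polynomial_map",
    "apply_polynomial_map",
    "load_chart_csv",
]


class DegenerateInputError(ValueError):
    """Raised when an image cannot be corrected (e.g. a zero channel mean)."""


@dataclass(frozen=True)
class ChannelMeans:
    """Per-channel means and the gray target K = (R̄ + Ḡ + B̄)/3."""

    r_avg: float
    g_avg: float
    b_avg: float

    @property
    def k(self) -> float:
        return (self.r_avg + self.g_avg + self.b_avg) / 3.0


# Nominal sRGB coordinates of the 24-patch ColorChecker Classic chart
# (widely published manufacturer values; override via load_chart_csv).
COLORCHECKER_CLASSIC: tuple[tuple[str, tuple[int, int, int]], ...] = (
    ("dark skin", (115, 82, 68)),
    ("light skin", (194, 150, 130)),
    ("blue sky", (98, 122, 157)),
    ("foliage", (87, 108, 67)),
    ("blue flower", (133, 128, 177)),
    ("bluish green", (103, 189, 170)),
    ("orange", (214, 126, 44)),
    ("purplish blue", (80, 91, 166)),
    ("moderate red", (193, 90, 99)),
    ("purple", (94, 60, 108)),
    ("yellow green", (157, 188, 64)),
    ("orange yellow", (224, 163, 46)),
    ("blue", (56, 61, 150)),
    ("green", (70, 148, 73)),
    ("red", (175, 54, 60)),
    ("yellow", (231, 199, 31)),
    ("magenta", (187, 86, 149)),
    ("cyan", (8, 133, 161)),
    ("white", (243, 243, 242)),
    ("neutral 8", (200, 200, 200)),
    ("neutral 6.5", (160, 160, 160)),
    ("neutral 5", (122, 122, 121)),
    ("neutral 3.5", (85, 85, 85)),
    ("black", (52, 52, 52)),
)


@dataclass(frozen=True)
class ReferenceChart:
    """A 24-patch calibration chart: patch names plus reference RGB levels."""

    names: tuple[str, ...] = tuple(n for n, _ in COLORCHECKER_CLASSIC)
    values: np.ndarray = field(
        default_factory=lambda: np.array([v for _, v in COLORCHECKER_CLASSIC], dtype=np.float64)
    )

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != (len(self.names), 3):
            raise ValueError("chart values must be one RGB triple per named patch")
        if len(self.names) != 24:
            raise ValueError(f"reference chart must have exactly 24 patches, got {len(self.names)}")
        if vals.min() < 0 or vals.max() > 255:
            raise ValueError("chart values must lie in [0, 255]")
        object.__setattr__(self, "values", vals)


def load_chart_csv(path: str | os.PathLike) -> ReferenceChart:
    """Read a user chart from CSV with columns ``name,R,G,B``."""
    names: list[str] = []
    values: list[list[float]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            names.append(row["name"])
            values.append([float(row["R"]), float(row["G"]), float(row["B"])])
    return ReferenceChart(names=tuple(names), values=np.array(values))


def gray_world(img: np.ndarray) -> np.ndarray:
    """Gray-world correction: scale each channel so its mean becomes K."""
    img = validate_rgb(img)
    arr = to_float(img)
    means = arr.reshape(-1, 3).mean(axis=0)
    if np.any(means == 0):
        raise DegenerateInputError("gray world undefined: a channel mean is zero")
    k = means.mean()
    return quantize(arr * (k / means))


def perfect_reflection(img: np.ndarray) -> np.ndarray:
    """Perfect-reflection correction: map the brightest pixel to white.

    The brightest pixel maximizes R+G+B; ties break to the first occurrence
    in row-major order.  Each channel is scaled by 255 / that pixel's value.
    """
    img = validate_rgb(img)
    arr = to_float(img)
    flat = arr.reshape(-1, 3)
    white = flat[int(np.argmax(flat.sum(axis=1)))]
    if np.any(white == 0):
        raise DegenerateInputError(
            "perfect reflection undefined: brightest pixel has a zero channel"
        )
    return quantize(arr * 255.0 / white)  # multiply first: keeps ratios like 25500/200 exact


def _block_slices(n: int, block: int):
    return [slice(i, min(i + block, n)) for i in range(0, n, block)]


def sdw_correct(img: np.ndarray, block_size: int = 16) -> np.ndarray:
    """Standard-deviation-weighted gray world over ``block_size`` blocks.

    Channel means are replaced by a weighted average of per-block channel
    means, the weight of a block being its spatial standard deviation
    (per-channel std over the block's pixels, averaged across channels,
    normalized to sum to 1), so flat single-color regions get weight ≈ 0;
    gray-world scaling then uses those means.  Falls back to plain gray
    world when every block has zero variance.
    """
    img = validate_rgb(img)
    if img.shape[0] < block_size or img.shape[1] < block_size:
        raise ValueError(f"image must be at least {block_size}×{block_size} for SDW")
    arr = to_float(img)
    stds = []
    means = []
    for rs in _block_slices(arr.shape[0], block_size):
        for cs in _block_slices(arr.shape[1], block_size):
            blk = arr[rs, cs].reshape(-1, 3)
            stds.append(blk.std(axis=0).mean())  # spatial spread, not channel spread
            means.append(blk.mean(axis=0))
    stds = np.array(stds)
    total = stds.sum()
    if total == 0:
        return gray_world(img)
    weights = stds / total
    wmeans = (weights[:, None] * np.array(means)).sum(axis=0)
    if np.any(wmeans == 0):
        raise DegenerateInputError("SDW undefined: a weighted channel mean is zero")
    k = wmeans.mean()
    return quantize(arr * (k / wmeans))


# Second-order polynomial expansion used for chart calibration.
DEFAULT_TERMS: tuple[str, ...] = ("R", "G", "B", "R2", "G2", "B2", "RG", "RB", "GB", "RGB", "1")


def expand_terms(colors: np.ndarray, terms: tuple[str, ...] = DEFAULT_TERMS) -> np.ndarray:
    """Evaluate the monomial expansion at each color.

    ``colors`` is (..., 3) on the normalized [0, 1] scale; returns (..., T).
    """
    r, g, b = colors[..., 0], colors[..., 1], colors[..., 2]
    basis = {
        "R": r, "G": g, "B": b,
        "R2": r * r, "G2": g * g, "B2": b * b,
        "RG": r * g, "RB": r * b, "GB": g * b,
        "RGB": r * g * b,
        "1": np.ones_like(r),
    }
    try:
        return np.stack([basis[t] for t in terms], axis=-1)
    except KeyError as exc:
        raise ValueError(f"unknown expansion term {exc.args[0]!r}") from None


@dataclass(frozen=True)
class PolynomialMap:
    """A fitted expansion → RGB linear map, on the normalized [0, 1] scale."""

    terms: tuple[str, ...]
    coefficients: np.ndarray  # (T, 3)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=np.float64)
        if coef.shape != (len(self.terms), 3):
            raise ValueError(
                f"coefficient matrix shape {coef.shape} does not match "
                f"{len(self.terms)} expansion terms"
            )
        object.__setattr__(self, "coefficients", coef)

    def transform(self, colors: np.ndarray) -> np.ndarray:
        """Map (..., 3) colors on [0, 1] through the fitted polynomial."""
        return expand_terms(np.asarray(colors, dtype=np.float64), self.terms) @ self.coefficients


def fit_polynomial_map(
    observed: np.ndarray,
    reference: ReferenceChart | np.ndarray,
    terms: tuple[str, ...] = DEFAULT_TERMS,
) -> PolynomialMap:
    """Least-squares fit of the observed → reference chart-color mapping.

    ``observed`` holds the chart patch colors as captured (same order as the
    reference chart), 0–255 levels.  Requires at least as many patches as
    expansion terms; the three linear terms must be present so the identity
    mapping lies in the model class.
    """
    ref_vals = reference.values if isinstance(reference, ReferenceChart) else np.asarray(reference)
    observed = np.asarray(observed, dtype=np.float64)
    if observed.shape != ref_vals.shape:
        raise ValueError(
            f"observed patch array {observed.shape} does not match reference {ref_vals.shape}"
        )
    if not {"R", "G", "B"}.issubset(terms):
        raise ValueError("term expansion must include the three linear terms R, G, B")
    n = observed.shape[0]
    if n < len(terms):
        raise ValueError(
            f"need at least {len(terms)} patches to fit {len(terms)} terms, got {n}"
        )
    design = expand_terms(observed / 255.0, terms)
    coef, _, rank, _ = np.linalg.lstsq(design, ref_vals / 255.0, rcond=None)
    if rank < len(terms):
        raise np.linalg.LinAlgError(
            f"rank-deficient calibration: design rank {rank} < {len(terms)} terms "
            "(observed patch colors are too degenerate to identify the map)"
        )
    return PolynomialMap(terms=tuple(terms), coefficients=coef)


def apply_polynomial_map(pmap: PolynomialMap, img: np.ndarray) -> np.ndarray:
    """Apply a fitted chart calibration to a whole image, pixel by pixel."""
    img = validate_rgb(img)
    out = pmap.transform(to_float(img) / 255.0)
    return quantize(out * 255.0)
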