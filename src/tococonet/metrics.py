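"""Image-quality evaluation: CIELAB ΔE, MAE/RMSE, PSNR, SSIM, cast grading.

The color-difference pipeline works in CIELAB under the sRGB → XYZ(D65) → Lab
standard transform.  ΔE is the plain CIE76 Euclidean distance

    ΔE*ab = sqrt((ΔL*)² + (Δa*)² + (Δb*)²)

summarized per image pair into mean, quartiles (Q1/Q2/Q3) and maximum over
all pixels — the "five-level" chromatic-distance summary.  A pair's mean ΔE
grades the cast severity: below 6 the images are visually the same, between
6 and 15 a mild cast, 15 and above a definite cast.

Scalar fidelity metrics follow two conventions, both reported:

* MAE and RMSE are computed on pixel values normalized to [0, 1];
* PSNR uses the 0–255 scale with MAX_I = 255,
  PSNR = 20·log10(255 / RMSE_255), reported as ``inf`` for identical images;
* SSIM uses the originating convention: c1 = (0.01·255)², c2 = (0.03·255)²,
  an 11-tap Gaussian window (σ = 1.5), computed per channel and averaged.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as _skcolor
from skimage.metrics import structural_similarity as _ssim

from .image import quantize, to_float, validate_rgb

__all__ = [
    "CastCategory",
    "DeltaESummary",
    "QualityReport",
    "rgb_to_lab",
    "lab_to_rgb",
    "delta_e_map",
    "delta_e_summary",
    "classify_cast",
    "ssim",
    "quality_report",
    "reports_to_frame",
    "CAST_SAME_THRESHOLD",
    "CAST_THRESHOLD",
]

#: Mean ΔE below which two images are considered visually identical.
CAST_SAME_THRESHOLD = 6.0
#: Mean ΔE at or above which an image is graded as a definite color cast.
CAST_THRESHOLD = 15.0

#: Report column order used everywhere a metric table is serialized.
REPORT_COLUMNS = ["PSNR", "SSIM", "E_mean", "E_Q1", "E_Q2", "E_Q3", "E_Max", "MAE", "RMSE"]


class CastCategory(enum.Enum):
    """Severity grade of a color cast judged from a mean ΔE value."""

    SAME = "same"
    MILD_CAST = "mild_cast"
    CAST = "cast"


@dataclass(frozen=True)
class DeltaESummary:
    """Five-level summary of per-pixel CIE76 ΔE over one image pair."""

    mean: float
    q1: float
    q2: float
    q3: float
    max: float

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("ΔE mean must be non-negative")
        eps = 1e-9
        if not (self.q1 <= self.q2 + eps <= self.q3 + 2 * eps <= self.max + 3 * eps):
            raise ValueError("ΔE quartiles must be ordered q1 ≤ q2 ≤ q3 ≤ max")


@dataclass(frozen=True)
class QualityReport:
    """All fidelity metrics for one (reference, test) image pair.

    ``mae`` and ``rmse`` are on the normalized [0, 1] pixel scale; ``psnr``
    is in decibels against MAX_I = 255 (``inf`` for identical images).
    """

    psnr: float
    ssim: float
    mae: float
    rmse: float
    delta_e: DeltaESummary = field(repr=False)

    def to_row(self) -> dict[str, float]:
        """Flatten into the standard report column order."""
        return {
            "PSNR": self.psnr,
            "SSIM": self.ssim,
            "E_mean": self.delta_e.mean,
            "E_Q1": self.delta_e.q1,
            "E_Q2": self.delta_e.q2,
            "E_Q3": self.delta_e.q3,
            "E_Max": self.delta_e.max,
            "MAE": self.mae,
            "RMSE": self.rmse,
        }


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to CIELAB (D65, sRGB companding).

    Returns a float array of the same spatial shape with channels
    (L*, a*, b*), L* in [0, 100].
    """
    img = validate_rgb(img)
    return _skcolor.rgb2lab(img)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`, quantized back to 8-bit RGB."""
    rgb = _skcolor.lab2rgb(lab)
    return quantize(rgb * 255.0)


def delta_e_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel CIE76 ΔE between two equally sized 8-bit RGB images."""
    a = validate_rgb(a, "first image")
    b = validate_rgb(b, "second image")
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    diff = rgb_to_lab(a) - rgb_to_lab(b)
    return np.sqrt(np.sum(diff * diff, axis=-1))


def delta_e_summary(a: np.ndarray, b: np.ndarray) -> DeltaESummary:
    """Mean / Q1 / Q2 / Q3 / max of per-pixel ΔE over all pixels of the pair.

    Quartiles use linear interpolation over the pooled pixel population.
    """
    de = delta_e_map(a, b)
    q1, q2, q3 = np.percentile(de, [25, 50, 75], method="linear")
    return DeltaESummary(
        mean=float(de.mean()), q1=float(q1), q2=float(q2), q3=float(q3), max=float(de.max())
    )


def classify_cast(mean_delta_e: float) -> CastCategory:
    """Grade a mean ΔE value: <6 same, [6, 15) mild cast, ≥15 cast.

    The boundary value 15 itself is graded as a cast (conservative flagging).
    """
    if mean_delta_e < 0:
        raise ValueError("mean ΔE must be non-negative")
    if mean_delta_e < CAST_SAME_THRESHOLD:
        return CastCategory.SAME
    if mean_delta_e < CAST_THRESHOLD:
        return CastCategory.MILD_CAST
    return CastCategory.CAST


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity of two 8-bit RGB images.

    Gaussian 11-tap window (σ = 1.5), stability constants c1 = (0.01·255)²
    and c2 = (0.03·255)², evaluated per channel and averaged.
    """
    a = validate_rgb(a, "first image")
    b = validate_rgb(b, "second image")
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    return float(
        _ssim(
            a,
            b,
            channel_axis=-1,
            data_range=255,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def quality_report(reference: np.ndarray, test: np.ndarray) -> QualityReport:
    """Full metric suite for one (reference, test) pair.

    PSNR of identical images is reported as ``inf`` — the documented
    "no distortion" sentinel — never raised as an error.
    """
    reference = validate_rgb(reference, "reference")
    test = validate_rgb(test, "test")
    if reference.shape != test.shape:
        raise ValueError(f"image dimensions differ: {reference.shape} vs {test.shape}")

    diff = to_float(reference) - to_float(test)
    mae_255 = float(np.mean(np.abs(diff)))
    rmse_255 = float(math.sqrt(np.mean(diff * diff)))
    psnr = math.inf if rmse_255 == 0.0 else 20.0 * math.log10(255.0 / rmse_255)
    return QualityReport(
        psnr=psnr,
        ssim=ssim(reference, test),
        mae=mae_255 / 255.0,
        rmse=rmse_255 / 255.0,
        delta_e=delta_e_summary(reference, test),
    )


def reports_to_frame(reports: dict[str, QualityReport] | list[QualityReport]) -> pd.DataFrame:
    """Tabulate reports as a DataFrame in the standard column order."""
    if isinstance(reports, dict):
        rows = {k: r.to_row() for k, r in reports.items()}
        return pd.DataFrame.from_dict(rows, orient="index")[REPORT_COLUMNS]
    return pd.DataFrame([r.to_row() for r in reports])[REPORT_COLUMNS]
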