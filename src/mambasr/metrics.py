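"""Paired image-quality metrics: PSNR, SSIM, GMSD and a perceptual distance.

All metrics assume single-channel 2D slices normalized to [0, 1]
(``data_range = 1``).  SSIM follows the Gaussian-window Wang-2004
formulation (11x11 window, sigma 1.5, K1 = 0.01, K2 = 0.03).  GMSD uses
Prewitt gradients and the population standard deviation of the gradient
magnitude similarity map, with the stabilizing constant rescaled from the
original 8-bit formulation (c = 170 / 255^2) to the unit range; lower is
better.  The perceptual distance dispatches to a pluggable backend and
falls back to the gradient-domain proxy when no pretrained backend is
registered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .perceptual import PREWITT_X, PREWITT_Y, get_backend

logger = logging.getLogger(__name__)

GMSD_C = 170.0 / 255.0 ** 2  # original constant rescaled to [0, 1] intensities

__all__ = ["MetricRecord", "psnr", "ssim", "gmsd", "lpips", "evaluate_pairs",
           "summarize_records", "format_summary", "GMSD_C"]


@dataclass
class MetricRecord:
    case_id: str
    method: str
    psnr: float
    ssim: float
    gmsd: float
    lpips: float


def _check_shapes(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError(f"expected two equally shaped 2D images, got {x.shape} vs {y.shape}")
    return x, y


def psnr(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> float:
    """``10 log10(range^2 / MSE)`` in dB; ``inf`` for identical images."""
    x, y = _check_shapes(x, y)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range ** 2 / mse)


def ssim(x: np.ndarray, y: np.ndarray, sigma: float = 1.5, k1: float = 0.01,
         k2: float = 0.03, data_range: float = 1.0) -> float:
    """Mean structural similarity with an 11x11 Gaussian window.

    Local means/variances/covariance are Gaussian-weighted (sigma 1.5,
    truncated at 3.5 sigma, i.e. an 11x11 support); the border of half the
    window is cropped before averaging the local map.
    """
    x, y = _check_shapes(x, y)
    truncate = 3.5
    radius = int(truncate * sigma + 0.5)
    win = 2 * radius + 1
    if min(x.shape) < win:
        raise ValueError(f"image {x.shape} smaller than the {win}x{win} SSIM window")

    def filt(img):
        return ndimage.gaussian_filter(img, sigma=sigma, truncate=truncate, mode="nearest")

    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    return float(s[radius:-radius, radius:-radius].mean())


def _prewitt_mag(img: np.ndarray) -> np.ndarray:
    # replicate boundaries: constant images then have identically zero
    # gradients, so degenerate inputs score GMS = 1 everywhere
    gx = ndimage.correlate(img, PREWITT_X, mode="nearest")
    gy = ndimage.correlate(img, PREWITT_Y, mode="nearest")
    return np.sqrt(gx ** 2 + gy ** 2)


def gmsd(x: np.ndarray, y: np.ndarray, c: float = GMSD_C) -> float:
    """Gradient magnitude similarity deviation (symmetric in x and y).

    ``GMS = (2 m1 m2 + c) / (m1^2 + m2^2 + c)`` on Prewitt gradient
    magnitudes; GMSD is the population standard deviation of the GMS map.
    Identical images — and any two constant images — score exactly 0.
    """
    x, y = _check_shapes(x, y)
    m1, m2 = _prewitt_mag(x), _prewitt_mag(y)
    gms = (2.0 * m1 * m2 + c) / (m1 ** 2 + m2 ** 2 + c)
    return float(gms.std())


def lpips(x: np.ndarray, y: np.ndarray, backend: str = "gradient_proxy") -> float:
    """Perceptual distance via a pluggable backend; 0 for identical inputs."""
    x, y = _check_shapes(x, y)
    try:
        distance, _ = get_backend(backend)
    except KeyError:
        logger.warning("perceptual backend %r unavailable; falling back to the "
                       "gradient-domain proxy", backend)
        distance, _ = get_backend("gradient_proxy")
    return float(distance(x, y))


def evaluate_pairs(cases: Sequence[Tuple[np.ndarray, np.ndarray]], method: str,
                   case_ids: Sequence[str] | None = None,
                   perceptual_backend: str = "gradient_proxy"
                   ) -> Tuple[List[MetricRecord], pd.DataFrame]:
    """Score (sr, hr) pairs and summarize as mean +/- sample SD per metric."""
    if len(cases) == 0:
        raise ValueError("no cases to evaluate")
    if case_ids is None:
        case_ids = [f"case{i:04d}" for i in range(len(cases))]
    records = [
        MetricRecord(case_id=cid, method=method,
                     psnr=psnr(sr, hr), ssim=ssim(sr, hr), gmsd=gmsd(sr, hr),
                     lpips=lpips(sr, hr, backend=perceptual_backend))
        for cid, (sr, hr) in zip(case_ids, cases)
    ]
    return records, summarize_records(records)


def summarize_records(records: Sequence[MetricRecord]) -> pd.DataFrame:
    """Mean and sample standard deviation of each metric, one row per method."""
    df = pd.DataFrame([r.__dict__ for r in records])
    out = df.groupby("method")[["psnr", "ssim", "gmsd", "lpips"]].agg(["mean", "std"])
    return out.fillna(0.0)


def format_summary(summary: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Round a summary table for reporting (2 decimals: table style; 3: text)."""
    return summary.round(decimals)
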