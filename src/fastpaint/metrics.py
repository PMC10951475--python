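"""Restoration quality metrics: RMSE, piecewise PSNR and global SSIM.

Given a ground-truth image ``GT`` and a restored output ``OP`` on a common
[0, 255] intensity scale:

    RMSE = sqrt(mean((GT - OP)^2))

    PSNR = 100                    if RMSE = 0
         = 20 * log10(255/RMSE)   if RMSE > 0

    SSIM = [2*mean(GT)*mean(OP) + c1] * [2*cov(GT, OP) + c2]
           ------------------------------------------------------------
           [mean(GT)^2 + mean(OP)^2 + c1] * [sd(GT)^2 + sd(OP)^2 + c2]

with small positive stabilizers c1 = (0.01*255)^2 and c2 = (0.03*255)^2.

Two conventions worth noting.  PSNR is defined piecewise so a perfect
restoration scores exactly 100 rather than +inf, and the dynamic-range
constant is 255 even though the pipeline's images are 16-bit — 16-bit
images are linearly rescaled to [0, 255] (division by 257) before the
formulas are applied, which keeps the printed constants meaningful.  SSIM
here uses *global* image statistics (population mean/sd/covariance over the
whole image), not the more common 11x11 sliding-window variant; a windowed
mode is available behind a flag.  Population (divide-by-N) normalization
makes ``ssim(a, a) = 1`` exact for any image, constant ones included.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np

from fastpaint.renderer import load_tiff

logger = logging.getLogger(__name__)

#: dynamic range used inside the PSNR/SSIM formulas (8-bit convention)
DYNAMIC_RANGE = 255.0

#: factor mapping the 16-bit range [0, 65535] onto [0, 255]
SIXTEEN_TO_EIGHT = 257.0


@dataclass(frozen=True)
class MetricConstants:
    """Stabilizers of the SSIM formula."""

    dynamic_range: float = DYNAMIC_RANGE
    c1: float = (0.01 * DYNAMIC_RANGE) ** 2
    c2: float = (0.03 * DYNAMIC_RANGE) ** 2

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("SSIM stabilizers c1, c2 must be positive")


@dataclass
class MetricsReport:
    """RMSE / PSNR / SSIM of one (ground truth, output) pair."""

    rmse: float
    psnr: float
    ssim: float
    gt_id: str = ""
    op_id: str = ""

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "gt_id": self.gt_id,
            "op_id": self.op_id,
        }


def _check_pair(gt, op) -> tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt, dtype=np.float64)
    op = np.asarray(op, dtype=np.float64)
    if gt.shape != op.shape:
        raise ValueError(f"image dimensions differ: {gt.shape} vs {op.shape}")
    if gt.size == 0:
        raise ValueError("empty images")
    return gt, op


def to_dynamic_range(image) -> np.ndarray:
    """Map a 16-bit image linearly onto the [0, 255] metric scale."""
    return np.asarray(image, dtype=np.float64) / SIXTEEN_TO_EIGHT


def rmse(gt, op) -> float:
    """Root-mean-square error between two images on a common scale."""
    gt, op = _check_pair(gt, op)
    return float(np.sqrt(np.mean((gt - op) ** 2)))


def psnr(gt, op) -> float:
    """Piecewise peak signal-to-noise ratio (100 for a perfect match)."""
    r = rmse(gt, op)
    if r == 0.0:
        return 100.0
    return float(20.0 * math.log10(DYNAMIC_RANGE / r))


def ssim(gt, op, constants: MetricConstants = MetricConstants(), windowed: bool = False) -> float:
    """Structural similarity from global image statistics.

    ``windowed=True`` switches to an 11x11 uniform sliding window averaged
    over the image (closer to the original SSIM literature); the default is
    the single global-statistics formula.
    """
    gt, op = _check_pair(gt, op)
    if windowed:
        return _ssim_windowed(gt, op, constants)
    mu_g, mu_o = gt.mean(), op.mean()
    # population normalization: divide by N, so ssim(a, a) == 1 exactly
    sd_g2 = gt.var()
    sd_o2 = op.var()
    cov = ((gt - mu_g) * (op - mu_o)).mean()
    num = (2.0 * mu_g * mu_o + constants.c1) * (2.0 * cov + constants.c2)
    den = (mu_g**2 + mu_o**2 + constants.c1) * (sd_g2 + sd_o2 + constants.c2)
    return float(num / den)


def _ssim_windowed(gt, op, constants: MetricConstants, win: int = 11) -> float:
    from scipy import ndimage

    mu_g = ndimage.uniform_filter(gt, win)
    mu_o = ndimage.uniform_filter(op, win)
    sd_g2 = ndimage.uniform_filter(gt * gt, win) - mu_g**2
    sd_o2 = ndimage.uniform_filter(op * op, win) - mu_o**2
    cov = ndimage.uniform_filter(gt * op, win) - mu_g * mu_o
    num = (2.0 * mu_g * mu_o + constants.c1) * (2.0 * cov + constants.c2)
    den = (mu_g**2 + mu_o**2 + constants.c1) * (sd_g2 + sd_o2 + constants.c2)
    return float((num / den).mean())


def evaluate_pair(gt_image, op_image, rescale_16bit: bool = True, gt_id: str = "", op_id: str = "") -> MetricsReport:
    """Compute all three metrics for an image pair.

    With ``rescale_16bit`` (the default) both images are divided by 257 to
    map the 16-bit range onto [0, 255] first; pass ``False`` for images
    already on the 8-bit scale.
    """
    gt = to_dynamic_range(gt_image) if rescale_16bit else np.asarray(gt_image, dtype=np.float64)
    op = to_dynamic_range(op_image) if rescale_16bit else np.asarray(op_image, dtype=np.float64)
    return MetricsReport(rmse=rmse(gt, op), psnr=psnr(gt, op), ssim=ssim(gt, op), gt_id=gt_id, op_id=op_id)


def performance_report(gt_path, op_path, json_path=None) -> MetricsReport:
    """Evaluate a (ground truth, output) TIFF pair and log the numbers.

    Loads both images (16-bit grayscale), rescales to the metric range,
    computes RMSE/PSNR/SSIM, logs them, and optionally writes the report as
    JSON alongside.
    """
    gt = load_tiff(gt_path, role="ground_truth").pixels
    op = load_tiff(op_path, role="ground_truth").pixels
    report = evaluate_pair(gt, op, gt_id=str(gt_path), op_id=str(op_path))
    logger.info(
        "PSNR=%.4f RMSE=%.6f SSIM=%.6f (%s vs %s)",
        report.psnr, report.rmse, report.ssim, gt_path, op_path,
    )
    if json_path is not None:
        with open(json_path, "w") as f:
            json.dump(report.to_dict(), f, indent=1)
    return report
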