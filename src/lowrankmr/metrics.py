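"""Global image-fidelity metrics: PSNR and whole-image SSIM.

Both metrics use whole-image statistics (no sliding window) and population
(1/n) variance.  PSNR uses a fixed peak of 255, so images are expected on a
0-255 nominal scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from lowrankmr.denoise_core import ImageMatrix

__all__ = ["QualityReport", "DegenerateImageError", "psnr", "ssim", "quality_report"]

_PEAK = 255.0
# stabilisation constants, standard convention for an 8-bit dynamic range
C1 = (0.01 * _PEAK) ** 2
C2 = (0.03 * _PEAK) ** 2
C3 = C2 / 2.0


class DegenerateImageError(ValueError):
    """Raised when the unstabilised SSIM form is undefined (constant image
    or zero-mean pair makes a denominator vanish)."""


def _values(img: ImageMatrix | np.ndarray) -> np.ndarray:
    if isinstance(img, ImageMatrix):
        return img.values
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite entries")
    return arr


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    x, y = _values(a), _values(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(reference, reconstructed) -> float:
    """Mean squared error over all pixels."""
    x, y = _pair(reference, reconstructed)
    return float(np.mean((x - y) ** 2))


def psnr(reference, reconstructed) -> float:
    """Peak signal-to-noise ratio in dB, ``10*log10(255^2 / MSE)``.

    Identical images (MSE = 0) return ``math.inf``.
    """
    err = mse(reference, reconstructed)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(_PEAK ** 2 / err)


def _stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    mu_x = float(np.mean(x))
    mu_y = float(np.mean(y))
    var_x = float(np.mean((x - mu_x) ** 2))  # population variance
    var_y = float(np.mean((y - mu_y) ** 2))
    cov = float(np.mean((x - mu_x) * (y - mu_y)))
    return mu_x, mu_y, var_x, var_y, cov


def ssim_components(x, y) -> tuple[float, float, float]:
    """Stabilised luminance, contrast and structure comparison terms."""
    xv, yv = _pair(x, y)
    mu_x, mu_y, var_x, var_y, cov = _stats(xv, yv)
    sd_x, sd_y = math.sqrt(var_x), math.sqrt(var_y)
    lum = (2 * mu_x * mu_y + C1) / (mu_x ** 2 + mu_y ** 2 + C1)
    con = (2 * sd_x * sd_y + C2) / (var_x + var_y + C2)
    stru = (cov + C3) / (sd_x * sd_y + C3)
    return lum, con, stru


def ssim(x, y, mode: str = "eq5") -> float:
    """Whole-image structural similarity.

    mode "eq5"
        The simplified closed form ``4*mu_x*mu_y*cov /
        ((mu_x^2 + mu_y^2) * (var_x + var_y))`` with no stabilising
        constants.  Undefined for constant images or a zero-mean pair;
        raises :class:`DegenerateImageError` rather than returning NaN.
    mode "stabilized"
        The product of the luminance, contrast and structure terms with
        C1 = (0.01*255)^2, C2 = (0.03*255)^2, C3 = C2/2.
    """
    xv, yv = _pair(x, y)
    if xv.size < 2:
        raise ValueError("SSIM requires at least 2 pixels")
    if mode == "eq5":
        mu_x, mu_y, var_x, var_y, cov = _stats(xv, yv)
        denom = (mu_x ** 2 + mu_y ** 2) * (var_x + var_y)
        if denom == 0.0:
            raise DegenerateImageError(
                "unstabilised SSIM is undefined: constant image or zero-mean pair"
            )
        return 4.0 * mu_x * mu_y * cov / denom
    if mode == "stabilized":
        lum, con, stru = ssim_components(xv, yv)
        return lum * con * stru
    raise ValueError(f"unknown SSIM mode {mode!r}; use 'eq5' or 'stabilized'")


@dataclass(frozen=True)
class QualityReport:
    """Per-image fidelity bundle for one reconstruction."""

    psnr_db: float
    ssim: float
    luminance: float
    contrast: float
    structure: float
    mse: float

    def to_dict(self) -> dict[str, float]:
        return {
            "psnr_db": self.psnr_db,
            "ssim": self.ssim,
            "luminance": self.luminance,
            "contrast": self.contrast,
            "structure": self.structure,
            "mse": self.mse,
        }


def quality_report(reference, reconstructed, ssim_mode: str = "stabilized") -> QualityReport:
    """Bundle PSNR, SSIM and the SSIM components into one report.

    The components are always the stabilised terms; the headline ``ssim``
    honours ``ssim_mode``.
    """
    err = mse(reference, reconstructed)
    lum, con, stru = ssim_components(reference, reconstructed)
    return QualityReport(
        psnr_db=psnr(reference, reconstructed),
        ssim=ssim(reference, reconstructed, mode=ssim_mode),
        luminance=lum,
        contrast=con,
        structure=stru,
        mse=err,
    )
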