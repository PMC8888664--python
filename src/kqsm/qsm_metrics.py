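"""Reconstruction-fidelity metrics and line-profile statistics.

Volumetric metrics (computed within a brain/phantom mask, against a
reference reconstruction):

* NRMSE — ``100 * ||x - ref||_2 / ||ref||_2``  (percent).
* PSNR — ``10 log10(peak^2 / MSE)`` with peak = max - min of the
  reference over the mask (dB); identical volumes report the cap
  ``PSNR_CAP``.
* HFEN — NRMSE of Laplacian-of-Gaussian filtered volumes (15^3 kernel,
  sigma 1.5, the QSM reconstruction-challenge convention), percent.
* SSIM — mean local structural similarity x 100, Gaussian window
  sigma 1.5, dynamic range taken from the reference over the mask.

Line profiles (susceptibility sampled along a segment through deep
gray-matter structures) are compared by MAE, RMSE and Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats
from skimage.metrics import structural_similarity

from .kspace_physics import ValidationError

__all__ = [
    "MetricReport",
    "LineProfile",
    "nrmse",
    "psnr",
    "hfen",
    "ssim",
    "profile_metrics",
    "extract_profile",
    "evaluate",
    "relative_improvement",
    "PSNR_CAP",
]

#: Sentinel reported instead of +inf for a zero-error PSNR.
PSNR_CAP = 200.0

_LOG_SIGMA = 1.5
_LOG_TRUNCATE = 7.0 / _LOG_SIGMA  # 15-voxel kernel extent


@dataclass
class MetricReport:
    """Bundle of the volumetric and profile metrics (all optional)."""

    nrmse_pct: Optional[float] = None
    psnr_db: Optional[float] = None
    hfen_pct: Optional[float] = None
    ssim_pct: Optional[float] = None
    mae: Optional[float] = None
    rmse: Optional[float] = None
    pcc: Optional[float] = None

    def __post_init__(self):
        for name in ("nrmse_pct", "hfen_pct"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.ssim_pct is not None and self.ssim_pct > 100.0 + 1e-9:
            raise ValidationError("ssim_pct cannot exceed 100")
        if self.pcc is not None and not (-1.0 - 1e-12 <= self.pcc <= 1.0 + 1e-12):
            raise ValidationError("pcc must lie in [-1, 1]")

    def as_dict(self) -> Dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


@dataclass
class LineProfile:
    """Ordered voxel samples along a segment, optionally labeled by the
    anatomical structure each stretch crosses."""

    coordinates: np.ndarray  # (n, 3) int voxel indices
    values: np.ndarray  # (n,) sampled susceptibility
    segment_labels: Optional[Sequence[str]] = None


def _masked(x, ref, mask):
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValidationError("volumes must share a shape")
    if mask is None:
        return x.ravel(), ref.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.shape:
        raise ValidationError("mask shape mismatch")
    return x[mask], ref[mask]


def nrmse(x, ref, mask=None) -> float:
    """Normalized root mean square error, percent of the reference norm."""
    xv, rv = _masked(x, ref, mask)
    rnorm = np.linalg.norm(rv)
    if rnorm == 0:
        raise ValidationError("NRMSE undefined for an all-zero reference")
    return 100.0 * float(np.linalg.norm(xv - rv) / rnorm)


def psnr(x, ref, mask=None) -> float:
    """Peak signal-to-noise ratio in dB; peak = reference range over mask."""
    xv, rv = _masked(x, ref, mask)
    peak = float(rv.max() - rv.min())
    if peak == 0:
        raise ValidationError("PSNR undefined for a constant reference")
    mse = float(np.mean((xv - rv) ** 2))
    if mse == 0:
        return PSNR_CAP
    return min(PSNR_CAP, 10.0 * float(np.log10(peak * peak / mse)))


def _log_filter(x: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_laplace(np.asarray(x, dtype=float),
                                    sigma=_LOG_SIGMA, truncate=_LOG_TRUNCATE)


def hfen(x, ref, mask=None) -> float:
    """High-frequency error norm: NRMSE of LoG-filtered volumes, percent."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValidationError("volumes must share a shape")
    if np.ptp(ref) == 0:
        raise ValidationError("HFEN undefined for a structure-free reference")
    fx, fr = _log_filter(x), _log_filter(ref)
    xv, rv = _masked(fx, fr, mask)
    rnorm = np.linalg.norm(rv)
    if rnorm == 0:
        raise ValidationError("HFEN undefined for a structure-free reference")
    return 100.0 * float(np.linalg.norm(xv - rv) / rnorm)


def ssim(x, ref, mask=None) -> float:
    """Mean local structural similarity over the mask, percent."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValidationError("volumes must share a shape")
    _, rv = _masked(x, ref, mask)
    drange = float(rv.max() - rv.min())
    if drange == 0:
        drange = 1.0
    _, ssim_map = structural_similarity(
        ref, x, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=drange, full=True)
    if mask is not None:
        ssim_map = ssim_map[np.asarray(mask, dtype=bool)]
    return 100.0 * float(ssim_map.mean())


def profile_metrics(profile_x, profile_ref) -> Tuple[float, float, float]:
    """MAE, RMSE and Pearson correlation between two line profiles."""
    xv = np.asarray(getattr(profile_x, "values", profile_x), dtype=float)
    rv = np.asarray(getattr(profile_ref, "values", profile_ref), dtype=float)
    if xv.shape != rv.shape or xv.ndim != 1 or xv.size < 2:
        raise ValidationError("profiles must be equal-length 1D with n >= 2")
    mae = float(np.mean(np.abs(xv - rv)))
    rmse = float(np.sqrt(np.mean((xv - rv) ** 2)))
    if np.ptp(xv) == 0 or np.ptp(rv) == 0:
        raise ValidationError("Pearson correlation undefined for a constant profile")
    pcc = float(stats.pearsonr(xv, rv).statistic)
    return mae, rmse, pcc


def extract_profile(volume, start_voxel, end_voxel,
                    segment_labels=None) -> LineProfile:
    """Sample a volume along the segment from start to end voxel.

    Stepping rule: ``n = max(|delta|_inf, 1) + 1`` points placed at equal
    parametric spacing along the segment, each rounded to the nearest
    voxel (nearest-neighbour sampling), order preserved from start to
    end.  Start == end yields a single sample.
    """
    vol = np.asarray(volume)
    start = np.asarray(start_voxel, dtype=float)
    end = np.asarray(end_voxel, dtype=float)
    for p in (start, end):
        if np.any(p < 0) or np.any(p > np.asarray(vol.shape) - 1):
            raise ValidationError(f"profile endpoint {p} outside the grid")
    n = int(np.max(np.abs(end - start))) + 1
    t = np.linspace(0.0, 1.0, n)
    coords = np.rint(start[None, :] + t[:, None] * (end - start)[None, :]).astype(int)
    values = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
    return LineProfile(coordinates=coords, values=values,
                       segment_labels=segment_labels)


def evaluate(x, ref, mask=None) -> MetricReport:
    """All four volumetric metrics in one report."""
    return MetricReport(
        nrmse_pct=nrmse(x, ref, mask),
        psnr_db=psnr(x, ref, mask),
        hfen_pct=hfen(x, ref, mask),
        ssim_pct=ssim(x, ref, mask),
    )


def relative_improvement(value: float, baseline: float,
                         higher_is_better: bool = False) -> float:
    """Percent improvement of ``value`` over ``baseline``.

    For error-type metrics (lower better) this is
    ``100 (baseline - value) / baseline``; for quality-type metrics
    (higher better), ``100 (value - baseline) / baseline``.
    """
    if baseline == 0:
        raise ValidationError("baseline must be nonzero")
    delta = (value - baseline) if higher_is_better else (baseline - value)
    return 100.0 * delta / abs(baseline)
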