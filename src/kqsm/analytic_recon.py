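"""Closed-form k-space dipole inversions: TKD and COSMOS.

Truncated k-space division (TKD) inverts the dipole relation pointwise,
flooring the kernel magnitude at a threshold ``thr`` to cap noise
amplification near the magic-angle cone:

    X_TKD(k) = deltaB(k) / ( sign(D) * max(|D|, thr) ).

COSMOS fuses field maps acquired at several head orientations by
least squares in k-space:

    X(k) = sum_i deltaB_i(k) D_i(k) / sum_i D_i(k)^2,

which is exact wherever at least one orientation has a non-vanishing
kernel; with three or more generic orientations the joint zero set is
empty away from DC.  Where the denominator falls below ``eps`` the
output is set to zero (this includes DC, where every D_i is zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .kspace_physics import (
    B0Vector,
    DipoleKernel,
    FieldMap,
    KSpaceVolume,
    SusceptibilityVolume,
    ValidationError,
    fft_volume,
    ifft_volume,
)

__all__ = [
    "TKDResult",
    "NonIllMask",
    "tkd_reconstruct",
    "nonill_mask",
    "cosmos_reconstruct",
    "min_sum_squared_kernel",
    "min_cosmos_orientations",
    "DEFAULT_TKD_THR",
    "COSMOS_EPS",
]

#: Threshold recommended for plain TKD; 0.1 is equally first-class for
#: the learned correction (both variants are trained in practice).
DEFAULT_TKD_THR = 0.2

#: Guard on the COSMOS denominator sum(D_i^2).
COSMOS_EPS = 1e-8


def min_sum_squared_kernel(
    b0s: Sequence[B0Vector],
    n_dirs: int = 100_000,
    seed: int = 0,
    refine: bool = True,
) -> float:
    """Minimum over k-directions of sum_i D_i(k)^2 for a set of
    orientations.

    Samples ``n_dirs`` random unit directions (the kernel depends only
    on direction), takes the coarse minimum and, when ``refine`` is on,
    polishes the best candidates with a local Nelder-Mead search on the
    sphere.  A minimum bounded away from zero means the orientation set
    jointly covers k-space — the condition multi-orientation fusion
    needs, met by three or more generic orientations but not by one or
    two (whose magic-angle cones intersect).
    """
    from scipy.optimize import minimize

    if len(b0s) == 0:
        raise ValidationError("need at least one orientation")
    bs = [np.asarray(b.direction) for b in b0s]
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((int(n_dirs), 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    d2 = np.stack([(1.0 / 3.0 - (dirs @ b) ** 2) ** 2 for b in bs])
    ssq = d2.sum(axis=0)
    best = float(ssq.min())
    if not refine:
        return best

    def objective(tp):
        t, p = tp
        d = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
        return sum((1.0 / 3.0 - float(d @ b) ** 2) ** 2 for b in bs)

    for i in np.argsort(ssq)[:20]:
        d = dirs[i]
        t0 = np.arccos(np.clip(d[2], -1.0, 1.0))
        p0 = np.arctan2(d[1], d[0])
        res = minimize(objective, [t0, p0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 500})
        best = min(best, float(res.fun))
    return best


def min_cosmos_orientations(
    b0s: Sequence[B0Vector],
    n_dirs: int = 100_000,
    threshold: float = 1e-3,
    seed: int = 0,
) -> int:
    """Smallest prefix of ``b0s`` whose joint kernel power stays above
    ``threshold`` for every k-direction (0 if none does)."""
    for k in range(1, len(b0s) + 1):
        if min_sum_squared_kernel(b0s[:k], n_dirs, seed) > threshold:
            return k
    return 0


@dataclass
class TKDResult:
    """TKD inversion: k-space estimate, spatial map, and the threshold."""

    kspace: KSpaceVolume
    susceptibility: SusceptibilityVolume
    thr: float


@dataclass
class NonIllMask:
    """Boolean k-space mask of the non-ill-posed region |D| >= thr."""

    values: np.ndarray
    thr: float

    @property
    def fraction(self) -> float:
        return float(self.values.mean())


def _check_thr(thr: float) -> float:
    thr = float(thr)
    if not (0.0 < thr < 1.0 / 3.0):
        raise ValidationError(
            f"TKD threshold must lie in (0, 1/3), got {thr}; outside this "
            "range the truncation either keeps nothing or truncates nothing"
        )
    return thr


def tkd_reconstruct(field: FieldMap, kernel: DipoleKernel, thr: float = DEFAULT_TKD_THR) -> TKDResult:
    """Invert the dipole model by truncated k-space division.

    The kernel magnitude is floored at ``thr`` (keeping the sign of D,
    with sign(0) taken as +1), so the amplification of any k-space
    sample is capped at 1/thr.  The spatial map is the real part of the
    inverse transform; the imaginary residue is asserted negligible.
    """
    thr = _check_thr(thr)
    if field.grid != kernel.grid:
        raise ValidationError("field and kernel grids differ")
    d = kernel.values
    denom = np.where(d >= 0.0, 1.0, -1.0) * np.maximum(np.abs(d), thr)
    spec = fft_volume(field.values, field.grid).complex / denom
    kvol = KSpaceVolume.from_complex(spec, field.grid)
    vol = ifft_volume(kvol)
    norm = np.linalg.norm(vol)
    if norm > 0 and np.linalg.norm(vol.imag) > 1e-8 * norm:
        raise ValidationError("TKD produced non-negligible imaginary part")
    chi = SusceptibilityVolume(values=vol.real, grid=field.grid)
    return TKDResult(kspace=kvol, susceptibility=chi, thr=thr)


def nonill_mask(kernel: DipoleKernel, thr: float) -> NonIllMask:
    """Mask of k-points where |D| >= thr (signals trusted by TKD)."""
    thr = float(thr)
    if thr <= 0:
        raise ValidationError("mask threshold must be positive")
    return NonIllMask(values=np.abs(kernel.values) >= thr, thr=thr)


def cosmos_reconstruct(
    acquisitions: Sequence[Tuple[FieldMap, DipoleKernel]],
    eps: float = COSMOS_EPS,
) -> SusceptibilityVolume:
    """Least-squares multi-orientation fusion of field maps in k-space.

    Parameters
    ----------
    acquisitions
        Pairs of (field map, dipole kernel); all on the same grid, each
        kernel built for the orientation its field map was acquired at.
    eps
        Denominator guard: where ``sum_i D_i^2 < eps`` the susceptibility
        estimate is set to zero (the joint null space, always including
        DC).
    """
    if len(acquisitions) == 0:
        raise ValidationError("COSMOS needs at least one acquisition")
    grid = acquisitions[0][0].grid
    num = np.zeros(grid.shape, dtype=complex)
    den = np.zeros(grid.shape, dtype=float)
    for fmap, kernel in acquisitions:
        if fmap.grid != grid or kernel.grid != grid:
            raise ValidationError("all acquisitions must share one grid")
        d = kernel.values
        num += fft_volume(fmap.values, grid).complex * d
        den += d * d
    bad = den < eps
    if bad.sum() > 1:  # DC is always in the null space
        warnings.warn(
            f"COSMOS denominator below eps at {int(bad.sum())} k-points; "
            "output zeroed there",
            stacklevel=2,
        )
    spec = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    vol = ifft_volume(KSpaceVolume.from_complex(spec, grid))
    return SusceptibilityVolume(values=vol.real, grid=grid)
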