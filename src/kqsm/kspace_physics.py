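"""Dipole-kernel physics and centered Fourier conventions.

Susceptibility-to-field forward model used throughout the package: a
susceptibility distribution chi (ppm) perturbs the local field along B0,
and in the Fourier domain the relation is a pointwise multiplication with
the dipole kernel

    D(k) = 1/3 - kp^2 / k^2,        kp = k . b0,

which vanishes on the cone at the magic angle arccos(sqrt(1/3)) ~ 54.74
degrees from the main-field direction and makes direct inversion
ill-posed there.

Conventions (fixed here, used by every module):

* k-space is **centered**: the DC component sits at the geometric center
  of the array (``shape // 2`` per axis).  ``fft_volume`` returns
  ``fftshift(fftn(v))`` and ``ifft_volume`` undoes it.
* FFTs use numpy's default normalization (no scaling forward, ``1/N`` on
  the inverse), so Parseval reads ``sum |v|^2 = sum |V|^2 / N``.
* Frequencies are physical (cycles/mm), derived from the voxel size; the
  kernel only depends on the *direction* of k, but the grid respects
  anisotropic voxels.
* ``D(k=0) := 0``: the mean susceptibility is unobservable from the
  local field, so the DC term is pinned to zero (``dc_policy="zero"``).
* All FFT work is done in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "B0Vector",
    "DipoleKernel",
    "SusceptibilityVolume",
    "FieldMap",
    "KSpaceVolume",
    "make_dipole_kernel",
    "fft_volume",
    "ifft_volume",
    "forward_field",
    "rotation_to_b0",
    "kernel_zero_crossing_angle",
    "MAGIC_ANGLE_DEG",
]

#: Angle from B0 at which the continuous dipole kernel crosses zero.
MAGIC_ANGLE_DEG = float(np.degrees(np.arccos(np.sqrt(1.0 / 3.0))))


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice: array shape plus voxel size in mm."""

    shape: tuple
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or len(vs) != 3:
            raise ValidationError("grid must be 3D")
        if any(s < 4 for s in shape):
            raise ValidationError(f"each axis needs >= 4 voxels, got {shape}")
        if any(v <= 0 for v in vs):
            raise ValidationError(f"voxel_size must be positive, got {vs}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)

    def freq_axes(self):
        """Centered frequency coordinates (cycles/mm) per axis."""
        return [
            np.fft.fftshift(np.fft.fftfreq(n, d=d))
            for n, d in zip(self.shape, self.voxel_size)
        ]

    def center(self):
        """Voxel index of the DC component in the centered layout."""
        return tuple(n // 2 for n in self.shape)


@dataclass(frozen=True)
class B0Vector:
    """Unit direction of the main magnetic field in the image frame."""

    direction: tuple

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,):
            raise ValidationError("B0 direction must have 3 components")
        if not np.all(np.isfinite(d)):
            raise ValidationError("B0 direction must be finite")
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValidationError(
                f"B0 direction must be unit-norm, |b0| = {np.linalg.norm(d)!r}"
            )
        object.__setattr__(self, "direction", tuple(float(x) for x in d))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.direction)


def _check_volume(values: np.ndarray, grid: VoxelGrid, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValidationError(
            f"{name} shape {values.shape} does not match grid {grid.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{name} contains non-finite values")
    return values


@dataclass
class SusceptibilityVolume:
    """Scalar susceptibility map chi in ppm, with optional brain mask."""

    values: np.ndarray
    grid: VoxelGrid
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = _check_volume(self.values, self.grid, "susceptibility")
        if self.mask is not None:
            m = np.asarray(self.mask)
            if m.shape != self.grid.shape:
                raise ValidationError("mask shape does not match grid")
            self.mask = m.astype(bool)


@dataclass
class FieldMap:
    """Relative local field offset deltaB (dimensionless) for one B0."""

    values: np.ndarray
    grid: VoxelGrid
    b0: B0Vector

    def __post_init__(self):
        self.values = _check_volume(self.values, self.grid, "field map")


@dataclass
class KSpaceVolume:
    """Complex centered-k-space volume carried as real/imag channels."""

    real_part: np.ndarray
    imag_part: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        self.real_part = _check_volume(self.real_part, self.grid, "real part")
        self.imag_part = _check_volume(self.imag_part, self.grid, "imag part")

    @property
    def complex(self) -> np.ndarray:
        return self.real_part + 1j * self.imag_part

    @classmethod
    def from_complex(cls, values: np.ndarray, grid: VoxelGrid) -> "KSpaceVolume":
        values = np.asarray(values)
        return cls(values.real.copy(), values.imag.copy(), grid)


@dataclass
class DipoleKernel:
    """Real dipole kernel D(k) on the centered k-grid for one B0."""

    values: np.ndarray
    b0: B0Vector
    grid: VoxelGrid
    dc_policy: str = "zero"

    def __post_init__(self):
        self.values = _check_volume(self.values, self.grid, "dipole kernel")
        if self.dc_policy != "zero":
            raise ValidationError(f"unknown dc_policy {self.dc_policy!r}")
        vmin, vmax = self.values.min(), self.values.max()
        if vmin < -2.0 / 3.0 - 1e-12 or vmax > 1.0 / 3.0 + 1e-12:
            raise ValidationError(
                f"dipole kernel out of [-2/3, 1/3]: [{vmin}, {vmax}]"
            )
        if self.values[self.grid.center()] != 0.0:
            raise ValidationError("dc_policy=zero requires D(0) = 0")


def make_dipole_kernel(
    grid: VoxelGrid, b0: B0Vector, dc_policy: str = "zero"
) -> DipoleKernel:
    """Build D(k) = 1/3 - (k.b0)^2 / |k|^2 on the centered frequency grid.

    The continuous-form kernel is evaluated on physical frequency
    coordinates (cycles/mm via ``grid.voxel_size``); the k=0 singularity
    is replaced by 0 (``dc_policy="zero"``).
    """
    if dc_policy != "zero":
        raise ValidationError(f"unknown dc_policy {dc_policy!r}")
    fx, fy, fz = grid.freq_axes()
    kx, ky, kz = np.meshgrid(fx, fy, fz, indexing="ij")
    bx, by, bz = b0.direction
    k2 = kx * kx + ky * ky + kz * kz
    kp = kx * bx + ky * by + kz * bz
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 / 3.0 - (kp * kp) / k2
    values[grid.center()] = 0.0
    # enforce evenness under k -> -k: on even-sized axes the Nyquist
    # plane has no mirror partner and a tilted B0 would otherwise break
    # the symmetry there (and make the forward field complex)
    values = 0.5 * (values + _mirror_centered(values))
    return DipoleKernel(values=values, b0=b0, grid=grid, dc_policy="zero")


def _mirror_centered(v: np.ndarray) -> np.ndarray:
    """v(-k) on the centered grid (Nyquist rows map to themselves)."""
    flipped = v[::-1, ::-1, ::-1]
    shifts = [1 if n % 2 == 0 else 0 for n in v.shape]
    return np.roll(flipped, shifts, axis=(0, 1, 2))


def fft_volume(values: np.ndarray, grid: Optional[VoxelGrid] = None) -> KSpaceVolume:
    """Forward FFT into the centered layout (DC at the array center)."""
    values = np.asarray(values)
    if not np.all(np.isfinite(values)):
        raise ValidationError("fft input must be finite")
    if grid is None:
        grid = VoxelGrid(values.shape)
    elif values.shape != grid.shape:
        raise ValidationError("fft input shape does not match grid")
    spec = np.fft.fftshift(np.fft.fftn(values.astype(np.float64)))
    return KSpaceVolume.from_complex(spec, grid)


def ifft_volume(kvol: KSpaceVolume) -> np.ndarray:
    """Inverse of :func:`fft_volume`; returns the complex spatial volume."""
    return np.fft.ifftn(np.fft.ifftshift(kvol.complex))


def forward_field(chi: SusceptibilityVolume, kernel: DipoleKernel) -> FieldMap:
    """Forward dipole model: deltaB = iFFT( D(k) * FFT(chi) ).

    chi is in ppm, so the returned relative field offset is in the same
    ppm scale.  D is real and even, hence the result is real up to
    floating-point residue; the imaginary part is asserted to be below
    1e-8 of the signal norm and discarded.
    """
    if chi.grid != kernel.grid:
        raise ValidationError("susceptibility and kernel grids differ")
    spec = fft_volume(chi.values, chi.grid).complex * kernel.values
    vol = np.fft.ifftn(np.fft.ifftshift(spec))
    norm = np.linalg.norm(vol)
    if norm > 0 and np.linalg.norm(vol.imag) > 1e-8 * norm:
        raise ValidationError("forward model produced non-negligible imaginary part")
    return FieldMap(values=vol.real, grid=chi.grid, b0=kernel.b0)


def kernel_zero_crossing_angle(tol_deg: float = 1e-9) -> float:
    """Angle (degrees from B0) where the continuous kernel crosses zero.

    Solves 1/3 = cos^2(theta) by bisection on [0, 90] degrees; the
    closed form is arccos(sqrt(1/3)) ~ 54.7356 degrees (the magic
    angle).  Found numerically so the geometry is checked, not assumed.
    """
    f = lambda deg: 1.0 / 3.0 - np.cos(np.radians(deg)) ** 2
    lo, hi = 0.0, 90.0  # f(0) < 0 < f(90)
    while hi - lo > tol_deg:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def rotation_to_b0(angle_x_deg: float, angle_y_deg: float = 0.0) -> B0Vector:
    """B0 direction after rotating the default (0, 0, 1) axis.

    Right-handed rotations, applied about the x axis first and then the
    y axis: ``b0 = Ry(angle_y) @ Rx(angle_x) @ (0, 0, 1)``.  Zero angles
    return (0, 0, 1); a +90 degree rotation about x maps it to (0, -1, 0).
    """
    ax = np.radians(float(angle_x_deg))
    ay = np.radians(float(angle_y_deg))
    if not (np.isfinite(ax) and np.isfinite(ay)):
        raise ValidationError("rotation angles must be finite")
    rx = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(ax), -np.sin(ax)],
            [0.0, np.sin(ax), np.cos(ax)],
        ]
    )
    ry = np.array(
        [
            [np.cos(ay), 0.0, np.sin(ay)],
            [0.0, 1.0, 0.0],
            [-np.sin(ay), 0.0, np.cos(ay)],
        ]
    )
    d = ry @ rx @ np.array([0.0, 0.0, 1.0])
    d /= np.linalg.norm(d)
    return B0Vector(tuple(d))
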