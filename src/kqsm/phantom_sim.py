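"""Synthetic susceptibility phantoms, analytic field oracles, and
multi-orientation field-map simulation.

This module stands in for multi-orientation in-vivo acquisitions: it
builds brain-like piecewise-smooth susceptibility volumes (ppm scale)
with integer ROI labels, simulates the field maps each head orientation
would measure through the dipole forward model, adds acquisition noise,
and can inject an orientation-dependent apparent susceptibility into
selected ROIs so that white-matter-style anisotropy statistics have
signal to detect.

The sphere phantom has a closed-form field, used as an independent
oracle for the FFT forward model:

    deltaB(r) = (dchi / 3) (a / r)^3 (3 cos^2(theta) - 1)   for r > a
    deltaB(r) = 0                                           for r < a

with ``a`` the radius and ``theta`` the angle between (r - center) and
B0.  The zero interior field matches the Lorentz-corrected convention
of the k-space dipole kernel (a uniform sphere shifts no local field
inside itself); the mean over the volume is likewise removed, mirroring
the kernel's pinned DC term.

The default phantom suite mimics a small multi-subject study: 6
training, 1 validation and 1 test phantom on 64^3 grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .kspace_physics import (
    B0Vector,
    FieldMap,
    SusceptibilityVolume,
    ValidationError,
    VoxelGrid,
    forward_field,
    make_dipole_kernel,
    rotation_to_b0,
)

__all__ = [
    "Shape",
    "PhantomSpec",
    "ROILabelMap",
    "AnisotropySpec",
    "generate_phantom",
    "smooth_random_phantom",
    "analytic_sphere_field",
    "simulate_multi_orientation",
    "apply_anisotropy",
    "default_phantom_suite",
    "default_orientations",
]


@dataclass(frozen=True)
class Shape:
    """One phantom structure: a hard sphere/cylinder or a soft blob.

    ``size`` is the radius in voxels (for blobs, the Gaussian sigma);
    ``chi`` the susceptibility in ppm assigned inside (for blobs, the
    peak amplitude added on top of the background).
    """

    kind: str
    center: tuple
    size: float
    chi: float
    name: str = ""

    def __post_init__(self):
        if self.kind not in ("sphere", "cylinder", "smooth-blob"):
            raise ValidationError(f"unknown shape kind {self.kind!r}")
        if self.size <= 0:
            raise ValidationError("shape size must be positive")
        if abs(self.chi) > 1.0:
            raise ValidationError(
                f"|chi| = {abs(self.chi)} ppm outside the brain-plausible 1 ppm range"
            )


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic susceptibility volume."""

    grid: VoxelGrid
    shapes: List[Shape] = field(default_factory=list)
    background_chi: float = 0.0
    texture_sd: float = 0.0  # ppm; smooth seeded texture added everywhere
    seed: int = 0

    def __post_init__(self):
        for s in self.shapes:
            c = np.asarray(s.center, dtype=float)
            if np.any(c - s.size < -0.5) or np.any(
                c + s.size > np.asarray(self.grid.shape) - 0.5
            ):
                raise ValidationError(f"shape {s} does not fit inside the grid")


@dataclass
class ROILabelMap:
    """Integer ROI labels (0 = background) with a label->name table."""

    labels: np.ndarray
    names: Dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels).tolist())
        for lab in self.names:
            if lab not in present:
                raise ValidationError(f"named label {lab} absent from label map")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class AnisotropySpec:
    """Per-ROI orientation-dependent apparent susceptibility.

    For each ROI label: an isotropic part ``chi_iso``, an anisotropic
    amplitude ``chi_aniso`` (both ppm) and a unit fiber direction.  The
    apparent susceptibility seen at main-field direction b0 is
    ``chi_iso + chi_aniso * (3 cos^2(psi) - 1) / 2`` with psi the angle
    between the fiber and b0 — a scalar stand-in for the full
    susceptibility-tensor picture, adequate for exercising
    orientation-variation statistics but not a tensor model.
    """

    rois: Dict[int, Tuple[float, float, Tuple[float, float, float]]]

    def __post_init__(self):
        for lab, (iso, aniso, fiber) in self.rois.items():
            f = np.asarray(fiber, dtype=float)
            n = np.linalg.norm(f)
            if abs(n - 1.0) > 1e-9:
                raise ValidationError(f"fiber direction for ROI {lab} not unit-norm")


def _voxel_coords(grid: VoxelGrid):
    ax = [np.arange(n, dtype=float) for n in grid.shape]
    return np.meshgrid(*ax, indexing="ij")


def generate_phantom(spec: PhantomSpec) -> Tuple[SusceptibilityVolume, ROILabelMap]:
    """Paint the spec's shapes into a susceptibility volume plus labels.

    Shapes are painted in list order; where they overlap the later shape
    wins (a warning is logged).  Hard shapes (sphere, cylinder) set chi
    exactly, so the per-ROI mean equals the spec value; smooth blobs add
    a Gaussian bump and label voxels within one sigma.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    x, y, z = _voxel_coords(spec.grid)
    chi = np.full(spec.grid.shape, float(spec.background_chi))
    if spec.texture_sd > 0:
        chi += _smooth_noise(spec.grid, rng, cutoff=0.15) * spec.texture_sd
    labels = np.zeros(spec.grid.shape, dtype=np.int32)
    names: Dict[int, str] = {}
    for i, s in enumerate(spec.shapes, start=1):
        cx, cy, cz = (float(c) for c in s.center)
        if s.kind == "sphere":
            inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= s.size**2
        elif s.kind == "cylinder":
            # infinite-in-z cylinder clipped to a 2*size extent about center
            inside = ((x - cx) ** 2 + (y - cy) ** 2 <= s.size**2) & (
                np.abs(z - cz) <= 2 * s.size
            )
        else:  # smooth-blob
            r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
            chi += s.chi * np.exp(-0.5 * r2 / s.size**2)
            inside = r2 <= s.size**2
        if s.kind != "smooth-blob":
            if np.any(labels[inside] != 0):
                warnings.warn(
                    f"shape {i} ({s.kind}) overlaps an earlier shape; later wins",
                    stacklevel=2,
                )
            chi[inside] = s.chi
        labels[inside] = i
        names[i] = s.name or f"{s.kind}-{i}"
    # shapes fully overwritten (or too small to label a voxel) drop out
    present = set(np.unique(labels).tolist())
    names = {lab: name for lab, name in names.items() if lab in present}
    vol = SusceptibilityVolume(values=chi, grid=spec.grid)
    return vol, ROILabelMap(labels=labels, names=names)


def _smooth_noise(grid: VoxelGrid, rng: np.random.Generator, cutoff: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian random field (cutoff in
    normalized frequency, cycles/voxel)."""
    white = rng.standard_normal(grid.shape)
    spec = np.fft.fftn(white)
    f = [np.fft.fftfreq(n) for n in grid.shape]
    fx, fy, fz = np.meshgrid(*f, indexing="ij")
    keep = np.sqrt(fx**2 + fy**2 + fz**2) <= cutoff
    out = np.fft.ifftn(spec * keep).real
    sd = out.std()
    return out / sd if sd > 0 else out


def smooth_random_phantom(
    grid: VoxelGrid, seed: int, amplitude: float = 0.1, cutoff: float = 0.15
) -> SusceptibilityVolume:
    """Band-limited random susceptibility field with the given ppm sd."""
    rng = np.random.default_rng(seed)
    values = _smooth_noise(grid, rng, cutoff) * amplitude
    return SusceptibilityVolume(values=values, grid=grid)


def analytic_sphere_field(
    radius: float,
    delta_chi: float,
    center: Sequence[float],
    grid: VoxelGrid,
    b0: B0Vector,
    periodic_images: int = 0,
) -> FieldMap:
    """Closed-form field of a uniform sphere (magnetostatic oracle).

    External field (Delta chi / 3) (a/r)^3 (3 cos^2 theta - 1) with
    theta the angle from B0, zero inside — the Lorentz-corrected
    convention of the k-space dipole kernel, under which a uniform
    sphere shifts no local field within itself.  The volume mean is
    subtracted so the DC term matches the kernel's pinned-zero
    convention.  Assumes isotropic voxels for the angular geometry
    (radius and distances in voxels).

    ``periodic_images``: the k-space forward model is a circular
    convolution, i.e. it computes the field of a periodic lattice of
    spheres; set this to 1 (or 2) to superpose that many shells of
    lattice-image spheres so the oracle shares the model's boundary
    convention.  The default 0 is the isolated-sphere solution.
    """
    if radius <= 0:
        raise ValidationError("sphere radius must be positive")
    if radius > min(grid.shape) / 2:
        raise ValidationError("sphere radius exceeds half the grid extent")
    x, y, z = _voxel_coords(grid)
    cx, cy, cz = (float(c) for c in center)
    bx, by, bz = b0.direction
    nx, ny, nz = grid.shape
    values = np.zeros(grid.shape)
    p = int(periodic_images)
    for ix in range(-p, p + 1):
        for iy in range(-p, p + 1):
            for iz in range(-p, p + 1):
                dx = x - cx - ix * nx
                dy = y - cy - iy * ny
                dz = z - cz - iz * nz
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                with np.errstate(divide="ignore", invalid="ignore"):
                    cos_t = (dx * bx + dy * by + dz * bz) / r
                    ext = (delta_chi / 3.0) * (radius / r) ** 3 * (
                        3.0 * cos_t**2 - 1.0)
                ext = np.where(r > radius, ext, 0.0)
                ext[~np.isfinite(ext)] = 0.0
                values += ext
    values -= values.mean()
    return FieldMap(values=values, grid=grid, b0=b0)


def simulate_multi_orientation(
    chi: SusceptibilityVolume,
    orientations: Sequence[B0Vector],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> List[FieldMap]:
    """Field map per head orientation: dipole forward model + white noise.

    ``noise_sd`` is the standard deviation of the additive Gaussian
    noise on the (ppm-scale) field.  Deterministic given ``seed``; the
    noiseless component is independent of the seed.
    """
    if len(orientations) == 0:
        raise ValidationError("need at least one orientation")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    fields = []
    for b0 in orientations:
        kernel = make_dipole_kernel(chi.grid, b0)
        fmap = forward_field(chi, kernel)
        values = fmap.values
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=chi.grid.shape)
        fields.append(FieldMap(values=values, grid=chi.grid, b0=b0))
    return fields


def apply_anisotropy(
    chi: SusceptibilityVolume,
    labels: ROILabelMap,
    aniso: AnisotropySpec,
    b0: B0Vector,
) -> SusceptibilityVolume:
    """Orientation-dependent apparent susceptibility inside chosen ROIs.

    Within each ROI of the spec the susceptibility is replaced by
    ``chi_iso + chi_aniso * (3 cos^2 psi - 1) / 2`` (psi = angle between
    the ROI's fiber direction and b0); voxels outside the spec's ROIs
    are left unchanged.
    """
    present = set(np.unique(labels.labels).tolist())
    values = chi.values.copy()
    for lab, (iso, amp, fiber) in aniso.rois.items():
        if lab not in present:
            raise ValidationError(f"anisotropy ROI label {lab} not in label map")
        cos_psi = float(np.dot(np.asarray(fiber), b0.array))
        apparent = iso + amp * (3.0 * cos_psi**2 - 1.0) / 2.0
        values[labels.labels == lab] = apparent
    return SusceptibilityVolume(values=values, grid=chi.grid, mask=chi.mask)


def default_orientations(n: int = 3, max_angle: float = 50.0) -> List[B0Vector]:
    """Evenly spaced head rotations about x, from 0 up to ``max_angle``
    degrees (3 orientations -> 0, 25, 50)."""
    if n < 1:
        raise ValidationError("need at least one orientation")
    angles = np.linspace(0.0, max_angle, n) if n > 1 else [0.0]
    return [rotation_to_b0(a) for a in angles]


def _subject_spec(grid: VoxelGrid, seed: int) -> PhantomSpec:
    """One brain-like phantom: deep-nuclei spheres, a vein-like cylinder,
    a diffuse blob, mild smooth texture; layout jittered per subject."""
    rng = np.random.default_rng(seed)
    n = np.asarray(grid.shape)
    c = n / 2.0
    u = min(grid.shape) / 64.0  # layout scale relative to a 64^3 grid

    def jitter(scale=3.0):
        return rng.uniform(-scale * u, scale * u, size=3)

    shapes = [
        Shape("sphere", tuple(c + u * np.array([-10, 6, 0]) + jitter()), 5.0 * u, 0.12, "nucleus-a"),
        Shape("sphere", tuple(c + u * np.array([10, -6, 2]) + jitter()), 4.0 * u, 0.09, "nucleus-b"),
        Shape("sphere", tuple(c + u * np.array([0, 10, -6]) + jitter()), 3.5 * u, -0.05, "wm-a"),
        Shape("cylinder", tuple(c + u * np.array([6, 6, 0]) + jitter(2.0)), 2.0 * u, 0.3, "vein"),
        Shape("smooth-blob", tuple(c + u * np.array([-6, -8, 4]) + jitter()), 4.0 * u, 0.06, "diffuse"),
    ]
    return PhantomSpec(grid=grid, shapes=shapes, background_chi=0.0,
                       texture_sd=0.01, seed=seed)


def default_phantom_suite(
    grid: Optional[VoxelGrid] = None, base_seed: int = 100
) -> Dict[str, List[Tuple[SusceptibilityVolume, ROILabelMap]]]:
    """The 6 train / 1 validation / 1 test phantom suite (64^3 default)."""
    if grid is None:
        grid = VoxelGrid((64, 64, 64))
    suite: Dict[str, List[Tuple[SusceptibilityVolume, ROILabelMap]]] = {
        "train": [], "val": [], "test": []
    }
    for i in range(6):
        suite["train"].append(generate_phantom(_subject_spec(grid, base_seed + i)))
    suite["val"].append(generate_phantom(_subject_spec(grid, base_seed + 6)))
    suite["test"].append(generate_phantom(_subject_spec(grid, base_seed + 7)))
    return suite
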