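"""Susceptibility-to-field forward models.

Two routes to the induced relative field offset ``dBz/B0``:

* :func:`field_offset_volume` — numerical, for arbitrary susceptibility
  grids, via multiplication with the k-space dipole kernel
  ``1/3 - kz^2/k^2`` (the static-dephasing Green's function in Fourier
  space), with zero-padding to suppress cyclic-convolution wraparound.
* :func:`cylinder_field_offset` — analytic, for an infinite cylinder at
  angle ``theta`` to B0: a ``cos(2*phi) * (a/r)^2`` dipolar pattern outside
  the vessel and a uniform offset inside.

Both return *relative* offsets; multiply by ``gamma * b0 * te`` for phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SimulationParams

__all__ = [
    "FieldVolume",
    "CylinderGeometry",
    "FieldQuery",
    "dipole_kernel",
    "field_offset_volume",
    "cylinder_field_offset",
]


@dataclass
class FieldVolume:
    """A gridded relative field offset dBz/B0 with voxel-size metadata."""

    data: np.ndarray  # 3D, dimensionless relative offset
    voxel_size: float  # mm, isotropic
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    b0_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("field data must be a non-empty 3D grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field data must be finite")


@dataclass(frozen=True)
class CylinderGeometry:
    """An infinite cylinder: radius (mm), zenith to B0 and in-plane azimuth."""

    radius_a: float
    zenith_theta: float
    azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_a <= 0:
            raise ValueError("radius_a must be > 0")
        if not 0.0 <= self.zenith_theta <= np.pi:
            raise ValueError("zenith_theta must be in [0, pi]")


@dataclass(frozen=True)
class FieldQuery:
    """Query point in cylinder coordinates.

    ``r`` is the distance (mm) from the cylinder axis in the perpendicular
    plane; ``phi`` the angle between the query vector and the projection of
    B0 onto that plane.
    """

    r: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be >= 0")


def dipole_kernel(
    shape: tuple[int, int, int], voxel_size: float | tuple[float, float, float]
) -> np.ndarray:
    """k-space dipole kernel ``1/3 - kz^2/k^2`` on the FFT frequency grid.

    The k=0 value is set to 0, which pins the spatial mean of the computed
    field to zero (a uniform susceptibility then produces no field).
    """
    if min(shape) < 2:
        raise ValueError("all grid dimensions must be >= 2")
    if np.isscalar(voxel_size):
        voxel_size = (voxel_size,) * 3
    kx = np.fft.fftfreq(shape[0], d=voxel_size[0])
    ky = np.fft.fftfreq(shape[1], d=voxel_size[1])
    kz = np.fft.fftfreq(shape[2], d=voxel_size[2])
    kx2 = (kx**2)[:, None, None]
    ky2 = (ky**2)[None, :, None]
    kz2 = (kz**2)[None, None, :]
    k2 = kx2 + ky2 + kz2
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 1.0 / 3.0 - kz2 / k2
    kernel[0, 0, 0] = 0.0
    return kernel


def field_offset_volume(
    chi: np.ndarray,
    voxel_size: float,
    pad: int | tuple[int, int, int] | None = None,
) -> FieldVolume:
    """Relative field offset induced by a susceptibility grid ``chi``.

    ``pad`` is the zero-padding per side in voxels; the default pads by one
    full field of view per side, which suppresses wraparound from the cyclic
    FFT convolution.  The result is cropped back to the input shape.
    """
    chi = np.asarray(chi, dtype=np.float64)
    if chi.ndim != 3:
        raise ValueError("chi must be a 3D grid")
    if not np.all(np.isfinite(chi)):
        raise ValueError("chi must be finite")
    if pad is None:
        pad = chi.shape
    elif np.isscalar(pad):
        pad = (int(pad),) * 3
    pad = tuple(int(p) for p in pad)
    if min(pad) < 0:
        raise ValueError("pad must be >= 0")

    padded = np.pad(chi, [(p, p) for p in pad])
    kernel = dipole_kernel(padded.shape, voxel_size)
    # kernel is real and even; rfft along the last axis halves the work
    spec = np.fft.rfftn(padded)
    dbz = np.fft.irfftn(
        kernel[..., : spec.shape[2]] * spec, s=padded.shape, axes=(0, 1, 2)
    )
    sl = tuple(slice(p, p + n) for p, n in zip(pad, chi.shape))
    return FieldVolume(data=dbz[sl], voxel_size=float(voxel_size))


def cylinder_field_offset(
    r,
    phi,
    geometry: CylinderGeometry,
    y: float,
    params: SimulationParams,
) -> np.ndarray | float:
    """Analytic relative field offset of an infinite cylinder of blood.

    Outside the vessel (r >= a)::

        dBz/B0 = (dChi/2) * Hct * (Y_tissue - Y) * sin^2(theta)
                 * (a/r)^2 * cos(2*phi)

    Inside (r < a)::

        dBz/B0 = (dChi/2) * Hct * (Y_tissue - Y) * (3*cos^2(theta) - 1) / 3

    ``r``/``phi`` may be scalars or broadcastable arrays.
    """
    r = np.asarray(r, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    scale = 0.5 * params.delta_chi * params.hct * (params.y_tissue - y)
    theta = geometry.zenith_theta
    a = geometry.radius_a
    sin2 = np.sin(theta) ** 2
    iv_val = scale * (3.0 * np.cos(theta) ** 2 - 1.0) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ev = scale * sin2 * (a / r) ** 2 * np.cos(2.0 * phi)
    out = np.where(r >= a, ev, iv_val)
    return out if out.ndim else float(out)


def cylinder_field_at(q: FieldQuery, geometry, y, params) -> float:
    """Scalar convenience wrapper of :func:`cylinder_field_offset`."""
    return float(cylinder_field_offset(q.r, q.phi, geometry, y, params))
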