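"""Core domain containers for cone-beam CT data.

Coordinate conventions
----------------------
Right-handed patient-style axes ``(x, y, z)`` in millimetres, with the
rotation (gantry) axis along ``z`` and the isocenter at the origin.

* Gantry angle 0 deg places the x-ray source on the ``-y`` axis at distance
  ``sad`` from the isocenter; the flat-panel detector sits on the opposite
  side at ``sdd - sad`` from the isocenter.
* At angle 0 the detector ``u`` axis increases with ``+x``; the ``v`` axis is
  parallel to ``+z`` at every angle.  Angles increase counter-clockwise when
  viewed from ``+z``.
* Volume arrays are indexed ``data[z, y, x]``; the centre of voxel
  ``(0, 0, 0)`` sits at ``origin`` and voxel centres are spaced by
  ``spacing`` along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "ScanGeometry",
    "GridSpec",
    "Volume",
    "ProjectionSet",
    "MU_WATER_DEFAULT",
]

#: Linear attenuation coefficient of water in 1/mm used throughout for HU
#: conversion and phantom definitions (config-overridable).
MU_WATER_DEFAULT = 0.02

_STAGES = ("raw", "preweighted", "filtered", "simulated")
_UNITS = ("mu_mm^-1", "HU")


@dataclass
class ScanGeometry:
    """Circular cone-beam acquisition geometry.

    Parameters
    ----------
    sad : float
        Source-to-axis (isocenter) distance in mm.
    sdd : float
        Source-to-detector distance in mm; ``sdd > sad``.
    det_nu, det_nv : int
        Detector pixel counts along the ``u`` (transaxial) and ``v``
        (axial) directions.
    det_du, det_dv : float
        Detector pixel pitch in mm.
    angles : ndarray
        Ordered gantry angles in degrees, one per view.
    arc_deg : float
        Total scan arc in degrees, in ``(0, 360]``.
    det_offset_u, det_offset_v : float
        Offset of the detector centre from the central ray, in mm.
    """

    sad: float
    sdd: float
    det_nu: int
    det_nv: int
    det_du: float
    det_dv: float
    angles: np.ndarray
    arc_deg: float
    det_offset_u: float = 0.0
    det_offset_v: float = 0.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if not (self.sdd > self.sad > 0):
            raise ValueError(f"require sdd > sad > 0, got sad={self.sad}, sdd={self.sdd}")
        if self.det_nu < 1 or self.det_nv < 1:
            raise ValueError("detector pixel counts must be >= 1")
        if self.det_du <= 0 or self.det_dv <= 0:
            raise ValueError("detector pixel pitch must be > 0")
        if self.angles.ndim != 1 or self.angles.size < 1:
            raise ValueError("angles must be a non-empty 1-D sequence")
        if not (0 < self.arc_deg <= 360):
            raise ValueError(f"arc_deg must lie in (0, 360], got {self.arc_deg}")

    # -- derived quantities -------------------------------------------------

    @property
    def n_views(self) -> int:
        return int(self.angles.size)

    @property
    def is_full_scan(self) -> bool:
        return self.arc_deg >= 360.0 - 1e-9

    def u_coords(self) -> np.ndarray:
        """Physical u coordinate (mm) of each detector column centre."""
        i = np.arange(self.det_nu, dtype=np.float64)
        return (i - (self.det_nu - 1) / 2.0) * self.det_du + self.det_offset_u

    def v_coords(self) -> np.ndarray:
        """Physical v coordinate (mm) of each detector row centre."""
        i = np.arange(self.det_nv, dtype=np.float64)
        return (i - (self.det_nv - 1) / 2.0) * self.det_dv + self.det_offset_v

    @property
    def fan_angle_max(self) -> float:
        """Largest absolute fan angle subtended by a detector column (radians)."""
        u = self.u_coords()
        return float(np.max(np.abs(np.arctan2(u, self.sdd))))

    def source_position(self, view: int) -> np.ndarray:
        """World position of the focal spot at the given view index."""
        b = np.deg2rad(self.angles[view])
        return np.array([self.sad * np.sin(b), -self.sad * np.cos(b), 0.0])

    def detector_frame(self, view: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(centre, u_hat, v_hat) of the detector plane at the given view."""
        b = np.deg2rad(self.angles[view])
        # central-ray direction: from source towards (and beyond) the isocenter
        c_hat = np.array([-np.sin(b), np.cos(b), 0.0])
        u_hat = np.array([np.cos(b), np.sin(b), 0.0])
        v_hat = np.array([0.0, 0.0, 1.0])
        centre = (
            c_hat * (self.sdd - self.sad)
            + u_hat * self.det_offset_u
            + v_hat * self.det_offset_v
        )
        return centre, u_hat, v_hat

    def pixel_position(self, view: int, iv: int, iu: int) -> np.ndarray:
        """World position of the centre of detector pixel (iv, iu)."""
        centre, u_hat, v_hat = self.detector_frame(view)
        u = (iu - (self.det_nu - 1) / 2.0) * self.det_du
        v = (iv - (self.det_nv - 1) / 2.0) * self.det_dv
        return centre + u * u_hat + v * v_hat

    # -- constructors -------------------------------------------------------

    @classmethod
    def circular(
        cls,
        n_views: int,
        arc_deg: float = 360.0,
        start_deg: float = 0.0,
        **kwargs,
    ) -> "ScanGeometry":
        """Evenly spaced views over ``arc_deg`` starting at ``start_deg``.

        For a full scan the end angle is excluded (no duplicate view).
        """
        angles = start_deg + np.arange(n_views) * (arc_deg / n_views)
        return cls(angles=angles, arc_deg=arc_deg, **kwargs)

    def with_detector(self, det_nu: int, det_nv: int, det_du: float, det_dv: float):
        return replace(self, det_nu=det_nu, det_nv=det_nv, det_du=det_du, det_dv=det_dv)


@dataclass
class GridSpec:
    """Axis-aligned voxel grid: ``shape=(nz, ny, nx)``, mm spacing and origin.

    ``origin`` is the world position of the centre of voxel ``(0, 0, 0)``.
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]  # (dx, dy, dz)
    origin: Tuple[float, float, float]  # (x0, y0, z0)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(n < 1 for n in self.shape):
            raise ValueError("grid shape entries must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be > 0")

    @classmethod
    def centered(cls, shape: Tuple[int, int, int], spacing: Tuple[float, float, float]):
        """Grid whose centre coincides with the isocenter."""
        nz, ny, nx = shape
        dx, dy, dz = spacing
        origin = (
            -(nx - 1) / 2.0 * dx,
            -(ny - 1) / 2.0 * dy,
            -(nz - 1) / 2.0 * dz,
        )
        return cls(shape=shape, spacing=spacing, origin=origin)

    @property
    def n_voxels(self) -> int:
        nz, ny, nx = self.shape
        return nz * ny * nx

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the grid bounding box in mm (x, y, z)."""
        nz, ny, nx = self.shape
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        lo = np.array([x0 - dx / 2, y0 - dy / 2, z0 - dz / 2])
        hi = lo + np.array([nx * dx, ny * dy, nz * dz])
        return lo, hi

    def axis_coords(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, z) voxel-centre coordinate vectors."""
        nz, ny, nx = self.shape
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        return (
            x0 + np.arange(nx) * dx,
            y0 + np.arange(ny) * dy,
            z0 + np.arange(nz) * dz,
        )


@dataclass
class Volume:
    """A 3-D voxel grid of attenuation values.

    ``data`` is indexed ``[z, y, x]``; ``unit`` is ``"mu_mm^-1"`` (linear
    attenuation, 1/mm) or ``"HU"`` (Hounsfield units).
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    unit: str = "mu_mm^-1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D (z, y, x)")
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {_UNITS}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def grid(self) -> GridSpec:
        nz, ny, nx = self.data.shape
        return GridSpec(shape=(nz, ny, nx), spacing=self.spacing, origin=self.origin)

    @classmethod
    def from_grid(cls, data: np.ndarray, grid: GridSpec, unit: str = "mu_mm^-1"):
        return cls(data=data, spacing=grid.spacing, origin=grid.origin, unit=unit)


@dataclass
class ProjectionSet:
    """Stack of 2-D detector readings bound to a scan geometry.

    ``data`` has shape ``(n_views, det_nv, det_nu)`` and holds post-log
    line-integral values (dimensionless).  ``stage`` tags the processing
    state: raw, preweighted, filtered or simulated.
    """

    geometry: ScanGeometry
    data: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        expected = (self.geometry.n_views, self.geometry.det_nv, self.geometry.det_nu)
        if self.data.shape != expected:
            raise ValueError(
                f"projection data shape {self.data.shape} does not match geometry "
                f"(views={expected[0]}, nv={expected[1]}, nu={expected[2]})"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.unique(np.nonzero(~np.isfinite(self.data).all(axis=(1, 2)))[0])
            raise ValueError(f"non-finite projection values in view(s) {bad.tolist()}")

    def with_data(self, data: np.ndarray, stage: str) -> "ProjectionSet":
        return ProjectionSet(geometry=self.geometry, data=data, stage=stage)
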