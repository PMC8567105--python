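"""Siddon-style exact ray/voxel intersection and ray-driven (back)projection.

The tracer computes, for a line segment between two points, the ordered list
of voxels it crosses and the exact intersection length inside each voxel, by
walking the parametric plane crossings of the grid.  The same traversal
drives both the forward projector (line integrals of attenuation for the
simulator) and the ray-driven backprojector, which accumulates

    mu_j = sum_k l_jk * P_k / sum_k l_jk

over all detector pixels k of all views, where l_jk is the intersection
length of the backprojection ray from pixel k with voxel j.

Accumulation order is fixed (views outer, then detector rows, then columns)
so results are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from numba import njit

from .core import GridSpec, ProjectionSet, ScanGeometry, Volume

__all__ = [
    "Ray",
    "RaySegmentList",
    "trace_ray",
    "forward_project",
    "backproject_ray_driven",
]

#: Segments shorter than this (mm) are corner-degeneracy artefacts; dropped.
LENGTH_EPS = 1e-12

#: Voxels whose accumulated intersection length falls below this floor (mm)
#: are treated as never traversed.
COVERAGE_FLOOR = 1e-9


@dataclass
class Ray:
    """A backprojection ray from detector pixel centre ``p0`` to source ``p1``."""

    p0: np.ndarray
    p1: np.ndarray
    view_index: int = 0
    pixel_index: Tuple[int, int] = (0, 0)  # (v, u)

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=np.float64)
        self.p1 = np.asarray(self.p1, dtype=np.float64)
        if not (np.all(np.isfinite(self.p0)) and np.all(np.isfinite(self.p1))):
            raise ValueError("ray endpoints must be finite")
        if np.allclose(self.p0, self.p1):
            raise ValueError("degenerate ray: p0 == p1")


@dataclass
class RaySegmentList:
    """Ordered (voxel linear index, intersection length mm) pairs along a ray."""

    indices: np.ndarray  # int64, linear index j = (iz*ny + iy)*nx + ix
    lengths: np.ndarray  # float64 mm

    @property
    def entries(self) -> List[Tuple[int, float]]:
        return list(zip(self.indices.tolist(), self.lengths.tolist()))

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


@njit(cache=True)
def _trace_kernel(
    p0x, p0y, p0z, p1x, p1y, p1z,
    nx, ny, nz, dx, dy, dz, bx, by, bz,
    idx_out, len_out,
):
    """Walk the segment p0 -> p1 through the grid; returns entry count.

    (bx, by, bz) is the lower corner of the grid bounding box.
    """
    ddx = p1x - p0x
    ddy = p1y - p0y
    ddz = p1z - p0z
    norm = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
    if norm == 0.0:
        return 0

    t_lo = 0.0
    t_hi = 1.0
    # slab clipping per axis
    for axis in range(3):
        if axis == 0:
            p, d, b, n, step = p0x, ddx, bx, nx, dx
        elif axis == 1:
            p, d, b, n, step = p0y, ddy, by, ny, dy
        else:
            p, d, b, n, step = p0z, ddz, bz, nz, dz
        hi = b + n * step
        if d == 0.0:
            if p < b or p > hi:
                return 0
        else:
            t1 = (b - p) / d
            t2 = (hi - p) / d
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > t_lo:
                t_lo = t1
            if t2 < t_hi:
                t_hi = t2
    if t_hi <= t_lo:
        return 0

    # entry voxel from the segment midpoint of the first step region
    t = t_lo
    eps_t = 1e-12
    px = p0x + t * ddx
    py = p0y + t * ddy
    pz = p0z + t * ddz
    ix = int(np.floor((px - bx) / dx))
    iy = int(np.floor((py - by) / dy))
    iz = int(np.floor((pz - bz) / dz))
    if ix < 0:
        ix = 0
    elif ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy > ny - 1:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz > nz - 1:
        iz = nz - 1

    # parametric t of the next plane crossing along each axis
    big = 1e30
    if ddx > 0.0:
        tx = (bx + (ix + 1) * dx - p0x) / ddx
        sx = 1
    elif ddx < 0.0:
        tx = (bx + ix * dx - p0x) / ddx
        sx = -1
    else:
        tx = big
        sx = 0
    if ddy > 0.0:
        ty = (by + (iy + 1) * dy - p0y) / ddy
        sy = 1
    elif ddy < 0.0:
        ty = (by + iy * dy - p0y) / ddy
        sy = -1
    else:
        ty = big
        sy = 0
    if ddz > 0.0:
        tz = (bz + (iz + 1) * dz - p0z) / ddz
        sz = 1
    elif ddz < 0.0:
        tz = (bz + iz * dz - p0z) / ddz
        sz = -1
    else:
        tz = big
        sz = 0

    count = 0
    while t < t_hi - eps_t:
        # next crossing
        tn = tx
        if ty < tn:
            tn = ty
        if tz < tn:
            tn = tz
        if tn > t_hi:
            tn = t_hi
        seg = (tn - t) * norm
        if seg > LENGTH_EPS:
            idx_out[count] = (iz * ny + iy) * nx + ix
            len_out[count] = seg
            count += 1
        t = tn
        # advance the axis (or axes, at corners) whose plane was crossed
        if tx <= tn + eps_t and sx != 0:
            ix += sx
            tx += dx / abs(ddx)
            if ix < 0 or ix >= nx:
                break
        if ty <= tn + eps_t and sy != 0:
            iy += sy
            ty += dy / abs(ddy)
            if iy < 0 or iy >= ny:
                break
        if tz <= tn + eps_t and sz != 0:
            iz += sz
            tz += dz / abs(ddz)
            if iz < 0 or iz >= nz:
                break
    return count


def _grid_params(grid: GridSpec):
    nz, ny, nx = grid.shape
    dx, dy, dz = grid.spacing
    lo, _ = grid.bounds()
    return nx, ny, nz, dx, dy, dz, lo[0], lo[1], lo[2]


def trace_ray(ray: Ray, grid: GridSpec) -> RaySegmentList:
    """Exact voxel intersection lengths of a ray segment through the grid.

    Returns an empty list if the segment misses the grid bounding box.
    """
    nx, ny, nz, dx, dy, dz, bx, by, bz = _grid_params(grid)
    cap = nx + ny + nz + 3
    idx = np.empty(cap, dtype=np.int64)
    lng = np.empty(cap, dtype=np.float64)
    n = _trace_kernel(
        ray.p0[0], ray.p0[1], ray.p0[2],
        ray.p1[0], ray.p1[1], ray.p1[2],
        nx, ny, nz, dx, dy, dz, bx, by, bz,
        idx, lng,
    )
    return RaySegmentList(indices=idx[:n].copy(), lengths=lng[:n].copy())


@njit(cache=True)
def _forward_kernel(
    mu, sx_arr, sy_arr, sz_arr, cx_arr, cy_arr, cz_arr,
    ux_arr, uy_arr, uz_arr, du, dv,
    n_views, nv, nu, nx, ny, nz, dx, dy, dz, bx, by, bz, out,
):
    cap = nx + ny + nz + 3
    idx = np.empty(cap, dtype=np.int64)
    lng = np.empty(cap, dtype=np.float64)
    for k in range(n_views):
        sx, sy, sz = sx_arr[k], sy_arr[k], sz_arr[k]
        cx, cy, cz = cx_arr[k], cy_arr[k], cz_arr[k]
        ux, uy, uz = ux_arr[k], uy_arr[k], uz_arr[k]
        for iv in range(nv):
            v = (iv - (nv - 1) / 2.0) * dv
            for iu in range(nu):
                u = (iu - (nu - 1) / 2.0) * du
                px = cx + u * ux
                py = cy + u * uy
                pz = cz + v  # v axis is +z
                n = _trace_kernel(
                    px, py, pz, sx, sy, sz,
                    nx, ny, nz, dx, dy, dz, bx, by, bz,
                    idx, lng,
                )
                acc = 0.0
                for m in range(n):
                    acc += lng[m] * mu[idx[m]]
                out[k, iv, iu] = acc


@njit(cache=True)
def _backproject_kernel(
    proj, sx_arr, sy_arr, sz_arr, cx_arr, cy_arr, cz_arr,
    ux_arr, uy_arr, uz_arr, du, dv,
    n_views, nv, nu, nx, ny, nz, dx, dy, dz, bx, by, bz,
    num, den,
):
    cap = nx + ny + nz + 3
    idx = np.empty(cap, dtype=np.int64)
    lng = np.empty(cap, dtype=np.float64)
    for k in range(n_views):
        sx, sy, sz = sx_arr[k], sy_arr[k], sz_arr[k]
        cx, cy, cz = cx_arr[k], cy_arr[k], cz_arr[k]
        ux, uy, uz = ux_arr[k], uy_arr[k], uz_arr[k]
        for iv in range(nv):
            v = (iv - (nv - 1) / 2.0) * dv
            for iu in range(nu):
                u = (iu - (nu - 1) / 2.0) * du
                p = proj[k, iv, iu]
                px = cx + u * ux
                py = cy + u * uy
                pz = cz + v
                n = _trace_kernel(
                    px, py, pz, sx, sy, sz,
                    nx, ny, nz, dx, dy, dz, bx, by, bz,
                    idx, lng,
                )
                for m in range(n):
                    num[idx[m]] += lng[m] * p
                    den[idx[m]] += lng[m]


def _view_frames(geometry: ScanGeometry):
    n = geometry.n_views
    s = np.empty((n, 3))
    c = np.empty((n, 3))
    u = np.empty((n, 3))
    for k in range(n):
        s[k] = geometry.source_position(k)
        centre, u_hat, _ = geometry.detector_frame(k)
        c[k] = centre
        u[k] = u_hat
    return s, c, u


def forward_project(vol: Volume, geometry: ScanGeometry) -> ProjectionSet:
    """Line integrals of attenuation from the source to every pixel centre."""
    if vol.unit != "mu_mm^-1":
        raise ValueError(f"forward projection needs a mu_mm^-1 volume, got {vol.unit}")
    grid = vol.grid
    nx, ny, nz, dx, dy, dz, bx, by, bz = _grid_params(grid)
    s, c, u = _view_frames(geometry)
    out = np.zeros((geometry.n_views, geometry.det_nv, geometry.det_nu))
    mu = np.ascontiguousarray(vol.data, dtype=np.float64).ravel()
    _forward_kernel(
        mu,
        s[:, 0].copy(), s[:, 1].copy(), s[:, 2].copy(),
        c[:, 0].copy(), c[:, 1].copy(), c[:, 2].copy(),
        u[:, 0].copy(), u[:, 1].copy(), u[:, 2].copy(),
        geometry.det_du, geometry.det_dv,
        geometry.n_views, geometry.det_nv, geometry.det_nu,
        nx, ny, nz, dx, dy, dz, bx, by, bz, out,
    )
    if not np.any(out):
        import logging

        logging.getLogger(__name__).warning(
            "forward projection produced all-zero projections (volume and "
            "geometry may not intersect)"
        )
    return ProjectionSet(geometry=geometry, data=out, stage="simulated")


def backproject_ray_driven(
    proj: ProjectionSet, grid: GridSpec
) -> Tuple[Volume, np.ndarray]:
    """Length-weighted mean of projection values along each voxel's rays.

    Every detector pixel of every view casts one ray to the focal spot;
    voxel j accumulates ``sum_k l_jk * P_k`` and ``sum_k l_jk`` and their
    ratio is returned.  Voxels never traversed are zero; the boolean
    coverage mask (second return value) flags the traversed ones.
    """
    g = proj.geometry
    nx, ny, nz, dx, dy, dz, bx, by, bz = _grid_params(grid)
    s, c, u = _view_frames(g)
    num = np.zeros(grid.n_voxels)
    den = np.zeros(grid.n_voxels)
    _backproject_kernel(
        np.ascontiguousarray(proj.data, dtype=np.float64),
        s[:, 0].copy(), s[:, 1].copy(), s[:, 2].copy(),
        c[:, 0].copy(), c[:, 1].copy(), c[:, 2].copy(),
        u[:, 0].copy(), u[:, 1].copy(), u[:, 2].copy(),
        g.det_du, g.det_dv,
        g.n_views, g.det_nv, g.det_nu,
        nx, ny, nz, dx, dy, dz, bx, by, bz,
        num, den,
    )
    covered = den > COVERAGE_FLOOR
    out = np.zeros_like(num)
    out[covered] = num[covered] / den[covered]
    vol = Volume.from_grid(out.reshape(grid.shape), grid, unit="mu_mm^-1")
    return vol, covered.reshape(grid.shape)
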