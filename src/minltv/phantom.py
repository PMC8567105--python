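"""Synthetic cone-beam data: a Catphan-like digital phantom and a low-mAs
Poisson transmission noise model.

The default phantom is a water-equivalent cylinder with three axial
modules, mimicking a physical image-quality phantom:

* a sensitometry module with seven density inserts (Delrin, Teflon, air,
  PMP, LDPE, polystyrene and a second air insert) on a ring,
* a uniformity module (plain water) for noise/NPS/SNU measurements,
* a resolution module with line-pair bar groups.

Insert attenuation values are package constants chosen to approximate the
named materials relative to water; they are documentation-level defaults,
not measured data.  The noise model emulates a low tube-current (mAs)
acquisition: detected counts are Poisson with mean ``I0 * exp(-p)`` per
pixel, optionally plus Gaussian electronic noise, and are converted back to
line integrals with ``-ln(max(counts, 1) / I0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .core import GridSpec, ProjectionSet, ScanGeometry, Volume, MU_WATER_DEFAULT
from .raytracer import forward_project

__all__ = [
    "Insert",
    "LinePairGroup",
    "PhantomSpec",
    "default_catphan_spec",
    "make_catphan_like",
    "simulate_projections",
]

#: Nominal HU of the sensitometry materials (approximate textbook values).
MATERIAL_HU = {
    "delrin": 340.0,
    "teflon": 990.0,
    "air": -1000.0,
    "pmp": -200.0,
    "ldpe": -100.0,
    "polystyrene": -35.0,
    "air2": -1000.0,
}


@dataclass
class Insert:
    """Cylindrical density insert: centre (x, y) mm, radius mm, mu 1/mm,
    spanning the z range [z_lo, z_hi] mm (inclusive of voxel centres)."""

    name: str
    center: Tuple[float, float]
    radius: float
    mu: float
    z_range: Tuple[float, float]


@dataclass
class LinePairGroup:
    """Bar pattern: bars of attenuation ``mu`` alternating with background
    along x at ``lp_per_cm`` line pairs per cm, inside the given region."""

    lp_per_cm: float
    mu: float
    x_range: Tuple[float, float]
    y_range: Tuple[float, float]
    z_range: Tuple[float, float]


@dataclass
class PhantomSpec:
    """Geometric description of the digital phantom (units mm and 1/mm)."""

    body_center: Tuple[float, float] = (0.0, 0.0)
    body_radius: float = 40.0
    body_mu: float = MU_WATER_DEFAULT
    inserts: List[Insert] = field(default_factory=list)
    line_pair_groups: List[LinePairGroup] = field(default_factory=list)
    uniformity_z_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        for ins in self.inserts:
            if ins.mu < 0:
                raise ValueError(f"insert {ins.name}: mu must be >= 0")
            d = np.hypot(
                ins.center[0] - self.body_center[0],
                ins.center[1] - self.body_center[1],
            )
            if d + ins.radius > self.body_radius + 1e-9:
                raise ValueError(f"insert {ins.name} extends outside the body")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1 :]:
                z_overlap = not (
                    a.z_range[1] < b.z_range[0] or b.z_range[1] < a.z_range[0]
                )
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if z_overlap and d < a.radius + b.radius - 1e-9:
                    raise ValueError(f"inserts {a.name} and {b.name} overlap")


def default_catphan_spec(
    mu_water: float = MU_WATER_DEFAULT,
    body_radius: float = 40.0,
    z_extent: Tuple[float, float] = (-8.0, 8.0),
) -> PhantomSpec:
    """Seven-insert sensitometry ring, a uniformity section and 1/2/3 lp/cm
    bar groups, stacked along z in equal thirds of ``z_extent``."""
    z0, z1 = z_extent
    thirds = np.linspace(z0, z1, 4)
    # half-open module assignment: no slice belongs to two modules
    sens_z = (thirds[0], thirds[1] - 1e-9)
    unif_z = (thirds[1], thirds[2] - 1e-9)
    bars_z = (thirds[2], thirds[3])

    ring_r = 0.6 * body_radius
    insert_r = 0.12 * body_radius
    names = list(MATERIAL_HU)
    inserts = []
    for i, name in enumerate(names):
        ang = 2 * np.pi * i / len(names)
        mu = mu_water * (1.0 + MATERIAL_HU[name] / 1000.0)
        inserts.append(
            Insert(
                name=name,
                center=(ring_r * np.cos(ang), ring_r * np.sin(ang)),
                radius=insert_r,
                mu=max(mu, 0.0),
                z_range=sens_z,
            )
        )

    bar_mu = mu_water * 2.0  # bone-like high-contrast bars
    half = 0.5 * body_radius
    groups = [
        LinePairGroup(1.0, bar_mu, (-half, half), (0.15 * body_radius, 0.45 * body_radius), bars_z),
        LinePairGroup(2.0, bar_mu, (-half, half), (-0.15 * body_radius, 0.15 * body_radius), bars_z),
        LinePairGroup(3.0, bar_mu, (-half, half), (-0.45 * body_radius, -0.15 * body_radius), bars_z),
    ]
    return PhantomSpec(
        body_radius=body_radius,
        body_mu=mu_water,
        inserts=inserts,
        line_pair_groups=groups,
        uniformity_z_range=unif_z,
    )


def spec_for_grid(grid: GridSpec, mu_water: float = MU_WATER_DEFAULT) -> PhantomSpec:
    """Default phantom sized to a reconstruction grid: the body fills ~83%
    of the transverse half-extent and the modules split the z extent."""
    nz, ny, nx = grid.shape
    dx, dy, _ = grid.spacing
    half = min(nx * dx, ny * dy) / 2.0
    x, y, z = grid.axis_coords()
    return default_catphan_spec(
        mu_water=mu_water,
        body_radius=round(0.83 * half, 1),
        z_extent=(float(z[0]), float(z[-1])),
    )


def make_catphan_like(grid: GridSpec, spec: PhantomSpec | None = None) -> Volume:
    """Voxelize the phantom on ``grid`` by centre-sampling.

    An empty spec (no body attenuation, no inserts) yields an all-zero
    volume.  Insert/bar values overwrite the body value where they apply.
    """
    if spec is None:
        spec = default_catphan_spec()
    x, y, z = grid.axis_coords()
    X, Y = np.meshgrid(x, y)  # (ny, nx)
    body = (X - spec.body_center[0]) ** 2 + (Y - spec.body_center[1]) ** 2 <= (
        spec.body_radius**2
    )
    data = np.zeros(grid.shape)
    for iz, zc in enumerate(z):
        sl = np.zeros(body.shape)
        sl[body] = spec.body_mu
        for ins in spec.inserts:
            if ins.z_range[0] <= zc <= ins.z_range[1]:
                mask = (X - ins.center[0]) ** 2 + (Y - ins.center[1]) ** 2 <= ins.radius**2
                sl[mask] = ins.mu
        for g in spec.line_pair_groups:
            if g.z_range[0] <= zc <= g.z_range[1]:
                region = (
                    (X >= g.x_range[0]) & (X <= g.x_range[1])
                    & (Y >= g.y_range[0]) & (Y <= g.y_range[1]) & body
                )
                period_mm = 10.0 / g.lp_per_cm
                phase = np.mod(X - g.x_range[0], period_mm)
                bars = phase < period_mm / 2.0
                sl[region & bars] = g.mu
        data[iz] = sl
    return Volume.from_grid(data, grid, unit="mu_mm^-1")


def simulate_projections(
    vol: Volume,
    geometry: ScanGeometry,
    i0: float | None = 2e4,
    seed: int = 0,
    electronic_sigma: float = 0.0,
    noise: bool = True,
) -> ProjectionSet:
    """Forward-project and apply the low-mAs transmission noise model.

    ``i0`` is the unattenuated photon count per detector pixel (the proxy
    for the mAs setting).  With ``noise=False`` or ``i0`` None/inf the
    noise-free line integrals are returned unchanged.  Counts are floored
    at one photon before the log (photon-starvation convention).
    """
    proj = forward_project(vol, geometry)
    if not noise or i0 is None or not np.isfinite(i0):
        return proj
    if i0 <= 0:
        raise ValueError("i0 must be > 0")
    rng = np.random.default_rng(seed)
    expected = i0 * np.exp(-proj.data)
    counts = rng.poisson(expected).astype(np.float64)
    if electronic_sigma > 0:
        counts = counts + rng.normal(0.0, electronic_sigma, counts.shape)
    p_hat = -np.log(np.maximum(counts, 1.0) / i0)
    return proj.with_data(p_hat, stage="simulated")
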