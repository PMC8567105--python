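"""Image-quality metrics for reconstructed CT volumes.

Implements the usual phantom measures: contrast-to-noise ratio (CNR),
root-mean-square error and Pearson correlation against a benchmark, spatial
non-uniformity (SNU) over five uniform ROIs, a 2-D noise power spectrum
(NPS) estimator with first-order detrending, maximum/minimum intensity
projections, and line-pair modulation for bar patterns.

CNR and SNU use the conventional definitions:
``CNR = |mean_fg - mean_bg| / sigma_bg`` (background-only noise; a pooled
variant is available) and ``SNU = (max_k mean_k - min_k mean_k)/1000 * 100``
with ROI means in HU.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .core import Volume

__all__ = [
    "RoiSpec",
    "roi_values",
    "cnr",
    "rmse",
    "pearson_correlation",
    "snu",
    "NpsResult",
    "nps_2d",
    "mip",
    "minip",
    "line_pair_modulation",
    "evaluate_report",
]


@dataclass
class RoiSpec:
    """A circular or square region of interest.

    ``center`` is (x, y) in mm, ``size`` the diameter/side length in mm and
    ``slices`` the inclusive (z_lo, z_hi) index range it spans.
    """

    shape: str  # "circle" | "square"
    center: Tuple[float, float]
    size: float
    slices: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "square"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        if self.size <= 0:
            raise ValueError("ROI size must be > 0")

    def mask(self, vol: Volume) -> np.ndarray:
        """Boolean in-plane mask of the ROI on the volume's (y, x) grid."""
        nz, ny, nx = vol.data.shape
        x = vol.origin[0] + np.arange(nx) * vol.spacing[0]
        y = vol.origin[1] + np.arange(ny) * vol.spacing[1]
        X, Y = np.meshgrid(x, y)
        cx, cy = self.center
        if self.shape == "circle":
            m = (X - cx) ** 2 + (Y - cy) ** 2 <= (self.size / 2.0) ** 2
        else:
            m = (np.abs(X - cx) <= self.size / 2.0) & (np.abs(Y - cy) <= self.size / 2.0)
        if not m.any():
            raise ValueError("ROI does not cover any voxel")
        z0, z1 = self.slices
        if z0 < 0 or z1 >= nz or z0 > z1:
            raise ValueError(f"ROI slice range {self.slices} outside volume (nz={nz})")
        return m


def roi_values(vol: Volume, roi: RoiSpec) -> np.ndarray:
    """All voxel values inside the ROI across its slice range, flattened."""
    m = roi.mask(vol)
    z0, z1 = roi.slices
    return vol.data[z0 : z1 + 1][:, m].ravel()


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def _cnr_1d(fg: np.ndarray, bg: np.ndarray, noise: str) -> float:
    if noise == "background":
        sigma = bg.std(ddof=1)
    elif noise == "pooled":
        sigma = np.sqrt((fg.var(ddof=1) + bg.var(ddof=1)) / 2.0)
    else:
        raise ValueError(f"unknown noise convention {noise!r}")
    if sigma == 0:
        raise ValueError("noise standard deviation is zero; CNR undefined")
    return float(abs(fg.mean() - bg.mean()) / sigma)


def cnr(
    vol: Volume,
    roi_fg: RoiSpec,
    roi_bg: RoiSpec,
    noise: str = "background",
    per_slice: bool = True,
) -> float:
    """Contrast-to-noise ratio between a foreground and a background ROI.

    With ``per_slice`` (the usual phantom-study convention) the CNR is
    computed on every axial slice of the ROIs' common slice range and
    averaged, so between-slice mean drift does not masquerade as noise;
    otherwise all slices pool into one sample.
    """
    if per_slice:
        m_fg, m_bg = roi_fg.mask(vol), roi_bg.mask(vol)
        z0 = max(roi_fg.slices[0], roi_bg.slices[0])
        z1 = min(roi_fg.slices[1], roi_bg.slices[1])
        if z0 > z1:
            raise ValueError("foreground and background ROIs share no slices")
        vals = [
            _cnr_1d(vol.data[iz][m_fg], vol.data[iz][m_bg], noise)
            for iz in range(z0, z1 + 1)
        ]
        return float(np.mean(vals))
    return _cnr_1d(roi_values(vol, roi_fg), roi_values(vol, roi_bg), noise)


def rmse(vol: Volume, ref: Volume, mask: np.ndarray | None = None) -> float:
    """Root-mean-square difference against a benchmark volume."""
    if vol.data.shape != ref.data.shape:
        raise ValueError("volume shapes differ")
    diff = vol.data - ref.data
    if mask is not None:
        if not np.any(mask):
            raise ValueError("empty mask")
        diff = diff[mask]
    return float(np.sqrt(np.mean(diff**2)))


def pearson_correlation(vol: Volume, ref: Volume, mask: np.ndarray | None = None) -> float:
    if vol.data.shape != ref.data.shape:
        raise ValueError("volume shapes differ")
    a = vol.data if mask is None else vol.data[mask]
    b = ref.data if mask is None else ref.data[mask]
    a = a.ravel()
    b = b.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(a, b)[0, 1])


def snu(vol: Volume, rois: Sequence[RoiSpec]) -> float:
    """Spatial non-uniformity over (typically five) uniform ROIs.

    ``SNU = (max ROI mean - min ROI mean) / 1000 * 100`` with means in HU;
    the input volume must carry the HU unit tag.
    """
    if vol.unit != "HU":
        raise ValueError("SNU is defined on HU volumes")
    if len(rois) < 2:
        raise ValueError("SNU needs at least two ROIs")
    means = [roi_values(vol, r).mean() for r in rois]
    return float((max(means) - min(means)) / 1000.0 * 100.0)


# ---------------------------------------------------------------------------
# noise power spectrum
# ---------------------------------------------------------------------------

@dataclass
class NpsResult:
    """Ensemble-averaged 2-D noise power spectrum and summaries."""

    nps: np.ndarray  # fftshifted, (n, n), HU^2 mm^2
    fx: np.ndarray  # fftshifted frequency axis, 1/mm
    fy: np.ndarray
    radial_freq: np.ndarray
    radial_profile: np.ndarray
    peak: float  # HU^2 mm^2
    mean_frequency: float  # intensity-weighted mean spatial frequency, 1/mm
    n_rois: int


def _detrend_first_order(patch: np.ndarray) -> np.ndarray:
    """Subtract the least-squares plane a + b x + c y."""
    ny, nx = patch.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    a = np.column_stack([np.ones(patch.size), xx.ravel(), yy.ravel()])
    coef, *_ = np.linalg.lstsq(a, patch.ravel(), rcond=None)
    return patch - (a @ coef).reshape(patch.shape)


def nps_2d(
    vol: Volume, rois: Sequence[RoiSpec], pixel_spacing: Tuple[float, float] | None = None
) -> NpsResult:
    """2-D NPS from square ROIs: per-ROI first-order detrend, squared DFT
    magnitude scaled by ``dx dy / (Nx Ny)``, averaged over the ensemble.

    All ROIs must be square and share one size.  Each slice of each ROI's
    slice range contributes one ensemble member.
    """
    if len(rois) < 2:
        raise ValueError("NPS estimation needs at least two ROIs")
    dx, dy = pixel_spacing if pixel_spacing is not None else vol.spacing[:2]
    patches = []
    for roi in rois:
        if roi.shape != "square":
            raise ValueError("NPS ROIs must be square")
        n = int(round(roi.size / dx))
        cx = int(round((roi.center[0] - vol.origin[0]) / vol.spacing[0]))
        cy = int(round((roi.center[1] - vol.origin[1]) / vol.spacing[1]))
        x0, y0 = cx - n // 2, cy - n // 2
        if x0 < 0 or y0 < 0 or x0 + n > vol.data.shape[2] or y0 + n > vol.data.shape[1]:
            raise ValueError("NPS ROI falls outside the volume")
        for iz in range(roi.slices[0], roi.slices[1] + 1):
            patches.append(vol.data[iz, y0 : y0 + n, x0 : x0 + n])
    n = patches[0].shape[0]
    if any(p.shape != (n, n) for p in patches):
        raise ValueError("all NPS ROIs must share one size")
    acc = np.zeros((n, n))
    for patch in patches:
        d = _detrend_first_order(np.asarray(patch, dtype=np.float64))
        spec = np.fft.fft2(d)
        acc += (np.abs(spec) ** 2) * dx * dy / (n * n)
    nps = np.fft.fftshift(acc / len(patches))
    fx = np.fft.fftshift(np.fft.fftfreq(n, d=dx))
    fy = np.fft.fftshift(np.fft.fftfreq(n, d=dy))
    FX, FY = np.meshgrid(fx, fy)
    fr = np.hypot(FX, FY)
    # radial average on annuli of width one frequency sample
    df = fx[1] - fx[0]
    nbin = int(np.ceil(fr.max() / df)) + 1
    which = np.minimum((fr / df).astype(int), nbin - 1)
    sums = np.bincount(which.ravel(), weights=nps.ravel(), minlength=nbin)
    cnts = np.bincount(which.ravel(), minlength=nbin)
    radial = sums / np.maximum(cnts, 1)
    radial_freq = (np.arange(nbin) + 0.5) * df
    total = nps.sum()
    mean_freq = float((nps * fr).sum() / total) if total > 0 else 0.0
    return NpsResult(
        nps=nps,
        fx=fx,
        fy=fy,
        radial_freq=radial_freq,
        radial_profile=radial,
        peak=float(nps.max()),
        mean_frequency=mean_freq,
        n_rois=len(patches),
    )


# ---------------------------------------------------------------------------
# intensity projections and bar-pattern modulation
# ---------------------------------------------------------------------------

def mip(vol: Volume, axis: int = 0) -> np.ndarray:
    """Maximum intensity projection along the given array axis."""
    return vol.data.max(axis=axis)


def minip(vol: Volume, axis: int = 0) -> np.ndarray:
    """Minimum intensity projection along the given array axis."""
    return vol.data.min(axis=axis)


def line_pair_modulation(
    vol: Volume,
    lp_per_cm: float,
    x_range: Tuple[float, float],
    y_range: Tuple[float, float],
    slices: Tuple[int, int],
) -> float:
    """Modulation amplitude of a bar pattern at its fundamental frequency.

    The profile across the bars (along x) is averaged over the bar length
    (y) and the slice range, then the magnitude of its discrete Fourier
    component at ``lp_per_cm`` (one bar pair = one cycle) is returned as a
    peak-to-mean amplitude: ``2 |sum profile exp(-2 pi i f x)| / n``.
    """
    x = vol.origin[0] + np.arange(vol.data.shape[2]) * vol.spacing[0]
    y = vol.origin[1] + np.arange(vol.data.shape[1]) * vol.spacing[1]
    ix = np.nonzero((x >= x_range[0]) & (x <= x_range[1]))[0]
    iy = np.nonzero((y >= y_range[0]) & (y <= y_range[1]))[0]
    if ix.size == 0 or iy.size == 0:
        raise ValueError("bar region does not intersect the volume grid")
    block = vol.data[slices[0] : slices[1] + 1][:, iy][:, :, ix]
    profile = block.mean(axis=(0, 1))
    f = lp_per_cm / 10.0  # cycles per mm
    phase = np.exp(-2j * np.pi * f * x[ix])
    return float(2.0 * np.abs(np.sum(profile * phase)) / profile.size)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def evaluate_report(
    vols: Dict[str, Volume],
    ref: Volume | None = None,
    cnr_rois: Iterable[Tuple[str, RoiSpec]] = (),
    bg_roi: RoiSpec | None = None,
    snu_rois: Sequence[RoiSpec] = (),
    mask: np.ndarray | None = None,
    out_csv: str | Path | None = None,
) -> List[Dict[str, float | str]]:
    """Tabulate CNR/RMSE/correlation/SNU for a named set of volumes.

    Returns one row (dict) per input volume; optionally writes a CSV.
    Volumes must be in HU for SNU to be included.
    """
    rows: List[Dict[str, float | str]] = []
    cnr_rois = list(cnr_rois)
    for name, vol in vols.items():
        row: Dict[str, float | str] = {"volume": name}
        if bg_roi is not None:
            for roi_name, roi in cnr_rois:
                row[f"cnr_{roi_name}"] = cnr(vol, roi, bg_roi)
        if ref is not None:
            row["rmse"] = rmse(vol, ref, mask)
            row["correlation"] = pearson_correlation(vol, ref, mask)
        if snu_rois and vol.unit == "HU":
            row["snu"] = snu(vol, snu_rois)
        rows.append(row)
    if out_csv is not None:
        keys = sorted({k for r in rows for k in r}, key=lambda k: (k != "volume", k))
        with open(out_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(rows)
    return rows
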