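"""File I/O for projection stacks and volumes.

Projections: multi-page float32 TIFF, or raw little-endian float32 with a
JSON sidecar ``{"views": ..., "nv": ..., "nu": ...}``.

Volumes: MetaImage (``.mha``) via SimpleITK, NIfTI (``.nii``/``.nii.gz``)
via nibabel, or raw float32 + JSON sidecar.  The physical-unit tag travels
in the MetaImage metadata dictionary, the NIfTI ``descrip`` header field, or
the sidecar, respectively.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

from .core import ProjectionSet, ScanGeometry, Volume

__all__ = [
    "read_projections",
    "write_projections",
    "read_volume",
    "write_volume",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def write_projections(proj: ProjectionSet, path: str | Path) -> Path:
    """Write a projection stack; format chosen from the file suffix."""
    path = Path(path)
    data = np.ascontiguousarray(proj.data, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data, photometric="minisblack")
    elif path.suffix.lower() == ".raw":
        data.astype("<f4").tofile(path)
        views, nv, nu = data.shape
        _sidecar(path).write_text(
            json.dumps({"views": views, "nv": nv, "nu": nu, "dtype": "<f4"})
        )
    else:
        raise ValueError(f"unsupported projection format {path.suffix!r}")
    return path


def read_projections(
    path: str | Path,
    geometry: ScanGeometry,
    layout: dict | None = None,
    stage: str = "raw",
) -> ProjectionSet:
    """Read a projection stack and bind it to ``geometry``.

    ``layout`` overrides the raw-file sidecar: a dict with keys ``views``,
    ``nv``, ``nu`` and optionally ``dtype`` (numpy dtype string, default
    little-endian float32).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path), dtype=np.float32)
        if data.ndim == 2:
            data = data[None]
    elif path.suffix.lower() == ".raw":
        if layout is None:
            sc = _sidecar(path)
            if not sc.exists():
                raise ValueError(f"raw projections need a layout or sidecar {sc}")
            layout = json.loads(sc.read_text())
        dtype = np.dtype(layout.get("dtype", "<f4"))
        data = np.fromfile(path, dtype=dtype)
        shape = (layout["views"], layout["nv"], layout["nu"])
        if data.size != int(np.prod(shape)):
            raise ValueError(
                f"raw file holds {data.size} values, layout implies {np.prod(shape)}"
            )
        data = data.reshape(shape).astype(np.float32)
    else:
        raise ValueError(f"unsupported projection format {path.suffix!r}")

    expected = (geometry.n_views, geometry.det_nv, geometry.det_nu)
    if data.shape != expected:
        raise ValueError(
            f"file {path} holds {data.shape[0]} views of {data.shape[1]}x{data.shape[2]}, "
            f"geometry declares {expected[0]} views of {expected[1]}x{expected[2]}"
        )
    if not np.all(np.isfinite(data)):
        bad = np.unique(np.nonzero(~np.isfinite(data).reshape(data.shape[0], -1).all(axis=1))[0])
        raise ValueError(f"non-finite values in projection view(s) {bad.tolist()}")
    return ProjectionSet(geometry=geometry, data=data, stage=stage)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as MetaImage, NIfTI or raw+sidecar based on suffix."""
    path = Path(path)
    data = np.ascontiguousarray(vol.data, dtype=np.float32)
    suffixes = "".join(path.suffixes).lower()
    if path.suffix.lower() == ".mha":
        img = sitk.GetImageFromArray(data)  # array is (z, y, x) -> image (x, y, z)
        img.SetSpacing(tuple(vol.spacing))
        img.SetOrigin(tuple(vol.origin))
        img.SetMetaData("unit", vol.unit)
        sitk.WriteImage(img, str(path))
    elif suffixes.endswith(".nii") or suffixes.endswith(".nii.gz"):
        affine = np.diag([*vol.spacing, 1.0])
        affine[:3, 3] = vol.origin
        img = nib.Nifti1Image(data.transpose(2, 1, 0), affine)
        img.header["descrip"] = f"unit={vol.unit}".encode()
        nib.save(img, str(path))
    elif path.suffix.lower() == ".raw":
        data.astype("<f4").tofile(path)
        _sidecar(path).write_text(
            json.dumps(
                {
                    "shape": list(data.shape),
                    "spacing": list(vol.spacing),
                    "origin": list(vol.origin),
                    "unit": vol.unit,
                    "dtype": "<f4",
                }
            )
        )
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")
    return path


def read_volume(path: str | Path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if path.suffix.lower() == ".mha":
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        unit = img.GetMetaData("unit") if img.HasMetaDataKey("unit") else "mu_mm^-1"
        return Volume(
            data=data,
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
            unit=unit,
        )
    if suffixes.endswith(".nii") or suffixes.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0)
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
        unit = descrip.split("unit=", 1)[1] if "unit=" in descrip else "mu_mm^-1"
        return Volume(data=data, spacing=spacing, origin=origin, unit=unit)
    if path.suffix.lower() == ".raw":
        sc = _sidecar(path)
        if not sc.exists():
            raise ValueError(f"raw volume {path} is missing its sidecar {sc}")
        meta = json.loads(sc.read_text())
        data = np.fromfile(path, dtype=np.dtype(meta.get("dtype", "<f4")))
        shape = tuple(meta["shape"])
        if data.size != int(np.prod(shape)):
            raise ValueError(
                f"raw volume {path} is truncated: {data.size} values, "
                f"sidecar implies {int(np.prod(shape))}"
            )
        return Volume(
            data=data.reshape(shape),
            spacing=tuple(meta["spacing"]),
            origin=tuple(meta["origin"]),
            unit=meta.get("unit", "mu_mm^-1"),
        )
    raise ValueError(f"unsupported volume format {path.suffix!r}")
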