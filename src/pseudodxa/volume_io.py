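"""Reading, writing, and Hounsfield calibration of isotropic 3D volumes.

Axis convention throughout the package: arrays are indexed ``(z, y, x)`` where

* ``z`` — anterior–posterior; the projection (ray) axis once the neck is aligned,
* ``y`` — superior–inferior, with ``y = 0`` at the superior side,
* ``x`` — along the femoral-neck axis.

NIfTI files store ``(x, y, z)`` and MHD spacing is ``(x, y, z)``; both readers
transpose into the ``(z, y, x)`` convention. Multipage TIFF stacks are read
page-major, i.e. already ``(z, y, x)``.

Anisotropic inputs are rejected rather than resampled: voxel counts are the
pipeline's core currency and resampling would silently change them.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = [
    "Volume3D",
    "CalibrationPhantoms",
    "read_volume",
    "write_volume",
    "calibrate_hu",
]

_ISO_RTOL = 1e-5  # relative tolerance when checking spacing isotropy


@dataclass
class Volume3D:
    """An isotropic 3D scalar volume (gray values or HU).

    Parameters
    ----------
    values
        3D array, axes ordered ``(z, y, x)``.
    voxel_size_mm
        Isotropic voxel edge length in millimetres (the reference acquisition
        uses 0.027 mm).
    """

    values: np.ndarray
    voxel_size_mm: float
    axes: tuple[str, str, str] = ("z", "y", "x")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.values.ndim}D array"
            )
        if self.values.size == 0:
            raise ValueError("volume is empty")
        if not np.isfinite(self.voxel_size_mm) or self.voxel_size_mm <= 0:
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class CalibrationPhantoms:
    """Mean gray values of in-scan calibration phantoms.

    ``air_gray`` and ``water_gray`` anchor the two-point HU map. The
    hydroxyapatite mimicker, when present, is carried only for QC reporting —
    it plays no role in the HU conversion.
    """

    air_gray: float
    water_gray: float
    ha_gray: float | None = None
    ha_density_mg_cc: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.air_gray) and np.isfinite(self.water_gray)):
            raise ValueError("phantom gray values must be finite")
        if np.isclose(self.air_gray, self.water_gray):
            raise ValueError(
                "air and water phantom gray values coincide; cannot calibrate"
            )


def _infer_format(path: pathlib.Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if name.endswith(".mhd"):
        return "mhd"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def _check_isotropic(zooms: tuple[float, ...], path) -> float:
    z = np.asarray(zooms, dtype=float)
    if np.any(z <= 0):
        raise ValueError(
            f"{path}: non-positive voxel spacing {tuple(z)}; supply "
            "voxel_size_mm explicitly in the call/config"
        )
    if not np.allclose(z, z[0], rtol=_ISO_RTOL):
        raise ValueError(
            f"{path}: anisotropic voxels {tuple(z)} are not supported — the "
            "pipeline counts voxels and will not resample; provide an "
            "isotropic volume"
        )
    return float(z[0])


def read_volume(
    path,
    format: str | None = None,
    voxel_size_mm: float | None = None,
) -> Volume3D:
    """Read a 3D volume from NIfTI, multipage TIFF, or MHD+RAW.

    ``voxel_size_mm`` overrides (NIfTI/MHD) or supplies (TIFF, which carries no
    trustworthy spacing) the voxel size. Missing spacing is a hard error
    instructing the caller to pass the override.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)

    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected 3D data, got {data.ndim}D")
        if voxel_size_mm is None:
            voxel_size_mm = _check_isotropic(img.header.get_zooms()[:3], path)
        values = np.ascontiguousarray(data.T)  # (x,y,z) -> (z,y,x)
    elif fmt == "tiff_stack":
        values = tifffile.imread(str(path))
        if values.ndim != 3:
            raise ValueError(f"{path}: expected a multipage stack, got {values.ndim}D")
        if voxel_size_mm is None:
            raise ValueError(
                f"{path}: TIFF stacks carry no voxel size; pass voxel_size_mm "
                "explicitly (config key voxel_size_mm)"
            )
    elif fmt == "mhd":
        img = sitk.ReadImage(str(path))
        if voxel_size_mm is None:
            voxel_size_mm = _check_isotropic(img.GetSpacing(), path)
        values = sitk.GetArrayFromImage(img)  # already (z,y,x)
        if values.ndim != 3:
            raise ValueError(f"{path}: expected 3D data, got {values.ndim}D")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    return Volume3D(values=values, voxel_size_mm=float(voxel_size_mm), meta={"path": str(path)})


def write_volume(vol: Volume3D, path, format: str | None = None) -> pathlib.Path:
    """Write a volume; round-trips bit-exactly with :func:`read_volume` for
    integer data."""
    path = pathlib.Path(path)
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        affine = np.diag([vol.voxel_size_mm] * 3 + [1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(vol.values.T), affine)
        img.header.set_data_dtype(vol.values.dtype)
        img.header.set_zooms((vol.voxel_size_mm,) * 3)
        nib.save(img, str(path))
    elif fmt == "tiff_stack":
        tifffile.imwrite(str(path), vol.values)
    elif fmt == "mhd":
        img = sitk.GetImageFromArray(vol.values)
        img.SetSpacing((vol.voxel_size_mm,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def calibrate_hu(vol: Volume3D, phantoms: CalibrationPhantoms) -> Volume3D:
    """Convert gray values to Hounsfield units from in-scan phantom means.

    The map is the affine with ``HU(air) = -1000`` and ``HU(water) = 0``::

        HU(g) = 1000 * (g - water) / (water - air)

    which is monotone increasing in gray value whenever ``water > air``.
    """
    g = np.asarray(vol.values, dtype=np.float64)
    hu = 1000.0 * (g - phantoms.water_gray) / (phantoms.water_gray - phantoms.air_gray)
    meta = dict(vol.meta)
    meta["hu_calibration"] = {
        "air_gray": phantoms.air_gray,
        "water_gray": phantoms.water_gray,
    }
    if phantoms.ha_gray is not None:
        # QC only: report where the HA mimicker lands on the HU scale.
        meta["hu_calibration"]["ha_hu"] = float(
            1000.0
            * (phantoms.ha_gray - phantoms.water_gray)
            / (phantoms.water_gray - phantoms.air_gray)
        )
    return Volume3D(values=hu, voxel_size_mm=vol.voxel_size_mm, meta=meta)
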