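"""Anteversion removal and femoral-neck VOI extraction.

The femoral neck is anteverted (rotated in the axial plane) relative to the
shaft. The pipeline first derotates the volume (default 15°) so the neck axis
lies parallel to the array ``x`` axis, then cuts a 15-mm-thick slab
perpendicular to the neck axis with one corner anchored at the inflection
point between the superior neck contour and the greater trochanter.

Landmarks (anchor voxel, neck axis, anteversion angle) are user inputs — in
practice placed in a viewer — supplied via :class:`VoiSpec` or a JSON landmark
file. :func:`find_neck_anchor` offers a heuristic helper for phantoms.

Indexing is 0-based and half-open; the slab includes the anchor slice.
mm→voxel conversions use round-half-to-even, recorded in output metadata.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import LabelVolume
from .volume_io import Volume3D

__all__ = ["VoiSpec", "derotate_volume", "extract_voi", "find_neck_anchor"]

_AXES = {"z": 0, "y": 1, "x": 2}


@dataclass
class VoiSpec:
    """Geometry of the femoral-neck VOI.

    ``fn_axis`` is a unit 3-vector in ``(z, y, x)`` component order; after
    derotation it must be axis-aligned (the default is +x). ``thickness_mm``
    is the slab extent along the neck axis (default 15 mm, the standard
    DXA-matched VOI). ``roi_height_mm`` optionally limits the
    superior–inferior extent of the ROI box, mirroring the scanner's ROI
    height; it is a free parameter because no numeric value is standardised.
    """

    anchor_voxel: tuple[int, int, int]
    fn_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    thickness_mm: float = 15.0
    anteversion_deg: float = 15.0
    roi_height_mm: float | None = None

    def __post_init__(self) -> None:
        ax = np.asarray(self.fn_axis, dtype=float)
        n = np.linalg.norm(ax)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"fn_axis must be a unit vector, |v| = {n}")
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be > 0")

    @classmethod
    def from_json(cls, path) -> "VoiSpec":
        """Load a landmark file: JSON with anchor_voxel, fn_axis,
        anteversion_deg and optionally thickness_mm / roi_height_mm."""
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            anchor_voxel=tuple(int(v) for v in d["anchor_voxel"]),
            fn_axis=tuple(float(v) for v in d.get("fn_axis", (0, 0, 1))),
            thickness_mm=float(d.get("thickness_mm", 15.0)),
            anteversion_deg=float(d.get("anteversion_deg", 15.0)),
            roi_height_mm=d.get("roi_height_mm"),
        )


def _rotate_array(arr: np.ndarray, angle_deg: float, is_labels: bool) -> np.ndarray:
    order = 0 if is_labels else 1
    out = ndimage.rotate(
        arr,
        angle_deg,
        axes=(0, 2),  # rotate in the (z, x) plane, about the vertical y axis
        reshape=False,
        order=order,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    if is_labels:
        out = out.astype(arr.dtype)
    return out


def derotate_volume(vol, angle_deg: float):
    """Rotate a volume in the axial (z, x) plane to remove anteversion.

    Positive ``angle_deg`` undoes a positive anteversion baked into the scan.
    Label volumes use nearest-neighbour interpolation so labels stay in
    {0, 1, 2}; gray volumes use trilinear. Identity for ``angle_deg == 0``.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    if abs(angle_deg) >= 90:
        raise ValueError(f"|angle| must be < 90°, got {angle_deg}")
    if isinstance(vol, LabelVolume):
        if angle_deg == 0:
            return vol
        rot = _rotate_array(vol.labels, angle_deg, is_labels=True)
        sub = None
        if vol.subendosteal is not None:
            sub = _rotate_array(
                vol.subendosteal.astype(np.uint8), angle_deg, is_labels=True
            ).astype(bool)
        meta = dict(vol.meta)
        meta["derotated_deg"] = angle_deg
        return LabelVolume(
            labels=rot, voxel_size_mm=vol.voxel_size_mm, subendosteal=sub, meta=meta
        )
    if isinstance(vol, Volume3D):
        if angle_deg == 0:
            return vol
        is_int = vol.values.dtype.kind in "iub"
        rot = _rotate_array(vol.values, angle_deg, is_labels=is_int)
        meta = dict(vol.meta)
        meta["derotated_deg"] = angle_deg
        return Volume3D(values=rot, voxel_size_mm=vol.voxel_size_mm, meta=meta)
    raise TypeError(f"cannot derotate {type(vol).__name__}")


def _axis_from_vector(v) -> tuple[int, int]:
    """Map an axis-aligned unit vector to (array axis, direction ±1)."""
    v = np.asarray(v, dtype=float)
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        if np.allclose(v, e, atol=1e-6):
            return i, +1
        if np.allclose(v, -e, atol=1e-6):
            return i, -1
    raise ValueError(
        f"fn_axis {tuple(v)} is not axis-aligned; derotate the volume first"
    )


def _round_half_even_mm(mm: float, voxel_size_mm: float) -> int:
    return int(round(mm / voxel_size_mm))  # Python round = half-to-even


def extract_voi(vol, spec: VoiSpec):
    """Cut the neck slab defined by ``spec`` from an axis-aligned volume.

    Returns the same type as the input (:class:`LabelVolume` or
    :class:`Volume3D`) with the ROI box geometry recorded in ``meta`` for the
    downstream projection. The box must fit inside the volume; the error on
    overflow lists the overhang per face.
    """
    if isinstance(vol, LabelVolume):
        arr, voxel = vol.labels, vol.voxel_size_mm
    elif isinstance(vol, Volume3D):
        arr, voxel = vol.values, vol.voxel_size_mm
    else:
        raise TypeError(f"cannot extract a VOI from {type(vol).__name__}")

    anchor = tuple(int(a) for a in spec.anchor_voxel)
    if any(a < 0 or a >= s for a, s in zip(anchor, arr.shape)):
        raise ValueError(f"anchor {anchor} outside volume of shape {arr.shape}")

    axis, direction = _axis_from_vector(spec.fn_axis)
    n_slices = _round_half_even_mm(spec.thickness_mm, voxel)
    if n_slices < 1:
        raise ValueError("thickness smaller than one voxel")

    slicer: list[slice] = [slice(None)] * 3
    a = anchor[axis]
    if direction > 0:
        lo, hi = a, a + n_slices
    else:
        lo, hi = a - n_slices + 1, a + 1
    overhang = []
    if lo < 0:
        overhang.append(f"{n_slices - a - 1 if direction < 0 else -lo} voxels past the low face of axis {axis}")
    if hi > arr.shape[axis]:
        overhang.append(f"{hi - arr.shape[axis]} voxels past the high face of axis {axis}")

    y_lo, y_hi = 0, arr.shape[1]
    if spec.roi_height_mm is not None:
        h = _round_half_even_mm(spec.roi_height_mm, voxel)
        y_lo = anchor[1]
        y_hi = y_lo + h
        if y_hi > arr.shape[1]:
            overhang.append(f"{y_hi - arr.shape[1]} voxels past the inferior face (axis 1)")
    if overhang:
        raise ValueError("VOI box exceeds volume bounds: " + "; ".join(overhang))

    slicer[axis] = slice(lo, hi)
    slicer[1] = slice(y_lo, y_hi)
    sub_arr = arr[tuple(slicer)]
    if direction < 0:  # orient the slab so the anchor slice comes first
        sub_arr = np.flip(sub_arr, axis=axis)

    roi_box = {
        "axis": axis,
        "direction": direction,
        "start": lo,
        "stop": hi,
        "n_slices": n_slices,
        "y_range": [y_lo, y_hi],
        "thickness_mm": spec.thickness_mm,
        "rounding": "half-to-even",
        "anchor_voxel": list(anchor),
    }

    if isinstance(vol, LabelVolume):
        sub = None
        if vol.subendosteal is not None:
            sub = np.ascontiguousarray(vol.subendosteal[tuple(slicer)])
            if direction < 0:
                sub = np.flip(sub, axis=axis)
        meta = dict(vol.meta)
        meta["roi_box"] = roi_box
        return LabelVolume(
            labels=np.ascontiguousarray(sub_arr),
            voxel_size_mm=voxel,
            subendosteal=sub,
            meta=meta,
        )
    meta = dict(vol.meta)
    meta["roi_box"] = roi_box
    return Volume3D(
        values=np.ascontiguousarray(sub_arr), voxel_size_mm=voxel, meta=meta
    )


def find_neck_anchor(vol, smooth_columns: int = 3) -> tuple[int, int, int]:
    """Heuristic locator for the superior neck–trochanter inflection.

    Scans the mid-coronal slice's superior contour (first bone row per column)
    and returns the column where the contour height is lowest, i.e. where the
    superior surface turns upward toward the trochanter. This is a rough
    stand-in for manual landmarking and should be reviewed on real data.
    """
    if isinstance(vol, LabelVolume):
        arr = vol.labels != 0
    else:
        arr = np.asarray(vol.values) > 0
    z_mid = arr.shape[0] // 2
    sl = arr[z_mid]  # (y, x)
    cols = np.flatnonzero(sl.any(axis=0))
    if cols.size == 0:
        raise ValueError("mid-coronal slice contains no bone")
    top = np.array([np.argmax(sl[:, c]) for c in cols], dtype=float)
    if smooth_columns > 1:
        kernel = np.ones(smooth_columns) / smooth_columns
        top = np.convolve(top, kernel, mode="same")
    c_best = cols[int(np.argmax(top))]  # deepest superior contour point
    y_best = int(np.argmax(sl[:, c_best]))
    return (z_mid, y_best, int(c_best))
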