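"""Bone segmentation and cortical/trabecular partitioning.

This module provides a deterministic substitute for interactive or learned
segmentation: a global threshold (fixed HU or Otsu) separates bone from
background, and a morphological endosteal-boundary construction splits the
bone mask into cortical and trabecular compartments. Externally produced
label volumes (e.g. from a dedicated segmentation tool) bypass both steps.

Label codes: 0 = background, 1 = cortical bone, 2 = trabecular bone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing as _gray_closing, disk

from .volume_io import Volume3D

__all__ = [
    "LabelVolume",
    "segment_bone",
    "partition_cortical_trabecular",
    "estimate_subendosteal",
    "apply_patches",
    "BACKGROUND",
    "CORTICAL",
    "TRABECULAR",
]

BACKGROUND, CORTICAL, TRABECULAR = 0, 1, 2


@dataclass
class LabelVolume:
    """A segmented VOI: per-voxel labels plus the recorded subendosteal region.

    ``subendosteal`` is the interior region enclosed by the endosteal boundary
    (marrow plus trabecular bone); it is the denominator of BV/TV and is
    recorded here by :func:`partition_cortical_trabecular` so morphometry does
    not have to re-derive it.
    """

    labels: np.ndarray
    voxel_size_mm: float
    subendosteal: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got {self.labels.ndim}D")
        if self.labels.size == 0:
            raise ValueError("label volume is empty")
        bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, CORTICAL, TRABECULAR])
        if bad.size:
            raise ValueError(f"labels outside {{0,1,2}}: {bad.tolist()}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if self.labels.dtype != np.uint8:
            self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def bone_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND


def segment_bone(
    vol: Volume3D,
    method: str = "otsu",
    threshold_hu: float | None = None,
) -> np.ndarray:
    """Threshold a volume into a boolean bone mask.

    ``fixed_hu`` uses the supplied threshold; ``otsu`` derives it from the
    volume histogram. The operation is idempotent: thresholding a mask
    (values in {0,1}) with the same recipe returns the mask unchanged.
    """
    values = np.asarray(vol.values)
    if values.size == 0:
        raise ValueError("empty volume")
    if method == "fixed_hu":
        if threshold_hu is None:
            raise ValueError("method='fixed_hu' requires threshold_hu")
        thr = float(threshold_hu)
    elif method == "otsu":
        if np.ptp(values) == 0:
            raise ValueError("constant volume: Otsu threshold undefined")
        thr = float(threshold_otsu(values))
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = values >= thr
    if not mask.any():
        warnings.warn("segmentation produced an all-background mask", stacklevel=2)
    return mask


def _partition_slice(
    mask2d: np.ndarray, selem: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return (subendosteal, periosteal) regions for one cross-section.

    The periosteal envelope is the hole-filled closing of the bone mask; the
    subendosteal interior is the hole-filled closing of the marrow space
    inside it. Closing the marrow (rather than relying on connectivity of the
    bone) keeps trabeculae that touch the cortex labelled trabecular.
    """
    closed = _gray_closing(mask2d.astype(np.uint8), selem).astype(bool)
    periosteal = ndimage.binary_fill_holes(closed)
    marrow = periosteal & ~mask2d
    if not marrow.any():
        return np.zeros_like(mask2d), periosteal
    marrow_closed = _gray_closing(marrow.astype(np.uint8), selem).astype(bool)
    sub = ndimage.binary_fill_holes(marrow_closed) & periosteal
    return sub, periosteal


def partition_cortical_trabecular(
    mask: np.ndarray,
    voxel_size_mm: float,
    closing_radius_mm: float = 0.5,
    slice_axis: int = 2,
) -> LabelVolume:
    """Split a bone mask into cortical and trabecular compartments.

    Works slice-by-slice on cross-sections perpendicular to the neck axis
    (``slice_axis``, default ``x``). Bone voxels inside the subendosteal
    interior become trabecular; the remainder (the shell) cortical. The
    partition is exhaustive and exclusive by construction.

    The closing radius (default 0.5 mm) sets the largest marrow gap bridged
    when reconstructing the periosteal and endosteal envelopes; it must be at
    least one voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("empty bone mask: nothing to partition")
    if closing_radius_mm < voxel_size_mm:
        raise ValueError(
            f"closing_radius_mm={closing_radius_mm} is below the voxel size "
            f"{voxel_size_mm}; the structuring element would be empty"
        )
    radius_px = max(1, int(round(closing_radius_mm / voxel_size_mm)))
    selem = disk(radius_px)

    labels = np.zeros(mask.shape, dtype=np.uint8)
    sub_vol = np.zeros(mask.shape, dtype=bool)
    mask_m = np.moveaxis(mask, slice_axis, 0)
    labels_m = np.moveaxis(labels, slice_axis, 0)
    sub_m = np.moveaxis(sub_vol, slice_axis, 0)
    for i in range(mask_m.shape[0]):
        sl = mask_m[i]
        if not sl.any():
            continue
        sub, _ = _partition_slice(sl, selem)
        labels_m[i][sl & ~sub] = CORTICAL
        labels_m[i][sl & sub] = TRABECULAR
        sub_m[i] = sub
    return LabelVolume(
        labels=labels,
        voxel_size_mm=voxel_size_mm,
        subendosteal=sub_vol,
        meta={"closing_radius_mm": closing_radius_mm, "slice_axis": slice_axis},
    )


def estimate_subendosteal(
    labels: np.ndarray,
    voxel_size_mm: float,
    closing_radius_mm: float = 0.5,
    slice_axis: int = 2,
) -> np.ndarray:
    """Reconstruct the subendosteal region for an externally supplied label
    volume that arrives without one (needed as the BV/TV denominator)."""
    mask = np.asarray(labels) != BACKGROUND
    radius_px = max(1, int(round(closing_radius_mm / voxel_size_mm)))
    selem = disk(radius_px)
    sub_vol = np.zeros(mask.shape, dtype=bool)
    mask_m = np.moveaxis(mask, slice_axis, 0)
    sub_m = np.moveaxis(sub_vol, slice_axis, 0)
    for i in range(mask_m.shape[0]):
        if not mask_m[i].any():
            continue
        sub, _ = _partition_slice(mask_m[i], selem)
        sub_m[i] = sub
    return sub_vol


def apply_patches(voi: LabelVolume, patches: pd.DataFrame) -> LabelVolume:
    """Apply a sparse voxel edit list (columns z, y, x, new_label).

    Stands in for interactive correction of misclassified voxels: each row
    overwrites one voxel's label.
    """
    required = {"z", "y", "x", "new_label"}
    if not required.issubset(patches.columns):
        raise ValueError(f"patch table needs columns {sorted(required)}")
    labels = voi.labels.copy()
    idx = patches[["z", "y", "x"]].to_numpy(dtype=int)
    new = patches["new_label"].to_numpy(dtype=int)
    if np.any((new < 0) | (new > 2)):
        raise ValueError("new_label must be in {0,1,2}")
    if np.any(idx < 0) or np.any(idx >= np.array(labels.shape)):
        raise IndexError("patch coordinates outside the volume")
    labels[idx[:, 0], idx[:, 1], idx[:, 2]] = new.astype(np.uint8)
    meta = dict(voi.meta)
    meta["patched_voxels"] = int(len(patches))
    return LabelVolume(
        labels=labels,
        voxel_size_mm=voi.voxel_size_mm,
        subendosteal=voi.subendosteal,
        meta=meta,
    )
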