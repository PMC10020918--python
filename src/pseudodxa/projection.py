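"""Pseudo-DXA projection and image-derived densitometric parameters.

A pseudo-DXA image is a 2D map of per-pixel bone-voxel counts obtained by
stacking (parallel projection, no attenuation physics) all labelled bone
voxels of the neck VOI along the anterior–posterior ray axis. Counts are kept
separately for cortical and trabecular bone; the pixel size equals the voxel
size (no rebinning), so all counts are integers and conservation laws hold
exactly:

* total projected counts = bone voxels in the VOI, per label;
* superior + inferior regional counts = total counts (BMC);
* BMD = BMC / area identically.

Densitometric conventions follow clinical DXA, expressed in voxel currency:
BMC is the total bone-voxel count, area the area (cm²) of pixels containing
at least one projected bone voxel, and BMD their ratio (voxels/cm²).
"""

from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .segmentation import CORTICAL, TRABECULAR, LabelVolume

__all__ = [
    "PseudoDxaImage",
    "PseudoDxaParams",
    "RegionalCounts",
    "project_voi",
    "compute_params",
    "regional_counts",
    "fn_widths",
    "save_pseudo_dxa",
    "load_pseudo_dxa",
]


@dataclass
class PseudoDxaImage:
    """Per-pixel projected voxel counts for one femoral-neck ROI.

    Rows run superior→inferior, columns along the neck axis. ``midline_row``
    is the geometric midline of the ROI box: rows strictly above it are the
    superior half (the superior half receives the extra row when the height
    is odd).
    """

    cortical_counts: np.ndarray
    trabecular_counts: np.ndarray
    pixel_size_mm: float
    roi_box: dict | None = None
    midline_row: int | None = None

    def __post_init__(self) -> None:
        self.cortical_counts = np.asarray(self.cortical_counts)
        self.trabecular_counts = np.asarray(self.trabecular_counts)
        if self.cortical_counts.shape != self.trabecular_counts.shape:
            raise ValueError("cortical and trabecular count maps differ in shape")
        if self.cortical_counts.ndim != 2:
            raise ValueError("count maps must be 2D")
        if np.any(self.cortical_counts < 0) or np.any(self.trabecular_counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be > 0")
        if self.midline_row is None:
            h = self.cortical_counts.shape[0]
            self.midline_row = (h + 1) // 2

    @property
    def total_counts(self) -> np.ndarray:
        return self.cortical_counts + self.trabecular_counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.cortical_counts.shape


@dataclass
class PseudoDxaParams:
    """Scalar densitometric traits of one pseudo-DXA image."""

    area_cm2: float
    bmc_voxels: int
    bmd_voxels_per_cm2: float
    avg_fn_width_mm: float
    min_fn_width_mm: float

    def __post_init__(self) -> None:
        if self.area_cm2 > 0:
            assert np.isclose(
                self.bmd_voxels_per_cm2, self.bmc_voxels / self.area_cm2, rtol=1e-12
            ), "BMD must equal BMC/area"
        if np.isfinite(self.min_fn_width_mm) and np.isfinite(self.avg_fn_width_mm):
            assert self.min_fn_width_mm <= self.avg_fn_width_mm + 1e-12


@dataclass
class RegionalCounts:
    """Cortical/trabecular voxel counts split at the ROI midline."""

    cortical_superior: int
    trabecular_superior: int
    cortical_inferior: int
    trabecular_inferior: int

    @property
    def total(self) -> int:
        return (
            self.cortical_superior
            + self.trabecular_superior
            + self.cortical_inferior
            + self.trabecular_inferior
        )

    @property
    def cortical_fraction(self) -> float:
        tot = self.total
        if tot == 0:
            return float("nan")
        return (self.cortical_superior + self.cortical_inferior) / tot


def project_voi(voi: LabelVolume, ray_axis: int = 0) -> PseudoDxaImage:
    """Project the VOI's bone voxels along ``ray_axis`` (default anterior–
    posterior, axis 0) into per-label count maps.

    Σ pixel counts equals the VOI's bone-voxel count per label, exactly.
    """
    if ray_axis not in (0, 1, 2):
        raise ValueError(f"invalid ray axis {ray_axis}")
    cort = (voi.labels == CORTICAL).sum(axis=ray_axis).astype(np.int64)
    trab = (voi.labels == TRABECULAR).sum(axis=ray_axis).astype(np.int64)
    return PseudoDxaImage(
        cortical_counts=cort,
        trabecular_counts=trab,
        pixel_size_mm=voi.voxel_size_mm,
        roi_box=voi.meta.get("roi_box"),
    )


def fn_widths(img: PseudoDxaImage) -> tuple[float, float]:
    """Average and minimum femoral-neck width from the projected image.

    Per column along the neck axis, the width is the superior–inferior bone
    extent, (last bone row − first bone row + 1) × pixel size. Columns with
    no bone are excluded with a warning. The minimum is taken over columns,
    the average over all included columns.
    """
    total = img.total_counts
    if not total.any():
        raise ValueError("empty pseudo-DXA image: no bone pixels")
    has_bone = total > 0
    col_any = has_bone.any(axis=0)
    if not col_any.all():
        warnings.warn(
            f"{int((~col_any).sum())} columns contain no bone and are "
            "excluded from the width measures",
            stacklevel=2,
        )
    rows = np.arange(total.shape[0])[:, None]
    big = total.shape[0] + 1
    first = np.where(has_bone, rows, big).min(axis=0)
    last = np.where(has_bone, rows, -1).max(axis=0)
    widths = (last[col_any] - first[col_any] + 1) * img.pixel_size_mm
    return float(widths.mean()), float(widths.min())


def compute_params(img: PseudoDxaImage) -> PseudoDxaParams:
    """Compute area, BMC, BMD, and width measures from one image.

    Area counts pixels containing ≥1 projected bone voxel (not the fixed ROI
    box), so area tracks neck width as observed empirically; BMC is the total
    count and BMD = BMC/area.
    """
    total = img.total_counts
    n_bone_pixels = int((total > 0).sum())
    if n_bone_pixels == 0:
        raise ValueError("no bone pixels: ROI area undefined")
    pixel_area_cm2 = (img.pixel_size_mm / 10.0) ** 2
    area_cm2 = n_bone_pixels * pixel_area_cm2
    bmc = int(total.sum())
    avg_w, min_w = fn_widths(img)
    return PseudoDxaParams(
        area_cm2=area_cm2,
        bmc_voxels=bmc,
        bmd_voxels_per_cm2=bmc / area_cm2,
        avg_fn_width_mm=avg_w,
        min_fn_width_mm=min_w,
    )


def regional_counts(img: PseudoDxaImage) -> RegionalCounts:
    """Split counts into superior (rows above the midline) and inferior halves.

    The four counts partition BMC exactly.
    """
    m = img.midline_row
    if m is None:
        raise ValueError("midline_row not set")
    cs = int(img.cortical_counts[:m].sum())
    ts = int(img.trabecular_counts[:m].sum())
    ci = int(img.cortical_counts[m:].sum())
    ti = int(img.trabecular_counts[m:].sum())
    return RegionalCounts(
        cortical_superior=cs,
        trabecular_superior=ts,
        cortical_inferior=ci,
        trabecular_inferior=ti,
    )


def save_pseudo_dxa(img: PseudoDxaImage, path) -> pathlib.Path:
    """Write the two count channels as a 32-bit TIFF with a JSON sidecar."""
    path = pathlib.Path(path)
    stack = np.stack(
        [img.cortical_counts, img.trabecular_counts]
    ).astype(np.int32)
    tifffile.imwrite(str(path), stack)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "pixel_size_mm": img.pixel_size_mm,
                "midline_row": img.midline_row,
                "roi_box": img.roi_box,
                "channels": ["cortical", "trabecular"],
            },
            fh,
            indent=2,
        )
    return path


def load_pseudo_dxa(path) -> PseudoDxaImage:
    path = pathlib.Path(path)
    stack = tifffile.imread(str(path))
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        side = json.load(fh)
    return PseudoDxaImage(
        cortical_counts=stack[0].astype(np.int64),
        trabecular_counts=stack[1].astype(np.int64),
        pixel_size_mm=side["pixel_size_mm"],
        roi_box=side.get("roi_box"),
        midline_row=side.get("midline_row"),
    )
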