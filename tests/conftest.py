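"""Shared fixtures: hand-built geometric phantoms with exact ground truth.

All fixtures are generated programmatically at test time; nothing is read
from disk. The rod phantom is deliberately simple enough that every expected
count can be derived by construction.
"""

from __future__ import annotations

import numpy as np
import pytest

from pseudodxa.segmentation import CORTICAL, TRABECULAR, LabelVolume


def make_hollow_cylinder(
    n_section: int = 64,
    n_len: int = 40,
    outer_radius_mm: float = 7.0,
    thickness_mm: float = 1.5,
    voxel_size_mm: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Hollow-cylinder bone mask along x: (mask, interior, geometry)."""
    c = (n_section - 1) / 2.0
    zz, yy = np.meshgrid(np.arange(n_section), np.arange(n_section), indexing="ij")
    rho = np.hypot(zz - c, yy - c) * voxel_size_mm
    shell2d = (rho <= outer_radius_mm) & (rho > outer_radius_mm - thickness_mm)
    interior2d = rho <= outer_radius_mm - thickness_mm
    mask = np.repeat(shell2d[:, :, None], n_len, axis=2)
    interior = np.repeat(interior2d[:, :, None], n_len, axis=2)
    geom = {
        "outer_radius_mm": outer_radius_mm,
        "thickness_mm": thickness_mm,
        "voxel_size_mm": voxel_size_mm,
        "center": c,
        "n_len": n_len,
    }
    return mask, interior, geom


@pytest.fixture(scope="session")
def hollow_cylinder():
    return make_hollow_cylinder()


@pytest.fixture(scope="session")
def rod_phantom():
    """Hollow cylinder with plate-like 'trabecular' rods spanning the interior.

    Rods are one voxel thick, placed every 4 voxels, and touch the endosteal
    surface — the hard case for cortical/trabecular partitioning. Returns the
    ground-truth LabelVolume and the bone mask.
    """
    mask, interior, geom = make_hollow_cylinder()
    n = mask.shape[0]
    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[mask] = CORTICAL
    rods2d = np.zeros(mask.shape[:2], dtype=bool)
    for gz in range(6, n, 4):
        rods2d[gz, interior[gz, :, 0]] = True
    for x in range(mask.shape[2]):
        labels[:, :, x][rods2d] = TRABECULAR
    full_mask = labels != 0
    voi = LabelVolume(
        labels=labels,
        voxel_size_mm=geom["voxel_size_mm"],
        subendosteal=interior,
    )
    return voi, full_mask, geom


@pytest.fixture()
def rng():
    return np.random.default_rng(20230116)
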