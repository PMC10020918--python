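"""Seed-deterministic synthetic data: femoral-neck phantoms, bilinear
load–displacement curves, and cohort tables with known ground truth.

Every generator returns both the object the pipeline consumes and a truth
record holding the analytically known quantities (voxel counts per label and
per half, shell thickness, yield point, generating standardized betas, ...)
so each pipeline stage can be tested for recovery without cadaveric data.

The phantom is a neck-like tube: an elliptic-annulus cortical shell, thicker
on the inferior side as in a real femoral neck, around a trabecular interior
realised as a thresholded smoothed Gaussian random field that hits the target
volume fraction essentially exactly. An optional hourglass waist and a baked-
in anteversion rotation exercise the width measures and the derotation stage.

Cohort covariates are drawn on Table-realistic scales (age ~67 ± 17 y, weight
~67 ± 24 kg, pseudo-DXA area ~4.6 ± 0.25 cm², BMC ~1.3e8 voxels) with the
regional cortical/trabecular shares centred on the observed means
(superior cortical 20.1%, superior trabecular 18.7%, inferior cortical 36.3%,
inferior trabecular 24.8% of BMC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .mechanics import LoadCurve
from .segmentation import CORTICAL, TRABECULAR, LabelVolume
from .stats import MODEL_PREDICTORS, _TRANSFORMS, split_subgroups
from .voi import _rotate_array
from .volume_io import Volume3D

__all__ = [
    "PhantomSpec",
    "CurveSpec",
    "CohortSpec",
    "PhantomResult",
    "generate_phantom",
    "generate_curve",
    "generate_cohort",
]

GENERATOR_VERSION = "1"


@dataclass
class PhantomSpec:
    """Geometry of a synthetic femoral-neck segment.

    Thicknesses and widths in mm; the shell thickness varies linearly from
    ``cortical_thickness_superior_mm`` at the top of the section to
    ``cortical_thickness_inferior_mm`` at the bottom. ``waist_fraction`` < 1
    tapers the outer radius linearly to a central hourglass waist.
    """

    neck_width_mm: float = 30.0
    cortical_thickness_superior_mm: float = 1.0
    cortical_thickness_inferior_mm: float = 3.0
    trabecular_bvtv: float = 0.3
    anteversion_deg: float = 0.0
    voxel_size_mm: float = 0.25
    length_mm: float = 15.0
    waist_fraction: float | None = None
    tb_feature_mm: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        half = self.neck_width_mm / 2
        if not (
            0 < self.cortical_thickness_superior_mm < half
            and 0 < self.cortical_thickness_inferior_mm < half
        ):
            raise ValueError("cortical thickness must lie in (0, neck_width/2)")
        if not 0 <= self.trabecular_bvtv <= 1:
            raise ValueError("BV/TV must lie in [0, 1]")
        if self.waist_fraction is not None and not (0 < self.waist_fraction <= 1):
            raise ValueError("waist_fraction must lie in (0, 1]")
        if self.voxel_size_mm <= 0 or self.length_mm <= 0:
            raise ValueError("voxel size and length must be > 0")


@dataclass
class PhantomResult:
    labels: LabelVolume          #: as-scanned (anteversion baked in, if any)
    labels_aligned: LabelVolume  #: axis-aligned ground truth
    grayscale: Volume3D          #: simulated gray-value volume of ``labels``
    truth: dict


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build a labelled phantom plus grayscale rendition and truth record."""
    v = spec.voxel_size_mm
    R = spec.neck_width_mm / 2.0
    n_len = max(int(round(spec.length_mm / v)), 3)
    n_rad = int(np.ceil(spec.neck_width_mm / v))
    # padding so the anteversion rotation (about y, mixing z and x) fits
    pad_zx = int(np.ceil(0.3 * max(n_len, n_rad))) + 4
    nz = n_rad + 2 * pad_zx
    ny = n_rad + 8
    nx = n_len + 2 * pad_zx
    cz, cy = nz / 2.0 - 0.5, ny / 2.0 - 0.5
    x0 = (nx - n_len) // 2

    zz, yy = np.meshgrid(np.arange(nz), np.arange(ny), indexing="ij")
    rho = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2) * v  # mm, in-section radius
    y_off = (yy - cy) * v  # signed superior(-) / inferior(+) offset, mm

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    interior = np.zeros((nz, ny, nx), dtype=bool)
    t_sup = spec.cortical_thickness_superior_mm
    t_inf = spec.cortical_thickness_inferior_mm

    xs = np.arange(n_len)
    if spec.waist_fraction is not None and n_len > 1:
        xc = (n_len - 1) / 2.0
        taper = spec.waist_fraction + (1 - spec.waist_fraction) * np.abs(xs - xc) / xc
    else:
        taper = np.ones(n_len)

    min_outer_width_mm = np.inf
    outer_widths = []
    for i, x in enumerate(xs):
        R_x = R * taper[i]
        outer = rho <= R_x
        y_hat = np.clip(y_off / R_x, -1.0, 1.0)
        t = t_sup * (1 - y_hat) / 2.0 + t_inf * (1 + y_hat) / 2.0
        shell = outer & (rho > R_x - t)
        inner = outer & ~shell
        sl = labels[:, :, x0 + x]
        sl[shell] = CORTICAL
        interior[:, :, x0 + x] = inner
        outer_widths.append(2 * R_x)
        min_outer_width_mm = min(min_outer_width_mm, 2 * R_x)

    rng = np.random.default_rng(spec.seed)
    n_interior = int(interior.sum())
    if spec.trabecular_bvtv > 0 and n_interior:
        field_ = ndimage.gaussian_filter(
            rng.standard_normal(labels.shape), sigma=spec.tb_feature_mm / v
        )
        vals = field_[interior]
        thr = np.quantile(vals, 1.0 - spec.trabecular_bvtv)
        trab = interior & (field_ >= thr)
        labels[trab] = TRABECULAR

    cy_row = int(np.floor(cy)) + 1  # rows < cy_row are superior
    bone = labels != 0
    truth = {
        "generator_version": GENERATOR_VERSION,
        "seed": spec.seed,
        "voxel_size_mm": v,
        "n_cortical": int((labels == CORTICAL).sum()),
        "n_trabecular": int((labels == TRABECULAR).sum()),
        "n_bone": int(bone.sum()),
        "n_interior": n_interior,
        "bvtv": float((labels == TRABECULAR).sum() / n_interior) if n_interior else 0.0,
        "ct_th_mean_mm": 0.5 * (t_sup + t_inf),
        "ct_th_superior_mm": t_sup,
        "ct_th_inferior_mm": t_inf,
        "outer_radius_mm": R,
        "min_width_mm": float(min_outer_width_mm),
        "avg_width_mm": float(np.mean(outer_widths)),
        "length_voxels": n_len,
        "x_range": [int(x0), int(x0 + n_len)],
        "midline_row": cy_row,
        "n_bone_superior": int(bone[:, :cy_row, :].sum()),
        "n_bone_inferior": int(bone[:, cy_row:, :].sum()),
        "n_cortical_superior": int((labels[:, :cy_row, :] == CORTICAL).sum()),
        "n_trabecular_superior": int((labels[:, :cy_row, :] == TRABECULAR).sum()),
        "anteversion_deg": spec.anteversion_deg,
    }

    aligned = LabelVolume(
        labels=labels.copy(),
        voxel_size_mm=v,
        subendosteal=interior.copy(),
        meta={"phantom": "aligned"},
    )
    if spec.anteversion_deg:
        rot = _rotate_array(labels, -spec.anteversion_deg, is_labels=True)
        rot_sub = _rotate_array(
            interior.astype(np.uint8), -spec.anteversion_deg, is_labels=True
        ).astype(bool)
        scanned = LabelVolume(
            labels=rot, voxel_size_mm=v, subendosteal=rot_sub,
            meta={"phantom": "anteverted", "anteversion_deg": spec.anteversion_deg},
        )
    else:
        scanned = aligned

    # grayscale rendition: background ~ N(1000, 30), bone ~ N(4000, 60)
    gray = np.where(scanned.labels != 0, 4000.0, 1000.0)
    gray += rng.normal(0.0, 30.0, size=gray.shape)
    grayscale = Volume3D(values=gray, voxel_size_mm=v, meta={"phantom": "gray"})

    return PhantomResult(
        labels=scanned, labels_aligned=aligned, grayscale=grayscale, truth=truth
    )


@dataclass
class CurveSpec:
    """A bilinear load–displacement path with Gaussian load noise.

    ``yield_load_n`` is the load at the slope break; the analytic 10%-rule
    yield point (slightly beyond the break) is stored in the truth record.
    """

    stiffness_n_per_mm: float = 2000.0
    yield_load_n: float = 2000.0
    postyield_slope_n_per_mm: float = 200.0
    failure_disp_mm: float = 4.0
    noise_sd_n: float = 0.0
    sample_spacing_mm: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.stiffness_n_per_mm > self.postyield_slope_n_per_mm >= 0):
            raise ValueError("need stiffness > post-yield slope ≥ 0")
        if self.yield_load_n <= 0 or self.failure_disp_mm <= 0:
            raise ValueError("yield load and failure displacement must be > 0")
        if self.sample_spacing_mm <= 0:
            raise ValueError("sample spacing must be > 0")


def generate_curve(spec: CurveSpec) -> tuple[LoadCurve, dict]:
    """Sample the bilinear path and return it with its analytic truth.

    Truth: the 10%-rule yield is the intersection of the 0.9·K line through
    the origin with the second limb, d* = (L1 − K2·d1)/(0.9K − K2); an
    elastic-brittle curve (failure before the break) is flagged with PYD 0.
    """
    K, K2 = spec.stiffness_n_per_mm, spec.postyield_slope_n_per_mm
    d1 = spec.yield_load_n / K  # displacement at the slope break
    d = np.arange(0.0, spec.failure_disp_mm + spec.sample_spacing_mm / 2,
                  spec.sample_spacing_mm)
    load = np.where(d <= d1, K * d, spec.yield_load_n + K2 * (d - d1))
    if spec.noise_sd_n > 0:
        rng = np.random.default_rng(spec.seed)
        load = load + rng.normal(0.0, spec.noise_sd_n, size=load.shape)

    truth: dict = {
        "generator_version": GENERATOR_VERSION,
        "seed": spec.seed,
        "stiffness_n_per_mm": K,
        "break_disp_mm": d1,
        "max_load_n": float(load[-1] if spec.noise_sd_n == 0 else
                            spec.yield_load_n + K2 * (spec.failure_disp_mm - d1)),
    }
    if spec.failure_disp_mm <= d1:
        truth.update(
            elastic_brittle=True,
            yield_disp_mm=float(spec.failure_disp_mm),
            yield_load_n=float(K * spec.failure_disp_mm),
            pyd_mm=0.0,
            max_load_n=float(K * spec.failure_disp_mm),
        )
    else:
        d_star = (spec.yield_load_n - K2 * d1) / (0.9 * K - K2)
        truth.update(
            elastic_brittle=False,
            yield_disp_mm=float(d_star),
            yield_load_n=float(0.9 * K * d_star),
            pyd_mm=float(spec.failure_disp_mm - d_star),
        )
    return LoadCurve(displacement_mm=d, load_n=load), truth


@dataclass
class CohortSpec:
    """A cohort drawn from a correlated covariate model with strength built
    from one ladder model's predictors at stated standardized effects.

    ``effects`` maps cohort columns (the generating model's predictors) to
    standardized beta coefficients. With ``noise_fraction`` None the residual
    variance is set so the outcome has unit generating variance and the
    requested betas are the true standardized betas; ``noise_fraction = 0``
    produces a deterministic outcome.
    """

    n: int = 30
    model_id: int = 1
    effects: dict[str, float] = field(default_factory=lambda: {
        "age_yr": -0.2, "body_weight_kg": 0.3, "bmd_voxels_per_cm2": 0.7,
    })
    correlation: np.ndarray | None = None
    noise_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        preds = MODEL_PREDICTORS[self.model_id]
        unknown = set(self.effects) - set(preds)
        if unknown:
            raise ValueError(
                f"effects name non-model-{self.model_id} predictors: {sorted(unknown)}"
            )
        if self.n <= len(preds) + 2:
            raise ValueError("n must exceed the predictor count + 2")


# natural scales (mean, sd, clip_lo, clip_hi) for each transformed predictor
_SCALES = {
    "age_yr": (67.0, 17.0, 36.0, 95.0),
    "log_body_weight_kg": (np.log(66.7), 0.33, np.log(40.0), np.log(120.0)),
    "area_cm2": (4.63, 0.25, 4.0, 5.3),
    "bmd_voxels_per_cm2": (28.3e6, 6.3e6, 10e6, 50e6),
    "bmc_voxels": (131.2e6, 30.0e6, 60e6, 220e6),
    "sqrt_pyd_mm": (1.55, 0.55, 0.05, 3.0),
}
# regional shares of BMC (mean, sd): sup-cortical, sup-trabecular,
# inf-cortical, inf-trabecular
_REGIONAL_SHARES = np.array(
    [[0.201, 0.038], [0.187, 0.043], [0.363, 0.067], [0.248, 0.064]]
)
_STRENGTH_MEAN_N = 3000.0
_STRENGTH_SD_N = 1000.0


def _default_correlation(p: int) -> np.ndarray:
    C = np.full((p, p), 0.15)
    np.fill_diagonal(C, 1.0)
    return C


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table and its truth record.

    Standardized predictors are drawn from a multivariate normal with the
    requested correlation; natural-scale covariates are reconstructed so that
    the ladder's own transforms (log body weight, sqrt PYD) recover linear
    functions of the generating scores. Regional counts are built from BMC
    with realistic cortical/trabecular shares so every model's columns exist
    regardless of the generating model.
    """
    rng = np.random.default_rng(spec.seed)
    preds = MODEL_PREDICTORS[spec.model_id]
    p = len(preds)
    C = spec.correlation if spec.correlation is not None else _default_correlation(p)
    C = np.asarray(C, dtype=float)
    if C.shape != (p, p):
        raise ValueError(f"correlation must be {p}×{p} for model {spec.model_id}")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc

    Z = rng.standard_normal((spec.n, p)) @ L.T  # generating scores, ~N(0,1)
    beta = np.array([spec.effects.get(c, 0.0) for c in preds])
    signal_var = float(beta @ C @ beta)
    if spec.noise_fraction is None:
        if signal_var > 1.0:
            raise ValueError(
                f"requested effects imply signal variance {signal_var:.3f} > 1; "
                "scale them down or set noise_fraction explicitly"
            )
        sigma = np.sqrt(1.0 - signal_var)
    else:
        sigma = np.sqrt(spec.noise_fraction)
    y_z = Z @ beta + sigma * rng.standard_normal(spec.n)

    df = pd.DataFrame({"id": [f"S{i:03d}" for i in range(spec.n)]})
    zcols = dict(zip(preds, Z.T))

    def _natural(col: str, z: np.ndarray) -> np.ndarray:
        tag = _TRANSFORMS.get(col)
        key = {"log": f"log_{col}", "sqrt": f"sqrt_{col}"}.get(tag, col)
        mu, sd, lo, hi = _SCALES[key]
        x = np.clip(mu + sd * z, lo, hi)
        if tag == "log":
            return np.exp(x)
        if tag == "sqrt":
            return x**2
        return x

    # covariates named by any generating model
    for col in ("age_yr", "body_weight_kg", "area_cm2"):
        z = zcols.get(col, rng.standard_normal(spec.n))
        df[col] = _natural(col, z)
    if "bmc_voxels" in zcols:
        df["bmc_voxels"] = np.round(_natural("bmc_voxels", zcols["bmc_voxels"]))
    elif "bmd_voxels_per_cm2" in zcols:
        bmd = _natural("bmd_voxels_per_cm2", zcols["bmd_voxels_per_cm2"])
        df["bmc_voxels"] = np.round(bmd * df["area_cm2"])
    else:
        # models 3-5 generate the regional counts directly; BMC is their sum
        df["bmc_voxels"] = np.round(
            _natural("bmc_voxels", rng.standard_normal(spec.n))
        )

    shares = np.clip(
        rng.normal(
            _REGIONAL_SHARES[:, 0], _REGIONAL_SHARES[:, 1], size=(spec.n, 4)
        ),
        0.02,
        None,
    )
    shares /= shares.sum(axis=1, keepdims=True)

    regional_cols = [
        "cortical_sup_voxels",
        "trabecular_sup_voxels",
        "cortical_inf_voxels",
        "trabecular_inf_voxels",
    ]
    if any(c in zcols for c in regional_cols + ["total_sup_voxels", "total_inf_voxels"]):
        # regional counts are generating predictors: build them from their own
        # scores around the share-implied scale
        base = df["bmc_voxels"].to_numpy()
        for j, c in enumerate(regional_cols):
            mu = float(_REGIONAL_SHARES[j, 0]) * base
            sd = 0.25 * mu.mean()
            z = zcols.get(c, rng.standard_normal(spec.n))
            df[c] = np.round(np.clip(mu.mean() + sd * z, 1, None))
        if "total_sup_voxels" in zcols or "total_inf_voxels" in zcols:
            for half, (a, b) in {
                "total_sup_voxels": ("cortical_sup_voxels", "trabecular_sup_voxels"),
                "total_inf_voxels": ("cortical_inf_voxels", "trabecular_inf_voxels"),
            }.items():
                if half in zcols:
                    tot = np.round(
                        np.clip(
                            df[[a, b]].to_numpy().sum(1).mean()
                            + 0.25
                            * df[[a, b]].to_numpy().sum(1).mean()
                            * zcols[half],
                            2,
                            None,
                        )
                    )
                    frac_a = df[a] / (df[a] + df[b])
                    df[a] = np.round(tot * frac_a)
                    df[b] = tot - df[a]
        df["bmc_voxels"] = df[regional_cols].sum(axis=1)
    else:
        counts = np.floor(shares * df["bmc_voxels"].to_numpy()[:, None])
        counts[:, 0] += df["bmc_voxels"].to_numpy() - counts.sum(axis=1)
        for j, c in enumerate(regional_cols):
            df[c] = counts[:, j].astype(np.int64)

    df["total_sup_voxels"] = df["cortical_sup_voxels"] + df["trabecular_sup_voxels"]
    df["total_inf_voxels"] = df["cortical_inf_voxels"] + df["trabecular_inf_voxels"]
    df["bmd_voxels_per_cm2"] = df["bmc_voxels"] / df["area_cm2"]
    if "bmd_voxels_per_cm2" in zcols:
        # the generating BMD score defines BMD; keep the identity BMD=BMC/area
        bmd = _natural("bmd_voxels_per_cm2", zcols["bmd_voxels_per_cm2"])
        df["bmc_voxels"] = np.round(bmd * df["area_cm2"])
        scale = df["bmc_voxels"] / df[regional_cols].sum(axis=1)
        for c in regional_cols:
            df[c] = np.round(df[c] * scale)
        df["bmc_voxels"] = df[regional_cols].sum(axis=1)
        df["total_sup_voxels"] = df["cortical_sup_voxels"] + df["trabecular_sup_voxels"]
        df["total_inf_voxels"] = df["cortical_inf_voxels"] + df["trabecular_inf_voxels"]
        df["bmd_voxels_per_cm2"] = df["bmc_voxels"] / df["area_cm2"]
    df["cortical_fraction"] = (
        df["cortical_sup_voxels"] + df["cortical_inf_voxels"]
    ) / df["bmc_voxels"]

    z_pyd = zcols.get("pyd_mm", rng.standard_normal(spec.n))
    df["pyd_mm"] = _natural("pyd_mm", z_pyd)

    df["max_load_n"] = _STRENGTH_MEAN_N + _STRENGTH_SD_N * y_z
    df = split_subgroups(df)

    truth = {
        "generator_version": GENERATOR_VERSION,
        "seed": spec.seed,
        "model_id": spec.model_id,
        "std_betas": {
            c: float(b / np.sqrt(signal_var + sigma**2))
            for c, b in zip(preds, beta)
        },
        "noise_sd": float(sigma),
        "signal_var": signal_var,
        "generating_scores": Z,
        "outcome_z": y_z,
    }
    return df, truth
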