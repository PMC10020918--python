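"""End-to-end orchestration: label volumes → pseudo-DXA traits → morphometry
→ merge with mechanics → cohort statistics.

The imaging and statistics halves communicate only through a flat cohort CSV,
so either half can be run (and validated) on its own. Outputs are plain CSV/
JSON and are bit-reproducible for a fixed config: the structured run log
records the config hash and per-stage provenance, and per-sample failures are
isolated — one bad input is reported and the run continues.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
import traceback
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import mechanics as mech
from .morphometry import compute_morphometry
from .projection import compute_params, project_voi, regional_counts
from .segmentation import LabelVolume, estimate_subendosteal
from .stats import (
    MODEL_PREDICTORS,
    fit_model_ladder,
    group_compare,
    sensitivity_exclusion,
    split_subgroups,
)
from .voi import VoiSpec, derotate_volume, extract_voi
from .volume_io import read_volume

__all__ = ["RunConfig", "run_pipeline", "cohort_statistics", "process_label_volume"]


@dataclass
class RunConfig:
    """All pipeline knobs in one serialisable record."""

    anteversion_deg: float = 15.0
    thickness_mm: float = 15.0
    roi_height_mm: float | None = None
    closing_radius_mm: float = 0.5
    stiffness_window: tuple[float, float] = (0.2, 0.8)
    preload_n: float = 100.0
    compliance_mm: float = 0.0
    failure_fraction: float = 0.5
    yield_anchor: str = "intercept"
    alpha: float = 0.05
    vif_cap: float = 10.0
    sensitivity_m: tuple[int, ...] = (0, 4, 8, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.failure_fraction < 1):
            raise ValueError("failure_fraction must lie in (0, 1)")
        if self.vif_cap <= 1:
            raise ValueError("vif_cap must exceed 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "stiffness_window" in d:
            d["stiffness_window"] = tuple(d["stiffness_window"])
        if "sensitivity_m" in d:
            d["sensitivity_m"] = tuple(d["sensitivity_m"])
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def process_label_volume(
    voi: LabelVolume, config: RunConfig, landmarks: VoiSpec | None = None
) -> dict:
    """Imaging half for one specimen: optional derotation + VOI cut, then
    projection traits, regional counts, and 3D morphometry as one flat row."""
    if landmarks is not None:
        if landmarks.anteversion_deg:
            voi = derotate_volume(voi, landmarks.anteversion_deg)
        voi = extract_voi(voi, landmarks)
    if voi.subendosteal is None:
        voi = LabelVolume(
            labels=voi.labels,
            voxel_size_mm=voi.voxel_size_mm,
            subendosteal=estimate_subendosteal(
                voi.labels, voi.voxel_size_mm, config.closing_radius_mm
            ),
            meta=voi.meta,
        )
    img = project_voi(voi)
    params = compute_params(img)
    reg = regional_counts(img)
    morpho = compute_morphometry(voi)
    return {
        "area_cm2": params.area_cm2,
        "bmc_voxels": params.bmc_voxels,
        "bmd_voxels_per_cm2": params.bmd_voxels_per_cm2,
        "avg_fn_width_mm": params.avg_fn_width_mm,
        "min_fn_width_mm": params.min_fn_width_mm,
        "cortical_sup_voxels": reg.cortical_superior,
        "trabecular_sup_voxels": reg.trabecular_superior,
        "cortical_inf_voxels": reg.cortical_inferior,
        "trabecular_inf_voxels": reg.trabecular_inferior,
        "total_sup_voxels": reg.cortical_superior + reg.trabecular_superior,
        "total_inf_voxels": reg.cortical_inferior + reg.trabecular_inferior,
        "cortical_fraction": reg.cortical_fraction,
        "bvtv": morpho.bvtv,
        "tb_th_mm": morpho.tb_th_mm,
        "ct_th_mm": morpho.ct_th_mm,
        "tt_ar_mm2": morpho.tt_ar_mm2,
        "ct_ar_mm2": morpho.ct_ar_mm2,
    }


def _process_curve(path, config: RunConfig) -> dict:
    curve = mech.read_curve_csv(path)
    curve = mech.preprocess_curve(
        curve, preload_n=config.preload_n, compliance_mm=config.compliance_mm
    )
    res = mech.extract_metrics(
        curve,
        window=config.stiffness_window,
        yield_anchor=config.yield_anchor,
        failure_fraction=config.failure_fraction,
    )
    return {
        "stiffness_n_per_mm": res.stiffness_n_per_mm,
        "yield_load_n": res.yield_load_n,
        "max_load_n": res.max_load_n,
        "pyd_mm": res.pyd_mm,
        "yield_flagged": res.yield_flagged,
    }


_T2_VARIABLES = [
    "age_yr",
    "body_weight_kg",
    "area_cm2",
    "bmc_voxels",
    "bmd_voxels_per_cm2",
    "cortical_fraction",
    "max_load_n",
    "pyd_mm",
]


def cohort_statistics(cohort: pd.DataFrame, config: RunConfig) -> dict[str, pd.DataFrame]:
    """Statistics half: subgroup split, group comparison table, regression
    ladder (tidy + wide), and the middle-exclusion sensitivity table."""
    cohort = split_subgroups(cohort)

    t2_rows = []
    for var in _T2_VARIABLES:
        if var not in cohort.columns or cohort[var].dropna().empty:
            continue
        row = {"variable": var}
        row.update(group_compare(cohort, var))
        t2_rows.append(row)
    table2 = pd.DataFrame(t2_rows)

    def _ladder(frame, grp):
        """Fit each ladder model separately so an underpowered model (too few
        rows for its predictor count) does not abort the others."""
        results = []
        for mid in MODEL_PREDICTORS:
            try:
                results.extend(
                    fit_model_ladder(
                        frame, group=grp, models=(mid,), vif_cap=config.vif_cap
                    )
                )
            except ValueError as exc:
                warnings.warn(f"ladder ({grp}, model {mid}) skipped: {exc}",
                              stacklevel=3)
        return results

    tidy_rows = []
    wide_rows = []
    for grp in ("all", "narrow", "wide"):
        results = _ladder(cohort, grp)
        for r in results:
            wide_rows.append(
                {
                    "group": grp,
                    "model": r.model_id,
                    "adj_r2": r.adj_r2,
                    "model_p": r.model_p,
                    "n": r.n,
                    "dropped_by_vif": ";".join(r.dropped_predictors),
                }
            )
            for pred in r.predictors:
                tidy_rows.append(
                    {
                        "group": grp,
                        "model": r.model_id,
                        "predictor": pred,
                        "std_beta": r.std_betas[pred],
                        "p": r.p_values[pred],
                        "vif": r.vifs.get(pred, np.nan),
                        "n": r.n,
                    }
                )
    table3_tidy = pd.DataFrame(tidy_rows)
    table3_wide = pd.DataFrame(wide_rows)

    sens_rows = []
    for m in config.sensitivity_m:
        try:
            sub = sensitivity_exclusion(cohort, m)
        except ValueError as exc:
            warnings.warn(f"sensitivity m={m} skipped: {exc}", stacklevel=2)
            continue
        for grp in ("narrow", "wide"):
            for r in _ladder(sub, grp):
                sens_rows.append(
                    {
                        "middle_excluded": m,
                        "group": grp,
                        "model": r.model_id,
                        "adj_r2": r.adj_r2,
                        "model_p": r.model_p,
                        "n": r.n,
                    }
                )
    sensitivity = pd.DataFrame(sens_rows)
    return {
        "cohort": cohort,
        "table2": table2,
        "table3_tidy": table3_tidy,
        "table3_wide": table3_wide,
        "sensitivity": sensitivity,
    }


def run_pipeline(
    config: RunConfig, manifest: pd.DataFrame, outdir
) -> dict[str, pd.DataFrame]:
    """Run the full pipeline over a sample manifest and write the output bundle.

    Manifest columns: ``id`` plus any of ``labels_path`` (NIfTI/TIFF/MHD label
    volume), ``landmarks_path`` (VOI landmark JSON), ``curve_path``
    (load–displacement CSV), ``age_yr``, ``body_weight_kg``. Per-sample
    failures are recorded in the run log and do not stop the run.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(config), "config_hash": config.hash(), "samples": {}}

    rows = []
    if len(manifest) == 0:
        warnings.warn("empty manifest: writing empty outputs", stacklevel=2)
    for _, entry in manifest.iterrows():
        sid = str(entry["id"])
        row: dict = {"id": sid}
        stages: dict = {}
        for c in ("age_yr", "body_weight_kg"):
            if c in manifest.columns and pd.notna(entry.get(c)):
                row[c] = float(entry[c])
        try:
            if "labels_path" in manifest.columns and pd.notna(entry.get("labels_path")):
                vol = read_volume(entry["labels_path"])
                voi = LabelVolume(
                    labels=vol.values.astype(np.uint8),
                    voxel_size_mm=vol.voxel_size_mm,
                )
                landmarks = None
                if "landmarks_path" in manifest.columns and pd.notna(
                    entry.get("landmarks_path")
                ):
                    landmarks = VoiSpec.from_json(entry["landmarks_path"])
                row.update(process_label_volume(voi, config, landmarks))
                stages["imaging"] = "ok"
            if "curve_path" in manifest.columns and pd.notna(entry.get("curve_path")):
                row.update(_process_curve(entry["curve_path"], config))
                stages["mechanics"] = "ok"
        except Exception as exc:  # noqa: BLE001 — isolate per-sample failures
            stages["error"] = f"{type(exc).__name__}: {exc}"
            stages["traceback"] = traceback.format_exc(limit=3)
        log["samples"][sid] = stages
        rows.append(row)

    cohort = pd.DataFrame(rows)
    cohort.to_csv(outdir / "cohort.csv", index=False)

    outputs: dict[str, pd.DataFrame] = {"cohort": cohort}
    if len(cohort) >= 6 and "area_cm2" in cohort.columns:
        try:
            stats_out = cohort_statistics(cohort, config)
        except ValueError as exc:
            warnings.warn(f"statistics stage skipped: {exc}", stacklevel=2)
        else:
            outputs.update(stats_out)
            stats_out["cohort"].to_csv(outdir / "cohort.csv", index=False)
            stats_out["table2"].to_csv(outdir / "table2_subgroups.csv", index=False)
            stats_out["table3_tidy"].to_csv(outdir / "table3_tidy.csv", index=False)
            stats_out["table3_wide"].to_csv(outdir / "table3_wide.csv", index=False)
            stats_out["sensitivity"].to_csv(outdir / "sensitivity.csv", index=False)

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return outputs
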