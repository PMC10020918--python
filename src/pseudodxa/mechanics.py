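"""Whole-bone strength metrics from load–displacement curves.

A sideways-fall test yields a load–displacement record per femur. This module
extracts:

* stiffness (N/mm) — least-squares slope over the elastic portion,
* yield point — where a line with 90% of the fitted stiffness (the "10%
  stiffness-reduction" rule), anchored at the stiffness regression's own
  intercept, first crosses the measured curve beyond the fit range,
* maximum load (N) — used synonymously with whole-bone strength,
* post-yield displacement (PYD, mm) — displacement accumulated between yield
  and failure; a whole-bone surrogate for tissue brittleness (low = brittle).

Preprocessing trims everything before the seating preload (default 100 N) and
re-zeroes displacement there. Fixture-compliance correction (subtracting a
constant deflection, scaled by load) is available but off by default: measured
fixture deflection is on the order of 1% of total displacement.
"""

from __future__ import annotations

import pathlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LoadCurve",
    "StiffnessFit",
    "MechanicsResult",
    "preprocess_curve",
    "fit_stiffness",
    "find_yield",
    "extract_metrics",
    "read_curve_csv",
]


@dataclass
class LoadCurve:
    """Sampled load–displacement record (displacement nondecreasing)."""

    displacement_mm: np.ndarray
    load_n: np.ndarray

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=np.float64)
        self.load_n = np.asarray(self.load_n, dtype=np.float64)
        if self.displacement_mm.shape != self.load_n.shape:
            raise ValueError("displacement and load vectors differ in length")
        if self.displacement_mm.ndim != 1 or self.displacement_mm.size < 10:
            raise ValueError("curve needs at least 10 samples")
        if np.any(np.diff(self.displacement_mm) < -1e-12):
            raise ValueError("displacement must be nondecreasing")

    def __len__(self) -> int:
        return self.displacement_mm.size


@dataclass
class StiffnessFit:
    stiffness_n_per_mm: float
    intercept_n: float
    fit_range_mm: tuple[float, float]
    r2: float


@dataclass
class MechanicsResult:
    stiffness_n_per_mm: float
    yield_load_n: float
    yield_disp_mm: float
    max_load_n: float
    pyd_mm: float
    yield_flagged: bool = False  # True when no 10%-rule crossing existed

    def __post_init__(self) -> None:
        if self.yield_load_n > self.max_load_n + 1e-9:
            raise ValueError("yield load cannot exceed maximum load")
        if self.pyd_mm < -1e-12:
            raise ValueError("PYD must be non-negative")
        self.pyd_mm = max(self.pyd_mm, 0.0)


def read_curve_csv(path) -> LoadCurve:
    """Read a two-column CSV (displacement_mm, load_n)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        d = df[cols["displacement_mm"]].to_numpy()
        f = df[cols["load_n"]].to_numpy()
    except KeyError as exc:
        raise ValueError(
            f"{path}: expected columns displacement_mm, load_n"
        ) from exc
    return LoadCurve(displacement_mm=d, load_n=f)


def preprocess_curve(
    raw: LoadCurve, preload_n: float = 100.0, compliance_mm: float = 0.0
) -> LoadCurve:
    """Trim to the seating preload and optionally remove fixture compliance.

    Samples before the first crossing of ``preload_n`` are dropped; a sample
    interpolated exactly at the preload is inserted and displacement is
    re-zeroed there. ``compliance_mm`` (a constant fixture deflection at peak
    load) is subtracted proportionally to load/max(load).
    """
    d, f = raw.displacement_mm, raw.load_n
    if f[0] >= preload_n:
        d0 = d - d[0]
        fz = f
    else:
        above = np.flatnonzero(f >= preload_n)
        if above.size == 0:
            raise ValueError(
                f"curve never reaches the {preload_n} N preload (max {f.max():.1f} N)"
            )
        i = above[0]
        if f[i] == preload_n:  # crossing lands exactly on a sample
            d0 = d[i:] - d[i]
            fz = f[i:]
        else:
            # linear interpolation of the crossing between samples i-1 and i
            f0, f1 = f[i - 1], f[i]
            t = (preload_n - f0) / (f1 - f0)
            d_cross = d[i - 1] + t * (d[i] - d[i - 1])
            d0 = np.concatenate([[d_cross], d[i:]]) - d_cross
            fz = np.concatenate([[preload_n], f[i:]])
    if compliance_mm:
        # deflection accrued beyond the preload state, full correction at peak
        rel = (fz - fz[0]) / (fz.max() - fz[0]) if fz.max() > fz[0] else 0.0
        d0 = np.maximum.accumulate(d0 - compliance_mm * rel)
    if d0.size < 10:  # pad is not meaningful; enforce the length invariant
        raise ValueError("fewer than 10 samples remain after preload trimming")
    return LoadCurve(displacement_mm=d0, load_n=fz)


def fit_stiffness(
    curve: LoadCurve,
    window: tuple[float, float] = (0.2, 0.8),
    refine: bool = True,
) -> StiffnessFit:
    """Least-squares stiffness over a load-fraction window of the rising limb.

    ``window`` selects samples whose load lies between the given fractions of
    the pre-maximum load. With ``refine``, the 0.4-wide sub-window (stepped in
    0.05) with the highest R² is used — on a clean elastic limb every
    sub-window returns the same slope, while on curves with early toe-in or
    late softening the refinement locks onto the straight segment.
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ValueError(f"window fractions must satisfy 0 ≤ lo < hi ≤ 1, got {window}")
    d, f = curve.displacement_mm, curve.load_n
    i_max = int(np.argmax(f))
    f_max = f[i_max]

    def _fit(frac_lo: float, frac_hi: float) -> StiffnessFit | None:
        sel = np.flatnonzero(
            (f[: i_max + 1] >= frac_lo * f_max) & (f[: i_max + 1] <= frac_hi * f_max)
        )
        if sel.size < 5:
            return None
        x, y = d[sel], f[sel]
        if np.ptp(x) == 0:
            return None
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - float(np.sum(resid**2) / sst) if sst > 0 else 1.0
        return StiffnessFit(
            stiffness_n_per_mm=float(slope),
            intercept_n=float(intercept),
            fit_range_mm=(float(x[0]), float(x[-1])),
            r2=r2,
        )

    best = _fit(lo, hi)
    if best is None:
        raise ValueError("fewer than 5 samples in the stiffness window")
    if refine and hi - lo > 0.4 + 1e-9:
        for a in np.arange(lo, hi - 0.4 + 1e-9, 0.05):
            cand = _fit(a, a + 0.4)
            if cand is not None and cand.r2 > best.r2 + 1e-12:
                best = cand
    if best.stiffness_n_per_mm <= 0:
        raise ValueError(
            f"nonpositive stiffness {best.stiffness_n_per_mm:.3g} N/mm: invalid test"
        )
    return best


def find_yield(
    curve: LoadCurve,
    fit: StiffnessFit,
    anchor: str = "intercept",
) -> tuple[float, float, bool]:
    """Yield point by the 10% stiffness-reduction rule.

    A line with slope 0.9 × stiffness is drawn; with ``anchor='intercept'``
    it shares the stiffness regression's intercept, with
    ``anchor='window_start'`` it passes through the start of the fit window.
    Yield is the first intersection of this line with the measured curve
    beyond the fit range (linear interpolation between samples). If the curve
    never falls to the reduced line, yield is placed at maximum load and
    flagged.

    Returns ``(yield_load, yield_disp, flagged)``.
    """
    k = fit.stiffness_n_per_mm
    k_red = 0.9 * k
    if anchor == "intercept":
        b = fit.intercept_n
    elif anchor == "window_start":
        d_lo = fit.fit_range_mm[0]
        y_lo = k * d_lo + fit.intercept_n
        b = y_lo - k_red * d_lo
    else:
        raise ValueError(f"unknown anchor {anchor!r}")

    d, f = curve.displacement_mm, curve.load_n
    start = np.searchsorted(d, fit.fit_range_mm[1], side="right")
    g = f - (k_red * d + b)  # curve minus reduced line; yield where g crosses ≤ 0
    for i in range(max(start, 1), len(d)):
        if g[i] <= 0 and g[i - 1] > 0:
            t = g[i - 1] / (g[i - 1] - g[i])
            dy = d[i - 1] + t * (d[i] - d[i - 1])
            return float(k_red * dy + b), float(dy), False
        if g[i] <= 0 and i == max(start, 1) and g[i - 1] <= 0:
            # already below the line at the start of the search region
            return float(f[i - 1]), float(d[i - 1]), False
    i_max = int(np.argmax(f))
    warnings.warn(
        "no 10%-rule crossing before curve end; yield set at maximum load",
        stacklevel=2,
    )
    return float(f[i_max]), float(d[i_max]), True


def extract_metrics(
    curve: LoadCurve,
    window: tuple[float, float] = (0.2, 0.8),
    refine: bool = True,
    yield_anchor: str = "intercept",
    failure_fraction: float = 0.5,
) -> MechanicsResult:
    """Full metric extraction from a preprocessed curve.

    Failure, the PYD endpoint, is the first sample after the maximum where
    load drops below ``failure_fraction`` × max load (default 50%); if the
    record ends before such a drop, the last sample is used.
    """
    fit = fit_stiffness(curve, window=window, refine=refine)
    y_load, y_disp, flagged = find_yield(curve, fit, anchor=yield_anchor)
    d, f = curve.displacement_mm, curve.load_n
    i_max = int(np.argmax(f))
    f_max = float(f[i_max])
    post = np.flatnonzero(f[i_max:] < failure_fraction * f_max)
    i_fail = i_max + post[0] if post.size else len(f) - 1
    pyd = max(float(d[i_fail]) - y_disp, 0.0)
    return MechanicsResult(
        stiffness_n_per_mm=fit.stiffness_n_per_mm,
        yield_load_n=min(y_load, f_max),
        yield_disp_mm=y_disp,
        max_load_n=f_max,
        pyd_mm=pyd,
        yield_flagged=flagged,
    )
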