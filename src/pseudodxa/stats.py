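"""Cohort statistics: normality-gated transforms, bivariate fits, ANCOVA,
ICC(3,1), subgroup splitting, the five-model strength-regression ladder with
standardized betas and iterative VIF pruning, and the middle-exclusion
sensitivity analysis.

The cohort is a plain :class:`pandas.DataFrame` with one row per specimen.
Canonical column names (units in the header) are listed in
:data:`COHORT_COLUMNS`; the ladder's five predictor sets progressively refine
the density information:

1. age, log(body weight), BMD;
2. BMD replaced by its constituents, area and BMC;
3. BMC replaced by the superior/inferior voxel totals;
4. the regional totals split into cortical and trabecular counts;
5. model 4 plus sqrt(PYD), the brittleness term.

Body weight enters log-transformed and PYD square-root-transformed (both fail
Shapiro–Wilk normality in the reference cohort); these two choices are
hard-wired defaults, while :func:`normality_gate` automates the same decision
for any other variable. The outcome throughout is maximum load (strength).
Rows missing a model's variables are dropped listwise for that model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "COHORT_COLUMNS",
    "MODEL_PREDICTORS",
    "RegressionResult",
    "IccResult",
    "BivariateFit",
    "normality_gate",
    "bivariate_fit",
    "ancova_compare",
    "icc_3_1",
    "split_subgroups",
    "fit_model_ladder",
    "vif_prune",
    "sensitivity_exclusion",
    "group_compare",
]

#: canonical cohort column names
COHORT_COLUMNS = [
    "id",
    "age_yr",
    "body_weight_kg",
    "area_cm2",
    "bmc_voxels",
    "bmd_voxels_per_cm2",
    "total_sup_voxels",
    "total_inf_voxels",
    "cortical_sup_voxels",
    "trabecular_sup_voxels",
    "cortical_inf_voxels",
    "trabecular_inf_voxels",
    "cortical_fraction",
    "max_load_n",
    "pyd_mm",
    "subgroup",
]

# predictor -> fixed transform applied before fitting (None = identity)
_TRANSFORMS = {"body_weight_kg": "log", "pyd_mm": "sqrt"}

#: the five ladder models' predictor sets, in cohort-column terms
MODEL_PREDICTORS: dict[int, list[str]] = {
    1: ["age_yr", "body_weight_kg", "bmd_voxels_per_cm2"],
    2: ["age_yr", "body_weight_kg", "area_cm2", "bmc_voxels"],
    3: ["age_yr", "body_weight_kg", "area_cm2", "total_sup_voxels", "total_inf_voxels"],
    4: [
        "age_yr",
        "body_weight_kg",
        "area_cm2",
        "cortical_sup_voxels",
        "trabecular_sup_voxels",
        "cortical_inf_voxels",
        "trabecular_inf_voxels",
    ],
    5: [
        "age_yr",
        "body_weight_kg",
        "area_cm2",
        "cortical_sup_voxels",
        "trabecular_sup_voxels",
        "cortical_inf_voxels",
        "trabecular_inf_voxels",
        "pyd_mm",
    ],
}

OUTCOME = "max_load_n"


@dataclass
class BivariateFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r2: float
    p: float
    n: int


@dataclass
class RegressionResult:
    """One fitted ladder model for one grouping."""

    model_id: int
    group: str
    predictors: list[str]
    std_betas: dict[str, float]
    p_values: dict[str, float]
    adj_r2: float
    model_p: float
    vifs: dict[str, float]
    dropped_predictors: list[str] = field(default_factory=list)
    n: int = 0


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    category: str


def _apply_transform(x: np.ndarray, tag: str | None) -> np.ndarray:
    if tag is None or tag == "identity":
        return np.asarray(x, dtype=float)
    if tag == "log":
        return np.log(np.asarray(x, dtype=float))
    if tag == "sqrt":
        return np.sqrt(np.asarray(x, dtype=float))
    raise ValueError(f"unknown transform {tag!r}")


def normality_gate(
    values, alpha: float = 0.05
) -> tuple[np.ndarray, str]:
    """Shapiro–Wilk-gated transform: identity if already normal, else the
    first of log, sqrt that passes, else the better of the two.

    Nonpositive values make log (and, if negative, sqrt) inadmissible; the
    returned tag records any skipped candidate.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or not np.all(np.isfinite(x)):
        raise ValueError("need ≥3 finite values")
    if sps.shapiro(x).pvalue >= alpha:
        return x, "identity"
    candidates: list[str] = []
    skipped: list[str] = []
    if np.all(x > 0):
        candidates.append("log")
    else:
        skipped.append("log(skipped:nonpositive)")
    if np.all(x >= 0):
        candidates.append("sqrt")
    else:
        skipped.append("sqrt(skipped:negative)")
    best: tuple[float, str, np.ndarray] | None = None
    for tag in candidates:
        t = _apply_transform(x, tag)
        p = sps.shapiro(t).pvalue
        if p >= alpha:
            return t, "+".join([tag] + skipped) if skipped else tag
        if best is None or p > best[0]:
            best = (p, tag, t)
    if best is None:
        return x, "identity(" + ",".join(skipped) + ")"
    tag = best[1] + "(best-effort)"
    if skipped:
        tag += "+" + "+".join(skipped)
    return best[2], tag


def bivariate_fit(x, y, alpha: float = 0.05) -> BivariateFit:
    """Ordinary least squares y ~ x with t-based 95% CIs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched vectors of length ≥3")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=alpha)
    return BivariateFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        r2=float(fit.rsquared),
        p=float(fit.pvalues[1]),
        n=int(x.size),
    )


def ancova_compare(x, y, groups) -> tuple[float, float]:
    """ANCOVA comparison of two (or more) regression lines.

    Returns ``(slope_p, intercept_p)``: the slope test is the F-test on the
    group×x interaction in the separate-slopes model; the intercept test is
    the F-test on group in the common-slope model (interpretable when the
    slopes are homogeneous). Identical groups degenerate to p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = pd.Categorical(np.asarray(groups))
    if len(g.categories) < 2:
        raise ValueError("need ≥2 groups")
    for lev in g.categories:
        if (g == lev).sum() < 3:
            raise ValueError(f"group {lev!r} has fewer than 3 observations")

    dummies = pd.get_dummies(pd.Series(g), drop_first=True, dtype=float).to_numpy()
    X_common = np.column_stack([np.ones_like(x), x, dummies])
    X_full = np.column_stack([X_common, dummies * x[:, None]])
    X_slope_only = np.column_stack([np.ones_like(x), x])

    def _ssr(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    ssr_full, p_full = _ssr(X_full)
    ssr_common, p_common = _ssr(X_common)
    ssr_slope, p_slope = _ssr(X_slope_only)
    n = y.size

    def _ftest(ssr_reduced, ssr_full_, df_num, df_den):
        if df_den <= 0:
            raise ValueError("singular design: no residual degrees of freedom")
        diff = max(ssr_reduced - ssr_full_, 0.0)
        if ssr_full_ <= 1e-30 * max(1.0, float(y @ y)):
            # noise-free data: either no group effect at all (p = 1) or an
            # exact effect (p = 0)
            return 1.0 if diff <= 1e-30 * max(1.0, float(y @ y)) else 0.0
        F = (diff / df_num) / (ssr_full_ / df_den)
        return float(sps.f.sf(F, df_num, df_den))

    slope_p = _ftest(ssr_common, ssr_full, p_full - p_common, n - p_full)
    intercept_p = _ftest(ssr_slope, ssr_common, p_common - p_slope, n - p_common)
    return slope_p, intercept_p


_ICC_BOUNDS = [(0.5, "poor"), (0.75, "moderate"), (0.9, "good")]


def icc_3_1(measurements, alpha: float = 0.05) -> IccResult:
    """ICC(3,1): two-way mixed effects, consistency, single rater.

    From the two-way ANOVA of an ``n_targets × k_raters`` complete matrix::

        ICC = (MSR - MSE) / (MSR + (k - 1) MSE)

    with the 95% CI from the F distribution of MSR/MSE. The reliability
    category (poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤ excellent) is
    assigned from the CI lower bound.
    """
    M = np.asarray(measurements, dtype=float)
    if M.ndim != 2:
        raise ValueError("need an n_targets × k_raters matrix")
    n, k = M.shape
    if n < 5 or k < 2:
        raise ValueError(f"need n ≥ 5 targets and k ≥ 2 raters, got {n}×{k}")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix must be complete (no missing values)")
    if np.ptp(M) == 0:
        return IccResult(float("nan"), float("nan"), float("nan"), "undefined")

    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((M - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    if mse <= 0:
        icc = 1.0
        return IccResult(1.0, 1.0, 1.0, "excellent")
    icc = (msr - mse) / (msr + (k - 1) * mse)

    F = msr / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = F / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_u = F * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (f_l - 1) / (f_l + k - 1)
    ci_high = (f_u - 1) / (f_u + k - 1)
    category = "excellent"
    for bound, name in _ICC_BOUNDS:
        if ci_low < bound:
            category = name
            break
    return IccResult(float(icc), float(ci_low), float(ci_high), category)


def split_subgroups(cohort: pd.DataFrame, area_col: str = "area_cm2") -> pd.DataFrame:
    """Label each specimen narrow/wide by the pseudo-DXA-area median split.

    Ranking ties are broken deterministically by id; with an odd count the
    median specimen goes to the narrow subgroup. The result is invariant to
    the input row order.
    """
    if area_col not in cohort.columns:
        raise ValueError(f"cohort lacks column {area_col!r}")
    if cohort[area_col].isna().any():
        raise ValueError("pseudo-DXA area missing for some specimens")
    df = cohort.copy()
    if df[area_col].nunique() == 1:
        warnings.warn(
            "all areas equal: narrow/wide split falls back to id order",
            stacklevel=2,
        )
    order = df.sort_values([area_col, "id"], kind="mergesort").index
    n = len(df)
    n_narrow = (n + 1) // 2
    df["subgroup"] = ""
    df.loc[order[:n_narrow], "subgroup"] = "narrow"
    df.loc[order[n_narrow:], "subgroup"] = "wide"
    return df


def vif_prune(
    X: pd.DataFrame, cap: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the max-VIF predictor until all VIFs are below ``cap``.

    VIF_j = 1/(1−R²_j) with R²_j from regressing predictor j (with intercept)
    on the remaining predictors. Returns the retained predictor names and a
    table of VIFs per iteration. Terminates in at most p−1 iterations.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("need ≥2 predictors to compute VIFs")
    records = []
    retained = cols[:]
    iteration = 0
    while True:
        vifs = {}
        for c in retained:
            others = [o for o in retained if o != c]
            if not others:
                vifs[c] = 1.0
                continue
            A = sm.add_constant(X[others].to_numpy(dtype=float))
            fit = sm.OLS(X[c].to_numpy(dtype=float), A).fit()
            r2 = min(float(fit.rsquared), 1 - 1e-12)
            vifs[c] = 1.0 / (1.0 - r2)
        for c, v in vifs.items():
            records.append({"iteration": iteration, "predictor": c, "vif": v})
        worst = max(vifs, key=vifs.get)
        if vifs[worst] < cap or len(retained) == 1:
            break
        retained.remove(worst)
        iteration += 1
        if len(retained) < 2:
            break
    if not retained:
        raise ValueError("all predictors pruned")
    return retained, pd.DataFrame.from_records(records)


def _design(
    cohort: pd.DataFrame, predictors: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    cols = predictors + [OUTCOME]
    sub = cohort[cols].dropna()
    Xt = pd.DataFrame(index=sub.index)
    for c in predictors:
        tag = _TRANSFORMS.get(c)
        name = {"log": f"log_{c}", "sqrt": f"sqrt_{c}"}.get(tag, c)
        Xt[name] = _apply_transform(sub[c].to_numpy(), tag)
    return Xt, sub[OUTCOME]


def fit_model_ladder(
    cohort: pd.DataFrame,
    group: str = "all",
    models: tuple[int, ...] = (1, 2, 3, 4, 5),
    vif_cap: float = 10.0,
    prune: bool = False,
) -> list[RegressionResult]:
    """Fit the strength-regression ladder for one grouping.

    ``group`` is ``all``, ``narrow`` or ``wide`` (the latter two require a
    ``subgroup`` column). Standardized betas are b·sd(x)/sd(y). VIFs are
    reported for every model; with ``prune=True`` the model is refit on the
    VIF-pruned predictor set (the default reports the full set and the VIF
    table side by side).
    """
    if group != "all":
        if "subgroup" not in cohort.columns:
            raise ValueError("cohort has no subgroup labels; run split_subgroups")
        cohort = cohort[cohort["subgroup"] == group]
    out: list[RegressionResult] = []
    for m in models:
        predictors = MODEL_PREDICTORS[m]
        missing = [c for c in predictors + [OUTCOME] if c not in cohort.columns]
        if missing:
            raise ValueError(f"model {m}: cohort lacks columns {missing}")
        X, y = _design(cohort, predictors)
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(
                f"model {m} ({group}): n={n} observations cannot support "
                f"p={p} predictors"
            )
        retained, vif_table = vif_prune(X, cap=vif_cap)
        dropped = [c for c in X.columns if c not in retained]
        fit_cols = retained if prune else list(X.columns)
        A = sm.add_constant(X[fit_cols].to_numpy(dtype=float))
        fit = sm.OLS(y.to_numpy(dtype=float), A).fit()
        sy = float(np.std(y, ddof=1))
        std_betas = {}
        p_values = {}
        for j, c in enumerate(fit_cols, start=1):
            sx = float(np.std(X[c], ddof=1))
            std_betas[c] = float(fit.params[j]) * sx / sy if sy > 0 else float("nan")
            p_values[c] = float(fit.pvalues[j])
        last_iter = vif_table["iteration"].max()
        vifs = dict(
            zip(
                vif_table.loc[vif_table["iteration"] == last_iter, "predictor"],
                vif_table.loc[vif_table["iteration"] == last_iter, "vif"],
            )
        )
        out.append(
            RegressionResult(
                model_id=m,
                group=group,
                predictors=fit_cols,
                std_betas=std_betas,
                p_values=p_values,
                adj_r2=float(fit.rsquared_adj),
                model_p=float(fit.f_pvalue),
                vifs=vifs,
                dropped_predictors=dropped,
                n=n,
            )
        )
    return out


def sensitivity_exclusion(
    cohort: pd.DataFrame, m: int, area_col: str = "area_cm2"
) -> pd.DataFrame:
    """Drop the ``m`` specimens closest to the narrow/wide boundary.

    After ranking by pseudo-DXA area, the m/2 largest-area narrow specimens
    and the m/2 smallest-area wide specimens are removed; subgroup labels are
    retained. ``m = 0`` is the identity.
    """
    if m % 2 != 0 or m < 0:
        raise ValueError("m must be a non-negative even integer")
    if m == 0:
        return cohort.copy()
    if "subgroup" not in cohort.columns:
        raise ValueError("run split_subgroups first")
    half = m // 2
    narrow = cohort[cohort["subgroup"] == "narrow"]
    wide = cohort[cohort["subgroup"] == "wide"]
    if half >= len(narrow) or half >= len(wide):
        raise ValueError(
            f"cannot remove {half} from subgroups of size "
            f"{len(narrow)}/{len(wide)}"
        )
    drop_narrow = narrow.sort_values([area_col, "id"], kind="mergesort").index[-half:]
    drop_wide = wide.sort_values([area_col, "id"], kind="mergesort").index[:half]
    return cohort.drop(index=drop_narrow.union(drop_wide))


def group_compare(
    cohort: pd.DataFrame, variable: str, equal_var: bool = True
) -> dict:
    """Two-sample comparison of a variable between narrow and wide subgroups.

    Returns per-group means/SDs/counts and the two-sided t-test p-value
    (equal-variance by default; Welch with ``equal_var=False``).
    """
    if "subgroup" not in cohort.columns:
        raise ValueError("run split_subgroups first")
    res = {}
    samples = {}
    for g in ("narrow", "wide"):
        vals = cohort.loc[cohort["subgroup"] == g, variable].dropna().to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"subgroup {g} has fewer than 2 values for {variable}")
        samples[g] = vals
        res[f"{g}_mean"] = float(vals.mean())
        res[f"{g}_sd"] = float(vals.std(ddof=1))
        res[f"{g}_n"] = int(vals.size)
    if res["narrow_sd"] == 0 and res["wide_sd"] == 0:
        res["t_p"] = (
            1.0 if res["narrow_mean"] == res["wide_mean"] else float("nan")
        )
    else:
        if np.array_equal(np.sort(samples["narrow"]), np.sort(samples["wide"])):
            res["t_p"] = 1.0
        else:
            res["t_p"] = float(
                sps.ttest_ind(
                    samples["narrow"], samples["wide"], equal_var=equal_var
                ).pvalue
            )
    return res
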