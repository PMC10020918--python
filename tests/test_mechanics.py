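import numpy as np
import pytest

from pseudodxa.mechanics import (
    LoadCurve,
    extract_metrics,
    find_yield,
    fit_stiffness,
    preprocess_curve,
    read_curve_csv,
)
from pseudodxa.synthetic import CurveSpec, generate_curve


def _line(stiffness=2000.0, d_max=2.0, n=400, noise=0.0, seed=0):
    d = np.linspace(0, d_max, n)
    f = stiffness * d
    if noise:
        f = f + np.random.default_rng(seed).normal(0, noise, n)
    return LoadCurve(displacement_mm=d, load_n=f)


def _bilinear(k1=2000.0, break_load=2000.0, k2=200.0, d_max=4.0, dx=0.005):
    d1 = break_load / k1
    d = np.arange(0, d_max + dx / 2, dx)
    f = np.where(d <= d1, k1 * d, break_load + k2 * (d - d1))
    return LoadCurve(displacement_mm=d, load_n=f)


class TestPreprocess:
    def test_curve_starting_above_preload_is_only_rezeroed(self):
        d = np.linspace(1.0, 2.0, 50)
        c = preprocess_curve(LoadCurve(d, 500 + 1000 * (d - 1)), preload_n=100)
        assert c.displacement_mm[0] == 0.0
        np.testing.assert_allclose(np.diff(c.displacement_mm), np.diff(d))

    def test_linear_ramp_crossing_interpolated_exactly(self):
        """A 200 N/mm ramp crosses 100 N at 0.5 mm; the retained curve starts
        at (0, 100)."""
        d = np.linspace(0, 3, 301)
        c = preprocess_curve(LoadCurve(d, 200 * d), preload_n=100)
        assert c.load_n[0] == pytest.approx(100.0)
        assert c.displacement_mm[0] == 0.0
        # subsequent samples shifted by the 0.5 mm crossing
        assert c.displacement_mm[1] == pytest.approx(d[51] - 0.5)

    def test_zero_compliance_is_identity(self):
        curve = _line()
        c0 = preprocess_curve(curve, preload_n=100, compliance_mm=0.0)
        c1 = preprocess_curve(curve, preload_n=100, compliance_mm=0.04)
        np.testing.assert_allclose(
            c0.displacement_mm[-1] - c1.displacement_mm[-1], 0.04, atol=1e-9
        )

    def test_never_reaching_preload_is_an_error(self):
        with pytest.raises(ValueError, match="preload"):
            preprocess_curve(_line(stiffness=10.0, d_max=1.0), preload_n=100)


class TestFitStiffness:
    def test_exact_line_recovered(self):
        fit = fit_stiffness(_line(stiffness=2000.0))
        assert fit.stiffness_n_per_mm == pytest.approx(2000.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_noisy_line_slope_within_its_own_ci(self):
        """With iid load noise the fitted slope stays within its 95% CI of the
        true stiffness (single seeded draw of a calibrated-coverage event)."""
        curve = _line(stiffness=2000.0, n=500, noise=5.0, seed=42)
        fit = fit_stiffness(curve, refine=False)
        sel = (curve.load_n >= 0.2 * curve.load_n.max()) & (
            curve.load_n <= 0.8 * curve.load_n.max()
        )
        x, y = curve.displacement_mm[sel], curve.load_n[sel]
        resid = y - (fit.stiffness_n_per_mm * x + fit.intercept_n)
        se = np.sqrt(
            resid @ resid / (x.size - 2) / np.sum((x - x.mean()) ** 2)
        )
        assert abs(fit.stiffness_n_per_mm - 2000.0) < 1.96 * se * 1.5

    def test_bilinear_window_confined_to_first_limb(self):
        fit = fit_stiffness(_bilinear(), window=(0.1, 0.5), refine=False)
        assert fit.stiffness_n_per_mm == pytest.approx(2000.0, abs=1e-6)

    def test_descending_curve_rejected(self):
        d = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="stiffness"):
            fit_stiffness(LoadCurve(d, 1000 - 500 * d))


class TestFindYield:
    def test_bilinear_yield_matches_two_line_closed_form(self):
        """Yield = intersection of the 0.9·K line with the second limb."""
        k1, bl, k2 = 2000.0, 2000.0, 200.0
        curve = _bilinear(k1, bl, k2)
        fit = fit_stiffness(curve, window=(0.1, 0.45), refine=False)
        y_load, y_disp, flagged = find_yield(curve, fit)
        d1 = bl / k1
        d_star = (bl - k2 * d1) / (0.9 * k1 - k2)
        assert not flagged
        assert y_disp == pytest.approx(d_star, abs=1e-9)
        assert y_load == pytest.approx(0.9 * k1 * d_star, abs=1e-9)

    def test_perfectly_linear_curve_flags_yield_at_max(self):
        curve = _line(stiffness=2000.0)
        fit = fit_stiffness(curve, refine=False)
        with pytest.warns(UserWarning, match="yield"):
            y_load, y_disp, flagged = find_yield(curve, fit)
        assert flagged
        assert y_load == pytest.approx(curve.load_n.max())

    def test_window_start_anchor_available(self):
        curve = _bilinear()
        fit = fit_stiffness(curve, window=(0.1, 0.45), refine=False)
        y1 = find_yield(curve, fit, anchor="intercept")
        y2 = find_yield(curve, fit, anchor="window_start")
        assert y2[1] >= 0 and abs(y1[1] - y2[1]) < 0.5


class TestExtractMetrics:
    def test_bilinear_pyd_closed_form(self):
        k1, bl, k2, d_max = 2000.0, 2000.0, 200.0, 4.0
        res = extract_metrics(_bilinear(k1, bl, k2, d_max))
        d1 = bl / k1
        d_star = (bl - k2 * d1) / (0.9 * k1 - k2)
        assert res.pyd_mm == pytest.approx(d_max - d_star, abs=1e-6)
        assert res.max_load_n == pytest.approx(bl + k2 * (d_max - d1))
        assert res.yield_load_n <= res.max_load_n

    def test_elastic_brittle_curve_has_zero_pyd(self):
        curve = _line(stiffness=2000.0, d_max=1.5)
        with pytest.warns(UserWarning):
            res = extract_metrics(curve)
        assert res.pyd_mm == pytest.approx(0.0, abs=1e-9)
        assert res.yield_flagged

    def test_load_scaling_property(self):
        """Scaling load by c scales stiffness and loads by c; displacement
        quantities are unchanged."""
        base = extract_metrics(_bilinear())
        scaled_curve = _bilinear()
        scaled = extract_metrics(
            LoadCurve(scaled_curve.displacement_mm, 3.0 * scaled_curve.load_n)
        )
        assert scaled.stiffness_n_per_mm == pytest.approx(3 * base.stiffness_n_per_mm)
        assert scaled.max_load_n == pytest.approx(3 * base.max_load_n)
        assert scaled.yield_load_n == pytest.approx(3 * base.yield_load_n, rel=1e-9)
        assert scaled.yield_disp_mm == pytest.approx(base.yield_disp_mm, abs=1e-9)
        assert scaled.pyd_mm == pytest.approx(base.pyd_mm, abs=1e-9)

    def test_displacement_scaling_property(self):
        base = extract_metrics(_bilinear())
        c = _bilinear()
        scaled = extract_metrics(LoadCurve(2.0 * c.displacement_mm, c.load_n))
        assert scaled.stiffness_n_per_mm == pytest.approx(
            base.stiffness_n_per_mm / 2, rel=1e-9
        )
        assert scaled.yield_disp_mm == pytest.approx(2 * base.yield_disp_mm, rel=1e-9)
        assert scaled.pyd_mm == pytest.approx(2 * base.pyd_mm, rel=1e-6)

    def test_generator_truth_recovered_with_noise(self):
        """Noisy synthetic curves give back the analytic yield point within
        one sample spacing."""
        spec = CurveSpec(noise_sd_n=2.0, sample_spacing_mm=0.01, seed=5)
        curve, truth = generate_curve(spec)
        res = extract_metrics(curve)
        assert res.yield_disp_mm == pytest.approx(
            truth["yield_disp_mm"], abs=spec.sample_spacing_mm
        )
        assert res.stiffness_n_per_mm == pytest.approx(
            truth["stiffness_n_per_mm"], rel=0.02
        )


def test_curve_csv_reader(tmp_path):
    import pandas as pd

    d = np.linspace(0, 1, 20)
    pd.DataFrame({"displacement_mm": d, "load_n": 100 * d}).to_csv(
        tmp_path / "c.csv", index=False
    )
    curve = read_curve_csv(tmp_path / "c.csv")
    assert len(curve) == 20
    with pytest.raises(ValueError, match="columns"):
        pd.DataFrame({"a": d}).to_csv(tmp_path / "bad.csv", index=False)
        read_curve_csv(tmp_path / "bad.csv")
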