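import numpy as np
import pytest

from grace_melt import (
    MeltCurve,
    MeltRun,
    SimSampleSpec,
    default_grid,
    detect_peaks,
    negative_derivative,
    normalize_between,
    place_windows,
    plateau_height,
    simulate_curve,
    smooth,
)
from grace_melt.errors import (
    GraceMeltError,
    NormalizationError,
    ParameterError,
)
from grace_melt.signal import NormalizationWindows, locate_plateaus

from conftest import ALL_COPY_PAIRS, make_run


def logistic_curve(a=1.0, w=0.4, tm=82.2, baseline=3.0, slope=0.0, sid="x"):
    t = default_grid()
    f = baseline + slope * (t - 77.0) + a / (1 + np.exp((t - tm) / w))
    return MeltCurve(sid, t, f)


class TestSmooth:
    def test_preserves_noiseless_logistic(self):
        c = logistic_curve(a=1.0, w=0.45)
        s = smooth(c, 7, 2)
        assert np.max(np.abs(s.fluorescence - c.fluorescence)) < 0.01  # 1% of amplitude

    def test_constant_curve_unchanged(self):
        c = MeltCurve("k", default_grid(), np.full(51, 5.5))
        s = smooth(c, 7, 2)
        np.testing.assert_allclose(s.fluorescence, 5.5, atol=1e-9)

    @pytest.mark.parametrize("window, order", [(6, 2), (3, 3), (101, 2)])
    def test_invalid_parameters(self, window, order):
        with pytest.raises(ParameterError):
            smooth(logistic_curve(), window, order)


class TestNegativeDerivative:
    def test_logistic_peak_height_analytic(self):
        # analytic max of -dF/dT is A/(4w); discretization on the 0.2 °C grid
        # costs ~2% at w=0.4
        d = negative_derivative(logistic_curve(a=1.0, w=0.4, tm=82.2))
        assert d.values.max() == pytest.approx(1.0 / 1.6, rel=0.03)
        assert d.temperatures_c[np.argmax(d.values)] == pytest.approx(82.2, abs=0.2)

    def test_linear_baseline_gives_constant(self):
        c = MeltCurve("lin", default_grid(), 10.0 - 0.3 * (default_grid() - 77.0))
        d = negative_derivative(c)
        np.testing.assert_allclose(d.values, 0.3, atol=1e-9)

    def test_two_separated_logistics_superpose(self):
        t = default_grid()
        f = 1.0 + 0.8 / (1 + np.exp((t - 80.0) / 0.4)) + 1.5 / (1 + np.exp((t - 84.6) / 0.4))
        d = negative_derivative(MeltCurve("two", t, f))
        h1 = d.values[(t > 79) & (t < 81)].max()
        h2 = d.values[(t > 83.6) & (t < 85.6)].max()
        assert h1 == pytest.approx(0.8 / 1.6, rel=0.03)
        assert h2 == pytest.approx(1.5 / 1.6, rel=0.03)


class TestDetectPeaks:
    def test_wildtype_peak_positions(self, panel, noiseless_run):
        run, _ = noiseless_run
        d = negative_derivative(run.control)
        ps = detect_peaks(d, panel)
        for gene, tm in zip(("CLCN7", "HBA1", "HBA2"), (79.4, 82.2, 85.2)):
            assert ps.peaks[gene].temperature_c == pytest.approx(tm, abs=0.2)
            assert ps.peaks[gene].height > 0

    def test_peak_heights_proportional_to_copies(self, panel):
        # heights per copy agree across copy states (the ratio the caller uses)
        run, pairs = make_run(panel, [(2, 2), (2, 1), (1, 1), (2, 3)])
        d_ctrl = negative_derivative(run.control)
        plateaus = locate_plateaus(d_ctrl, panel)
        ctrl = detect_peaks(d_ctrl, panel, plateaus)
        per_copy = []
        for sid, (c1, c2) in pairs.items():
            ps = detect_peaks(negative_derivative(run.curves[sid]), panel, plateaus, ctrl)
            per_copy.append(ps.peaks["HBA1"].height / c1)
            per_copy.append(ps.peaks["HBA2"].height / c2)
        assert np.ptp(per_copy) / np.mean(per_copy) < 0.03

    def test_absent_target_flagged_with_zero_height(self, panel):
        run, _ = make_run(panel, [(2, 0)])
        d_ctrl = negative_derivative(run.control)
        plateaus = locate_plateaus(d_ctrl, panel)
        ctrl = detect_peaks(d_ctrl, panel, plateaus)
        ps = detect_peaks(negative_derivative(run.curves["S0"]), panel, plateaus, ctrl)
        assert "HBA2" in ps.absent
        assert ps.peaks["HBA2"].height == 0.0

    def test_pure_noise_curve_fails(self, panel):
        rng = np.random.default_rng(0)
        c = MeltCurve("noise", default_grid(), np.abs(rng.normal(1.0, 0.05, 51)))
        with pytest.raises(GraceMeltError):
            detect_peaks(negative_derivative(c), panel)


class TestWindows:
    def test_automatic_placement_geometry(self, panel, noiseless_run):
        run, _ = noiseless_run
        w1 = place_windows(run, panel, "reference_vs_target1")
        w2 = place_windows(run, panel, "target1_vs_target2")
        # stage 1: pre below the reference melt, post between the target melts
        assert 77.0 <= w1.pre_window[0] and w1.pre_window[1] <= 78.4
        assert 82.2 < w1.post_window[0] and w1.post_window[1] < 85.2
        # stage 2: pre in the reference→HBA1 gap, post above the HBA2 melt
        assert 79.4 < w2.pre_window[0] and w2.pre_window[1] < 82.2
        assert 85.2 < w2.post_window[0] and w2.post_window[1] <= 87.0

    def test_windows_invariants(self):
        with pytest.raises(ValueError, match="below"):
            NormalizationWindows((80.0, 81.0), (80.5, 82.0))
        with pytest.raises(ValueError, match="t_start"):
            NormalizationWindows((81.0, 80.0), (83.0, 84.0))

    def test_placement_error_without_plateaus(self, panel):
        # overlapping melts: one wide transition spanning the whole range
        t = default_grid()
        f = 2.0 + 6.0 / (1 + np.exp((t - 82.0) / 2.5))
        run = MeltRun("r", {"c": MeltCurve("c", t, f)}, "c")
        with pytest.raises(GraceMeltError):
            place_windows(run, panel, "reference_vs_target1")


class TestNormalizeAndPlateau:
    def test_pre_100_post_0_by_construction(self, panel, noiseless_run):
        run, _ = noiseless_run
        for stage in ("reference_vs_target1", "target1_vs_target2"):
            w = place_windows(run, panel, stage)
            n = normalize_between(run.control, w)
            t = n.temperatures_c
            pre = n.values[(t >= w.pre_window[0]) & (t <= w.pre_window[1])]
            post = n.values[(t >= w.post_window[0]) & (t <= w.post_window[1])]
            assert np.mean(pre) == pytest.approx(100.0, abs=0.5)
            assert np.mean(post) == pytest.approx(0.0, abs=0.5)

    def test_constant_curve_degenerate(self, panel):
        c = MeltCurve("k", default_grid(), np.full(51, 4.0))
        w = NormalizationWindows((77.0, 78.2), (83.2, 84.4))
        with pytest.raises(NormalizationError):
            normalize_between(c, w)

    @pytest.mark.parametrize(
        "pair, stage, expected",
        [
            ((2, 2), "reference_vs_target1", 0.5),     # A1/(Aref+A1), equal amplitudes
            ((1, 1), "reference_vs_target1", 1 / 3),
            ((2, 1), "target1_vs_target2", 1 / 3),     # A2/(A1+A2) = 1/(2+1)
            ((2, 3), "target1_vs_target2", 0.6),
            ((2, 0), "target1_vs_target2", 0.0),
        ],
    )
    def test_plateau_matches_amplitude_fraction(self, panel, noiseless_run, pair, stage, expected):
        run, pairs = noiseless_run
        sid = next(s for s, p in pairs.items() if p == pair)
        w = place_windows(run, panel, stage)
        p = plateau_height(normalize_between(run.curves[sid], w), w, panel, stage)
        assert p.plateau_fraction == pytest.approx(expected, abs=0.02)
        assert 0.0 <= p.plateau_fraction <= 1.0

    def test_linear_baseline_absorbed(self, panel):
        # identical sample with and without a fluorescence baseline slope
        flat, _ = make_run(panel, [(2, 1)], baseline_slope=0.0)
        sloped, _ = make_run(panel, [(2, 1)], baseline_slope=-0.08)
        for stage in ("reference_vs_target1", "target1_vs_target2"):
            vals = []
            for run in (flat, sloped):
                w = place_windows(run, panel, stage)
                p = plateau_height(
                    normalize_between(run.curves["S0"], w), w, panel, stage
                )
                vals.append(p.plateau_fraction)
            assert abs(vals[0] - vals[1]) < 0.01

    def test_scale_invariance(self, panel, noiseless_run):
        run, _ = noiseless_run
        w = place_windows(run, panel, "reference_vs_target1")
        base = plateau_height(
            normalize_between(run.curves["S1"], w), w, panel, "reference_vs_target1"
        ).plateau_fraction
        scaled = plateau_height(
            normalize_between(run.curves["S1"].scaled(7.3), w),
            w, panel, "reference_vs_target1",
        ).plateau_fraction
        assert scaled == pytest.approx(base, abs=1e-9)
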