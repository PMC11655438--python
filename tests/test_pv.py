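"""Pressure-volume curve analysis: WSD, calibration, pooling, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedhydro.pv import (
    PsychrometerCalibration,
    PVSeries,
    apply_calibration,
    compute_wsd,
    fit_pv_curve,
    pool_series,
    summarize_pv,
)
from seedhydro.simulate import PVGenParams, gen_pv_series


class TestComputeWSD:
    def test_saturation_and_full_deficit_limits(self):
        s = PVSeries("x", 0.1, 0.06,
                     [(0.1, -0.1), (0.0600001, -3.0)])
        wsd = [w for w, _ in compute_wsd(s)]
        assert wsd[0] == 0.0
        assert wsd[1] == pytest.approx(1.0, abs=1e-5)

    def test_hand_value(self):
        s = PVSeries("x", 0.100, 0.060, [(0.090, -0.5)])
        (w, psi), = compute_wsd(s)
        assert w == pytest.approx(0.25)
        assert psi == -0.5

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    @settings(deadline=None, max_examples=30)
    def test_affine_invariance_of_weights(self, scale):
        base = PVSeries("x", 0.100, 0.060, [(0.090, -0.5), (0.080, -1.2)])
        scaled = PVSeries("x", 0.100 * scale, 0.060 * scale,
                          [(0.090 * scale, -0.5), (0.080 * scale, -1.2)])
        w0 = [w for w, _ in compute_wsd(base)]
        w1 = [w for w, _ in compute_wsd(scaled)]
        assert w0 == pytest.approx(w1, rel=1e-12)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="turgid weight"):
            PVSeries("bad", 0.05, 0.06, [(0.055, -0.5)])

    def test_out_of_range_point_named(self):
        with pytest.raises(ValueError, match="point 1"):
            PVSeries("bad", 0.1, 0.06, [(0.09, -0.5), (0.05, -1.0)])


class TestCalibration:
    @pytest.mark.parametrize(
        "slope,intercept,reading,expected",
        [
            (-0.01, 0.0, 100.0, -1.0),
            (-0.5, 0.7, 0.0, 0.7),
            (-0.012, 0.05, 150.0, -1.75),
        ],
    )
    def test_linear_map(self, slope, intercept, reading, expected):
        cal = PsychrometerCalibration(slope=slope, intercept=intercept)
        assert apply_calibration([reading], cal)[0] == pytest.approx(expected)

    def test_out_of_range_warns_but_computes(self):
        cal = PsychrometerCalibration(-0.01, 0.0, valid_range=(0.0, 50.0))
        with pytest.warns(UserWarning, match="outside"):
            out = apply_calibration([100.0], cal)
        assert out[0] == pytest.approx(-1.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            PsychrometerCalibration(slope=0.0)


class TestPooling:
    def test_self_pooling_doubles_points(self, simple_pv_series):
        pooled = pool_series(simple_pv_series, simple_pv_series)
        assert len(pooled.points) == 2 * len(simple_pv_series.points)
        wsd = [w for w, _ in compute_wsd(pooled)]
        assert wsd == sorted(wsd)
        assert pooled.pooled_from == ["s1", "s1"]

    def test_two_samples_merge_sorted(self, simple_pv_series):
        other = PVSeries("s2", 0.2, 0.1,
                         [(0.19, -0.4), (0.17, -0.9), (0.15, -1.5),
                          (0.13, -2.2), (0.12, -2.8)],
                         species="Picea abies", age_weeks=3)
        pooled = pool_series(simple_pv_series, other)
        assert len(pooled.points) == 9
        wsd = [w for w, _ in compute_wsd(pooled)]
        assert wsd == sorted(wsd)
        # per-sample normalisation: s2's first point is (0.2-0.19)/0.1 = 0.1
        assert any(abs(w - 0.1) < 1e-9 for w in wsd)

    def test_group_mismatch_rejected(self, simple_pv_series):
        other = PVSeries("s2", 0.2, 0.1, [(0.15, -1.0)],
                         species="Picea abies", age_weeks=8)
        with pytest.raises(ValueError, match="cannot pool"):
            pool_series(simple_pv_series, other)


class TestFitExactModel:
    """Noise-free quadratic + line constructed directly in reciprocal space."""

    def _construct(self, x_break=0.2):
        m, q = 0.8, -1.0  # osmotic line y = m x + q
        y0 = m * x_break + q
        a, b = -5.0, 2.0  # curvature/slope of the turgescent parabola
        quad = lambda x: a * (x - x_break) ** 2 + b * (x - x_break) + y0
        xs_t = np.linspace(0.0, x_break - 0.01, 6)
        xs_o = np.linspace(x_break + 0.01, 0.5, 6)
        pts = [(float(x), float(1.0 / quad(x))) for x in xs_t]
        pts += [(float(x), float(1.0 / (m * x + q))) for x in xs_o]
        psi_tlp = 1.0 / y0
        psi_osat = 1.0 / q
        return pts, x_break, psi_tlp, psi_osat

    def test_recovers_construction_exactly(self):
        pts, x_break, psi_tlp, psi_osat = self._construct()
        tr = fit_pv_curve(pts)
        assert tr.split_index == 6
        assert tr.wsd_tlp == pytest.approx(x_break, abs=1e-6)
        assert tr.psi_tlp == pytest.approx(psi_tlp, abs=1e-6)
        assert tr.psi_osat == pytest.approx(psi_osat, abs=1e-9)
        assert tr.fit_rss == pytest.approx(0.0, abs=1e-12)

    def test_epsilon_positive_and_turgor_based(self):
        pts, *_ = self._construct()
        tr = fit_pv_curve(pts, epsilon_mode="turgor")
        assert tr.epsilon > 0

    def test_too_few_points_rejected(self):
        pts, *_ = self._construct()
        with pytest.raises(ValueError, match="at least"):
            fit_pv_curve(pts[:5])


class TestFitGeneratorRecovery:
    def test_noiseless_recovery(self):
        series, truth = gen_pv_series(PVGenParams(psi_noise_sd=0.0, seed=1))
        tr = fit_pv_curve(compute_wsd(series))
        assert tr.psi_osat == pytest.approx(truth["psi_osat"], abs=0.01)
        assert tr.psi_tlp == pytest.approx(truth["psi_tlp"], abs=0.02)

    def test_noisy_monte_carlo_recovery(self):
        errs_tlp, errs_osat = [], []
        for seed in range(100):
            series, truth = gen_pv_series(
                PVGenParams(psi_noise_sd=0.03, seed=seed)
            )
            tr = fit_pv_curve(compute_wsd(series))
            errs_tlp.append(abs(tr.psi_tlp - truth["psi_tlp"]))
            errs_osat.append(abs(tr.psi_osat - truth["psi_osat"]))
            assert tr.psi_tlp <= tr.psi_osat < 0
            assert tr.epsilon > 0
        assert np.mean(errs_tlp) < 0.05
        assert np.median(errs_osat) <= 0.05

    def test_deeper_osmotic_potential_deepens_turgor_loss(self):
        """Recovered psi_tlp is non-increasing in the true |psi_osat|."""
        recovered = []
        for osat in (-0.6, -0.8, -1.0, -1.2, -1.4):
            series, _ = gen_pv_series(
                PVGenParams(psi_osat_true=osat, psi_noise_sd=0.0, seed=7)
            )
            recovered.append(fit_pv_curve(compute_wsd(series)).psi_tlp)
        assert all(b <= a + 1e-6 for a, b in zip(recovered, recovered[1:]))


class TestSummarize:
    def test_single_trait_has_missing_se(self):
        series, _ = gen_pv_series(PVGenParams(seed=3))
        tr = fit_pv_curve(compute_wsd(series), species="Picea abies",
                          age_weeks=3)
        out = summarize_pv([tr])
        assert out["psi_tlp_mean"].iloc[0] == pytest.approx(tr.psi_tlp)
        assert np.isnan(out["psi_tlp_se"].iloc[0])

    def test_hand_se(self):
        series, _ = gen_pv_series(PVGenParams(seed=3))
        base = fit_pv_curve(compute_wsd(series), species="X", age_weeks=3)
        traits = []
        for shift in (-0.2, 0.0, 0.2):
            t = type(base)(
                psi_tlp=-1.0 + shift - 0.5, psi_osat=-1.0 + shift,
                epsilon=base.epsilon, wsd_tlp=base.wsd_tlp,
                split_index=base.split_index, fit_rss=base.fit_rss,
                n_turgescent=base.n_turgescent, n_osmotic=base.n_osmotic,
                species="X", age_weeks=3,
            )
            traits.append(t)
        out = summarize_pv(traits)
        assert out["psi_osat_mean"].iloc[0] == pytest.approx(-1.0)
        assert out["psi_osat_se"].iloc[0] == pytest.approx(0.11547, abs=1e-4)
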