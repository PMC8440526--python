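"""Ratio normalization, spectra, bleedthrough, sensitivity, smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_hyp

from idrfret import fretspec, synth
from idrfret.errors import (
    DegenerateDesignError,
    DivisionError,
    InsufficientDataError,
    InvalidParameterError,
    MissingControlError,
    NormalizationError,
    SpanError,
)


def make_wells(rows):
    return pd.DataFrame(rows)


class TestRatioNormalize:
    def test_control_mean_is_exactly_one(self):
        df = synth.gen_plate_dataset(synth.PlateTruth(noise_cv=0.08, seed=3))
        out = fretspec.fret_ratio_normalize(df, "control")
        ctrl = out[out.treatment == "control"]
        assert abs(ctrl.normalized_ratio.mean() - 1.0) < 1e-12

    def test_forced_arithmetic(self):
        df = make_wells([
            {"well_id": "a", "DxDm": 100, "DxAm": 160, "AxAm": 1, "treatment": "control"},
            {"well_id": "b", "DxDm": 100, "DxAm": 200, "AxAm": 1, "treatment": "NaCl"},
        ])
        out = fretspec.fret_ratio_normalize(df, "control")
        assert out.loc[out.well_id == "b", "normalized_ratio"].item() == pytest.approx(1.25)

    def test_planted_slope_reaches_expected_ratio(self):
        truth = synth.PlateTruth(baseline_ratio=1.0, slope_per_M=0.5,
                                 noise_cv=0.0, concentrations=[0.0, 1.0])
        out = fretspec.fret_ratio_normalize(synth.gen_plate_dataset(truth), "control")
        at_1m = out[out.concentration_M == 1.0]
        np.testing.assert_allclose(at_1m.normalized_ratio, 1.5, rtol=1e-12)

    def test_errors(self):
        df = make_wells([{"well_id": "a", "DxDm": 0.0, "DxAm": 1, "AxAm": 1,
                          "treatment": "control"}])
        with pytest.raises(DivisionError):
            fretspec.fret_ratio_normalize(df, "control")
        df2 = make_wells([{"well_id": "a", "DxDm": 10, "DxAm": 1, "AxAm": 1,
                           "treatment": "NaCl"}])
        with pytest.raises(MissingControlError):
            fretspec.fret_ratio_normalize(df2, "control")

    @settings(max_examples=25, derandomize=True)
    @given(k=st_hyp.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        df = make_wells([
            {"well_id": "a", "DxDm": 100.0, "DxAm": 150.0, "AxAm": 1, "treatment": "control"},
            {"well_id": "b", "DxDm": 80.0, "DxAm": 200.0, "AxAm": 1, "treatment": "NaCl"},
        ])
        base = fretspec.fret_ratio_normalize(df, "control")
        scaled = df.copy()
        scaled[["DxDm", "DxAm", "AxAm"]] *= k
        out = fretspec.fret_ratio_normalize(scaled, "control")
        np.testing.assert_allclose(out.normalized_ratio, base.normalized_ratio,
                                   rtol=1e-9)


class TestSpectrum:
    def test_anchor_normalization(self):
        spec = fretspec.EmissionSpectrum([480.0, 515.0], [4.0, 2.0])
        out = fretspec.normalize_spectrum(spec)
        np.testing.assert_allclose(out.intensities, [2.0, 1.0])

    def test_flat_spectrum_all_ones(self):
        w = np.arange(460.0, 551.0, 5.0)
        out = fretspec.normalize_spectrum(
            fretspec.EmissionSpectrum(w, np.full_like(w, 7.0)))
        np.testing.assert_allclose(out.intensities, 1.0)

    def test_anchor_snaps_to_nearest_sample(self):
        w = np.arange(460.0, 551.0, 5.0)
        inten = np.ones_like(w)
        inten[w == 515.0] = 4.0
        out = fretspec.normalize_spectrum(
            fretspec.EmissionSpectrum(w, inten), anchor=514.6)
        assert out.intensities[np.where(w == 515.0)[0][0]] == 1.0

    def test_zero_anchor_error(self):
        spec = fretspec.EmissionSpectrum([510.0, 515.0, 520.0], [1.0, 0.0, 1.0])
        with pytest.raises(NormalizationError):
            fretspec.normalize_spectrum(spec)

    def test_band_ratio_inclusive_bounds(self):
        w = np.arange(460.0, 601.0)  # 1-nm sampling
        ratio = fretspec.band_ratio(fretspec.EmissionSpectrum(w, np.ones_like(w)))
        assert ratio == pytest.approx(101 / 40)

    def test_band_ratio_zero_acceptor(self):
        w = np.arange(460.0, 601.0)
        inten = np.where(w <= 499, 1.0, 0.0)
        assert fretspec.band_ratio(fretspec.EmissionSpectrum(w, inten)) == 0.0

    def test_band_ratio_monotone_in_planted_efficiency(self):
        # donor/acceptor basis spectra mixed at two planted E values
        w = np.arange(460.0, 601.0)
        donor = np.exp(-0.5 * ((w - 476) / 15.0) ** 2)
        acceptor = np.exp(-0.5 * ((w - 529) / 18.0) ** 2)
        def mix(e):
            return fretspec.EmissionSpectrum(w, (1 - e) * donor + e * acceptor)
        assert fretspec.band_ratio(mix(0.3)) > fretspec.band_ratio(mix(0.1))

    def test_band_ratio_of_sum_bounded_by_parts(self):
        w = np.arange(460.0, 601.0)
        a = fretspec.EmissionSpectrum(w, np.where(w < 500, 2.0, 1.0))
        b = fretspec.EmissionSpectrum(w, np.where(w < 500, 1.0, 3.0))
        rs = fretspec.band_ratio(
            fretspec.EmissionSpectrum(w, a.intensities + b.intensities))
        ra, rb = fretspec.band_ratio(a), fretspec.band_ratio(b)
        assert min(ra, rb) <= rs <= max(ra, rb)


class TestBleedthrough:
    def test_beta_zero_is_identity(self):
        df = make_wells([{"DxDm": 100.0, "DxAm": 60.0}])
        out, beta, _ = fretspec.bleedthrough_correct(df, beta=0.0)
        assert beta == 0.0
        pd.testing.assert_frame_equal(out, df)

    def test_noiseless_estimation_is_exact(self):
        dxdm = np.linspace(50, 500, 10)
        pb = pd.DataFrame({"DxDm": dxdm, "DxAm": 0.3 * dxdm})
        df = make_wells([{"DxDm": 100.0, "DxAm": 60.0}])
        out, beta, intercept = fretspec.bleedthrough_correct(
            df, beta="estimate", photobleached_set=pb)
        assert beta == pytest.approx(0.3, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert out.DxAm.item() == pytest.approx(60.0 - 0.3 * 100.0)

    def test_noisy_recovery_within_001(self, rng):
        dxdm = rng.uniform(100, 1000, size=50)
        dxam = 0.3 * dxdm * (1 + rng.normal(0, 0.02, size=50))
        pb = pd.DataFrame({"DxDm": dxdm, "DxAm": dxam})
        _, beta, _ = fretspec.bleedthrough_correct(
            make_wells([{"DxDm": 1.0, "DxAm": 1.0}]), "estimate", pb)
        assert abs(beta - 0.3) < 0.01

    def test_insufficient_points(self):
        pb = pd.DataFrame({"DxDm": [1.0, 2.0], "DxAm": [0.3, 0.6]})
        with pytest.raises(InsufficientDataError):
            fretspec.bleedthrough_correct(
                make_wells([{"DxDm": 1.0, "DxAm": 1.0}]), "estimate", pb)


class TestSensitivity:
    def test_exact_ols(self):
        df = pd.DataFrame({"normalized_ratio": [1.0, 1.1, 1.2, 1.3],
                           "concentration_M": [0.0, 0.5, 1.0, 1.5]})
        score = fretspec.dose_response_sensitivity(df)
        assert score.slope == pytest.approx(0.2)
        assert score.direction == "compaction"
        assert score.r_squared == pytest.approx(1.0)

    def test_constant_series_direction_none(self):
        df = pd.DataFrame({"normalized_ratio": [1.0] * 4,
                           "concentration_M": [0.0, 0.5, 1.0, 1.5]})
        score = fretspec.dose_response_sensitivity(df)
        assert score.slope == pytest.approx(0.0)
        assert score.direction == "none"

    def test_expansion_direction(self):
        df = pd.DataFrame({"normalized_ratio": [1.3, 1.2, 1.1, 1.0],
                           "concentration_M": [0.0, 0.5, 1.0, 1.5]})
        assert fretspec.dose_response_sensitivity(df).direction == "expansion"

    def test_degenerate_design(self):
        df = pd.DataFrame({"normalized_ratio": [1.0, 1.1],
                           "concentration_M": [1.0, 1.0]})
        with pytest.raises(DegenerateDesignError):
            fretspec.dose_response_sensitivity(df)

    def test_planted_slope_recovery_and_order_invariance(self):
        truth = synth.PlateTruth(slope_per_M=0.5, noise_cv=0.05, n_replicates=9,
                                 concentrations=[0.0, 0.25, 0.5, 0.75, 1.0],
                                 seed=17)
        df = fretspec.fret_ratio_normalize(synth.gen_plate_dataset(truth), "control")
        score = fretspec.dose_response_sensitivity(df)
        assert abs(score.slope - 0.5) < 0.05
        shuffled = df.sample(frac=1.0, random_state=0)
        assert fretspec.dose_response_sensitivity(shuffled).slope == \
            pytest.approx(score.slope)


class TestSmoothTimecourse:
    def test_constant_and_linear_exactness(self):
        t = np.arange(20.0)
        const, lo, hi = fretspec.smooth_timecourse(t, np.full(20, 3.0))
        np.testing.assert_allclose(const, 3.0, atol=1e-10)
        lin, _, _ = fretspec.smooth_timecourse(t, 2.0 * t + 1.0)
        np.testing.assert_allclose(lin, 2.0 * t + 1.0, atol=1e-9)

    def test_noisy_step_tracked_within_2_sigma(self, rng):
        t = np.arange(100.0)
        truth = np.where(t < 50, 1.0, 1.4)
        noise_sd = 0.05
        y = truth + rng.normal(0, noise_sd, size=t.size)
        sm, _, _ = fretspec.smooth_timecourse(t, y, span=0.12)
        interior = slice(5, 95)
        ok = np.abs(sm[interior] - truth[interior]) < 2 * noise_sd
        assert ok.mean() >= 0.90

    def test_agrees_with_reference_lowess_on_smooth_data(self, rng):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        t = np.linspace(0, 10, 80)
        y = np.sin(t) + rng.normal(0, 0.02, size=t.size)
        ours, _, _ = fretspec.smooth_timecourse(t, y, span=0.3)
        ref = lowess(y, t, frac=0.3, it=0, return_sorted=False)
        assert np.max(np.abs(ours - ref)) < 0.05

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            fretspec.smooth_timecourse([0, 1, 2], [1, 2, 3])
        with pytest.raises(SpanError):
            fretspec.smooth_timecourse(np.arange(10.0), np.arange(10.0), span=0.2)
        with pytest.raises(InvalidParameterError):
            fretspec.smooth_timecourse(np.arange(10.0), np.arange(10.0), span=1.5)
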