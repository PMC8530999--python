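"""Variability-map extraction: FD, scrubbing, filtering, SD/ALFF/MSSD,
z-scoring, masks, and the composed per-participant pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import boldpls as bp
from boldpls.variability import (
    AnalysisMask,
    BoldRun,
    ExclusionVerdict,
    VariabilityConfig,
    alff,
    bandpass_filter,
    build_analysis_mask,
    extract_variability,
    framewise_displacement,
    min_duration_ok,
    mssd,
    nuisance_regress,
    scrub_mask,
    variability_sd,
    zscore_map,
)


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero(self):
        fd = framewise_displacement(np.ones((20, 6)))
        np.testing.assert_allclose(fd, 0.0)

    def test_single_translation_step(self):
        m = np.zeros((10, 6))
        m[5:, 0] = 0.6
        fd = framewise_displacement(m)
        expected = np.zeros(10)
        expected[5] = 0.6
        np.testing.assert_allclose(fd, expected)

    def test_rotation_converted_to_arc_length_on_50mm_sphere(self):
        m = np.zeros((4, 6))
        m[2:, 4] = 0.01  # rad
        fd = framewise_displacement(m)
        assert fd[2] == pytest.approx(0.5)  # 50 mm * 0.01 rad

    def test_literal_reading_sums_parameters_without_differencing(self):
        m = np.full((5, 6), 0.1)
        fd = framewise_displacement(m, literal=True)
        np.testing.assert_allclose(fd, 0.3 + 50 * 0.3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            framewise_displacement(np.zeros((1, 6)))


def _brute_force_scrub(fd, threshold=0.5, n_before=1, n_after=2):
    T = len(fd)
    keep = [True] * T
    for s in range(T):
        if fd[s] > threshold:
            for t in range(max(0, s - n_before), min(T, s + n_after + 1)):
                keep[t] = False
    return np.array(keep)


class TestScrubbing:
    def test_all_below_threshold_keeps_everything(self):
        assert scrub_mask(np.full(20, 0.3)).all()

    def test_single_excursion_window(self):
        fd = np.zeros(10)
        fd[5] = 0.6
        keep = scrub_mask(fd)
        assert set(np.flatnonzero(~keep)) == {4, 5, 6, 7}

    def test_boundary_clip_at_start(self):
        fd = np.zeros(10)
        fd[0] = 0.9
        assert set(np.flatnonzero(~scrub_mask(fd))) == {0, 1, 2}

    def test_threshold_is_strictly_greater(self):
        assert scrub_mask(np.full(5, 0.5)).all()

    @given(st.lists(st.sampled_from([0.4, 0.6]), min_size=1, max_size=12))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_brute_force_window_expansion(self, fd):
        np.testing.assert_array_equal(scrub_mask(np.array(fd)), _brute_force_scrub(fd))


@pytest.mark.parametrize(
    "kept,tr,expected", [(130, 2.0, True), (119, 2.0, False), (120, 2.0, True)]
)
def test_min_duration_gate(kept, tr, expected):
    keep = np.zeros(200, bool)
    keep[:kept] = True
    assert min_duration_ok(keep, tr) is expected


class TestNuisanceRegression:
    def test_self_regression_zeroes_the_voxel(self, rng):
        v = rng.standard_normal((50, 1))
        resid = nuisance_regress(v, v)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        data = rng.standard_normal((200, 7))
        reg = rng.standard_normal((200, 5))
        D = np.column_stack([np.ones(200), reg])
        beta = np.linalg.solve(D.T @ D, D.T @ data)
        np.testing.assert_allclose(nuisance_regress(data, reg), data - D @ beta, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        data = rng.standard_normal((100, 4))
        reg = rng.standard_normal((100, 3))
        resid = nuisance_regress(data, reg)
        D = np.column_stack([np.ones(100), reg])
        np.testing.assert_allclose(D.T @ resid, 0.0, atol=1e-8)

    def test_rank_deficient_design_names_columns(self, rng):
        reg = rng.standard_normal((50, 2))
        reg = np.column_stack([reg, reg[:, 0] + reg[:, 1]])
        with pytest.raises(ValueError, match="column.*2"):
            nuisance_regress(rng.standard_normal((50, 3)), reg)


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(300) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass_filter(x, tr=2.0)
        assert out.std() == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_out_of_band_sinusoid_rejected(self):
        t = np.arange(300) * 2.0
        out = bandpass_filter(np.sin(2 * np.pi * 0.2 * t), tr=2.0)
        assert out.std() < 1e-6

    def test_constant_series_zeroed(self):
        np.testing.assert_allclose(bandpass_filter(np.full(100, 3.7), tr=2.0), 0.0, atol=1e-12)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(np.zeros(100), tr=2.0, f_lo=0.01, f_hi=0.3)


class TestVariabilityMeasures:
    def test_population_sd_hand_value(self):
        data = np.array([1.0, 2, 3, 4, 5])[:, None]
        assert variability_sd(data)[0] == pytest.approx(np.sqrt(2.0))

    def test_constant_voxel_zero(self):
        assert variability_sd(np.ones((10, 1)))[0] == 0.0

    def test_scale_equivariance(self, rng):
        data = rng.standard_normal((40, 3))
        np.testing.assert_allclose(variability_sd(3.5 * data), 3.5 * variability_sd(data))

    def test_parseval_identity_sd_equals_alff(self, rng):
        data = bandpass_filter(rng.standard_normal((200, 10)), tr=2.0)
        np.testing.assert_allclose(variability_sd(data), alff(data, tr=2.0), atol=1e-8)

    def test_alff_matches_brute_force_periodogram(self, rng):
        x = rng.standard_normal(128)
        tr = 2.5
        # direct DFT summation oracle
        T = len(x)
        freqs = np.fft.rfftfreq(T, tr)
        amps = np.abs(np.fft.rfft(x))
        band = (freqs >= 0.01) & (freqs <= 0.10)
        band[0] = False
        w = np.where((freqs == 0) | np.isclose(freqs, 1 / (2 * tr)), 1.0, 2.0)
        oracle = np.sqrt(np.sum(w[band] * amps[band] ** 2)) / T
        assert alff(x, tr)[()] == pytest.approx(oracle, abs=1e-12)

    def test_alff_zero_for_out_of_band_signal(self):
        t = np.arange(300) * 2.0
        assert alff(np.sin(2 * np.pi * 0.2 * t), tr=2.0) < 1e-8

    def test_mssd_hand_value_and_constant(self):
        assert mssd(np.array([0.0, 1, 0, 1])[:, None])[0] == pytest.approx(1.0)
        assert mssd(np.ones((5, 1)))[0] == 0.0

    def test_mssd_respects_scrub_gaps(self):
        data = np.arange(6, dtype=float)[:, None]
        keep = np.array([True, True, False, True, True, True])
        # consecutive kept pairs: (0,1), (3,4), (4,5) -> diffs all 1
        assert mssd(data, keep)[0] == pytest.approx(1.0)

    def test_mssd_rank_correlates_with_sd(self, rng):
        data = bandpass_filter(rng.standard_normal((300, 100)) * rng.uniform(0.5, 3, 100), tr=2.0)
        from scipy.stats import spearmanr

        rho = spearmanr(mssd(data), variability_sd(data)).statistic
        assert rho > 0.8


class TestZScoreAndMask:
    def test_hand_zscore(self):
        mask = AnalysisMask(include=np.array([True, True, True]))
        out = zscore_map(np.array([1.0, 2, 3]), mask).values
        np.testing.assert_allclose(out, [-1.22474487, 0, 1.22474487], atol=1e-8)

    def test_idempotence_and_out_of_mask_nan(self):
        mask = AnalysisMask(include=np.array([True, True, True, False]))
        first = zscore_map(np.array([1.0, 5, 9, 99]), mask).values
        again = zscore_map(first, mask).values
        np.testing.assert_allclose(first[:3], again[:3], atol=1e-12)
        assert np.isnan(first[3])

    def test_single_voxel_mask_rejected(self):
        mask = AnalysisMask(include=np.array([True, False]))
        with pytest.raises(ValueError, match="variance"):
            zscore_map(np.array([2.0, 3.0]), mask)

    def test_gm_threshold_is_inclusive(self):
        m = build_analysis_mask(np.array([0.4, 0.5, 0.9]))
        np.testing.assert_array_equal(m.include, [False, True, True])

    def test_exclusion_overrides_gm(self):
        m = build_analysis_mask(np.array([0.4, 0.9, 0.9]), np.array([False, False, True]))
        np.testing.assert_array_equal(m.include, [False, True, False])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            build_analysis_mask(np.array([0.1, 0.2]), np.array([False, False]))


class TestExtractVariability:
    def test_clean_run_yields_zscored_map(self):
        target = np.linspace(0.5, 2.0, 30)
        run = bp.generate_bold_run(300, 30, tr=2.0, target_sd=target, seed=0)
        mask = AnalysisMask(include=np.ones(30, bool))
        vmap, scrub = extract_variability(run, None, mask)
        assert vmap.zscored
        assert vmap.values.mean() == pytest.approx(0.0, abs=1e-9)
        assert vmap.values.std() == pytest.approx(1.0, abs=1e-9)
        assert scrub.retained_seconds == 600.0

    def test_heavy_motion_run_excluded_with_retained_seconds(self):
        # spikes every 4th frame leave < 240 s at TR 2 s
        spikes = set(range(2, 150, 4))
        run = bp.generate_bold_run(150, 10, tr=2.0, target_sd=1.0, spike_frames=spikes, seed=1)
        verdict = extract_variability(run, None, AnalysisMask(include=np.ones(10, bool)))
        assert isinstance(verdict, ExclusionVerdict)
        assert verdict.retained_seconds < 240.0

    def test_recovers_generator_target_sd_ranking(self):
        target = np.linspace(0.5, 3.0, 50)
        run = bp.generate_bold_run(600, 50, tr=2.0, target_sd=target, seed=2)
        mask = AnalysisMask(include=np.ones(50, bool))
        vmap, _ = extract_variability(run, None, mask)
        from scipy.stats import spearmanr

        assert spearmanr(vmap.values, target).statistic > 0.9

    def test_filter_then_scrub_differs_from_scrub_then_filter(self):
        """The pipeline filters first, then drops censored frames from the
        SD; censoring before filtering would give different maps."""
        run = bp.generate_bold_run(200, 5, tr=2.0, target_sd=1.0, spike_frames={60}, seed=3)
        fd = framewise_displacement(run.motion)
        keep = scrub_mask(fd)
        filtered = bandpass_filter(run.data, run.tr)
        paper_order = variability_sd(filtered, keep)
        other_order = variability_sd(bandpass_filter(run.data[keep], run.tr))
        assert not np.allclose(paper_order, other_order)
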