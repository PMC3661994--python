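import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import icfilter as icf
from icfilter.criteria import (
    BandConfig,
    FilterThresholds,
    Spectrum,
    band_power_ks,
    correlation_pvalue,
    kolmogorov_pvalue,
    motion_glm_score,
    normalize_timecourse,
    power_spectrum,
    score_components,
)
from icfilter.errors import DegenerateComponentError, InputError
from icfilter.io import ARTIFACT, RSN_CANDIDATE, ICTimecourseSet, MotionParams


def kolmogorov_series(lam, terms=200):
    """Independent evaluation of 2 * sum (-1)^(j-1) exp(-2 j^2 lam^2)."""
    j = np.arange(1, terms + 1)
    return float(2.0 * np.sum((-1.0) ** (j - 1) * np.exp(-2.0 * j**2 * lam**2)))


class TestNormalize:
    def test_affine_map_preserves_order(self):
        z = normalize_timecourse(np.arange(1.0, 11.0))
        assert abs(z.mean()) < 1e-12
        assert z.std() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(z) > 0)

    def test_idempotent(self, rng):
        z = normalize_timecourse(rng.standard_normal(100))
        np.testing.assert_allclose(normalize_timecourse(z), z, atol=1e-12)

    def test_constant_is_degenerate(self):
        with pytest.raises(DegenerateComponentError):
            normalize_timecourse(np.full(20, 5.0))

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            normalize_timecourse(np.arange(5.0))


class TestMotionGLM:
    def _motion(self, rng, T=270):
        return MotionParams("s", rng.standard_normal((T, 6)))

    def test_motion_column_gives_perfect_fit(self, rng):
        motion = self._motion(rng)
        fit = motion_glm_score(motion.values[:, 0], motion)
        assert fit.r_moco == pytest.approx(1.0, abs=1e-10)
        assert fit.p_moco < 1e-50  # below any threshold in the scan range

    def test_residualized_timecourse_is_null(self, rng):
        motion = self._motion(rng)
        T = motion.n_timepoints
        design = np.column_stack([np.ones(T), motion.values])
        x = rng.standard_normal(T)
        x = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        fit = motion_glm_score(x, motion)
        assert fit.r_moco == pytest.approx(0.0, abs=1e-8)
        assert fit.p_moco == pytest.approx(1.0, abs=1e-8)

    def test_constant_columns_dropped_with_warning(self, rng):
        values = rng.standard_normal((64, 6))
        values[:, 2] = 1.5
        motion = MotionParams("s", values)
        with pytest.warns(UserWarning, match="constant motion column"):
            fit = motion_glm_score(rng.standard_normal(64), motion)
        assert fit.coefficients[3] == 0.0  # beta of the dropped column

    @pytest.mark.parametrize("T", [64, 270])
    def test_pvalue_matches_circular_shift_oracle(self, T):
        # exact permutation null: Pearson r over every nontrivial circular shift
        rng = np.random.default_rng(97 + T)
        x = rng.standard_normal(T)
        y = rng.standard_normal(T)
        xc = (x - x.mean()) / x.std()
        yc = (y - y.mean()) / y.std()
        r_obs = abs(float(np.corrcoef(x, y)[0, 1]))
        rs = np.array([np.dot(np.roll(xc, s), yc) / T for s in range(1, T)])
        p_perm = float(np.mean(np.abs(rs) >= r_obs))
        p_t = correlation_pvalue(r_obs, T)
        se = np.sqrt(max(p_t * (1 - p_t), 1e-12) / (T - 1))
        assert abs(p_perm - p_t) <= 3 * se

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            motion_glm_score(rng.standard_normal(100), self._motion(rng, T=64))


class TestPowerSpectrum:
    def test_pure_sinusoid_concentrates_in_one_bin(self):
        T, tr = 200, 1.0  # bin grid k/200; 0.03 Hz = bin k=6
        t = np.arange(T)
        tc = normalize_timecourse(np.sin(2 * np.pi * 0.03 * t))
        spec = power_spectrum(tc, tr)
        k = np.argmax(spec.power)
        assert spec.freqs[k] == pytest.approx(0.03)
        assert spec.power[k] / spec.total_power > 1 - 1e-10

    def test_parseval_on_white_noise(self, rng):
        tc = normalize_timecourse(rng.standard_normal(270))
        spec = power_spectrum(tc, 1.98)
        assert spec.total_power == pytest.approx(270 * tc.var(), rel=1e-8)

    def test_band_bin_count_matches_enumeration(self):
        # brute-force enumeration of the grid k/(T*TR) inside (0.009, 0.08)
        T, tr = 270, 1.98
        expected = sum(
            1 for k in range(1, T // 2 + 1) if 0.009 < k / (T * tr) < 0.08
        )
        spec = power_spectrum(normalize_timecourse(np.random.default_rng(0).standard_normal(T)), tr)
        assert spec.freqs[0] == pytest.approx(1 / (T * tr))
        assert int(BandConfig().in_band(spec.freqs).sum()) == expected

    def test_odd_length_has_no_nyquist_bin(self, rng):
        spec = power_spectrum(normalize_timecourse(rng.standard_normal(271)), 2.0)
        assert spec.n_bins == 135
        assert spec.total_power == pytest.approx(271 * 1.0, rel=1e-8)

    def test_welch_estimator_available(self, rng):
        spec = power_spectrum(normalize_timecourse(rng.standard_normal(270)), 1.98,
                              estimator="welch")
        assert spec.n_bins >= 4 and np.all(spec.freqs > 0)


class TestBandPowerKS:
    def _spectrum(self, power):
        freqs = 0.004 * np.arange(1, len(power) + 1)  # grid up to 0.004*n Hz
        return Spectrum(freqs=freqs, power=np.asarray(power, float))

    def test_all_power_in_band_is_null(self):
        power = np.zeros(40)
        power[2:19] = 1.0  # 0.012..0.076 Hz, strictly inside the band
        res = band_power_ks(self._spectrum(power), BandConfig())
        assert res.ks_D == 0.0
        assert res.p_pow == 1.0

    def test_all_power_outside_band_is_degenerate(self):
        power = np.zeros(40)
        power[25:] = 1.0  # >= 0.104 Hz
        res = band_power_ks(self._spectrum(power), BandConfig())
        assert res.ks_D == 1.0 and res.p_pow == 0.0 and res.band_power_zero

    def test_half_in_half_below_matches_series_oracle(self):
        power = np.zeros(40)
        power[0] = 1.0  # 0.004 Hz, below f_lo
        power[10] = 1.0  # 0.044 Hz, inside
        res = band_power_ks(self._spectrum(power), BandConfig())
        assert res.ks_D == pytest.approx(0.5)
        n_eff = 40 / 2
        lam = (np.sqrt(n_eff) + 0.12 + 0.11 / np.sqrt(n_eff)) * 0.5
        assert res.p_pow == pytest.approx(kolmogorov_series(lam), rel=1e-10)

    def test_pvalue_monotone_in_D(self):
        n_eff = 64.0
        ds = np.linspace(0.0, 1.0, 51)
        ps = [kolmogorov_pvalue(d, n_eff) for d in ds]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_too_few_bins_rejected(self):
        with pytest.raises(InputError):
            band_power_ks(self._spectrum([1.0, 1.0, 1.0]), BandConfig())


class TestScoreComponents:
    def test_motion_component_flagged_as_motion(self, one_subject, reference_thresholds):
        motion = one_subject.motion
        tc = motion.values @ np.array([0.3, 0.2, 0.1, 1.0, 0.8, 0.5])
        tcs = ICTimecourseSet("s", tc[:, None], tr_seconds=1.98)
        table = score_components(tcs, motion, BandConfig(), reference_thresholds)
        assert table.loc[0, "label"] == ARTIFACT
        assert "MOTION" in table.loc[0, "reason"]

    def test_band_limited_component_is_candidate(self, one_subject, reference_thresholds, band):
        cfg = icf.CohortConfig(seed=5)
        tc = icf.simulate_component("RSN", one_subject.motion, cfg, seed=5)
        tcs = ICTimecourseSet("s", tc[:, None], tr_seconds=1.98)
        table = score_components(tcs, one_subject.motion, band, reference_thresholds)
        assert table.loc[0, "label"] == RSN_CANDIDATE
        assert table.loc[0, "reason"] == ""

    def test_zero_variance_component_degenerate(self, one_subject, reference_thresholds, band):
        tc = np.column_stack([np.full(270, 3.0), one_subject.timecourses.timecourses[:, 0]])
        tcs = ICTimecourseSet("s", tc, tr_seconds=1.98)
        table = score_components(tcs, one_subject.motion, band, reference_thresholds)
        assert table.loc[0, "label"] == ARTIFACT
        assert table.loc[0, "reason"] == "DEGENERATE"
        assert np.isnan(table.loc[0, "r_moco"])

    def test_sign_flip_leaves_scores_unchanged(self, one_subject, reference_thresholds, band):
        tcs = one_subject.timecourses
        flipped = ICTimecourseSet(tcs.subject_id, -tcs.timecourses, tcs.tr_seconds)
        a = score_components(tcs, one_subject.motion, band, reference_thresholds)
        b = score_components(flipped, one_subject.motion, band, reference_thresholds)
        for col in ("r_moco", "p_moco", "ks_D", "p_pow"):
            np.testing.assert_allclose(a[col], b[col], atol=1e-10)
        assert (a["label"] == b["label"]).all()

    @given(a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-10, 10))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_affine_rescaling_invariance(self, a, b):
        rng = np.random.default_rng(3)
        motion = MotionParams("s", rng.standard_normal((64, 6)))
        tc = rng.standard_normal(64) + 0.5 * motion.values[:, 0]
        base = ICTimecourseSet("s", tc[:, None], 2.0)
        scaled = ICTimecourseSet("s", (a * tc + b)[:, None], 2.0)
        thr = FilterThresholds(1e-17, 1e-8)
        ta = score_components(base, motion, BandConfig(), thr)
        tb = score_components(scaled, motion, BandConfig(), thr)
        for col in ("r_moco", "p_moco", "ks_D", "p_pow"):
            np.testing.assert_allclose(ta[col], tb[col], atol=1e-9)

    def test_band_above_nyquist_rejected(self, one_subject, reference_thresholds):
        with pytest.raises(InputError, match="Nyquist"):
            score_components(one_subject.timecourses, one_subject.motion,
                             BandConfig(f_lo=0.009, f_hi=0.4), reference_thresholds)
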