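"""Auditory-performance score, sigma mapping, correlations, linear model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cimodel as cm
from cimodel.cohort import PUBLISHED_COHORT


class TestAuditoryPerformance:
    def test_zero_record(self):
        rec = cm.AnamnesisRecord(0, 0, "none", 0.0, 0.0)
        assert cm.auditory_performance(rec) == 0.0

    def test_hand_evaluated_cases(self):
        rec = cm.AnamnesisRecord(10, 5, "both_sides", 0.0, 0.0)
        assert cm.auditory_performance(rec) == pytest.approx(-4.55, abs=1e-9)
        rec = cm.AnamnesisRecord(0, 10, "none", 0.0, 0.0)
        assert cm.auditory_performance(rec) == pytest.approx(-8.3, abs=1e-9)

    def test_unknown_hearing_aid_category(self):
        with pytest.raises(ValueError, match="hearing_aid_use"):
            cm.AnamnesisRecord(1, 1, "three", 0.0, 0.0)


class TestSigmaMapping:
    def test_published_trt_cells(self):
        sigma = cm.map_sigma(PUBLISHED_COHORT["trt"])
        by_id = dict(zip(PUBLISHED_COHORT["id"], sigma))
        assert cm.round_half_up(by_id["08"]) == 0.205
        assert by_id["12"] == pytest.approx(0.150, abs=1e-12)  # best performer
        assert by_id["32"] == pytest.approx(0.250, abs=1e-12)  # poorest

    def test_published_ap_cells(self):
        sigma = cm.map_sigma(PUBLISHED_COHORT["ap"])
        by_id = dict(zip(PUBLISHED_COHORT["id"], sigma))
        assert cm.round_half_up(by_id["08"]) == 0.216
        assert cm.round_half_up(by_id["30"]) == 0.150

    def test_combination_published_cells(self):
        st_ = cm.map_sigma(PUBLISHED_COHORT["trt"])
        sa = cm.map_sigma(PUBLISHED_COHORT["ap"])
        combined = cm.combine_sigmas(st_, sa)
        by_id = dict(zip(PUBLISHED_COHORT["id"], combined))
        assert cm.round_half_up(by_id["08"]) == 0.211
        assert cm.round_half_up(by_id["12"]) == 0.180

    def test_idempotent_combination(self):
        assert cm.combine_sigmas(0.2, 0.2) == 0.2

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            cm.map_sigma([1.0, 1.0, 1.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100),
            min_size=3,
            max_size=30,
            unique=True,
        )
    )
    def test_affine_identity(self, metrics):
        """Mapping the cohort mean equals the mean of mapped sigmas."""
        sigma = cm.map_sigma(metrics)
        mapping = cm.SigmaMapping()
        m = np.asarray(metrics)
        at_mean = mapping.sigma_max - (m.mean() - m.min()) / (m.max() - m.min()) * 0.1
        assert sigma.mean() == pytest.approx(at_mean, abs=1e-12)
        assert sigma.min() == pytest.approx(mapping.sigma_min, abs=1e-12)
        assert sigma.max() == pytest.approx(mapping.sigma_max, abs=1e-12)


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.2105, 0.211), (0.2104999, 0.210), (0.1835, 0.184), (0.15, 0.150)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert cm.round_half_up(value) == expected


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = cm.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = cm.pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_published_trt_srt_correlation(self):
        r, p = cm.pearson(PUBLISHED_COHORT["trt"], PUBLISHED_COHORT["srt"])
        assert round(r, 2) == -0.72
        assert p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cm.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=30)
    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        r0, _ = cm.pearson(x, y)
        r1, _ = cm.pearson(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestGLM:
    def _cohort(self, n, rng, noise_sd=0.0):
        df = pd.DataFrame(
            {
                "fwhm_mean": rng.uniform(4, 10, n),
                "ap": rng.uniform(-30, 6, n),
                "trt": rng.uniform(30, 63, n),
            }
        )
        df["measured_srt"] = cm.glm_predict(
            cm.PUBLISHED_GLM, df["fwhm_mean"], df["ap"], df["trt"]
        ) + noise_sd * rng.standard_normal(n)
        return df

    def test_noiseless_coefficient_recovery(self):
        model = cm.fit_glm(self._cohort(20, np.random.default_rng(0)))
        assert model.intercept_db == pytest.approx(11.62, abs=1e-9)
        assert model.coef_fwhm_db_per_mm == pytest.approx(-0.0183, abs=1e-9)
        assert model.coef_ap_db_per_pct == pytest.approx(0.0644, abs=1e-9)
        assert model.coef_trt_db_per_pct == pytest.approx(-0.1403, abs=1e-9)
        assert model.r_fitted_measured == pytest.approx(1.0, abs=1e-9)

    def test_null_response_uninformative(self):
        """SRT independent of the predictors: F-test rarely significant,
        fitted-measured correlation small."""
        rng = np.random.default_rng(1)
        pvals, rs = [], []
        for _ in range(30):
            df = self._cohort(200, rng)
            df["measured_srt"] = rng.standard_normal(200)
            model = cm.fit_glm(df)
            pvals.append(model.f_pvalue)
            rs.append(model.r_fitted_measured)
        assert np.mean(np.array(pvals) < 0.05) < 0.25
        assert np.median(np.abs(rs)) < 0.25

    def test_predict_hand_cases(self):
        assert cm.glm_predict(cm.PUBLISHED_GLM, 0, 0, 0) == pytest.approx(11.62)
        # participant 46: FWHM 5.1 mm, AP 2.6%, TRT 49.8%
        assert cm.glm_predict(cm.PUBLISHED_GLM, 5.1, 2.6, 49.8) == pytest.approx(
            11.62 - 0.0183 * 5.1 + 0.0644 * 2.6 - 0.1403 * 49.8, abs=1e-12
        )
        lo = cm.glm_predict(cm.PUBLISHED_GLM, 5.0, 0.0, 50.0)
        hi = cm.glm_predict(cm.PUBLISHED_GLM, 5.0, 0.0, 60.0)
        assert lo - hi == pytest.approx(1.403, abs=1e-9)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            cm.fit_glm(self._cohort(4, np.random.default_rng(2)))

    def test_missing_columns_reported(self):
        with pytest.raises(ValueError, match="fwhm_mean"):
            cm.fit_glm(pd.DataFrame({"ap": [1, 2, 3], "trt": [1, 2, 3]}))
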