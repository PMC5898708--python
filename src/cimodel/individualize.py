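"""Individualization machinery: auditory-performance score, internal-noise
mapping, correlation statistics and the linear SRT prediction model.

Two behavioural/anamnestic measures characterize a CI user outside the
audio pathway:

* the auditory-performance score AP (%), a phenomenological summary of
  the hearing-loss history:
  ``AP = Dur(mHL) * (-0.23 %/y) + Dur(sHL) * ds + B1 + B2``
  where ``ds`` depends on hearing-aid use during the severe-loss phase
  (-0.83 %/y none, -0.64 %/y one side, -0.45 %/y both sides) and B1/B2
  are age-at-implantation and etiology adjustments supplied as numbers;
* the text-reception threshold TRT (%), the tolerated visual sentence
  coverage at 50% word recall — a non-auditory cognitive measure.

Either measure (higher = better) is mapped linearly onto the internal
noise range [0.15, 0.25]: the cohort's best performer receives 0.15, the
poorest 0.25.  The equal-weight combination is the arithmetic mean of
the two unrounded sigma values.

A linear model (ordinary least squares) relates mean spread FWHM, AP and
TRT to the measured SRT.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DELTA_S = {"none": -0.83, "one_side": -0.64, "both_sides": -0.45}


@dataclass(frozen=True)
class AnamnesisRecord:
    dur_mhl_years: float
    dur_shl_years: float
    hearing_aid_use: str
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if self.dur_mhl_years < 0 or self.dur_shl_years < 0:
            raise ValueError("durations must be non-negative")
        if self.hearing_aid_use not in DELTA_S:
            raise ValueError(
                f"unknown hearing_aid_use {self.hearing_aid_use!r}; "
                f"expected one of {sorted(DELTA_S)}"
            )
        if not (np.isfinite(self.b1) and np.isfinite(self.b2)):
            raise ValueError("B1 and B2 must be finite")


def auditory_performance(record: AnamnesisRecord) -> float:
    """Auditory-performance score in % from the anamnesis record."""
    return (
        record.dur_mhl_years * (-0.23)
        + record.dur_shl_years * DELTA_S[record.hearing_aid_use]
        + record.b1
        + record.b2
    )


@dataclass(frozen=True)
class SigmaMapping:
    """Linear map from a higher-is-better metric onto the internal-noise
    range: cohort maximum -> sigma_min, cohort minimum -> sigma_max."""

    sigma_min: float = 0.15
    sigma_max: float = 0.25

    def __post_init__(self) -> None:
        if not self.sigma_max > self.sigma_min:
            raise ValueError("sigma_max must exceed sigma_min")


def map_sigma(
    metrics: Iterable[float], mapping: SigmaMapping = SigmaMapping()
) -> np.ndarray:
    """Map cohort metric values onto per-participant internal-noise sigmas.

    ``sigma_i = sigma_max - (m_i - min m) / (max m - min m)
    * (sigma_max - sigma_min)``; the cohort endpoints map exactly onto
    the range endpoints.
    """
    m = np.asarray(list(metrics), dtype=float)
    if len(m) < 2:
        raise ValueError("need at least 2 metric values")
    span = m.max() - m.min()
    if span <= 0:
        raise ValueError("metric range is degenerate")
    return mapping.sigma_max - (m - m.min()) / span * (
        mapping.sigma_max - mapping.sigma_min
    )


def combine_sigmas(sigma_a, sigma_b):
    """Equal-weight combination: arithmetic mean of the unrounded sigmas."""
    a, b = np.asarray(sigma_a, float), np.asarray(sigma_b, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("sigmas must be finite")
    out = (a + b) / 2.0
    return float(out) if out.ndim == 0 else out


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round half away from zero (the convention of printed tables;
    numpy/banker's rounding would turn 0.2105 into 0.210 instead of 0.211)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of at least 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GLMModel:
    """Linear SRT model: SRT = intercept + c_fwhm * FWHM + c_ap * AP
    + c_trt * TRT, with fit diagnostics."""

    intercept_db: float
    coef_fwhm_db_per_mm: float
    coef_ap_db_per_pct: float
    coef_trt_db_per_pct: float
    f_statistic: float = np.nan
    f_pvalue: float = np.nan
    r_fitted_measured: float = np.nan
    coef_pvalues: dict | None = None

    def predict(self, fwhm_mm, ap_pct, trt_pct):
        return glm_predict(self, fwhm_mm, ap_pct, trt_pct)


#: Published cohort fit of the linear SRT model (dB):
#: SRT = 11.62 - 0.0183 FWHM + 0.0644 AP - 0.1403 TRT
PUBLISHED_GLM = GLMModel(
    intercept_db=11.62,
    coef_fwhm_db_per_mm=-0.0183,
    coef_ap_db_per_pct=0.0644,
    coef_trt_db_per_pct=-0.1403,
)


def glm_predict(model: GLMModel, fwhm_mm, ap_pct, trt_pct):
    """Evaluate the linear SRT model (dB SNR)."""
    out = (
        model.intercept_db
        + model.coef_fwhm_db_per_mm * np.asarray(fwhm_mm, float)
        + model.coef_ap_db_per_pct * np.asarray(ap_pct, float)
        + model.coef_trt_db_per_pct * np.asarray(trt_pct, float)
    )
    return float(out) if out.ndim == 0 else out


def fit_glm(cohort: pd.DataFrame, response: str = "measured_srt") -> GLMModel:
    """Ordinary least squares of measured SRT on (fwhm_mean, ap, trt).

    ``cohort`` must contain columns ``fwhm_mean``, ``ap``, ``trt`` and the
    response column.  Attaches the F-test against the constant model and
    the correlation between fitted and measured values.
    """
    required = ["fwhm_mean", "ap", "trt", response]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    clean = cohort.dropna(subset=required)
    if len(clean) < 5:
        raise ValueError("need at least 5 complete records")
    X = sm.add_constant(clean[["fwhm_mean", "ap", "trt"]].to_numpy(float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(clean[response].to_numpy(float), X).fit()
    r, _ = pearson(res.fittedvalues, clean[response].to_numpy(float))
    return GLMModel(
        intercept_db=float(res.params[0]),
        coef_fwhm_db_per_mm=float(res.params[1]),
        coef_ap_db_per_pct=float(res.params[2]),
        coef_trt_db_per_pct=float(res.params[3]),
        f_statistic=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        r_fitted_measured=r,
        coef_pvalues={
            "intercept": float(res.pvalues[0]),
            "fwhm_mean": float(res.pvalues[1]),
            "ap": float(res.pvalues[2]),
            "trt": float(res.pvalues[3]),
        },
    )
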