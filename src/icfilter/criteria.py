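"""Time-course-based artifact criteria for single-subject ICA components.

Two features of an IC time course decide whether it is an obvious artifact:

* **Criterion I (motion).**  An ordinary least-squares fit of the time
  course on the six rigid-body motion parameters (plus intercept) yields a
  prediction; the significance ``p_moco`` of the Pearson correlation between
  the time course and that prediction is computed from the t statistic
  ``t = r * sqrt((T - 2) / (1 - r^2))`` on ``T - 2`` degrees of freedom
  (two-sided).  Components with ``p_moco`` below a trained threshold are
  flagged as residual-motion artifacts.

* **Criterion II (power).**  The periodogram of the time course is compared
  with its restriction to the resting-state band 0.009 < f < 0.08 Hz, where
  spontaneous BOLD fluctuations of resting-state networks are expected.
  Both spectra are treated as discrete distributions over the frequency
  grid; a Kolmogorov-Smirnov statistic on their cumulative curves with
  effective sample size ``n_bins / 2`` yields ``p_pow``.  Components whose
  ``p_pow`` falls below a trained threshold carry too much out-of-band power
  and are flagged as artifacts.

Either criterion firing marks the component ARTIFACT; otherwise it remains
an RSN candidate.  All scores are invariant under sign flips and affine
rescalings of the time course, as required by the sign/scale ambiguity of
ICA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, special, stats

from .errors import DegenerateComponentError, InputError
from .io import (
    ARTIFACT,
    MIN_TIMEPOINTS,
    RSN_CANDIDATE,
    SCORE_COLUMNS,
    ICTimecourseSet,
    MotionParams,
)

REASON_MOTION = "MOTION"
REASON_POWER = "POWER"
REASON_DEGENERATE = "DEGENERATE"


@dataclass
class BandConfig:
    """Frequency band (Hz) where RSN-like BOLD fluctuations are expected.

    Band edges are open: a bin exactly at ``f_lo`` or ``f_hi`` is outside.
    """

    f_lo: float = 0.009
    f_hi: float = 0.08

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise InputError(f"need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")

    def in_band(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs > self.f_lo) & (freqs < self.f_hi)


@dataclass
class FilterThresholds:
    """Significance thresholds (p_moco_crit, p_pow_crit) of the filter."""

    p_moco_crit: float
    p_pow_crit: float

    def __post_init__(self) -> None:
        for name, v in (("p_moco_crit", self.p_moco_crit), ("p_pow_crit", self.p_pow_crit)):
            if not (0.0 < v < 1.0):
                raise InputError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class GLMFit:
    coefficients: np.ndarray  # intercept + 6 motion betas (dropped columns -> 0)
    prediction: np.ndarray
    r_moco: float
    p_moco: float


@dataclass
class Spectrum:
    """One-sided power spectrum on the grid f_k = k / (T * TR), DC excluded."""

    freqs: np.ndarray
    power: np.ndarray
    total_power: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise InputError("freqs and power must have the same length")
        if np.any(self.freqs <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise InputError("freqs must be positive and strictly increasing")
        if np.any(self.power < 0):
            raise InputError("power must be non-negative")
        if self.total_power is None:
            self.total_power = float(self.power.sum())

    @property
    def n_bins(self) -> int:
        return len(self.freqs)


@dataclass
class BandKSResult:
    ks_D: float
    p_pow: float
    band_power_zero: bool = False


def normalize_timecourse(tc: np.ndarray) -> np.ndarray:
    """Normalize to zero mean and unit variance (population convention).

    Raises :class:`DegenerateComponentError` for a constant input; callers
    scoring whole subjects catch this and flag the component DEGENERATE.
    """
    tc = np.asarray(tc, dtype=float)
    if tc.ndim != 1:
        raise InputError("expected a 1-D time course")
    if tc.size < MIN_TIMEPOINTS:
        raise InputError(f"need at least {MIN_TIMEPOINTS} time points, got {tc.size}")
    sd = tc.std()
    if not np.isfinite(sd) or sd <= 1e-300 or sd < 1e-13 * max(1.0, abs(tc.mean())):
        raise DegenerateComponentError("constant (zero-variance) time course")
    return (tc - tc.mean()) / sd


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided significance of a Pearson correlation on n pairs.

    Uses t = r * sqrt((n - 2) / (1 - r^2)) with n - 2 degrees of freedom.
    """
    r = float(np.clip(r, -1.0, 1.0))
    if n < 3:
        raise InputError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def motion_glm_score(tc: np.ndarray, motion: MotionParams) -> GLMFit:
    """Criterion I: fit the time course on motion regressors, score the fit.

    The design is an intercept plus the six motion traces (constant columns
    are dropped with a warning).  ``r_moco`` is the Pearson correlation of
    the time course with the least-squares prediction — non-negative by
    construction — and ``p_moco`` its two-sided t significance.
    """
    tc = np.asarray(tc, dtype=float)
    T = tc.size
    if motion.n_timepoints != T:
        raise InputError(
            f"time course has {T} points but motion has {motion.n_timepoints}"
        )
    cols = motion.values
    keep = cols.std(axis=0) > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} constant motion column(s) from the design",
            stacklevel=2,
        )
    design = np.column_stack([np.ones(T), cols[:, keep]])
    beta, *_ = np.linalg.lstsq(design, tc, rcond=None)
    prediction = design @ beta
    coefficients = np.zeros(7)
    coefficients[0] = beta[0]
    coefficients[1:][keep] = beta[1:]

    pred_sd = prediction.std()
    if pred_sd <= 1e-12 * max(1.0, tc.std()):
        # prediction is (numerically) constant: time course orthogonal to
        # the motion design; no evidence of motion coupling
        return GLMFit(coefficients, prediction, r_moco=0.0, p_moco=1.0)
    r = float(np.corrcoef(tc, prediction)[0, 1])
    r = float(np.clip(r, 0.0, 1.0))  # >= 0 by construction; clip rounding noise
    return GLMFit(coefficients, prediction, r_moco=r, p_moco=correlation_pvalue(r, T))


def power_spectrum(
    tc: np.ndarray, tr_seconds: float, estimator: str = "periodogram"
) -> Spectrum:
    """Estimate the spectral power of a (normalized) time course.

    The default estimator is the plain periodogram on the grid
    ``f_k = k / (T * TR)`` for ``k = 1 .. floor(T/2)`` (DC excluded, Nyquist
    included for even T), scaled so that the total power equals
    ``T x population variance`` (Parseval).  A Welch estimate is available
    as an alternative; its frequency grid is coarser.
    """
    tc = np.asarray(tc, dtype=float)
    T = tc.size
    if T < MIN_TIMEPOINTS:
        raise InputError(f"need at least {MIN_TIMEPOINTS} time points, got {T}")
    if not tr_seconds > 0:
        raise InputError("tr_seconds must be positive")
    if estimator == "periodogram":
        fft = np.fft.rfft(tc - tc.mean())
        k = np.arange(1, T // 2 + 1)
        freqs = k / (T * tr_seconds)
        power = np.abs(fft[1 : T // 2 + 1]) ** 2 / T
        # fold the redundant negative frequencies into the one-sided bins
        double = np.ones_like(power) * 2.0
        if T % 2 == 0:
            double[-1] = 1.0  # Nyquist bin is its own conjugate
        power = power * double
        return Spectrum(freqs=freqs, power=power)
    if estimator == "welch":
        f, p = signal.welch(tc, fs=1.0 / tr_seconds, nperseg=min(T, 128))
        keep = f > 0
        return Spectrum(freqs=f[keep], power=p[keep])
    raise ValueError(f"unknown estimator {estimator!r}")


def kolmogorov_pvalue(d: float, n_eff: float) -> float:
    """Asymptotic KS p-value with the standard small-sample correction.

    lambda = (sqrt(n_eff) + 0.12 + 0.11 / sqrt(n_eff)) * D, and the p-value
    is the Kolmogorov survival function 2 * sum_j (-1)^(j-1) exp(-2 j^2 lambda^2).
    """
    if d <= 0:
        return 1.0
    s = np.sqrt(n_eff)
    lam = (s + 0.12 + 0.11 / s) * d
    return float(np.clip(special.kolmogorov(lam), 0.0, 1.0))


def band_power_ks(spec: Spectrum, band: BandConfig) -> BandKSResult:
    """Criterion II: KS distance between the spectrum and its band-filtered self.

    Both the original spectrum and the copy with all out-of-band power
    zeroed are normalized to unit total power over the frequency grid; the
    statistic is the maximal absolute difference of their cumulative curves.
    The p-value uses the two-sample asymptotic form with effective size
    ``n_bins / 2`` (equal counts).  A spectrum with no in-band power at all
    is degenerate: D = 1, p = 0.
    """
    if spec.n_bins < 4:
        raise InputError(f"need at least 4 spectral bins, got {spec.n_bins}")
    total = spec.power.sum()
    if total <= 0:
        raise InputError("spectrum has zero total power")
    mask = band.in_band(spec.freqs)
    filtered = np.where(mask, spec.power, 0.0)
    band_total = filtered.sum()
    if band_total <= 0:
        return BandKSResult(ks_D=1.0, p_pow=0.0, band_power_zero=True)
    cdf_orig = np.cumsum(spec.power) / total
    cdf_filt = np.cumsum(filtered) / band_total
    d = float(np.max(np.abs(cdf_orig - cdf_filt)))
    d = min(max(d, 0.0), 1.0)
    return BandKSResult(ks_D=d, p_pow=kolmogorov_pvalue(d, spec.n_bins / 2.0))


def compute_component_scores(
    tcs: ICTimecourseSet,
    motion: MotionParams,
    band: BandConfig | None = None,
    estimator: str = "periodogram",
) -> pd.DataFrame:
    """Score every component of one subject (no thresholding applied).

    Returns a DataFrame with one row per component: r_moco, p_moco, ks_D,
    p_pow and the degeneracy flags.  Zero-variance components get NaN motion
    scores and (ks_D, p_pow) = (1, 0).
    """
    band = band or BandConfig()
    if motion.n_timepoints != tcs.n_timepoints:
        raise InputError(
            f"subject {tcs.subject_id}: {tcs.n_timepoints} time points "
            f"but motion has {motion.n_timepoints}"
        )
    nyquist = 0.5 / tcs.tr_seconds
    if band.f_hi >= nyquist:
        raise InputError(f"f_hi={band.f_hi} Hz is not below Nyquist={nyquist:.4g} Hz")
    rows = []
    for j in range(tcs.n_components):
        tc = tcs.timecourses[:, j]
        try:
            z = normalize_timecourse(tc)
        except DegenerateComponentError:
            rows.append(
                dict(component=j + 1, r_moco=np.nan, p_moco=np.nan,
                     ks_D=1.0, p_pow=0.0, zero_variance=True, band_power_zero=False)
            )
            continue
        fit = motion_glm_score(z, motion)
        spec = power_spectrum(z, tcs.tr_seconds, estimator=estimator)
        ks = band_power_ks(spec, band)
        rows.append(
            dict(component=j + 1, r_moco=fit.r_moco, p_moco=fit.p_moco,
                 ks_D=ks.ks_D, p_pow=ks.p_pow, zero_variance=False,
                 band_power_zero=ks.band_power_zero)
        )
    df = pd.DataFrame(rows)
    df.insert(0, "subject", tcs.subject_id)
    return df


def apply_thresholds(scores: pd.DataFrame, thresholds: FilterThresholds) -> pd.DataFrame:
    """Attach label and reason columns given the two significance thresholds.

    A component is ARTIFACT if p_moco < p_moco_crit (reason MOTION), or
    p_pow < p_pow_crit (reason POWER), or it is degenerate (reason
    DEGENERATE); both criterion reasons are recorded when both fire.
    """
    out = scores.copy()
    labels, reasons = [], []
    for _, row in out.iterrows():
        r = []
        if bool(row.get("zero_variance", False)):
            r.append(REASON_DEGENERATE)
        else:
            if row["p_moco"] < thresholds.p_moco_crit:
                r.append(REASON_MOTION)
            if row["p_pow"] < thresholds.p_pow_crit:
                r.append(REASON_POWER)
            if bool(row.get("band_power_zero", False)):
                r.append(REASON_DEGENERATE)
        labels.append(ARTIFACT if r else RSN_CANDIDATE)
        reasons.append(",".join(r))
    out["label"] = labels
    out["reason"] = reasons
    return out


def score_components(
    tcs: ICTimecourseSet,
    motion: MotionParams,
    band: BandConfig,
    thresholds: FilterThresholds,
    estimator: str = "periodogram",
) -> pd.DataFrame:
    """Full per-subject scoring: criteria I and II plus classification.

    Returns the score table (one row per component) with the fixed column
    order used by :func:`icfilter.io.write_score_table`.
    """
    scored = compute_component_scores(tcs, motion, band, estimator=estimator)
    labelled = apply_thresholds(scored, thresholds)
    return labelled[SCORE_COLUMNS + ["zero_variance", "band_power_zero"]]
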