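"""Agreement statistics between measured and predicted VO2.

For any predictor on any test session this module computes the full battery
used to compare models: residual summaries (MAE, RMSE, Pearson r, R²) in
absolute units and as a percentage of VO2MAX; a Bland-Altman analysis of
the paired differences (bias, 95% limits of agreement, a t-based confidence
interval on the bias, and two significance flags — bias different from
zero, and bias beyond an a-priori meaningful limit of 200 mlO2·min⁻¹,
which is of the order of breath-by-breath measurement noise at high
intensity); and the residual autocorrelation function with white-noise
confidence bands, which exposes predictors that fail to capture
relationships between current VO2 and past inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "ResidualStats",
    "BlandAltman",
    "AcfResult",
    "EvalReport",
    "residual_stats",
    "bland_altman",
    "residual_acf",
    "evaluate_predictor",
]

#: A-priori meaningful maximal acceptable bias, mlO2·min⁻¹.
MEANINGFUL_LIMIT = 200.0


@dataclass(frozen=True)
class ResidualStats:
    mae_abs: float  # mlO2·min⁻¹
    rmse_abs: float
    mae_pct: float  # % of VO2MAX
    rmse_pct: float
    pearson_r: float
    r_squared: float


@dataclass(frozen=True)
class BlandAltman:
    bias_abs: float  # mlO2·min⁻¹, mean of measured − predicted
    loa95_abs: float  # 1.96·SD of the differences
    ci95_halfwidth_abs: float  # t-based half-width of the bias CI
    bias_pct: float  # same three, % of VO2MAX
    loa95_pct: float
    ci95_halfwidth_pct: float
    bias_significant_zero: bool
    bias_exceeds_meaningful: bool


@dataclass(frozen=True)
class AcfResult:
    acf: np.ndarray  # lags 1..max_lag
    band: float  # ±z_{1−α/2}/√n
    frac_outside: float


@dataclass(frozen=True)
class EvalReport:
    """Everything known about one predictor on one test session."""

    residuals: ResidualStats
    bland_altman: BlandAltman
    acf: AcfResult
    n: int

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=enc)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        d["acf"]["acf"] = np.asarray(d["acf"]["acf"])
        return cls(residuals=ResidualStats(**d["residuals"]),
                   bland_altman=BlandAltman(**d["bland_altman"]),
                   acf=AcfResult(**d["acf"]), n=d["n"])


def _to_abs(x: np.ndarray, vo2max: float, vo2r: float) -> np.ndarray:
    """Range-denormalize a [VO2R, VO2MAX]-normalized series to mlO2·min⁻¹."""
    return np.asarray(x, dtype=float) * (vo2max - vo2r) + vo2r


def residual_stats(measured: np.ndarray, predicted: np.ndarray,
                   vo2max: float, vo2r: float, *,
                   normalized: bool = True) -> ResidualStats:
    """Residual summary in both unit systems.

    ``measured``/``predicted`` are normalized over the [VO2R, VO2MAX] range
    by default (set ``normalized=False`` to pass absolute values).  Absolute
    errors come from range-denormalized values; percentage errors divide the
    absolute errors by VO2MAX.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError("length mismatch")
    if m.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(m) == 0:
        raise ValueError("measured series is constant; r undefined")
    if np.ptp(p) == 0:
        raise ValueError("predicted series is constant; r undefined")
    if normalized:
        m = _to_abs(m, vo2max, vo2r)
        p = _to_abs(p, vo2max, vo2r)
    resid = m - p
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    r = float(stats.pearsonr(m, p).statistic)
    return ResidualStats(mae_abs=mae, rmse_abs=rmse,
                         mae_pct=100.0 * mae / vo2max,
                         rmse_pct=100.0 * rmse / vo2max,
                         pearson_r=r, r_squared=r * r)


def bland_altman(measured: np.ndarray, predicted: np.ndarray,
                 vo2max: float, vo2r: float, *, alpha: float = 0.05,
                 meaningful_limit: float = MEANINGFUL_LIMIT,
                 normalized: bool = True) -> BlandAltman:
    """Bland-Altman agreement analysis of measured − predicted differences.

    The bias is flagged significant when zero lies outside the t-based
    ``1−alpha`` confidence interval of the mean difference, and flagged as
    exceeding the meaningful limit when that whole interval lies outside
    ``±meaningful_limit`` (absolute units).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError("length mismatch")
    n = m.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if normalized:
        m = _to_abs(m, vo2max, vo2r)
        p = _to_abs(p, vo2max, vo2r)
    d = m - p
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = 1.96 * sd
    ci = float(stats.t.ppf(1 - alpha / 2, n - 1)) * sd / np.sqrt(n)
    sig_zero = not (bias - ci <= 0.0 <= bias + ci)
    exceeds = (bias - ci > meaningful_limit) or (bias + ci < -meaningful_limit)
    to_pct = 100.0 / vo2max
    return BlandAltman(bias_abs=bias, loa95_abs=loa, ci95_halfwidth_abs=ci,
                       bias_pct=bias * to_pct, loa95_pct=loa * to_pct,
                       ci95_halfwidth_pct=ci * to_pct,
                       bias_significant_zero=bool(sig_zero),
                       bias_exceeds_meaningful=bool(exceeds))


def residual_acf(residuals: np.ndarray, max_lag: int | None = None,
                 alpha: float = 0.05) -> AcfResult:
    """Sample autocorrelation of the residuals with white-noise bands.

    The band is ``±z_{1−α/2}/√n``; ``frac_outside`` is the fraction of lags
    1..max_lag whose autocorrelation falls beyond it.  ``max_lag`` defaults
    to ``min(n // 4, 100)``.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if max_lag is None:
        max_lag = min(n // 4, 100)
    if not (1 <= max_lag < n):
        raise ValueError("need n > max_lag >= 1")
    if np.ptp(r) == 0:
        raise ValueError("constant residuals have no autocorrelation")
    vals = _sm_acf(r, nlags=max_lag, fft=n > 512)[1:]
    band = float(stats.norm.ppf(1 - alpha / 2)) / np.sqrt(n)
    frac = float(np.mean(np.abs(vals) > band))
    return AcfResult(acf=vals, band=band, frac_outside=frac)


def evaluate_predictor(measured: np.ndarray, predicted: np.ndarray,
                       vo2max: float, vo2r: float, *, alpha: float = 0.05,
                       meaningful_limit: float = MEANINGFUL_LIMIT,
                       max_lag: int | None = None,
                       normalized: bool = True) -> EvalReport:
    """Bundle the full statistics battery for one predictor on one session."""
    res = residual_stats(measured, predicted, vo2max, vo2r,
                         normalized=normalized)
    ba = bland_altman(measured, predicted, vo2max, vo2r, alpha=alpha,
                      meaningful_limit=meaningful_limit, normalized=normalized)
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if normalized:
        m = _to_abs(m, vo2max, vo2r)
        p = _to_abs(p, vo2max, vo2r)
    acf_res = residual_acf(m - p, max_lag=max_lag, alpha=alpha)
    return EvalReport(residuals=res, bland_altman=ba, acf=acf_res,
                      n=int(m.size))
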