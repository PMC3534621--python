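"""SGT-to-concentration calibration.

Under exponential growth from inoculum N0 with doubling time td, the time to
reach the threshold cell density N_thr is

    SGT = td * log2(N_thr / N0) = intercept + slope * log10(N0),

with slope = -td * log2(10). Fitting SGT against log10(CFU/mL) over a
dilution series therefore yields a straight line whose inverse predicts the
live-cell concentration of an unknown sample without plating, and whose
slope encodes the culture's doubling time.

The regression direction is SGT on log10(CFU) — concentration is the known
quantity in a calibration series — and inversion is analytic. One model is
valid for one growth condition only: media that lengthen the lag phase shift
the intercept and would masquerade as lower inocula.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as _stats

from .exceptions import FitError, ModelSanityError, RangeError, UsageError

__all__ = [
    "CalibrationModel",
    "ConcentrationEstimate",
    "fit_calibration",
    "estimate_concentration",
    "doubling_time_from_slope",
]


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Inverse-predicted concentration with a confidence interval (CFU/mL)."""

    cfu_per_ml: float
    lower: float
    upper: float
    confidence: float


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted linear SGT ~ log10(CFU/mL) calibration.

    Results object: carries the estimates, their uncertainties and the fit
    diagnostics, and exposes prediction, inverse prediction, ``summary()``
    and JSON round-tripping.

    Attributes
    ----------
    slope : float
        Hours per log10(CFU/mL); negative for any growing culture.
    intercept : float
        Hours; the nominal SGT of a 1 CFU/mL inoculum.
    r_squared : float
        Coefficient of determination of the fit.
    residual_sd : float
        Root mean squared residual (n-2 denominator), hours.
    slope_se, intercept_se : float
        Standard errors of the coefficients.
    n_points : int
    sgt_range, log10_cfu_range : (float, float)
        Extent of the fitted data; predictions outside it require
        ``allow_extrapolation``.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    slope_se: float
    intercept_se: float
    n_points: int
    sgt_range: tuple[float, float]
    log10_cfu_range: tuple[float, float]
    log_base: int = 10

    # -- prediction ----------------------------------------------------------
    def predict_sgt(self, cfu_per_ml: float) -> float:
        """Forward prediction: expected SGT (hours) of a known concentration."""
        if not cfu_per_ml > 0:
            raise UsageError("cfu_per_ml must be positive")
        return self.intercept + self.slope * math.log10(cfu_per_ml)

    def estimate_concentration(
        self,
        sgt_hours: float,
        allow_extrapolation: bool = False,
        confidence: float = 0.95,
    ) -> ConcentrationEstimate:
        """Inverse prediction: live-cell concentration from an observed SGT.

        Point estimate ``10 ** ((sgt - intercept) / slope)``; the interval
        propagates the calibration's residual sd through the inverse map
        (delta method on the log10 scale, normal quantile).
        """
        if not self.slope < 0:
            raise ModelSanityError(
                f"calibration slope must be negative (got {self.slope:g}); "
                "SGT cannot increase with inoculum"
            )
        if not np.isfinite(sgt_hours):
            raise UsageError("sgt_hours must be a finite, non-censored SGT")
        lo, hi = self.sgt_range
        if not allow_extrapolation and not (lo <= sgt_hours <= hi):
            raise RangeError(
                f"SGT {sgt_hours:g} h outside fitted range [{lo:g}, {hi:g}] h; "
                "pass allow_extrapolation=True to extrapolate"
            )
        log10_n = (sgt_hours - self.intercept) / self.slope
        sd_log10 = self.residual_sd / abs(self.slope)
        z = _stats.norm.ppf(0.5 + confidence / 2.0)
        return ConcentrationEstimate(
            10.0 ** log10_n,
            10.0 ** (log10_n - z * sd_log10),
            10.0 ** (log10_n + z * sd_log10),
            confidence,
        )

    def doubling_time_hours(self) -> float:
        """Doubling time implied by the slope: td = -slope * log10(2)."""
        if not self.slope < 0:
            raise ModelSanityError(
                f"slope must be negative to imply a doubling time, got {self.slope:g}"
            )
        return -self.slope * math.log10(2.0)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "SGT calibration: SGT[h] ~ log10(CFU/mL)",
            "=" * 46,
            f"n points        {self.n_points:>12d}",
            f"slope           {self.slope:>12.4f}  h/log10  (se {self.slope_se:.4f})",
            f"intercept       {self.intercept:>12.4f}  h        (se {self.intercept_se:.4f})",
            f"R-squared       {self.r_squared:>12.6f}",
            f"residual sd     {self.residual_sd:>12.4f}  h",
            f"doubling time   {self.doubling_time_hours():>12.4f}  h (from slope)"
            if self.slope < 0
            else "doubling time            n/a  (non-negative slope)",
            f"SGT range       [{self.sgt_range[0]:.3f}, {self.sgt_range[1]:.3f}] h",
            f"log10 CFU range [{self.log10_cfu_range[0]:.3f}, {self.log10_cfu_range[1]:.3f}]",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        doc["sgt_range"] = list(doc["sgt_range"])
        doc["log10_cfu_range"] = list(doc["log10_cfu_range"])
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationModel":
        p = Path(source)
        doc = json.loads(p.read_text() if p.exists() else str(source))
        doc["sgt_range"] = tuple(doc["sgt_range"])
        doc["log10_cfu_range"] = tuple(doc["log10_cfu_range"])
        return cls(**doc)


def fit_calibration(
    points: Iterable[tuple[float, float]] | Sequence
) -> CalibrationModel:
    """Fit the linear calibration from ``(sgt_hours, cfu_per_ml)`` pairs.

    Ordinary least squares of SGT on log10(CFU/mL); requires at least three
    points, positive concentrations, non-censored SGTs and non-degenerate
    spread in log10(CFU).
    """
    pts = [(float(s), float(c)) for s, c in points]
    if len(pts) < 3:
        raise FitError(f"calibration needs >= 3 points, got {len(pts)}")
    sgt = np.array([p[0] for p in pts])
    cfu = np.array([p[1] for p in pts])
    if np.any(cfu <= 0):
        raise FitError("all cfu_per_ml must be positive")
    if not np.all(np.isfinite(sgt)):
        raise FitError("all SGT values must be finite and non-censored")
    x = np.log10(cfu)
    if np.ptp(x) == 0:
        raise FitError("zero variance in log10(cfu_per_ml); cannot fit a slope")

    res = sm.OLS(sgt, sm.add_constant(x)).fit()
    intercept, slope = res.params
    intercept_se, slope_se = res.bse
    residual_sd = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(res.rsquared),
        residual_sd=residual_sd,
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        n_points=len(pts),
        sgt_range=(float(sgt.min()), float(sgt.max())),
        log10_cfu_range=(float(x.min()), float(x.max())),
    )


def estimate_concentration(
    model: CalibrationModel,
    sgt_hours: float,
    allow_extrapolation: bool = False,
    confidence: float = 0.95,
) -> ConcentrationEstimate:
    """Functional form of :meth:`CalibrationModel.estimate_concentration`."""
    return model.estimate_concentration(sgt_hours, allow_extrapolation, confidence)


def doubling_time_from_slope(model: CalibrationModel) -> float:
    """Functional form of :meth:`CalibrationModel.doubling_time_hours`."""
    return model.doubling_time_hours()
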