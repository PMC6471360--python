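"""Power-law calibration of evaporative light-scattering detector response.

ELSD response is a power function of analyte mass.  With an internal
standard (IS) co-injected at fixed concentration, the calibration relates
the area ratio y = A_analyte / A_IS to the concentration ratio
x = C_analyte / C_IS as

    y = a * x**b,    a > 0, b > 0

The model is fitted by ordinary least squares on the log-log scale
(log y = log a + b log x), where the multiplicative detector noise is
approximately homoscedastic; R^2 is reported on that scale.  An optional
nonlinear refinement minimises squared residuals on the original scale
starting from the log-log estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import CalibrationError, ValidationError

__all__ = ["CalibrationCurve", "CalibrationResult", "PowerLawCalibration"]


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted (or externally supplied) power model y = a * x**b."""

    a: float
    b: float
    r_squared: float = float("nan")
    fit_scale: str = "log-log"

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValidationError("power-model coefficients a and b must be positive")

    def predict(self, conc_ratio):
        """Forward model: area ratio expected at a concentration ratio."""
        x = np.asarray(conc_ratio, dtype=float)
        return self.a * x**self.b

    def invert(self, area_ratio):
        """Inverse model: concentration ratio from an area ratio, (y/a)**(1/b).

        Zero maps to zero; negative areas are rejected.
        """
        y = np.asarray(area_ratio, dtype=float)
        if np.any(y < 0):
            raise ValidationError("area ratio must be non-negative")
        return (y / self.a) ** (1.0 / self.b)


@dataclass(frozen=True)
class CalibrationResult(CalibrationCurve):
    """Fit results: coefficients with log-scale standard errors.

    ``bse`` holds the standard errors of (log a, b); ``nobs`` the number of
    calibration points.
    """

    bse_log_a: float = float("nan")
    bse_b: float = float("nan")
    nobs: int = 0

    def summary(self) -> str:
        lines = [
            "ELSD power-law calibration (y = a * x^b)",
            f"  fitted on: {self.fit_scale} scale, n = {self.nobs}",
            f"  a        = {self.a:.6g}  (se(log a) = {self.bse_log_a:.3g})",
            f"  b        = {self.b:.6g}  (se = {self.bse_b:.3g})",
            f"  R^2      = {self.r_squared:.6g}",
        ]
        return "\n".join(lines)


class PowerLawCalibration:
    """Model object for fitting y = a * x**b to a dilution series.

    Parameters
    ----------
    conc_ratio, area_ratio : array-like
        Strictly positive concentration ratios x and area ratios y; at least
        three points are required.
    """

    def __init__(self, conc_ratio, area_ratio):
        x = np.asarray(conc_ratio, dtype=float)
        y = np.asarray(area_ratio, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValidationError("conc_ratio and area_ratio must be equal-length 1-D")
        if x.size < 3:
            raise CalibrationError(f"need >= 3 calibration points, got {x.size}")
        if np.any(x <= 0) or np.any(y <= 0):
            raise CalibrationError(
                "calibration points must be strictly positive (log-log fit)"
            )
        self.conc_ratio = x
        self.area_ratio = y

    @classmethod
    def from_dataframe(cls, df, x: str = "conc_ratio", y: str = "area_ratio"):
        return cls(df[x].to_numpy(), df[y].to_numpy())

    def fit(self, method: str = "log-ols") -> CalibrationResult:
        """Fit the power model.

        ``method="log-ols"`` (default) is closed-form OLS on the log-log
        scale.  ``method="nls"`` refines (a, b) by nonlinear least squares on
        the original scale, seeded from the log-log fit; R^2 is then reported
        on the original scale.
        """
        lx, ly = np.log(self.conc_ratio), np.log(self.area_ratio)
        res = stats.linregress(lx, ly)
        a, b = float(np.exp(res.intercept)), float(res.slope)
        if not b > 0:
            raise CalibrationError(f"fitted exponent b = {b:.4g} is not positive")
        # perfectly collinear points give rvalue nan in degenerate cases
        r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
        if method == "log-ols":
            return CalibrationResult(
                a=a, b=b, r_squared=r2, fit_scale="log-log",
                bse_log_a=float(res.intercept_stderr), bse_b=float(res.stderr),
                nobs=self.conc_ratio.size,
            )
        if method == "nls":
            popt, pcov = optimize.curve_fit(
                lambda x, a_, b_: a_ * x**b_, self.conc_ratio, self.area_ratio,
                p0=[a, b],
            )
            a_n, b_n = map(float, popt)
            if not (a_n > 0 and b_n > 0):
                raise CalibrationError("nonlinear refinement left the a,b > 0 domain")
            resid = self.area_ratio - a_n * self.conc_ratio**b_n
            ss_tot = float(np.sum((self.area_ratio - self.area_ratio.mean()) ** 2))
            r2_lin = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
            se = np.sqrt(np.diag(pcov))
            return CalibrationResult(
                a=a_n, b=b_n, r_squared=r2_lin, fit_scale="linear",
                bse_log_a=float(se[0] / a_n), bse_b=float(se[1]),
                nobs=self.conc_ratio.size,
            )
        raise ValidationError(f"unknown fit method {method!r}")
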