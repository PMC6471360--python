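"""Internal-standard ELSD quantification of residual TAG and lipolysis rates.

Residual triacylglycerol after digestion is quantified from HPLC-ELSD peak
tables taken at 0 min and t min.  With the power calibration
A/A_IS = a (C/C_IS)^b, the TAG mass in a weighed lipolysis product is

    m_TTGS = [(A/A_IS)/a]^(1/b) * C_IS * m_LP / C_S * (150 / m_a)

where m_LP is the weighed lipolysis product (mg), C_S the injected product
concentration (mg/mL), C_IS the internal-standard concentration, m_a the oil
mass actually digested (mg), and 150 mg the normalisation mass.  The
lipolysis rate after t minutes is the fractional TAG loss

    rate(%) = (1 - m_TTGS(t) / m_TTGS(0)) * 100 .

Because both time points share the same calibration, the coefficient ``a``
cancels exactly in the rate — only the exponent ``b`` matters.  The same
machinery applies per TAG species by substituting that species' peak area
and calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationCurve
from .errors import CalibrationError, ValidationError

__all__ = [
    "Peak",
    "PeakTable",
    "fit_power_calibration",
    "invert_calibration",
    "ttgs_mass",
    "total_tag_area",
    "species_area",
    "lipolysis_rate",
    "species_lipolysis_rates",
]

#: Mass (mg) to which residual-TAG amounts are normalised.
NORMALIZE_MG = 150.0


@dataclass(frozen=True)
class Peak:
    """One chromatogram peak: retention time (min), area, optional annotation."""

    retention_min: float
    area: float
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValidationError("peak area must be non-negative")


@dataclass(frozen=True)
class PeakTable:
    """One HPLC-ELSD observation of a sample at a single digestion time point."""

    sample_id: str
    time_point_min: float
    is_area: float                       # internal-standard peak area
    peaks: tuple[Peak, ...]
    m_lp_mg: float                       # weighed lipolysis product
    m_a_mg: float                        # oil mass actually digested
    c_s_mg_per_ml: float = 1.0           # injected product concentration
    c_is_mg_per_ml: float = 0.05         # internal-standard concentration

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if not self.is_area > 0:
            raise ValidationError("internal-standard area must be positive")
        for name in ("m_lp_mg", "m_a_mg", "c_s_mg_per_ml", "c_is_mg_per_ml"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")

    def annotations(self) -> list[str]:
        """Distinct non-Unknown annotations in peak order."""
        seen: list[str] = []
        for p in self.peaks:
            if p.annotation and p.annotation != "Unknown" and p.annotation not in seen:
                seen.append(p.annotation)
        return seen


def fit_power_calibration(points) -> "CalibrationCurve":
    """Fit the power calibration from (conc_ratio, area_ratio) pairs.

    Thin wrapper over :class:`~lipolyzer.calibration.PowerLawCalibration`
    with the default log-log OLS fit.
    """
    from .calibration import PowerLawCalibration

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be a sequence of (conc_ratio, area_ratio)")
    return PowerLawCalibration(pts[:, 0], pts[:, 1]).fit()


def invert_calibration(curve: CalibrationCurve, area_ratio: float) -> float:
    """Concentration ratio [(A/A_IS)/a]^(1/b) for one area ratio."""
    return float(curve.invert(area_ratio))


def total_tag_area(table: PeakTable) -> float:
    """Summed area of all TAG peaks (annotated or not), excluding the IS peak."""
    return float(sum(p.area for p in table.peaks))


def species_area(table: PeakTable, label: str) -> float:
    """Summed area of the peak(s) annotated with ``label`` (0 if absent)."""
    return float(sum(p.area for p in table.peaks if p.annotation == label))


def _select_area(table: PeakTable, selector: str) -> float:
    if selector == "total":
        return total_tag_area(table)
    return species_area(table, selector)


def ttgs_mass(
    obs: PeakTable,
    curve: CalibrationCurve,
    area: float,
    normalize_to: float = NORMALIZE_MG,
) -> float:
    """Residual TAG mass (mg) behind ``area``, normalised to ``normalize_to`` mg oil."""
    if area < 0:
        raise ValidationError("area must be non-negative")
    conc_ratio = float(curve.invert(area / obs.is_area))
    mass = conc_ratio * obs.c_is_mg_per_ml * obs.m_lp_mg / obs.c_s_mg_per_ml
    return mass * normalize_to / obs.m_a_mg


def lipolysis_rate(
    obs0: PeakTable,
    obst: PeakTable,
    curve: CalibrationCurve,
    selector: str = "total",
    normalize_to: float = NORMALIZE_MG,
) -> float:
    """Lipolysis rate (%) between time 0 and time t for one area selector.

    ``selector`` is ``"total"`` (sum of all TAG peaks) or a species
    annotation.  Values outside [0, 100] are physically impossible and are
    reported as-is with a warning — they signal detector noise or a
    normalisation problem, and clipping would hide that.
    """
    if obs0.time_point_min != 0:
        raise ValidationError("obs0 must be the 0-min observation")
    if obs0.sample_id.split("@")[0] != obst.sample_id.split("@")[0]:
        warnings.warn(
            f"comparing different samples: {obs0.sample_id!r} vs {obst.sample_id!r}",
            stacklevel=2,
        )
    m0 = ttgs_mass(obs0, curve, _select_area(obs0, selector), normalize_to)
    if m0 == 0:
        raise ValidationError(f"no TAG mass at time 0 for selector {selector!r}")
    mt = ttgs_mass(obst, curve, _select_area(obst, selector), normalize_to)
    rate = (1.0 - mt / m0) * 100.0
    if not 0.0 <= rate <= 100.0:
        warnings.warn(
            f"lipolysis rate {rate:.2f}% outside [0, 100] for {selector!r}; "
            "likely noise or inconsistent normalisation",
            stacklevel=2,
        )
    return rate


def species_lipolysis_rates(
    obs0: PeakTable,
    obst: PeakTable,
    curves: dict[str, CalibrationCurve],
) -> dict[str, float]:
    """Per-species lipolysis rates (%) using each species' own calibration.

    Species annotated only at time t (absent at time 0) are skipped with a
    warning; a species annotated at time 0 without a calibration curve is an
    error.
    """
    labels0 = obs0.annotations()
    if not labels0:
        raise ValidationError("0-min peak table carries no species annotations")
    for label in obst.annotations():
        if label not in labels0:
            warnings.warn(
                f"species {label!r} present at t but absent at 0 min; skipped",
                stacklevel=2,
            )
    out: dict[str, float] = {}
    for label in labels0:
        if label not in curves:
            raise CalibrationError(f"no calibration curve for species {label!r}")
        out[label] = lipolysis_rate(obs0, obst, curves[label], selector=label)
    return out
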