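"""Emulsion droplet-size and physical-stability metrics.

Two quantities characterise an emulsified oil in digestion fluid:

* the Sauter (surface-weighted) mean diameter of the droplet population,
  d32 = sum(n_i d_i^3) / sum(n_i d_i^2);
* destabilisation rates from multiple light scattering: the slope (%/h) of
  the zone-averaged backscattering change dBS(t) in the creaming zone (top
  3 mm of the sample) and the clarification zone (bottom 5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ParticleSizeDistribution",
    "BackscatterScan",
    "sauter_mean_diameter",
    "backscatter_rate",
    "CREAMING_ZONE_MM",
    "CLARIFICATION_ZONE_MM",
]

CREAMING_ZONE_MM = 3.0        # measured down from the liquid level
CLARIFICATION_ZONE_MM = 5.0   # measured up from the cell bottom


@dataclass(frozen=True)
class ParticleSizeDistribution:
    """Binned droplet sizes: diameters (um, strictly increasing) and counts."""

    diameters_um: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_um, dtype=float)
        n = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "diameters_um", d)
        object.__setattr__(self, "counts", n)
        if d.ndim != 1 or d.shape != n.shape or d.size == 0:
            raise ValidationError("diameters and counts must be equal-length 1-D arrays")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValidationError("diameters must be positive and strictly increasing")
        if np.any(n < 0):
            raise ValidationError("counts must be non-negative")
        if not n.sum() > 0:
            raise ValidationError("at least one bin must have a positive count")


@dataclass(frozen=True)
class BackscatterScan:
    """A Turbiscan-style dBS(%) grid over measurement time and sample height."""

    times_min: np.ndarray
    heights_mm: np.ndarray
    dbs_percent: np.ndarray      # shape (n_times, n_heights)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        h = np.asarray(self.heights_mm, dtype=float)
        m = np.asarray(self.dbs_percent, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "heights_mm", h)
        object.__setattr__(self, "dbs_percent", m)
        if t.ndim != 1 or h.ndim != 1:
            raise ValidationError("time and height axes must be 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if m.shape != (t.size, h.size):
            raise ValidationError(
                f"dbs matrix shape {m.shape} does not match (n_times={t.size}, "
                f"n_heights={h.size})"
            )


def sauter_mean_diameter(psd: ParticleSizeDistribution) -> float:
    """Surface-weighted mean diameter d32 = sum(n d^3) / sum(n d^2), in um."""
    d, n = psd.diameters_um, psd.counts
    return float(np.sum(n * d**3) / np.sum(n * d**2))


def backscatter_rate(scan: BackscatterScan, zone: str = "creaming") -> float:
    """Destabilisation rate (%/h): OLS slope of zone-mean dBS versus time.

    ``zone="creaming"`` averages the top 3 mm (from the liquid level, taken
    as the maximum scanned height); ``zone="clarification"`` averages the
    bottom 5 mm.  The slope is fitted over all time points, which is far less
    noise-sensitive than an endpoint difference.
    """
    if scan.times_min.size < 2:
        raise ValidationError("need at least 2 time points for a rate")
    h = scan.heights_mm
    if zone == "creaming":
        mask = h >= h.max() - CREAMING_ZONE_MM
    elif zone == "clarification":
        mask = h <= h.min() + CLARIFICATION_ZONE_MM
    else:
        raise ValidationError(f"unknown zone {zone!r}; use 'creaming' or 'clarification'")
    if not mask.any():
        raise ValidationError(f"{zone} zone lies outside the scanned heights")
    zone_mean = scan.dbs_percent[:, mask].mean(axis=1)
    res = stats.linregress(scan.times_min / 60.0, zone_mean)
    return float(res.slope)
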