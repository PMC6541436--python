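"""Quantification of the cell-surface reporter population.

The experimental chain: surface-bound probe recovered from two cell lines
is quantified against serial dilutions of purified probe (densitometry),
giving the reference:test surface ratio ``r``; protease protection gives
the surface-localized fraction ``f_ref`` of the well-folded reference
reporter; since total expression of the two reporters is matched, the
surface fraction of the test (misfolded) reporter follows as
``f_s = f_ref / r``.

The densitometry response is modeled as log-log linear within the standard
range; calibration is interpolation-only, and an unknown outside the range
of standard intensities raises :class:`ExtrapolationError` naming the
bracketing standards rather than silently extrapolating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

__all__ = [
    "CalibrationError",
    "ExtrapolationError",
    "DilutionSeries",
    "DilutionCalibration",
    "SurfaceQuantResult",
    "fit_dilution_standard",
    "surface_ratio",
    "trypsin_surface_fraction",
    "deduce_surface_fraction",
    "format_percent",
]


class CalibrationError(ValueError):
    """Standards unusable for calibration (too few, or non-monotone)."""


class ExtrapolationError(ValueError):
    """Unknown intensity outside the calibrated standard range."""


@dataclass(frozen=True)
class DilutionSeries:
    """Serial-dilution standards plus unknown band intensities.

    ``standards`` are (amount_pg, intensity) pairs; ``unknowns`` are
    (label, intensity) pairs.  At least three standards with strictly
    positive, distinct amounts and positive intensities are required.
    """

    standards: tuple[tuple[float, float], ...]
    unknowns: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        std = tuple((float(a), float(i)) for a, i in self.standards)
        if len(std) < 3:
            raise ValueError("need at least 3 dilution standards")
        amounts = [a for a, _ in std]
        if any(a <= 0 for a in amounts):
            raise ValueError("standard amounts must be strictly positive")
        if len(set(amounts)) != len(amounts):
            raise ValueError("standard amounts must be distinct")
        if any(i <= 0 for _, i in std):
            raise ValueError("standard intensities must be positive")
        object.__setattr__(self, "standards", std)
        object.__setattr__(self, "unknowns", tuple((str(l), float(i)) for l, i in self.unknowns))


@dataclass(frozen=True)
class DilutionCalibration:
    """Fitted log-log linear densitometry response.

    ``log(intensity) = slope * log(amount) + intercept``; :meth:`amount`
    inverts the fit, valid only within the intensity range spanned by the
    standards.
    """

    slope: float
    intercept: float
    intensity_range: tuple[float, float]
    standards: tuple[tuple[float, float], ...]

    def amount(self, intensity: float) -> float:
        """Map a band intensity to an amount (pg) by inverting the fit."""
        if intensity <= 0:
            raise ValueError("intensity must be positive")
        lo, hi = self.intensity_range
        if not (lo <= intensity <= hi):
            below = max((s for s in self.standards if s[1] <= intensity),
                        key=lambda s: s[1], default=None)
            above = min((s for s in self.standards if s[1] >= intensity),
                        key=lambda s: s[1], default=None)
            raise ExtrapolationError(
                f"intensity {intensity:g} outside standard range [{lo:g}, {hi:g}]; "
                f"bracketing standards: below={below}, above={above}"
            )
        return float(np.exp((np.log(intensity) - self.intercept) / self.slope))


def fit_dilution_standard(series: DilutionSeries) -> DilutionCalibration:
    """Least-squares log-log line through the dilution standards.

    Standards must be monotone in intensity once sorted by amount,
    otherwise the response is not invertible and a
    :class:`CalibrationError` is raised.
    """
    std = sorted(series.standards)
    intensities = np.array([i for _, i in std])
    diffs = np.diff(intensities)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise CalibrationError("standard intensities are not monotone in amount")
    log_a = np.log([a for a, _ in std])
    log_i = np.log(intensities)
    slope, intercept = np.polyfit(log_a, log_i, 1)
    return DilutionCalibration(
        slope=float(slope),
        intercept=float(intercept),
        intensity_range=(float(intensities.min()), float(intensities.max())),
        standards=tuple(std),
    )


def surface_ratio(amount_ref: float, amount_test: float) -> float:
    """Reference:test ratio of surface-recovered probe amounts."""
    if amount_ref <= 0 or amount_test <= 0:
        raise ValueError("amounts must be strictly positive")
    return amount_ref / amount_test


def trypsin_surface_fraction(i_total: float, i_protected: float) -> float:
    """Surface-localized fraction from a protease-protection band pair.

    The protease-resistant (intracellular) band carries the protected
    fraction, so f = (I_total - I_protected) / I_total.  Protected bands
    exceeding the total by up to 5% (densitometry noise) are clipped to
    f = 0 with a warning; larger excess is an error.
    """
    if i_total <= 0:
        raise ValueError("I_total must be positive")
    if i_protected < 0:
        raise ValueError("I_protected must be >= 0")
    if i_protected > i_total:
        if i_protected <= 1.05 * i_total:
            warnings.warn(
                "protected band exceeds total by <= 5%; clipping surface fraction to 0",
                stacklevel=2,
            )
            return 0.0
        raise ValueError("I_protected exceeds I_total by more than 5%")
    return (i_total - i_protected) / i_total


def deduce_surface_fraction(f_ref: float, r: float) -> float:
    """Surface fraction of the test reporter: f_s = f_ref / r."""
    if not 0 <= f_ref <= 1:
        raise ValueError("f_ref must be in [0, 1]")
    if r < 1:
        raise ValueError(
            "surface ratio r must be >= 1 (reference is the larger population); "
            "swap reference and test"
        )
    return f_ref / r


def format_percent(x: float) -> str:
    """One-decimal percent with half-up rounding (0.0435 -> '4.4%').

    The value is first snapped to 6 decimals so that binary float
    representation (0.0435 * 100 = 4.3499999...) does not defeat the
    half-up rule.
    """
    snapped = Decimal(f"{x * 100:.6f}")
    return f"{snapped.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


@dataclass(frozen=True)
class SurfaceQuantResult:
    """Outcome of the surface-population quantification chain."""

    r: float
    f_ref: float
    f_s: float

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if not 0 <= self.f_ref <= 1:
            raise ValueError("f_ref must be in [0, 1]")
        if not 0 <= self.f_s <= 1:
            raise ValueError("f_s must be in [0, 1]")

    @classmethod
    def from_measurements(cls, amount_ref: float, amount_test: float,
                          i_total: float, i_protected: float) -> "SurfaceQuantResult":
        r = surface_ratio(amount_ref, amount_test)
        f_ref = trypsin_surface_fraction(i_total, i_protected)
        return cls(r=r, f_ref=f_ref, f_s=deduce_surface_fraction(f_ref, r))

    def to_dict(self) -> dict:
        return {
            "surface_ratio": self.r,
            "f_ref": self.f_ref,
            "f_s": self.f_s,
            "f_ref_percent": format_percent(self.f_ref),
            "f_s_percent": format_percent(self.f_s),
        }
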