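"""Mass-balance inference of reporter flux through the cell surface.

An irreversibly binding extracellular probe converts transient surface
visits into a cumulative, quantifiable signal.  Uptake into test cells is
normalized to a fluorescence standard — saturating surface labeling of
reference cells, which marks a known fraction ``f_ref`` of an equal total
reporter pool.  If cumulative uptake equals ``U_norm`` standards, the
pre-existing surface pool ``f_s`` accounts for part of it and the rest
must have come from the intracellular pool, giving the accessed fraction

    A = (U_norm * f_ref - f_s) / (1 - f_s)

of the initially intracellular pool, and an overall transit fraction
``A_total = A * (1 - f_s) + f_s``.  Also provided: lag-time estimation of
an uptake time course against its matched background trace, and the
stress:basal slope ratio on a fixed time window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "UptakeTimecourse",
    "FluxResult",
    "normalize_uptake",
    "infer_access_fraction",
    "overall_access_fraction",
    "estimate_lag",
    "slope_ratio",
]

#: Fraction of the dynamic range used as the lag-threshold floor when the
#: background trace is noiseless (see estimate_lag).
LAG_RANGE_FLOOR = 0.05

#: Time window (min) over which uptake slopes are compared.
SLOPE_WINDOW = (30.0, 90.0)


@dataclass(frozen=True)
class UptakeTimecourse:
    """Background-subtracted median probe uptake versus time.

    ``values[i]`` is the median captured-probe fluorescence of the induced
    population minus the median of a matched uninduced population at
    ``times[i]``; ``background`` keeps the raw uninduced median trace for
    lag thresholding.
    """

    times: np.ndarray
    values: np.ndarray
    condition: str = ""
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-d and equally long")
        if t.size and t[0] != 0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.background is not None:
            b = np.asarray(self.background, dtype=float)
            if b.shape != t.shape:
                raise ValueError("background must match times")
            object.__setattr__(self, "background", b)


@dataclass(frozen=True)
class FluxResult:
    """Inferred surface-flux quantities.

    ``U_norm``: uptake in units of the fluorescence standard; ``A``:
    fraction of the intracellular pool that accessed the surface (may
    exceed 1, see ``exceeded_flag``); ``A_total``: overall transit
    fraction; ``lag`` in minutes (None when no uptake was detected);
    ``slope_ratio``: stress/basal uptake-slope ratio, when both traces
    were provided.
    """

    U_norm: float
    A: float
    A_total: float
    lag: float | None = None
    slope_ratio: float | None = None
    exceeded_flag: bool = False

    def to_dict(self) -> dict:
        return {
            "U_norm": float(self.U_norm),
            "A": float(self.A),
            "A_total": float(self.A_total),
            "lag_min": None if self.lag is None else float(self.lag),
            "slope_ratio": None if self.slope_ratio is None else float(self.slope_ratio),
            "exceeded_flag": bool(self.exceeded_flag),
        }


def normalize_uptake(uptake_fluor: float, standard_fluor: float) -> float:
    """Uptake in units of the fluorescence standard."""
    if standard_fluor <= 0:
        raise ValueError("standard fluorescence must be positive")
    if uptake_fluor < 0:
        raise ValueError("uptake fluorescence must be >= 0")
    return uptake_fluor / standard_fluor


def infer_access_fraction(u_norm: float, f_ref: float, f_s: float) -> float:
    """Fraction of the intracellular pool that accessed the surface.

    The standard marks ``f_ref`` of the (equal) total reporter pool, so
    cumulative capture in units of total pool is ``u_norm * f_ref``.  The
    pre-existing surface pool ``f_s`` is captured immediately; the rest
    must come from the intracellular pool ``1 - f_s``.  Values above 1 are
    returned unmodified (standard exceeded and/or new synthesis —
    interpret with :class:`FluxResult`'s ``exceeded_flag``); negative
    values are floored to 0 with a warning.
    """
    if not 0 < f_ref <= 1:
        raise ValueError("f_ref must be in (0, 1]")
    if not 0 <= f_s < 1:
        raise ValueError("f_s must be in [0, 1)")
    if u_norm < 0:
        raise ValueError("U_norm must be >= 0")
    a = (u_norm * f_ref - f_s) / (1.0 - f_s)
    if a < 0:
        warnings.warn("uptake below the pre-existing surface pool; flooring A to 0",
                      stacklevel=2)
        return 0.0
    return a


def overall_access_fraction(a: float, f_s: float) -> float:
    """Overall fraction of molecules that transit the surface.

    Intracellular accessors plus the pre-existing surface pool:
    ``A_total = A * (1 - f_s) + f_s``.  ``A`` above 1 is clipped (with a
    warning) because the output is a proportion by definition.
    """
    if not 0 <= f_s < 1:
        raise ValueError("f_s must be in [0, 1)")
    if a < 0:
        raise ValueError("A must be >= 0")
    if a > 1:
        warnings.warn("A > 1 clipped to 1 for the overall transit fraction",
                      stacklevel=2)
        a = 1.0
    return a * (1.0 - f_s) + f_s


def _background_spread(tc: UptakeTimecourse) -> float:
    """Robust SD of the background median trace (MAD scaled to SD)."""
    if tc.background is None:
        warnings.warn("no matched background trace; lag threshold uses the "
                      "trace value at t = 0 only", stacklevel=3)
        return 0.0
    b = tc.background
    return 1.4826 * float(np.median(np.abs(b - np.median(b))))


def estimate_lag(tc: UptakeTimecourse) -> float | None:
    """Onset time of probe uptake, in minutes.

    The lag is the first time the (background-subtracted) trace exceeds
    its t = 0 value by ``max(3 * spread, 5% of the dynamic range)``, where
    ``spread`` is the MAD-based SD of the matched background median trace.
    The crossing is located by linear interpolation between the bracketing
    samples.  Returns 0.0 when the trace is already above threshold at
    t = 0, and None ("no uptake detected") when it never crosses.
    """
    if tc.times.size < 4:
        raise ValueError("need at least 4 time points to estimate a lag")
    v = tc.values
    v0 = v[0]
    vmax = float(v.max())
    if vmax <= v0:
        return None
    threshold = v0 + max(3.0 * _background_spread(tc), LAG_RANGE_FLOOR * (vmax - v0))
    above = v > threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    t0, t1 = tc.times[i - 1], tc.times[i]
    y0, y1 = v[i - 1], v[i]
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def _window_slope(tc: UptakeTimecourse, window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (tc.times >= lo) & (tc.times <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 samples inside the window [{lo:g}, {hi:g}] min "
            f"(condition {tc.condition!r} has {int(mask.sum())})"
        )
    slope, _ = np.polyfit(tc.times[mask], tc.values[mask], 1)
    return float(slope)


def slope_ratio(tc_stress: UptakeTimecourse, tc_basal: UptakeTimecourse,
                window: tuple[float, float] = SLOPE_WINDOW) -> float:
    """Ratio of OLS uptake slopes (stress / basal) on a closed window."""
    s_stress = _window_slope(tc_stress, window)
    s_basal = _window_slope(tc_basal, window)
    if s_basal <= 0:
        raise ValueError("basal uptake not detected in window")
    return s_stress / s_basal
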