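"""Calibration of the default trafficking rate constants.

Rather than hard-coding invented rate constants, the packaged defaults
are fitted so that the closed-form kinetics reproduce four observed
summary quantities:

1. probe-uptake lag of ~30 min under acute ER stress,
2. ~80% of the reporter degraded by 180 min of stress,
3. basal steady-state surface fraction of ~4.4%,
4. stress:basal uptake slope ratio of ~6 on the 30-90 min window.

The four observations over-constrain the four-state chain: a cascade of
first-order steps has no dead time, so once 80% degradation by 180 min is
imposed, the onset lag of the capture curve cannot exceed ~13 min under
any rate assignment (the exponential ER-exit waiting time starts surface
delivery immediately).  The calibration therefore proceeds in two stages,
both deterministic:

* targets 2-4 are solved *exactly*: the basal surface fraction fixes
  ``k_endo`` given the other rates; ``k_exit`` (stress), ``k_deg`` and
  the stress:basal exit-rate ratio are solved so that degradation at
  180 min and the slope ratio hit their targets;
* the remaining freedom (``k_gp``) is used to push the lag as close to
  30 min as the chain allows; the residual shortfall is recorded in the
  config metadata rather than spread across the other observations.

Note the *slope* ratio is the observed quantity; because the stressed ER
pool depletes appreciably inside the 30-90 min window, reproducing a
6-fold slope ratio requires an exit-rate ratio well above 6 (the fitted
value, ~16, is stored as ``stress_basal_exit_ratio``).

Both uptake curves start from the basal steady-state occupancy, matching
an experiment in which stress (or probe) is applied to cells equilibrated
beforehand.  ``scripts/fit_defaults.py`` runs :func:`fit_default_params`
and freezes the result into ``data/default_params.yaml``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .flux import LAG_RANGE_FLOOR, SLOPE_WINDOW
from .kinetics import (KineticParams, ProbeModel, capture_fraction,
                       occupancy_closed_form)

__all__ = [
    "CalibrationTargets",
    "capture_lag",
    "fit_default_params",
    "evaluate_params",
]

#: (lag_min, degraded_at_180, basal_surface_fraction, slope_ratio)
CalibrationTargets = (30.0, 0.80, 0.044, 6.0)

_SATURATING = ProbeModel(concentration=200.0)
_DURATION = 180.0


def capture_lag(params: KineticParams, duration: float = _DURATION,
                rel_threshold: float = LAG_RANGE_FLOOR) -> float:
    """Lag of the noiseless closed-form capture curve.

    First time the captured fraction exceeds its t = 0 value by
    ``rel_threshold`` of the dynamic range — the noiseless limit of the
    uptake-lag estimator.
    """
    t = np.linspace(0.0, duration, 721)
    c = capture_fraction(params, _SATURATING, t)
    threshold = c[0] + rel_threshold * (c[-1] - c[0])
    above = c > threshold
    if not above.any():
        return float("inf")
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    return float(np.interp(threshold, [c[i - 1], c[i]], [t[i - 1], t[i]]))


def _window_slope(params: KineticParams, window=SLOPE_WINDOW) -> float:
    t = np.arange(window[0], window[1] + 1e-9, 10.0)
    c = capture_fraction(params, _SATURATING, t)
    return float(np.polyfit(t, c, 1)[0])


def _chains(k_exit_s: float, k_gp: float, k_deg: float, exit_ratio: float,
            fs_target: float) -> tuple[KineticParams, KineticParams]:
    """Stress/basal chain pair; k_endo eliminated by the f_s target.

    At basal steady state the surface fraction is
    (1/k_endo) / sum(1/k), so the target fixes
    1/k_endo = fs/(1-fs) * (1/k_exit_basal + 1/k_gp + 1/k_deg).
    """
    k_exit_b = k_exit_s / exit_ratio
    inv_k_endo = fs_target / (1.0 - fs_target) * (1 / k_exit_b + 1 / k_gp + 1 / k_deg)
    basal = KineticParams(k_exit=k_exit_b, k_gp=k_gp, k_endo=1.0 / inv_k_endo,
                          k_deg=k_deg)
    f0 = tuple(basal.steady_state_fractions())
    stress = basal.with_(k_exit=k_exit_s, f0=f0)
    return stress, basal.with_(f0=f0)


def _solve_given_kgp(k_gp: float, targets) -> tuple[KineticParams, KineticParams]:
    """Solve deg(180) and slope-ratio targets exactly for fixed k_gp."""
    _, deg_t, fs_t, ratio_t = targets

    def eqs(x):
        stress, basal = _chains(np.exp(x[0]), k_gp, np.exp(x[1]), np.exp(x[2]), fs_t)
        return [occupancy_closed_form(stress, _DURATION)[4] - deg_t,
                _window_slope(stress) / _window_slope(basal) - ratio_t]

    sol = least_squares(eqs, np.log([0.02, 0.1, 15.0]), xtol=1e-15, ftol=1e-15,
                        gtol=1e-15)
    if np.max(np.abs(sol.fun)) > 1e-8:
        raise RuntimeError(f"calibration did not converge at k_gp={k_gp}")
    return _chains(np.exp(sol.x[0]), k_gp, np.exp(sol.x[1]), np.exp(sol.x[2]), fs_t)


def fit_default_params(targets=CalibrationTargets) -> dict:
    """Fit the default rate constants; returns the config dictionary.

    Deterministic: fixed grid and starting points, no randomness.  The
    returned dict has ``stress``, ``basal`` and ``wt`` blocks plus fit
    metadata, and is what ``data/default_params.yaml`` holds.
    """
    lag_t = targets[0]
    best = None
    for k_gp in np.geomspace(0.01, 0.2, 31):
        try:
            stress, basal = _solve_given_kgp(k_gp, targets)
        except RuntimeError:
            continue
        gap = abs(capture_lag(stress) - lag_t)
        if best is None or gap < best[0]:
            best = (gap, stress, basal)
    if best is None:
        raise RuntimeError("calibration failed on the whole k_gp grid")
    _, stress, basal = best

    def block(p: KineticParams) -> dict:
        return {k: float(getattr(p, k)) for k in ("k_exit", "k_gp", "k_endo", "k_deg")}

    # Folded-reporter chain: ER and Golgi residence 5 min each, lysosomal
    # residence 50 min; k_endo solved so the steady-state PM fraction is
    # the protease-protection value 0.87.
    f_pm = 0.87
    other_residence = 5.0 + 5.0 + 50.0
    k_endo_wt = (1.0 - f_pm) / (f_pm * other_residence)
    wt = KineticParams(k_exit=1 / 5.0, k_gp=1 / 5.0, k_endo=k_endo_wt, k_deg=1 / 50.0)

    fitted = {
        "lag_min": capture_lag(stress),
        "degraded_180min": float(occupancy_closed_form(stress, _DURATION)[4]),
        "basal_surface_fraction": basal.f0[2],
        "slope_ratio_30_90": _window_slope(stress) / _window_slope(basal),
    }
    return {
        "calibration": {
            "targets": {"lag_min": targets[0], "degraded_180min": targets[1],
                        "basal_surface_fraction": targets[2],
                        "slope_ratio_30_90": targets[3]},
            "fitted": {k: float(v) for k, v in fitted.items()},
            "stress_basal_exit_ratio": float(stress.k_exit / basal.k_exit),
            "note": ("lag is the closest the first-order chain can come to the "
                     "30 min target once 80% degradation at 180 min is imposed; "
                     "see docs/methods.md"),
        },
        "stress": block(stress),
        "basal": block(basal),
        "wt": block(wt),
    }


def evaluate_params(config: dict) -> dict:
    """Recompute the four calibration observables from a config dict."""
    stress = KineticParams(**config["stress"])
    basal = KineticParams(**config["basal"])
    f0 = tuple(basal.steady_state_fractions())
    stress, basal = stress.with_(f0=f0), basal.with_(f0=f0)
    return {
        "lag_min": capture_lag(stress),
        "degraded_180min": float(occupancy_closed_form(stress, _DURATION)[4]),
        "basal_surface_fraction": f0[2],
        "slope_ratio_30_90": _window_slope(stress) / _window_slope(basal),
    }
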