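"""Synthetic-assay generators built on the trafficking kinetic model.

Every measurement the analysis pipeline consumes can be generated here
with known ground truth: surface staining and uptake time courses (flow
cytometry), protease-protection band pairs and densitometry dilution
series (immunoblots), and planted-effect TMT ratio tables.  Named
scenarios return parameter bundles emulating the pharmacological and
genetic perturbations of the trafficking route (ER-export block,
endocytosis knockdown, lysosome neutralization, acute ER stress).

Default rate constants are not invented point values: they are the result
of a least-squares calibration of the closed-form kinetics to four
observed quantities (uptake lag ~30 min, ~80% degraded at 180 min under
stress, basal steady-state surface fraction ~4.4%, stress:basal uptake
slope ratio ~6 with the ER-exit rate ratio fixed at 6), frozen in
``data/default_params.yaml`` by ``scripts/fit_defaults.py``.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import yaml

from .flux import UptakeTimecourse
from .io import FlowSample
from .kinetics import (CellPopulation, KineticParams, ProbeModel,
                       capture_fraction, occupancy_closed_form)
from .surface_quant import DilutionSeries
from .tmt import TMTExperiment

import pandas as pd

__all__ = [
    "SCENARIOS",
    "default_params",
    "scenario",
    "simulate_uptake_timecourse",
    "simulate_surface_staining",
    "simulate_trypsin_assay",
    "simulate_dilution_series",
    "simulate_tmt_experiment",
]

SCENARIOS = ("prp_wt", "prpstar_basal", "prpstar_stress", "tmed10_ko",
             "bfa", "ap2_kd", "bafa1")

#: Endocytosis-knockdown scenarios reduce the PM internalization rate by
#: this factor (partial knockdown; complete block would trap the reporter).
AP2_KNOCKDOWN_FACTOR = 0.25


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@functools.cache
def default_params() -> dict:
    """Calibrated default rate constants (see module docstring)."""
    text = resources.files("prpflux").joinpath("data/default_params.yaml").read_text()
    return yaml.safe_load(text)


def _params_from(block: dict, f0) -> KineticParams:
    return KineticParams(k_exit=block["k_exit"], k_gp=block["k_gp"],
                         k_endo=block["k_endo"], k_deg=block["k_deg"],
                         f0=tuple(f0))


def scenario(name: str, probe_concentration: float = 200.0,
             pop: CellPopulation | None = None):
    """Preset (KineticParams, ProbeModel, CellPopulation) bundles.

    ``prpstar_basal``/``prpstar_stress`` start from the basal steady-state
    occupancy; ``tmed10_ko`` (no ER exit, reporter confined to the ER)
    starts all-ER; ``bfa`` blocks ER exit acutely in cells at basal steady
    state; ``ap2_kd`` slows endocytosis and equilibrates at its own steady
    state; ``bafa1`` abolishes lysosomal degradation under stress.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid: {', '.join(SCENARIOS)}")
    cfg = default_params()
    basal = _params_from(cfg["basal"], (1, 0, 0, 0))
    f0_basal = tuple(basal.steady_state_fractions())
    if name == "prp_wt":
        wt = _params_from(cfg["wt"], (1, 0, 0, 0))
        params = wt.with_(f0=tuple(wt.steady_state_fractions()))
    elif name == "prpstar_basal":
        params = basal.with_(f0=f0_basal)
    elif name == "prpstar_stress":
        params = _params_from(cfg["stress"], f0_basal)
    elif name == "tmed10_ko":
        params = _params_from(cfg["stress"], (1, 0, 0, 0)).with_(k_exit=0.0)
    elif name == "bfa":
        params = basal.with_(k_exit=0.0, f0=f0_basal)
    elif name == "ap2_kd":
        slowed = basal.with_(k_endo=basal.k_endo * AP2_KNOCKDOWN_FACTOR)
        params = slowed.with_(f0=tuple(slowed.steady_state_fractions()))
    elif name == "bafa1":
        params = _params_from(cfg["stress"], f0_basal).with_(k_deg=0.0)
    probe = ProbeModel(concentration=probe_concentration)
    return params, probe, pop or CellPopulation()


def simulate_uptake_timecourse(params: KineticParams, probe: ProbeModel,
                               pop: CellPopulation, times, seed,
                               condition: str = "induced") -> UptakeTimecourse:
    """Cumulative probe-uptake flow time course with matched background.

    Per cell, captured-probe fluorescence at time t is (copy number) x
    (closed-form captured fraction by t), under multiplicative measurement
    noise plus autofluorescence background; each time point is an
    independent aliquot of cells.  The returned values are the per-time
    median of the induced population minus the median of a matched
    uninduced population; the raw uninduced median trace is attached as
    the background reference.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    rng = _rng(seed)
    cap = capture_fraction(params, probe, times)
    n, nt = pop.n_cells, times.size
    with np.errstate(over="ignore"):
        copies = rng.lognormal(pop.expr_mu, pop.expr_sigma, size=(n, nt))
    copies = np.where(np.isfinite(copies), copies, 0.0)
    noise = np.clip(rng.normal(1.0, pop.meas_cv, size=(n, nt)), 0.0, None)
    bg = rng.lognormal(pop.background_mu, pop.background_sigma, size=(n, nt))
    signal = copies * cap[None, :] * noise + bg
    bg_only = rng.lognormal(pop.background_mu, pop.background_sigma, size=(n, nt))
    med = np.median(signal, axis=0)
    med_bg = np.median(bg_only, axis=0)
    return UptakeTimecourse(times=times, values=med - med_bg,
                            condition=condition, background=med_bg)


def simulate_surface_staining(params: KineticParams, probe: ProbeModel,
                              pop: CellPopulation, seed,
                              condition: str = "induced", t: float = 0.0,
                              include_uninduced: bool = True) -> FlowSample:
    """On-ice surface staining: a snapshot with no trafficking during stain.

    The occupancy is first evolved to time ``t`` (default 0: stain the
    initial state).  Probe channel = copy number x current PM occupancy x
    probe occupancy + background; total-reporter channel = copy number x
    undegraded fraction + background.  A matched uninduced population
    (condition suffixed ``_uninduced``) is included by default.
    """
    rng = _rng(seed)
    occ = occupancy_closed_form(params, t)
    frames = []
    pops = [(condition, pop)] + ([(f"{condition}_uninduced", pop.uninduced())]
                                 if include_uninduced else [])
    for label, p in pops:
        n = p.n_cells
        with np.errstate(over="ignore"):
            copies = rng.lognormal(p.expr_mu, p.expr_sigma, size=n)
        copies = np.where(np.isfinite(copies), copies, 0.0)
        noise = np.clip(rng.normal(1.0, p.meas_cv, size=(2, n)), 0.0, None)
        bg = rng.lognormal(p.background_mu, p.background_sigma, size=(2, n))
        probe_chan = copies * occ[2] * probe.occupancy * noise[0] + bg[0]
        total_chan = copies * (1.0 - occ[4]) * noise[1] + bg[1]
        frames.append(pd.DataFrame({
            "cell_id": np.arange(n), "condition": label,
            "channel_total": total_chan, "channel_probe": probe_chan,
        }))
    return FlowSample(pd.concat(frames, ignore_index=True))


def simulate_trypsin_assay(surface_fraction: float, noise_cv: float,
                           seed=0) -> tuple[float, float]:
    """Protease-protection band pair (I_total, I_protected).

    The protected (intracellular) band is ``1 - surface_fraction`` of the
    total before independent multiplicative noise on each band.
    """
    if not 0 <= surface_fraction <= 1:
        raise ValueError("surface_fraction must be in [0, 1]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed)
    base = 100.0
    noise = np.clip(rng.normal(1.0, noise_cv, size=2), 1e-6, None)
    return float(base * noise[0]), float(base * (1.0 - surface_fraction) * noise[1])


def simulate_dilution_series(true_amount_pg: float, standards_pg, noise_cv: float,
                             seed=0, gain: float = 100.0, response_slope: float = 1.0,
                             unknown_label: str = "unknown") -> DilutionSeries:
    """Densitometry dilution series under a log-log linear response.

    ``intensity = gain * amount**response_slope`` with multiplicative
    log-normal noise of coefficient ``noise_cv``; the unknown band is
    generated from ``true_amount_pg`` under the same response.
    """
    standards_pg = np.asarray(standards_pg, dtype=float)
    if standards_pg.size < 3:
        raise ValueError("need at least 3 standard amounts")
    if np.any(standards_pg <= 0) or true_amount_pg <= 0:
        raise ValueError("amounts must be strictly positive")
    rng = _rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))

    def response(amount, size):
        return gain * amount ** response_slope * np.exp(rng.normal(0.0, sigma, size))

    std_int = response(standards_pg, standards_pg.size)
    unk_int = float(response(np.array([true_amount_pg]), 1)[0])
    return DilutionSeries(standards=tuple(zip(standards_pg, std_int)),
                          unknowns=((unknown_label, unk_int),))


def simulate_tmt_experiment(n_proteins: int, planted_full, planted_partial,
                            effect_log2: float = 1.0, noise_sd_log2: float = 0.1,
                            n_replicates: int = 3, bait_id: str = "BAIT",
                            seed=0, bait_scale: float = 1.7) -> TMTExperiment:
    """Planted-effect TMT WT/KO ratio table.

    Null proteins have replicate log2 ratios ~ Normal(0, noise_sd);
    ``planted_full`` proteins are shifted by ``effect_log2`` in every
    replicate and ``planted_partial`` in all but one (chosen at random per
    protein).  Every ratio in a replicate additionally carries the channel
    scale ``bait_scale`` — the bait's raw ratio sits at that scale, so
    bait normalization must undo it.  Protein ids are ``P0001``... and
    planted sets may be given as ids or 0-based indices.
    """
    if effect_log2 <= 0:
        raise ValueError("effect_log2 must be > 0")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    ids = [f"P{i + 1:04d}" for i in range(n_proteins)]

    def as_ids(s):
        return {ids[p] if isinstance(p, (int, np.integer)) else str(p) for p in s}

    full, partial = as_ids(planted_full), as_ids(planted_partial)
    if full & partial:
        raise ValueError("planted sets must be disjoint")
    unknown = (full | partial) - set(ids)
    if unknown or len(full | partial) > n_proteins:
        raise ValueError("planted proteins must be among the simulated proteins")

    rng = _rng(seed)
    log2 = rng.normal(0.0, noise_sd_log2, size=(n_proteins, n_replicates))
    for i, pid in enumerate(ids):
        if pid in full:
            log2[i] += effect_log2
        elif pid in partial:
            mask = np.ones(n_replicates, bool)
            mask[rng.integers(n_replicates)] = False
            log2[i, mask] += effect_log2
    # bait reference row: channel scale only, no planted effect or noise
    table = np.vstack([log2, np.zeros((1, n_replicates))])
    ratios = bait_scale * np.exp2(table)
    columns = [f"rep{j + 1}" for j in range(n_replicates)]
    frame = pd.DataFrame(ratios, index=ids + [bait_id], columns=columns)
    abundance = pd.Series(rng.lognormal(np.log(1e6), 1.0, size=n_proteins), index=ids)
    abundance[bait_id] = 10.0 * abundance.max()
    return TMTExperiment(ratios=frame, bait=bait_id, abundance=abundance)
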