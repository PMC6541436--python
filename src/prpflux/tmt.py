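"""Isobaric-tag (TMT) interactome ratio analysis.

Protein-level WT/KO abundance ratios from bait immunoprecipitations are
normalized so the bait's ratio is exactly 1 in every replicate, converted
to log2, and classified by replicate consistency against a strict
threshold (log2 > 0.5, i.e. a ratio of at least ~1.4): *full* calls are
above threshold in every replicate, *partial* calls in all but one.
Cross-time-point comparison pairs the per-protein log2 ratios at two time
points and flags proteins enriched at exactly one of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TMTExperiment",
    "EnrichmentCall",
    "normalize_to_bait",
    "log2_ratios",
    "classify_enrichment",
    "rank_by_abundance",
    "compare_timepoints",
    "combine_timepoints",
    "calls_to_frame",
]

ENRICHMENT_THRESHOLD = 0.5  # log2 WT/KO; ratio >= ~1.4


@dataclass(frozen=True)
class TMTExperiment:
    """Protein x replicate WT/KO ratio table with bait identity.

    ``ratios``: DataFrame indexed by protein id; columns are replicate
    labels, or a (timepoint, replicate) MultiIndex for time-course
    designs.  Ratios are positive where present; NaN marks a protein not
    quantified in that replicate.  ``abundance`` (summed reporter
    intensity per protein) is the basis of abundance ranking;
    ``annotations`` holds optional per-protein tags.
    """

    ratios: pd.DataFrame
    bait: str
    abundance: pd.Series | None = None
    annotations: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.bait not in self.ratios.index:
            raise ValueError(f"bait {self.bait!r} missing from the ratio table")
        vals = self.ratios.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("ratios must be positive where present")

    @property
    def replicates(self) -> list:
        return list(self.ratios.columns)


@dataclass(frozen=True)
class EnrichmentCall:
    """Replicate-consistency classification of one protein."""

    protein: str
    log2: tuple
    n_above: int
    klass: str  # "full" | "partial" | "none"


def normalize_to_bait(exp: TMTExperiment) -> TMTExperiment:
    """Divide every replicate column by the bait's ratio in that replicate.

    After normalization the bait ratio is exactly 1 everywhere; the
    operation is idempotent.  A bait ratio that is missing or non-positive
    in any replicate is an error naming the replicate.
    """
    bait_row = exp.ratios.loc[exp.bait]
    bad = [col for col in exp.ratios.columns
           if not np.isfinite(bait_row[col]) or bait_row[col] <= 0]
    if bad:
        raise ValueError(f"bait ratio missing or non-positive in replicate(s) {bad}")
    return replace(exp, ratios=exp.ratios / bait_row)


def log2_ratios(exp: TMTExperiment | pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2 of the ratio table; missing stays missing.

    Zero or negative entries (possible in externally supplied tables) are
    replaced by NaN with a warning, never silently floored.
    """
    table = exp.ratios if isinstance(exp, TMTExperiment) else exp
    vals = table.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} non-positive ratio(s) set to missing",
                      stacklevel=2)
        vals = np.where(bad, np.nan, vals)
    return pd.DataFrame(np.log2(vals), index=table.index, columns=table.columns)


def classify_enrichment(log2_table: pd.DataFrame,
                        threshold: float = ENRICHMENT_THRESHOLD) -> list[EnrichmentCall]:
    """Replicate-consistency enrichment calls from a log2 ratio table.

    Strict inequality (> threshold).  *full*: quantified in every
    replicate and above threshold in all of them; *partial*: above
    threshold in exactly (replicates - 1) quantified replicates (a protein
    missing in one replicate but above threshold in all others also
    qualifies); otherwise *none*.
    """
    n_rep = log2_table.shape[1]
    if n_rep < 2:
        raise ValueError("need at least 2 replicates")
    vals = log2_table.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        above = (vals > threshold)
    n_above = above.sum(axis=1)
    n_quant = (~np.isnan(vals)).sum(axis=1)
    calls = []
    for i, protein in enumerate(log2_table.index):
        if n_quant[i] == n_rep and n_above[i] == n_rep:
            klass = "full"
        elif n_above[i] == n_rep - 1:
            klass = "partial"
        else:
            klass = "none"
        calls.append(EnrichmentCall(protein=str(protein), log2=tuple(vals[i]),
                                    n_above=int(n_above[i]), klass=klass))
    return calls


def calls_to_frame(calls: list[EnrichmentCall]) -> pd.DataFrame:
    """Tabular view of enrichment calls (one row per protein)."""
    return pd.DataFrame(
        {"protein": [c.protein for c in calls],
         "n_above": [c.n_above for c in calls],
         "class": [c.klass for c in calls]}
    ).set_index("protein")


def rank_by_abundance(exp: TMTExperiment) -> pd.Series:
    """Descending abundance ranks (1 = most abundant; ties lexicographic)."""
    if exp.abundance is None:
        raise ValueError("experiment carries no abundance data")
    order = sorted(exp.abundance.index, key=lambda p: (-exp.abundance[p], str(p)))
    return pd.Series(np.arange(1, len(order) + 1), index=order, name="rank")


def _timepoint_log2(exp: TMTExperiment, t) -> pd.Series:
    if not isinstance(exp.ratios.columns, pd.MultiIndex):
        raise ValueError("experiment has no time-point structure")
    if t not in exp.ratios.columns.get_level_values(0):
        raise ValueError(f"time point {t!r} not present")
    sub = log2_ratios(exp.ratios.xs(t, axis=1, level=0))
    return sub.mean(axis=1, skipna=False)


def compare_timepoints(exp: TMTExperiment, t_x=0, t_y=60,
                       threshold: float = ENRICHMENT_THRESHOLD) -> pd.DataFrame:
    """Paired per-protein log2 ratios at two time points.

    Averages log2 ratios over replicates within each time point (a protein
    must be quantified in every replicate to enter the pair), and flags as
    discordant any protein above threshold at exactly one of the two time
    points.  Columns: ``log2_x``, ``log2_y``, ``discordant``.
    """
    x = _timepoint_log2(exp, t_x)
    y = _timepoint_log2(exp, t_y)
    both = x.notna() & y.notna()
    out = pd.DataFrame({"log2_x": x[both], "log2_y": y[both]})
    out["discordant"] = (out["log2_x"] > threshold) ^ (out["log2_y"] > threshold)
    return out


def combine_timepoints(experiments: dict, bait: str) -> TMTExperiment:
    """Assemble per-time-point experiments into one multi-time-point table.

    ``experiments`` maps time point (min) to a :class:`TMTExperiment`;
    columns of the result are a (timepoint, replicate) MultiIndex.
    Abundances are summed across time points where present.
    """
    frames = {}
    abundance = None
    for t, exp in sorted(experiments.items()):
        frames[t] = exp.ratios
        if exp.abundance is not None:
            abundance = exp.abundance if abundance is None else abundance.add(
                exp.abundance, fill_value=0.0)
    ratios = pd.concat(frames, axis=1)
    return TMTExperiment(ratios=ratios, bait=bait, abundance=abundance)
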