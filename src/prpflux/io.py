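"""File formats: per-cell flow tables, uptake time courses, densitometry
and protease-protection tables, TMT ratio tables (TSV/XLSX), and a minimal
FCS 3.0/3.1 list-mode reader.

All CSV/TSV schemas carry headers and are validated on read; malformed
files raise :class:`ParseError` with file context.  The FCS reader covers
the subset needed to ingest cytometer exports (list mode, float or double
data, 3.0/3.1); FCS *writing* is provided only as a private helper for
generating synthetic round-trip fixtures.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tmt import TMTExperiment

__all__ = [
    "ParseError",
    "FlowSample",
    "write_flow_csv",
    "read_flow_table",
    "read_fcs",
    "write_uptake_csv",
    "read_uptake_csv",
    "read_dilution_csv",
    "read_trypsin_csv",
    "read_tmt_table",
]


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class FlowSample:
    """Per-cell fluorescence records with a condition label.

    ``data`` columns: ``cell_id``, ``condition``, ``channel_total``
    (total-reporter channel) and ``channel_probe`` (surface-probe
    channel).
    """

    data: pd.DataFrame

    REQUIRED = ("cell_id", "condition", "channel_total", "channel_probe")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"FlowSample missing column(s) {missing}")

    def median(self, channel: str = "channel_probe", condition: str | None = None) -> float:
        df = self.data
        if condition is not None:
            df = df[df["condition"] == condition]
        return float(df[channel].median())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    def filter_viable(self, min_total: float = 0.0) -> "FlowSample":
        """Viability-gate stub: drop cells below a total-channel floor."""
        return FlowSample(self.data[self.data["channel_total"] >= min_total]
                          .reset_index(drop=True))


def write_flow_csv(sample: FlowSample, path) -> None:
    sample.data.to_csv(path, index=False, columns=list(FlowSample.REQUIRED))


def read_flow_table(path) -> FlowSample:
    """Read a per-cell flow CSV (cell_id, condition, channel_total, channel_probe)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in FlowSample.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return FlowSample(df[list(FlowSample.REQUIRED)].copy())


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 (list mode, float data) — minimal reader
# ---------------------------------------------------------------------------

def _read_fcs_text(raw: bytes, start: int, end: int) -> dict:
    seg = raw[start:end + 1]
    if not seg:
        raise ParseError("empty FCS TEXT segment")
    delim = seg[0:1]
    parts = seg[1:].split(delim)
    kv = {}
    for k, v in zip(parts[::2], parts[1::2]):
        key = k.decode("ascii", "replace").strip().upper()
        if key:
            kv[key] = v.decode("ascii", "replace").strip()
    return kv


def read_fcs(path, channel_map: dict[str, str]) -> FlowSample:
    """Read an FCS 3.0/3.1 file into a :class:`FlowSample`.

    ``channel_map`` maps FCS channel names ($PnN) to the two FlowSample
    channels, e.g. ``{"GFP-A": "channel_total", "APC-A": "channel_probe"}``.
    Only list-mode files with float (``$DATATYPE F``) or double (``D``)
    data are supported.
    """
    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise ParseError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as exc:
        raise ParseError(f"{path}: malformed FCS header offsets") from exc
    kv = _read_fcs_text(raw, text_start, text_end)

    def need(key: str) -> str:
        if key not in kv:
            raise ParseError(f"{path}: missing required FCS keyword {key}")
        return kv[key]

    if need("$MODE") != "L":
        raise ParseError(f"{path}: only list-mode ($MODE L) FCS is supported")
    dtype_code = need("$DATATYPE")
    if dtype_code not in ("F", "D"):
        raise ParseError(f"{path}: only $DATATYPE F/D supported, got {dtype_code}")
    n_par = int(need("$PAR"))
    n_tot = int(need("$TOT"))
    byteord = need("$BYTEORD")
    endian = "<" if byteord.startswith("1") else ">"
    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]

    data_start = int(kv.get("$BEGINDATA") or raw[26:34])
    data_end = int(kv.get("$ENDDATA") or raw[34:42])
    width = 4 if dtype_code == "F" else 8
    expected = n_par * n_tot * width
    blob = raw[data_start:data_start + expected]
    if len(blob) != expected or data_end < data_start:
        raise ParseError(f"{path}: DATA segment truncated "
                         f"(expected {expected} bytes)")
    arr = np.frombuffer(blob, dtype=f"{endian}f{width}").reshape(n_tot, n_par)

    unknown = [c for c in channel_map if c not in names]
    if unknown:
        raise ParseError(f"{path}: channel(s) {unknown} not in file; "
                         f"available: {names}")
    targets = set(channel_map.values())
    if targets != {"channel_total", "channel_probe"}:
        raise ParseError("channel_map must map onto channel_total and channel_probe")
    df = pd.DataFrame({"cell_id": np.arange(n_tot), "condition": kv.get("$SRC", "fcs")})
    for src, dst in channel_map.items():
        df[dst] = arr[:, names.index(src)].astype(float)
    return FlowSample(df[list(FlowSample.REQUIRED)])


def _write_fcs(path, channels: dict[str, np.ndarray], source: str = "synthetic") -> None:
    """Write a minimal FCS 3.0 file (synthetic fixtures / round-trip tests only)."""
    names = list(channels)
    arr = np.column_stack([np.asarray(channels[n], dtype="<f4") for n in names])
    n_tot, n_par = arr.shape
    data = arr.astype("<f4").tobytes()
    kv = {"$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
          "$PAR": str(n_par), "$TOT": str(n_tot), "$SRC": source,
          "$NEXTDATA": "0"}
    for i, name in enumerate(names, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}R"] = "262144"
        kv[f"$P{i}E"] = "0,0"
    header_len = 58
    # Two-pass sizing: keyword values include data offsets which depend on
    # the TEXT length, so write with padded placeholders.
    for _ in range(3):
        text = "/" + "".join(f"{k}/{v}/" for k, v in kv.items())
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + len(data) - 1
        kv["$BEGINDATA"] = str(data_start)
        kv["$ENDDATA"] = str(data_end)
    header = (f"FCS3.0    {text_start:>8}{text_end:>8}{data_start:>8}"
              f"{data_end:>8}{0:>8}{0:>8}").encode("ascii")
    assert len(header) == header_len
    Path(path).write_bytes(header + text.encode("ascii") + data)


# ---------------------------------------------------------------------------
# Uptake time courses and densitometry tables
# ---------------------------------------------------------------------------

def write_uptake_csv(tc, path) -> None:
    """Write an uptake time course (time_min, condition, median_fluor).

    The matched background trace, when present, is written under the
    condition label ``<condition>__background``.
    """
    rows = [{"time_min": t, "condition": tc.condition, "median_fluor": v}
            for t, v in zip(tc.times, tc.values)]
    if tc.background is not None:
        rows += [{"time_min": t, "condition": f"{tc.condition}__background",
                  "median_fluor": b} for t, b in zip(tc.times, tc.background)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_uptake_csv(path, condition: str | None = None):
    """Read an uptake time course written by :func:`write_uptake_csv`."""
    from .flux import UptakeTimecourse

    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"time_min", "condition", "median_fluor"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    conditions = [c for c in df["condition"].unique() if not c.endswith("__background")]
    if condition is None:
        if len(conditions) != 1:
            raise ParseError(f"{path}: specify condition; found {conditions}")
        condition = conditions[0]
    sub = df[df["condition"] == condition].sort_values("time_min")
    if sub.empty:
        raise ParseError(f"{path}: condition {condition!r} not found")
    bg = df[df["condition"] == f"{condition}__background"].sort_values("time_min")
    background = bg["median_fluor"].to_numpy() if len(bg) == len(sub) else None
    return UptakeTimecourse(times=sub["time_min"].to_numpy(),
                            values=sub["median_fluor"].to_numpy(),
                            condition=condition, background=background)


def read_dilution_csv(standards_path, unknowns_path=None):
    """Read dilution standards (amount_pg, intensity) and optional unknowns
    (label, intensity) into a :class:`~prpflux.surface_quant.DilutionSeries`."""
    from .surface_quant import DilutionSeries

    std = pd.read_csv(standards_path)
    if not {"amount_pg", "intensity"}.issubset(std.columns):
        raise ParseError(f"{standards_path}: expected columns amount_pg, intensity")
    unknowns = ()
    if unknowns_path is not None:
        unk = pd.read_csv(unknowns_path)
        if not {"label", "intensity"}.issubset(unk.columns):
            raise ParseError(f"{unknowns_path}: expected columns label, intensity")
        unknowns = tuple(zip(unk["label"], unk["intensity"]))
    return DilutionSeries(standards=tuple(zip(std["amount_pg"], std["intensity"])),
                          unknowns=unknowns)


def read_trypsin_csv(path) -> pd.DataFrame:
    """Read protease-protection band pairs
    (label, intensity_total, intensity_protected)."""
    df = pd.read_csv(path)
    required = {"label", "intensity_total", "intensity_protected"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# TMT tables
# ---------------------------------------------------------------------------

def read_tmt_table(path, bait: str, channel_norm: bool = True) -> TMTExperiment:
    """Read a long-format TMT table into a :class:`TMTExperiment`.

    Columns: ``protein_id``, ``replicate``, optional ``timepoint`` and
    ``annotation``, and either ``ratio`` or the pair ``wt_intensity`` /
    ``ko_intensity``.  TSV/CSV by extension; ``.xlsx`` via openpyxl.
    With intensity columns, per-channel sum scaling (each WT and KO
    channel scaled to the mean channel total within its replicate/time
    point) is applied before forming ratios when ``channel_norm`` is on.
    """
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".txt") else ",")
    if "protein_id" not in df.columns or "replicate" not in df.columns:
        raise ParseError(f"{path}: expected at least protein_id and replicate columns")

    group_keys = ["timepoint", "replicate"] if "timepoint" in df.columns else ["replicate"]
    if "ratio" in df.columns:
        df = df.assign(_ratio=df["ratio"].astype(float))
        abundance = None
    elif {"wt_intensity", "ko_intensity"}.issubset(df.columns):
        df = df.copy()
        abundance = (df.groupby("protein_id")[["wt_intensity", "ko_intensity"]]
                     .sum().sum(axis=1))
        if channel_norm:
            # per-channel loading normalization: each WT and KO channel is
            # sum-scaled within its replicate (/time point) before ratios
            for col in ("wt_intensity", "ko_intensity"):
                totals = df.groupby(group_keys)[col].transform("sum")
                df[col] = df[col] / totals
        df["_ratio"] = df["wt_intensity"] / df["ko_intensity"]
    else:
        raise ParseError(f"{path}: need a ratio column or wt_intensity/ko_intensity")

    ratios = df.pivot_table(index="protein_id", columns=group_keys, values="_ratio",
                            aggfunc="first")
    annotations = None
    if "annotation" in df.columns:
        annotations = df.groupby("protein_id")["annotation"].first()
    return TMTExperiment(ratios=ratios, bait=bait, abundance=abundance,
                         annotations=annotations)
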