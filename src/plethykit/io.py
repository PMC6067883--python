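"""CSV readers and writers for traces, breath tables and results.

All on-disk formats are plain text: a flow trace is a two-column CSV
(time_s, flow_ml_per_s); breath tables and minute summaries use documented
column names.  Vendor binary formats are out of scope; an import shim would
slot in at :func:`read_flow_trace`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trace import BREATH_COLUMNS, FlowTrace, MinuteSummary, minutes_to_frame

_TABLE_RENAME = {  # external column names <-> internal schema
    "onset_s": "onset_s", "ti_s": "ti_s", "te_s": "te_s", "cycle_s": "cycle_s",
    "tv_ml": "tv_ml", "expvol_ml": "expvol_ml", "pif": "pif", "pef": "pef",
}


def write_flow_trace(trace: FlowTrace, path) -> None:
    """Write a trace as ``time_s,flow_ml_per_s`` CSV."""
    df = pd.DataFrame({"time_s": trace.times, "flow_ml_per_s": trace.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def read_flow_trace(path) -> FlowTrace:
    """Read a two-column flow CSV; the sampling rate is inferred and must be
    uniform to within 1 ppm."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty trace")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_s, flow_ml_per_s")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if np.isnan(t).any() or np.isnan(x).any():
        bad = int(np.flatnonzero(np.isnan(t) | np.isnan(x))[0]) + 2
        raise ValueError(f"{path}: non-numeric value at line {bad}")
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if dt[0] <= 0:
        raise ValueError(f"{path}: non-increasing time at line 3")
    rel = np.abs(dt - dt[0]) / dt[0]
    if (rel > 1e-6).any():
        bad = int(np.flatnonzero(rel > 1e-6)[0]) + 3
        raise ValueError(f"{path}: non-uniform sampling at line {bad}")
    return FlowTrace(x, sampling_rate=1.0 / float(np.mean(dt)),
                     start_time=float(t[0]))


def write_breath_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.9g")


def read_breath_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BREATH_COLUMNS if c not in df.columns
               and c not in ("pif_time_s", "pef_time_s")]
    if missing:
        raise ValueError(f"{path}: missing breath-table columns {missing}")
    if "pif_time_s" not in df.columns:
        df["pif_time_s"] = df["onset_s"] + df["ti_s"] / 2.0
    if "pef_time_s" not in df.columns:
        df["pef_time_s"] = df["onset_s"] + df["ti_s"] + df["te_s"] / 2.0
    df["accepted"] = df["accepted"].astype(bool)
    df["reject_reason"] = df["reject_reason"].fillna("").astype(str)
    return df[BREATH_COLUMNS]


def write_minute_summaries(minutes: list[MinuteSummary], path) -> None:
    minutes_to_frame(minutes).to_csv(path, index=False, float_format="%.9g")


def read_minute_summaries(path) -> list[MinuteSummary]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        out.append(MinuteSummary(
            minute_index=int(r.minute), vf_bpm=float(r.vf_bpm),
            tv_ml=float(r.tv_ml), ve_ml_min=float(r.ve_ml_min),
            rinx_pct=float(r.rinx_pct), included=bool(r.included),
            exclusion_reason="" if pd.isna(r.reason) else str(r.reason),
            segment="" if pd.isna(r.segment) else str(r.segment),
        ))
    return out


def write_ground_truth(truth, path) -> None:
    """Ground-truth event CSV (breath_index, event_type, subtype)."""
    rows = [dict(breath_index=i, event_type="sigh", subtype="")
            for i in truth.planted_sigh_indices]
    rows += [dict(breath_index=i, event_type="apnea", subtype=s)
             for i, s in truth.planted_apnea_indices]
    pd.DataFrame(rows, columns=["breath_index", "event_type", "subtype"]) \
        .sort_values("breath_index").to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
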