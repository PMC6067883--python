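"""Sigh and apnea detection and hourly event rates.

Definitions (applied to retained breaths only):

* **Sigh** -- breath whose inspiratory tidal volume is at least 2.5x, and
  inspiratory time at least 1.25x, the mean of the previous five retained
  breaths.  Earlier sighs are excluded from that five-breath baseline so one
  sigh cannot mask the next; the first five retained breaths are never sighs.
* **Apnea** -- breath whose cycle length (onset-to-onset, so post-expiratory
  pauses count) is strictly greater than 0.5 s AND at least twice the mean
  cycle length of the six surrounding retained breaths (three before, three
  after).  Breaths without three retained neighbours on each side are never
  apneas.  An apnea is *post-sigh* if a sigh occurred one or two retained
  breaths earlier, otherwise *spontaneous*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

APNEA_ABS_GATE_S = 0.5
APNEA_SURROUND_FACTOR = 2.0
SIGH_TV_FACTOR = 2.5
SIGH_TI_FACTOR = 1.25
SIGH_BASELINE_BREATHS = 5
POST_SIGH_WINDOW = 2      # sigh at n-1 or n-2 makes apnea n post-sigh


@dataclass
class EventCalls:
    """Detected events with per-hour rates."""

    sigh_indices: list[int] = field(default_factory=list)
    apnea_indices: list[tuple[int, str]] = field(default_factory=list)
    analyzed_duration_h: float = 0.0
    sighs_per_h: float = 0.0
    apneas_spont_per_h: float = 0.0
    apneas_post_sigh_per_h: float = 0.0

    @property
    def apnea_index_list(self) -> list[int]:
        return [i for i, _ in self.apnea_indices]

    @property
    def apnea_subtypes(self) -> dict[int, str]:
        return dict(self.apnea_indices)

    def to_frame(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        rows = [dict(breath_index=i, event_type="sigh", subtype="")
                for i in self.sigh_indices]
        rows += [dict(breath_index=i, event_type="apnea", subtype=sub)
                 for i, sub in self.apnea_indices]
        df = pd.DataFrame(rows, columns=["breath_index", "event_type", "subtype"])
        df = df.sort_values("breath_index", ignore_index=True)
        if table is not None and not df.empty:
            df["onset_s"] = table["onset_s"].to_numpy()[df["breath_index"]]
        return df


def detect_sighs(
    table: pd.DataFrame,
    tv_factor: float = SIGH_TV_FACTOR,
    ti_factor: float = SIGH_TI_FACTOR,
    baseline_breaths: int = SIGH_BASELINE_BREATHS,
) -> list[int]:
    """Return (positional) indices of sigh breaths.

    The baseline is the mean over the previous `baseline_breaths` retained,
    non-sigh breaths; both the tidal-volume and inspiratory-time thresholds
    must be met (conjunction).
    """
    acc_pos = np.flatnonzero(table["accepted"].to_numpy())
    tv = table["tv_ml"].to_numpy()
    ti = table["ti_s"].to_numpy()
    sighs: list[int] = []
    window: list[int] = []          # last `baseline_breaths` non-sigh retained
    for pos in acc_pos:
        if len(window) >= baseline_breaths:
            base = window[-baseline_breaths:]
            tv_base = tv[base].mean()
            ti_base = ti[base].mean()
            if tv[pos] >= tv_factor * tv_base and ti[pos] >= ti_factor * ti_base:
                sighs.append(int(pos))
                continue             # sighs stay out of later baselines
        window.append(int(pos))
    return sighs


def detect_apneas(
    table: pd.DataFrame,
    sighs: list[int] | None = None,
    abs_gate_s: float = APNEA_ABS_GATE_S,
    surround_factor: float = APNEA_SURROUND_FACTOR,
    post_sigh_window: int = POST_SIGH_WINDOW,
) -> list[tuple[int, str]]:
    """Return (index, subtype) apnea calls, subtype spontaneous | post_sigh.

    Surrounding breaths are the three retained breaths on each side,
    regardless of whether they are themselves events.  Without a sigh list
    every apnea is spontaneous.
    """
    sigh_set = set(sighs or [])
    acc_pos = np.flatnonzero(table["accepted"].to_numpy())
    cyc = table["cycle_s"].to_numpy()[acc_pos]
    calls: list[tuple[int, str]] = []
    for k in range(3, len(acc_pos) - 3):
        c = cyc[k]
        if c <= abs_gate_s:
            continue
        surround = np.r_[cyc[k - 3:k], cyc[k + 1:k + 4]].mean()
        if c < surround_factor * surround:
            continue
        pos = int(acc_pos[k])
        recent = {int(acc_pos[k - j]) for j in range(1, post_sigh_window + 1)
                  if k - j >= 0}
        subtype = "post_sigh" if (recent & sigh_set) else "spontaneous"
        calls.append((pos, subtype))
    return calls


def event_rates(
    sighs: list[int],
    apneas: list[tuple[int, str]],
    analyzed_duration_h: float,
) -> EventCalls:
    """Convert event calls to per-hour rates over the analysed duration.

    `analyzed_duration_h` should count only included minutes.
    """
    if analyzed_duration_h <= 0:
        raise ValueError("analyzed duration must be positive")
    n_post = sum(1 for _, s in apneas if s == "post_sigh")
    n_spont = len(apneas) - n_post
    return EventCalls(
        sigh_indices=sorted(sighs),
        apnea_indices=sorted(apneas),
        analyzed_duration_h=analyzed_duration_h,
        sighs_per_h=len(sighs) / analyzed_duration_h,
        apneas_spont_per_h=n_spont / analyzed_duration_h,
        apneas_post_sigh_per_h=n_post / analyzed_duration_h,
    )


def call_events(table: pd.DataFrame, analyzed_duration_h: float) -> EventCalls:
    """Sigh + apnea detection and rate conversion in one step."""
    sighs = detect_sighs(table)
    apneas = detect_apneas(table, sighs)
    return event_rates(sighs, apneas, analyzed_duration_h)
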