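"""Core containers for plethysmography recordings.

A recording is a uniformly sampled respiratory flow signal (inspiration
positive by convention; a flag inverts it on read).  Breaths derived from it
live in a plain :class:`pandas.DataFrame` with a fixed column set
(:data:`BREATH_COLUMNS`), so every downstream stage composes with ordinary
pandas operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column schema of a breath table.  One row per breath, ordered by onset.
#: ``cycle_s`` is onset-to-next-onset (so post-expiratory pauses count toward
#: breath length); ``accepted`` / ``reject_reason`` are set by the quality
#: filters and are flag-only -- no stage ever drops rows.
BREATH_COLUMNS = [
    "onset_s",      # breath onset (inspiratory zero up-crossing), s
    "ti_s",         # inspiratory time, s
    "te_s",         # expiratory time, s
    "cycle_s",      # onset-to-next-onset breath length, s
    "tv_ml",        # inspiratory tidal volume (positive-lobe integral), ml
    "expvol_ml",    # expiratory volume (negative-lobe integral magnitude), ml
    "pif",          # peak inspiratory flow, ml/s
    "pef",          # peak expiratory flow magnitude, ml/s
    "pif_time_s",   # time of peak inspiratory flow, s
    "pef_time_s",   # time of peak expiratory flow, s
    "accepted",     # quality flag (bool)
    "reject_reason",  # "" when accepted, else the first failed rule
]


def empty_breath_table() -> pd.DataFrame:
    """Return an empty breath table with the canonical schema."""
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in BREATH_COLUMNS})
    df["accepted"] = df["accepted"].astype(bool)
    df["reject_reason"] = df["reject_reason"].astype(str)
    return df


def make_breath_table(
    onset_s, ti_s, te_s, cycle_s, tv_ml, expvol_ml, pif, pef,
    pif_time_s=None, pef_time_s=None,
) -> pd.DataFrame:
    """Assemble a breath table from per-breath arrays.

    Peak-flow times default to the half-sine positions (mid-inspiration /
    mid-expiration) when not given, which is what the synthetic renderer
    produces.
    """
    onset_s = np.asarray(onset_s, dtype=float)
    ti_s = np.asarray(ti_s, dtype=float)
    te_s = np.asarray(te_s, dtype=float)
    if pif_time_s is None:
        pif_time_s = onset_s + ti_s / 2.0
    if pef_time_s is None:
        pef_time_s = onset_s + ti_s + te_s / 2.0
    df = pd.DataFrame(
        {
            "onset_s": onset_s,
            "ti_s": ti_s,
            "te_s": te_s,
            "cycle_s": np.asarray(cycle_s, dtype=float),
            "tv_ml": np.asarray(tv_ml, dtype=float),
            "expvol_ml": np.asarray(expvol_ml, dtype=float),
            "pif": np.asarray(pif, dtype=float),
            "pef": np.asarray(pef, dtype=float),
            "pif_time_s": np.asarray(pif_time_s, dtype=float),
            "pef_time_s": np.asarray(pef_time_s, dtype=float),
        }
    )
    df["accepted"] = True
    df["reject_reason"] = ""
    return df


@dataclass
class FlowTrace:
    """Uniformly sampled respiratory flow signal.

    Parameters
    ----------
    samples
        Flow in ml/s, inspiration positive.
    sampling_rate
        Samples per second (Hz), > 0.
    start_time
        Time of the first sample, seconds.
    metadata
        Free-form session metadata (animal id, genotype, treatment,
        age_mode ``"adult"`` or ``"pup"``).
    minute_labels
        Optional protocol segment label per recording minute
        (``"baseline"`` / ``"challenge"`` / ``"recovery"``).
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    metadata: dict = field(default_factory=dict)
    minute_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def n_minutes(self) -> int:
        """Number of (possibly partial) recording minutes."""
        return int(np.ceil(self.duration / 60.0 - 1e-12))


@dataclass
class MinuteSummary:
    """Per-minute ventilation summary.

    ``minute_index`` is 1-based so that "baseline is minutes one to twenty"
    reads literally.  ``ve_ml_min`` always equals ``vf_bpm * tv_ml``.
    """

    minute_index: int
    vf_bpm: float           # breathing frequency, breaths/min
    tv_ml: float            # mean (corrected) tidal volume, ml
    ve_ml_min: float        # minute ventilation = vf * tv, ml/min
    rinx_pct: float = 0.0   # rejection index, percent of minute not covered
    included: bool = True
    exclusion_reason: str = ""
    segment: str = ""       # baseline | challenge | recovery


def minutes_to_frame(minutes: list[MinuteSummary]) -> pd.DataFrame:
    """Tidy DataFrame view of a minute-summary list."""
    return pd.DataFrame(
        {
            "minute": [m.minute_index for m in minutes],
            "segment": [m.segment for m in minutes],
            "vf_bpm": [m.vf_bpm for m in minutes],
            "tv_ml": [m.tv_ml for m in minutes],
            "ve_ml_min": [m.ve_ml_min for m in minutes],
            "rinx_pct": [m.rinx_pct for m in minutes],
            "included": [m.included for m in minutes],
            "reason": [m.exclusion_reason for m in minutes],
        }
    )
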