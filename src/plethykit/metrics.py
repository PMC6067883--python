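"""Adult breath filters, minute-level ventilation summaries, irregularity.

The juvenile (P21) analysis keeps every segmented breath whose inspiratory
time is at least 0.03 s and whose expiratory time is at most 10 s, summarises
ventilation minute by minute (excluding minutes whose breathing frequency
exceeds 500 breaths/min, which in mice indicates sniffing or exploratory
behaviour rather than resting respiration), and scores rhythm stability by
the inter-breath-interval (IBI) irregularity

    irregularity(n) = |L(n+1) - L(n)| / L(n)

over consecutive retained breath lengths L (onset-to-onset cycle length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import MinuteSummary

TI_MIN_ADULT_S = 0.03
TE_MAX_ADULT_S = 10.0
VF_SNIFF_GATE_BPM = 500.0


@dataclass
class CorrectionConstants:
    """Inputs of the barometric tidal-volume correction.

    Defaults: mouse core temperature 37 C, chamber at 24 C room conditions,
    sea-level pressure.  ``chamber_humidity`` is relative humidity as a
    fraction.  With body and chamber at the same temperature and saturated
    equal humidity the correction is the identity.
    """

    body_temp_c: float = 37.0
    chamber_temp_c: float = 24.0
    barometric_pressure_mmhg: float = 760.0
    chamber_humidity: float = 0.5
    calibration_volume_ml: float = 1.0

    def __post_init__(self) -> None:
        if not 15.0 <= self.body_temp_c <= 45.0:
            raise ValueError("body temperature outside physiological range")
        if not -10.0 <= self.chamber_temp_c <= 45.0:
            raise ValueError("chamber temperature outside ambient range")
        if self.barometric_pressure_mmhg <= 0:
            raise ValueError("barometric pressure must be positive")
        if not 0.0 <= self.chamber_humidity <= 1.0:
            raise ValueError("humidity must be a fraction in [0, 1]")


def identity_constants() -> CorrectionConstants:
    """Constants for which the tidal-volume correction is exactly 1."""
    return CorrectionConstants(body_temp_c=37.0, chamber_temp_c=37.0,
                               chamber_humidity=1.0)


def _saturation_pressure_mmhg(temp_c: float) -> float:
    # Arden Buck equation (kPa), converted to mmHg
    kpa = 0.61121 * math.exp((18.678 - temp_c / 234.5) * temp_c / (257.14 + temp_c))
    return kpa * 7.50062


def correction_factor(constants: CorrectionConstants) -> float:
    """Multiplicative barometric correction on tidal volume.

    Drorbaugh-Fenn-style gas-law factor: volumes measured at chamber
    temperature/humidity are rescaled to body conditions (saturated at body
    temperature),

        factor = [T_body (P_B - P_H2O,chamber)] / [T_chamber (P_B - P_sat,body)]

    with temperatures in kelvin.  Equals 1 when body and chamber states
    coincide (same temperature, chamber saturated).
    """
    c = constants
    t_body = c.body_temp_c + 273.15
    t_chamber = c.chamber_temp_c + 273.15
    p_chamber_h2o = c.chamber_humidity * _saturation_pressure_mmhg(c.chamber_temp_c)
    p_body_h2o = _saturation_pressure_mmhg(c.body_temp_c)
    denom = t_chamber * (c.barometric_pressure_mmhg - p_body_h2o)
    if denom <= 0:
        raise ValueError("non-physical constants: body vapour pressure exceeds "
                         "barometric pressure")
    return t_body * (c.barometric_pressure_mmhg - p_chamber_h2o) / denom


def correct_tidal_volume(raw_tv_ml, constants: CorrectionConstants):
    """Apply the barometric correction to raw tidal volume(s), ml."""
    return np.asarray(raw_tv_ml, dtype=float) * correction_factor(constants) \
        if np.ndim(raw_tv_ml) else float(raw_tv_ml) * correction_factor(constants)


def apply_adult_breath_filters(table: pd.DataFrame) -> pd.DataFrame:
    """Flag breaths with T_I < 0.03 s or T_E > 10 s as excluded.

    Strict inequalities: a breath at exactly 0.03 s / 10 s is retained.
    Flag-only and idempotent; rows already rejected by earlier (pup) rules
    keep their reason.
    """
    out = table.copy()
    reason = out["reject_reason"].astype(object).to_numpy(copy=True)
    # re-derive this filter's own flags so the operation is idempotent
    reason[np.isin(reason, ("ti_short_adult", "te_long_adult"))] = ""
    short_ti = (out["ti_s"] < TI_MIN_ADULT_S).to_numpy() & (reason == "")
    reason[short_ti] = "ti_short_adult"
    long_te = (out["te_s"] > TE_MAX_ADULT_S).to_numpy() & (reason == "")
    reason[long_te] = "te_long_adult"
    out["reject_reason"] = reason
    out["accepted"] = reason == ""
    return out


def summarize_minutes(
    table: pd.DataFrame,
    constants: CorrectionConstants | None = None,
    total_duration: float | None = None,
    start_time: float = 0.0,
    segment_labels: list[str] | None = None,
) -> list[MinuteSummary]:
    """Per-minute ventilation summary from a filtered breath table.

    V_f is the accepted-breath count scaled to breaths/min by the minute's
    actual duration (partial trailing minutes are scaled up); T_V is the mean
    corrected tidal volume of those breaths; V_E = V_f x T_V.  Minutes with
    V_f above 500 breaths/min are flagged excluded (sniffing gate); empty
    minutes are flagged ``empty`` with V_f = 0.
    """
    factor = correction_factor(constants) if constants is not None else 1.0
    if total_duration is None:
        if table.empty:
            raise ValueError("cannot infer duration from an empty table")
        total_duration = float(table["onset_s"].iloc[-1]
                               + table["cycle_s"].iloc[-1]) - start_time
    n_minutes = int(np.ceil(total_duration / 60.0 - 1e-9))
    acc = table[table["accepted"]]
    onset = acc["onset_s"].to_numpy() - start_time
    tv = acc["tv_ml"].to_numpy() * factor
    minutes: list[MinuteSummary] = []
    for m in range(1, n_minutes + 1):
        lo, hi = (m - 1) * 60.0, m * 60.0
        span = min(hi, total_duration) - lo
        mask = (onset >= lo) & (onset < hi)
        count = int(mask.sum())
        vf = count * 60.0 / span if span > 0 else 0.0
        tvm = float(tv[mask].mean()) if count else 0.0
        summ = MinuteSummary(
            minute_index=m, vf_bpm=vf, tv_ml=tvm, ve_ml_min=vf * tvm,
            segment=(segment_labels[m - 1] if segment_labels else ""),
        )
        if count == 0:
            summ.included = False
            summ.exclusion_reason = "empty"
        elif vf > VF_SNIFF_GATE_BPM:
            summ.included = False
            summ.exclusion_reason = "vf_gate"
        minutes.append(summ)
    return minutes


@dataclass
class IrregularityResult:
    """IBI irregularity scores for one recording."""

    per_pair_scores: np.ndarray
    mean_score: float
    median_score: float
    n_pairs: int


def ibi_irregularity(table: pd.DataFrame) -> IrregularityResult:
    """Inter-breath-interval irregularity over consecutive retained breaths.

    Score for a pair = |L(n+1) - L(n)| / L(n) with L the cycle length.
    Pairs spanning a rejected breath (non-adjacent row indices after
    filtering) are skipped, not bridged.  Requires at least two consecutive
    retained breaths.
    """
    acc = table[table["accepted"]]
    if len(acc) < 2:
        raise ValueError("need at least two retained breaths")
    idx = acc.index.to_numpy()
    L = acc["cycle_s"].to_numpy()
    adjacent = np.diff(idx) == 1
    if not adjacent.any():
        raise ValueError("no consecutive retained breath pairs")
    scores = np.abs(np.diff(L))[adjacent] / L[:-1][adjacent]
    return IrregularityResult(
        per_pair_scores=scores,
        mean_score=float(scores.mean()),
        median_score=float(np.median(scores)),
        n_pairs=int(scores.size),
    )
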