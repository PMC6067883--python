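"""Flow-waveform segmentation, pup breath-quality rules, RINX, inclusion.

Breath onsets are zero up-crossings of the flow signal, made noise-robust by
requiring each lobe to exceed a hysteresis amplitude; crossing times are
linearly interpolated between samples.  The pup-mode quality rules and the
per-minute rejection index (RINX) implement the neonatal recording
quality-control scheme: a minute enters the analysis only if less than 40%
of it is unaccounted for by accepted breaths, and an animal only if it has
at least three such minutes in both room air and gas challenge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import FlowTrace, MinuteSummary, make_breath_table, empty_breath_table

#: pup acceptance bounds (inclusive on the acceptance side)
TV_MIN_ML = 0.005
TV_MAX_ML = 1.0
TI_MIN_S = 0.02
IMBALANCE_LO = 0.5   # inspiratory volume as a fraction of expiratory volume
IMBALANCE_HI = 1.5
RINX_INCLUSION_PCT = 40.0   # minute included iff RINX strictly below this
MIN_RELIABLE_MINUTES = 3    # per segment (room air AND challenge)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (half-open) indices of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _interp_crossing(x, times, i, rising: bool) -> float:
    """Zero-crossing time between samples i-1 and i (linear)."""
    if i == 0:
        return times[0]
    x0, x1 = x[i - 1], x[i]
    if x1 == x0:
        return times[i]
    return times[i - 1] + (times[i] - times[i - 1]) * (0.0 - x0) / (x1 - x0)


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise scale from the median absolute deviation of the first difference
    (insensitive to the breathing waveform itself)."""
    d = np.diff(x)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def segment_flow_trace(
    trace: FlowTrace,
    min_amplitude: float | None = None,
    invert: bool = False,
) -> pd.DataFrame:
    """Segment a flow trace into a breath table.

    Parameters
    ----------
    trace
        Uniformly sampled flow, inspiration positive (set ``invert`` if the
        recording used the opposite convention).
    min_amplitude
        Hysteresis band: a lobe counts only if its peak magnitude reaches
        this value.  Defaults to 5x the robust noise SD of the trace.

    Returns
    -------
    Breath table (one row per inspiration/expiration pair).  T_I runs from
    the inspiratory zero up-crossing to the down-crossing, T_E from the
    down-crossing to the end of the expiratory lobe, and ``cycle_s`` to the
    next breath onset so post-expiratory pauses count toward breath length.
    """
    x = np.asarray(trace.samples, dtype=float)
    if np.isnan(x).any():
        raise ValueError("trace contains NaN samples")
    if trace.duration < 1.0:
        raise ValueError("trace shorter than 1 s")
    if invert:
        x = -x
    if min_amplitude is None:
        min_amplitude = 5.0 * robust_noise_sd(x)
    h = max(float(min_amplitude), 0.0)

    times = trace.times
    dt = 1.0 / trace.sampling_rate

    # cores: samples decisively inside a lobe; dead zone |x| <= h is ignored,
    # so small noise ripple neither starts nor splits a lobe
    pos_runs = [r for r in _runs(x > h)]
    neg_runs = [r for r in _runs(x < -h)]
    if not pos_runs or not neg_runs:
        warnings.warn("no breaths found (flat or sub-threshold trace)")
        return empty_breath_table()

    # merge cores of the same sign separated only by dead zone
    def _merge(runs, other_starts):
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            prev = merged[-1]
            # an opposite-sign core strictly between prev end and this start?
            between = other_starts[(other_starts >= prev[1]) & (other_starts < s)]
            if between.size == 0:
                prev[1] = e
            else:
                merged.append([s, e])
        return merged

    pos_starts = np.array([s for s, _ in pos_runs])
    neg_starts = np.array([s for s, _ in neg_runs])
    insp_cores = _merge(pos_runs, neg_starts)
    exp_cores = _merge(neg_runs, pos_starts)

    def _extend(core, sign):
        """Walk outward from a core to the enclosing zero crossings."""
        s, e = core
        while s > 0 and sign * x[s - 1] > 0:
            s -= 1
        while e < x.size and sign * x[e] > 0:
            e += 1
        t0 = _interp_crossing(x, times, s, rising=(sign > 0))
        t1 = times[e - 1] + dt if e == x.size else _interp_crossing(x, times, e, rising=(sign < 0))
        return s, e, t0, t1

    insp = [_extend(c, +1) for c in insp_cores]
    exp_ = [_extend(c, -1) for c in exp_cores]

    rows = []
    ei = 0
    for k, (s, e, t_on, t_down) in enumerate(insp):
        # first expiratory lobe starting at/after this inspiration's end
        while ei < len(exp_) and exp_[ei][0] < e:
            ei += 1
        if ei >= len(exp_):
            break
        es, ee, t_edown, t_eup = exp_[ei]
        # expiration must precede the next inspiration
        if k + 1 < len(insp) and es >= insp[k + 1][0]:
            continue
        seg = x[s:e]
        tv = float(np.trapezoid(np.clip(seg, 0.0, None), dx=dt))
        eseg = x[es:ee]
        expvol = float(-np.trapezoid(np.clip(eseg, None, 0.0), dx=dt))
        pif_i = int(np.argmax(seg))
        pef_i = int(np.argmin(eseg))
        rows.append(
            dict(
                onset=t_on, ti=max(t_down - t_on, dt), te=max(t_eup - t_edown, dt),
                tv=tv, expvol=expvol,
                pif=float(seg[pif_i]), pef=float(-eseg[pef_i]),
                pif_t=times[s + pif_i], pef_t=times[es + pef_i],
            )
        )
    if not rows:
        warnings.warn("no breaths found (flat or sub-threshold trace)")
        return empty_breath_table()

    onsets = np.array([r["onset"] for r in rows])
    ti = np.array([r["ti"] for r in rows])
    te = np.array([r["te"] for r in rows])
    cycle = np.empty_like(onsets)
    cycle[:-1] = np.diff(onsets)
    cycle[-1] = ti[-1] + te[-1]   # last breath: no next onset, no pause info
    return make_breath_table(
        onsets, ti, te, cycle,
        [r["tv"] for r in rows], [r["expvol"] for r in rows],
        [r["pif"] for r in rows], [r["pef"] for r in rows],
        [r["pif_t"] for r in rows], [r["pef_t"] for r in rows],
    )


def apply_pup_rejection_rules(table: pd.DataFrame) -> pd.DataFrame:
    """Flag breaths against the neonatal acceptance rules.

    Rules (acceptance bounds inclusive; first failed rule is recorded):

    a. peak inspiratory flow must occur before peak expiratory flow;
    b. 0.005 ml <= T_V <= 1.0 ml;
    c. T_I >= 0.02 s and T_I <= 2 x T_E;
    d. inspiratory volume within 50-150% of the paired expiratory volume.

    Flag-only: the returned table has the same rows, with ``accepted`` and
    ``reject_reason`` set.  Idempotent.
    """
    out = table.copy()
    n = len(out)
    reason = np.array([""] * n, dtype=object)

    def _flag(mask, why):
        fresh = mask.to_numpy() & (reason == "")
        reason[fresh] = why

    _flag(out["pif_time_s"] >= out["pef_time_s"], "pif_after_pef")
    _flag(out["tv_ml"] < TV_MIN_ML, "volume_low")
    _flag(out["tv_ml"] > TV_MAX_ML, "volume_high")
    _flag(out["ti_s"] < TI_MIN_S, "ti_short")
    _flag(out["ti_s"] > 2.0 * out["te_s"], "ti_te_ratio")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["tv_ml"] / out["expvol_ml"]
    bad_ratio = (~np.isfinite(ratio)) | (ratio < IMBALANCE_LO) | (ratio > IMBALANCE_HI)
    _flag(pd.Series(bad_ratio, index=out.index), "volume_imbalance")

    out["reject_reason"] = reason
    out["accepted"] = reason == ""
    return out


def compute_minute_rinx(
    trace_duration: float, table: pd.DataFrame, minute_index: int,
    start_time: float = 0.0,
) -> float:
    """Rejection index of one recording minute, percent.

    RINX = 100 x (60 s - time covered by accepted breaths) / 60 s, where a
    breath covers [onset, onset + cycle).  Minutes are 1-based.  The first
    argument may be a :class:`FlowTrace` or a duration in seconds.
    """
    if isinstance(trace_duration, FlowTrace):
        start_time = trace_duration.start_time
        trace_duration = trace_duration.duration
    if minute_index < 1 or (minute_index - 1) * 60.0 >= trace_duration - 1e-9:
        raise ValueError(f"minute {minute_index} outside trace")
    m0 = start_time + (minute_index - 1) * 60.0
    m1 = m0 + 60.0
    acc = table[table["accepted"]]
    if acc.empty:
        return 100.0
    b0 = acc["onset_s"].to_numpy()
    b1 = b0 + acc["cycle_s"].to_numpy()
    covered = float(np.clip(np.minimum(b1, m1) - np.maximum(b0, m0), 0.0, None).sum())
    return float(np.clip(100.0 * (60.0 - covered) / 60.0, 0.0, 100.0))


def minute_rinx_series(
    trace: FlowTrace, table: pd.DataFrame
) -> list[float]:
    """RINX for every minute of a trace."""
    return [
        compute_minute_rinx(trace.duration, table, m, trace.start_time)
        for m in range(1, trace.n_minutes + 1)
    ]


@dataclass
class AnimalInclusion:
    """Per-minute and per-animal inclusion decision for one recording."""

    minute_included: list[bool]
    reliable_roomair: int
    reliable_challenge: int
    animal_included: bool


def evaluate_inclusion(minutes: list[MinuteSummary]) -> AnimalInclusion:
    """Apply the neonatal inclusion criteria to one animal's minutes.

    A minute is reliable iff its RINX is strictly below 40%; the animal is
    included iff it has at least three reliable minutes in room air
    (baseline) AND at least three during the gas challenge.  Minutes must
    carry segment labels.
    """
    if any(not m.segment for m in minutes):
        raise ValueError("all minutes must carry a segment label")
    flags = [m.rinx_pct < RINX_INCLUSION_PCT for m in minutes]
    for m, ok in zip(minutes, flags):
        m.included = ok
        m.exclusion_reason = "" if ok else "rinx"
    n_room = sum(ok for m, ok in zip(minutes, flags) if m.segment == "baseline")
    n_chal = sum(ok for m, ok in zip(minutes, flags) if m.segment == "challenge")
    return AnimalInclusion(
        minute_included=flags,
        reliable_roomair=n_room,
        reliable_challenge=n_chal,
        animal_included=(n_room >= MIN_RELIABLE_MINUTES
                         and n_chal >= MIN_RELIABLE_MINUTES),
    )


def group_inclusion_report(group_flags: dict[str, list[bool]]) -> pd.DataFrame:
    """Inclusion counts and nearest-integer percentage per group.

    ``group_flags`` maps a group label to the per-animal inclusion flags
    produced by :func:`evaluate_inclusion`.
    """
    rows = []
    for label, flags in group_flags.items():
        n = len(flags)
        k = int(sum(flags))
        rows.append(
            dict(group=label, n_animals=n, n_included=k,
                 pct_included=int(round(100.0 * k / n)) if n else 0)
        )
    return pd.DataFrame(rows)
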