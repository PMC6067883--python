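"""Synthetic respiratory data with known ground truth.

Everything downstream (segmentation, event calling, chemoresponse
normalization, group statistics) is tested against sequences generated here,
where the true breath timings, planted sighs and apneas, artifact windows and
challenge-response factors are known exactly.

Design notes
------------
* Cycle lengths and tidal volumes are log-normal (positive support,
  right-skewed like real breathing), with the multiplicative deviation
  clipped so that no background breath can satisfy the apnea or sigh
  definitions by chance: the clip bounds the ratio of any breath to the mean
  of its neighbours below the 2x (apnea) and 2.5x (sigh tidal-volume)
  thresholds deterministically.
* Planted events exceed their defining thresholds by a 25% margin, so
  detector recovery tests can assert precision = recall = 1.0 exactly rather
  than statistically.
* Apneas are realised as post-expiratory pauses (cycle lengthened, T_I/T_E
  untouched); sighs as augmented breaths (T_V and T_I scaled up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import FlowTrace, MinuteSummary, make_breath_table

# multiplicative clip on background log-normal deviates; 1.3/(1/1.3) = 1.69
# keeps any breath/neighbour-mean ratio below the 2x apnea and 2.5x sigh gates
_CLIP_FACTOR = 1.3
# planted events exceed their thresholds by this factor
_PLANT_MARGIN = 1.25
# minimum breath-index separation between planted events (post-sigh apneas
# excepted: they sit at sigh index + 1 by construction)
_MIN_EVENT_GAP = 12


@dataclass
class GenotypeProfile:
    """Breathing phenotype of one genotype/treatment group.

    Rates are per hour of recording; ``hypoxia_curve`` / ``hypercapnia_curve``
    give per-minute multiplicative factors applied to tidal volume and
    breathing frequency during the challenge and recovery segments of a
    session (one entry per challenge+recovery minute).
    """

    label: str = "control"
    mean_cycle_s: float = 0.25      # ~240 breaths/min, juvenile mouse
    cycle_cv: float = 0.10
    mean_tv_ml: float = 0.15
    tv_cv: float = 0.10
    apnea_rate_per_h: float = 10.0  # spontaneous apneas
    post_sigh_apnea_prob: float = 0.3
    sigh_rate_per_h: float = 25.0
    hypoxia_curve: dict[str, np.ndarray] | None = None   # {"tv": ..., "vf": ...}
    hypercapnia_curve: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if min(self.mean_cycle_s, self.mean_tv_ml) <= 0:
            raise ValueError("mean cycle length and tidal volume must be positive")
        if min(self.cycle_cv, self.tv_cv, self.apnea_rate_per_h,
               self.sigh_rate_per_h) < 0:
            raise ValueError("variabilities and rates must be non-negative")
        if not 0.0 <= self.post_sigh_apnea_prob <= 1.0:
            raise ValueError("post_sigh_apnea_prob must be a probability")
        for name in ("hypoxia_curve", "hypercapnia_curve"):
            curve = getattr(self, name)
            if curve is not None:
                for key in ("tv", "vf"):
                    arr = np.asarray(curve[key], dtype=float)
                    if np.any(arr <= 0):
                        raise ValueError(f"{name}[{key!r}] factors must be > 0")
                    curve[key] = arr

    def curve_for(self, gas: str) -> dict[str, np.ndarray] | None:
        if gas == "hypoxia":
            return self.hypoxia_curve
        if gas == "hypercapnia":
            return self.hypercapnia_curve
        return None


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery oracles."""

    breath_onsets: np.ndarray
    planted_sigh_indices: list[int] = field(default_factory=list)
    planted_apnea_indices: list[tuple[int, str]] = field(default_factory=list)
    artifact_windows: list[tuple[float, float]] = field(default_factory=list)

    @property
    def apnea_index_list(self) -> list[int]:
        return [i for i, _ in self.planted_apnea_indices]

    @property
    def apnea_subtypes(self) -> dict[int, str]:
        return dict(self.planted_apnea_indices)


@dataclass
class SessionGroundTruth:
    """Planted per-minute challenge factors of a simulated session."""

    tv_factors: np.ndarray   # one entry per session minute, baseline = 1.0
    vf_factors: np.ndarray


def control_profile(**overrides) -> GenotypeProfile:
    """Wild-type-like defaults: few apneas, brisk hypoxic/hypercapnic response.

    The hypoxia curve is biphasic (augmentation then roll-off back toward
    baseline); the hypercapnia curve a sustained increase with recovery.
    """
    hypoxia_tv = np.concatenate([
        [1.15, 1.20, 1.15, 1.10, 1.05, 1.0, 0.98, 0.97, 0.97],   # 9 challenge
        np.linspace(0.98, 1.0, 15),                                # 15 recovery
    ])
    hypoxia_vf = np.concatenate([
        [1.20, 1.25, 1.15, 1.05, 0.95, 0.90, 0.88, 0.87, 0.87],
        np.linspace(0.95, 1.0, 15),
    ])
    hcap_tv = np.concatenate([
        [1.3, 1.45, 1.5, 1.5, 1.5, 1.5, 1.45, 1.45, 1.4],
        np.linspace(1.2, 1.0, 15),
    ])
    hcap_vf = np.concatenate([
        [1.2, 1.3, 1.35, 1.35, 1.35, 1.3, 1.3, 1.3, 1.25],
        np.linspace(1.1, 1.0, 15),
    ])
    kw = dict(
        label="control",
        hypoxia_curve={"tv": hypoxia_tv, "vf": hypoxia_vf},
        hypercapnia_curve={"tv": hcap_tv, "vf": hcap_vf},
    )
    kw.update(overrides)
    return GenotypeProfile(**kw)


def cko_profile(**overrides) -> GenotypeProfile:
    """Conditional-knockout-like defaults: frequent apneas and sighs,
    sustained respiratory depression in hypoxia, blunted hypercapnic
    response."""
    hypoxia_tv = np.concatenate([
        [1.10, 1.05, 0.95, 0.90, 0.85, 0.85, 0.85, 0.85, 0.85],
        np.linspace(0.90, 1.0, 15),
    ])
    hypoxia_vf = np.concatenate([
        [1.05, 0.90, 0.75, 0.65, 0.60, 0.60, 0.60, 0.60, 0.60],
        np.linspace(0.80, 1.0, 15),
    ])
    hcap_tv = np.concatenate([
        [1.05, 1.10, 1.10, 1.10, 1.10, 1.10, 1.10, 1.05, 1.05],
        np.linspace(1.05, 1.0, 15),
    ])
    hcap_vf = np.concatenate([
        [1.05, 1.08, 1.10, 1.10, 1.10, 1.08, 1.08, 1.05, 1.05],
        np.linspace(1.02, 1.0, 15),
    ])
    kw = dict(
        label="cko",
        cycle_cv=0.15,
        apnea_rate_per_h=40.0,
        sigh_rate_per_h=60.0,
        post_sigh_apnea_prob=0.5,
        hypoxia_curve={"tv": hypoxia_tv, "vf": hypoxia_vf},
        hypercapnia_curve={"tv": hcap_tv, "vf": hcap_vf},
    )
    kw.update(overrides)
    return GenotypeProfile(**kw)


def _clipped_lognormal(rng, mean, cv, n):
    """Log-normal deviates with the stated arithmetic mean and CV, with the
    multiplicative deviation hard-clipped to [1/1.3, 1.3] (and to 2.5 sigma
    in log space) so extreme draws cannot mimic planted events."""
    if cv == 0:
        return np.full(n, mean)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    mu = math.log(mean) - 0.5 * sigma * sigma
    z = rng.standard_normal(n)
    z = np.clip(z, -2.5, 2.5)
    log_dev = np.clip(z * sigma, -math.log(_CLIP_FACTOR), math.log(_CLIP_FACTOR))
    return np.exp(mu + 0.5 * sigma * sigma + log_dev)  # centred on `mean`


def _place_events(rng, n_breaths: int, n_events: int, gap: int) -> np.ndarray:
    """Choose `n_events` breath indices in [8, n-8) pairwise at least `gap`
    apart (so planted events never share neighbourhood windows)."""
    lo, hi = 8, n_breaths - 8
    if hi <= lo:
        raise ValueError("sequence too short to place events")
    chosen: list[int] = []
    candidates = np.arange(lo, hi)
    rng.shuffle(candidates)
    for idx in candidates:
        if all(abs(idx - c) >= gap for c in chosen):
            chosen.append(int(idx))
            if len(chosen) == n_events:
                break
    if len(chosen) < n_events:
        raise ValueError(
            f"cannot place {n_events} events {gap} breaths apart in "
            f"{n_breaths} breaths; lower the event rates or extend duration"
        )
    return np.sort(np.array(chosen, dtype=int))


def simulate_breath_sequence(
    profile: GenotypeProfile, duration: float, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a breath table covering `duration` seconds with planted events.

    Planted apneas satisfy both apnea criteria (cycle > 0.5 s and >= 2x the
    mean of the six surrounding breaths) with a 25% margin; planted sighs
    likewise for both sigh criteria.  Background variability is clipped so no
    other breath satisfies either definition.  Deterministic per seed.

    Returns
    -------
    (breath_table, ground_truth)
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)

    # overshoot the breath count, trim to duration after planting
    mc = profile.mean_cycle_s
    n = int(duration / mc * 1.4) + 50
    cycle = _clipped_lognormal(rng, mc, profile.cycle_cv, n)
    tv = _clipped_lognormal(rng, profile.mean_tv_ml, profile.tv_cv, n)
    ti_frac = np.clip(rng.normal(0.40, 0.01, n), 0.38, 0.42)
    ti = ti_frac * cycle
    te = cycle - ti                      # no post-expiratory pause at baseline
    expvol = tv * rng.uniform(0.95, 1.05, n)

    hours = duration / 3600.0
    n_sighs = int(round(profile.sigh_rate_per_h * hours))
    n_spont = int(round(profile.apnea_rate_per_h * hours))

    # events lengthen cycles, pushing later breaths past `duration`; bound the
    # shrinkage so all planted indices survive the final trim
    bg_onsets = np.concatenate([[0.0], np.cumsum(cycle)[:-1]])
    n_bg = int(np.searchsorted(bg_onsets, duration))
    apnea_pause = max(0.5 * _PLANT_MARGIN, 2.0 * _PLANT_MARGIN * _CLIP_FACTOR * mc)
    est_added = (n_sighs + n_spont) * (apnea_pause + 0.3 * mc)
    n_drop = int(math.ceil(est_added / (mc / _CLIP_FACTOR)))

    sigh_idx = np.array([], dtype=int)
    spont_idx = np.array([], dtype=int)
    if n_sighs + n_spont:
        slots = _place_events(rng, n_bg - n_drop, n_sighs + n_spont, _MIN_EVENT_GAP)
        which = rng.permutation(np.r_[np.zeros(n_sighs, int), np.ones(n_spont, int)])
        sigh_idx = slots[which == 0]
        spont_idx = slots[which == 1]

    # sighs: augmented breaths; thresholds are vs the mean of the previous
    # five breaths, planted with margin _PLANT_MARGIN
    for i in sigh_idx:
        prev_tv = tv[i - 5:i].mean()
        prev_ti = ti[i - 5:i].mean()
        tv[i] = 2.5 * _PLANT_MARGIN * prev_tv
        ti[i] = 1.25 * _PLANT_MARGIN * prev_ti
        expvol[i] = tv[i]
        te[i] = 0.8 * te[i]
        cycle[i] = ti[i] + te[i]

    post_sigh: list[int] = []
    if profile.post_sigh_apnea_prob > 0:
        draws = rng.uniform(size=len(sigh_idx))
        post_sigh = [int(i) + 1 for i, u in zip(sigh_idx, draws)
                     if u < profile.post_sigh_apnea_prob]

    apneas: list[tuple[int, str]] = sorted(
        [(int(i), "spontaneous") for i in spont_idx]
        + [(i, "post_sigh") for i in post_sigh]
    )
    # apneas: prolonged cycles (pause after expiration); both criteria with margin
    for j, _sub in apneas:
        surround = np.r_[cycle[j - 3:j], cycle[j + 1:j + 4]].mean()
        cycle[j] = max(0.5 * _PLANT_MARGIN, 2.0 * _PLANT_MARGIN * surround)

    onsets = np.concatenate([[0.0], np.cumsum(cycle)[:-1]])
    keep = onsets < duration
    n_keep = int(keep.sum())
    # planted indices must stay clear of the trimmed tail (need 3+5 neighbours)
    if any(i >= n_keep - 8 for i in list(sigh_idx) + [j for j, _ in apneas]):
        # regenerate is overkill; the overshoot above makes this unreachable
        # for sane rates, so treat it as a placement failure
        raise ValueError("planted event too close to sequence end")

    pif = math.pi * tv / (2.0 * ti)
    pef = math.pi * expvol / (2.0 * te)
    table = make_breath_table(
        onsets[keep], ti[keep], te[keep], cycle[keep], tv[keep],
        expvol[keep], pif[keep], pef[keep],
    )
    truth = GroundTruth(
        breath_onsets=onsets[keep],
        planted_sigh_indices=[int(i) for i in sigh_idx],
        planted_apnea_indices=apneas,
    )
    return table, truth


def render_flow_trace(
    table: pd.DataFrame,
    sampling_rate: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    metadata: dict | None = None,
) -> FlowTrace:
    """Render a breath table as a flow waveform.

    Each breath is an inspiratory half-sine (positive, duration T_I, area
    T_V) followed by an expiratory half-sine (negative, duration T_E, area
    the expiratory volume); any remaining cycle time is zero-flow pause.
    Lobe samples are renormalised so the discrete trapezoid integral equals
    the tabulated volume exactly, then Gaussian noise of `noise_sd` is added.
    """
    if table.empty:
        raise ValueError("breath table is empty")
    if sampling_rate < 100:
        raise ValueError("sampling_rate must be at least 100 Hz")
    dt = 1.0 / sampling_rate
    min_phase = min(table["ti_s"].min(), table["te_s"].min())
    if min_phase < 4 * dt:
        raise ValueError(
            f"sampling too coarse: shortest half-wave {min_phase:.4f}s spans "
            f"fewer than 4 samples at {sampling_rate} Hz"
        )
    t_end = float(table["onset_s"].iloc[-1] + table["cycle_s"].iloc[-1])
    n = int(round(t_end * sampling_rate)) + 1
    flow = np.zeros(n)
    times = np.arange(n) * dt

    def _lobe(t0, width, area, sign):
        i0 = int(np.ceil(t0 * sampling_rate))
        i1 = int(np.floor((t0 + width) * sampling_rate))
        if i1 <= i0:
            return
        tt = times[i0:i1 + 1]
        lobe = np.sin(np.pi * (tt - t0) / width)
        discrete_area = np.trapezoid(lobe, dx=dt)
        if discrete_area > 0:
            lobe *= area / discrete_area
        flow[i0:i1 + 1] += sign * lobe

    for b in table.itertuples():
        _lobe(b.onset_s, b.ti_s, b.tv_ml, +1.0)
        _lobe(b.onset_s + b.ti_s, b.te_s, b.expvol_ml, -1.0)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flow = flow + rng.normal(0.0, noise_sd, n)
    return FlowTrace(flow, sampling_rate, metadata=metadata or {})


def corrupt_trace(
    trace: FlowTrace,
    artifact_windows: list[tuple[float, float]],
    seed: int = 0,
    amplitude: float | None = None,
) -> FlowTrace:
    """Overwrite windows with high-amplitude broadband noise.

    Emulates movement artifacts in pup recordings: within a window the signal
    crosses zero every few samples, so segmentation yields only sub-0.02 s
    "breaths" that the pup rejection rules discard, driving the minute's
    rejection index up by at least the window fraction.
    """
    windows = sorted((float(a), float(b)) for a, b in artifact_windows)
    for (a0, b0), (a1, _b1) in zip(windows, windows[1:]):
        if a1 < b0:
            raise ValueError(f"overlapping artifact windows at {a1:.2f}s")
    for a, b in windows:
        if a < trace.start_time or b > trace.start_time + trace.duration or b <= a:
            raise ValueError(f"window ({a}, {b}) outside trace span")
    if not windows:
        return FlowTrace(trace.samples.copy(), trace.sampling_rate,
                         trace.start_time, dict(trace.metadata),
                         trace.minute_labels)
    rng = np.random.default_rng(seed)
    if amplitude is None:
        amplitude = 8.0 * float(np.abs(trace.samples).max() or 1.0)
    out = trace.samples.copy()
    fs = trace.sampling_rate
    for a, b in windows:
        i0 = int(round((a - trace.start_time) * fs))
        i1 = int(round((b - trace.start_time) * fs))
        out[i0:i1] = rng.normal(0.0, amplitude, i1 - i0)
    return FlowTrace(out, fs, trace.start_time, dict(trace.metadata),
                     trace.minute_labels)


def simulate_session(
    profile: GenotypeProfile,
    protocol,
    seed: int,
    minute_cv: float = 0.02,
) -> tuple[list[MinuteSummary], SessionGroundTruth]:
    """Simulate one animal's minute-resolved chemochallenge session.

    Baseline minutes fluctuate around the profile's resting frequency
    (60 / mean cycle length) and tidal volume with within-minute coefficient
    of variation `minute_cv`; challenge and recovery minutes are additionally
    multiplied by the profile's gas-response curve.  Deterministic per seed.
    """
    from .chemoresponse import ChallengeProtocol  # avoid import cycle

    if not isinstance(protocol, ChallengeProtocol):
        raise TypeError("protocol must be a ChallengeProtocol")
    total = protocol.total_minutes
    n_resp = protocol.challenge_minutes + protocol.recovery_minutes
    curve = profile.curve_for(protocol.gas)
    tv_fac = np.ones(total)
    vf_fac = np.ones(total)
    if curve is not None:
        for key, fac in (("tv", tv_fac), ("vf", vf_fac)):
            arr = np.asarray(curve[key], dtype=float)
            if arr.size < n_resp:
                raise ValueError(
                    f"{protocol.gas} curve has {arr.size} minutes, protocol "
                    f"needs {n_resp} (challenge + recovery)"
                )
            fac[protocol.baseline_minutes:] = arr[:n_resp]

    rng = np.random.default_rng(seed)
    vf0 = 60.0 / profile.mean_cycle_s
    tv0 = profile.mean_tv_ml
    minutes: list[MinuteSummary] = []
    for m in range(total):
        vf = vf0 * vf_fac[m] * (1.0 + minute_cv * rng.standard_normal())
        tv = tv0 * tv_fac[m] * (1.0 + minute_cv * rng.standard_normal())
        minutes.append(
            MinuteSummary(
                minute_index=m + 1,
                vf_bpm=vf,
                tv_ml=tv,
                ve_ml_min=vf * tv,
                segment=protocol.segment_of_minute(m + 1),
            )
        )
    return minutes, SessionGroundTruth(tv_factors=tv_fac, vf_factors=vf_fac)
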