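"""Chemochallenge protocol structure and baseline normalization.

A session is baseline room air, a gas challenge (10% O2 hypoxia or 5% CO2
hypercapnia), and room-air recovery.  The juvenile protocol is 20 baseline,
9 challenge, 15 recovery minutes (44 compared minutes); the neonatal protocol
is 5 baseline and 5 challenge minutes with no recovery.

Minute-wise parameters are normalized to the animal's own baseline:

    normalized y(m) = y(m) / mean(y over included baseline minutes)

Minutes excluded upstream (sniffing gate, RINX) are emitted as NaN and never
interpolated; they also stay out of the baseline mean so a sniffing bout
cannot contaminate the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import MinuteSummary

GASES = ("hypoxia", "hypercapnia", "room air")
ADULT_SEGMENTS = (20, 9, 15)
PUP_SEGMENTS = (5, 5, 0)
PARAMETERS = {"tv": "tv_ml", "vf": "vf_bpm", "ve": "ve_ml_min"}


@dataclass(frozen=True)
class ChallengeProtocol:
    """Segment structure of one chemochallenge session."""

    baseline_minutes: int
    challenge_minutes: int
    recovery_minutes: int
    gas: str = "hypoxia"
    age_mode: str = "adult"

    def __post_init__(self) -> None:
        if self.baseline_minutes < 1 or self.challenge_minutes < 1 \
                or self.recovery_minutes < 0:
            raise ValueError("segment lengths must be positive "
                             "(recovery may be zero)")
        if self.gas not in GASES:
            raise ValueError(f"unknown gas {self.gas!r}; expected one of {GASES}")

    @property
    def total_minutes(self) -> int:
        return self.baseline_minutes + self.challenge_minutes + self.recovery_minutes

    def segment_of_minute(self, minute_index: int) -> str:
        """Segment label of a 1-based minute index."""
        if not 1 <= minute_index <= self.total_minutes:
            raise ValueError(f"minute {minute_index} outside protocol")
        if minute_index <= self.baseline_minutes:
            return "baseline"
        if minute_index <= self.baseline_minutes + self.challenge_minutes:
            return "challenge"
        return "recovery"

    @property
    def minute_labels(self) -> list[str]:
        return [self.segment_of_minute(m) for m in range(1, self.total_minutes + 1)]


def build_protocol(age_mode: str, gas: str, segments: tuple[int, int, int] | None = None
                   ) -> ChallengeProtocol:
    """Standard protocol for an age mode, optionally overriding segment lengths.

    Adult: 20/9/15 minutes (44 total).  Pup: 5/5/0.
    """
    if age_mode not in ("adult", "pup"):
        raise ValueError("age_mode must be 'adult' or 'pup'")
    if segments is None:
        segments = ADULT_SEGMENTS if age_mode == "adult" else PUP_SEGMENTS
    return ChallengeProtocol(*segments, gas=gas, age_mode=age_mode)


@dataclass
class NormalizedResponse:
    """Minute-wise parameter series divided by its baseline mean."""

    parameter: str
    values: np.ndarray          # length = protocol minutes; NaN where excluded
    baseline_mean: float
    minutes_used: np.ndarray    # 1-based indices of contributing minutes
    protocol: ChallengeProtocol

    def segment_values(self, segment: str) -> np.ndarray:
        labels = np.array(self.protocol.minute_labels)
        return self.values[labels == segment]


def normalize_response(
    minutes: list[MinuteSummary],
    protocol: ChallengeProtocol,
    parameter: str,
) -> NormalizedResponse:
    """Normalize one animal's minute series to its included-baseline mean.

    `parameter` is one of ``"tv"``, ``"vf"``, ``"ve"``.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {sorted(PARAMETERS)}")
    if len(minutes) != protocol.total_minutes:
        raise ValueError(
            f"session has {len(minutes)} minutes, protocol expects "
            f"{protocol.total_minutes}"
        )
    attr = PARAMETERS[parameter]
    raw = np.array([getattr(m, attr) for m in minutes], dtype=float)
    included = np.array([m.included for m in minutes], dtype=bool)
    labels = np.array(protocol.minute_labels)
    base_mask = included & (labels == "baseline")
    if not base_mask.any():
        raise ValueError("no included baseline minutes")
    baseline_mean = float(raw[base_mask].mean())
    if baseline_mean <= 0:
        raise ValueError("baseline mean is zero or negative")
    values = np.where(included, raw / baseline_mean, np.nan)
    return NormalizedResponse(
        parameter=parameter,
        values=values,
        baseline_mean=baseline_mean,
        minutes_used=np.flatnonzero(included) + 1,
        protocol=protocol,
    )
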