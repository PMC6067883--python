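"""Run configuration: every analysis constant in one overridable record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .metrics import CorrectionConstants


@dataclass
class RunConfig:
    """All thresholds of the analysis, with the standard protocol defaults.

    Defaults are the published juvenile/neonatal protocol constants; any can
    be overridden for sensitivity analyses.
    """

    age_mode: str = "adult"                 # adult | pup
    gas: str = "hypoxia"                    # hypoxia | hypercapnia | room air
    # event definitions
    apnea_abs_gate_s: float = 0.5
    apnea_surround_factor: float = 2.0
    sigh_tv_factor: float = 2.5
    sigh_ti_factor: float = 1.25
    post_sigh_window: int = 2
    # adult breath filters
    ti_min_adult_s: float = 0.03
    te_max_adult_s: float = 10.0
    vf_sniff_gate_bpm: float = 500.0
    # pup quality control
    tv_min_ml: float = 0.005
    tv_max_ml: float = 1.0
    ti_min_pup_s: float = 0.02
    rinx_inclusion_pct: float = 40.0
    min_reliable_minutes: int = 3
    # protocol segment lengths (minutes): adult 20/9/15, pup 5/5/0
    baseline_minutes: int = 20
    challenge_minutes: int = 9
    recovery_minutes: int = 15
    # statistics
    familywise_alpha: float = 0.05
    # temperature correction
    correction: CorrectionConstants = field(default_factory=CorrectionConstants)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_mode == "pup" and (self.baseline_minutes, self.challenge_minutes,
                                       self.recovery_minutes) == (20, 9, 15):
            self.baseline_minutes, self.challenge_minutes, self.recovery_minutes = 5, 5, 0
        positive = ["apnea_abs_gate_s", "apnea_surround_factor", "sigh_tv_factor",
                    "sigh_ti_factor", "ti_min_adult_s", "te_max_adult_s",
                    "vf_sniff_gate_bpm", "tv_min_ml", "tv_max_ml", "ti_min_pup_s",
                    "rinx_inclusion_pct", "familywise_alpha"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        corr = d.pop("correction", None)
        cfg = cls(**d) if corr is None else cls(
            correction=CorrectionConstants(**corr), **d)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
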