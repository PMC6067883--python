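"""End-to-end pipeline driver: segment -> filter -> summarize -> events ->
normalize -> group statistics, with CSV outputs and a reproducibility
manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemoresponse import NormalizedResponse, build_protocol, normalize_response
from .config import RunConfig
from .events import EventCalls, detect_apneas, detect_sighs, event_rates
from .io import (ensure_dir, write_breath_table, write_minute_summaries)
from .metrics import apply_adult_breath_filters, ibi_irregularity, summarize_minutes
from .segmentation import (apply_pup_rejection_rules, compute_minute_rinx,
                           evaluate_inclusion, segment_flow_trace)
from .stats import results_to_frame, serial_group_tests
from .trace import FlowTrace, MinuteSummary

log = logging.getLogger("plethykit")


@dataclass
class SessionResult:
    """Everything computed for one animal's recording."""

    name: str
    table: pd.DataFrame
    minutes: list[MinuteSummary]
    events: EventCalls | None = None
    irregularity_mean: float | None = None
    normalized: dict[str, NormalizedResponse] = field(default_factory=dict)
    animal_included: bool = True


def analyze_session(
    config: RunConfig,
    trace: FlowTrace | None = None,
    table: pd.DataFrame | None = None,
    name: str = "session",
) -> SessionResult:
    """Run the per-animal stages on a flow trace or pre-segmented table."""
    if (trace is None) == (table is None):
        raise ValueError("provide exactly one of trace or table")
    protocol = build_protocol(
        config.age_mode, config.gas,
        (config.baseline_minutes, config.challenge_minutes,
         config.recovery_minutes),
    )
    if table is None:
        table = segment_flow_trace(trace)
        log.info("%s: segmented %d breaths", name, len(table))

    duration = float(table["onset_s"].iloc[-1] + table["cycle_s"].iloc[-1]) \
        if len(table) else 0.0
    minute_rinx: list[float] = []
    if config.age_mode == "pup":
        table = apply_pup_rejection_rules(table)
        n_min = max(int(np.ceil(duration / 60.0 - 1e-9)), 1)
        minute_rinx = [compute_minute_rinx(duration, table, m)
                       for m in range(1, n_min + 1)]
    else:
        table = apply_adult_breath_filters(table)
    log.info("%s: %d/%d breaths accepted", name,
             int(table["accepted"].sum()), len(table))

    labels = protocol.minute_labels
    minutes = summarize_minutes(
        table, config.correction, total_duration=protocol.total_minutes * 60.0,
        segment_labels=labels,
    )
    for m, rinx in zip(minutes, minute_rinx):
        m.rinx_pct = rinx

    result = SessionResult(name=name, table=table, minutes=minutes)
    if config.age_mode == "pup":
        inclusion = evaluate_inclusion(minutes)
        result.animal_included = inclusion.animal_included

    included_h = sum(1.0 for m in minutes if m.included) / 60.0
    if included_h > 0 and int(table["accepted"].sum()) >= 8:
        sighs = detect_sighs(table, config.sigh_tv_factor, config.sigh_ti_factor)
        apneas = detect_apneas(table, sighs, config.apnea_abs_gate_s,
                               config.apnea_surround_factor,
                               config.post_sigh_window)
        result.events = event_rates(sighs, apneas, included_h)
        log.info("%s: %d sighs, %d apneas in %.2f h", name,
                 len(sighs), len(apneas), included_h)
    if int(table["accepted"].sum()) >= 2:
        try:
            result.irregularity_mean = ibi_irregularity(table).mean_score
        except ValueError:
            pass
    for param in ("tv", "vf", "ve"):
        try:
            result.normalized[param] = normalize_response(minutes, protocol, param)
        except ValueError as exc:
            log.warning("%s: normalization of %s skipped (%s)", name, param, exc)
    return result


def run_pipeline(
    config: RunConfig,
    sessions: list[tuple[str, str, FlowTrace | pd.DataFrame]],
    outdir,
) -> dict:
    """Analyze many sessions and compare groups.

    Parameters
    ----------
    sessions
        List of ``(name, group_label, trace_or_table)``.
    outdir
        Output directory; per-session CSVs, group comparison CSVs and a JSON
        manifest are written there.

    Returns the manifest dictionary.
    """
    out = ensure_dir(outdir)
    results: list[tuple[str, SessionResult]] = []
    for name, group, obj in sessions:
        try:
            if isinstance(obj, FlowTrace):
                res = analyze_session(config, trace=obj, name=name)
            else:
                res = analyze_session(config, table=obj, name=name)
        except Exception as exc:
            raise RuntimeError(f"session {name!r} failed: {exc}") from exc
        results.append((group, res))
        write_breath_table(res.table, out / f"{name}_breaths.csv")
        write_minute_summaries(res.minutes, out / f"{name}_minutes.csv")
        if res.events is not None:
            res.events.to_frame(res.table).to_csv(
                out / f"{name}_events.csv", index=False)

    groups = sorted({g for g, _ in results})
    stats_written = None
    if len(groups) == 2:
        by_group = {
            g: [r.normalized["ve"] for gg, r in results
                if gg == g and "ve" in r.normalized and r.animal_included]
            for g in groups
        }
        if all(len(v) >= 2 for v in by_group.values()):
            tests = serial_group_tests(by_group[groups[0]], by_group[groups[1]],
                                       config.familywise_alpha)
            results_to_frame(tests).to_csv(out / "serial_tests_ve.csv",
                                           index=False)
            stats_written = "serial_tests_ve.csv"

    manifest = {
        "plethykit_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "sessions": [
            {
                "name": r.name,
                "group": g,
                "n_breaths": int(len(r.table)),
                "n_accepted": int(r.table["accepted"].sum()),
                "n_included_minutes": int(sum(m.included for m in r.minutes)),
                "animal_included": bool(r.animal_included),
                "sighs_per_h": None if r.events is None else r.events.sighs_per_h,
                "apneas_spont_per_h": None if r.events is None
                else r.events.apneas_spont_per_h,
                "apneas_post_sigh_per_h": None if r.events is None
                else r.events.apneas_post_sigh_per_h,
                "ibi_irregularity": r.irregularity_mean,
            }
            for g, r in results
        ],
        "group_stats": stats_written,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
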