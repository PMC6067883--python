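"""Segmentation round-trips, pup quality rules, RINX, inclusion criteria."""

import numpy as np
import pandas as pd
import pytest

import plethykit as pk
from plethykit.segmentation import (RINX_INCLUSION_PCT, apply_pup_rejection_rules,
                                    compute_minute_rinx, group_inclusion_report,
                                    minute_rinx_series)
from plethykit.trace import FlowTrace, MinuteSummary, make_breath_table


class TestSegmentFlowTrace:
    def test_round_trip_noise_free(self, busy_profile):
        table, _ = pk.simulate_breath_sequence(busy_profile, 60.0, seed=21)
        trace = pk.render_flow_trace(table, 1000.0)
        seg = pk.segment_flow_trace(trace)
        assert len(seg) == len(table)
        for col in ("ti_s", "te_s", "tv_ml"):
            rel = np.abs(seg[col].to_numpy() - table[col].to_numpy()) \
                / table[col].to_numpy()
            assert rel.max() < 0.02, col

    def test_round_trip_with_noise(self, busy_profile):
        table, _ = pk.simulate_breath_sequence(busy_profile, 60.0, seed=22)
        trace = pk.render_flow_trace(table, 1000.0, noise_sd=0.03, seed=22)
        seg = pk.segment_flow_trace(trace)
        assert len(seg) == len(table)

    def test_pure_zero_trace_gives_empty_table(self):
        trace = FlowTrace(np.zeros(5000), 1000.0)
        with pytest.warns(UserWarning, match="no breaths"):
            out = pk.segment_flow_trace(trace, min_amplitude=0.01)
        assert out.empty

    def test_inversion_flag_restores_table(self, quiet_profile):
        table, _ = pk.simulate_breath_sequence(quiet_profile, 20.0, seed=0)
        trace = pk.render_flow_trace(table, 1000.0)
        flipped = FlowTrace(-trace.samples, trace.sampling_rate)
        a = pk.segment_flow_trace(trace)
        b = pk.segment_flow_trace(flipped, invert=True)
        pd.testing.assert_frame_equal(a, b)

    def test_nan_samples_raise(self):
        x = np.zeros(2000)
        x[100] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            pk.segment_flow_trace(FlowTrace(x, 1000.0))


def _one_breath(**kw):
    d = dict(onset=0.0, ti=0.1, te=0.15, cycle=0.3, tv=0.05, expvol=0.05)
    d.update(kw)
    return make_breath_table([d["onset"]], [d["ti"]], [d["te"]], [d["cycle"]],
                             [d["tv"]], [d["expvol"]], [1.0], [1.0])


class TestPupRejectionRules:
    @pytest.mark.parametrize(
        "kw,reason",
        [
            (dict(tv=0.004, expvol=0.004), "volume_low"),
            (dict(tv=1.2, expvol=1.2), "volume_high"),
            (dict(ti=0.01), "ti_short"),
            (dict(ti=0.35, te=0.15, cycle=0.5), "ti_te_ratio"),
            (dict(tv=0.30, expvol=0.10), "volume_imbalance"),
        ],
    )
    def test_each_rule_fires(self, kw, reason):
        out = apply_pup_rejection_rules(_one_breath(**kw))
        assert not out["accepted"].iloc[0]
        assert out["reject_reason"].iloc[0] == reason

    @pytest.mark.parametrize(
        "kw",
        [
            dict(tv=0.005, expvol=0.005),    # lower volume bound inclusive
            dict(tv=1.0, expvol=1.0),        # upper volume bound inclusive
            dict(ti=0.02),                   # T_I bound inclusive
            dict(ti=0.2, te=0.1, cycle=0.35),   # T_I = 2 T_E exactly
            dict(tv=0.075, expvol=0.05),     # ratio = 1.5 exactly
            dict(tv=0.025, expvol=0.05),     # ratio = 0.5 exactly
        ],
    )
    def test_acceptance_boundaries_inclusive(self, kw):
        out = apply_pup_rejection_rules(_one_breath(**kw))
        assert out["accepted"].iloc[0]

    def test_pif_after_pef_rejected(self):
        t = _one_breath()
        t.loc[0, "pif_time_s"] = 0.2
        t.loc[0, "pef_time_s"] = 0.1
        out = apply_pup_rejection_rules(t)
        assert out["reject_reason"].iloc[0] == "pif_after_pef"

    def test_flag_only_and_idempotent(self, short_sequence):
        table, _ = short_sequence
        once = apply_pup_rejection_rules(table)
        assert len(once) == len(table)
        twice = apply_pup_rejection_rules(once)
        pd.testing.assert_frame_equal(once, twice)


class TestRinx:
    def _tiled_table(self, duration, start=0.0, cycle=0.5):
        n = int(duration / cycle)
        onsets = start + np.arange(n) * cycle
        return make_breath_table(onsets, np.full(n, 0.2), np.full(n, 0.3),
                                 np.full(n, cycle), np.full(n, 0.05),
                                 np.full(n, 0.05), [1.0] * n, [1.0] * n)

    def test_fully_tiled_minute_is_zero(self):
        assert compute_minute_rinx(60.0, self._tiled_table(60.0), 1) == 0.0

    def test_twelve_second_gap_is_twenty_percent(self):
        t1 = self._tiled_table(24.0)
        t2 = self._tiled_table(24.0, start=36.0)
        table = pd.concat([t1, t2], ignore_index=True)
        assert compute_minute_rinx(60.0, table, 1) == pytest.approx(20.0)

    def test_no_accepted_breaths_is_hundred(self):
        table = self._tiled_table(60.0)
        table["accepted"] = False
        assert compute_minute_rinx(60.0, table, 1) == 100.0

    def test_minute_outside_trace_raises(self):
        with pytest.raises(ValueError, match="outside"):
            compute_minute_rinx(60.0, self._tiled_table(60.0), 2)

    def test_artifact_never_decreases_rinx(self, quiet_profile):
        """Corrupting a window can only raise the RINX of overlapped minutes."""
        table, _ = pk.simulate_breath_sequence(quiet_profile, 180.0, seed=0)
        trace = pk.render_flow_trace(table, 500.0)
        base = apply_pup_rejection_rules(pk.segment_flow_trace(trace))
        before = minute_rinx_series(trace, base)
        bad = pk.corrupt_trace(trace, [(70.0, 85.0)], seed=1)
        seg = apply_pup_rejection_rules(pk.segment_flow_trace(bad))
        after = minute_rinx_series(bad, seg)
        assert all(a >= b - 1e-6 for a, b in zip(after, before))
        assert after[1] >= before[1] + 20.0   # 15 s of minute 2 destroyed

    def test_full_minute_artifact_excludes_minute(self, quiet_profile):
        table, _ = pk.simulate_breath_sequence(quiet_profile, 180.0, seed=0)
        trace = pk.render_flow_trace(table, 500.0)
        bad = pk.corrupt_trace(trace, [(60.0, 120.0)], seed=1)
        seg = apply_pup_rejection_rules(pk.segment_flow_trace(bad))
        assert compute_minute_rinx(bad, seg, 2) >= RINX_INCLUSION_PCT


def _minutes(rinx_room, rinx_chal):
    out = []
    for i, r in enumerate(rinx_room):
        out.append(MinuteSummary(i + 1, 150.0, 0.05, 7.5, rinx_pct=r,
                                 segment="baseline"))
    for i, r in enumerate(rinx_chal):
        out.append(MinuteSummary(len(rinx_room) + i + 1, 150.0, 0.05, 7.5,
                                 rinx_pct=r, segment="challenge"))
    return out


class TestInclusion:
    def test_three_reliable_minutes_each_segment_required(self):
        good = pk.evaluate_inclusion(_minutes([10, 10, 10, 50, 50],
                                              [10, 10, 10, 50, 50]))
        assert good.animal_included
        # 2 reliable room-air minutes, 5 reliable challenge minutes -> excluded
        bad = pk.evaluate_inclusion(_minutes([10, 10, 50, 50, 50],
                                             [10, 10, 10, 10, 10]))
        assert not bad.animal_included
        assert bad.reliable_roomair == 2 and bad.reliable_challenge == 5

    def test_rinx_exactly_forty_excluded(self):
        res = pk.evaluate_inclusion(_minutes([40.0] * 5, [10.0] * 5))
        assert res.reliable_roomair == 0

    def test_unlabelled_minutes_raise(self):
        ms = _minutes([10] * 5, [10] * 5)
        ms[0].segment = ""
        with pytest.raises(ValueError, match="segment"):
            pk.evaluate_inclusion(ms)

    def test_group_report_percentages(self):
        rep = group_inclusion_report({
            "control": [True] * 23 + [False] * 10,
            "cko": [True] * 12 + [False] * 4,
        })
        rep = rep.set_index("group")
        assert rep.loc["control", "pct_included"] == 70
        assert rep.loc["cko", "pct_included"] == 75
        assert rep.loc["control", "n_animals"] == 33
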