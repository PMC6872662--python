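"""Stage assignment, frequency normalization, statistics policy, report."""

import numpy as np
import pytest

from mitocoupling.event_detection import CaEvent
from mitocoupling.stage_stats import (
    assign_stages,
    build_report,
    compare_groups,
    event_frequency,
)

import pandas as pd

TRIAL_INTERVALS = [("pre_run", 0.0, 100.0), ("run", 100.0, 200.0),
                   ("post_run", 200.0, 300.0)]


def _ev(onset, channel="cyto", roi="r0", amp=30.0, dur=3.0, peak=None):
    return CaEvent(channel=channel, onset_s=onset, offset_s=onset + dur,
                   peak_amp_pct=amp,
                   peak_time_s=onset + 1.0 if peak is None else peak,
                   roi_id=roi)


class TestAssignStages:
    def test_exercise_protocol_assignment(self):
        # 300-frame trial at 1 Hz, frames 101-200 stimulated: an onset at
        # frame 150 belongs to the run stage
        events = assign_stages([_ev(150.0)], TRIAL_INTERVALS)
        assert events[0].stage == "run"

    def test_boundaries_are_half_open(self):
        events = assign_stages([_ev(99.5), _ev(100.0), _ev(200.0)], TRIAL_INTERVALS)
        assert [e.stage for e in events] == ["pre_run", "run", "post_run"]

    def test_outside_intervals_is_unstaged(self):
        events = assign_stages([_ev(500.0)], TRIAL_INTERVALS)
        assert events[0].stage == "unstaged"

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            assign_stages([_ev(1.0)], [("a", 0.0, 10.0), ("b", 5.0, 20.0)])


class TestEventFrequency:
    def test_soma_rate(self):
        res = event_frequency(3, "rest", "soma", minutes=100.0 / 60.0)
        assert res.rate == pytest.approx(1.8)
        assert res.units == "events per min"

    def test_dendrite_area_normalization(self):
        res = event_frequency(1, "rest", "dendrite", minutes=1.0, area_um2=500.0)
        assert res.rate == pytest.approx(2.0)
        assert "1000 um2" in res.units

    def test_zero_events(self):
        assert event_frequency(0, "rest", "soma", minutes=5.0).rate == 0.0

    def test_dendrite_without_area_rejected(self):
        with pytest.raises(ValueError):
            event_frequency(1, "rest", "dendrite", minutes=1.0)

    def test_nonpositive_exposure_rejected(self):
        with pytest.raises(ValueError):
            event_frequency(1, "rest", "soma", minutes=0.0)


class TestCompareGroups:
    def test_identical_normal_groups_not_significant(self, rng):
        g = rng.normal(0, 1, 10)
        res = compare_groups([g, g.copy()])
        assert res.p_value > 0.05

    def test_clear_shift_detected_consistently(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            res = compare_groups([r.normal(0, 1, 20), r.normal(3, 1, 20)])
            hits += res.p_value < 0.05
        assert hits == 20

    def test_skewed_groups_take_nonparametric_branch(self, rng):
        a = np.exp(rng.normal(0, 1.5, 40))
        b = np.exp(rng.normal(0.2, 1.5, 40))
        res = compare_groups([a, b])
        assert not res.parametric
        assert res.test_name == "mann_whitney"

    def test_three_group_parametric_with_posthoc(self, rng):
        groups = [rng.normal(m, 1, 25) for m in (0.0, 0.0, 2.5)]
        res = compare_groups(groups, labels=["a", "b", "c"])
        assert res.test_name in ("anova", "kruskal_wallis")
        assert res.p_value < 0.05
        assert res.posthoc is not None
        worst = res.posthoc.sort_values("p_adj").iloc[0]
        assert {worst["group_a"], worst["group_b"]} & {"c"}

    def test_three_group_nonparametric_uses_dunn(self, rng):
        groups = [np.exp(rng.normal(m, 1.2, 30)) for m in (0.0, 0.0, 2.0)]
        res = compare_groups(groups)
        assert res.test_name == "kruskal_wallis"
        assert res.posthoc is not None
        assert (res.posthoc["method"] == "dunn_sidak").all()

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_groups([rng.normal(0, 1, 10), np.array([1.0, 2.0])])

    def test_type_one_error_calibration(self):
        """Null rejection rate of the two-group path stays near nominal."""
        rejections = 0
        reps = 2000
        r = np.random.default_rng(2024)
        for _ in range(reps):
            res = compare_groups([r.normal(0, 1, 10), r.normal(0, 1, 10)])
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestBuildReport:
    def _session_tables(self):
        events = []
        for roi, peak in (("r0", 30.0), ("r1", 10.0), ("r2", 20.0)):
            events.append(_ev(5.0, roi=roi, peak=peak))
            events.append(_ev(150.0, roi=roi))
            events.append(_ev(150.0, channel="mito", roi=roi))
        for e in events:
            e.stage = "run" if 100.0 <= e.onset_s < 200.0 else "pre_run"
            e.event_id = f"{e.roi_id}/{e.channel}/{e.onset_s}"
        from mitocoupling.pipeline import events_to_frame
        ev = events_to_frame(events)
        fid = pd.DataFrame([
            {"roi_id": r, "stage": s, "n_cyto": 1, "n_mito": m,
             "fidelity_pct": 100.0 * m, "defined": True, "over_100": False}
            for r in ("r0", "r1", "r2")
            for s, m in (("pre_run", 0), ("run", 1))
        ])
        meta = pd.DataFrame({
            "roi_id": ["r0", "r1", "r2"], "trial": 0, "compartment": "soma",
            "sampling_rate_hz": 1.0, "roi_area_um2": np.nan,
        })
        stages = pd.DataFrame([
            {"roi_id": r, "trial": 0, "stage": s, "t_start_s": a, "t_end_s": b}
            for r in ("r0", "r1", "r2")
            for s, a, b in (("pre_run", 0.0, 100.0), ("run", 100.0, 200.0))
        ])
        return ev, fid, meta, stages

    def test_one_row_per_compartment_stage(self):
        ev, fid, meta, stages = self._session_tables()
        rep = build_report(ev, fid, meta, stages)
        assert len(rep["summary"]) == 2
        assert set(rep["summary"]["stage"]) == {"pre_run", "run"}

    def test_frequencies_and_fidelity_summaries(self):
        ev, fid, meta, stages = self._session_tables()
        rep = build_report(ev, fid, meta, stages)
        run = rep["summary"].set_index("stage").loc["run"]
        # one cyto event per ROI in 100 s -> 0.6 events/min
        assert run["cyto_rate_mean"] == pytest.approx(0.6)
        assert run["fidelity_pct_mean"] == pytest.approx(100.0)
        pre = rep["summary"].set_index("stage").loc["pre_run"]
        assert pre["mito_rate_mean"] == 0.0
        assert pre["fidelity_pct_mean"] == pytest.approx(0.0)

    def test_heatmap_rows_sorted_by_cyto_peak_time(self):
        ev, fid, meta, stages = self._session_tables()
        order = build_report(ev, fid, meta, stages)["heatmap_order"]
        # largest-amplitude event is at 5 s for each ROI; peaks 30, 10, 20
        assert order["roi_id"].tolist() == ["r1", "r2", "r0"]

    def test_missing_stages_rejected(self):
        ev, fid, meta, _ = self._session_tables()
        with pytest.raises(ValueError):
            build_report(ev, fid, meta, pd.DataFrame())
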