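"""Event pairing, coupling fidelity, contrasts, regression, latency."""

import math

import numpy as np
import pytest

from mitocoupling.coupling_analysis import (
    amplitude_correlation,
    coupled_vs_uncoupled_stats,
    coupling_fidelity,
    latency_summary,
    pair_events,
)
from mitocoupling.event_detection import CaEvent
from mitocoupling.pipeline import analyze_session
from mitocoupling.synthetic_data import LogNormal, SimConfig, simulate_session


def _ev(channel, onset, amp=30.0, dur=3.0, roi="r0"):
    return CaEvent(channel=channel, onset_s=onset, offset_s=onset + dur,
                   peak_amp_pct=amp, peak_time_s=onset + 1.0, roi_id=roi)


class TestPairEvents:
    def test_simple_pair_and_latency(self):
        pairs = pair_events([_ev("cyto", 10.0)], [_ev("mito", 12.0)], l_max_s=6.0)
        assert len(pairs) == 1 and not pairs[0].orphan
        assert pairs[0].latency_s == pytest.approx(2.0)

    def test_trigger_too_old_gives_orphan(self):
        pairs = pair_events([_ev("cyto", 1.0)], [_ev("mito", 10.0)], l_max_s=6.0)
        assert pairs[0].orphan

    def test_latest_onset_wins(self):
        cyto = [_ev("cyto", 10.0), _ev("cyto", 13.0)]
        pairs = pair_events(cyto, [_ev("mito", 14.0)], l_max_s=6.0)
        assert pairs[0].cyto_event.onset_s == 13.0
        assert pairs[0].latency_s == pytest.approx(1.0)

    def test_onset_tie_broken_by_amplitude(self):
        cyto = [_ev("cyto", 10.0, amp=20.0), _ev("cyto", 10.0, amp=50.0)]
        pairs = pair_events(cyto, [_ev("mito", 12.0)], l_max_s=6.0)
        assert pairs[0].cyto_event.peak_amp_pct == 50.0

    def test_one_cyto_triggers_at_most_one_mito(self):
        cyto = [_ev("cyto", 10.0)]
        mito = [_ev("mito", 11.0), _ev("mito", 14.0)]
        pairs = pair_events(cyto, mito, l_max_s=6.0)
        assert sum(not p.orphan for p in pairs) == 1
        assert sum(p.orphan for p in pairs) == 1

    def test_small_negative_latency_within_delta_pre(self):
        pairs = pair_events([_ev("cyto", 12.5)], [_ev("mito", 12.0)],
                            delta_pre_s=1.0, l_max_s=6.0)
        assert pairs[0].latency_s == pytest.approx(-0.5)

    def test_permutation_stability(self, rng):
        cyto = [_ev("cyto", t) for t in rng.uniform(0, 500, 40)]
        mito = [_ev("mito", t) for t in rng.uniform(0, 500, 10)]
        ref = pair_events(cyto, mito, l_max_s=6.0)
        perm = pair_events(list(reversed(cyto)), list(np.random.default_rng(1).permutation(mito)),
                           l_max_s=6.0)
        key = lambda p: (p.mito_event.onset_s,
                         None if p.orphan else p.cyto_event.onset_s)
        assert sorted(map(key, ref)) == sorted(map(key, perm))

    def test_conservation_pairs_plus_orphans(self, rng):
        cyto = [_ev("cyto", t) for t in rng.uniform(0, 300, 25)]
        mito = [_ev("mito", t) for t in rng.uniform(0, 300, 12)]
        pairs = pair_events(cyto, mito, l_max_s=6.0)
        assert len(pairs) == 12

    def test_mixed_rois_rejected(self):
        with pytest.raises(ValueError):
            pair_events([_ev("cyto", 1.0, roi="a")], [_ev("mito", 2.0, roi="b")])


class TestCouplingFidelity:
    def test_formula(self):
        res = coupling_fidelity([_ev("cyto", t) for t in range(20)],
                                [_ev("mito", 5.0)])
        assert res.fidelity_pct == pytest.approx(5.0)

    def test_no_mito_gives_zero(self):
        res = coupling_fidelity([_ev("cyto", 1.0)], [])
        assert res.fidelity_pct == 0.0

    def test_zero_cyto_is_undefined(self):
        res = coupling_fidelity([], [_ev("mito", 1.0)])
        assert not res.defined and res.n_mito == 1

    def test_over_100_flagged(self):
        res = coupling_fidelity([_ev("cyto", 1.0)], [_ev("mito", 2.0), _ev("mito", 50.0)])
        assert res.over_100

    def test_staircase_counts_once_by_default(self):
        m = _ev("mito", 5.0)
        m.n_steps = 3
        cyto = [_ev("cyto", t) for t in range(10)]
        assert coupling_fidelity(cyto, [m]).fidelity_pct == pytest.approx(10.0)
        assert coupling_fidelity(cyto, [m], count_steps=True).fidelity_pct == pytest.approx(30.0)


def test_bernoulli_fidelity_recovery_bound():
    """Zero-noise pipeline fidelity within 3*sqrt(p(1-p)/n) of p = 0.5."""
    cfg = SimConfig(
        stage_schedule=[("rest", 600.0, 0.5)],
        p_couple={"rest": 0.5},
        cyto_amp=LogNormal(30.0, 0.2),
        cyto_dur=LogNormal(5.0, 0.2),
        mito_dur=LogNormal(10.0, 0.3),
        noise_sigma_pct=0.0,
        sampling_rate_hz=2.0,
        compartment="dendrite",
    )
    recordings, log = simulate_session(cfg, 40, seed=3)
    tables = analyze_session(recordings)
    ev = tables["events"]
    n_cyto = int((ev["channel"] == "cyto").sum())
    n_mito = int((ev["channel"] == "mito").sum())
    bound = 3.0 * math.sqrt(0.25 / n_cyto)
    assert abs(n_mito / n_cyto - 0.5) <= bound + 0.05  # small collision allowance


class TestCoupledVsUncoupled:
    def test_group_means(self):
        cyto = [_ev("cyto", 0.0, amp=30.0), _ev("cyto", 10.0, amp=40.0),
                _ev("cyto", 20.0, amp=10.0), _ev("cyto", 30.0, amp=20.0)]
        pairs = pair_events(cyto[:2] + cyto[2:],
                            [_ev("mito", 1.0), _ev("mito", 11.0)], l_max_s=6.0)
        table = coupled_vs_uncoupled_stats(cyto, pairs)
        amp = table[table["metric"] == "peak_amp_pct"].iloc[0]
        assert amp["coupled_mean"] == pytest.approx(35.0)
        assert amp["uncoupled_mean"] == pytest.approx(15.0)

    def test_small_groups_skip_test(self):
        cyto = [_ev("cyto", 0.0), _ev("cyto", 10.0)]
        pairs = pair_events(cyto, [_ev("mito", 1.0)], l_max_s=6.0)
        table = coupled_vs_uncoupled_stats(cyto, pairs)
        assert table["test"].str.startswith("skipped").all()

    def test_amplitude_dependent_coupling_detected(self, rng):
        # logistic amplitude->coupling: coupled mean amplitude exceeds
        # uncoupled in nearly every seeded run
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            amps = 30.0 * np.exp(0.4 * r.standard_normal(120))
            onsets = np.sort(r.uniform(0, 6000, 120))
            p = 1.0 / (1.0 + np.exp(-(amps - 30.0) / 10.0))
            coupled = r.random(120) < p
            cyto = [_ev("cyto", t, amp=a) for t, a in zip(onsets, amps)]
            mito = [_ev("mito", t + 2.0) for t, c in zip(onsets, coupled) if c]
            pairs = pair_events(cyto, mito, l_max_s=6.0)
            table = coupled_vs_uncoupled_stats(cyto, pairs)
            amp_row = table[table["metric"] == "peak_amp_pct"].iloc[0]
            wins += amp_row["coupled_mean"] > amp_row["uncoupled_mean"]
        assert wins >= 19


class TestAmplitudeCorrelation:
    def _pairs(self, x, y):
        cyto = [_ev("cyto", 10.0 * i, amp=a) for i, a in enumerate(x)]
        mito = [_ev("mito", 10.0 * i + 1.0, amp=b) for i, b in enumerate(y)]
        return pair_events(cyto, mito, l_max_s=6.0)

    def test_exact_line(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        res = amplitude_correlation(self._pairs(x, 2.0 * x))
        assert res["slope"] == pytest.approx(2.0)
        assert res["r"] == pytest.approx(1.0)

    def test_constant_response(self):
        x = np.array([10.0, 20.0, 30.0])
        res = amplitude_correlation(self._pairs(x, np.full(3, 5.0)))
        assert res["slope"] == 0.0 and res["r"] == 0.0

    def test_recovers_simulated_slope(self, rng):
        x = rng.uniform(10, 60, 100)
        y = 0.8 * x + rng.normal(0, 0.1, 100)
        res = amplitude_correlation(self._pairs(x, y))
        assert res["slope"] == pytest.approx(0.8, abs=0.06)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            amplitude_correlation(self._pairs(np.full(4, 30.0), np.arange(4.0)))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            amplitude_correlation(self._pairs(np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestLatencySummary:
    def test_basic_stats(self):
        cyto = [_ev("cyto", 0.0), _ev("cyto", 10.0), _ev("cyto", 20.0)]
        mito = [_ev("mito", 1.0), _ev("mito", 12.0), _ev("mito", 23.0)]
        summary = latency_summary(pair_events(cyto, mito, l_max_s=6.0))
        assert summary["mean_s"] == pytest.approx(2.0)
        assert summary["max_s"] == pytest.approx(3.0)
        assert summary["hist_counts"].sum() == 3

    def test_empty_summary(self):
        assert latency_summary([])["n"] == 0

    def test_gamma_sample_mean(self, rng):
        lat = rng.gamma(2.0, 1.05, 1000)
        cyto = [_ev("cyto", 20.0 * i) for i in range(1000)]
        mito = [_ev("mito", 20.0 * i + l) for i, l in enumerate(lat)]
        summary = latency_summary(pair_events(cyto, mito, l_max_s=12.0))
        assert summary["mean_s"] == pytest.approx(2.1, abs=0.15)
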