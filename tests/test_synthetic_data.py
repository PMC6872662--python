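"""Generator: point process, marks, coupling decisions, integrator, rendering."""

import dataclasses
import math

import numpy as np
import pytest

import mitocoupling as mc
from mitocoupling.synthetic_data import (
    EDGE_GUARD_S,
    LogNormal,
    SimConfig,
    TrueCytoEvent,
    TrueMitoEvent,
    decide_couplings,
    integrator_response,
    min_crossing_frequency,
    render_session,
    sample_cyto_events,
    simulate_session,
)


class TestCytoPointProcess:
    def test_zero_rate_gives_no_events(self, rng):
        events = sample_cyto_events([("rest", 600.0, 0.0)], LogNormal(30, 0.4),
                                    LogNormal(2.5, 0.6), rng)
        assert events == []

    def test_poisson_count_within_tail_bound(self, rng):
        # 6/min over 1000 min: count within 3*sqrt(6000) of 6000
        events = sample_cyto_events([("s", 60_000.0, 6.0)], LogNormal(30, 0.4),
                                    LogNormal(2.5, 0.6), rng)
        assert abs(len(events) - 6000) <= 3 * math.sqrt(6000)

    def test_onsets_sorted_and_stage_labelled(self, rng):
        events = sample_cyto_events(
            [("pre", 100.0, 2.0), ("run", 100.0, 4.0)],
            LogNormal(30, 0.4), LogNormal(2.5, 0.6), rng)
        onsets = [e.onset_s for e in events]
        assert onsets == sorted(onsets)
        for e in events:
            assert e.stage == ("pre" if e.onset_s < 100.0 else "run")

    def test_duration_median_converges(self, rng):
        d = LogNormal(2.5, 0.6).sample(rng, 100_000)
        assert np.median(d) == pytest.approx(2.5, abs=0.05)


class TestIntegrator:
    def test_constant_input_steady_state(self):
        k, tau, c, dt = 2.0, 3.0, 5.0, 0.01
        a = integrator_response(np.full(int(10 * tau / dt), c), k, tau, dt)
        assert a[-1] == pytest.approx(k * c * tau, rel=0.01)

    def test_efold_decay_after_input_stops(self):
        tau, dt = 3.0, 0.05
        c = np.zeros(2000)
        c[:400] = 1.0
        a = integrator_response(c, 1.0, tau, dt)
        i0 = 500
        i1 = i0 + int(tau / dt)
        assert a[i1] / a[i0] == pytest.approx(math.exp(-1.0), abs=1e-6)

    @pytest.mark.parametrize("f", [2, 5, 13])
    def test_impulse_train_matches_geometric_series(self, f):
        # peak after n impulses = (1 - r^n) / (1 - r), r = exp(-1/(f*tau))
        tau = 3.0
        n = 5 * f
        dt = 1.0 / f
        impulses = np.full(n, 1.0 / dt)
        a = integrator_response(impulses, 1.0, tau, dt)
        r = math.exp(-1.0 / (f * tau))
        assert a[-1] == pytest.approx((1 - r ** n) / (1 - r), rel=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(0, 10, 200)
        a1 = integrator_response(c, 1.0, 3.0, 0.5)
        a3 = integrator_response(3.0 * c, 1.0, 3.0, 0.5)
        assert np.allclose(a3, 3.0 * a1)

    def test_min_crossing_frequency_well_defined(self):
        # below threshold at every frequency when theta is out of reach
        assert min_crossing_frequency(theta=1e9) is None
        with pytest.raises(ValueError):
            min_crossing_frequency(theta=-1.0)


class TestCouplingDecisions:
    def _cyto(self, rng, rate=2.0, minutes=200.0, p=0.5):
        cfg = SimConfig(stage_schedule=[("rest", minutes * 60.0, rate)],
                        p_couple={"rest": p})
        events = sample_cyto_events(cfg.stage_schedule, cfg.cyto_amp,
                                    cfg.cyto_dur, rng)
        return cfg, events

    def test_p_one_links_every_event(self, rng):
        cfg, cyto = self._cyto(rng, rate=0.5, minutes=60.0, p=1.0)
        mito, links = decide_couplings(cyto, cfg, rng,
                                       trial_duration_s=cfg.trial_duration_s)
        triggered_ids = {l.cyto_id for l in links if l.triggered}
        eligible = [c for c in cyto]  # edge-guarded events already dropped
        # every cyto event triggers; some initiations near the end are
        # discarded by the edge guard
        late = {c.event_id for c in cyto
                if c.onset_s > cfg.trial_duration_s - 2 * EDGE_GUARD_S}
        assert {c.event_id for c in eligible} - late <= triggered_ids

    def test_p_zero_gives_no_mito_events(self, rng):
        cfg, cyto = self._cyto(rng, p=0.0)
        mito, links = decide_couplings(cyto, cfg, rng)
        assert mito == [] and links == []

    def test_triggered_fraction_matches_p(self, rng):
        # p=0.5 over ~10^4 events: fraction within the 3-sigma binomial band
        cfg, cyto = self._cyto(rng, rate=2.0, minutes=5000.0, p=0.5)
        assert len(cyto) > 8000
        mito, links = decide_couplings(cyto, cfg, rng,
                                       trial_duration_s=cfg.trial_duration_s)
        frac = len({l.cyto_id for l in links if l.triggered}) / len(cyto)
        assert frac == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(len(cyto)))

    def test_latencies_nonnegative_and_gamma_mean(self, rng):
        cfg, cyto = self._cyto(rng, rate=1.0, minutes=2000.0, p=1.0)
        _, links = decide_couplings(cyto, cfg, rng,
                                    trial_duration_s=cfg.trial_duration_s)
        lat = np.array([l.latency_s for l in links if not l.is_step])
        assert (lat >= 0).all()
        assert lat.mean() == pytest.approx(2.1, abs=0.15)

    def test_ground_truth_invariants(self, rng):
        cfg, cyto = self._cyto(rng, rate=1.0, minutes=500.0, p=0.3)
        mito, links = decide_couplings(cyto, cfg, rng,
                                       trial_duration_s=cfg.trial_duration_s)
        log = mc.GroundTruthLog(cyto_events=cyto, mito_events=mito, links=links)
        log.validate()  # every mito linked; staircases have >= 2 distinct triggers
        # mitochondrial transients never overlap
        spans = sorted((m.onset_s, m.end_s) for m in mito)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 >= e1

    def test_integrator_mode_fires_on_threshold_crossing(self, rng):
        cfg = SimConfig(
            stage_schedule=[("stim", 120.0, 0.0)],
            coupling_model="integrator",
            integrator_k=1.0, integrator_tau_s=3.0, integrator_theta=50.0,
            mito_dur=LogNormal(20.0, 0.3),
            sampling_rate_hz=2.0,
        )
        # one large cytosolic event: activity integrates over its plateau
        cyto = [TrueCytoEvent("c0", 20.0, 60.0, 10.0, "stim")]
        mito, links = decide_couplings(cyto, cfg, rng, trial_duration_s=120.0)
        assert len(mito) == 1
        assert links[0].cyto_id == "c0"
        assert links[0].latency_s > 0
        # with an unreachable threshold: silence
        cfg2 = dataclasses.replace(cfg, integrator_theta=1e6)
        mito2, _ = decide_couplings(cyto, cfg2, rng, trial_duration_s=120.0)
        assert mito2 == []


class TestRendering:
    def test_isolated_event_peak_matches_amplitude(self, rng, clean_config):
        ev = TrueCytoEvent("c0", 100.0, 30.0, 5.0, "rest")
        rec, _ = render_session([ev], [], [], clean_config, rng, duration_s=300.0)
        dff = (rec.raw_f["cyto"] / 100.0 - 1.0) * 100.0
        assert dff.max() == pytest.approx(30.0, abs=0.3)

    def test_rendered_width_matches_drawn_duration(self, rng, clean_config):
        for d in (2.0, 4.0, 8.0):
            ev = TrueCytoEvent("c0", 100.25, 30.0, d, "rest")
            rec, _ = render_session([ev], [], [], clean_config, rng,
                                    duration_s=300.0)
            dff = (rec.raw_f["cyto"] / 100.0 - 1.0) * 100.0
            width = (dff > 3.0).sum() / clean_config.sampling_rate_hz
            assert width == pytest.approx(d, abs=1.0)

    def test_noise_sd_calibration(self, rng):
        cfg = SimConfig(stage_schedule=[("rest", 50_000.0, 0.0)],
                        p_couple={"rest": 0.0}, noise_sigma_pct=1.0)
        rec, _ = render_session([], [], [], cfg, rng)
        dff = (rec.raw_f["cyto"] / cfg.f_base - 1.0) * 100.0
        assert np.std(dff) == pytest.approx(1.0, abs=0.02)

    def test_staircase_renders_distinct_steps(self, rng, clean_config):
        m = TrueMitoEvent("m0", 50.0, 120.0, "staircase",
                          step_onsets_s=[50.0, 80.0, 110.0],
                          step_amps_pct=[30.0, 30.0, 30.0])
        rec, _ = render_session([], [m], [], clean_config, rng, duration_s=300.0)
        dff = (rec.raw_f["mito"] / 100.0 - 1.0) * 100.0
        t = rec.time_s
        # levels between steps approximate the cumulative step amplitudes
        assert np.median(dff[(t > 65) & (t < 78)]) == pytest.approx(30.0, abs=2.0)
        assert np.median(dff[(t > 95) & (t < 108)]) == pytest.approx(60.0, abs=2.0)
        assert np.median(dff[(t > 125) & (t < 140)]) == pytest.approx(90.0, abs=2.0)

    def test_negative_f_base_rejected(self, rng, clean_config):
        bad = dataclasses.replace(clean_config, f_base=-1.0)
        with pytest.raises(ValueError):
            render_session([], [], [], bad, rng)


class TestSessionDeterminism:
    def test_identical_seed_identical_session(self):
        cfg = mc.get_preset("REST-DEND")
        a_recs, a_log = simulate_session(cfg, 3, duration_s=300.0, seed=42)
        b_recs, b_log = simulate_session(cfg, 3, duration_s=300.0, seed=42)
        for ra, rb in zip(a_recs, b_recs):
            for ch in ra.raw_f:
                assert np.array_equal(ra.raw_f[ch], rb.raw_f[ch])
        assert len(a_log.cyto_events) == len(b_log.cyto_events)
        for ea, eb in zip(a_log.cyto_events, b_log.cyto_events):
            assert ea == eb

    def test_different_seeds_differ(self):
        cfg = mc.get_preset("REST-DEND")
        a, _ = simulate_session(cfg, 1, duration_s=300.0, seed=1)
        b, _ = simulate_session(cfg, 1, duration_s=300.0, seed=2)
        assert not np.array_equal(a[0].raw_f["cyto"], b[0].raw_f["cyto"])


def test_preset_catalogue_is_valid():
    for name in mc.PRESETS:
        cfg = mc.get_preset(name)
        assert sum(cfg.type_probs) == pytest.approx(1.0)
        for stage, p in cfg.p_couple.items():
            assert 0.0 <= p <= 1.0
    with pytest.raises(KeyError):
        mc.get_preset("NO-SUCH-PRESET")
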