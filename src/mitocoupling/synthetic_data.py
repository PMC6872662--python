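"""Synthetic two-channel calcium-imaging sessions with known ground truth.

Cytosolic transients form a rate-modulated marked point process (log-normal
amplitude and duration marks, per-stage constant rates); mitochondrial
transients are coupled to them either by a per-event Bernoulli trigger with
gamma-distributed latency or by a CaMKII-like leaky integrator that fires on
threshold crossings of an activity variable accumulating recent cytosolic
dF/F.  Rendered traces add Gaussian photon noise around a baseline
fluorescence; every drawn event and coupling link is recorded in a
:class:`GroundTruthLog` so each pipeline stage can be validated against
truth.

The preset configurations encode the study conditions the analyses target:
resting/running dendritic (2 Hz) and somatic (1 Hz) sessions with coupling
probabilities mirroring the reported coupling fidelities, and an in vitro
integrator preset whose 5-s stimulation trains (1-15 Hz) reproduce the
observed 13-Hz threshold for robust coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import Recording

LN10 = math.log(10.0)

#: Mitochondrial events whose onset falls closer than this to the end of a
#: trial are discarded: they cannot rise far enough to be a measurable
#: transient within the acquisition.
EDGE_GUARD_S = 3.0


# ---------------------------------------------------------------------------
# Mark distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogNormal:
    """Log-normal parameterized by its median and log-space SD."""

    median: float
    sigma_log: float

    def __post_init__(self):
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma_log * rng.standard_normal(n))

    def sf(self, x: float) -> float:
        """P(X >= x)."""
        from scipy.stats import norm
        return float(norm.sf(math.log(x / self.median) / self.sigma_log))


@dataclass(frozen=True)
class Gamma:
    shape: float
    scale: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size=n)

    @property
    def mean(self) -> float:
        return self.shape * self.scale


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generative parameters of one simulated session.

    ``stage_schedule`` lists (label, duration_s, cyto_rate_per_min) in trial
    order; one pass through the schedule is one trial (one acquisition).
    ``p_couple`` maps stage labels to the per-event Bernoulli trigger
    probability (bernoulli mode).  Amplitudes are % dF/F, durations seconds.
    """

    stage_schedule: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("rest", 600.0, 0.5)])
    p_couple: dict[str, float] = field(default_factory=lambda: {"rest": 0.033})
    coupling_model: str = "bernoulli"        # 'bernoulli' | 'integrator'
    cyto_amp: LogNormal = LogNormal(30.0, 0.4)
    mito_amp: LogNormal = LogNormal(40.0, 0.4)
    cyto_dur: LogNormal = LogNormal(2.5, 0.6)
    mito_dur: LogNormal = LogNormal(90.0, 0.5)
    rise_time_cyto_s: float = 1.0
    rise_time_mito_s: float = 2.5            # mid of the observed 2-3 s rise
    latency: Gamma = Gamma(2.0, 1.05)        # mean 2.1 s
    type_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    integrator_k: float = 1.0                # activity gain per (% * s)
    integrator_tau_s: float = 3.0
    integrator_theta: float = 31.0
    noise_sigma_pct: float = 1.0
    f_base: float = 100.0
    drift_amp_pct: float = 0.0
    drift_period_s: float = 120.0
    sampling_rate_hz: float = 2.0
    compartment: str = "dendrite"
    roi_area_um2: float | None = 500.0

    def __post_init__(self):
        if abs(sum(self.type_probs) - 1.0) > 1e-9:
            raise ValueError("type_probs must sum to 1")
        for _, dur, rate in self.stage_schedule:
            if rate < 0 or dur <= 0:
                raise ValueError("stage durations must be > 0 and rates >= 0")
        if self.integrator_tau_s <= 0:
            raise ValueError("integrator_tau_s must be > 0")

    @property
    def trial_duration_s(self) -> float:
        return sum(d for _, d, _ in self.stage_schedule)

    def stage_of(self, t: float) -> str:
        start = 0.0
        for label, dur, _ in self.stage_schedule:
            if start <= t < start + dur:
                return label
            start += dur
        return self.stage_schedule[-1][0]

    def stage_intervals(self) -> list[tuple[str, float, float]]:
        out, start = [], 0.0
        for label, dur, _ in self.stage_schedule:
            out.append((label, start, start + dur))
            start += dur
        return out


def _preset_configs() -> dict[str, SimConfig]:
    rest_dend = SimConfig(
        stage_schedule=[("rest", 600.0, 0.5)],
        p_couple={"rest": 0.033},
        sampling_rate_hz=2.0, compartment="dendrite",
    )
    run_dend = SimConfig(
        # sustained running-stage conditions (~2-fold the resting rate)
        stage_schedule=[("run", 600.0, 1.0)],
        p_couple={"run": 0.193},
        sampling_rate_hz=2.0, compartment="dendrite",
    )
    rest_soma = SimConfig(
        stage_schedule=[("rest", 600.0, 0.33)],
        p_couple={"rest": 0.035},
        sampling_rate_hz=1.0, compartment="soma", roi_area_um2=None,
    )
    run_soma = SimConfig(
        stage_schedule=[("run", 600.0, 0.66)],
        p_couple={"run": 0.139},
        sampling_rate_hz=1.0, compartment="soma", roi_area_um2=None,
    )
    # the exercise protocol: 300-frame trials, middle third stimulated
    trial_dend = SimConfig(
        stage_schedule=[("pre_run", 50.0, 0.5), ("run", 50.0, 1.0), ("post_run", 50.0, 0.5)],
        p_couple={"pre_run": 0.033, "run": 0.193, "post_run": 0.033},
        sampling_rate_hz=2.0, compartment="dendrite",
    )
    trial_soma = SimConfig(
        stage_schedule=[("pre_run", 100.0, 0.33), ("run", 100.0, 0.66), ("post_run", 100.0, 0.33)],
        p_couple={"pre_run": 0.035, "run": 0.139, "post_run": 0.035},
        sampling_rate_hz=1.0, compartment="soma", roi_area_um2=None,
    )
    invitro = SimConfig(
        stage_schedule=[("stim", 60.0, 1.0)],
        p_couple={"stim": 1.0},
        coupling_model="integrator",
        integrator_k=1.0, integrator_tau_s=3.0, integrator_theta=31.0,
        mito_dur=LogNormal(20.0, 0.3),
        noise_sigma_pct=0.5,
        sampling_rate_hz=2.0, compartment="in_vitro", roi_area_um2=None,
    )
    return {
        "REST-DEND": rest_dend,
        "RUN-DEND": run_dend,
        "REST-SOMA": rest_soma,
        "RUN-SOMA": run_soma,
        "TRIAL-DEND": trial_dend,
        "TRIAL-SOMA": trial_soma,
        "INVITRO": invitro,
    }


PRESETS = _preset_configs()


def get_preset(name: str, **overrides) -> SimConfig:
    """A fresh copy of a named preset, optionally with field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class TrueCytoEvent:
    event_id: str
    onset_s: float
    amplitude_pct: float
    duration_s: float
    stage: str
    roi_id: str = ""
    trial: int = 0


@dataclass
class TrueMitoEvent:
    event_id: str
    onset_s: float
    duration_s: float
    kinetic_type: str = ""          # assigned after step structure is known
    step_onsets_s: list[float] = field(default_factory=list)
    step_amps_pct: list[float] = field(default_factory=list)
    roi_id: str = ""
    trial: int = 0

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def amplitude_pct(self) -> float:
        return float(sum(self.step_amps_pct))


@dataclass
class CouplingLink:
    """A mito->cyto coupling in the ground truth.

    ``is_step`` marks links that appear as staircase steps rather than the
    initial rise.  ``triggered`` marks Bernoulli successes (independent
    per-event triggers with probability p) — collision steps are triggered,
    steps recruited to give a categorical staircase its kinetics are not.
    """

    mito_id: str
    cyto_id: str
    latency_s: float
    is_step: bool = False
    triggered: bool = True


@dataclass
class GroundTruthLog:
    """The true event and coupling record of a simulated session."""

    cyto_events: list[TrueCytoEvent] = field(default_factory=list)
    mito_events: list[TrueMitoEvent] = field(default_factory=list)
    links: list[CouplingLink] = field(default_factory=list)

    def extend(self, other: "GroundTruthLog") -> None:
        self.cyto_events.extend(other.cyto_events)
        self.mito_events.extend(other.mito_events)
        self.links.extend(other.links)

    def validate(self) -> None:
        linked = {}
        for link in self.links:
            linked.setdefault(link.mito_id, []).append(link)
        for m in self.mito_events:
            if m.event_id not in linked:
                raise ValueError(f"mito event {m.event_id} has no coupling link")
            if m.kinetic_type == "staircase":
                if len(m.step_onsets_s) < 2:
                    raise ValueError(f"staircase {m.event_id} has < 2 steps")
                cyto_ids = [lk.cyto_id for lk in linked[m.event_id]]
                if len(set(cyto_ids)) != len(cyto_ids):
                    raise ValueError(f"staircase {m.event_id} reuses a cyto trigger")

    def to_frames(self) -> dict[str, pd.DataFrame]:
        cyto = pd.DataFrame([{
            "event_id": e.event_id, "roi_id": e.roi_id, "trial": e.trial,
            "channel": "cyto", "onset_s": e.onset_s, "amplitude_pct": e.amplitude_pct,
            "duration_s": e.duration_s, "stage": e.stage, "kinetic_type": "",
            "n_steps": 1,
        } for e in self.cyto_events])
        mito = pd.DataFrame([{
            "event_id": e.event_id, "roi_id": e.roi_id, "trial": e.trial,
            "channel": "mito", "onset_s": e.onset_s, "amplitude_pct": e.amplitude_pct,
            "duration_s": e.duration_s, "stage": "", "kinetic_type": e.kinetic_type,
            "n_steps": len(e.step_onsets_s),
        } for e in self.mito_events])
        cols = ["event_id", "roi_id", "trial", "channel", "onset_s", "amplitude_pct",
                "duration_s", "stage", "kinetic_type", "n_steps"]
        events = pd.concat([f for f in (cyto, mito) if len(f)], ignore_index=True) \
            if (len(cyto) or len(mito)) else pd.DataFrame(columns=cols)
        links = pd.DataFrame(
            [{"mito_id": lk.mito_id, "cyto_id": lk.cyto_id, "latency_s": lk.latency_s,
              "is_step": lk.is_step, "triggered": lk.triggered} for lk in self.links],
            columns=["mito_id", "cyto_id", "latency_s", "is_step", "triggered"])
        return {"true_events": events.reindex(columns=cols), "true_links": links}


# ---------------------------------------------------------------------------
# Cytosolic point process
# ---------------------------------------------------------------------------

def sample_cyto_events(
    schedule: list[tuple[str, float, float]],
    amp_dist: LogNormal,
    dur_dist: LogNormal,
    rng: np.random.Generator,
    *,
    roi_id: str = "",
    trial: int = 0,
) -> list[TrueCytoEvent]:
    """Draw one trial of cytosolic events (inhomogeneous Poisson, per-stage
    constant rate; i.i.d. log-normal amplitude and duration marks).

    Onsets are sorted; events overlapping a stage boundary keep their drawn
    duration.  Onsets inside the trailing edge guard are discarded (they
    cannot form a measurable transient before the acquisition ends).
    """
    onsets, stages = [], []
    start = 0.0
    total = sum(d for _, d, _ in schedule)
    for label, dur, rate_per_min in schedule:
        n = rng.poisson(rate_per_min * dur / 60.0)
        ts = np.sort(start + rng.uniform(0.0, dur, size=n))
        onsets.extend(ts)
        stages.extend([label] * n)
        start += dur
    events = []
    order = np.argsort(onsets, kind="stable")
    amps = amp_dist.sample(rng, len(onsets))
    durs = dur_dist.sample(rng, len(onsets))
    idx = 0
    for j in order:
        if onsets[j] > total - EDGE_GUARD_S:
            continue
        events.append(TrueCytoEvent(
            event_id=f"{roi_id}/t{trial}/cyto/{idx}",
            onset_s=float(onsets[j]),
            amplitude_pct=float(amps[j]),
            duration_s=float(durs[j]),
            stage=stages[j],
            roi_id=roi_id,
            trial=trial,
        ))
        idx += 1
    return events


# ---------------------------------------------------------------------------
# Leaky-integrator frequency decoder
# ---------------------------------------------------------------------------

def integrator_response(clean_cyto_pct: np.ndarray, k: float, tau_a_s: float,
                        dt_s: float) -> np.ndarray:
    """Activity of the CaMKII-like leaky integrator driven by cytosolic dF/F.

    a[i] = a[i-1] * exp(-dt/tau_a) + k * c[i] * dt, a starting from 0: an
    exponentially-forgetting memory of recent cytosolic calcium.  The
    response is non-negative (for non-negative input), linear in the input
    and deterministic; a constant input c settles at ~k*c*tau_a and decays
    e-fold per tau_a once the input stops.
    """
    c = np.asarray(clean_cyto_pct, dtype=float)
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite input")
    decay = math.exp(-dt_s / tau_a_s)
    a = np.empty_like(c)
    acc = 0.0
    drive = k * c * dt_s
    for i in range(c.size):
        acc = acc * decay + drive[i]
        a[i] = acc
    return a


def min_crossing_frequency(
    tau_a_s: float = 3.0,
    theta: float = 31.0,
    train_duration_s: float = 5.0,
    freqs_hz: range = range(1, 16),
    impulse_gain: float = 1.0,
) -> int | None:
    """Smallest stimulation frequency whose 5-s impulse train crosses theta.

    Each stimulus contributes a unit impulse (k*A = ``impulse_gain``) to the
    integrator; a train at f Hz delivers f * train_duration_s impulses
    spaced 1/f apart.  After n impulses the activity is
    impulse_gain * (1 - r^n) / (1 - r) with r = exp(-1/(f*tau_a)), so the
    peak response grows with frequency; returns the first integer frequency
    in ``freqs_hz`` whose peak exceeds ``theta`` (None if none does).
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    for f in freqs_hz:
        dt = 1.0 / f
        n = int(round(train_duration_s * f))
        impulses = np.full(n, impulse_gain / (dt * 1.0))  # k=1: c*dt = gain
        a = integrator_response(impulses, k=1.0, tau_a_s=tau_a_s, dt_s=dt)
        if float(np.max(a)) > theta:
            return int(f)
    return None


# ---------------------------------------------------------------------------
# Coupling decisions
# ---------------------------------------------------------------------------

_TYPES = ("regular", "plateaued", "staircase")


def _assign_types(
    mito_events: list[TrueMitoEvent],
    links: list[CouplingLink],
    cyto_events: list[TrueCytoEvent],
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    staircase_prob_extra: bool = True,
) -> None:
    """Finalize kinetic types; categorical staircases borrow step triggers.

    Events that already accumulated >= 2 step onsets (triggers landing
    inside an ongoing transient) are staircases by construction.  Remaining
    events draw from ``cfg.type_probs``; an event drawn as staircase takes
    one or two otherwise non-triggering cytosolic events inside its span as
    step triggers (each linked, with its own latency draw), falling back to
    regular/plateaued when no such candidate exists.
    """
    linked_cyto = {lk.cyto_id for lk in links}
    by_onset = sorted(cyto_events, key=lambda e: e.onset_s)
    for m in mito_events:
        if len(m.step_onsets_s) >= 2:
            m.kinetic_type = "staircase"
            continue
        draw = rng.random()
        if draw < cfg.type_probs[0]:
            m.kinetic_type = "regular"
            continue
        if draw < cfg.type_probs[0] + cfg.type_probs[1]:
            m.kinetic_type = "plateaued"
            continue
        if not staircase_prob_extra:
            m.kinetic_type = "regular" if rng.random() < 0.5 else "plateaued"
            continue
        # staircase: recruit 1-2 unlinked cyto events inside the span whose
        # stepped rise stays clear of the previous step and the event end
        n_extra = 1 + int(rng.random() < 0.5)
        added = 0
        for c in by_onset:
            if added >= n_extra:
                break
            if c.event_id in linked_cyto:
                continue
            lat = float(cfg.latency.sample(rng, 1)[0])
            t_step = c.onset_s + lat
            if (t_step > m.step_onsets_s[-1] + 5.0
                    and t_step < m.end_s - 5.0):
                amp = float(cfg.mito_amp.sample(rng, 1)[0])
                m.step_onsets_s.append(t_step)
                m.step_amps_pct.append(amp)
                links.append(CouplingLink(mito_id=m.event_id, cyto_id=c.event_id,
                                          latency_s=lat, is_step=True, triggered=False))
                linked_cyto.add(c.event_id)
                added += 1
        if added >= 1:
            m.kinetic_type = "staircase"
        else:
            m.kinetic_type = "regular" if rng.random() < 0.5 else "plateaued"


def decide_couplings(
    true_cyto: list[TrueCytoEvent],
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    trial_duration_s: float | None = None,
) -> tuple[list[TrueMitoEvent], list[CouplingLink]]:
    """Decide which cytosolic events trigger mitochondrial transients.

    Bernoulli mode: each cytosolic event triggers independently with its
    stage's probability; the transient initiates after a gamma latency.  A
    trigger landing inside an ongoing mitochondrial transient adds a
    staircase step instead of a new event (mitochondrial transients do not
    overlap).  Integrator mode: the leaky integrator runs over the clean
    cytosolic trace and a transient initiates at each upward crossing of
    theta (crossings during an ongoing transient add steps); the latency is
    the crossing time minus the most recent cytosolic onset.
    """
    total = trial_duration_s if trial_duration_s is not None else (
        max((c.onset_s for c in true_cyto), default=0.0) + EDGE_GUARD_S)
    roi = true_cyto[0].roi_id if true_cyto else ""
    trial = true_cyto[0].trial if true_cyto else 0

    mito_events: list[TrueMitoEvent] = []
    links: list[CouplingLink] = []

    def _initiate(t_init: float, cyto: TrueCytoEvent, latency: float) -> None:
        if t_init > total - EDGE_GUARD_S:
            return
        ongoing = mito_events[-1] if mito_events else None
        amp = float(cfg.mito_amp.sample(rng, 1)[0])
        if ongoing is not None and ongoing.onset_s <= t_init < ongoing.end_s:
            ongoing.step_onsets_s.append(t_init)
            ongoing.step_amps_pct.append(amp)
            links.append(CouplingLink(mito_id=ongoing.event_id, cyto_id=cyto.event_id,
                                      latency_s=latency, is_step=True))
            return
        m = TrueMitoEvent(
            event_id=f"{roi}/t{trial}/mito/{len(mito_events)}",
            onset_s=t_init,
            duration_s=float(cfg.mito_dur.sample(rng, 1)[0]),
            step_onsets_s=[t_init],
            step_amps_pct=[amp],
            roi_id=roi,
            trial=trial,
        )
        mito_events.append(m)
        links.append(CouplingLink(mito_id=m.event_id, cyto_id=cyto.event_id,
                                  latency_s=latency, is_step=False))

    if cfg.coupling_model == "bernoulli":
        triggers = []
        for c in sorted(true_cyto, key=lambda e: e.onset_s):
            p = cfg.p_couple.get(c.stage, 0.0)
            if rng.random() < p:
                latency = float(cfg.latency.sample(rng, 1)[0])
                triggers.append((c.onset_s + latency, c, latency))
        # initiations are not monotone in cyto order (latencies vary):
        # process them in initiation order so the ongoing-event check holds
        for t_init, c, latency in sorted(triggers, key=lambda tr: tr[0]):
            _initiate(t_init, c, latency)
        _assign_types(mito_events, links, true_cyto, cfg, rng)
    elif cfg.coupling_model == "integrator":
        if cfg.integrator_theta <= 0:
            raise ValueError("integrator mode requires theta > 0")
        fs = cfg.sampling_rate_hz
        n = int(round(total * fs))
        t = np.arange(n) / fs
        clean = np.zeros(n)
        for c in sorted(true_cyto, key=lambda e: e.onset_s):
            _add_cyto_waveform(clean, t, c, cfg)
        a = integrator_response(clean, cfg.integrator_k, cfg.integrator_tau_s, 1.0 / fs)
        above = a > cfg.integrator_theta
        crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        onsets = sorted(true_cyto, key=lambda e: e.onset_s)
        for i in crossings:
            t_c = float(t[i])
            recent = [c for c in onsets if c.onset_s <= t_c]
            if not recent:
                continue
            c = recent[-1]
            _initiate(t_c, c, t_c - c.onset_s)
        _assign_types(mito_events, links, true_cyto, cfg, rng,
                      staircase_prob_extra=False)
    else:
        raise ValueError(f"unknown coupling model {cfg.coupling_model!r}")
    return mito_events, links


# ---------------------------------------------------------------------------
# Waveform rendering
# ---------------------------------------------------------------------------

def _rise_hold_decay(
    x: np.ndarray,
    amp: float,
    rise: float,
    hold_end: float,
    tau: float,
    fast_after: float | None = None,
    tau_fast: float = 0.5,
) -> np.ndarray:
    """Linear rise to ``amp`` over ``rise``, hold to ``hold_end`` (times since
    component start), then exponential decay with time constant ``tau``.

    When ``fast_after`` is given the decay accelerates to ``tau_fast`` from
    that time on — the terminal return to baseline is brisk instead of an
    indefinitely slow tail hovering near the detection threshold.
    """
    y = np.zeros_like(x)
    rising = (x >= 0) & (x < rise)
    y[rising] = amp * x[rising] / rise
    holding = (x >= rise) & (x < hold_end)
    y[holding] = amp
    if fast_after is None:
        decaying = x >= hold_end
        y[decaying] = amp * np.exp(-(x[decaying] - hold_end) / tau)
    else:
        fast_after = max(fast_after, hold_end)
        slow = (x >= hold_end) & (x < fast_after)
        y[slow] = amp * np.exp(-(x[slow] - hold_end) / tau)
        v_switch = amp * math.exp(-(fast_after - hold_end) / tau)
        fast = x >= fast_after
        y[fast] = v_switch * np.exp(-(x[fast] - fast_after) / tau_fast)
    return y


#: Reference dF/F level (%) defining the duration semantics of rendered
#: events: a drawn duration is the width of the clean waveform above this
#: level — the detection-relevant width under the default 1% noise and the
#: 3-sigma rule, since the duration models are calibrated to *measured*
#: transient durations.
REF_LEVEL_PCT = 3.0


def _decay_tau(amp: float, duration: float, rise: float, hold: float) -> float:
    """Decay constant putting the downward REF_LEVEL crossing at ``duration``."""
    log_ratio = max(math.log(max(amp, 2.0 * REF_LEVEL_PCT) / REF_LEVEL_PCT), 0.5)
    return max(duration - rise - hold, 0.05) / log_ratio


def _add_cyto_waveform(clean: np.ndarray, t: np.ndarray, ev: TrueCytoEvent,
                       cfg: SimConfig) -> None:
    d = ev.duration_s
    rise = min(cfg.rise_time_cyto_s, 0.3 * d)
    hold = min(1.0, 0.3 * d)
    tau = _decay_tau(ev.amplitude_pct, d, rise, hold)
    x = t - ev.onset_s
    sel = (x >= 0) & (x <= d + 10.0)
    # the sub-threshold tail decays on the indicator's own timescale
    clean[sel] += _rise_hold_decay(x[sel], ev.amplitude_pct, rise, rise + hold, tau,
                                   fast_after=d, tau_fast=1.2)


def _add_mito_waveform(clean: np.ndarray, t: np.ndarray, ev: TrueMitoEvent,
                       cfg: SimConfig) -> None:
    d = ev.duration_s
    rise = min(cfg.rise_time_mito_s, 0.2 * d)
    if ev.kinetic_type == "regular":
        hold = min(2.0, 0.1 * d)
        tau = _decay_tau(ev.step_amps_pct[0], d, rise, hold)
        x = t - ev.onset_s
        sel = (x >= 0) & (x <= d + 15.0)
        clean[sel] += _rise_hold_decay(x[sel], ev.step_amps_pct[0], rise,
                                       rise + hold, tau, fast_after=d, tau_fast=1.5)
        return
    # plateaued and staircase events hold their (stepped) level and return
    # to baseline with a fast terminal fall
    tau_f = 1.5
    for s_on, s_amp in zip(ev.step_onsets_s, ev.step_amps_pct):
        s_rise = min(cfg.rise_time_mito_s, max(ev.end_s - s_on, 0.5))
        hold_end = max(ev.end_s - s_on - 3.0 * tau_f, s_rise)
        x = t - s_on
        sel = (x >= 0) & (x <= (ev.end_s - s_on) + 6.0 * tau_f)
        clean[sel] += _rise_hold_decay(x[sel], s_amp, s_rise, hold_end, tau_f)


def render_session(
    cyto_events: list[TrueCytoEvent],
    mito_events: list[TrueMitoEvent],
    links: list[CouplingLink],
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    duration_s: float | None = None,
    roi_id: str = "",
    trial: int = 0,
) -> tuple[Recording, GroundTruthLog]:
    """Render one trial's Recording from true events.

    raw_F = f_base * (1 + dF/F_true / 100) + Gaussian(0, noise_sigma_pct *
    f_base / 100), plus an optional sinusoidal drift.  At zero noise the
    sampled peak of an isolated event matches its drawn amplitude to within
    the sampling resolution of its peak hold.
    """
    if cfg.f_base <= 0:
        raise ValueError("f_base must be > 0")
    total = duration_s if duration_s is not None else cfg.trial_duration_s
    fs = cfg.sampling_rate_hz
    n = int(round(total * fs))
    t = np.arange(n) / fs
    clean = {"cyto": np.zeros(n), "mito": np.zeros(n)}
    for ev in cyto_events:
        _add_cyto_waveform(clean["cyto"], t, ev, cfg)
    for ev in mito_events:
        _add_mito_waveform(clean["mito"], t, ev, cfg)
    if cfg.drift_amp_pct:
        drift = cfg.drift_amp_pct * np.sin(2.0 * np.pi * t / cfg.drift_period_s)
        for ch in clean:
            clean[ch] = clean[ch] + drift
    raw = {}
    for ch in ("cyto", "mito"):
        noise = rng.normal(0.0, cfg.noise_sigma_pct * cfg.f_base / 100.0, size=n)
        raw[ch] = np.clip(cfg.f_base * (1.0 + clean[ch] / 100.0) + noise, 0.0, None)
    grid_end = n / fs  # clip annotation to the sampled grid
    intervals = [(lab, s, min(e, grid_end)) for lab, s, e in cfg.stage_intervals()
                 if s < grid_end]
    rec = Recording(
        roi_id=roi_id,
        compartment=cfg.compartment,
        sampling_rate_hz=fs,
        time_s=t,
        raw_f=raw,
        stage_intervals=intervals,
        roi_area_um2=cfg.roi_area_um2,
        trial=trial,
    )
    log = GroundTruthLog(cyto_events=list(cyto_events), mito_events=list(mito_events),
                         links=list(links))
    return rec, log


def simulate_trial(cfg: SimConfig, rng: np.random.Generator, *, roi_id: str = "roi0",
                   trial: int = 0) -> tuple[Recording, GroundTruthLog]:
    """Sample and render one trial (one pass through the stage schedule)."""
    cyto = sample_cyto_events(cfg.stage_schedule, cfg.cyto_amp, cfg.cyto_dur, rng,
                              roi_id=roi_id, trial=trial)
    mito, links = decide_couplings(cyto, cfg, rng,
                                   trial_duration_s=cfg.trial_duration_s)
    return render_session(cyto, mito, links, cfg, rng, roi_id=roi_id, trial=trial)


def simulate_session(
    cfg: SimConfig,
    n_rois: int,
    duration_s: float | None = None,
    seed: int | np.random.Generator = 0,
    *,
    roi_prefix: str = "roi",
) -> tuple[list[Recording], GroundTruthLog]:
    """Simulate a session of ``n_rois`` ROIs with known ground truth.

    Each ROI records for ``duration_s`` (default: one trial).  A
    single-stage schedule is stretched to the requested duration (one
    continuous acquisition); a multi-stage schedule is repeated in as many
    whole trials as fit — each trial a separate acquisition with its own
    clock, as in the treadmill / visual-stimulation protocols.  Identical
    (cfg, seed) give identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration_s is not None and len(cfg.stage_schedule) == 1:
        label, _, rate = cfg.stage_schedule[0]
        cfg = replace(cfg, stage_schedule=[(label, float(duration_s), rate)])
    trial_dur = cfg.trial_duration_s
    n_trials = 1 if duration_s is None else max(int(round(duration_s / trial_dur)), 1)
    recordings = []
    log = GroundTruthLog()
    for r in range(n_rois):
        roi_id = f"{roi_prefix}{r:03d}"
        for k in range(n_trials):
            rec, trial_log = simulate_trial(cfg, rng, roi_id=roi_id, trial=k)
            recordings.append(rec)
            log.extend(trial_log)
    log.validate()
    return recordings, log
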