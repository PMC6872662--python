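"""Calibrated-recovery experiments: simulate sessions under the preset study
conditions and measure the headline quantities through the full pipeline.

These are the package's end-to-end checks — the generator encodes the study
conditions (rates, coupling probabilities, mark distributions), the pipeline
runs blind to the ground truth, and the recovered statistics are compared to
the values those conditions should produce.
"""

from __future__ import annotations

import numpy as np

from .pipeline import analyze_session
from .synthetic_data import Gamma, LogNormal, SimConfig, get_preset, min_crossing_frequency, simulate_session

#: (preset, per-ROI duration, fidelity stage) of the three fidelity
#: recovery conditions: resting dendrites, running dendrites, running somas.
FIDELITY_CONDITIONS = {
    "REST-DEND": {"duration_s": 600.0, "stage": "rest"},
    "RUN-DEND": {"duration_s": 600.0, "stage": "run"},
    "RUN-SOMA": {"duration_s": 900.0, "stage": "run"},
}


def duration_tail_fractions(n: int = 1000, seed: int = 1) -> dict[str, float]:
    """Tail fractions of the default duration models (percent).

    Draws ``n`` durations from each channel's default log-normal and
    reports the percentage of mitochondrial durations >= 60 s and of
    cytosolic durations > 8 s.
    """
    cfg = SimConfig()
    rng = np.random.default_rng(seed)
    mito = cfg.mito_dur.sample(rng, n)
    cyto = cfg.cyto_dur.sample(rng, n)
    return {
        "pct_mito_ge_60s": 100.0 * float(np.mean(mito >= 60.0)),
        "pct_cyto_gt_8s": 100.0 * float(np.mean(cyto > 8.0)),
        "n": n,
    }


def fidelity_recovery(
    preset: str,
    n_rois: int = 60,
    seed: int = 1,
    duration_s: float | None = None,
    stage: str | None = None,
) -> dict:
    """Per-ROI mean coupling fidelity through the full pipeline.

    Simulates ``n_rois`` ROIs under the named preset, runs dF/F conversion,
    detection, pairing and fidelity, and averages the per-ROI fidelity of
    the condition's stage over ROIs with a defined value (N_cyto > 0).
    """
    cond = FIDELITY_CONDITIONS.get(preset, {})
    duration_s = duration_s if duration_s is not None else cond.get("duration_s", 600.0)
    stage = stage if stage is not None else cond.get("stage", "rest")
    cfg = get_preset(preset)
    recordings, _ = simulate_session(cfg, n_rois, duration_s=duration_s, seed=seed)
    tables = analyze_session(recordings)
    fid = tables["fidelity"]
    sub = fid[(fid["stage"] == stage) & fid["defined"].astype(bool)]
    values = sub["fidelity_pct"].to_numpy(dtype=float)
    return {
        "mean_fidelity_pct": float(np.mean(values)),
        "sem_fidelity_pct": float(np.std(values, ddof=1) / np.sqrt(values.size)),
        "n_rois": int(values.size),
        "per_roi": values,
        "tables": tables,
    }


def invitro_latency_config() -> SimConfig:
    """Field-stimulation-style trials for latency recovery.

    Separate 60-s high-SNR acquisitions (noise 0.5%) at 2 Hz with a silent
    5-s opening (clean fixed baseline window), sparse cytosolic events that
    always couple (p = 1) after a gamma(2, 1.05 s) latency, and shortened
    mitochondrial durations (median 20 s) so consecutive coupled pairs stay
    temporally resolved within a trial.
    """
    return SimConfig(
        stage_schedule=[("pre", 5.0, 0.0), ("stim", 55.0, 1.0)],
        p_couple={"pre": 1.0, "stim": 1.0},
        latency=Gamma(2.0, 1.05),
        mito_dur=LogNormal(20.0, 0.3),
        noise_sigma_pct=0.5,
        sampling_rate_hz=2.0,
        compartment="in_vitro",
        roi_area_um2=None,
    )


def latency_recovery(n_trials: int = 1000, seed: int = 1) -> dict:
    """Mean pipeline-measured coupling latency over >= 500 coupled pairs."""
    cfg = invitro_latency_config()
    recordings, _ = simulate_session(cfg, n_trials, seed=seed)
    tables = analyze_session(recordings)   # in_vitro: L_max 8 s
    pairs = tables["pairs"]
    lat = pairs.loc[~pairs["orphan"].astype(bool), "latency_s"].to_numpy(dtype=float)
    return {
        "mean_latency_s": float(np.mean(lat)),
        "max_latency_s": float(np.max(lat)),
        "n_pairs": int(lat.size),
        "tables": tables,
    }


def mito_rate_config() -> SimConfig:
    """Somatic resting sessions with a true coupled-event rate of 0.03/min
    (cytosolic rate 0.3/min x coupling probability 0.1)."""
    return SimConfig(
        stage_schedule=[("rest", 3600.0, 0.3)],
        p_couple={"rest": 0.1},
        sampling_rate_hz=1.0,
        compartment="soma",
        roi_area_um2=None,
    )


def mito_rate_recovery(n_rois: int = 100, seed: int = 1) -> dict:
    """Detected mitochondrial events per soma per minute over 6000 soma-min."""
    cfg = mito_rate_config()
    recordings, _ = simulate_session(cfg, n_rois, seed=seed)
    tables = analyze_session(recordings)
    events = tables["events"]
    n_mito = int((events["channel"] == "mito").sum())
    minutes = n_rois * cfg.trial_duration_s / 60.0
    return {
        "rate_per_soma_min": n_mito / minutes,
        "n_mito": n_mito,
        "soma_minutes": minutes,
        "tables": tables,
    }


def integrator_threshold() -> dict:
    """Minimum 5-s train frequency crossing the in vitro integrator preset."""
    cfg = get_preset("INVITRO")
    f_min = min_crossing_frequency(
        tau_a_s=cfg.integrator_tau_s,
        theta=cfg.integrator_theta,
        train_duration_s=5.0,
        freqs_hz=range(1, 16),
        impulse_gain=1.0,
    )
    return {"min_frequency_hz": f_min}
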