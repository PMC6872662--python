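"""End-to-end analysis: dF/F -> detection -> kinetic typing -> stage
assignment -> pairing -> fidelity -> peri-onset windows.

`analyze_recording` processes one acquisition; `analyze_session` aggregates
a list of recordings (ROIs x trials) into the flat event/pair/fidelity/
window tables written by :mod:`mitocoupling.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coupling_analysis import (
    L_MAX_DEFAULTS,
    CouplingPair,
    coupling_fidelity,
    pair_events,
)
from .event_detection import CaEvent, detect_transients
from .history_windows import WindowProfile, window_profile
from .io_formats import EVENT_COLUMNS, FIDELITY_COLUMNS, PAIR_COLUMNS, Recording
from .kinetic_classification import classify_kinetics
from .stage_stats import assign_stages
from .trace_processing import DffTrace, compute_dff


@dataclass
class AnalysisParams:
    """Tunable analysis parameters with study defaults.

    The baseline method is chosen per trace: the classical fixed 2-s window
    for records up to ``fixed_baseline_max_s`` (short in vitro trials, where
    an event-free opening window is realistic), a running low-percentile
    otherwise.  The mitochondrial baseline window is much longer than the
    cytosolic one because mitochondrial transients themselves last on the
    order of 100 s and must not be absorbed into the baseline.
    """

    k_thresh: float = 3.0
    min_duration_s: float = 1.0
    hysteresis_mult: float = 1.0
    merge_gap_s: float = 0.5
    baseline_percentile: float = 10.0
    baseline_window_cyto_s: float = 60.0
    baseline_window_mito_s: float = 600.0
    merge_gap_mito_s: float = 5.0
    fixed_baseline_max_s: float = 60.0
    fixed_baseline_t0_s: float = 0.0
    delta_pre_s: float = 1.0
    l_max_s: float | None = None   # None: compartment default
    count_steps: bool = False


def _dff_for_channel(rec: Recording, channel: str, params: AnalysisParams) -> DffTrace:
    raw = rec.raw_f[channel]
    if rec.duration_s <= params.fixed_baseline_max_s:
        return compute_dff(raw, rec.sampling_rate_hz, "fixed_window",
                           t0_s=params.fixed_baseline_t0_s)
    window = (params.baseline_window_cyto_s if channel == "cyto"
              else params.baseline_window_mito_s)
    return compute_dff(raw, rec.sampling_rate_hz, "running_percentile",
                       percentile=params.baseline_percentile, window_s=window)


def analyze_recording(
    rec: Recording,
    params: AnalysisParams | None = None,
) -> dict:
    """Run the full single-acquisition analysis.

    Returns a dict with per-channel 'dff' traces, detected 'events'
    (stage-labelled, mitochondrial ones kinetically typed), and coupling
    'pairs'.
    """
    params = params or AnalysisParams()
    dffs: dict[str, DffTrace] = {}
    events: dict[str, list[CaEvent]] = {"cyto": [], "mito": []}
    for channel in rec.raw_f:
        dff = _dff_for_channel(rec, channel, params)
        dffs[channel] = dff
        merge_gap = params.merge_gap_s if channel == "cyto" else params.merge_gap_mito_s
        evs = detect_transients(
            dff, rec.sampling_rate_hz,
            k_thresh=params.k_thresh,
            min_duration_s=params.min_duration_s,
            hysteresis_mult=params.hysteresis_mult,
            merge_gap_s=merge_gap,
            channel=channel,
            t0_s=float(rec.time_s[0]),
        )
        for i, ev in enumerate(evs):
            ev.roi_id = rec.roi_id
            ev.trial = rec.trial
            ev.event_id = f"{rec.roi_id}/t{rec.trial}/{channel}/{i}"
        events[channel] = evs

    for ev in events.get("mito", []):
        kind, metrics = classify_kinetics(ev, dffs["mito"], rec.sampling_rate_hz)
        ev.kinetic_type = kind
        ev.n_steps = metrics.n_steps

    for channel in events:
        assign_stages(events[channel], rec.stage_intervals)

    l_max = params.l_max_s
    if l_max is None:
        l_max = L_MAX_DEFAULTS[rec.compartment]
    pairs = pair_events(events.get("cyto", []), events.get("mito", []),
                        delta_pre_s=params.delta_pre_s, l_max_s=l_max)
    return {"dff": dffs, "events": events, "pairs": pairs, "recording": rec}


def events_to_frame(events: list[CaEvent]) -> pd.DataFrame:
    rows = [{
        "event_id": e.event_id, "roi_id": e.roi_id, "trial": e.trial,
        "channel": e.channel, "stage": e.stage, "onset_s": e.onset_s,
        "offset_s": e.offset_s, "duration_s": e.duration_s,
        "peak_amp_pct": e.peak_amp_pct, "peak_time_s": e.peak_time_s,
        "kinetic_type": e.kinetic_type, "n_steps": e.n_steps,
        "truncated": e.truncated,
    } for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def pairs_to_frame(pairs: list[CouplingPair]) -> pd.DataFrame:
    rows = [{
        "roi_id": p.mito_event.roi_id, "trial": p.mito_event.trial,
        "mito_event_id": p.mito_event.event_id,
        "cyto_event_id": "" if p.orphan else p.cyto_event.event_id,
        "latency_s": np.nan if p.orphan else p.latency_s,
        "orphan": p.orphan,
    } for p in pairs]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def analyze_session(
    recordings: list[Recording],
    params: AnalysisParams | None = None,
    *,
    window_width_s: float = 5.0,
    n_windows: int = 8,
) -> dict:
    """Analyze a session and aggregate per-(ROI, stage) fidelity.

    Counts are summed over each ROI's trials before forming
    N_mito / N_cyto, so multi-trial sessions yield one fidelity value per
    (ROI, stage).  The peri-onset window profile pools all recordings.
    Returns DataFrames 'events', 'pairs', 'fidelity', 'windows' plus the raw
    per-recording results under 'results'.
    """
    params = params or AnalysisParams()
    results = [analyze_recording(rec, params) for rec in recordings]

    all_events: list[CaEvent] = []
    all_pairs: list[CouplingPair] = []
    for res in results:
        all_events.extend(res["events"].get("cyto", []))
        all_events.extend(res["events"].get("mito", []))
        all_pairs.extend(res["pairs"])

    # fidelity per (roi, stage): counts pooled over the ROI's trials
    scope: dict[tuple[str, str], dict[str, list[CaEvent]]] = {}
    stage_labels: dict[str, set[str]] = {}
    for rec in recordings:
        labels = {lab for lab, _, _ in rec.stage_intervals} or {"unstaged"}
        stage_labels.setdefault(rec.roi_id, set()).update(labels)
    for ev in all_events:
        bucket = scope.setdefault((ev.roi_id, ev.stage), {"cyto": [], "mito": []})
        bucket[ev.channel].append(ev)
    fid_rows = []
    for roi in sorted(stage_labels):
        for stage in sorted(stage_labels[roi]):
            bucket = scope.get((roi, stage), {"cyto": [], "mito": []})
            fid = coupling_fidelity(bucket["cyto"], bucket["mito"], roi_id=roi,
                                    stage=stage, count_steps=params.count_steps)
            fid_rows.append({
                "roi_id": roi, "stage": stage, "n_cyto": fid.n_cyto,
                "n_mito": fid.n_mito,
                "fidelity_pct": np.nan if fid.fidelity_pct is None else fid.fidelity_pct,
                "defined": fid.defined, "over_100": fid.over_100,
            })
    fidelity = pd.DataFrame(fid_rows, columns=FIDELITY_COLUMNS)

    profiles = []
    for res in results:
        mito = res["events"].get("mito", [])
        cyto = res["events"].get("cyto", [])
        if not mito:
            continue
        rec = res["recording"]
        profiles.append(window_profile(
            cyto, np.array([m.onset_s for m in mito]),
            width_s=window_width_s, n_windows=n_windows,
            record_start_s=float(rec.time_s[0]), record_end_s=float(rec.time_s[-1])))
    windows = (combine_profiles(profiles).to_frame("session") if profiles
               else pd.DataFrame())

    return {
        "events": events_to_frame(all_events),
        "pairs": pairs_to_frame(all_pairs),
        "fidelity": fidelity,
        "windows": windows,
        "results": results,
    }


def combine_profiles(profiles: list[WindowProfile]) -> WindowProfile:
    """Pool peri-onset profiles computed over separate recordings."""
    if not profiles:
        raise ValueError("no profiles to combine")
    edges = profiles[0].edges
    if any(p.edges != edges for p in profiles):
        raise ValueError("profiles have mismatched window layouts")
    n_win = len(edges)
    return WindowProfile(
        edges=edges,
        counts=np.sum([p.counts for p in profiles], axis=0),
        counts_per_mito=np.vstack([p.counts_per_mito for p in profiles]),
        amp_samples=[sum((p.amp_samples[k] for p in profiles), []) for k in range(n_win)],
        dur_samples=[sum((p.dur_samples[k] for p in profiles), []) for k in range(n_win)],
        n_mito=int(sum(p.n_mito for p in profiles)),
        n_dropped_windows=int(sum(p.n_dropped_windows for p in profiles)),
    )
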