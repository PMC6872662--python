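"""Peri-onset history windows.

Frequencies, amplitudes and durations of cytosolic transients in eight 5-s
windows centered on each mitochondrial onset ([-20, -15) ... [15, 20) s)
probe whether the recent history of cytosolic activity predicts an imminent
mitochondrial transient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_detection import CaEvent


@dataclass
class WindowProfile:
    """Aggregated peri-onset profile.

    ``edges`` are the half-open window intervals relative to the
    mitochondrial onset; per-window sample lists (one entry per cytosolic
    onset falling in that window, over all aggregated mitochondrial events)
    are retained so downstream tests can re-derive every summary.
    """

    edges: list[tuple[float, float]]
    counts: np.ndarray            # total cyto onsets per window
    counts_per_mito: np.ndarray   # (n_mito, n_windows) onset counts
    amp_samples: list[list[float]] = field(default_factory=list)
    dur_samples: list[list[float]] = field(default_factory=list)
    n_mito: int = 0
    n_dropped_windows: int = 0

    def to_frame(self, scope: str = "all") -> pd.DataFrame:
        rows = []
        for k, (lo, hi) in enumerate(self.edges):
            amps = self.amp_samples[k]
            durs = self.dur_samples[k]
            rows.append({
                "scope": scope,
                "window_lo_s": lo,
                "window_hi_s": hi,
                "n_cyto_onsets": int(self.counts[k]),
                "mean_peak_amp_pct": float(np.mean(amps)) if amps else np.nan,
                "mean_duration_s": float(np.mean(durs)) if durs else np.nan,
                "n_mito": self.n_mito,
                "n_dropped_windows": self.n_dropped_windows,
            })
        return pd.DataFrame(rows)


def window_edges(width_s: float = 5.0, n_windows: int = 8) -> list[tuple[float, float]]:
    """Symmetric half-open windows about 0: n/2 before, n/2 after."""
    if n_windows % 2:
        raise ValueError("n_windows must be even (symmetric about the onset)")
    half = n_windows // 2
    return [(width_s * (k - half), width_s * (k - half + 1)) for k in range(n_windows)]


def window_profile(
    cyto_events: list[CaEvent],
    mito_onsets: np.ndarray,
    width_s: float = 5.0,
    n_windows: int = 8,
    *,
    record_start_s: float | None = None,
    record_end_s: float | None = None,
) -> WindowProfile:
    """Assign cytosolic onsets to peri-onset windows of each mito onset.

    A cytosolic event belongs to the window containing its onset relative to
    each mitochondrial onset (one event may count toward several close mito
    onsets).  Windows extending beyond [record_start_s, record_end_s] are
    dropped for that mito event and tallied in ``n_dropped_windows``.
    Translating all onsets by a constant leaves the profile unchanged.
    """
    mito_onsets = np.atleast_1d(np.asarray(mito_onsets, dtype=float))
    if mito_onsets.size == 0:
        raise ValueError("no mitochondrial onsets: empty profile")
    edges = window_edges(width_s, n_windows)
    counts_per_mito = np.zeros((mito_onsets.size, n_windows), dtype=int)
    amp_samples: list[list[float]] = [[] for _ in range(n_windows)]
    dur_samples: list[list[float]] = [[] for _ in range(n_windows)]
    dropped = 0
    onsets = np.array([e.onset_s for e in cyto_events])
    for j, m in enumerate(mito_onsets):
        for k, (lo, hi) in enumerate(edges):
            if record_start_s is not None and m + lo < record_start_s:
                dropped += 1
                continue
            if record_end_s is not None and m + hi > record_end_s:
                dropped += 1
                continue
            in_win = np.flatnonzero((onsets >= m + lo) & (onsets < m + hi))
            counts_per_mito[j, k] = in_win.size
            for idx in in_win:
                amp_samples[k].append(cyto_events[idx].peak_amp_pct)
                dur_samples[k].append(cyto_events[idx].duration_s)
    return WindowProfile(
        edges=edges,
        counts=counts_per_mito.sum(axis=0),
        counts_per_mito=counts_per_mito,
        amp_samples=amp_samples,
        dur_samples=dur_samples,
        n_mito=int(mito_onsets.size),
        n_dropped_windows=dropped,
    )


def window_contrast(profile: WindowProfile, metric: str = "count") -> dict:
    """One-way comparison of a metric across the peri-onset windows.

    metric = 'count' compares per-mito-event onset counts; 'amplitude' /
    'duration' compare the event-level samples.  Groups are the windows;
    the omnibus test and post hoc come from
    :func:`mitocoupling.stage_stats.compare_groups` (ANOVA + Sidak or
    Kruskal-Wallis + Dunn depending on normality).
    """
    from .stage_stats import compare_groups

    if metric == "count":
        groups = [profile.counts_per_mito[:, k].astype(float)
                  for k in range(len(profile.edges))]
    elif metric == "amplitude":
        groups = [np.asarray(s, dtype=float) for s in profile.amp_samples]
    elif metric == "duration":
        groups = [np.asarray(s, dtype=float) for s in profile.dur_samples]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    labeled = [(k, g) for k, g in enumerate(groups) if g.size >= 3]
    if len(labeled) < 2:
        raise ValueError("need >= 2 windows with >= 3 samples")
    res = compare_groups([g for _, g in labeled],
                         labels=[f"[{profile.edges[k][0]:g},{profile.edges[k][1]:g})"
                                 for k, _ in labeled])
    return {"metric": metric, "result": res}
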