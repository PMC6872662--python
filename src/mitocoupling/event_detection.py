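"""Transient detection in dF/F traces by the threshold/duration rule.

A candidate transient is a maximal run of samples exceeding ``k_thresh``
times the baseline-noise SD; its offset is extended forward while the trace
stays above a lower hysteresis level (long mitochondrial decays hover near
the detection threshold and would otherwise fragment); candidates closer
than ``merge_gap_s`` merge; a candidate is accepted iff its duration is
strictly greater than ``min_duration_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace_processing import DffTrace

#: Minimum usable noise SD (% dF/F); avoids zero-sigma degenerate thresholds
#: on noiseless synthetic traces.
SIGMA_FLOOR_PCT = 0.1


@dataclass
class CaEvent:
    """A detected Ca2+ transient.

    Times are in seconds on the recording's clock.  ``kinetic_type`` is one
    of regular/plateaued/staircase/unclassified for mitochondrial events and
    'not_applicable' for cytosolic ones; ``n_steps`` counts upward steps
    (1 for a non-staircase event).  ``truncated`` flags events touching the
    end of the record.
    """

    channel: str
    onset_s: float
    offset_s: float
    peak_amp_pct: float
    peak_time_s: float
    kinetic_type: str = "not_applicable"
    n_steps: int = 1
    truncated: bool = False
    onset_idx: int = 0
    offset_idx: int = 0
    event_id: str = ""
    roi_id: str = ""
    trial: int = 0
    stage: str = "unstaged"
    step_times_s: list[float] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive indices."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(s), int(e) - 1) for s, e in zip(idx[::2], idx[1::2])]


def detect_transients(
    dff: DffTrace | np.ndarray,
    fs: float,
    k_thresh: float = 3.0,
    min_duration_s: float = 1.0,
    hysteresis_mult: float = 1.0,
    merge_gap_s: float = 0.5,
    *,
    sigma: float | None = None,
    channel: str = "cyto",
    t0_s: float = 0.0,
) -> list[CaEvent]:
    """Detect transients in a dF/F trace.

    ``sigma`` defaults to the trace's own noise estimate and is floored at
    ``SIGMA_FLOOR_PCT``.  Returned events are sorted by onset; cytosolic
    events carry kinetic_type='not_applicable', mitochondrial ones start as
    'unclassified' (typed later by the kinetic classifier).
    """
    if isinstance(dff, DffTrace):
        values = dff.values
        if sigma is None:
            sigma = dff.noise_sigma_pct
    else:
        values = np.asarray(dff, dtype=float)
        if sigma is None:
            raise ValueError("sigma required when passing a bare array")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in dF/F trace")
    sigma = max(float(sigma), SIGMA_FLOOR_PCT)
    dt = 1.0 / fs
    n = values.size

    hi_runs = _runs(values > k_thresh * sigma)
    if not hi_runs:
        return []
    lo_runs = _runs(values > hysteresis_mult * sigma)
    # map each sample to its hysteresis-run end for forward extension
    lo_end = np.full(n, -1, dtype=int)
    for s, e in lo_runs:
        lo_end[s:e + 1] = e

    extended = [(s, int(lo_end[e])) for s, e in hi_runs]

    # the gap between candidates is the extent of the subthreshold
    # interlude (number of subthreshold samples x dt)
    merged: list[list[int]] = []
    for s, e in extended:
        if merged and (s - merged[-1][1] - 1) * dt < merge_gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        if (e - s) * dt <= min_duration_s:
            continue
        seg = values[s:e + 1]
        pk = int(np.argmax(seg))
        events.append(CaEvent(
            channel=channel,
            onset_s=t0_s + s * dt,
            offset_s=t0_s + e * dt,
            peak_amp_pct=float(seg[pk]),
            peak_time_s=t0_s + (s + pk) * dt,
            kinetic_type="not_applicable" if channel == "cyto" else "unclassified",
            truncated=(e == n - 1),
            onset_idx=s,
            offset_idx=e,
        ))
    return events


def detect_steps(
    segment: np.ndarray,
    fs: float,
    sigma: float,
    step_k: float = 3.0,
    sustain_s: float = 2.0,
    *,
    t0_s: float = 0.0,
) -> list[float]:
    """Locate upward-step onsets within a detected mitochondrial event.

    The step contrast at time t is the forward 2-s mean minus the backward
    2-s mean of the dF/F segment.  Each maximal run of contrast above
    ``step_k * sigma`` contributes one step at its contrast maximum; the
    first run corresponds to the event's initial rise, which is always step
    1 and reported at the segment start.  Steps closer than ``sustain_s`` to
    the previous step are suppressed.  Segments shorter than 2*sustain_s
    return only step 1.
    """
    segment = np.asarray(segment, dtype=float)
    sigma = max(float(sigma), SIGMA_FLOOR_PCT)
    dt = 1.0 / fs
    n = segment.size
    w = max(int(round(2.0 * fs)), 1)
    if n * dt < 2.0 * sustain_s or n < 2 * w + 1:
        return [t0_s]

    cs = np.concatenate(([0.0], np.cumsum(segment)))
    # contrast defined where both 2-s windows fit
    i = np.arange(w, n - w)
    fwd = (cs[i + w] - cs[i]) / w
    bwd = (cs[i] - cs[i - w]) / w
    contrast = fwd - bwd

    steps = [t0_s]
    for run_idx, (s, e) in enumerate(_runs(contrast > step_k * sigma)):
        if run_idx == 0 and s == 0:
            continue  # contrast already high at the boundary: the initial rise
        t_max = t0_s + float(i[s + int(np.argmax(contrast[s:e + 1]))]) * dt
        if t_max - steps[-1] > sustain_s:
            steps.append(t_max)
        # runs too close to the previous step are absorbed into it
    return steps
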