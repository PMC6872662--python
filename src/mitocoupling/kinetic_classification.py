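"""Kinetic typing of mitochondrial transients.

The three families observed in vivo: *regular* (monotonic post-peak
decline), *plateaued* (stable elevation) and *staircase* (multiple upward
steps).  The numeric cutoffs operationalizing these qualitative classes are
package choices, exposed as parameters and frozen as defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .event_detection import CaEvent
from .trace_processing import DffTrace


@dataclass
class KineticMetrics:
    """Post-peak shape metrics backing a kinetic-type call.

    ``decay_fraction`` = (peak - end) / peak over the scored post-peak
    window (1 = full return to baseline, ~0 = sustained plateau);
    ``monotonicity`` is the Spearman rank correlation of the post-peak
    segment against time (-1 = strictly declining).
    """

    decay_fraction: float
    monotonicity: float
    n_steps: int


def classify_kinetics(
    event: CaEvent,
    dff: DffTrace | np.ndarray,
    fs: float,
    post_window_s: float = 30.0,
    plateau_max_decay: float = 0.25,
    regular_min_decay: float = 0.5,
    mono_cut: float = -0.5,
    *,
    sigma: float | None = None,
    step_k: float = 3.0,
    sustain_s: float = 2.0,
    end_margin_frac: float = 0.8,
) -> tuple[str, KineticMetrics]:
    """Assign a mitochondrial event to regular / plateaued / staircase.

    Precedence: staircase (n_steps >= 2) -> plateaued (decay_fraction <
    ``plateau_max_decay`` and not steadily declining) -> regular
    (decay_fraction >= ``regular_min_decay`` or monotonicity <=
    ``mono_cut``) -> unclassified.
    The scored window runs from the peak to min(``post_window_s``,
    ``end_margin_frac`` x the peak-to-offset span): the margin excludes the
    terminal return to baseline so that short plateaued events are not
    scored on their final fall.  Events with fewer than 10 post-peak samples
    are left unclassified.  Deterministic: classifying twice is identical.
    """
    if event.channel != "mito":
        raise ValueError("kinetic classification applies to mitochondrial events")
    if isinstance(dff, DffTrace):
        values = dff.values
        if sigma is None:
            sigma = dff.noise_sigma_pct
    else:
        values = np.asarray(dff, dtype=float)
        if sigma is None:
            raise ValueError("sigma required when passing a bare array")

    from .event_detection import detect_steps

    dt = 1.0 / fs
    seg = values[event.onset_idx:event.offset_idx + 1]
    step_times = detect_steps(seg, fs, sigma, step_k=step_k, sustain_s=sustain_s,
                              t0_s=event.onset_s)
    n_steps = len(step_times)

    # effective peak: first time a 2-s smoothed trace reaches 95% of its
    # maximum.  The raw argmax of a flat noisy plateau falls anywhere on it,
    # which would push the "post-peak" window into the terminal fall.
    w = max(int(round(2.0 * fs)), 1)
    if seg.size >= w:
        kernel = np.ones(w) / w
        smoothed = np.convolve(seg, kernel, mode="same")
    else:
        smoothed = seg
    pk_idx = int(np.flatnonzero(smoothed >= 0.95 * smoothed.max())[0])
    post = seg[pk_idx:]
    if post.size < 10:
        metrics = KineticMetrics(decay_fraction=np.nan, monotonicity=np.nan, n_steps=n_steps)
        kind = "staircase" if n_steps >= 2 else "unclassified"
        return kind, metrics

    # the scored span ends at the last sample still above the detection
    # level: the sub-threshold hysteresis tail must not pull the endpoint
    # into an event's terminal fall
    from .event_detection import SIGMA_FLOOR_PCT

    level = 3.0 * max(sigma, SIGMA_FLOOR_PCT)
    above = np.flatnonzero(post > level)
    span_s = (float(above[-1]) if above.size else (post.size - 1)) * dt
    win_s = min(post_window_s, end_margin_frac * span_s)
    win_n = max(int(round(win_s / dt)), 1)
    scored = post[:win_n + 1]
    peak = float(smoothed[pk_idx])  # noise-robust level at the effective peak
    # endpoint averaged over the last 2 s of the window for noise robustness
    tail_n = max(int(round(2.0 * fs)), 1)
    end_val = float(np.mean(scored[-tail_n:]))
    decay_fraction = (peak - end_val) / peak if peak != 0 else np.nan

    if np.all(scored == scored[0]):
        mono = 0.0
    else:
        mono = float(stats.spearmanr(np.arange(scored.size), scored).statistic)
    metrics = KineticMetrics(decay_fraction=float(decay_fraction),
                             monotonicity=mono, n_steps=n_steps)

    if n_steps >= 2:
        return "staircase", metrics
    if decay_fraction < plateau_max_decay and mono > mono_cut:
        # a stable elevation must not be steadily declining: very slow
        # monotonic decays belong to the regular class
        return "plateaued", metrics
    if decay_fraction >= regular_min_decay or mono <= mono_cut:
        return "regular", metrics
    return "unclassified", metrics
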