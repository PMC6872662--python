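"""Raw fluorescence to dF/F0 conversion and baseline-noise estimation.

dF/F0 = (F - F0) / F0 x 100, expressed in percent throughout the package.
Two baseline estimators are provided: the classical fixed 2-s window mean
(exact when the window is event-free, appropriate for short traces) and a
centered running low-percentile that tolerates events anywhere in longer
records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DffTrace:
    """A dF/F0 trace (%), its baseline and its noise level.

    ``values`` and ``f0`` have the length of the source recording; ``f0`` is
    in raw fluorescence units.  ``noise_sigma_pct`` is the standard deviation
    of the baseline noise in % dF/F.
    """

    values: np.ndarray
    f0: np.ndarray
    noise_sigma_pct: float
    baseline_method: str
    noise_method: str = "mad_first_diff"


def _fixed_window_f0(raw_f: np.ndarray, fs: float, t0_s: float, window_s: float) -> np.ndarray:
    i0 = int(round(t0_s * fs))
    n = max(int(round(window_s * fs)), 1)
    if i0 < 0 or i0 + n > raw_f.size:
        raise ValueError("baseline window outside the record")
    return np.full_like(raw_f, float(np.mean(raw_f[i0:i0 + n])), dtype=float)


def _running_percentile_f0(raw_f: np.ndarray, fs: float, q: float, window_s: float) -> np.ndarray:
    win = max(int(round(window_s * fs)), 1)
    win = min(win, raw_f.size)
    # centered rolling percentile; window shrinks at the edges
    roll = (
        pd.Series(raw_f)
        .rolling(win, center=True, min_periods=1)
        .quantile(q / 100.0)
        .to_numpy()
    )
    # a low percentile sits below the quiescent mean by the Gaussian
    # quantile gap z_{1-q} * sigma; recenter with a robust raw-noise SD from
    # first differences (insensitive to event pedestals of any occupancy)
    from scipy.stats import norm
    sigma_raw = 1.4826 * np.median(np.abs(np.diff(raw_f))) / np.sqrt(2.0)
    return roll + float(norm.ppf(1.0 - q / 100.0)) * sigma_raw


def compute_dff(
    raw_f: np.ndarray,
    fs: float,
    baseline: str = "running_percentile",
    *,
    t0_s: float = 0.0,
    fixed_window_s: float = 2.0,
    percentile: float = 10.0,
    window_s: float = 60.0,
) -> DffTrace:
    """Convert raw fluorescence to dF/F0 in percent.

    Parameters
    ----------
    baseline : {'running_percentile', 'fixed_window'}
        'fixed_window': F0 is the mean of a ``fixed_window_s``-long window
        starting at ``t0_s`` (the classical 2-s baseline).
        'running_percentile': F0 is the centered rolling ``percentile``-th
        percentile over ``window_s`` (edges shrink the window).

    Raises
    ------
    ValueError
        If the resulting baseline is non-positive anywhere.
    """
    raw_f = np.asarray(raw_f, dtype=float)
    if baseline == "fixed_window":
        f0 = _fixed_window_f0(raw_f, fs, t0_s, fixed_window_s)
    elif baseline == "running_percentile":
        f0 = _running_percentile_f0(raw_f, fs, percentile, window_s)
    else:
        raise ValueError(f"unknown baseline method {baseline!r}")
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 <= 0; cannot form dF/F0")
    values = (raw_f - f0) / f0 * 100.0
    sigma = estimate_noise_sigma(values, fs)
    return DffTrace(values=values, f0=f0, noise_sigma_pct=sigma, baseline_method=baseline)


def estimate_noise_sigma(dff_values: np.ndarray, fs: float | None = None) -> float:
    """Robust baseline-noise SD (% dF/F) from median absolute first differences.

    For i.i.d. Gaussian noise the first differences have SD sigma*sqrt(2), so
    1.4826 * median(|diff|) / sqrt(2) estimates sigma while ignoring slow
    trends and sparse event pedestals (<= 10% bias for events occupying up to
    ~20% of samples).  A constant trace returns 0.
    """
    dff_values = np.asarray(dff_values, dtype=float)
    if dff_values.size < 20:
        raise ValueError("need >= 20 samples to estimate noise")
    diffs = np.abs(np.diff(dff_values))
    return float(1.4826 * np.median(diffs) / np.sqrt(2.0))


def extract_roi_means(stack: np.ndarray, label_mask: np.ndarray) -> dict[int, np.ndarray]:
    """Per-frame unweighted pixel means for each ROI label of an image stack.

    ``stack`` is (n_frames, h, w); ``label_mask`` is an integer image of the
    frame shape where 0 marks background (excluded) and labels >= 1 mark ROIs.
    Returns {label: trace of length n_frames}.
    """
    stack = np.asarray(stack)
    label_mask = np.asarray(label_mask)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, h, w)")
    if label_mask.shape != stack.shape[1:]:
        raise ValueError("mask shape must equal frame shape")
    labels = np.unique(label_mask)
    labels = labels[labels >= 1]
    if labels.size == 0:
        raise ValueError("mask contains no ROI labels >= 1")
    flat = stack.reshape(stack.shape[0], -1).astype(float)
    mask_flat = label_mask.ravel()
    traces = {}
    for lab in labels:
        idx = np.flatnonzero(mask_flat == lab)
        if idx.size == 0:  # unreachable via np.unique, kept for slice inputs
            raise ValueError(f"empty label {lab}")
        traces[int(lab)] = flat[:, idx].mean(axis=1)
    return traces


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF stack as (n_frames, h, w)."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return arr
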