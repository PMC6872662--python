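import numpy as np
import pytest

from mitocoupling.synthetic_data import LogNormal, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Noiseless, well-separated events: every transient is unambiguous."""
    return SimConfig(
        stage_schedule=[("rest", 300.0, 0.3)],
        p_couple={"rest": 0.3},
        cyto_amp=LogNormal(30.0, 0.2),
        mito_amp=LogNormal(40.0, 0.2),
        cyto_dur=LogNormal(5.0, 0.2),
        mito_dur=LogNormal(40.0, 0.2),
        noise_sigma_pct=0.0,
        sampling_rate_hz=2.0,
        compartment="dendrite",
    )


def brute_force_detect(values, fs, sigma, k_thresh=3.0, min_duration_s=1.0,
                       hysteresis_mult=1.0, merge_gap_s=0.5):
    """Reference transient scan: direct sample-by-sample implementation of
    the threshold / hysteresis / merge / duration rules."""
    dt = 1.0 / fs
    n = len(values)
    runs = []
    i = 0
    while i < n:
        if values[i] > k_thresh * sigma:
            j = i
            while j + 1 < n and values[j + 1] > k_thresh * sigma:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    extended = []
    for s, e in runs:
        j = e
        while j + 1 < n and values[j + 1] > hysteresis_mult * sigma:
            j += 1
        extended.append([s, j])
    merged = []
    for s, e in extended:
        if merged and (s - merged[-1][1] - 1) * dt < merge_gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if (e - s) * dt > min_duration_s]
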