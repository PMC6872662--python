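"""Session data model and CSV readers/writers shared by all analysis stages.

A *session* is a collection of :class:`Recording` objects — one per ROI and
trial — holding the two-channel raw fluorescence, the sampling rate and the
stage annotation.  Event/pair/fidelity tables are flat pandas DataFrames with
fixed, documented column schemas; every writer/reader pair round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

VALID_CHANNELS = ("cyto", "mito")
VALID_COMPARTMENTS = ("dendrite", "soma", "in_vitro")

#: Fixed column schemas of the flat tables (order is the on-disk order).
EVENT_COLUMNS = [
    "event_id", "roi_id", "trial", "channel", "stage",
    "onset_s", "offset_s", "duration_s", "peak_amp_pct", "peak_time_s",
    "kinetic_type", "n_steps", "truncated",
]
PAIR_COLUMNS = ["roi_id", "trial", "mito_event_id", "cyto_event_id", "latency_s", "orphan"]
FIDELITY_COLUMNS = ["roi_id", "stage", "n_cyto", "n_mito", "fidelity_pct", "defined", "over_100"]
WINDOW_COLUMNS = [
    "scope", "window_lo_s", "window_hi_s", "n_cyto_onsets",
    "mean_peak_amp_pct", "mean_duration_s", "n_mito", "n_dropped_windows",
]

FLOAT_FORMAT = "%.10g"  # >= 9 significant digits: round-trip safe for our data


class FormatError(ValueError):
    """Raised when an input table or config violates its contract."""


@dataclass
class Recording:
    """One ROI's (and trial's) two-channel raw fluorescence time series.

    Parameters
    ----------
    roi_id : str
        Identifier of the region of interest.
    compartment : {'dendrite', 'soma', 'in_vitro'}
        Anatomical compartment; selects analysis defaults (sampling rate,
        pairing window, area normalization).
    sampling_rate_hz : float
        Frame rate in samples/s (2 Hz for L1 dendrites, 1 Hz for somas).
    time_s : ndarray
        Monotone sample times in seconds, uniform grid.
    raw_f : dict of {channel: ndarray}
        Raw fluorescence per channel, arbitrary units, channels a subset of
        ``{'cyto', 'mito'}``.
    stage_intervals : list of (label, t_start_s, t_end_s)
        Non-overlapping half-open intervals [start, end) annotating behaviour
        stages (e.g. pre_run / run / post_run).
    roi_area_um2 : float, optional
        ROI area; required for dendritic per-1000-um2 frequency normalization.
    trial : int
        Trial index when a session splits one ROI into several acquisitions.
    """

    roi_id: str
    compartment: str
    sampling_rate_hz: float
    time_s: np.ndarray
    raw_f: dict[str, np.ndarray]
    stage_intervals: list[tuple[str, float, float]] = field(default_factory=list)
    roi_area_um2: float | None = None
    trial: int = 0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.raw_f = {ch: np.asarray(v, dtype=float) for ch, v in self.raw_f.items()}
        self.validate()

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if self.time_s.size else 0.0

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.raw_f)

    def validate(self) -> None:
        if self.compartment not in VALID_COMPARTMENTS:
            raise FormatError(f"unknown compartment {self.compartment!r}")
        if not self.sampling_rate_hz > 0:
            raise FormatError("sampling_rate_hz must be > 0")
        if self.time_s.ndim != 1 or self.time_s.size < 2:
            raise FormatError("time_s must be a 1-d array with >= 2 samples")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise FormatError("time_s must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate_hz)) > 1e-6:
            raise FormatError("time step inconsistent with sampling_rate_hz")
        for ch, values in self.raw_f.items():
            if ch not in VALID_CHANNELS:
                raise FormatError(f"unknown channel {ch!r}")
            if values.shape != self.time_s.shape:
                raise FormatError(f"channel {ch!r} length differs from time_s")
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise FormatError(f"channel {ch!r} has non-finite or negative values")
        t0, t1 = float(self.time_s[0]), float(self.time_s[-1])
        prev_end = None
        for label, s, e in sorted(self.stage_intervals, key=lambda iv: iv[1]):
            if not (s < e):
                raise FormatError(f"stage {label!r}: empty or inverted interval")
            if s < t0 - 1e-9 or e > t1 + 1.0 / self.sampling_rate_hz + 1e-9:
                raise FormatError(f"stage {label!r} outside the recording")
            if prev_end is not None and s < prev_end - 1e-9:
                raise FormatError("stage intervals overlap")
            prev_end = e


# ---------------------------------------------------------------------------
# Trace tables
# ---------------------------------------------------------------------------

DEFAULT_TRACE_SCHEMA = {
    "time_col": "time_s",
    "roi_col": "roi_id",
    "channel_col": "channel",
    "value_col": "F",
}


def read_traces_table(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    meta: pd.DataFrame | None = None,
    stages: pd.DataFrame | None = None,
) -> list[Recording]:
    """Read a long-format trace table (one row per time, roi, channel).

    All channels of a given (roi, trial) must share the same time grid;
    missing samples are an error, not interpolated.  ``meta`` (columns
    roi_id, trial, compartment, sampling_rate_hz, roi_area_um2) and
    ``stages`` (roi_id, trial, stage, t_start_s, t_end_s) attach session
    metadata; without them the compartment defaults to 'soma' and the
    sampling rate is inferred from the grid.
    """
    schema = dict(DEFAULT_TRACE_SCHEMA, **(schema or {}))
    df = pd.read_csv(path)
    required = {schema["time_col"], schema["roi_col"], schema["channel_col"], schema["value_col"]}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"trace table missing columns: {sorted(missing)}")
    has_trial = "trial" in df.columns
    tcol, rcol, ccol, vcol = (
        schema["time_col"], schema["roi_col"], schema["channel_col"], schema["value_col"])

    unknown = set(df[ccol].unique()) - set(VALID_CHANNELS)
    if unknown:
        raise FormatError(f"unknown channel labels: {sorted(unknown)}")
    keys = [rcol, "trial", ccol, tcol] if has_trial else [rcol, ccol, tcol]
    if df.duplicated(subset=keys).any():
        raise FormatError("duplicated (time, roi, channel) rows")

    meta_idx = {}
    if meta is not None:
        for row in meta.itertuples(index=False):
            meta_idx[(str(row.roi_id), int(getattr(row, "trial", 0)))] = row
    stage_idx: dict[tuple[str, int], list] = {}
    if stages is not None:
        for row in stages.itertuples(index=False):
            key = (str(row.roi_id), int(getattr(row, "trial", 0)))
            stage_idx.setdefault(key, []).append(
                (str(row.stage), float(row.t_start_s), float(row.t_end_s)))

    recordings = []
    group_keys = [rcol, "trial"] if has_trial else [rcol]
    for gkey, group in df.groupby(group_keys, sort=True):
        roi = str(gkey[0]) if isinstance(gkey, tuple) else str(gkey)
        trial = int(gkey[1]) if has_trial else 0
        ref_time = None
        raw = {}
        for ch, sub in group.groupby(ccol, sort=True):
            sub = sub.sort_values(tcol)
            t = sub[tcol].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise FormatError(f"roi {roi}: non-monotone time for channel {ch}")
            if ref_time is None:
                ref_time = t
            elif t.shape != ref_time.shape or not np.allclose(t, ref_time, atol=1e-9):
                raise FormatError(f"roi {roi}: channel time grids differ")
            raw[str(ch)] = sub[vcol].to_numpy(dtype=float)
        m = meta_idx.get((roi, trial))
        fs = float(m.sampling_rate_hz) if m is not None else 1.0 / float(np.median(np.diff(ref_time)))
        area = None
        if m is not None and not pd.isna(getattr(m, "roi_area_um2", np.nan)):
            area = float(m.roi_area_um2)
        recordings.append(Recording(
            roi_id=roi,
            compartment=str(m.compartment) if m is not None else "soma",
            sampling_rate_hz=fs,
            time_s=ref_time,
            raw_f=raw,
            stage_intervals=stage_idx.get((roi, trial), []),
            roi_area_um2=area,
            trial=trial,
        ))
    return recordings


def write_traces_table(recordings: Sequence[Recording], path) -> None:
    """Write recordings in long format (time_s, roi_id, trial, channel, F)."""
    frames = []
    for rec in recordings:
        for ch, values in sorted(rec.raw_f.items()):
            frames.append(pd.DataFrame({
                "time_s": rec.time_s,
                "roi_id": rec.roi_id,
                "trial": rec.trial,
                "channel": ch,
                "F": values,
            }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["time_s", "roi_id", "trial", "channel", "F"])
    df = df.sort_values(["roi_id", "trial", "channel", "time_s"], kind="mergesort")
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def session_meta_frames(recordings: Sequence[Recording]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the (meta, stages) side tables for a list of recordings."""
    meta = pd.DataFrame([
        {
            "roi_id": r.roi_id,
            "trial": r.trial,
            "compartment": r.compartment,
            "sampling_rate_hz": r.sampling_rate_hz,
            "roi_area_um2": np.nan if r.roi_area_um2 is None else r.roi_area_um2,
        }
        for r in recordings
    ], columns=["roi_id", "trial", "compartment", "sampling_rate_hz", "roi_area_um2"])
    stages = pd.DataFrame([
        {"roi_id": r.roi_id, "trial": r.trial, "stage": lab, "t_start_s": s, "t_end_s": e}
        for r in recordings
        for lab, s, e in r.stage_intervals
    ], columns=["roi_id", "trial", "stage", "t_start_s", "t_end_s"])
    return meta, stages


def write_session(recordings: Sequence[Recording], out_dir) -> dict[str, Path]:
    """Write traces.csv, recordings.csv and stages.csv for a session."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out_dir / "traces.csv",
        "recordings": out_dir / "recordings.csv",
        "stages": out_dir / "stages.csv",
    }
    write_traces_table(recordings, paths["traces"])
    meta, stages = session_meta_frames(recordings)
    meta.to_csv(paths["recordings"], index=False, float_format=FLOAT_FORMAT)
    stages.to_csv(paths["stages"], index=False, float_format=FLOAT_FORMAT)
    return paths


def read_session(session_dir) -> list[Recording]:
    """Read a session written by :func:`write_session`."""
    session_dir = Path(session_dir)
    meta = pd.read_csv(session_dir / "recordings.csv")
    stages_path = session_dir / "stages.csv"
    stages = pd.read_csv(stages_path) if stages_path.exists() else None
    return read_traces_table(session_dir / "traces.csv", meta=meta, stages=stages)


# ---------------------------------------------------------------------------
# Event / pair / fidelity / window tables
# ---------------------------------------------------------------------------

def _check_references(events: pd.DataFrame, pairs: pd.DataFrame) -> None:
    ids = set(events["event_id"]) if len(events) else set()
    for col in ("mito_event_id", "cyto_event_id"):
        ref = pairs[col].dropna()
        ref = ref[ref != ""]
        dangling = set(ref) - ids
        if dangling:
            raise FormatError(f"pairs reference unknown events: {sorted(dangling)[:5]}")


def write_event_tables(
    events: pd.DataFrame,
    pairs: pd.DataFrame,
    fidelity: pd.DataFrame,
    out_dir,
    windows: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the events/pairs/fidelity (and optionally windows) CSV tables.

    Raises :class:`FormatError` on dangling event references.  The write ->
    read round-trip is the identity up to float formatting (10 significant
    digits).
    """
    events = events.reindex(columns=EVENT_COLUMNS)
    pairs = pairs.reindex(columns=PAIR_COLUMNS)
    fidelity = fidelity.reindex(columns=FIDELITY_COLUMNS)
    _check_references(events, pairs)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out_dir / "events.csv",
        "pairs": out_dir / "pairs.csv",
        "fidelity": out_dir / "fidelity.csv",
    }
    events.to_csv(paths["events"], index=False, float_format=FLOAT_FORMAT)
    pairs.to_csv(paths["pairs"], index=False, float_format=FLOAT_FORMAT)
    fidelity.to_csv(paths["fidelity"], index=False, float_format=FLOAT_FORMAT)
    if windows is not None:
        paths["windows"] = out_dir / "windows.csv"
        windows.reindex(columns=WINDOW_COLUMNS).to_csv(
            paths["windows"], index=False, float_format=FLOAT_FORMAT)
    return paths


def read_event_tables(out_dir) -> dict[str, pd.DataFrame]:
    out_dir = Path(out_dir)
    tables = {
        "events": pd.read_csv(out_dir / "events.csv", dtype={"event_id": str, "roi_id": str}),
        "pairs": pd.read_csv(
            out_dir / "pairs.csv",
            dtype={"mito_event_id": str, "cyto_event_id": str, "roi_id": str})
        .fillna({"mito_event_id": "", "cyto_event_id": ""}),
        "fidelity": pd.read_csv(out_dir / "fidelity.csv", dtype={"roi_id": str}),
    }
    wpath = out_dir / "windows.csv"
    if wpath.exists():
        tables["windows"] = pd.read_csv(wpath)
    return tables


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

#: Allowed config keys.  A dict value means a nested section; ``...`` means
#: the section's keys are validated elsewhere (SimConfig field names).
CONFIG_SCHEMA = {
    "preset": str,
    "compartment": str,
    "n_rois": int,
    "duration_s": float,
    "sim": ...,
    "analysis": {
        "k_thresh": float,
        "min_duration_s": float,
        "hysteresis_mult": float,
        "merge_gap_s": float,
        "baseline_window_cyto_s": float,
        "baseline_window_mito_s": float,
        "baseline_percentile": float,
        "delta_pre_s": float,
        "l_max_s": float,
        "count_steps": bool,
    },
}

DEFAULT_CONFIG = {
    "preset": "REST-DEND",
    "n_rois": 10,
    "duration_s": 600.0,
    "sim": {},
    "analysis": {},
}


def validate_config(cfg: Mapping, sim_fields: set[str] | None = None) -> None:
    """Reject unknown keys (silent mis-specification is worse than an error)."""
    for key, value in cfg.items():
        if key not in CONFIG_SCHEMA:
            raise FormatError(f"unknown config key: {key!r}")
        allowed = CONFIG_SCHEMA[key]
        if allowed is ...:
            if sim_fields is not None:
                bad = set(value or {}) - sim_fields
                if bad:
                    raise FormatError(f"unknown sim config keys: {sorted(bad)}")
        elif isinstance(allowed, dict):
            bad = set(value or {}) - set(allowed)
            if bad:
                raise FormatError(f"unknown keys in section {key!r}: {sorted(bad)}")


def load_config(path, sim_fields: set[str] | None = None) -> dict:
    """Load a YAML config, validate keys, and merge over the defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config root must be a mapping")
    validate_config(cfg, sim_fields=sim_fields)
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in cfg.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged
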