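"""Stage partitioning, frequency normalization, the statistics policy and
report assembly.

The statistics policy mirrors common practice in the field: every group is
Shapiro-Wilk tested for normality (alpha = 0.05); two normal groups get a
two-tailed unpaired t-test, otherwise Mann-Whitney; more than two groups get
ordinary one-way ANOVA with Sidak post hoc, or Kruskal-Wallis with Dunn's
post hoc on the nonparametric branch.  The chosen branch is always reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .event_detection import CaEvent


# ---------------------------------------------------------------------------
# Stage assignment
# ---------------------------------------------------------------------------

def assign_stages(
    events: list[CaEvent],
    stage_intervals: list[tuple[str, float, float]],
) -> list[CaEvent]:
    """Label each event with the stage containing its onset.

    Intervals are half-open [start, end); an event spanning a boundary
    belongs to its onset's stage.  Onsets outside every interval are
    labelled 'unstaged'.  Overlapping intervals are an error.
    """
    ivs = sorted(stage_intervals, key=lambda iv: iv[1])
    for (l1, s1, e1), (l2, s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1 - 1e-9:
            raise ValueError(f"stage intervals {l1!r} and {l2!r} overlap")
    for ev in events:
        ev.stage = "unstaged"
        for label, s, e in ivs:
            if s <= ev.onset_s < e:
                ev.stage = label
                break
    return events


# ---------------------------------------------------------------------------
# Frequency normalization
# ---------------------------------------------------------------------------

@dataclass
class FrequencyResult:
    """Event rate for one scope with the compartment's normalization.

    Somatic (and in vitro) rates are events/min; dendritic rates are events
    per 1000 um2 per min (cell-wide dendritic transients are reported per
    imaged membrane area).
    """

    roi_id: str
    stage: str
    compartment: str
    n_events: int
    minutes: float
    area_um2: float | None
    rate: float
    units: str


def event_frequency(
    events: list[CaEvent] | int,
    stage: str,
    compartment: str,
    minutes: float,
    area_um2: float | None = None,
    roi_id: str = "",
) -> FrequencyResult:
    """Normalize an event count to a rate for the given scope."""
    if minutes <= 0:
        raise ValueError("exposure must be positive")
    n = events if isinstance(events, int) else len(events)
    if compartment == "dendrite":
        if area_um2 is None or area_um2 <= 0:
            raise ValueError("dendritic frequency needs a positive ROI area")
        rate = n / (area_um2 / 1000.0) / minutes
        units = "events per 1000 um2 per min"
    else:
        rate = n / minutes
        units = "events per min"
    return FrequencyResult(roi_id=roi_id, stage=stage, compartment=compartment,
                           n_events=n, minutes=minutes, area_um2=area_um2,
                           rate=rate, units=units)


# ---------------------------------------------------------------------------
# Group comparison policy
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    parametric: bool
    labels: list[str]
    posthoc: pd.DataFrame | None = None
    reason: str = ""


def _dunn_posthoc(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with tie correction, Sidak-adjusted."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start:start + g.size])))
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    rows = []
    raw_p = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                     * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j], "statistic": z, "p_raw": p})
        raw_p.append(min(p, 1.0 - 1e-15))  # keep the Sidak transform finite
    adj = multipletests(raw_p, method="sidak")[1] if raw_p else []
    out = pd.DataFrame(rows)
    out["p_adj"] = adj
    out["method"] = "dunn_sidak"
    return out


def _sidak_posthoc(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    rows = []
    raw_p = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        t, p = stats.ttest_ind(groups[i], groups[j])
        rows.append({"group_a": labels[i], "group_b": labels[j], "statistic": float(t),
                     "p_raw": float(p)})
        raw_p.append(p)
    adj = multipletests(raw_p, method="sidak")[1] if raw_p else []
    out = pd.DataFrame(rows)
    out["p_adj"] = adj
    out["method"] = "t_sidak"
    return out


def compare_groups(
    samples: list[np.ndarray],
    labels: list[str] | None = None,
    alpha_normality: float = 0.05,
    posthoc_alpha: float = 0.05,
) -> GroupComparison:
    """Normality-gated group comparison (the package's statistics policy).

    All groups must have n >= 3; otherwise only descriptives are meaningful
    and a ValueError is raised.  The parametric branch is taken only when
    every group passes Shapiro-Wilk at ``alpha_normality``.  For more than
    two groups a post hoc table is attached only if the omnibus test is
    significant at ``posthoc_alpha``.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if any(g.size < 3 for g in groups):
        raise ValueError("each group needs n >= 3 (report descriptives only)")
    if np.ptp(np.concatenate(groups)) == 0:
        # no variation anywhere: trivially no group difference
        return GroupComparison(test_name="degenerate", statistic=0.0, p_value=1.0,
                               parametric=False, labels=list(labels))

    def _normal(g: np.ndarray) -> bool:
        if np.ptp(g) == 0:
            return False  # degenerate: Shapiro undefined, treat as non-normal
        return stats.shapiro(g).pvalue > alpha_normality

    parametric = all(_normal(g) for g in groups)
    posthoc = None
    if len(groups) == 2:
        if parametric:
            res = stats.ttest_ind(groups[0], groups[1])
            name = "t_unpaired"
        else:
            res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            name = "mann_whitney"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        if parametric:
            res = stats.f_oneway(*groups)
            name = "anova"
        else:
            res = stats.kruskal(*groups)
            name = "kruskal_wallis"
        statistic, p = float(res.statistic), float(res.pvalue)
        if p < posthoc_alpha:
            posthoc = (_sidak_posthoc if parametric else _dunn_posthoc)(groups, labels)
    return GroupComparison(test_name=name, statistic=statistic, p_value=p,
                           parametric=parametric, labels=list(labels), posthoc=posthoc)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan, np.nan
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
    return float(np.mean(x)), sem


def build_report(
    events: pd.DataFrame,
    fidelity: pd.DataFrame,
    meta: pd.DataFrame,
    stages: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the per-(compartment, stage) summary and heatmap row order.

    Summary rows carry ROI-level mean +/- SEM of event frequencies,
    amplitudes, durations, coupling fidelity, and latency statistics (SEM
    over ROI-level values, matching how figure-level n's count ROIs).  The
    heatmap ordering sorts ROIs by the peak time of their largest cytosolic
    transient, as activity heatmaps are conventionally displayed.
    """
    comp_of = dict(zip(meta["roi_id"].astype(str), meta["compartment"]))
    area_of = {
        str(r.roi_id): (None if pd.isna(r.roi_area_um2) else float(r.roi_area_um2))
        for r in meta.drop_duplicates("roi_id").itertuples(index=False)
    }
    if stages is None or stages.empty:
        raise ValueError("missing stage annotation")
    stages = stages.copy()
    stages["minutes"] = (stages["t_end_s"] - stages["t_start_s"]) / 60.0
    exposure = stages.groupby([stages["roi_id"].astype(str), "stage"])["minutes"].sum()

    rows = []
    ev = events.copy()
    ev["roi_id"] = ev["roi_id"].astype(str)
    ev["compartment"] = ev["roi_id"].map(comp_of)
    fid = fidelity.copy()
    fid["roi_id"] = fid["roi_id"].astype(str)
    fid["compartment"] = fid["roi_id"].map(comp_of)

    for (comp, stage), grp in sorted(exposure.groupby(
            [exposure.index.get_level_values(0).map(comp_of),
             exposure.index.get_level_values(1)]).groups.items()):
        rois = sorted({roi for roi, _ in grp})
        row = {"compartment": comp, "stage": stage, "n_rois": len(rois)}
        for channel in ("cyto", "mito"):
            rates, amps, durs = [], [], []
            for roi in rois:
                minutes = float(exposure.loc[(roi, stage)])
                sub = ev[(ev["roi_id"] == roi) & (ev["stage"] == stage)
                         & (ev["channel"] == channel)]
                freq = event_frequency(len(sub), stage, comp, minutes,
                                       area_um2=area_of.get(roi), roi_id=roi)
                rates.append(freq.rate)
                if len(sub):
                    amps.append(sub["peak_amp_pct"].mean())
                    durs.append(sub["duration_s"].mean())
            for name, vals in ((f"{channel}_rate", rates), (f"{channel}_amp_pct", amps),
                               (f"{channel}_dur_s", durs)):
                m, s = _mean_sem(np.array(vals, dtype=float))
                row[f"{name}_mean"], row[f"{name}_sem"] = m, s
        sub_fid = fid[(fid["compartment"] == comp) & (fid["stage"] == stage)
                      & fid["defined"].astype(bool)]
        m, s = _mean_sem(sub_fid["fidelity_pct"].to_numpy())
        row["fidelity_pct_mean"], row["fidelity_pct_sem"] = m, s
        if pairs is not None and len(pairs):
            sub_pairs = pairs[(pairs["roi_id"].astype(str).map(comp_of) == comp)
                              & (~pairs["orphan"].astype(bool))]
            lat = sub_pairs["latency_s"].to_numpy(dtype=float)
            row["latency_mean_s"] = float(np.mean(lat)) if lat.size else np.nan
            row["latency_max_s"] = float(np.max(lat)) if lat.size else np.nan
        rows.append(row)
    summary = pd.DataFrame(rows)

    order_rows = []
    cyto = ev[ev["channel"] == "cyto"]
    for comp in sorted(set(comp_of.values())):
        sub = cyto[cyto["compartment"] == comp]
        peaks = {}
        for roi, grp in sub.groupby("roi_id"):
            best = grp.loc[grp["peak_amp_pct"].idxmax()]
            peaks[roi] = float(best["peak_time_s"])
        for rank, (roi, t_peak) in enumerate(
                sorted(peaks.items(), key=lambda kv: (kv[1], kv[0]))):
            order_rows.append({"compartment": comp, "roi_id": roi,
                               "order_index": rank, "peak_time_s": t_peak})
    heatmap_order = pd.DataFrame(order_rows,
                                 columns=["compartment", "roi_id", "order_index", "peak_time_s"])
    return {"summary": summary, "heatmap_order": heatmap_order}
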