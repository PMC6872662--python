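"""Pairing of mitochondrial events to their trigger cytosolic events and the
coupling-fidelity statistic.

Every mitochondrial transient is assumed to be triggered by an ongoing
cytosolic transient with its onset lagging by a seconds-scale latency, so a
mitochondrial event pairs with the *most recent* cytosolic onset inside a
compartment-specific window.  Coupling fidelity = N_mito / N_cyto x 100%,
the fraction of cytosolic transients accompanied by a mitochondrial one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .event_detection import CaEvent

#: Default maximum pairing latency (s) per compartment.  Observed latencies
#: are typically < 3 s in dendrites and < 6 s in somas (max 6.3 s in vitro);
#: the windows bound them with slack.
L_MAX_DEFAULTS = {"dendrite": 3.0, "soma": 6.0, "in_vitro": 8.0}


@dataclass
class CouplingPair:
    """A mitochondrial event linked to its trigger cytosolic event.

    ``cyto_event`` is None for orphans (no candidate trigger in the window).
    ``latency_s`` = mito onset - cyto onset; small negative values (down to
    -delta_pre) tolerate onset-detection jitter.
    """

    mito_event: CaEvent
    cyto_event: CaEvent | None
    latency_s: float | None

    @property
    def orphan(self) -> bool:
        return self.cyto_event is None


@dataclass
class FidelityResult:
    """Coupling fidelity for one scope (ROI x stage).

    ``fidelity_pct`` is None (undefined) when ``n_cyto`` = 0; ``over_100``
    flags the anomalous case of more mitochondrial than cytosolic events.
    """

    n_cyto: int
    n_mito: int
    fidelity_pct: float | None
    roi_id: str = ""
    stage: str = "all"

    @property
    def defined(self) -> bool:
        return self.fidelity_pct is not None

    @property
    def over_100(self) -> bool:
        return self.defined and self.fidelity_pct > 100.0


def pair_events(
    cyto_events: list[CaEvent],
    mito_events: list[CaEvent],
    delta_pre_s: float = 1.0,
    l_max_s: float = 6.0,
) -> list[CouplingPair]:
    """Pair each mitochondrial event with its most recent cytosolic trigger.

    Candidates for mito event m are cyto events with onset in
    [onset(m) - l_max_s, onset(m) + delta_pre_s]; the latest onset wins
    (ties broken toward the larger amplitude).  One cytosolic event triggers
    at most one mitochondrial event; unmatched mito events become orphans.
    Pairing depends only on onsets and is stable under input permutation.
    """
    rois = {e.roi_id for e in cyto_events} | {e.roi_id for e in mito_events}
    if len(rois) > 1:
        raise ValueError(f"pair_events expects a single ROI, got {sorted(rois)}")
    cyto_sorted = sorted(cyto_events, key=lambda e: (e.onset_s, -e.peak_amp_pct))
    used: set[int] = set()
    pairs = []
    for m in sorted(mito_events, key=lambda e: e.onset_s):
        best = None
        for idx, c in enumerate(cyto_sorted):
            if idx in used:
                continue
            if m.onset_s - l_max_s <= c.onset_s <= m.onset_s + delta_pre_s:
                if (best is None
                        or c.onset_s > cyto_sorted[best].onset_s
                        or (c.onset_s == cyto_sorted[best].onset_s
                            and c.peak_amp_pct > cyto_sorted[best].peak_amp_pct)):
                    best = idx
        if best is None:
            pairs.append(CouplingPair(mito_event=m, cyto_event=None, latency_s=None))
        else:
            used.add(best)
            c = cyto_sorted[best]
            pairs.append(CouplingPair(mito_event=m, cyto_event=c,
                                      latency_s=m.onset_s - c.onset_s))
    return pairs


def coupling_fidelity(
    cyto_events: list[CaEvent],
    mito_events: list[CaEvent],
    roi_id: str = "",
    stage: str = "all",
    count_steps: bool = False,
) -> FidelityResult:
    """N_mito / N_cyto x 100% over events already restricted to the scope.

    By default each transient counts once regardless of its number of
    staircase steps.  ``count_steps=True`` instead counts initiations
    (sum of n_steps), the unbiased trigger count when long transients
    absorb later triggers as steps.
    """
    n_cyto = len(cyto_events)
    n_mito = sum(max(e.n_steps, 1) for e in mito_events) if count_steps else len(mito_events)
    fidelity = None if n_cyto == 0 else 100.0 * n_mito / n_cyto
    return FidelityResult(n_cyto=n_cyto, n_mito=n_mito, fidelity_pct=fidelity,
                          roi_id=roi_id, stage=stage)


def coupled_vs_uncoupled_stats(
    cyto_events: list[CaEvent],
    pairs: list[CouplingPair],
) -> pd.DataFrame:
    """Contrast peak amplitude and duration of coupled vs uncoupled cyto events.

    Coupled = cytosolic events referenced by a non-orphan pair.  Means and
    SEMs are reported per group; the two-group test (normality-gated t /
    Mann-Whitney, via :func:`mitocoupling.stage_stats.compare_groups`) runs
    when both groups have >= 3 events, otherwise it is skipped with a reason.
    """
    from .stage_stats import compare_groups

    coupled_ids = {id(p.cyto_event) for p in pairs if not p.orphan}
    groups = {
        "coupled": [e for e in cyto_events if id(e) in coupled_ids],
        "uncoupled": [e for e in cyto_events if id(e) not in coupled_ids],
    }
    rows = []
    for metric, getter in (("peak_amp_pct", lambda e: e.peak_amp_pct),
                           ("duration_s", lambda e: e.duration_s)):
        samples = {g: np.array([getter(e) for e in evs]) for g, evs in groups.items()}
        row = {"metric": metric}
        for g, x in samples.items():
            row[f"{g}_n"] = x.size
            row[f"{g}_mean"] = float(np.mean(x)) if x.size else np.nan
            row[f"{g}_sem"] = float(stats.sem(x)) if x.size > 1 else np.nan
        if all(x.size >= 3 for x in samples.values()):
            res = compare_groups([samples["coupled"], samples["uncoupled"]])
            row.update(test=res.test_name, statistic=res.statistic, p_value=res.p_value)
        else:
            row.update(test="skipped: group with n < 3", statistic=np.nan, p_value=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def amplitude_correlation(pairs: list[CouplingPair]) -> dict[str, float]:
    """OLS regression of mito peak amplitude on its trigger cyto amplitude.

    Requires >= 3 non-orphan pairs and non-degenerate cytosolic amplitude
    variance.  Returns slope, intercept, Pearson r and its p value.
    """
    linked = [p for p in pairs if not p.orphan]
    if len(linked) < 3:
        raise ValueError("need >= 3 paired events for the amplitude regression")
    x = np.array([p.cyto_event.peak_amp_pct for p in linked])
    y = np.array([p.mito_event.peak_amp_pct for p in linked])
    if np.ptp(x) == 0:
        raise ValueError("degenerate cytosolic amplitude variance")
    if np.ptp(y) == 0:
        # constant response: slope 0 by convention, no linear association
        return {"slope": 0.0, "intercept": float(y[0]), "r": 0.0, "p": 1.0, "n": len(linked)}
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r": float(fit.rvalue), "p": float(fit.pvalue), "n": len(linked)}


def latency_summary(pairs: list[CouplingPair], bin_width_s: float = 1.0) -> dict:
    """Mean/max latency and a histogram (1-s bins) over non-orphan pairs.

    Negative latencies (onset jitter) are included in the mean and flagged.
    An empty pairing returns an empty summary (n = 0).
    """
    lat = np.array([p.latency_s for p in pairs if not p.orphan], dtype=float)
    if lat.size == 0:
        return {"n": 0, "mean_s": None, "max_s": None, "n_negative": 0,
                "hist_counts": np.array([], dtype=int), "hist_edges": np.array([])}
    lo = np.floor(lat.min() / bin_width_s) * bin_width_s
    hi = np.ceil(lat.max() / bin_width_s) * bin_width_s
    edges = np.arange(lo, hi + bin_width_s, bin_width_s)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width_s])
    counts, edges = np.histogram(lat, bins=edges)
    return {
        "n": int(lat.size),
        "mean_s": float(np.mean(lat)),
        "max_s": float(np.max(lat)),
        "n_negative": int(np.sum(lat < 0)),
        "hist_counts": counts,
        "hist_edges": edges,
    }
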