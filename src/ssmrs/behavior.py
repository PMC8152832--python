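"""Stop-signal task performance measures.

Computes the standard behavioral measures of an anticipated-response
stop-signal task from a trial-level table:

* ``go_rt`` — mean go response time in the 0% stop-signal-probability (SSP)
  baseline block (the internal timing response; 800 ms is a perfectly timed
  lift).
* ``go_rt_20`` / ``go_rt_40`` — mean go RT in the 20% / 40% SSP contexts.
* ``proactive_slowing`` — GoRT(40%) - GoRT(20%), the amount of proactive
  slowing induced by a higher stop probability.
* ``ssrt`` — stop-signal reaction time by the integration method: go RTs are
  rank-ordered and the mean stop-signal delay (SSD) is subtracted from the
  n-th go RT, with n = the number of go RTs times P(inhibit).
* ``mean_ssd``, ``p_inhibit``, ``rt_sf`` — mean stop-signal delay, proportion
  of successfully cancelled stop trials, and mean RT on failed stops.

Go trials with early responses (< 400 ms) or no response before the 1280 ms
trial deadline are removed before any RT statistic.  Measures are computed
per session and then averaged across the two assessment sessions; SSRT uses
the go RTs pooled over the 20% and 40% SSP conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GO_RT_MIN_MS",
    "GO_RT_MAX_MS",
    "SubjectPerformance",
    "filter_go_trials",
    "estimate_ssrt_integration",
    "compute_subject_performance",
    "performance_table",
    "summarize_group",
]

#: Go-trial RT filter: responses faster than this are discarded as early.
GO_RT_MIN_MS = 400.0
#: Go-trial RT filter: the indicator empties at 1280 ms; later/no lifts are omissions.
GO_RT_MAX_MS = 1280.0

#: The measures reported per subject, in table order.
PERFORMANCE_MEASURES = (
    "go_rt",
    "go_rt_20",
    "go_rt_40",
    "proactive_slowing",
    "ssrt",
    "mean_ssd",
    "p_inhibit",
    "rt_sf",
)


@dataclass(frozen=True)
class SubjectPerformance:
    """Session-averaged performance measures for one subject."""

    subject_id: str
    group: str
    go_rt: float
    go_rt_20: float
    go_rt_40: float
    proactive_slowing: float
    ssrt: float
    mean_ssd: float
    p_inhibit: float
    rt_sf: float
    n_valid_go: int
    n_stop: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def filter_go_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep go trials with a response inside the [400, 1280] ms window.

    Rows must all be go trials (raises ``ValueError`` otherwise).  Omissions
    (missing RT) are removed.  Row order is preserved.
    """
    if not (trials["trial_type"] == "go").all():
        raise ValueError("filter_go_trials expects go trials only")
    rt = trials["rt_ms"]
    keep = rt.notna() & (rt >= GO_RT_MIN_MS) & (rt <= GO_RT_MAX_MS)
    return trials[keep]


def estimate_ssrt_integration(
    go_rts: np.ndarray | list[float], mean_ssd: float, p_inhibit: float
) -> float:
    """Integration-method SSRT: n-th rank-ordered go RT minus mean SSD.

    ``n = round(N * p_inhibit)`` (half-up), clamped to ``[1, N]``.  Requires
    at least one (already filtered) go RT and ``0 < p_inhibit < 1``; at the
    boundaries the targeted go-RT quantile is undefined for this estimator.
    """
    rts = np.asarray(go_rts, dtype=float)
    if rts.size == 0:
        raise ValueError("cannot estimate SSRT from an empty go-RT sample")
    if not (0.0 < p_inhibit < 1.0):
        raise ValueError(
            f"integration SSRT undefined for p_inhibit={p_inhibit}; need 0 < p < 1"
        )
    if not math.isfinite(mean_ssd):
        raise ValueError("mean_ssd must be finite")
    n_total = rts.size
    n = int(math.floor(n_total * p_inhibit + 0.5))
    n = min(max(n, 1), n_total)
    return float(np.sort(rts)[n - 1] - mean_ssd)


def _session_measures(
    session_trials: pd.DataFrame, subject_id: str
) -> dict[str, float]:
    """Raw measures for a single session (NaN where undefined)."""
    go = session_trials[session_trials["trial_type"] == "go"]
    stop = session_trials[session_trials["trial_type"] == "stop"]
    valid_go = filter_go_trials(go)

    def mean_rt(ssp: int) -> float:
        rts = valid_go.loc[valid_go["ssp"] == ssp, "rt_ms"]
        return float(rts.mean()) if len(rts) else np.nan

    out = {
        "go_rt": mean_rt(0),
        "go_rt_20": mean_rt(20),
        "go_rt_40": mean_rt(40),
        "n_valid_go": float(len(valid_go)),
        "n_stop": float(len(stop)),
        "mean_ssd": np.nan,
        "p_inhibit": np.nan,
        "rt_sf": np.nan,
        "ssrt": np.nan,
    }
    if len(stop) == 0:
        logger.warning(
            "subject %s: session with no stop trials; SSRT excluded from average",
            subject_id,
        )
        return out
    success = stop["stop_success"].astype(bool).to_numpy()
    out["mean_ssd"] = float(stop["ssd_ms"].mean())
    out["p_inhibit"] = float(success.mean())
    failed_rts = stop.loc[~success, "rt_ms"].dropna()
    out["rt_sf"] = float(failed_rts.mean()) if len(failed_rts) else np.nan
    pooled = valid_go.loc[valid_go["ssp"].isin((20, 40)), "rt_ms"].to_numpy()
    if pooled.size and 0.0 < out["p_inhibit"] < 1.0:
        out["ssrt"] = estimate_ssrt_integration(
            pooled, out["mean_ssd"], out["p_inhibit"]
        )
    else:
        logger.warning(
            "subject %s: SSRT undefined this session (p_inhibit=%.2f, "
            "n pooled go=%d); excluded from average",
            subject_id,
            out["p_inhibit"],
            pooled.size,
        )
    return out


def compute_subject_performance(
    trials: pd.DataFrame, slowing: str = "difference-of-averages"
) -> SubjectPerformance:
    """Session-averaged performance measures for one subject's trials.

    Each measure is computed per session and averaged across sessions,
    skipping sessions where it is undefined.  ``slowing`` selects whether
    proactive slowing is the difference of session-averaged GoRT_40 and
    GoRT_20 (default) or the session-average of per-session differences —
    identical when both sessions contribute both conditions.
    """
    if slowing not in ("difference-of-averages", "average-of-differences"):
        raise ValueError(f"unknown slowing convention: {slowing!r}")
    subject_ids = trials["subject_id"].unique()
    if len(subject_ids) != 1:
        raise ValueError("compute_subject_performance expects a single subject")
    subject_id = str(subject_ids[0])
    group = str(trials["group"].iloc[0])

    per_session = [
        _session_measures(trials[trials["session"] == s], subject_id)
        for s in sorted(trials["session"].unique())
    ]
    with np.errstate(invalid="ignore"):
        avg = {
            key: float(np.nanmean([m[key] for m in per_session]))
            if not all(np.isnan(m[key]) for m in per_session)
            else np.nan
            for key in per_session[0]
        }
    if slowing == "difference-of-averages":
        proactive = avg["go_rt_40"] - avg["go_rt_20"]
    else:
        diffs = [m["go_rt_40"] - m["go_rt_20"] for m in per_session]
        proactive = float(np.nanmean(diffs)) if not all(np.isnan(diffs)) else np.nan
    return SubjectPerformance(
        subject_id=subject_id,
        group=group,
        go_rt=avg["go_rt"],
        go_rt_20=avg["go_rt_20"],
        go_rt_40=avg["go_rt_40"],
        proactive_slowing=proactive,
        ssrt=avg["ssrt"],
        mean_ssd=avg["mean_ssd"],
        p_inhibit=avg["p_inhibit"],
        rt_sf=avg["rt_sf"],
        n_valid_go=int(sum(m["n_valid_go"] for m in per_session)),
        n_stop=int(sum(m["n_stop"] for m in per_session)),
    )


def performance_table(
    trials: pd.DataFrame, slowing: str = "difference-of-averages"
) -> pd.DataFrame:
    """One row of :class:`SubjectPerformance` per subject, in subject order."""
    rows = [
        compute_subject_performance(sub, slowing=slowing).as_dict()
        for _, sub in trials.groupby("subject_id", sort=True)
    ]
    return pd.DataFrame(rows)


def summarize_group(
    performance: pd.DataFrame,
    measures: tuple[str, ...] = PERFORMANCE_MEASURES,
) -> pd.DataFrame:
    """Group means and sample SDs (n-1 denominator) of each measure.

    Returns a table with one row per measure and a (group, statistic) column
    hierarchy.  Every group must contribute at least two subjects.
    """
    counts = performance.groupby("group").size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 subjects: {small}")
    agg = performance.groupby("group")[list(measures)].agg(["mean", "std"])
    # pandas std defaults to ddof=1 (sample SD), matching group-summary convention
    table = agg.T.unstack(level=-1)
    table.columns = pd.MultiIndex.from_tuples(
        [(g, s) for g, s in table.columns], names=["group", "stat"]
    )
    return table.loc[list(measures)]
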