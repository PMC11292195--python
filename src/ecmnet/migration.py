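"""Per-track cell motility metrics and condition-level comparisons.

Metrics per track: total path length (sum of consecutive Euclidean
steps), net displacement (start to end), directionality index
DI = net / total in [0, 1] (1 = perfectly persistent motion, 0 for a
closed loop), and speed = total path length / elapsed time in um/hour.
The path-length speed definition is robust to dropped frames; gaps are
bridged by straight segments, matching common tracker behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import dunn_test
from .cohort_io import TrackTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrackMetrics:
    track_id: object
    speed: float                 # um/hour
    directionality_index: float  # dimensionless, [0, 1]
    net_distance: float          # um
    total_distance: float        # um
    duration: float              # hours
    n_points: int
    condition: object = None


def track_metrics(track: pd.DataFrame, track_id=None, condition=None) -> TrackMetrics:
    """Metrics for one time-ordered track (columns t [min], x, y [um])."""
    t = np.asarray(track["t"], dtype=float)
    x = np.asarray(track["x"], dtype=float)
    y = np.asarray(track["y"], dtype=float)
    if t.size < 2:
        raise ValueError("track needs >= 2 points")
    order = np.argsort(t, kind="stable")
    t, x, y = t[order], x[order], y[order]
    if (np.diff(t) <= 0).any():
        raise ValueError("duplicate or non-increasing timestamps in track")
    steps = np.hypot(np.diff(x), np.diff(y))
    total = float(steps.sum())
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    duration_h = float((t[-1] - t[0]) / 60.0)
    di = net / total if total > 0 else 0.0
    return TrackMetrics(
        track_id=track_id, speed=total / duration_h,
        directionality_index=min(di, 1.0), net_distance=net,
        total_distance=total, duration=duration_h, n_points=int(t.size),
        condition=condition,
    )


def table_metrics(table: TrackTable) -> pd.DataFrame:
    """TrackMetrics for every track in a table, as a DataFrame."""
    rows = []
    has_condition = "condition" in table.data.columns
    for tid, grp in table.tracks():
        condition = grp["condition"].iloc[0] if has_condition else None
        m = track_metrics(grp, track_id=tid, condition=condition)
        rows.append(m.__dict__)
    return pd.DataFrame(rows).set_index("track_id")


def filter_tracks(table: TrackTable, min_duration: float = 0.0,
                  min_points: int = 2) -> TrackTable:
    """Drop tracks below duration (minutes, inclusive threshold) or point count."""
    keep_ids = []
    for tid, grp in table.tracks():
        duration = float(grp["t"].max() - grp["t"].min())
        if len(grp) >= min_points and duration >= min_duration:
            keep_ids.append(tid)
    dropped = len(table) - len(keep_ids)
    if dropped:
        logger.info("filter_tracks dropped %d of %d tracks", dropped, len(table))
    if not keep_ids:
        raise ValueError("no track passes the filters")
    return TrackTable(table.data[table.data["track_id"].isin(keep_ids)].reset_index(drop=True))


def compare_conditions(metrics: pd.DataFrame, value: str = "speed",
                       condition_col: str = "condition", min_tracks: int = 3) -> dict:
    """Compare a per-track metric across conditions (pooled-experiment mode).

    Two conditions: two-sided Mann-Whitney U.  More: Kruskal-Wallis plus
    Dunn pairwise tests with BH adjustment.  Conditions with fewer than
    ``min_tracks`` tracks are excluded (logged).
    """
    groups = {}
    for cond, grp in metrics.groupby(condition_col):
        vals = grp[value].dropna().to_numpy()
        if len(vals) < min_tracks:
            logger.warning("condition %r has %d tracks (< %d); excluded",
                           cond, len(vals), min_tracks)
            continue
        groups[cond] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 usable conditions")
    names = sorted(groups)
    report = {
        "value": value,
        "conditions": names,
        "n": {c: int(len(groups[c])) for c in names},
        "medians": {c: float(np.median(groups[c])) for c in names},
    }
    if len(names) == 2:
        a, b = groups[names[0]], groups[names[1]]
        if np.ptp(np.concatenate([a, b])) == 0:
            u, p = len(a) * len(b) / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        report.update(test="mannwhitney", statistic=float(u), p_value=float(p))
    else:
        kw = stats.kruskal(*(groups[c] for c in names))
        values = np.concatenate([groups[c] for c in names])
        labels = np.concatenate([np.full(len(groups[c]), c) for c in names])
        report.update(test="kruskal+dunn", statistic=float(kw.statistic),
                      p_value=float(kw.pvalue), dunn=dunn_test(values, labels))
    return report
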