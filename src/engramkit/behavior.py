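"""Recognition-memory trial scoring.

Turns manually-scored exploration logs (one bout = one approach to an
object with the nose directed at it) into per-object exploration times,
interaction counts, a discrimination index, locomotion distance, and
nose-position occupancy heatmaps, plus the one-sample test of the group
discrimination index against chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParseError, UndefinedStatistic

REQUIRED_LOG_COLUMNS = ("object_label", "t_start_s", "t_stop_s")


@dataclass
class TrialLog:
    """Ordered exploration bouts for one trial of one animal.

    ``bouts`` has columns ``object_label``, ``t_start_s``, ``t_stop_s``
    (seconds, floats).  Bouts with ``t_stop <= t_start`` are invalid;
    overlapping bouts — a manual-scoring artifact — are tolerated with a
    warning and summed as recorded.
    """

    animal_id: str
    trial_id: str
    bouts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_LOG_COLUMNS if c not in self.bouts.columns]
        if missing:
            raise ParseError(f"trial log missing columns: {missing}")
        bad = self.bouts["t_stop_s"] < self.bouts["t_start_s"]
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"bout row {row}: t_stop_s < t_start_s "
                f"({self.bouts['t_stop_s'].iloc[row]} < {self.bouts['t_start_s'].iloc[row]})"
            )
        b = self.bouts.sort_values("t_start_s")
        if len(b) > 1 and (b["t_start_s"].to_numpy()[1:] < b["t_stop_s"].to_numpy()[:-1]).any():
            warnings.warn(
                f"trial {self.animal_id}/{self.trial_id}: overlapping bouts "
                "(manual-scoring artifact); durations summed as recorded",
                stacklevel=2,
            )


class TrialSummary(NamedTuple):
    animal_id: str
    trial_id: str
    time_per_object: dict
    interactions_per_object: dict
    di: float  # NaN when exploration time is zero (undefined)
    total_distance: float | None


def read_event_log(path, animal_id: str = "", trial_id: str = "") -> TrialLog:
    """Parse a bout-level event-log CSV into a validated :class:`TrialLog`.

    Expects columns ``object_label, t_start_s, t_stop_s`` (a leading
    ``bout_index`` column is accepted and ignored).  Malformed rows raise
    :class:`ParseError` naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("t_start_s", "t_stop_s"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise ParseError(f"{path}: non-numeric {col} at row {int(np.flatnonzero(bad)[0])}")
        df[col] = vals
    if (df["t_start_s"] < 0).any():
        row = int(np.flatnonzero((df["t_start_s"] < 0).to_numpy())[0])
        raise ParseError(f"{path}: negative t_start_s at row {row}")
    return TrialLog(animal_id=animal_id, trial_id=trial_id, bouts=df)


def discrimination_index(t_novel: float, t_familiar: float) -> float:
    """Discrimination index: (t_novel − t_familiar) / (t_novel + t_familiar).

    Lies in [−1, 1]; positive values indicate preference for the novel
    object.  Undefined when total exploration time is zero — that case
    raises :class:`UndefinedStatistic` rather than returning 0, since an
    animal that explored nothing expresses no preference.
    """
    if t_novel < 0 or t_familiar < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_novel + t_familiar
    if total == 0:
        raise UndefinedStatistic("DI undefined: zero total exploration time")
    return (t_novel - t_familiar) / total


def _label_pair(labels) -> tuple[str, str]:
    """Return (novel-like, familiar-like) labels for DI computation."""
    s = set(labels)
    if {"novel", "familiar"} <= s or s <= {"novel", "familiar"}:
        return "novel", "familiar"
    if s <= {"object1", "object2"}:
        return "object1", "object2"
    raise ParseError(f"unrecognized object labels: {sorted(s)}")


def summarize_trial(log: TrialLog, coords: pd.DataFrame | None = None) -> TrialSummary:
    """Score one trial: per-object time, interaction counts, DI, distance.

    Per-object time is the sum of bout durations; interactions the bout
    count.  DI is NaN (flagged for QC, excluded from group means) when
    total exploration is zero.  When a coordinate track is supplied, total
    distance is the summed frame-to-frame Euclidean step length of the
    body-center marker.
    """
    b = log.bouts
    dur = b["t_stop_s"] - b["t_start_s"]
    time_per = dur.groupby(b["object_label"]).sum().to_dict()
    n_per = b["object_label"].value_counts().to_dict()
    novel_lab, fam_lab = _label_pair(b["object_label"]) if len(b) else ("novel", "familiar")
    t_n = float(time_per.get(novel_lab, 0.0))
    t_f = float(time_per.get(fam_lab, 0.0))
    try:
        di = discrimination_index(t_n, t_f)
    except UndefinedStatistic:
        di = float("nan")
    dist = total_distance(coords) if coords is not None else None
    return TrialSummary(log.animal_id, log.trial_id, time_per, n_per, di, dist)


def total_distance(coords: pd.DataFrame, x_col: str = "x_cm", y_col: str = "y_cm") -> float:
    """Path length (cm) of a tracked marker: sum of per-frame Euclidean steps."""
    xy = coords[[x_col, y_col]].to_numpy(dtype=float)
    if len(xy) < 2:
        return 0.0
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def occupancy_heatmap(
    coords: pd.DataFrame,
    arena_size: tuple[float, float],
    n_bins: int = 20,
    x_col: str = "x_cm",
    y_col: str = "y_cm",
) -> np.ndarray:
    """Percent-time occupancy grid of a position track.

    Bins the track into an ``n_bins x n_bins`` histogram over the arena
    (origin at a corner, extents ``arena_size`` in cm) and normalizes it to
    sum to exactly 100.  Samples outside the arena are clipped to the
    boundary with a warning.
    """
    x = coords[x_col].to_numpy(dtype=float)
    y = coords[y_col].to_numpy(dtype=float)
    if len(x) == 0:
        raise ValueError("empty coordinate track")
    w, h = arena_size
    if (x < 0).any() or (x > w).any() or (y < 0).any() or (y > h).any():
        warnings.warn("coordinates outside arena bounds; clipping", stacklevel=2)
        x = np.clip(x, 0, w)
        y = np.clip(y, 0, h)
    grid, _, _ = np.histogram2d(x, y, bins=n_bins, range=[[0, w], [0, h]])
    return grid * (100.0 / grid.sum())


def di_vs_chance(di_values: Sequence[float]) -> tuple[float, float]:
    """One-sample two-sided t-test of per-animal DIs against chance (0).

    Returns ``(t, p)``.  NaN DIs (zero-exploration animals) are excluded.
    With zero variance the t statistic is degenerate: all-zero samples give
    ``(0, 1)``; constant non-zero samples give a signed infinite t with
    p = 0, emitted with a warning.
    """
    v = np.asarray(di_values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 DI values for a one-sample t-test")
    if np.ptp(v) == 0:
        if v[0] == 0:
            return 0.0, 1.0
        warnings.warn("zero-variance DI sample: t statistic is infinite", stacklevel=2)
        return float(np.sign(v[0]) * np.inf), 0.0
    res = stats.ttest_1samp(v, popmean=0.0)
    return float(res.statistic), float(res.pvalue)
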