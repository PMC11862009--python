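"""Frame-to-frame linking of condensate detections, nucleus-motion
correction, MSD and anomalous-exponent estimation.

Linking solves the linear assignment problem per frame pair on squared
displacements, with a gating cost above which links are forbidden and
detections start or terminate tracks instead (default 16,900, i.e. a
130-pixel gating radius when coordinates are pixels).  A new track whose
first point lies within the splitting cost of a live track at the previous
frame is recorded as that track's split child.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress

_BIG = 1e30


def correct_for_nucleus(
    detections: pd.DataFrame, nucleus_centers: pd.DataFrame
) -> pd.DataFrame:
    """Subtract the per-frame nucleus center (columns frame, x, y) from
    detection coordinates (columns frame, x, y)."""
    merged = detections.merge(
        nucleus_centers, on="frame", suffixes=("", "_nuc"), validate="many_to_one"
    )
    out = detections.copy()
    out["x"] = merged["x"].to_numpy() - merged["x_nuc"].to_numpy()
    out["y"] = merged["y"].to_numpy() - merged["y_nuc"].to_numpy()
    return out


def _lap_frame_pair(prev_xy: np.ndarray, next_xy: np.ndarray, cost_cutoff: float):
    """Jaqaman-style augmented LAP; returns list of (i_prev, j_next) links."""
    n, m = len(prev_xy), len(next_xy)
    diff = prev_xy[:, None, :] - next_xy[None, :, :]
    cost = (diff**2).sum(axis=2)
    feasible = cost <= cost_cutoff
    big = np.full((n + m, m + n), _BIG)
    big[:n, :m] = np.where(feasible, cost, _BIG)
    big[np.arange(n), m + np.arange(n)] = cost_cutoff  # deaths
    big[n + np.arange(m), np.arange(m)] = cost_cutoff  # births
    big[n:, m:] = np.where(feasible.T, 0.0, _BIG)  # auxiliary block
    rows, cols = linear_sum_assignment(big)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and feasible[r, c]
    ]


def link_tracks(
    detections: pd.DataFrame,
    cost_cutoff: float = 16_900.0,
    split_cutoff: float = 100.0,
) -> pd.DataFrame:
    """Link per-frame 2D detections (columns frame, x, y) into tracks.

    Returns the detection table with ``track_id`` and ``parent_id`` columns
    (parent_id = -1 for tracks without a split parent).  Assignment per
    frame pair is the exact global LAP minimum, so results do not depend on
    detection order within a frame.
    """
    for col in ("frame", "x", "y"):
        if col not in detections.columns:
            raise ValueError(f"detections must have a {col!r} column")
    frames = np.sort(detections["frame"].unique())
    if len(frames) < 2:
        raise ValueError("need detections in at least 2 frames to link")
    det = detections.sort_values(["frame"]).reset_index(drop=True)
    det["track_id"] = -1
    det["parent_id"] = -1

    by_frame = {f: det.index[det["frame"] == f].to_numpy() for f in frames}
    next_tid = 0
    for i in by_frame[frames[0]]:
        det.loc[i, "track_id"] = next_tid
        next_tid += 1
    for fprev, fnext in zip(frames[:-1], frames[1:]):
        prev_idx, next_idx = by_frame[fprev], by_frame[fnext]
        prev_xy = det.loc[prev_idx, ["x", "y"]].to_numpy(float)
        next_xy = det.loc[next_idx, ["x", "y"]].to_numpy(float)
        links = (
            _lap_frame_pair(prev_xy, next_xy, cost_cutoff)
            if len(prev_idx) and len(next_idx)
            else []
        )
        linked_next = set()
        for i, j in links:
            det.loc[next_idx[j], "track_id"] = det.loc[prev_idx[i], "track_id"]
            linked_next.add(j)
        for j in range(len(next_idx)):
            if j not in linked_next:
                det.loc[next_idx[j], "track_id"] = next_tid
                next_tid += 1
        # split detection: a fresh track starting next to a live track
        for j in range(len(next_idx)):
            if j in linked_next or len(prev_idx) == 0:
                continue
            d2 = ((prev_xy - next_xy[j]) ** 2).sum(axis=1)
            k = int(np.argmin(d2))
            if d2[k] <= split_cutoff:
                det.loc[next_idx[j], "parent_id"] = det.loc[prev_idx[k], "track_id"]
    # propagate parent to whole child track
    starts = det.loc[det["parent_id"] >= 0, ["track_id", "parent_id"]]
    parent_map = dict(zip(starts["track_id"], starts["parent_id"]))
    det["parent_id"] = det["track_id"].map(parent_map).fillna(-1).astype(int)
    return det


def compute_msd(tracks: pd.DataFrame, time_averaged: bool = False) -> pd.DataFrame:
    """Ensemble MSD per lag.

    Default follows the reference-point definition: each track contributes
    |r(t) - r(t0)|^2 with t0 its own first frame, averaged across tracks at
    each elapsed time.  ``time_averaged=True`` instead averages over all
    same-lag pairs within each track before the ensemble mean.

    Expects columns track_id, t_min, x_um, y_um; returns columns
    lag_min, msd, sd, n.
    """
    required = {"track_id", "t_min", "x_um", "y_um"}
    missing = required - set(tracks.columns)
    if missing:
        raise ValueError(f"track table missing column(s) {sorted(missing)}")
    per_lag: dict[float, list[float]] = {}
    for _, grp in tracks.groupby("track_id"):
        g = grp.sort_values("t_min")
        t = g["t_min"].to_numpy(float)
        xy = g[["x_um", "y_um"]].to_numpy(float)
        if time_averaged:
            n = len(t)
            dt0 = np.diff(t).min() if n > 1 else 0.0
            for lag_steps in range(1, n):
                d = xy[lag_steps:] - xy[:-lag_steps]
                per_lag.setdefault(round(lag_steps * dt0, 9), []).append(
                    float((d**2).sum(axis=1).mean())
                )
        else:
            sq = ((xy - xy[0]) ** 2).sum(axis=1)
            for lag, v in zip(t - t[0], sq):
                per_lag.setdefault(round(float(lag), 9), []).append(float(v))
    rows = [
        (lag, float(np.mean(v)), float(np.std(v)), len(v))
        for lag, v in sorted(per_lag.items())
    ]
    return pd.DataFrame(rows, columns=["lag_min", "msd", "sd", "n"])


def fit_alpha(
    msd: pd.DataFrame, window_hours: float = 7.0
) -> tuple[float, float]:
    """Least-squares line on (log t, log MSD) for lags within the window;
    returns (alpha, D) with MSD = D * t^alpha, t in minutes."""
    sel = msd[(msd["lag_min"] > 0) & (msd["lag_min"] <= window_hours * 60.0)]
    bad = sel["msd"] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} nonpositive MSD value(s) from fit")
        sel = sel[~bad]
    if len(sel) < 3:
        raise ValueError("need at least 3 positive-lag MSD points inside the window")
    res = linregress(np.log(sel["lag_min"]), np.log(sel["msd"]))
    return float(res.slope), float(np.exp(res.intercept))


def displacement_stats(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-track mean absolute displacement per minute, lifetime, and total
    path length.  Single-frame tracks get lifetime 0 and null displacement."""
    rows = []
    for tid, grp in tracks.groupby("track_id"):
        g = grp.sort_values("t_min")
        t = g["t_min"].to_numpy(float)
        xy = g[["x_um", "y_um"]].to_numpy(float)
        lifetime = float(t[-1] - t[0])
        if len(t) < 2:
            rows.append((tid, np.nan, 0.0, 0.0))
            continue
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        intervals = np.diff(t)
        rate = float(np.mean(steps / intervals))
        rows.append((tid, rate, lifetime, float(steps.sum())))
    return pd.DataFrame(
        rows, columns=["track_id", "um_per_min", "lifetime_min", "path_length_um"]
    )
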