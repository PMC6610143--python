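"""Nearest-neighbor track linking and the bound-molecule track filter.

Linking is greedy by ascending pairwise distance between the heads of
open tracks and the localizations of the next frame, one-to-one, which
makes conflicts and ties deterministic (exact ties break toward the lower
localization row index).  No gap closing is performed by default: the
bound-molecule filter demands strictly consecutive frames, so gaps would
be pathological anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BoundFilterParams",
    "link_nearest_neighbor",
    "filter_bound",
    "track_jump_stats",
    "track_jumps_um",
]

TRACK_TABLE_COLUMNS = ["track_id", "frame", "x_um", "y_um", "channel"]


@dataclass
class BoundFilterParams:
    """Mobility filter used to isolate chromatin-bound molecules.

    A track is kept only when it spans at least ``min_length_frames``
    consecutive frames and every frame-to-frame jump is strictly below
    ``max_jump_nm``.
    """

    min_length_frames: int = 16
    max_jump_nm: float = 220.0

    def __post_init__(self) -> None:
        if self.min_length_frames < 2:
            raise ValueError("min_length_frames must be >= 2")
        if self.max_jump_nm <= 0:
            raise ValueError("max_jump_nm must be > 0")


def link_nearest_neighbor(
    locs: pd.DataFrame,
    max_disp_um: float,
    memory_frames: int = 0,
) -> pd.DataFrame:
    """Link localizations frame-to-frame into tracks.

    Parameters
    ----------
    locs
        Localization table with at least ``frame``, ``x_um``, ``y_um``
        (``channel`` optional, carried through).
    max_disp_um
        Maximum allowed displacement per frame transition, µm.
    memory_frames
        Number of consecutive frames a track may go unmatched before it is
        terminated.  Default 0: a track ends as soon as it misses a frame.

    Returns
    -------
    DataFrame
        The input rows with a ``track_id`` column, sorted by
        ``(track_id, frame)``.
    """
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be > 0")
    if memory_frames < 0:
        raise ValueError("memory_frames must be >= 0")
    if len(locs) == 0:
        out = locs.copy()
        out["track_id"] = pd.Series(dtype=int)
        return out

    df = locs.reset_index(drop=True).copy()
    df["_row"] = np.arange(len(df))
    # deterministic candidate order regardless of input row order
    df = df.sort_values(["frame", "x_um", "y_um"], kind="mergesort").reset_index(drop=True)

    track_ids = np.full(len(df), -1, dtype=int)
    next_tid = 0
    # open tracks: tid -> (x, y, last_frame)
    open_tracks: dict[int, tuple[float, float, int]] = {}

    for frame, grp in df.groupby("frame", sort=True):
        frame = int(frame)
        idx = grp.index.to_numpy()
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        # prune tracks whose memory expired
        open_tracks = {
            tid: st for tid, st in open_tracks.items() if frame - st[2] <= memory_frames + 1
        }
        cands = []
        for tid, (tx, ty, _last) in open_tracks.items():
            d = np.hypot(xy[:, 0] - tx, xy[:, 1] - ty)
            for j in np.flatnonzero(d <= max_disp_um):
                cands.append((d[j], tid, int(idx[j])))
        cands.sort(key=lambda c: (c[0], c[2], c[1]))
        used_tracks: set[int] = set()
        used_locs: set[int] = set()
        for d, tid, j in cands:
            if tid in used_tracks or j in used_locs:
                continue
            used_tracks.add(tid)
            used_locs.add(j)
            track_ids[j] = tid
            open_tracks[tid] = (df.at[j, "x_um"], df.at[j, "y_um"], frame)
        # close tracks that missed this frame (memory handled by prune above)
        for j in idx:
            if track_ids[j] < 0:
                track_ids[j] = next_tid
                open_tracks[next_tid] = (df.at[j, "x_um"], df.at[j, "y_um"], frame)
                next_tid += 1

    df["track_id"] = track_ids
    df = df.sort_values(["track_id", "frame"], kind="mergesort")
    cols = ["track_id"] + [c for c in df.columns if c not in ("track_id", "_row")]
    return df[cols].reset_index(drop=True)


def track_jumps_um(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-step Euclidean displacements (µm) within each track."""
    t = tracks.sort_values(["track_id", "frame"], kind="mergesort")
    dx = t.groupby("track_id")["x_um"].diff()
    dy = t.groupby("track_id")["y_um"].diff()
    out = t.assign(jump_um=np.hypot(dx, dy))
    return out[out["jump_um"].notna()][["track_id", "frame", "jump_um"]]


def filter_bound(tracks: pd.DataFrame, params: BoundFilterParams | None = None) -> pd.DataFrame:
    """Keep only tracks consistent with a bound (immobile) molecule.

    Retains exactly the tracks with length ≥ ``min_length_frames`` frames
    and all frame-to-frame jumps strictly below ``max_jump_nm``; row order
    is preserved.  Idempotent, and the output is always a subset of the
    input.
    """
    params = params or BoundFilterParams()
    if len(tracks) == 0:
        return tracks.copy()
    lengths = tracks.groupby("track_id")["frame"].size()
    jumps = track_jumps_um(tracks)
    max_jump = jumps.groupby("track_id")["jump_um"].max()
    keep = set(lengths[lengths >= params.min_length_frames].index)
    limit_um = params.max_jump_nm / 1000.0
    keep &= set(max_jump[max_jump < limit_um].index)
    return tracks[tracks["track_id"].isin(keep)].copy()


def track_jump_stats(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-track summary: length, mean position, mean frame-to-frame jump.

    Length-1 tracks have no jumps; their mean jump is reported as NaN.
    """
    if len(tracks) == 0:
        return pd.DataFrame(
            columns=["track_id", "n_frames", "mean_jump_um", "mean_x_um", "mean_y_um"]
        )
    g = tracks.groupby("track_id")
    summary = pd.DataFrame(
        {
            "n_frames": g["frame"].size(),
            "mean_x_um": g["x_um"].mean(),
            "mean_y_um": g["y_um"].mean(),
        }
    )
    jumps = track_jumps_um(tracks)
    summary["mean_jump_um"] = jumps.groupby("track_id")["jump_um"].mean()
    summary = summary.reset_index()
    return summary[["track_id", "n_frames", "mean_jump_um", "mean_x_um", "mean_y_um"]]
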