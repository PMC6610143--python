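"""Mobility read-outs from tracks: MSD, diffusion fits, mobility maps, directed motion.

The ensemble MSD is time-averaged within each track (over all ordered
frame pairs of a given lag) and then averaged across tracks, with the
across-track SEM as the error bar.  The diffusion coefficient comes from
an ordinary least-squares line through the first few lags with a free
intercept (which absorbs static localization error), via the 2-D Brownian
relation MSD(τ) = m·τ with slope m = 4D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "DirectedEvent",
    "ensemble_msd",
    "fit_diffusion",
    "mobility_map",
    "directed_events",
]


@dataclass
class MSDCurve:
    lags_s: np.ndarray
    msd_um2: np.ndarray
    sem_um2: np.ndarray
    n_tracks: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_s": self.lags_s, "msd_um2": self.msd_um2, "sem_um2": self.sem_um2}
        )


@dataclass
class DiffusionFit:
    """Line fit MSD(τ) = intercept + m·τ with D = m/4."""

    m: float
    intercept: float
    D: float
    ci95: float
    n_points_fit: int
    negative_slope: bool = False


@dataclass
class DirectedEvent:
    track_id: int
    start_frame: int
    end_frame: int
    mean_speed_um_s: float
    path_length_um: float
    net_displacement_um: float


def ensemble_msd(
    tracks: pd.DataFrame,
    max_lag_frames: int,
    frame_interval_s: float = 1.0,
) -> MSDCurve:
    """Ensemble (across-track) average of time-averaged per-track MSDs.

    For each track, MSD at lag ℓ averages the squared displacement over
    every ordered frame pair ℓ apart; the curve is the unweighted mean of
    these per-track values across all tracks long enough for that lag,
    with SEM = across-track SD / √n.
    """
    if max_lag_frames < 1:
        raise ValueError("max_lag_frames must be >= 1")
    groups = [
        g[["x_um", "y_um"]].to_numpy(float)
        for _, g in tracks.sort_values(["track_id", "frame"]).groupby("track_id")
        if len(g) >= 2
    ]
    if not groups:
        raise ValueError("need at least one track of length >= 2")
    longest = max(len(g) for g in groups)
    if max_lag_frames > longest - 1:
        raise ValueError(
            f"max_lag_frames={max_lag_frames} exceeds every track length (longest {longest})"
        )
    per_track = np.full((len(groups), max_lag_frames), np.nan)
    for i, xy in enumerate(groups):
        n = len(xy)
        for lag in range(1, min(max_lag_frames, n - 1) + 1):
            d = xy[lag:] - xy[:-lag]
            per_track[i, lag - 1] = np.mean(np.sum(d * d, axis=1))
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        msd = np.nanmean(per_track, axis=0)
        counts = np.sum(~np.isnan(per_track), axis=0)
        sd = np.nanstd(per_track, axis=0, ddof=1)
    sem = np.where(counts > 1, sd / np.sqrt(counts), 0.0)
    lags = np.arange(1, max_lag_frames + 1) * frame_interval_s
    return MSDCurve(lags, msd, sem, n_tracks=len(groups))


def fit_diffusion(msd: MSDCurve, n_points: int = 5) -> DiffusionFit:
    """Fit the first ``n_points`` MSD lags to a line with slope m = 4D.

    The 95% CI half-width on D is the slope's standard error times the
    two-sided t quantile at n_points − 2 degrees of freedom, divided by 4.
    When the curve carries across-track SEMs, the slope error is obtained
    by propagating those SEMs through the OLS slope coefficients (the
    residual-based error of a nearly straight ensemble curve wildly
    understates the sampling error of D); otherwise the residual-based
    standard error is used.  A negative fitted slope is reported as-is
    with ``negative_slope=True`` (subdiffusion or noise), never silently
    clipped.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if len(msd.lags_s) < n_points:
        raise ValueError(f"MSD curve has {len(msd.lags_s)} lags, need {n_points}")
    x = np.asarray(msd.lags_s[:n_points], float)
    y = np.asarray(msd.msd_um2[:n_points], float)
    sem = np.asarray(msd.sem_um2[:n_points], float)
    res = stats.linregress(x, y)
    dof = n_points - 2
    tq = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    if np.all(np.isfinite(sem)) and np.any(sem > 0):
        cx = x - x.mean()
        slope_se = float(np.sqrt(np.sum((cx / np.sum(cx**2)) ** 2 * sem**2)))
    else:
        slope_se = float(res.stderr)
    ci95 = float(tq * slope_se / 4.0) if dof > 0 else float("nan")
    D = res.slope / 4.0
    return DiffusionFit(
        m=float(res.slope),
        intercept=float(res.intercept),
        D=float(D),
        ci95=ci95,
        n_points_fit=n_points,
        negative_slope=bool(res.slope < 0),
    )


def mobility_map(tracks: pd.DataFrame, figure_path: str | None = None) -> pd.DataFrame:
    """One point per track at its mean position, valued by its mean jump.

    Reproduces the standard single-molecule mobility map: filtered tracks
    plotted at their centroid and color-coded by average frame-to-frame
    jump size.  Optionally writes a scatter figure with a continuous
    color scale.
    """
    from livespot.linker import track_jump_stats

    stats_df = track_jump_stats(tracks)
    out = stats_df.rename(columns={"mean_jump_um": "jump_um"})[
        ["track_id", "mean_x_um", "mean_y_um", "jump_um", "n_frames"]
    ]
    out["jump_um"] = out["jump_um"].fillna(0.0)
    if figure_path is not None and len(out):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        sc = ax.scatter(
            out["mean_x_um"], out["mean_y_um"], c=out["jump_um"] * 1000, s=6, cmap="viridis"
        )
        fig.colorbar(sc, ax=ax, label="mean jump (nm)")
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        ax.set_aspect("equal")
        fig.savefig(figure_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return out


def directed_events(
    track: pd.DataFrame,
    frame_interval_s: float,
    speed_threshold_um_s: float = 1.0,
    min_run_frames: int = 3,
    smoothing_frames: int = 3,
) -> tuple[list[DirectedEvent], pd.DataFrame]:
    """Detect directed-transport runs in one track.

    The instantaneous speed profile is the magnitude of the centered
    moving-average velocity vector over ``smoothing_frames`` consecutive
    steps — i.e. the net displacement rate across the window.  Averaging
    the vector (not the step lengths) makes the profile directionally
    coherent: Brownian steps cancel while motor-driven runs retain their
    full velocity, which is what separates transport from diffusion.  An
    event is at least ``min_run_frames`` consecutive smoothed samples
    strictly above ``speed_threshold_um_s``.  Also returns the cumulative
    travel-distance profile relative to the track origin, which is
    produced even when the track is too short for any event.
    """
    t = track.sort_values("frame")
    xy = t[["x_um", "y_um"]].to_numpy(float)
    frames = t["frame"].to_numpy(int)
    d = np.diff(xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    travel = pd.DataFrame(
        {
            "frame": frames,
            "time_s": (frames - frames[0]) * frame_interval_s,
            "travel_um": np.concatenate([[0.0], np.cumsum(steps)]),
        }
    )
    if len(d) < smoothing_frames:
        return [], travel
    kernel = np.ones(smoothing_frames) / smoothing_frames
    # sample s covers steps s .. s+smoothing_frames-1 ('valid' window)
    vx = np.convolve(d[:, 0], kernel, mode="valid") / frame_interval_s
    vy = np.convolve(d[:, 1], kernel, mode="valid") / frame_interval_s
    speed = np.hypot(vx, vy)
    above = speed > speed_threshold_um_s

    events: list[DirectedEvent] = []
    i = 0
    tid = int(t["track_id"].iloc[0]) if "track_id" in t else 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j < len(above) and above[j]:
            j += 1
        if j - i >= min_run_frames:
            # samples i..j-1 span steps i..j+smoothing_frames-2,
            # i.e. positions i..j+smoothing_frames-1
            last = j + smoothing_frames - 1
            path = float(steps[i:last].sum())
            net = float(np.hypot(*(xy[last] - xy[i])))
            events.append(
                DirectedEvent(
                    track_id=tid,
                    start_frame=int(frames[i]),
                    end_frame=int(frames[last]),
                    mean_speed_um_s=float(speed[i:j].mean()),
                    path_length_um=path,
                    net_displacement_um=net,
                )
            )
        i = j
    return events, travel
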