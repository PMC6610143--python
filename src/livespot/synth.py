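"""Synthetic ground-truth data for every stage of the pipeline.

Every generator takes an explicit integer seed and is bit-reproducible:
the same arguments plus the same seed give identical output.  Ground-truth
tables are emitted in micrometres with the pixel scale recorded on the
rendered movie, so pixel/µm conversions are exercised by the tests rather
than assumed.

The camera model is Poisson shot noise on (signal + background) plus
Gaussian read noise — the simplest model that reproduces realistic
localization error for diffraction-limited spots on an EM-CCD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from livespot.movie import Movie

__all__ = [
    "MotionModel",
    "PhotoKinetics",
    "Optics",
    "RunoffScene",
    "make_tracks",
    "render_movie",
    "make_frap_trace",
    "make_sensorgram",
    "make_runoff_scene",
    "make_embryo_sequence",
    "FrapTraceData",
    "KineticTrace",
]

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "channel", "state"]


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if v is not None and not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")


@dataclass
class MotionModel:
    """Emitter motion law for track simulation.

    ``kind`` selects between free 2-D Brownian motion (``brownian``),
    a chromatin-bound emitter jittering about a fixed anchor (``bound``),
    and a motor-transported cargo that alternates directed runs with
    diffusive pauses (``motored``).

    Parameters
    ----------
    D
        Diffusion coefficient in µm²/s (per-axis jump variance 2·D·dt).
    jitter_sd
        Positional jitter of a bound emitter about its anchor, µm.
    segments
        For ``motored``: sequence of ``("run", duration_s, velocity_um_s,
        heading_rad)`` and ``("pause", duration_s)`` entries, cycled for the
        length of the track.
    mobility_field
        Optional map ``f(x_um, y_um) -> scale`` multiplying D locally, used
        to emulate spatially structured mobility (e.g. reduced mobility at
        the nuclear periphery).
    """

    kind: str = "brownian"
    D: float = 0.1
    jitter_sd: float = 0.03
    segments: Sequence[tuple] = field(default_factory=tuple)
    mobility_field: Callable[[float, float], float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"brownian", "bound", "motored"}:
            raise ValueError(f"unknown motion kind {self.kind!r}")
        _check_finite("D", self.D)
        _check_finite("jitter_sd", self.jitter_sd)
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for seg in self.segments:
            if seg[0] == "run":
                _, dur, v, _heading = seg
                if v < 0:
                    raise ValueError("run velocity must be >= 0")
                if dur <= 0:
                    raise ValueError("segment duration must be > 0")
            elif seg[0] == "pause":
                if seg[1] <= 0:
                    raise ValueError("segment duration must be > 0")
            else:
                raise ValueError(f"unknown segment kind {seg[0]!r}")


@dataclass
class PhotoKinetics:
    """Photoactivation / photobleaching schedule for sparse tracking.

    Emulates the standard sparse-activation protocol: most emitters start
    dark, a brief activation pulse fires every ``activation_pulse_period``
    seconds and switches each dark emitter on with probability
    ``activation_prob_per_pulse``; active emitters bleach irreversibly at
    ``bleach_rate`` per second.
    """

    activation_pulse_period: float = 10.0
    activation_prob_per_pulse: float = 0.3
    bleach_rate: float = 0.5
    initially_dark_fraction: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.activation_prob_per_pulse, self.initially_dark_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.bleach_rate < 0 or self.activation_pulse_period <= 0:
            raise ValueError("rates must be >= 0 and pulse period > 0")


@dataclass
class Optics:
    """Camera / objective parameters for rendering.

    Defaults model a ×100 system with 130 nm pixels and a one-pixel-wide
    Gaussian PSF (a diffraction-limited spot is about one pixel at that
    magnification).
    """

    pixel_size_um: float = 0.13
    psf_sigma_px: float = 1.0
    photons_per_spot: float = 400.0
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    frame_interval_s: float = 1.0
    field_px: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if min(self.field_px) < 16:
            raise ValueError("field dims must be >= 16 px")
        for name in ("photons_per_spot", "background_level", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def field_um(self) -> tuple[float, float]:
        h, w = self.field_px
        return h * self.pixel_size_um, w * self.pixel_size_um


@dataclass
class RunoffScene:
    """Parameters of a translational-inhibitor run-off experiment."""

    n_cells: int = 3
    spots_per_cell: int = 16
    n_frames: int = 30
    drug_time_s: float = 50.0
    runoff_rate: float = 0.05
    mrna_channel_persists: bool = True

    def __post_init__(self) -> None:
        if self.runoff_rate < 0:
            raise ValueError("runoff_rate must be >= 0")
        if self.n_cells < 1 or self.spots_per_cell < 1:
            raise ValueError("need at least one cell and one spot")
        if self.drug_time_s < 0:
            raise ValueError("drug_time_s must be >= 0")


# ---------------------------------------------------------------------------
# track simulation


def _bounds_tuple(bounds) -> tuple[float, float, float, float]:
    if len(bounds) == 2:  # (width, height) shorthand, origin at 0
        return 0.0, float(bounds[0]), 0.0, float(bounds[1])
    x0, x1, y0, y1 = map(float, bounds)
    if not (x1 > x0 and y1 > y0):
        raise ValueError("bounds must describe a non-empty box")
    return x0, x1, y0, y1


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions back into [lo, hi] by mirror reflection."""
    span = hi - lo
    x = np.mod(x - lo, 2 * span)
    x = np.where(x > span, 2 * span - x, x)
    return x + lo


def make_tracks(
    model: MotionModel,
    n_tracks: int,
    n_frames: int,
    dt: float,
    bounds=(10.0, 10.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ground-truth emitter tracks.

    Returns a long-format table with columns
    ``(track_id, frame, x_um, y_um, channel, state)``; positions are in
    micrometres.  Brownian steps are Gaussian with per-axis variance
    2·D·dt and reflecting boundaries; bound emitters jitter about a fixed
    anchor; motored emitters follow their segment schedule (directed runs
    at constant velocity, diffusive pauses at D).
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not (dt > 0) or not np.isfinite(dt):
        raise ValueError("dt must be a positive finite number")
    x0, x1, y0, y1 = _bounds_tuple(bounds)
    rng = np.random.default_rng(seed)

    xs = np.empty((n_tracks, n_frames))
    ys = np.empty((n_tracks, n_frames))
    start_x = rng.uniform(x0, x1, size=n_tracks)
    start_y = rng.uniform(y0, y1, size=n_tracks)

    if model.kind == "bound":
        jit_x = rng.normal(0.0, model.jitter_sd, size=(n_tracks, n_frames))
        jit_y = rng.normal(0.0, model.jitter_sd, size=(n_tracks, n_frames))
        xs = start_x[:, None] + jit_x
        ys = start_y[:, None] + jit_y
    elif model.kind == "brownian":
        sd = math.sqrt(2.0 * model.D * dt)
        if model.mobility_field is None:
            jumps_x = rng.normal(0.0, sd, size=(n_tracks, n_frames - 1)) if n_frames > 1 else np.empty((n_tracks, 0))
            jumps_y = rng.normal(0.0, sd, size=(n_tracks, n_frames - 1)) if n_frames > 1 else np.empty((n_tracks, 0))
            xs[:, 0], ys[:, 0] = start_x, start_y
            if n_frames > 1:
                xs[:, 1:] = start_x[:, None] + np.cumsum(jumps_x, axis=1)
                ys[:, 1:] = start_y[:, None] + np.cumsum(jumps_y, axis=1)
            xs = _reflect(xs, x0, x1)
            ys = _reflect(ys, y0, y1)
        else:
            xs[:, 0], ys[:, 0] = start_x, start_y
            for t in range(1, n_frames):
                scale = np.array(
                    [model.mobility_field(x, y) for x, y in zip(xs[:, t - 1], ys[:, t - 1])]
                )
                step_sd = np.sqrt(2.0 * model.D * np.clip(scale, 0, None) * dt)
                xs[:, t] = _reflect(xs[:, t - 1] + rng.normal(0, 1, n_tracks) * step_sd, x0, x1)
                ys[:, t] = _reflect(ys[:, t - 1] + rng.normal(0, 1, n_tracks) * step_sd, y0, y1)
    else:  # motored
        segments = model.segments or (("run", 5 * dt, 1.0, 0.0), ("pause", 5 * dt))
        sd = math.sqrt(2.0 * model.D * dt)
        for i in range(n_tracks):
            x, y = start_x[i], start_y[i]
            xs[i, 0], ys[i, 0] = x, y
            seg_idx, seg_left = 0, segments[0][1]
            for t in range(1, n_frames):
                seg = segments[seg_idx % len(segments)]
                if seg[0] == "run":
                    _, _, v, heading = seg
                    x += v * dt * math.cos(heading)
                    y += v * dt * math.sin(heading)
                else:
                    x += rng.normal(0.0, sd)
                    y += rng.normal(0.0, sd)
                x = float(_reflect(np.array([x]), x0, x1)[0])
                y = float(_reflect(np.array([y]), y0, y1)[0])
                xs[i, t], ys[i, t] = x, y
                seg_left -= dt
                if seg_left <= 1e-12:
                    seg_idx += 1
                    seg_left = segments[seg_idx % len(segments)][1]

    frames = np.tile(np.arange(n_frames), n_tracks)
    ids = np.repeat(np.arange(n_tracks), n_frames)
    return pd.DataFrame(
        {
            "track_id": ids,
            "frame": frames,
            "x_um": xs.ravel(),
            "y_um": ys.ravel(),
            "channel": 0,
            "state": model.kind,
        }
    )


# ---------------------------------------------------------------------------
# rendering


def _draw_spots(
    frame: np.ndarray, x_px: np.ndarray, y_px: np.ndarray, amp: float, sigma: float
) -> None:
    """Accumulate 2-D Gaussians (in place) at sub-pixel positions."""
    h, w = frame.shape
    half = max(3, int(math.ceil(5 * sigma)))
    for x0, y0 in zip(x_px, y_px):
        cx, cy = int(round(x0)), int(round(y0))
        xlo, xhi = max(0, cx - half), min(w, cx + half + 1)
        ylo, yhi = max(0, cy - half), min(h, cy + half + 1)
        if xlo >= xhi or ylo >= yhi:
            continue
        yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
        frame[ylo:yhi, xlo:xhi] += amp * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2)
        )


def _emitter_visibility(
    n_emitters: int,
    n_frames: int,
    photo: PhotoKinetics | None,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean (n_emitters, n_frames) on/off matrix from photophysics."""
    if photo is None:
        return np.ones((n_emitters, n_frames), dtype=bool)
    vis = np.zeros((n_emitters, n_frames), dtype=bool)
    dark = rng.random(n_emitters) < photo.initially_dark_fraction
    active = ~dark
    bleached = np.zeros(n_emitters, dtype=bool)
    p_bleach = 1.0 - math.exp(-photo.bleach_rate * dt)
    pulse_every = max(1, int(round(photo.activation_pulse_period / dt)))
    for t in range(n_frames):
        if t % pulse_every == 0:
            candidates = dark & ~bleached
            fire = rng.random(n_emitters) < photo.activation_prob_per_pulse
            newly = candidates & fire
            active |= newly
            dark &= ~newly
        vis[:, t] = active
        dying = active & (rng.random(n_emitters) < p_bleach)
        active &= ~dying
        bleached |= dying
    return vis


def render_movie(
    tracks: pd.DataFrame,
    optics: Optics,
    photo: PhotoKinetics | None = None,
    seed: int = 0,
    shot_noise: bool = True,
) -> Movie:
    """Render a track table into a camera movie.

    Each visible emitter is drawn as a 2-D Gaussian of width
    ``psf_sigma_px`` and amplitude ``photons_per_spot`` on
    ``background_level``; Poisson shot noise is applied to the expected
    image and Gaussian read noise added on top.  Pass ``shot_noise=False``
    together with ``read_noise_sd=0`` for a noiseless render (useful for
    oracle tests).  An empty track table yields a pure-background movie.
    """
    rng = np.random.default_rng(seed)
    h, w = optics.field_px
    if len(tracks) == 0:
        n_frames, channels = 1, [0]
    else:
        n_frames = int(tracks["frame"].max()) + 1
        channels = sorted(tracks["channel"].unique()) if "channel" in tracks else [0]
    n_ch = len(channels)
    data = np.zeros((n_frames, n_ch, 1, h, w))

    if len(tracks):
        ids = np.sort(tracks["track_id"].unique())
        id_index = {tid: i for i, tid in enumerate(ids)}
        vis = _emitter_visibility(len(ids), n_frames, photo, optics.frame_interval_s, rng)
        for ci, ch in enumerate(channels):
            sub = tracks[tracks["channel"] == ch] if "channel" in tracks else tracks
            for t, grp in sub.groupby("frame"):
                rows = np.array([id_index[tid] for tid in grp["track_id"]])
                on = vis[rows, int(t)]
                if not on.any():
                    continue
                x_px = grp["x_um"].to_numpy()[on] / optics.pixel_size_um
                y_px = grp["y_um"].to_numpy()[on] / optics.pixel_size_um
                inside = (x_px > -3) & (x_px < w + 3) & (y_px > -3) & (y_px < h + 3)
                _draw_spots(
                    data[int(t), ci, 0],
                    x_px[inside],
                    y_px[inside],
                    optics.photons_per_spot,
                    optics.psf_sigma_px,
                )

    data += optics.background_level
    if shot_noise:
        data = rng.poisson(data).astype(float)
    if optics.read_noise_sd > 0:
        data += rng.normal(0.0, optics.read_noise_sd, size=data.shape)
    return Movie(
        data,
        pixel_size_um=optics.pixel_size_um,
        frame_interval_s=optics.frame_interval_s,
        channel_names=[f"ch{c}" for c in channels],
    )


# ---------------------------------------------------------------------------
# kinetic traces


@dataclass
class FrapTraceData:
    """Raw FRAP measurement series (bleach spot, whole compartment, background)."""

    time_s: np.ndarray
    roi_intensity: np.ndarray
    whole_intensity: np.ndarray
    background: np.ndarray
    bleach_frame: int

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.roi_intensity) == len(self.whole_intensity) == len(self.background) == n):
            raise ValueError("all FRAP series must have equal length")
        if self.bleach_frame <= 0:
            raise ValueError("bleach_frame must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "roi_intensity": self.roi_intensity,
                "whole_intensity": self.whole_intensity,
                "background": self.background,
            }
        )


@dataclass
class KineticTrace:
    """A generic intensity-vs-time trace (used for SPR sensorgrams)."""

    time_s: np.ndarray
    value: np.ndarray
    concentration_M: float = float("nan")
    t_assoc_end_s: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time_s, "value": self.value})
        df["concentration_nM"] = self.concentration_M * 1e9
        df["phase"] = np.where(self.time_s <= self.t_assoc_end_s, "association", "dissociation")
        return df


def make_frap_trace(
    k: float,
    mobile_fraction: float = 1.0,
    bleach_depth: float = 0.6,
    acq_bleach_rate: float = 0.0,
    pre_frames: int = 20,
    post_frames: int = 200,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 1000.0,
    background_level: float = 50.0,
) -> FrapTraceData:
    """Simulate a photobleaching-recovery experiment.

    The bleach-spot signal sits at a pre-bleach plateau, drops
    instantaneously by ``bleach_depth`` at the bleach frame, then recovers
    as ``I(t) = I_post0 + mobile_fraction·bleach_depth·(1 − e^{−k·t})``.
    The whole-compartment reference channel decays as
    ``e^{−acq_bleach_rate·t}`` (acquisition photobleaching), and the same
    factor multiplies the bleach-spot signal so that double normalization
    can cancel it.
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must lie in [0, 1]")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must lie in (0, 1]")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if k < 0 or acq_bleach_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    n = pre_frames + post_frames
    t = np.arange(n) * dt
    rel = np.ones(n)
    t_post = t[pre_frames:] - t[pre_frames]
    rel[pre_frames:] = (1.0 - bleach_depth) + mobile_fraction * bleach_depth * (
        1.0 - np.exp(-k * t_post)
    )
    acq = np.exp(-acq_bleach_rate * t)
    roi = background_level + baseline * rel * acq
    whole = background_level + baseline * acq
    if noise_sd > 0:
        roi = roi + rng.normal(0.0, noise_sd * baseline, n)
        whole = whole + rng.normal(0.0, noise_sd * baseline, n)
    return FrapTraceData(
        time_s=t,
        roi_intensity=roi,
        whole_intensity=whole,
        background=np.full(n, background_level),
        bleach_frame=pre_frames,
    )


def make_sensorgram(
    k_on: float,
    k_off: float,
    R_max: float,
    C: float,
    t_assoc: float = 300.0,
    t_dissoc: float = 600.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> KineticTrace:
    """Simulate a one-to-one binding sensorgram.

    Association follows ``R(t) = R_eq·(1 − e^{−(k_on·C + k_off)·t})`` with
    ``R_eq = R_max·C·k_on/(C·k_on + k_off)``; after ``t_assoc`` the analyte
    is washed out and the response decays as ``R(t_assoc)·e^{−k_off·Δt}``.
    """
    if k_on < 0 or k_off < 0 or R_max < 0 or C < 0:
        raise ValueError("rates, R_max and concentration must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    kobs = k_on * C + k_off
    r_eq = 0.0 if kobs == 0 else R_max * C * k_on / kobs
    r = np.where(
        t <= t_assoc,
        r_eq * (1.0 - np.exp(-kobs * t)),
        r_eq * (1.0 - math.exp(-kobs * t_assoc)) * np.exp(-k_off * np.clip(t - t_assoc, 0, None)),
    )
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, len(t))
    return KineticTrace(time_s=t, value=r, concentration_M=C, t_assoc_end_s=t_assoc)


# ---------------------------------------------------------------------------
# run-off scene


def make_runoff_scene(
    scene: RunoffScene,
    optics: Optics,
    seed: int = 0,
) -> tuple[Movie, pd.DataFrame]:
    """Simulate a drug-induced translation-site run-off.

    Channel 0 carries the nascent-chain spots; each spot disappears after
    ``drug_time_s`` with an exponential waiting time at ``runoff_rate``.
    Channel 1 carries mRNA spots at the same positions which persist when
    ``mrna_channel_persists``.  Returns the rendered two-channel movie and
    a per-frame ground-truth table
    ``(cell_id, track_id, frame, x_um, y_um, channel, state)`` listing the
    spots present in each frame.
    """
    rng = np.random.default_rng(seed)
    dt = optics.frame_interval_s
    n_frames = scene.n_frames
    h_um, w_um = optics.field_um
    rows = []
    sid = 0
    for cell in range(scene.n_cells):
        x = rng.uniform(0.08 * w_um, 0.92 * w_um, scene.spots_per_cell)
        y = rng.uniform(0.08 * h_um, 0.92 * h_um, scene.spots_per_cell)
        if scene.runoff_rate > 0:
            wait = rng.exponential(1.0 / scene.runoff_rate, scene.spots_per_cell)
        else:
            wait = np.full(scene.spots_per_cell, np.inf)
        vanish_t = scene.drug_time_s + wait
        for j in range(scene.spots_per_cell):
            for t in range(n_frames):
                time_s = t * dt
                if time_s < vanish_t[j]:
                    rows.append((cell, sid, t, x[j], y[j], 0, "nascent"))
                if scene.mrna_channel_persists:
                    rows.append((cell, sid, t, x[j], y[j], 1, "mrna"))
            sid += 1
    truth = pd.DataFrame(
        rows, columns=["cell_id", "track_id", "frame", "x_um", "y_um", "channel", "state"]
    )
    movie = render_movie(truth, optics, photo=None, seed=seed + 1)
    return movie, truth


# ---------------------------------------------------------------------------
# embryo development


def make_embryo_sequence(
    n_start_nuclei: int = 4,
    division_period_frames: int = 10,
    n_frames: int = 25,
    nucleus_radius_px: float = 12.0,
    optics: Optics | None = None,
    expression_ramp: tuple[float, float] | Sequence[float] = (1.0, 2.5),
    seed: int = 0,
    noise_sd: float = 3.0,
) -> tuple[Movie, pd.DataFrame]:
    """Simulate an early-embryo nuclear time-lapse with synchronous divisions.

    Nuclei are bright disks in a mask channel (the nuclear-marker Fab
    analogue); a probe channel whose nuclear enrichment over cytoplasm
    follows ``expression_ramp``; and a target channel with the same
    enrichment.  Every ``division_period_frames`` frames each nucleus
    divides into two daughters displaced symmetrically from the parent,
    the spacing scale halving and the nuclear area roughly halving
    (radius ÷ √2) per generation.

    Returns the three-channel movie and a ground-truth table
    ``(frame, nucleus_id, parent_id, x_px, y_px, radius_px, true_ratio)``.
    """
    if n_start_nuclei < 1:
        raise ValueError("n_start_nuclei must be >= 1")
    if nucleus_radius_px < 2:
        raise ValueError("nucleus_radius_px < 2 px is unsegmentable")
    optics = optics or Optics(
        pixel_size_um=0.662, field_px=(256, 256), frame_interval_s=300.0
    )
    rng = np.random.default_rng(seed)
    h, w = optics.field_px

    ramp = np.asarray(expression_ramp, dtype=float)
    if ramp.size == 2 and n_frames != 2:
        ramp = np.linspace(ramp[0], ramp[1], n_frames)
    if ramp.size != n_frames:
        raise ValueError("expression_ramp must be (start, end) or one value per frame")

    # initial positions: jittered grid with generous margins
    side = int(math.ceil(math.sqrt(n_start_nuclei)))
    margin = 0.2
    gx = np.linspace(margin * w, (1 - margin) * w, side)
    gy = np.linspace(margin * h, (1 - margin) * h, side)
    centers = [(gx[i % side], gy[i // side]) for i in range(n_start_nuclei)]
    nuclei = [
        {"id": i, "parent": -1, "x": cx, "y": cy, "r": float(nucleus_radius_px)}
        for i, (cx, cy) in enumerate(centers)
    ]
    next_id = n_start_nuclei
    spacing = 0.30 * min(h, w) / side
    generation = 0

    yy, xx = np.mgrid[0:h, 0:w]
    data = np.zeros((n_frames, 3, 1, h, w))
    rows = []
    cyt_level = 100.0
    mask_bg, mask_fg = 20.0, 800.0

    for t in range(n_frames):
        if t > 0 and t % division_period_frames == 0:
            # synchronous division: alternate split axis per generation
            angle = 0.0 if generation % 2 == 0 else math.pi / 2
            new = []
            for nuc in nuclei:
                dx = spacing * math.cos(angle)
                dy = spacing * math.sin(angle)
                r_new = nuc["r"] / math.sqrt(2)
                for sign in (+1, -1):
                    new.append(
                        {
                            "id": next_id,
                            "parent": nuc["id"],
                            "x": min(max(nuc["x"] + sign * dx, r_new + 2), w - r_new - 3),
                            "y": min(max(nuc["y"] + sign * dy, r_new + 2), h - r_new - 3),
                            "r": r_new,
                        }
                    )
                    next_id += 1
            nuclei = new
            spacing /= 2
            generation += 1

        mask_frame = np.full((h, w), mask_bg)
        probe_frame = np.full((h, w), cyt_level)
        target_frame = np.full((h, w), cyt_level)
        ratio = float(ramp[t])
        for nuc in nuclei:
            disk = (xx - nuc["x"]) ** 2 + (yy - nuc["y"]) ** 2 <= nuc["r"] ** 2
            mask_frame[disk] = mask_fg
            probe_frame[disk] = cyt_level * ratio
            target_frame[disk] = cyt_level * ratio
            rows.append((t, nuc["id"], nuc["parent"], nuc["x"], nuc["y"], nuc["r"], ratio))
        if noise_sd > 0:
            mask_frame = mask_frame + rng.normal(0, noise_sd, (h, w))
            probe_frame = probe_frame + rng.normal(0, noise_sd, (h, w))
            target_frame = target_frame + rng.normal(0, noise_sd, (h, w))
        data[t, 0, 0] = mask_frame
        data[t, 1, 0] = probe_frame
        data[t, 2, 0] = target_frame

    truth = pd.DataFrame(
        rows,
        columns=["frame", "nucleus_id", "parent_id", "x_px", "y_px", "radius_px", "true_ratio"],
    )
    movie = Movie(
        data,
        pixel_size_um=optics.pixel_size_um,
        frame_interval_s=optics.frame_interval_s,
        channel_names=["nuclear_marker", "probe", "target"],
    )
    return movie, truth
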