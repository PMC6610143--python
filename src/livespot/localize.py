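"""Spot detection, sub-pixel Gaussian localization, drift and channel registration.

Detection follows the classic bandpass → binarize → intensity-centroid
scheme; candidate positions are then refined by nonlinear least-squares
fitting of an elliptical 2-D Gaussian

    I(x, y) = I_BG + I·exp(−(x−x0)²/(2σx²) − (y−y0)²/(2σy²))

over a small window around each candidate.  Coordinates are 0-based with
x = column and y = row, origin at the center of the top-left pixel; all
public tables carry both pixel and micrometre coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, SimilarityTransform

from livespot.movie import Movie

__all__ = [
    "GaussianFit",
    "RegistrationTransform",
    "detect_spots",
    "fit_gaussian_2d",
    "localize_movie",
    "estimate_drift",
    "fit_registration",
    "apply_registration",
]

LOCALIZATION_COLUMNS = [
    "frame",
    "channel",
    "x_px",
    "y_px",
    "x_um",
    "y_um",
    "I",
    "I_BG",
    "sigma_x",
    "sigma_y",
    "converged",
]


@dataclass
class GaussianFit:
    """Result of a 2-D elliptical Gaussian fit on a fit window."""

    I_BG: float
    I: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    converged: bool
    residual_norm: float


@dataclass
class RegistrationTransform:
    """Affine map (matrix + offset) from moving to reference pixel coordinates."""

    model: str
    matrix: np.ndarray  # 2x2
    offset: np.ndarray  # (2,) applied after the matrix, x/y order
    rmse_px: float

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ self.matrix.T + self.offset

    def inverse(self) -> "RegistrationTransform":
        inv = np.linalg.inv(self.matrix)
        return RegistrationTransform(self.model, inv, -inv @ self.offset, self.rmse_px)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "matrix": self.matrix.tolist(),
            "offset": self.offset.tolist(),
            "rmse_px": float(self.rmse_px),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationTransform":
        return cls(d["model"], np.asarray(d["matrix"]), np.asarray(d["offset"]), d["rmse_px"])


# ---------------------------------------------------------------------------
# detection


def detect_spots(
    frame_image: np.ndarray,
    band_low_sigma: float = 1.0,
    band_high_sigma: float = 3.0,
    threshold: str = "mean_sd",
    min_area: int = 3,
    n_sd: float = 3.0,
) -> pd.DataFrame:
    """Detect candidate spots in one frame.

    The image is bandpassed with a difference of Gaussians (spot-sized
    passband), binarized (``mean_sd``: mean + n_sd·SD of the bandpassed
    frame; ``otsu``: Otsu's threshold), and each connected component with
    at least ``min_area`` pixels contributes one intensity-weighted
    centroid.  Returns a table with columns ``(x_px, y_px, area_px2)``.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("frame must be a 2-D image of at least 16x16 px")
    if not np.all(np.isfinite(img)):
        raise ValueError("frame contains non-finite pixels")
    if not band_low_sigma < band_high_sigma:
        raise ValueError("band_low_sigma must be < band_high_sigma")

    band = ndimage.gaussian_filter(img, band_low_sigma) - ndimage.gaussian_filter(
        img, band_high_sigma
    )
    if threshold == "mean_sd":
        thr = band.mean() + n_sd * band.std()
    elif threshold == "otsu":
        thr = threshold_otsu(band)
    else:
        raise ValueError(f"unknown threshold strategy {threshold!r}")

    binary = band > thr
    if not binary.any():
        return pd.DataFrame(columns=["x_px", "y_px", "area_px2"])
    labels, n = ndimage.label(binary)
    if n == 0:
        return pd.DataFrame(columns=["x_px", "y_px", "area_px2"])
    areas = ndimage.sum_labels(np.ones_like(band), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    rows = []
    weight = np.clip(band, 0, None)
    for lab in keep:
        mask = labels == lab
        wsum = weight[mask].sum()
        if wsum <= 0:
            continue
        ys, xs = np.nonzero(mask)
        x_c = float((xs * weight[mask]).sum() / wsum)
        y_c = float((ys * weight[mask]).sum() / wsum)
        rows.append((x_c, y_c, float(mask.sum())))
    return pd.DataFrame(rows, columns=["x_px", "y_px", "area_px2"])


# ---------------------------------------------------------------------------
# Gaussian refinement


def _gauss2d(params, xx, yy):
    bg, amp, x0, y0, sx, sy = params
    return bg + amp * np.exp(-((xx - x0) ** 2) / (2 * sx**2) - ((yy - y0) ** 2) / (2 * sy**2))


def fit_gaussian_2d(
    frame_image: np.ndarray,
    x_px: float,
    y_px: float,
    window_halfwidth: int = 5,
    circular: bool = False,
) -> GaussianFit:
    """Refine a candidate position by least-squares 2-D Gaussian fitting.

    The fit window is centred on the rounded candidate position and shrunk
    at frame borders (never below 5×5, which is rejected).  Initialization
    uses the window minimum as background, the peak excess as amplitude,
    and moment-based widths.  A stalled or degenerate optimization returns
    ``converged=False`` with the initial centroid rather than raising.
    """
    img = np.asarray(frame_image, dtype=float)
    h, w = img.shape
    cx, cy = int(round(x_px)), int(round(y_px))
    xlo, xhi = max(0, cx - window_halfwidth), min(w, cx + window_halfwidth + 1)
    ylo, yhi = max(0, cy - window_halfwidth), min(h, cy + window_halfwidth + 1)
    if xhi - xlo < 5 or yhi - ylo < 5:
        raise ValueError("fit window smaller than 5x5 px")
    win = img[ylo:yhi, xlo:xhi]
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi].astype(float)

    bg0 = float(win.min())
    amp0 = float(win.max() - bg0)
    if amp0 <= 0 or win.std() == 0:
        return GaussianFit(bg0, 0.0, x_px, y_px, 1.0, 1.0, False, float(np.linalg.norm(win - win.mean())))

    # moment-based width initialization on background-subtracted window
    excess = np.clip(win - bg0, 0, None)
    tot = excess.sum()
    mx = float((xx * excess).sum() / tot)
    my = float((yy * excess).sum() / tot)
    sx0 = math_sqrt_safe(((xx - mx) ** 2 * excess).sum() / tot)
    sy0 = math_sqrt_safe(((yy - my) ** 2 * excess).sum() / tot)
    p0 = [bg0, amp0, x_px, y_px, sx0, sy0]

    lo = [-np.inf, 0.0, xlo - 1.0, ylo - 1.0, 0.05, 0.05]
    hi = [np.inf, np.inf, xhi, yhi, xhi - xlo, yhi - ylo]

    def resid(p):
        if circular:
            p = [p[0], p[1], p[2], p[3], p[4], p[4]]
        return (_gauss2d(p, xx, yy) - win).ravel()

    try:
        if circular:
            res = optimize.least_squares(resid, p0[:5], bounds=(lo[:5], hi[:5]), xtol=1e-12, ftol=1e-12)
            bg, amp, x0, y0, sx = res.x
            sy = sx
        else:
            res = optimize.least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
            bg, amp, x0, y0, sx, sy = res.x
    except Exception:
        return GaussianFit(bg0, amp0, x_px, y_px, sx0, sy0, False, float("inf"))
    ok = bool(res.success) and amp > 0 and xlo - 1 <= x0 <= xhi and ylo - 1 <= y0 <= yhi
    return GaussianFit(float(bg), float(amp), float(x0), float(y0), float(sx), float(sy), ok, float(np.linalg.norm(res.fun)))


def math_sqrt_safe(v: float, floor: float = 0.5) -> float:
    return max(float(np.sqrt(max(v, 0.0))), floor)


# ---------------------------------------------------------------------------
# per-movie localization


def localize_movie(
    movie: Movie,
    channel: int = 0,
    band_low_sigma: float = 1.0,
    band_high_sigma: float = 3.0,
    threshold: str = "mean_sd",
    min_area: int = 3,
    n_sd: float = 3.0,
    window_halfwidth: int = 5,
    z_policy: str = "max_project",
) -> pd.DataFrame:
    """Detect and Gaussian-refine spots in every frame of one channel.

    Multi-z movies are max-projected per time point before detection.
    Non-converged fits keep the detection centroid and are flagged in the
    ``converged`` column.  Returns the standard localization table with
    pixel and µm coordinates.
    """
    if channel < 0 or channel >= movie.n_channels:
        raise ValueError(f"channel {channel} absent (movie has {movie.n_channels})")
    px = movie.pixel_size_um
    rows = []
    for t in range(movie.n_frames):
        img = movie.frame(t, channel, z_policy=z_policy)
        cands = detect_spots(img, band_low_sigma, band_high_sigma, threshold, min_area, n_sd)
        for _, c in cands.iterrows():
            try:
                fit = fit_gaussian_2d(img, c.x_px, c.y_px, window_halfwidth)
            except ValueError:
                continue
            if fit.converged:
                x, y = fit.x0, fit.y0
            else:
                x, y = c.x_px, c.y_px
            rows.append(
                (t, channel, x, y, x * px, y * px, fit.I, fit.I_BG, fit.sigma_x, fit.sigma_y, fit.converged)
            )
    return pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)


# ---------------------------------------------------------------------------
# drift estimation


def estimate_drift(movie: Movie, reference_frame: int = 0, channel: int = 0) -> pd.DataFrame:
    """Estimate per-frame rigid translation against a reference frame.

    Uses the cross-correlation peak with sub-pixel refinement (upsampled
    DFT).  Featureless frames get zero drift with ``confident=False``.
    Applying the negated drift re-centers the movie.  Returns a table
    ``(frame, dx_px, dy_px, confident)``.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate drift")
    ref = movie.frame(reference_frame, channel)
    rows = []
    for t in range(movie.n_frames):
        img = movie.frame(t, channel)
        if img.std() == 0 or ref.std() == 0:
            rows.append((t, 0.0, 0.0, False))
            continue
        shift, _err, _ = phase_cross_correlation(ref, img, upsample_factor=50, normalization=None)
        # shift = (dy, dx) needed to register img onto ref; drift is the negative
        rows.append((t, float(-shift[1]), float(-shift[0]), True))
    return pd.DataFrame(rows, columns=["frame", "dx_px", "dy_px", "confident"])


# ---------------------------------------------------------------------------
# channel registration


def _pair_mutual_nn(ref_xy: np.ndarray, mov_xy: np.ndarray, gate_px: float) -> tuple[np.ndarray, np.ndarray]:
    tree_r, tree_m = cKDTree(ref_xy), cKDTree(mov_xy)
    d_rm, idx_rm = tree_m.query(ref_xy, distance_upper_bound=gate_px)
    d_mr, idx_mr = tree_r.query(mov_xy, distance_upper_bound=gate_px)
    pairs_r, pairs_m = [], []
    for i, (d, j) in enumerate(zip(d_rm, idx_rm)):
        if np.isfinite(d) and j < len(mov_xy) and idx_mr[j] == i:
            pairs_r.append(i)
            pairs_m.append(j)
    return np.array(pairs_r, dtype=int), np.array(pairs_m, dtype=int)


def fit_registration(
    reference_locs: pd.DataFrame,
    moving_locs: pd.DataFrame,
    model: str = "affine",
    gate_px: float = 3.0,
) -> RegistrationTransform:
    """Fit the moving→reference transform from fiducial bead localizations.

    Beads are paired by mutual nearest neighbor within ``gate_px``; the
    least-squares transform of the requested family (translation,
    similarity, or affine) is then estimated from the paired coordinates
    and its residual RMSE reported in pixels.
    """
    min_pairs = {"translation": 1, "similarity": 2, "affine": 3}
    if model not in min_pairs:
        raise ValueError(f"unknown transform model {model!r}")
    ref_xy = reference_locs[["x_px", "y_px"]].to_numpy(float)
    mov_xy = moving_locs[["x_px", "y_px"]].to_numpy(float)
    ir, im = _pair_mutual_nn(ref_xy, mov_xy, gate_px)
    if len(ir) < min_pairs[model]:
        raise ValueError(
            f"{model} registration needs >= {min_pairs[model]} bead pairs, found {len(ir)}"
        )
    src, dst = mov_xy[im], ref_xy[ir]
    if model == "translation":
        off = dst.mean(axis=0) - src.mean(axis=0)
        mat = np.eye(2)
        offset = off
    else:
        cls = SimilarityTransform if model == "similarity" else AffineTransform
        if hasattr(cls, "from_estimate"):
            tf = cls.from_estimate(src, dst)
            if not tf:
                raise ValueError("transform estimation failed (degenerate bead layout)")
        else:  # older scikit-image
            tf = cls()
            if not tf.estimate(src, dst):
                raise ValueError("transform estimation failed (degenerate bead layout)")
        mat = np.asarray(tf.params[:2, :2])
        offset = np.asarray(tf.params[:2, 2])
    pred = src @ mat.T + offset
    rmse = float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))
    return RegistrationTransform(model, mat, offset, rmse)


def apply_registration(
    transform: RegistrationTransform,
    locs: pd.DataFrame,
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """Map a localization table through a registration transform.

    Pixel coordinates are transformed; µm coordinates are recomputed from
    the given pixel size (or rescaled from the existing columns if the
    table carries both).  The input table is not modified.
    """
    out = locs.copy()
    xy = out[["x_px", "y_px"]].to_numpy(float)
    new = transform.apply(xy)
    if pixel_size_um is None and {"x_um", "x_px"} <= set(out.columns) and len(out) > 0:
        nz = out["x_px"] != 0
        pixel_size_um = float((out.loc[nz, "x_um"] / out.loc[nz, "x_px"]).iloc[0]) if nz.any() else None
    out["x_px"], out["y_px"] = new[:, 0], new[:, 1]
    if pixel_size_um is not None:
        out["x_um"] = out["x_px"] * pixel_size_um
        out["y_um"] = out["y_px"] * pixel_size_um
    return out
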