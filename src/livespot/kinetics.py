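"""FRAP normalization and recovery fitting, and SPR one-to-one binding fits.

FRAP traces are double-normalized: both the bleach-spot and the
whole-compartment series are background-subtracted, each is divided by
its own pre-bleach mean, and the ratio of the two cancels acquisition
photobleaching.  Recovery is fit as I(t) = I0 + A·(1 − e^{−k·t}) (single
exponential, the default) with t_half = ln2/k read from the fitted model
rather than a raw-curve crossing.

SPR sensorgrams are fit globally across analyte concentrations to the
one-to-one (pseudo-first-order) binding model with shared k_on, k_off and
R_max; K_D = k_off/k_on by definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from livespot.synth import FrapTraceData, KineticTrace

__all__ = ["FrapFit", "BindingFit", "normalize_frap", "fit_frap", "fit_binding"]


@dataclass
class FrapFit:
    k: float
    t_half_s: float
    mobile_fraction: float
    plateau: float
    model: str = "single"
    converged: bool = True
    params: dict = field(default_factory=dict)


@dataclass
class BindingFit:
    k_on: float  # 1/(M s)
    k_off: float  # 1/s
    R_max: float
    K_D: float  # M, = k_off/k_on
    residual_rms: float
    k_on_se: float = float("nan")
    k_off_se: float = float("nan")
    K_D_se: float = float("nan")
    converged: bool = True


def normalize_frap(trace: FrapTraceData, mode: str = "double") -> pd.DataFrame:
    """Normalize a raw FRAP trace for fitting.

    ``double`` (default): background-subtract both series, divide each by
    its pre-bleach mean, and take the ratio roi/whole — acquisition
    bleaching common to both channels cancels.  ``full_scale``: roi only,
    normalized to its pre-bleach mean.  Returns a table
    ``(time_s, t_post_s, normalized, phase)``; pre-bleach normalized
    values average 1 by construction.
    """
    if trace.bleach_frame < 3:
        raise ValueError("need at least 3 pre-bleach frames")
    roi = trace.roi_intensity - trace.background
    whole = trace.whole_intensity - trace.background
    if np.any(whole <= 0):
        raise ValueError("whole-compartment intensity at or below background; trace unusable")
    pre = slice(0, trace.bleach_frame)
    roi_n = roi / roi[pre].mean()
    if mode == "double":
        whole_n = whole / whole[pre].mean()
        norm = roi_n / whole_n
    elif mode == "full_scale":
        norm = roi_n
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    t = np.asarray(trace.time_s, float)
    t_bleach = t[trace.bleach_frame]
    return pd.DataFrame(
        {
            "time_s": t,
            "t_post_s": t - t_bleach,
            "normalized": norm,
            "phase": np.where(np.arange(len(t)) < trace.bleach_frame, "pre", "post"),
        }
    )


def _single_exp(t, i0, a, k):
    return i0 + a * (1.0 - np.exp(-k * t))


def _double_exp(t, i0, a1, k1, a2, k2):
    return i0 + a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))


def fit_frap(normalized: pd.DataFrame, model: str = "single") -> FrapFit:
    """Fit the post-bleach recovery of a normalized FRAP curve.

    t_half is the time at which the fitted curve reaches half of
    (plateau − I0); for the single exponential this is ln2/k.  The mobile
    fraction is (plateau − I0)/(1 − I0), i.e. the recovered share of the
    bleached signal.  An essentially flat recovery (A ≈ 0) reports
    t_half as NaN.  Optimizer failure is flagged, not raised.
    """
    post = normalized[normalized["phase"] == "post"]
    if len(post) < 10:
        raise ValueError("need at least 10 post-bleach points")
    t = post["t_post_s"].to_numpy(float)
    y = post["normalized"].to_numpy(float)
    i0_guess = float(y[0])
    plateau_guess = float(np.median(y[max(len(y) - 10, 0):]))
    a_guess = max(plateau_guess - i0_guess, 1e-6)
    t_span = max(t[-1], 1.0)
    try:
        if model == "single":
            p, cov = optimize.curve_fit(
                _single_exp,
                t,
                y,
                p0=[i0_guess, a_guess, 1.0 / t_span * 5],
                bounds=([-1.0, 0.0, 0.0], [2.0, 2.0, np.inf]),
                maxfev=20000,
            )
            i0, a, k = p
            plateau = i0 + a
            t_half = math.log(2.0) / k if (k > 0 and a > 1e-4) else float("nan")
            params = {"I0": i0, "A": a, "k": k}
        elif model == "double":
            p, cov = optimize.curve_fit(
                _double_exp,
                t,
                y,
                p0=[i0_guess, a_guess / 2, 5.0 / t_span, a_guess / 2, 0.5 / t_span],
                bounds=([-1.0, 0.0, 0.0, 0.0, 0.0], [2.0, 2.0, np.inf, 2.0, np.inf]),
                maxfev=40000,
            )
            i0 = p[0]
            plateau = i0 + p[1] + p[3]
            amp = plateau - i0
            if amp > 1e-4:
                # numeric half-rise of the fitted curve
                tt = np.linspace(0, t[-1] * 3, 30000)
                yy = _double_exp(tt, *p)
                t_half = float(np.interp(i0 + amp / 2.0, yy, tt))
            else:
                t_half = float("nan")
            k = float("nan")
            params = {"I0": p[0], "A1": p[1], "k1": p[2], "A2": p[3], "k2": p[4]}
        else:
            raise ValueError(f"unknown FRAP model {model!r}")
    except RuntimeError:
        return FrapFit(float("nan"), float("nan"), float("nan"), float("nan"), model, False)
    denom = 1.0 - i0
    mobile = float((plateau - i0) / denom) if abs(denom) > 1e-9 else float("nan")
    mobile = float(np.clip(mobile, 0.0, 1.0)) if np.isfinite(mobile) else mobile
    return FrapFit(
        k=float(k),
        t_half_s=float(t_half),
        mobile_fraction=mobile,
        plateau=float(plateau),
        model=model,
        converged=True,
        params={kk: float(vv) for kk, vv in params.items()},
    )


# ---------------------------------------------------------------------------
# SPR


def _sensorgram_model(t: np.ndarray, t_assoc: float, C: float, k_on: float, k_off: float, r_max: float) -> np.ndarray:
    kobs = k_on * C + k_off
    r_eq = 0.0 if kobs == 0 else r_max * C * k_on / kobs
    assoc = r_eq * (1.0 - np.exp(-kobs * np.clip(t, 0, t_assoc)))
    r_end = r_eq * (1.0 - math.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-k_off * np.clip(t - t_assoc, 0, None))
    return np.where(t <= t_assoc, assoc, dissoc)


def fit_binding(
    sensorgrams: list[KineticTrace],
    shared: bool = True,
) -> BindingFit:
    """Global one-to-one binding fit across sensorgrams.

    All curves share k_on, k_off and R_max (``shared=True``, the default);
    the association/dissociation boundary and analyte concentration are
    taken from each trace.  Parameter standard errors come from the
    Jacobian-based covariance of the least-squares problem, and the K_D
    uncertainty by first-order propagation of the rate uncertainties.

    A single concentration with no dissociation data leaves k_on and
    k_off unidentifiable (only their sum k_obs is constrained) and is
    rejected.
    """
    if not sensorgrams:
        raise ValueError("need at least one sensorgram")
    for tr in sensorgrams:
        if not np.isfinite(tr.concentration_M) or tr.concentration_M < 0:
            raise ValueError("every sensorgram needs a valid concentration")
        if not np.isfinite(tr.t_assoc_end_s):
            raise ValueError("every sensorgram needs its association end time")
    has_dissoc = any(tr.time_s.max() > tr.t_assoc_end_s for tr in sensorgrams)
    if len(sensorgrams) == 1 and not has_dissoc:
        raise ValueError(
            "one concentration with association data only: k_on and k_off are "
            "unidentifiable (only k_obs = k_on*C + k_off is constrained); supply "
            "a dissociation phase or more concentrations"
        )
    if not shared:
        fits = [fit_binding([tr], shared=True) for tr in sensorgrams]
        best = min(fits, key=lambda f: f.residual_rms)
        return best

    r_scale = max(float(np.max(np.abs(tr.value))) for tr in sensorgrams)
    r_scale = r_scale if r_scale > 0 else 1.0
    c_scale = max(tr.concentration_M for tr in sensorgrams) or 1e-9

    def resid(logp):
        k_on, k_off, r_max = np.exp(logp)
        k_on /= c_scale  # work in units of the largest concentration
        out = []
        for tr in sensorgrams:
            pred = _sensorgram_model(tr.time_s, tr.t_assoc_end_s, tr.concentration_M, k_on, k_off, r_max * r_scale)
            out.append(pred - tr.value)
        return np.concatenate(out)

    # initial guesses: k_obs from curve shape, k_off from dissociation tail
    p0 = np.log([1.0, 1e-2, 1.0])
    res = optimize.least_squares(resid, p0, xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000)
    k_on = float(np.exp(res.x[0]) / c_scale)
    k_off = float(np.exp(res.x[1]))
    r_max = float(np.exp(res.x[2]) * r_scale)
    n_obs = sum(len(tr.time_s) for tr in sensorgrams)
    rms = float(np.sqrt(np.mean(res.fun**2)))

    # covariance of log-params -> delta method on rates
    k_on_se = k_off_se = kd_se = float("nan")
    dof = n_obs - 3
    if dof > 0:
        try:
            jtj = res.jac.T @ res.jac
            cov_log = np.linalg.inv(jtj) * (res.fun @ res.fun) / dof
            k_on_se = k_on * math.sqrt(max(cov_log[0, 0], 0.0))
            k_off_se = k_off * math.sqrt(max(cov_log[1, 1], 0.0))
            # K_D = k_off/k_on; in log space var(log KD) = v11 + v00 - 2 v01
            v = cov_log[1, 1] + cov_log[0, 0] - 2 * cov_log[0, 1]
            kd_se = (k_off / k_on) * math.sqrt(max(v, 0.0))
        except np.linalg.LinAlgError:
            pass
    return BindingFit(
        k_on=k_on,
        k_off=k_off,
        R_max=r_max,
        K_D=k_off / k_on,
        residual_rms=rms,
        k_on_se=k_on_se,
        k_off_se=k_off_se,
        K_D_se=kd_se,
        converged=bool(res.success),
    )
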