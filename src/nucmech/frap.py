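"""FRAP trace normalization and single-diffusion recovery fitting.

The recovery model is

    F(t) = (F0 + Finf * (t/t1)/2) / (1 + (t/t1)/2)

which reaches (F0 + Finf)/2 at t = 2*t1, so the half-recovery time is
t_half = 2*t1 analytically.  The immobile fraction is 1 - Finf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class FrapCurve:
    times: np.ndarray  # seconds, 0 at the first post-bleach frame
    values: np.ndarray  # normalized to pre-bleach = 1
    prebleach_level: float = 1.0
    roi_kind: str = "inside_condensate"


@dataclass
class FrapFit:
    f0: float
    finf: float
    t1: float
    residual: float

    @property
    def t_half(self) -> float:
        return 2.0 * self.t1

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.finf


def recovery_model(t, f0, finf, t1):
    x = (np.asarray(t, dtype=float) / t1) / 2.0
    return (f0 + finf * x) / (1.0 + x)


def normalize_frap(
    roi: np.ndarray,
    reference: np.ndarray,
    prebleach_frames: int,
    dt: float = 0.002101,
) -> FrapCurve:
    """Double normalization: F(t) = (ROI/Ref) / (mean ROI_pre / mean Ref_pre).

    Dividing by the reference trace removes acquisition bleaching shared by
    both ROIs; the pre-bleach ratio anchors the scale at 1.  Time is zeroed
    at the first post-bleach frame.
    """
    roi = np.asarray(roi, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if roi.shape != reference.shape:
        raise ValueError("ROI and reference traces must have identical length")
    if prebleach_frames < 1:
        raise ValueError("need at least one pre-bleach frame")
    if prebleach_frames >= len(roi):
        raise ValueError("no post-bleach data after the pre-bleach frames")
    if np.any(reference == 0):
        raise ValueError("reference trace contains zero intensity")
    pre_ratio = roi[:prebleach_frames].mean() / reference[:prebleach_frames].mean()
    values = (roi / reference) / pre_ratio
    post = values[prebleach_frames:]
    times = np.arange(len(post)) * dt
    return FrapCurve(times=times, values=post)


def fit_recovery(curve: FrapCurve) -> FrapFit:
    """Bounded nonlinear least squares of the recovery model with a
    logarithmic multi-start grid over t1 (the model is monotone in t and
    prone to flat objectives at extreme timescales)."""
    t, f = np.asarray(curve.times, float), np.asarray(curve.values, float)
    if len(t) < 10:
        raise ValueError("need at least 10 post-bleach points to fit")
    duration = max(t[-1], 10 * np.min(np.diff(t)) if len(t) > 1 else 1.0)
    dt = max(np.min(np.diff(t)), 1e-12) if len(t) > 1 else 1e-3
    f0_init = float(np.clip(f[0], 0.0, 1.2))
    finf_init = float(np.clip(np.median(f[-max(5, len(f) // 10):]), f0_init, 1.2))
    best = None
    lower, upper = [0.0, 0.0, 1e-12], [1.2, 1.2, np.inf]
    for t1_init in np.geomspace(dt, duration, 8):
        try:
            popt, _ = curve_fit(
                recovery_model,
                t,
                f,
                p0=[f0_init, finf_init, t1_init],
                bounds=(lower, upper),
                maxfev=20_000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((recovery_model(t, *popt) - f) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError(
            "recovery fit failed to converge from every multi-start point"
        )
    (f0, finf, t1), resid = best
    if f0 > finf:  # degenerate flat curves can invert the ordering slightly
        f0, finf = finf, f0
    return FrapFit(f0=float(f0), finf=float(finf), t1=float(t1), residual=resid)


def fit_report(fit: FrapFit, curve: FrapCurve) -> dict:
    """Fitted parameters plus the last-frame recovery level (the paper-style
    maxima can be read either as the plateau or the final observed value)."""
    return {
        "F0": fit.f0,
        "Finf": fit.finf,
        "t1_s": fit.t1,
        "t_half_s": fit.t_half,
        "immobile_fraction": fit.immobile_fraction,
        "last_frame_value": float(np.asarray(curve.values)[-1]),
        "residual": fit.residual,
    }


def curve_from_table(df: pd.DataFrame, prebleach_frames: int = 0) -> FrapCurve:
    """Build a FrapCurve from a table with either (time_s, intensity) columns
    (already normalized) or (time_s, roi, reference) raw traces."""
    if {"roi", "reference"} <= set(df.columns):
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        return normalize_frap(
            df["roi"].to_numpy(), df["reference"].to_numpy(), prebleach_frames, dt
        )
    return FrapCurve(
        times=df["time_s"].to_numpy(float), values=df["intensity"].to_numpy(float)
    )
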