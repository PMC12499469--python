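"""FRAP recovery analysis: drift correction, normalization and
single-exponential fitting.

The pipeline mirrors standard condensate FRAP practice:

1. drift correction — subtract the (pre-bleach-anchored) intensity trace of
   an unbleached control condensate from the photobleached trace;
2. standardization — divide by the pre-bleach mean, so the pre-bleach level
   maps to 1 and the first post-bleach frame to its fraction of pre-bleach
   (R_norm);
3. fractional recovery

       R_fract(t) = (R_norm(t) − R_norm(0)) / (1 − R_norm(0)),

   which is 0 at the first post-bleach frame by construction;
4. nonlinear least-squares fit of the single-exponential recovery

       R_fract(t) = A (1 − e^{−t/τ}),

   where A is the mobile fraction and τ the recovery time constant; the
   percentage recovery is %R = A × 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FRAPTrace",
    "RecoveryFit",
    "correct_and_normalize",
    "fractional_recovery",
    "fit_recovery",
]


@dataclass
class FRAPTrace:
    time: np.ndarray  # seconds; time[bleach_index] is the first post-bleach frame
    raw_bleached: np.ndarray
    raw_control: np.ndarray | None
    bleach_index: int
    r_norm: np.ndarray | None = None
    r_fract: np.ndarray | None = None  # post-bleach frames only

    @property
    def post_time(self) -> np.ndarray:
        """Time since bleach for the post-bleach frames."""
        return self.time[self.bleach_index:] - self.time[self.bleach_index]


@dataclass
class RecoveryFit:
    mobile_fraction: float  # A
    tau_s: float
    percent_recovery: float  # 100 * A, exact
    residual_norm: float
    converged: bool
    immobile_fraction: float  # 1 - A, derived convenience
    flags: list[str]


def correct_and_normalize(
    raw_bleached: np.ndarray,
    raw_control: np.ndarray | None,
    bleach_index: int,
    time: np.ndarray | None = None,
) -> FRAPTrace:
    """Drift-correct against a control trace and standardize to R_norm.

    ``bleach_index`` is the index of the first post-bleach frame; at least
    3 pre-bleach and 5 post-bleach frames are required.  The control trace
    is re-anchored to its own pre-bleach mean before subtraction, so a
    drift shared by both traces cancels while the bleached trace keeps its
    intensity scale.  R_norm is the corrected trace divided by its
    pre-bleach mean.
    """
    bleached = np.asarray(raw_bleached, dtype=float)
    if bleach_index < 3:
        raise ValueError("need at least 3 pre-bleach frames")
    if bleached.size - bleach_index < 5:
        raise ValueError("need at least 5 post-bleach frames")
    if time is None:
        time = np.arange(bleached.size, dtype=float) - bleach_index
    time = np.asarray(time, dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")

    control = None
    if raw_control is not None:
        control = np.asarray(raw_control, dtype=float)
        if control.size < bleached.size:
            raise ValueError("control trace shorter than bleached trace")
        control = control[:bleached.size]
        corrected = bleached - (control - control[:bleach_index].mean())
    else:
        corrected = bleached.copy()

    pre_mean = corrected[:bleach_index].mean()
    if pre_mean <= corrected[bleach_index]:
        raise ValueError("no bleach detected")
    r_norm = corrected / pre_mean
    return FRAPTrace(
        time=time,
        raw_bleached=bleached,
        raw_control=control,
        bleach_index=int(bleach_index),
        r_norm=r_norm,
    )


def fractional_recovery(trace: FRAPTrace, min_depth: float = 1e-3) -> FRAPTrace:
    """Populate R_fract on the post-bleach frames.

    R_fract(0) is exactly 0; a bleach depth ``1 − R_norm(0)`` below
    ``min_depth`` is rejected as too shallow to normalize.
    """
    if trace.r_norm is None:
        raise ValueError("r_norm not populated; run correct_and_normalize first")
    r0 = trace.r_norm[trace.bleach_index]
    depth = 1.0 - r0
    if depth < min_depth:
        raise ValueError(f"bleach depth too shallow ({depth:.2g} < {min_depth:.2g})")
    post = trace.r_norm[trace.bleach_index:]
    trace.r_fract = (post - r0) / depth
    return trace


def _recovery_model(t: np.ndarray, A: float, tau: float) -> np.ndarray:
    return A * (1.0 - np.exp(-t / tau))


def fit_recovery(trace: FRAPTrace) -> RecoveryFit:
    """Least-squares fit of A(1 − e^{−t/τ}) to the post-bleach R_fract.

    Initialization: A₀ = final R_fract value, τ₀ = time at which R_fract
    first exceeds A₀/2.  Bounds: A ∈ [0, 1.5] (slightly above 1 to avoid
    boundary bias under noise; fits with A > 1 are flagged), τ ∈ (0,
    10·t_max].  Non-convergence returns ``converged=False`` rather than
    raising.
    """
    if trace.r_fract is None:
        raise ValueError("r_fract not populated; run fractional_recovery first")
    t = trace.post_time
    y = trace.r_fract
    if y.size < 5:
        raise ValueError("need at least 5 post-bleach frames to fit")
    t_max = float(t[-1]) if t[-1] > 0 else 1.0

    a0 = float(np.clip(y[-1], 0.01, 1.5))
    above = np.nonzero(y >= a0 / 2)[0]
    tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else 0.1 * t_max

    flags: list[str] = []
    try:
        popt, _ = curve_fit(
            _recovery_model, t, y,
            p0=(a0, tau0),
            bounds=([0.0, 1e-9], [1.5, 10.0 * t_max]),
            maxfev=10000,
        )
        A, tau = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        A, tau = a0, tau0
        converged = False
        flags.append("fit did not converge; reporting initial estimates")
    if A > 1.0:
        flags.append("mobile fraction exceeds 1 (noise or incomplete pre-bleach)")
    resid = float(np.linalg.norm(y - _recovery_model(t, A, tau)))
    return RecoveryFit(
        mobile_fraction=A,
        tau_s=tau,
        percent_recovery=100.0 * A,
        residual_norm=resid,
        converged=converged,
        immobile_fraction=1.0 - A,
        flags=flags,
    )
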