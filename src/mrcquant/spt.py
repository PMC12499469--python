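"""Single-particle tracking: linking, time-averaged MSD and diffusion fits.

Particle motion is summarized by the time-averaged mean squared
displacement of each trajectory,

    MSD(kΔt) = ⟨ |r(t + kΔt) − r(t)|² ⟩_t ,

fitted through the origin with the 2D free-diffusion model
MSD = 4·D_eff·Δt.  The anomalous exponent α is the log-log slope of the
MSD over the same lag range; α ≈ 1 indicates simple diffusion and α < 1
subdiffusion, as seen for particles confined inside condensates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "Trajectory",
    "MSDCurve",
    "DiffusionFit",
    "link_detections",
    "time_averaged_msd",
    "ensemble_msd",
    "fit_diffusion",
    "compare_regions",
    "label_trajectory",
]


@dataclass
class Trajectory:
    track_id: int
    frames: np.ndarray  # frame indices
    positions: np.ndarray  # (n, 2) in µm
    dt: float  # s per frame
    location_label: str = "unlabeled"  # inside_condensate | outside_condensate

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.frames = np.asarray(self.frames, dtype=int)
        if self.positions.shape[0] < 2:
            raise ValueError("trajectory needs at least 2 positions")


@dataclass
class MSDCurve:
    lags: np.ndarray  # seconds
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray


@dataclass
class DiffusionFit:
    D_eff: float  # µm²/s
    alpha: float
    fit_lags: int
    regime: str  # subdiffusive | normal | superdiffusive


def link_detections(
    detections: list[np.ndarray],
    max_disp_um: float,
    max_gap_frames: int = 0,
    dt: float = 0.1,
) -> list[Trajectory]:
    """Greedy nearest-neighbour frame-to-frame linking.

    ``detections[f]`` is an ``(n_f, 2)`` array of positions at frame ``f``.
    Closest pairs link first; links longer than ``max_disp_um`` (scaled by
    the gap length when frames are bridged) are rejected; a track is kept
    alive across up to ``max_gap_frames`` empty frames.
    """
    active: list[dict] = []  # {'frames': [...], 'pos': [...], 'last_frame': f}
    finished: list[dict] = []

    for f, pts in enumerate(detections):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        # retire tracks that gapped out
        still = []
        for tr in active:
            if f - tr["last_frame"] > max_gap_frames + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        if len(active) and len(pts):
            last = np.array([tr["pos"][-1] for tr in active])
            d = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=2)
            used_t: set[int] = set()
            used_p: set[int] = set()
            for flat in np.argsort(d, axis=None):
                i, j = np.unravel_index(flat, d.shape)
                gap = f - active[i]["last_frame"]
                if d[i, j] > max_disp_um * gap:
                    break
                if i in used_t or j in used_p:
                    continue
                used_t.add(int(i))
                used_p.add(int(j))
                active[i]["frames"].append(f)
                active[i]["pos"].append(pts[j])
                active[i]["last_frame"] = f
            unmatched = [j for j in range(len(pts)) if j not in used_p]
        else:
            unmatched = list(range(len(pts)))
        for j in unmatched:
            active.append({"frames": [f], "pos": [pts[j]], "last_frame": f})

    finished.extend(active)
    out = []
    for k, tr in enumerate(t for t in finished if len(t["pos"]) >= 2):
        out.append(Trajectory(
            track_id=k,
            frames=np.array(tr["frames"]),
            positions=np.array(tr["pos"]),
            dt=dt,
        ))
    return out


def time_averaged_msd(
    traj: Trajectory, max_lag_fraction: float = 0.25
) -> MSDCurve:
    """Time-averaged MSD of one trajectory up to a fraction of its length.

    For a gap-free track of length L, lag k averages over L − k
    displacement pairs.
    """
    pos = traj.positions
    n = pos.shape[0]
    if n < 4:
        raise ValueError("trajectory too short for MSD (need >= 4 positions)")
    max_lag = max(1, int(np.floor(max_lag_fraction * n)))
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for i, k in enumerate(lags):
        disp = pos[k:] - pos[:-k]
        msd[i] = float(np.mean(np.sum(disp**2, axis=1)))
        n_pairs[i] = n - k
    return MSDCurve(lags=lags * traj.dt, msd=msd, n_pairs=n_pairs)


def ensemble_msd(trajectories: list[Trajectory], max_lag: int = 10) -> MSDCurve:
    """Average the time-averaged MSD over an ensemble of tracks,
    weighting each lag by its number of displacement pairs."""
    if not trajectories:
        raise ValueError("no trajectories")
    dt = trajectories[0].dt
    num = np.zeros(max_lag)
    den = np.zeros(max_lag, dtype=int)
    for traj in trajectories:
        pos = traj.positions
        n = pos.shape[0]
        for k in range(1, min(max_lag, n - 1) + 1):
            disp = pos[k:] - pos[:-k]
            num[k - 1] += float(np.sum(np.sum(disp**2, axis=1)))
            den[k - 1] += n - k
    keep = den > 0
    return MSDCurve(
        lags=np.arange(1, max_lag + 1)[keep] * dt,
        msd=num[keep] / den[keep],
        n_pairs=den[keep],
    )


def fit_diffusion(msd: MSDCurve, n_fit_lags: int = 4) -> DiffusionFit:
    """Fit MSD = 4·D_eff·Δt through the origin over the first lags.

    D_eff is the through-origin least-squares slope divided by 4; α is the
    slope of log(MSD) versus log(lag) over the same range.  Regime:
    subdiffusive if α < 0.9, superdiffusive if α > 1.1, else normal.
    """
    k = min(n_fit_lags, msd.lags.size)
    lags, vals = msd.lags[:k], msd.msd[:k]
    ok = vals > 0
    lags, vals = lags[ok], vals[ok]
    if lags.size < 2:
        raise ValueError("fewer than 2 usable (positive) MSD lags")
    slope = float(np.dot(lags, vals) / np.dot(lags, lags))
    alpha = float(np.polyfit(np.log(lags), np.log(vals), 1)[0])
    regime = ("subdiffusive" if alpha < 0.9
              else "superdiffusive" if alpha > 1.1 else "normal")
    return DiffusionFit(
        D_eff=max(slope / 4.0, 0.0),
        alpha=alpha,
        fit_lags=int(lags.size),
        regime=regime,
    )


def compare_regions(
    fits_inside: list[DiffusionFit],
    fits_outside: list[DiffusionFit],
) -> dict:
    """Welch t-test on D_eff between particles inside and outside
    condensates, with a direction flag ("inside_slower", "inside_faster"
    or "none" when not significant at 0.05)."""
    d_in = np.array([f.D_eff for f in fits_inside])
    d_out = np.array([f.D_eff for f in fits_outside])
    if d_in.size < 2 or d_out.size < 2:
        raise ValueError("need at least 2 fits per group")
    tol = 1e-12 * (abs(d_in.mean()) + abs(d_out.mean()) + 1.0)
    if d_in.std() <= tol and d_out.std() <= tol:
        p = 1.0 if d_in.mean() == d_out.mean() else 0.0
        stat = np.inf if p == 0.0 else 0.0
        degenerate = True
    else:
        res = sps.ttest_ind(d_in, d_out, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        degenerate = False
    if p < 0.05:
        direction = "inside_slower" if d_in.mean() < d_out.mean() else "inside_faster"
    else:
        direction = "none"
    return {
        "n_inside": int(d_in.size),
        "n_outside": int(d_out.size),
        "mean_inside": float(d_in.mean()),
        "mean_outside": float(d_out.mean()),
        "sd_inside": float(d_in.std(ddof=1)),
        "sd_outside": float(d_out.std(ddof=1)),
        "t_statistic": stat,
        "p_value": p,
        "direction": direction,
        "degenerate_variance": degenerate,
    }


def label_trajectory(
    traj: Trajectory,
    condensate_mask: np.ndarray,
    pixel_size_um: float,
) -> Trajectory:
    """Assign inside/outside-condensate labels by majority vote over the
    trajectory's positions; exact ties stay unlabeled."""
    cols = np.round(traj.positions[:, 0] / pixel_size_um).astype(int)
    rows = np.round(traj.positions[:, 1] / pixel_size_um).astype(int)
    ny, nx = condensate_mask.shape
    inside = 0
    total = traj.positions.shape[0]
    for r, c in zip(rows, cols):
        if 0 <= r < ny and 0 <= c < nx and condensate_mask[r, c] > 0:
            inside += 1
    if inside * 2 > total:
        traj.location_label = "inside_condensate"
    elif inside * 2 < total:
        traj.location_label = "outside_condensate"
    else:
        traj.location_label = "unlabeled"
    return traj
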