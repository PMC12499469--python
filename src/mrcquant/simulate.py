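"""Seeded synthetic-microscopy generators with recoverable ground truth.

Every downstream stage (spot detection, SNR, colocalization, condensate
morphometrics, FRAP fitting, MSD analysis) is validated against images,
traces and trajectories produced here, where the truth — spot centroids,
colocalization pairs, condensate geometry, recovery parameters (A, τ) and
diffusion coefficients — is known by construction.

The image model is deliberately simple: a nucleus is a disk of uniform
background, puncta are 2D Gaussian point-spread-function profiles, and
condensates are disks (or ellipses, for low-circularity truth) with a soft
edge of width ``psf_sigma``. Noise is either pure additive Gaussian (kept
for exact oracles) or Poisson shot noise plus Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

from .core import ImageStack

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cell_image",
    "generate_condensate_image",
    "generate_frap_trace",
    "generate_trajectories",
    "default_frap_time_grid",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic imaging experiment.

    ``spots_per_cell`` is either a fixed integer count or a sequence of
    probabilities ``P(k spots) for k = 0, 1, ...``.  ``prey_to_bait_ratio``
    is the prey/bait peak-amplitude ratio r, and ``coloc_fraction`` the
    probability p that a bait spot has a prey partner.
    """

    image_shape: tuple[int, int] = (192, 192)  # (Y, X) pixels
    pixel_size: float = 0.08  # µm/px, ~100x/1.4NA sampling
    n_cells: int = 1
    spots_per_cell: int | Sequence[float] = 2
    psf_sigma: float = 1.6  # px (~130 nm)
    bait_peak: float = 300.0  # peak amplitude above background, a.u.
    prey_to_bait_ratio: float = 1.0
    coloc_fraction: float = 1.0
    condensate_radius: float = 12.0  # px
    condensates_per_cell: int = 1
    condensate_axis_ratio: float = 1.0  # 1 → disk; >1 → ellipse
    bg_mean: float = 50.0
    bg_sd: float = 5.0
    noise_model: str = "gaussian"  # "gaussian" | "poisson+gaussian" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if min(self.bait_peak, self.bg_mean, self.bg_sd) < 0:
            raise ValueError("intensities must be non-negative")
        if self.noise_model not in ("gaussian", "poisson+gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.condensate_axis_ratio < 1.0:
            raise ValueError("condensate_axis_ratio must be >= 1")


@dataclass
class GroundTruth:
    """One record per generated object, in physical units."""

    # cell_id -> list of (x_um, y_um) per channel index
    spot_centroids: dict[int, dict[int, list[tuple[float, float]]]] = field(
        default_factory=dict
    )
    # cell_id -> list of (bait_index, prey_index) pairs
    coloc_pairs: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    # cell_id -> list of dicts (center_um, radius_um, axis_ratio, peak)
    condensates: dict[int, list[dict]] = field(default_factory=dict)
    frap_params: dict | None = None
    true_D: float | None = None
    confinement_radius: float | None = None

    def n_spots(self, cell_id: int, channel: int) -> int:
        return len(self.spot_centroids.get(cell_id, {}).get(channel, []))


# ---------------------------------------------------------------------------
# field layout helpers

def _cell_grid(config: SimulationConfig) -> list[tuple[float, float, float]]:
    """Lay ``n_cells`` nuclei on a square grid; return (cy, cx, radius) px."""
    ny, nx = config.image_shape
    ncols = int(math.ceil(math.sqrt(config.n_cells)))
    nrows = int(math.ceil(config.n_cells / ncols))
    tile_y, tile_x = ny / nrows, nx / ncols
    radius = 0.42 * min(tile_y, tile_x)
    if radius < 4:
        raise ValueError(
            f"image_shape {config.image_shape} too small for {config.n_cells} nuclei"
        )
    centers = []
    for i in range(config.n_cells):
        r, c = divmod(i, ncols)
        centers.append(((r + 0.5) * tile_y, (c + 0.5) * tile_x, radius))
    return centers


def _render_gaussian_spot(img: np.ndarray, cy: int, cx: int, amp: float,
                          sigma: float) -> None:
    """Add a 2D Gaussian of peak ``amp`` centred on pixel (cy, cx) in place."""
    half = int(math.ceil(5 * sigma))
    y0, y1 = max(0, cy - half), min(img.shape[0], cy + half + 1)
    x0, x1 = max(0, cx - half), min(img.shape[1], cx + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
    )


def _sample_spot_count(config: SimulationConfig, rng: np.random.Generator) -> int:
    if isinstance(config.spots_per_cell, (int, np.integer)):
        return int(config.spots_per_cell)
    probs = np.asarray(config.spots_per_cell, dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(len(probs), p=probs))


def _place_points(rng: np.random.Generator, center: tuple[float, float],
                  radius: float, n: int, min_sep: float) -> list[tuple[int, int]]:
    """Rejection-sample ``n`` integer pixel positions inside a disk, pairwise
    separated by at least ``min_sep`` px."""
    cy, cx = center
    placed: list[tuple[int, int]] = []
    for _ in range(2000 * max(n, 1)):
        if len(placed) == n:
            break
        ang = rng.uniform(0, 2 * np.pi)
        rad = radius * 0.75 * math.sqrt(rng.uniform())
        y, x = int(round(cy + rad * math.sin(ang))), int(round(cx + rad * math.cos(ang)))
        if all((y - py) ** 2 + (x - px) ** 2 >= min_sep**2 for py, px in placed):
            placed.append((y, x))
    if len(placed) < n:
        raise ValueError("cannot place spots without overlap")
    return placed


def _apply_noise(clean: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "none" or (
        config.noise_model == "gaussian" and config.bg_sd == 0
    ):
        return clean
    if config.noise_model == "gaussian":
        noisy = clean + rng.normal(0.0, config.bg_sd, size=clean.shape)
    else:  # poisson shot noise + gaussian read noise
        noisy = rng.poisson(np.clip(clean, 0, None)).astype(float)
        if config.bg_sd > 0:
            noisy += rng.normal(0.0, config.bg_sd, size=clean.shape)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# image generators

def generate_cell_image(
    config: SimulationConfig,
) -> tuple[ImageStack, np.ndarray, GroundTruth]:
    """Render a two-channel field of nuclei with bait and prey puncta.

    Channel 0 is the bait: each nucleus receives its sampled number of
    Gaussian puncta of peak ``bait_peak`` above background.  Channel 1 is
    the prey: each bait spot gains a partner at the same centroid with
    probability ``coloc_fraction`` and peak ratio ``prey_to_bait_ratio``.

    Returns the image stack, a nuclear label mask (0 = outside,
    1..n_cells = nucleus id) and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    ny, nx = config.image_shape
    bait = np.full((ny, nx), float(config.bg_mean))
    prey = np.full((ny, nx), float(config.bg_mean))
    mask = np.zeros((ny, nx), dtype=np.int32)
    truth = GroundTruth()

    yy, xx = np.mgrid[0:ny, 0:nx]
    min_sep = 4.0 * config.psf_sigma
    for cell_id, (cy, cx, radius) in enumerate(_cell_grid(config), start=1):
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = cell_id
        n_spots = _sample_spot_count(config, rng)
        positions = _place_points(rng, (cy, cx), radius, n_spots, min_sep)
        bait_cents: list[tuple[float, float]] = []
        prey_cents: list[tuple[float, float]] = []
        pairs: list[tuple[int, int]] = []
        for y, x in positions:
            _render_gaussian_spot(bait, y, x, config.bait_peak, config.psf_sigma)
            bait_cents.append((x * config.pixel_size, y * config.pixel_size))
            if rng.uniform() < config.coloc_fraction:
                _render_gaussian_spot(
                    prey, y, x,
                    config.bait_peak * config.prey_to_bait_ratio,
                    config.psf_sigma,
                )
                pairs.append((len(bait_cents) - 1, len(prey_cents)))
                prey_cents.append((x * config.pixel_size, y * config.pixel_size))
        truth.spot_centroids[cell_id] = {0: bait_cents, 1: prey_cents}
        truth.coloc_pairs[cell_id] = pairs

    data = np.stack([
        _apply_noise(bait, config, rng),
        _apply_noise(prey, config, rng),
    ])
    stack = ImageStack(
        data=data,
        pixel_size_xy=config.pixel_size,
        channel_names=("bait", "prey"),
    )
    return stack, mask, truth


def generate_condensate_image(
    config: SimulationConfig,
) -> tuple[ImageStack, np.ndarray, GroundTruth]:
    """Render nuclei containing disk- or ellipse-shaped condensates.

    Condensates have a soft edge of width ``psf_sigma`` (an erf profile, the
    convolution of a hard disk edge with the PSF).  ``condensate_axis_ratio``
    elongates the shape at constant area to generate low-circularity truth.
    """
    if config.condensate_radius < 2:
        raise ValueError("condensate_radius must be >= 2 px")
    rng = np.random.default_rng(config.seed)
    ny, nx = config.image_shape
    img = np.full((ny, nx), float(config.bg_mean))
    mask = np.zeros((ny, nx), dtype=np.int32)
    truth = GroundTruth()

    yy, xx = np.mgrid[0:ny, 0:nx]
    for cell_id, (cy, cx, nuc_radius) in enumerate(_cell_grid(config), start=1):
        if config.condensate_radius >= nuc_radius:
            raise ValueError(
                f"condensate_radius {config.condensate_radius} px exceeds "
                f"nucleus radius {nuc_radius:.1f} px"
            )
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= nuc_radius**2] = cell_id
        min_sep = 2.5 * config.condensate_radius + 4 * config.psf_sigma
        centers = _place_points(
            rng, (cy, cx), nuc_radius - config.condensate_radius,
            config.condensates_per_cell, min_sep,
        )
        records = []
        q = config.condensate_axis_ratio
        # semi-axes a*sqrt(q), a/sqrt(q) preserve the disk area pi*r^2
        for y, x in centers:
            r_ell = np.sqrt(
                (yy - y) ** 2 / q + (xx - x) ** 2 * q
            )
            edge = 0.5 * (1.0 - erf(
                (r_ell - config.condensate_radius) / (math.sqrt(2) * config.psf_sigma)
            ))
            img += config.bait_peak * edge
            records.append({
                "center_um": (x * config.pixel_size, y * config.pixel_size),
                "radius_um": config.condensate_radius * config.pixel_size,
                "axis_ratio": q,
                "peak": config.bait_peak,
            })
        truth.condensates[cell_id] = records

    data = _apply_noise(img, config, rng)[None, ...]
    stack = ImageStack(
        data=data, pixel_size_xy=config.pixel_size, channel_names=("condensate",)
    )
    return stack, mask, truth


# ---------------------------------------------------------------------------
# FRAP trace generator

def default_frap_time_grid(n_pre: int = 5, n_post: int = 60,
                           dt: float = 0.5) -> np.ndarray:
    """Time axis in seconds with t = 0 at the first post-bleach frame."""
    return np.concatenate([
        -dt * np.arange(n_pre, 0, -1), dt * np.arange(n_post)
    ])


def generate_frap_trace(
    A: float,
    tau: float,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    drift_rate: float = 0.0,
    seed: int = 0,
    plateau: float = 100.0,
    bleach_depth: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward model of a photobleaching recovery experiment.

    The bleached trace sits at ``plateau`` before the bleach, drops
    instantaneously to ``plateau * (1 - bleach_depth)`` at t = 0, then
    recovers as ``A (1 - e^{-t/τ})`` of the bleached amount.  A linear
    drift of ``drift_rate`` a.u./s and Gaussian noise of SD ``noise_sd``
    are added; the control trace carries the same drift with independent
    noise, emulating an unbleached reference condensate.  The drift is
    referenced to the pre-bleach baseline (it averages to zero over the
    pre-bleach frames), so the acquisition starts on the calibrated
    plateau and control-anchored subtraction removes it exactly.

    Returns ``(bleached, control)`` on the given time grid (t = 0 marks the
    first post-bleach frame; at least 3 pre-bleach points are required).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if not (0.0 <= A <= 1.0):
        raise ValueError("mobile fraction A must be in [0, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if np.sum(t_grid < 0) < 3:
        raise ValueError("t_grid must include at least 3 pre-bleach points")
    rng = np.random.default_rng(seed)

    pre = t_grid < 0
    floor = plateau * (1.0 - bleach_depth)
    recovery = floor + (plateau - floor) * A * (1.0 - np.exp(
        -np.clip(t_grid, 0.0, None) / tau
    ))
    bleached = np.where(pre, plateau, recovery)
    control = np.full_like(t_grid, plateau)

    drift = drift_rate * (t_grid - t_grid[pre].mean())
    bleached = bleached + drift
    control = control + drift
    if noise_sd > 0:
        bleached = bleached + rng.normal(0.0, noise_sd, size=t_grid.shape)
        control = control + rng.normal(0.0, noise_sd, size=t_grid.shape)
    return bleached, control


# ---------------------------------------------------------------------------
# trajectory generator

def generate_trajectories(
    D: float,
    dt: float,
    n_steps: int,
    n_tracks: int,
    confinement_radius: float | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Simulate 2D random walks, optionally confined in a circular domain.

    Free motion: per-axis displacement variance 2·D·dt per step, so the
    2D mean squared displacement grows as MSD(τ) = 4·D·τ.  Confined
    motion reflects each step at a circle of ``confinement_radius`` µm
    centred on the track origin, producing the MSD plateau characteristic
    of particles trapped inside condensates.

    Returns a list of ``(n_steps + 1, 2)`` position arrays in µm.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    step_sd = math.sqrt(2.0 * D * dt)
    tracks = []
    for _ in range(n_tracks):
        steps = rng.normal(0.0, step_sd, size=(n_steps, 2))
        if confinement_radius is None:
            pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        else:
            R = float(confinement_radius)
            pos = np.zeros((n_steps + 1, 2))
            for i in range(n_steps):
                nxt = pos[i] + steps[i]
                r = np.hypot(*nxt)
                if r > R:  # reflect radially back inside the boundary
                    nxt = nxt * ((2 * R - r) / r)
                    r2 = np.hypot(*nxt)
                    if r2 > R:  # pathological large step: clamp to boundary
                        nxt = nxt * (R / r2)
                pos[i + 1] = nxt
        tracks.append(pos)
    return tracks
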