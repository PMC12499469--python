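"""Spot SNR, cross-channel matching and binding-capability statistics.

The signal-to-noise ratio of a punctum is defined as

    SNR = (peak intensity − background mean) / background SD,

with the background taken from a circular region of 3–4 µm diameter centred
on the spot, excluding a neighbourhood around every labelled spot.  The
ratio of bait SNR to prey SNR over matched spot pairs, averaged over
repeats, serves as a relative proxy for binding capability; the
colocalization percentage is the fraction of bait spots with a prey
partner within a distance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ImageStack, Spot

__all__ = [
    "SNRMeasurement",
    "ColocResult",
    "SNRRatioStat",
    "spot_snr",
    "match_spots",
    "snr_ratio_stat",
    "pixel_correlation",
]


@dataclass
class SNRMeasurement:
    spot: Spot
    background_mean: float
    background_sd: float
    snr: float
    n_background_px: int


@dataclass
class ColocResult:
    cell_id: int
    pairs: list[tuple[Spot, Spot, float]]  # (bait, prey, distance µm)
    n_bait: int
    n_prey: int
    coloc_percent: float  # 100 * matched bait / total bait


@dataclass
class SNRRatioStat:
    ratios: np.ndarray  # per-pair bait/prey SNR
    n: int
    mean: float
    sd: float


def spot_snr(
    image: ImageStack | np.ndarray,
    spot: Spot,
    bg_diameter_um: float = 3.5,
    exclusion_spots: list[Spot] | None = None,
    psf_sigma: float = 1.6,
    pixel_size_um: float | None = None,
    min_background_px: int = 50,
) -> SNRMeasurement:
    """SNR of one spot against its local background.

    The background region is a disk of ``bg_diameter_um`` centred on the
    spot, minus a disk of radius ``2 * psf_sigma`` px around every spot in
    ``exclusion_spots`` (the measured spot is always excluded).
    """
    if isinstance(image, ImageStack):
        img = np.asarray(image.channel(spot.channel), dtype=float)
        if img.ndim == 3:
            img = img.max(axis=0)
        px = image.pixel_size_xy
    else:
        img = np.asarray(image, dtype=float)
        px = pixel_size_um if pixel_size_um is not None else 1.0

    cy, cx = spot.centroid_px
    if not np.isfinite(cy):
        cx_um, cy_um = spot.centroid_um
        cy, cx = cy_um / px, cx_um / px

    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    bg_radius_px = 0.5 * bg_diameter_um / px
    region = (yy - cy) ** 2 + (xx - cx) ** 2 <= bg_radius_px**2

    excl = list(exclusion_spots) if exclusion_spots is not None else []
    if spot not in excl:
        excl.append(spot)
    excl_r2 = (2.0 * psf_sigma) ** 2
    for s in excl:
        sy, sx = s.centroid_px
        if not np.isfinite(sy):
            sx_um, sy_um = s.centroid_um
            sy, sx = sy_um / px, sx_um / px
        region &= (yy - sy) ** 2 + (xx - sx) ** 2 > excl_r2

    vals = img[region]
    if vals.size < min_background_px:
        raise ValueError(
            f"background region has only {vals.size} pixels "
            f"(minimum {min_background_px})"
        )
    bg_mean = float(vals.mean())
    bg_sd = float(vals.std())
    if bg_sd == 0:
        raise ValueError("degenerate background: SD is zero")
    return SNRMeasurement(
        spot=spot,
        background_mean=bg_mean,
        background_sd=bg_sd,
        snr=(spot.peak_intensity - bg_mean) / bg_sd,
        n_background_px=int(vals.size),
    )


def match_spots(
    bait_spots: list[Spot],
    prey_spots: list[Spot],
    max_dist_um: float = 0.3,
) -> ColocResult:
    """Greedy nearest-neighbour matching of bait to prey spots.

    Closest pairs are matched first, each spot used at most once, and a
    pair is kept only if its centroid distance is at most ``max_dist_um``.
    ``coloc_percent`` is 100 · matched bait / total bait (0 when there are
    no bait spots).
    """
    cell_id = bait_spots[0].cell_id if bait_spots else (
        prey_spots[0].cell_id if prey_spots else -1
    )
    pairs: list[tuple[Spot, Spot, float]] = []
    if bait_spots and prey_spots:
        b = np.array([s.centroid_um for s in bait_spots])
        p = np.array([s.centroid_um for s in prey_spots])
        d = np.linalg.norm(b[:, None, :] - p[None, :, :], axis=2)
        used_b: set[int] = set()
        used_p: set[int] = set()
        for flat in np.argsort(d, axis=None):
            i, j = np.unravel_index(flat, d.shape)
            if d[i, j] > max_dist_um:
                break
            if i in used_b or j in used_p:
                continue
            used_b.add(int(i))
            used_p.add(int(j))
            pairs.append((bait_spots[i], prey_spots[j], float(d[i, j])))
    pct = 100.0 * len(pairs) / len(bait_spots) if bait_spots else 0.0
    return ColocResult(
        cell_id=cell_id,
        pairs=pairs,
        n_bait=len(bait_spots),
        n_prey=len(prey_spots),
        coloc_percent=pct,
    )


def snr_ratio_stat(
    pairs: list[tuple[SNRMeasurement, SNRMeasurement]],
) -> SNRRatioStat:
    """Mean ± SD of the per-pair bait/prey SNR ratio.

    Pairs with non-positive prey SNR are dropped with a warning; at least
    one valid pair is required.
    """
    ratios = []
    for bait_m, prey_m in pairs:
        if prey_m.snr <= 0:
            warnings.warn(
                f"dropping pair with non-positive prey SNR ({prey_m.snr:.3g})",
                stacklevel=2,
            )
            continue
        ratios.append(bait_m.snr / prey_m.snr)
    if not ratios:
        raise ValueError("no valid SNR pairs")
    arr = np.asarray(ratios)
    return SNRRatioStat(
        ratios=arr,
        n=arr.size,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    )


def pixel_correlation(
    image_a: np.ndarray,
    image_b: np.ndarray,
    mask: np.ndarray,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
) -> dict:
    """Pixel-wise Pearson r and Manders M1/M2 within a mask.

    Manders coefficients use per-channel thresholds (default: channel mean
    within the mask): M1 is the fraction of channel-A intensity found where
    channel B is above its threshold, and symmetrically for M2.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    m = np.asarray(mask) > 0
    if not m.any():
        raise ValueError("mask is empty")
    av, bv = a[m], b[m]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("zero variance in a channel within the mask")
    r = float(np.corrcoef(av, bv)[0, 1])

    ta = float(av.mean()) if threshold_a is None else threshold_a
    tb = float(bv.mean()) if threshold_b is None else threshold_b
    sa, sb = av.sum(), bv.sum()
    m1 = float(av[bv > tb].sum() / sa) if sa > 0 else 0.0
    m2 = float(bv[av > ta].sum() / sb) if sb > 0 else 0.0
    return {"pearson_r": r, "manders_m1": m1, "manders_m2": m2}
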