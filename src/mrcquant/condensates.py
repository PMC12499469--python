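"""Condensate segmentation and morphometrics.

Condensates — large, round, bright foci formed by phase-separation-prone
proteins — are segmented by intensity thresholding inside the nuclear mask
and characterized by area, perimeter and circularity,

    circularity = 4π · area / perimeter²,

which equals 1 for a perfect circle and approaches 0 for elongated or
irregular shapes.  Objects are classified as "condensate" versus small
"punctum" by joint area and circularity thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "Condensate",
    "MorphologySummary",
    "circularity",
    "segment_condensates",
    "morphology_summary",
    "classify_condensate_vs_punctum",
]


def circularity(area: float, perimeter: float) -> float:
    """4π·area/perimeter², clamped to [0, 1].

    For the analytic circle (area πr², perimeter 2πr) this is exactly 1;
    discretized contours can nominally exceed 1, hence the clamp.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return float(min(max(4.0 * math.pi * area / perimeter**2, 0.0), 1.0))


@dataclass
class Condensate:
    cell_id: int
    label: int
    area_um2: float
    area_px: int
    perimeter_um: float
    circularity: float
    mean_intensity: float
    peak_intensity: float
    centroid_um: tuple[float, float]  # (x, y)


@dataclass
class MorphologySummary:
    n_cells: int
    percent_cells_with_condensates: float
    counts_per_cell: dict[int, int]
    log10_areas: np.ndarray
    circularities: np.ndarray
    area_normalization_um2: float


def _robust_background(values: np.ndarray, n_iter: int = 10) -> tuple[float, float]:
    """Median/MAD-anchored sigma clip: bright condensate pixels are far from
    the median on the MAD scale even when they dominate the plain SD, so the
    clip converges to the background population."""
    v = values.astype(float)
    for _ in range(n_iter):
        med = np.median(v)
        mad_sigma = 1.4826 * np.median(np.abs(v - med))
        sigma = mad_sigma if mad_sigma > 0 else v.std()
        if sigma == 0:
            break
        keep = np.abs(v - med) <= 3.0 * sigma
        if keep.all():
            break
        v = v[keep]
    return float(v.mean()), float(v.std())


def segment_condensates(
    image: np.ndarray,
    mask: np.ndarray,
    threshold_k: float = 3.0,
    min_area_um2: float = 0.05,
    pixel_size_um: float = 0.08,
) -> list[Condensate]:
    """Threshold-based condensate segmentation inside a nuclear label mask.

    Pixels above ``background_mean + threshold_k * background_sd`` (robust,
    sigma-clipped estimate over nuclear pixels) are labelled by connectivity;
    components of at least ``min_area_um2`` are measured.  Perimeter uses the
    Crofton contour estimator, which corrects the diagonal-step inflation of
    raw pixel-edge counting; circularity is clamped to [0, 1].
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if not np.any(mask > 0):
        raise ValueError("nuclear mask is empty")

    bg_mean, bg_sd = _robust_background(img[mask > 0])
    threshold = bg_mean + threshold_k * bg_sd
    # On an effectively noiseless image the k·SD band collapses onto the
    # background and the faint PSF-tail skirt would be segmented; fall back
    # to the half-maximum level, which marks the true edge of a soft disk.
    dyn_range = float(img[mask > 0].max()) - bg_mean
    if dyn_range > 0 and threshold_k * bg_sd < 0.02 * dyn_range:
        threshold = bg_mean + 0.5 * dyn_range
    binary = (img > threshold) & (mask > 0)
    labels, _ = ndimage.label(binary)

    out: list[Condensate] = []
    px_area = pixel_size_um**2
    for rp in measure.regionprops(labels, intensity_image=img):
        area_um2 = rp.area * px_area
        if area_um2 < min_area_um2:
            continue
        perim_px = rp.perimeter_crofton
        if perim_px <= 0:
            continue
        cy, cx = rp.centroid
        cell = int(mask[int(round(cy)), int(round(cx))])
        out.append(Condensate(
            cell_id=cell,
            label=int(rp.label),
            area_um2=float(area_um2),
            area_px=int(rp.area),
            perimeter_um=float(perim_px * pixel_size_um),
            circularity=circularity(rp.area, perim_px),
            mean_intensity=float(rp.intensity_mean),
            peak_intensity=float(rp.intensity_max),
            centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
        ))
    out.sort(key=lambda c: -c.area_um2)
    return out


def morphology_summary(
    condensates: list[Condensate],
    n_cells: int,
    area_normalization_um2: float = 1.0,
) -> MorphologySummary:
    """Population morphometrics: positive-cell percentage, per-cell counts
    and log10-normalized areas (area in µm² divided by the normalization
    constant, then log10)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if area_normalization_um2 <= 0:
        raise ValueError("area_normalization_um2 must be positive")
    counts: dict[int, int] = {}
    for c in condensates:
        counts[c.cell_id] = counts.get(c.cell_id, 0) + 1
    areas = np.array([c.area_um2 for c in condensates])
    return MorphologySummary(
        n_cells=n_cells,
        percent_cells_with_condensates=100.0 * len(counts) / n_cells,
        counts_per_cell=counts,
        log10_areas=np.log10(areas / area_normalization_um2) if areas.size
        else np.array([]),
        circularities=np.array([c.circularity for c in condensates]),
        area_normalization_um2=area_normalization_um2,
    )


def classify_condensate_vs_punctum(
    objects: list[Condensate],
    area_threshold_um2: float = 0.5,
    circularity_threshold: float = 0.8,
) -> list[str]:
    """Label each object "condensate" iff it is both large and round
    (area ≥ area threshold AND circularity ≥ circularity threshold),
    otherwise "punctum"."""
    return [
        "condensate"
        if (o.area_um2 >= area_threshold_um2
            and o.circularity >= circularity_threshold)
        else "punctum"
        for o in objects
    ]
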