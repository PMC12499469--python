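"""Core containers shared by all analysis stages.

The pipeline operates on multi-channel fluorescence stacks of recruited
genomic loci: a *bait* protein enriched at a repeat locus forms
diffraction-limited puncta, and a *prey* protein co-recruited through a
protein-protein interaction forms colocalized puncta in a second channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass
class ImageStack:
    """Multi-channel intensity array with physical pixel sizes.

    ``data`` is either ``(C, Y, X)`` or ``(C, Z, Y, X)``; intensities are
    arbitrary units and must be non-negative.
    """

    data: np.ndarray
    pixel_size_xy: float  # µm per pixel
    pixel_size_z: float | None = None  # µm per plane, None for 2D
    channel_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"data must be (C,Y,X) or (C,Z,Y,X); got shape {self.data.shape}"
            )
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[0]))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    def channel(self, c: int) -> np.ndarray:
        """Return the 2D (or 3D) array of a single channel."""
        return self.data[c]

    def with_data(self, data: np.ndarray, *, drop_z: bool = False) -> "ImageStack":
        return replace(
            self,
            data=data,
            pixel_size_z=None if drop_z else self.pixel_size_z,
        )


@dataclass
class Spot:
    """A detected diffraction-limited punctum.

    Centroids are in µm (x, y) relative to the image origin; ``snr`` is
    populated by the SNR stage and is ``None`` until then.
    """

    cell_id: int
    channel: int
    centroid_um: tuple[float, float]
    peak_intensity: float
    area_um2: float
    centroid_px: tuple[float, float] = (np.nan, np.nan)  # (row, col), 0-based
    snr: float | None = None


@dataclass
class CellSpotSummary:
    cell_id: int
    n_spots: dict[int, int]  # channel -> count

    def has_spots(self, channel: int) -> bool:
        return self.n_spots.get(channel, 0) > 0
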