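"""Shared container types."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class BScan:
    """A single OCT B-scan.

    Rows index axial depth ``s`` (0 at the vitreous, increasing toward the
    choroid), columns index lateral position ``t`` (one A-scan per column).
    Intensities are floats nominally in [0, 1]. Physical calibration is
    optional; when present it is carried through resizing and into features.
    """

    pixels: np.ndarray
    axial_um_per_px: float | None = None
    lateral_um_per_px: float | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("BScan.pixels must be 2-D (rows=axial, cols=lateral)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "BScan":
        """Copy of this scan with new pixel data, metadata preserved."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))
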