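"""Channel selection, spatial normalization and adaptive Wiener denoising.

The screening pipeline expects every scan at a common working resolution of
480 rows x 1280 columns. Denoising uses the classic adaptive (local
mean/variance) Wiener filter: in flat regions the output collapses to the
local mean, near structure it preserves the original pixel, with the noise
floor estimated as the image-wide mean of the local variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import InvalidWindow, UnsupportedImage
from .types import BScan

#: Common working resolution (rows, cols) of the pipeline.
TARGET_SHAPE = (480, 1280)


@dataclass(frozen=True)
class WienerParams:
    """Adaptive Wiener smoothing window. Both extents must be odd and >= 3."""

    window_rows: int = 5
    window_cols: int = 5

    def validate(self) -> None:
        for w in (self.window_rows, self.window_cols):
            if w < 3 or w % 2 == 0:
                raise InvalidWindow(f"window extents must be odd and >= 3, got {self}")


def to_gray(image: np.ndarray, *, channel_rule: str = "max_sum") -> BScan:
    """Collapse a raster image to a single-channel scan in [0, 1].

    RGB inputs keep only the channel contributing the most intensity
    (``max_sum``; ties break toward the lowest channel index). A
    ``max_variance`` rule is available as an alternative reading of
    "highest contributing channel".
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise UnsupportedImage("empty image")
    if arr.ndim == 2:
        chan = arr
    elif arr.ndim == 3 and arr.shape[2] in (1, 3):
        if arr.shape[2] == 1:
            chan = arr[:, :, 0]
        else:
            flat = arr.reshape(-1, arr.shape[2]).astype(np.float64)
            if channel_rule == "max_variance":
                score = flat.var(axis=0)
            else:
                score = flat.sum(axis=0)
            chan = arr[:, :, int(np.argmax(score))]  # argmax: lowest index wins ties
    else:
        raise UnsupportedImage(f"expected 1 or 3 channels, got shape {arr.shape}")

    chan = np.asarray(chan, dtype=np.float64)
    if np.issubdtype(arr.dtype, np.integer):
        chan = chan / np.iinfo(arr.dtype).max
    elif chan.size and chan.max() > 1.0:
        chan = chan / chan.max()
    return BScan(pixels=np.clip(chan, 0.0, 1.0))


def normalize_size(scan: BScan, target_shape: tuple[int, int] = TARGET_SHAPE) -> BScan:
    """Bilinearly resample a scan to the common working resolution.

    Calibration is rescaled by the same factors: halving the pixel count in a
    direction doubles the physical extent each remaining pixel covers.
    """
    rows, cols = scan.shape
    trows, tcols = target_shape
    if (rows, cols) == (trows, tcols):
        return scan.with_pixels(scan.pixels.copy())
    out = resize(scan.pixels, (trows, tcols), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    axial = scan.axial_um_per_px
    lateral = scan.lateral_um_per_px
    if axial is not None:
        axial = axial * rows / trows
    if lateral is not None:
        lateral = lateral * cols / tcols
    return BScan(pixels=out, axial_um_per_px=axial, lateral_um_per_px=lateral,
                 source_id=scan.source_id)


def wiener_denoise(scan: BScan, params: WienerParams | None = None,
                   noise_variance: float | None = None) -> BScan:
    """Adaptive Wiener filter with reflective border handling.

    Per pixel: ``out = m + (v - nv)/v * (x - m)`` where ``m`` and ``v`` are
    the local window mean and variance and ``nv`` is the noise variance
    (image-wide mean of ``v`` unless supplied). Wherever ``v <= nv`` the
    output is the local mean, which also covers the ``v = 0`` case.
    """
    params = params or WienerParams()
    params.validate()
    size = (params.window_rows, params.window_cols)
    x = scan.pixels
    m = ndimage.uniform_filter(x, size=size, mode="reflect")
    m2 = ndimage.uniform_filter(x * x, size=size, mode="reflect")
    v = np.maximum(m2 - m * m, 0.0)
    nv = float(v.mean()) if noise_variance is None else float(noise_variance)
    gain = np.where(v > nv, (v - np.minimum(v, nv)) / np.where(v > 0, v, 1.0), 0.0)
    out = m + gain * (x - m)
    return scan.with_pixels(out)
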