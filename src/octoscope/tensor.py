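"""Second-order structure tensor, coherency, and the derived binary/edge maps.

The structure tensor at each pixel is the Gaussian-smoothed outer product of
the intensity gradient with itself:

    J = G_sigma * [ dS*dS  dS*dT ]
                  [ dS*dT  dT*dT ]

Its eigenvalues (l1 >= l2 >= 0) describe local orientation energy; the
coherency  H = ((l1 - l2) / (l1 + l2))**2  is 1 for perfectly oriented
(layered) structure and 0 for isotropic texture, with the 0/0 case mapped
to 0 by convention. Retinal layers are strongly oriented and bright, so a
coherency-weighted gradient-magnitude image highlights the retinal band;
Otsu thresholding then yields the tissue map and Canny the layer edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature

from .errors import InvalidSigma
from .types import BScan


@dataclass
class TensorField:
    """Per-pixel smoothed gradient products, eigenvalues and coherency."""

    gamma_ss: np.ndarray
    gamma_st: np.ndarray
    gamma_tt: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    coherency: np.ndarray
    smoothing_sigma: float

    @property
    def gamma_ts(self) -> np.ndarray:
        # symmetric tensor: the off-diagonal channels coincide
        return self.gamma_st


def gradients(scan: BScan | np.ndarray, operator: str = "sobel") -> tuple[np.ndarray, np.ndarray]:
    """Axial (dS, along rows) and lateral (dT, along columns) derivatives."""
    img = scan.pixels if isinstance(scan, BScan) else np.asarray(scan, dtype=np.float64)
    if operator == "sobel":
        ds = ndimage.sobel(img, axis=0, mode="reflect")
        dt = ndimage.sobel(img, axis=1, mode="reflect")
    elif operator == "central":
        ds = np.gradient(img, axis=0)
        dt = np.gradient(img, axis=1)
    else:
        raise ValueError(f"unknown gradient operator {operator!r}")
    return ds, dt


def eigenvalues_2x2(gss: np.ndarray, gst: np.ndarray, gtt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigenvalues of the symmetric 2x2 tensor, l1 >= l2.

    For a positive semidefinite tensor both eigenvalues are nonnegative; l2
    is clipped at 0 to absorb floating-point round-off.
    """
    half_tr = 0.5 * (gss + gtt)
    disc = np.sqrt(np.maximum((0.5 * (gss - gtt)) ** 2 + gst**2, 0.0))
    l1 = half_tr + disc
    l2 = np.maximum(half_tr - disc, 0.0)
    return l1, l2


def coherency_map(l1: np.ndarray, l2: np.ndarray) -> np.ndarray:
    """Squared normalized eigenvalue anisotropy, in [0, 1]; 0/0 -> 0."""
    tr = l1 + l2
    h = np.where(tr > 0, ((l1 - l2) / np.where(tr > 0, tr, 1.0)) ** 2, 0.0)
    return np.clip(h, 0.0, 1.0)


def structure_tensor(ds: np.ndarray, dt: np.ndarray, sigma: float = 2.0) -> TensorField:
    """Smooth the gradient products with a Gaussian window and decompose."""
    if sigma <= 0:
        raise InvalidSigma(f"sigma must be positive, got {sigma}")
    ds = np.asarray(ds, dtype=np.float64)
    dt = np.asarray(dt, dtype=np.float64)
    if ds.shape != dt.shape:
        raise ValueError("gradient grids must share a shape")
    smooth = lambda a: ndimage.gaussian_filter(a, sigma=sigma, truncate=3.0, mode="reflect")
    gss = smooth(ds * ds)
    gst = smooth(ds * dt)
    gtt = smooth(dt * dt)
    l1, l2 = eigenvalues_2x2(gss, gst, gtt)
    return TensorField(gamma_ss=gss, gamma_st=gst, gamma_tt=gtt,
                       lambda1=l1, lambda2=l2,
                       coherency=coherency_map(l1, l2), smoothing_sigma=float(sigma))


def coherent_image(field: TensorField, mode: str = "amplitude") -> np.ndarray:
    """Scalar image highlighting oriented, high-energy (layered) structure.

    ``amplitude`` (default): sqrt(H * (l1 + l2)), a coherency-weighted
    gradient magnitude. The square root compresses the dynamic range of the
    squared-gradient energy so that weakly and strongly contrasted layer
    interfaces land in the same Otsu class (tissue) instead of being split
    apart. ``energy`` keeps the raw H * (l1 + l2); ``gamma_ss`` exposes the
    axial channel alone. All modes are rescaled to [0, 1].
    """
    if mode == "amplitude":
        ic = np.sqrt(np.maximum(field.coherency * (field.lambda1 + field.lambda2), 0.0))
    elif mode == "energy":
        ic = field.coherency * (field.lambda1 + field.lambda2)
    elif mode == "gamma_ss":
        ic = np.maximum(field.gamma_ss, 0.0)
    else:
        raise ValueError(f"unknown coherent image mode {mode!r}")
    peak = ic.max()
    return ic / peak if peak > 0 else np.zeros_like(ic)


def otsu_threshold(img: np.ndarray, nbins: int = 256) -> float | None:
    """Between-class-variance-maximizing threshold on an [0, 1] histogram.

    Evaluates every candidate split of a ``nbins``-bin histogram; ties break
    toward the lowest threshold. Returns None (with a warning) for a
    constant image, where no split exists.
    """
    img = np.asarray(img, dtype=np.float64)
    hist, edges = np.histogram(np.clip(img, 0.0, 1.0), bins=nbins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = hist.astype(np.float64)
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1]            # mass at or below candidate bin k
    w1 = total - w0
    s0 = np.cumsum(hist * centers)[:-1]
    s_total = (hist * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        warnings.warn("constant image: no Otsu threshold exists, returning empty foreground",
                      stacklevel=2)
        return None
    mu0 = np.where(valid, s0 / np.where(w0 > 0, w0, 1.0), 0.0)
    mu1 = np.where(valid, (s_total - s0) / np.where(w1 > 0, w1, 1.0), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -1.0)
    k = int(np.argmax(sigma_b))          # first max -> lowest threshold
    return float(centers[k])


def binarize_otsu(img: np.ndarray) -> np.ndarray:
    """Foreground map of an [0, 1] image: pixels strictly above the Otsu threshold."""
    t = otsu_threshold(img)
    if t is None:
        return np.zeros(np.asarray(img).shape, dtype=bool)
    return np.asarray(img) > t


def canny_edges(binmap: np.ndarray, sigma: float = 1.0,
                high_threshold: float = 0.5, low_ratio: float = 0.4) -> np.ndarray:
    """Canny edges of a binary map: 1-px curves bordering foreground regions.

    On an already-binary input any positive threshold pair works; fixed
    defaults keep the result deterministic.
    """
    img = np.asarray(binmap, dtype=np.float64)
    return feature.canny(img, sigma=sigma,
                         low_threshold=low_ratio * high_threshold,
                         high_threshold=high_threshold)
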