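"""Synthetic OCT B-scan phantoms with known ground truth.

Each phantom renders a curved, bright retinal band on a dark background:
a striated neurosensory band (thin constant-intensity sublayers emulating
the real intraretinal layering), a hyper-reflective RPE stripe near its
base, and a striated outer band down to the choroid boundary. Pathology is
label-specific:

    RE    - several hypo-reflective elliptical intraretinal cysts;
    CSCR  - one dome-shaped serous detachment lifting the neurosensory
            retina off the RPE;
    ARMD  - dome-shaped RPE elevations (drusen) with hypo-reflective
            sub-RPE deposit beneath each dome.

Noise is multiplicative unit-mean Gamma speckle followed by additive
Gaussian sensor noise; a global rotation (bilinear, background-filled) is
applied last. The striation is essential rather than cosmetic: a perfectly
homogeneous band has zero gradient energy, so coherency-based segmentation
would see its interior as background; layered texture is precisely what the
structure tensor keys on in clinical scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidPhantomSpec
from .types import BScan

LABELS = ("healthy", "RE", "CSCR", "ARMD")

BACKGROUND = 0.05
NEURO_PALETTE = (0.60, 0.36, 0.58, 0.34)   # cycling sublayer intensities
OUTER_PALETTE = (0.62, 0.34)
SUBLAYER_PX = 6                            # sublayer thickness, px
RPE_VALUE = 0.92
RPE_STRIPE_PX = 4
CYST_VALUE = 0.12
FLUID_VALUE = 0.10
DEPOSIT_VALUE = 0.14
#: fraction of the retinal band above the RPE stripe (neurosensory retina)
NEURO_FRACTION = 0.78

#: default physical calibration carried on generated scans (um per pixel)
DEFAULT_AXIAL_UM = 3.5
DEFAULT_LATERAL_UM = 11.0


@dataclass
class PhantomSpec:
    """Geometry, pathology, and noise parameters of one synthetic B-scan."""

    label: str = "healthy"
    image_shape: tuple[int, int] = (480, 1280)
    retina_top_depth: float = 120.0
    retina_thickness: float = 130.0
    bow_px: float = 18.0            # quadratic curvature amplitude
    wobble_px: float = 3.0          # sinusoidal perturbation amplitude
    wobble_cycles: float = 1.5
    n_cysts: int = 10               # RE only
    cyst_radius_range: tuple[float, float] = (12.0, 22.0)   # axial semi-axis
    cyst_aspect_range: tuple[float, float] = (1.6, 2.4)     # lateral/axial
    detachment_height: float = 50.0                         # CSCR only
    detachment_halfwidth: float = 115.0
    n_drusen: int = 5                                       # ARMD only
    drusen_height_range: tuple[float, float] = (18.0, 35.0)
    drusen_halfwidth_range: tuple[float, float] = (30.0, 60.0)
    speckle_scale: float = 0.5      # 0 disables all noise
    speckle_shape: float = 4.0      # Gamma shape k of the unit-mean field
    additive_sigma: float = 0.015
    rotation_deg: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.image_shape
        if self.label not in LABELS:
            raise InvalidPhantomSpec(f"unknown label {self.label!r}")
        if rows < 32 or cols < 32:
            raise InvalidPhantomSpec("image too small")
        if self.retina_top_depth + self.retina_thickness >= rows:
            raise InvalidPhantomSpec("retina does not fit in the image")
        nonneg = (self.retina_top_depth, self.retina_thickness, self.n_cysts,
                  self.detachment_height, self.n_drusen, self.speckle_scale,
                  self.additive_sigma, *self.cyst_radius_range,
                  *self.drusen_height_range)
        if any(v < 0 for v in nonneg):
            raise InvalidPhantomSpec("counts, radii and heights must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground truth of one phantom (pre-rotation geometry)."""

    ilm: np.ndarray
    rpe: np.ndarray
    choroid: np.ndarray
    cyst_mask: np.ndarray
    drusen_apices: list
    label: str
    spec: PhantomSpec = None
    inner: dict = field(default_factory=dict)


def _dome(t: np.ndarray, center: float, halfwidth: float, height: float) -> np.ndarray:
    """Parabolic cap profile: height at the center, 0 beyond +/- halfwidth."""
    return height * np.clip(1.0 - ((t - center) / halfwidth) ** 2, 0.0, None)


def make_phantom(spec: PhantomSpec) -> tuple[BScan, PhantomTruth]:
    """Render one synthetic B-scan and its ground truth, deterministically."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    t = np.arange(cols, dtype=np.float64)
    x = (t - (cols - 1) / 2) / ((cols - 1) / 2)

    phase = rng.uniform(0.0, 1.0)
    ilm0 = (spec.retina_top_depth + spec.bow_px * x**2
            + spec.wobble_px * np.sin(2 * np.pi * (spec.wobble_cycles * x + phase)))
    neuro_th = NEURO_FRACTION * spec.retina_thickness
    rpe0 = ilm0 + neuro_th                       # top of the RPE stripe
    choroid = ilm0 + spec.retina_thickness       # deepest tissue row

    detach = np.zeros(cols)
    elevation = np.zeros(cols)
    drusen_apices: list[tuple[int, float]] = []
    if spec.label == "CSCR":
        center = rng.uniform(0.35 * cols, 0.65 * cols)
        detach = _dome(t, center, spec.detachment_halfwidth, spec.detachment_height)
    elif spec.label == "ARMD":
        # one lateral slot per druse keeps the domes disjoint
        span_lo, span_hi = 0.05 * cols, 0.95 * cols
        slot = (span_hi - span_lo) / max(spec.n_drusen, 1)
        for i in range(spec.n_drusen):
            c = span_lo + (i + rng.uniform(0.35, 0.65)) * slot
            w = min(rng.uniform(*spec.drusen_halfwidth_range), 0.48 * slot)
            h = rng.uniform(*spec.drusen_height_range)
            elevation += _dome(t, c, w, h)
            drusen_apices.append((int(round(c)), float(h)))

    ilm = ilm0 - detach                  # CSCR lifts the neurosensory retina
    neuro_bottom = rpe0 - detach
    rpe_eff = rpe0 - elevation           # ARMD elevates the RPE stripe

    R = np.arange(rows, dtype=np.float64)[:, None]
    img = np.full((rows, cols), BACKGROUND)

    # striated neurosensory band (sublayers follow the ILM curvature)
    in_neuro = (R >= ilm) & (R < neuro_bottom)
    rel = np.clip(R - ilm, 0.0, None)
    pal = np.asarray(NEURO_PALETTE)
    idx = (rel // SUBLAYER_PX).astype(int) % pal.size
    img = np.where(in_neuro, pal[idx], img)

    # striated outer band between the RPE stripe and the choroid boundary
    in_outer = (R >= rpe0 + RPE_STRIPE_PX) & (R <= choroid)
    opal = np.asarray(OUTER_PALETTE)
    oidx = (np.clip(R - rpe0 - RPE_STRIPE_PX, 0, None) // SUBLAYER_PX).astype(int) % opal.size
    img = np.where(in_outer, opal[oidx], img)

    cyst_mask = np.zeros((rows, cols), dtype=bool)
    if spec.label == "CSCR":
        fluid = (R >= neuro_bottom) & (R < rpe0) & (detach >= 1.0)
        img = np.where(fluid, FLUID_VALUE, img)
        cyst_mask |= fluid
    if spec.label == "ARMD":
        deposit = (R >= rpe_eff + RPE_STRIPE_PX) & (R < rpe0 + RPE_STRIPE_PX) \
            & (elevation >= 2.0)
        img = np.where(deposit, DEPOSIT_VALUE, img)
        cyst_mask |= deposit

    # hyper-reflective RPE stripe (drawn after the deposit so it stays on top)
    in_stripe = (R >= rpe_eff) & (R < rpe_eff + RPE_STRIPE_PX)
    img = np.where(in_stripe, RPE_VALUE, img)

    if spec.label == "RE" and spec.n_cysts:
        # one lateral slot per cyst guarantees disjoint components
        span_lo, span_hi = 0.05 * cols, 0.95 * cols
        slot = (span_hi - span_lo) / spec.n_cysts
        C = t[None, :]
        for i in range(spec.n_cysts):
            cx = span_lo + (i + rng.uniform(0.35, 0.65)) * slot
            a = rng.uniform(*spec.cyst_radius_range)
            b = min(a * rng.uniform(*spec.cyst_aspect_range), 0.45 * slot)
            j = int(round(cx))
            lo = ilm0[j] + a + 6
            hi = rpe0[j] - a - 6
            if hi <= lo:   # band too thin for this cyst; shrink to fit
                a = max(4.0, (rpe0[j] - ilm0[j] - 14) / 2)
                b = min(a * spec.cyst_aspect_range[0], 0.45 * slot)
                lo, hi = ilm0[j] + a + 6, rpe0[j] - a - 6
            cy = rng.uniform(lo, max(hi, lo + 1e-6))
            ell = ((R - cy) / a) ** 2 + ((C - cx) / b) ** 2 <= 1.0
            cyst_mask |= ell
        img = np.where(cyst_mask, CYST_VALUE, img)

    if spec.speckle_scale > 0:
        k = spec.speckle_shape
        field_g = rng.gamma(k, 1.0 / k, size=img.shape)
        img = img * (1.0 + spec.speckle_scale * (field_g - 1.0))
        if spec.additive_sigma > 0:
            img = img + rng.normal(0.0, spec.additive_sigma, size=img.shape)
        img = np.clip(img, 0.0, 1.0)

    if spec.rotation_deg:
        # edge replication emulates adjacent tissue entering the rotated
        # field of view; a flat background fill would clip the band at the
        # lateral extremes, which no skewed acquisition actually does
        img = ndimage.rotate(img, spec.rotation_deg, reshape=False, order=1,
                             mode="nearest")
        img = np.clip(img, 0.0, 1.0)

    scan = BScan(pixels=img, axial_um_per_px=DEFAULT_AXIAL_UM,
                 lateral_um_per_px=DEFAULT_LATERAL_UM,
                 source_id=f"phantom-{spec.label}-{spec.seed}")
    # the RPE truth marks the stripe's brightest locus (its center row),
    # which is what an intensity-argmax tracer estimates
    rpe_truth = rpe_eff + (RPE_STRIPE_PX - 1) / 2
    truth = PhantomTruth(ilm=ilm, rpe=rpe_truth, choroid=choroid,
                         cyst_mask=cyst_mask, drusen_apices=drusen_apices,
                         label=spec.label, spec=spec)
    _check_truth(truth, rows)
    return scan, truth


def _check_truth(truth: PhantomTruth, rows: int) -> None:
    if not (np.all(truth.ilm < truth.rpe) and np.all(truth.rpe < truth.choroid)):
        raise InvalidPhantomSpec("ground-truth boundary ordering violated")
    if truth.choroid.max() >= rows or truth.ilm.min() < 0:
        raise InvalidPhantomSpec("ground-truth boundaries leave the image")


def make_cohort(n_per_class: int, base_seed: int,
                **spec_overrides) -> list[tuple[BScan, PhantomTruth]]:
    """Balanced cohort of 4*n_per_class phantoms with jittered geometry.

    Per-scan parameters are drawn from seeded, class-conditional ranges so
    that every cohort reproduces the qualitative clinical structure: edema
    and serous scans are thickened and fluid-laden, drusen scans match
    healthy thickness but carry RPE deformity. ``spec_overrides`` are
    applied to every spec after jittering (e.g. ``speckle_scale=0``).
    """
    if n_per_class < 1:
        raise InvalidPhantomSpec("n_per_class must be >= 1")
    rng = np.random.default_rng(base_seed)
    cohort = []
    for label in LABELS:
        for _ in range(n_per_class):
            common = dict(
                label=label,
                retina_top_depth=rng.uniform(100, 150),
                bow_px=rng.uniform(10, 24),
                wobble_px=rng.uniform(2, 4),
                wobble_cycles=rng.uniform(1.0, 2.5),
                seed=int(rng.integers(2**31)),
            )
            if label == "RE":
                common["retina_thickness"] = rng.uniform(175, 230)
                common["n_cysts"] = int(rng.integers(8, 13))
            elif label == "CSCR":
                common["retina_thickness"] = rng.uniform(115, 150)
                common["detachment_height"] = rng.uniform(40, 60)
                common["detachment_halfwidth"] = rng.uniform(95, 140)
            elif label == "ARMD":
                common["retina_thickness"] = rng.uniform(115, 150)
                common["n_drusen"] = int(rng.integers(4, 8))
            else:
                common["retina_thickness"] = rng.uniform(115, 150)
            spec = replace(PhantomSpec(), **{**common, **spec_overrides})
            cohort.append(make_phantom(spec))
    return cohort
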