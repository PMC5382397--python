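"""Pathology quantification and the 9-feature descriptor.

The nine scalars summarize a B-scan for classification:

    f1, f2, f3 - max, min and spread of the retinal thickness profile;
    f4         - total cyst / serous fluid area inside the retinal mask;
    f5         - cyst energy: summed squared level-2 approximation
                 coefficients of a 2-D Haar decomposition of the cyst mask;
    f6, f7, f8 - max, min and spread of the RPE elevation profile
                 (deviation of the traced RPE from a quadratic baseline,
                 positive toward the ILM, i.e. a drusen bump);
    f9         - summed squared RPE elevation.

Fluid diseases (retinal edema, central serous chorioretinopathy) separate
on thickness and cyst terms; drusen-driven degeneration (ARMD) separates on
the RPE terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from skimage import morphology

from .errors import SegmentationFailure
from .layers import LayerSet, ThicknessProfile

FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 10))


@dataclass
class CystSegmentation:
    retina_mask: np.ndarray
    cyst_mask: np.ndarray
    area: float
    column_profile: np.ndarray
    area_unit: str = "px^2"


@dataclass
class RPEProfile:
    deviation: np.ndarray
    baseline_coeffs: np.ndarray
    unit: str = "px"


@dataclass
class FeatureVector:
    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    f7: float
    f8: float
    f9: float
    units: dict = field(default_factory=dict)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64)

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in FEATURE_NAMES}


def cyst_segmentation(layerset: LayerSet, binmap: np.ndarray,
                      min_size: int = 25, fill_holes_px: int = 256,
                      fusion: str = "masked_complement",
                      lateral_um_per_px: float | None = None) -> CystSegmentation:
    """Fuse the retinal mask with the tissue map to isolate fluid pockets.

    The retinal mask R_M covers pixels strictly between the ILM and choroid
    traces. Cysts are hypo-reflective, so they appear as background inside
    R_M: the default fusion keeps ``R_M AND NOT binmap`` (holes smaller than
    ``fill_holes_px`` in the tissue map are treated as speckle and filled
    first); ``fusion='xor'`` keeps the literal exclusive-or. Components
    smaller than ``min_size`` pixels are dropped as noise.
    """
    if layerset.valid is not None and not layerset.valid.any():
        raise SegmentationFailure("layer set has no valid columns")
    binmap = np.asarray(binmap, dtype=bool)
    nrows = binmap.shape[0]
    rows = np.arange(nrows)[:, None]
    retina = (rows > layerset.ilm[None, :]) & (rows < layerset.choroid[None, :])
    tissue = binmap
    if fill_holes_px:
        # fill holes strictly smaller than fill_holes_px (max_size is inclusive)
        tissue = morphology.remove_small_holes(tissue, max_size=fill_holes_px - 1)
    if fusion == "masked_complement":
        cyst = retina & ~tissue
    elif fusion == "xor":
        cyst = retina ^ tissue
    else:
        raise ValueError(f"unknown fusion {fusion!r}")
    if min_size:
        # drop components strictly smaller than min_size (max_size is inclusive)
        cyst = morphology.remove_small_objects(cyst, max_size=min_size - 1)
    area = float(cyst.sum())
    unit = "px^2"
    if layerset.axial_um_per_px is not None and lateral_um_per_px is not None:
        area *= layerset.axial_um_per_px * lateral_um_per_px * 1e-6
        unit = "mm^2"
    return CystSegmentation(retina_mask=retina, cyst_mask=cyst, area=area,
                            column_profile=cyst.sum(axis=0), area_unit=unit)


def rpe_profile(layerset: LayerSet) -> RPEProfile:
    """RPE elevation relative to a least-squares quadratic baseline.

    A healthy RPE follows the smooth curvature of the eye, which an order-2
    polynomial absorbs; drusen appear as localized positive deviations
    (the trace sits above the baseline, i.e. at smaller depth). Least
    squares makes the deviation mean-zero by construction.
    """
    t = np.arange(layerset.n_cols, dtype=np.float64)
    coeffs = np.polyfit(t, layerset.rpe, deg=2)
    baseline = np.polyval(coeffs, t)
    deviation = baseline - layerset.rpe
    unit = "px"
    if layerset.axial_um_per_px is not None:
        deviation = deviation * layerset.axial_um_per_px
        unit = "um"
    return RPEProfile(deviation=deviation, baseline_coeffs=coeffs, unit=unit)


def cyst_energy(seg: CystSegmentation | np.ndarray, wavelet: str = "haar",
                levels: int = 2) -> float:
    """Low-band wavelet energy of the cyst mask.

    The binary mask is decomposed ``levels`` times and the energy of the
    final approximation band is returned; an empty mask has zero energy.
    For solid regions this tracks total area, while fragmented masks lose
    energy to the detail bands - which is what separates a single serous
    detachment from scattered edema cysts of similar total area.
    """
    mask = seg.cyst_mask if isinstance(seg, CystSegmentation) else np.asarray(seg)
    mask = mask.astype(np.float64)
    if not mask.any():
        return 0.0
    coeffs = pywt.wavedec2(mask, wavelet, level=levels)
    return float((coeffs[0] ** 2).sum())


def feature_vector(thickness: ThicknessProfile, seg: CystSegmentation,
                   rpe: RPEProfile) -> FeatureVector:
    """Fuse the three per-scan profiles into the 9-feature descriptor."""
    rt = np.asarray(thickness.rt, dtype=np.float64)
    dev = np.asarray(rpe.deviation, dtype=np.float64)
    f1 = float(rt.max())
    f2 = float(rt.min())
    f4 = float(seg.area)
    f5 = cyst_energy(seg)
    f6 = float(dev.max())
    f7 = float(dev.min())
    return FeatureVector(
        f1=f1, f2=f2, f3=abs(f1 - f2), f4=f4, f5=f5,
        f6=f6, f7=f7, f8=abs(f6 - f7), f9=float((dev**2).sum()),
        units={"thickness": thickness.unit, "area": seg.area_unit, "rpe": rpe.unit},
    )


def feature_table(vectors: list[FeatureVector], labels: list[str]) -> pd.DataFrame:
    """Tidy per-scan feature table: one row per scan, columns f1..f9 + label."""
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must align")
    if not vectors:
        raise ValueError("need at least one feature vector")
    rows = [dict(fv.to_dict(), label=lab) for fv, lab in zip(vectors, labels)]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["label"])


def class_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class mean and sample SD (n-1 denominator) of each feature.

    Single-member classes have no sample SD; it is reported as 0 with the
    ``sd_degenerate`` flag set.
    """
    out = []
    for label, grp in table.groupby("label", sort=False):
        vals = grp[list(FEATURE_NAMES)]
        n = len(grp)
        mean_row = {"label": label, "stat": "mean", "n": n, "sd_degenerate": False}
        mean_row.update(vals.mean().to_dict())
        sd_row = {"label": label, "stat": "sd", "n": n, "sd_degenerate": n < 2}
        sd = vals.std(ddof=1) if n > 1 else vals.iloc[0] * 0.0
        sd_row.update(sd.to_dict())
        out.extend([mean_row, sd_row])
    cols = ["label", "stat", "n", "sd_degenerate"] + list(FEATURE_NAMES)
    return pd.DataFrame(out)[cols]
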