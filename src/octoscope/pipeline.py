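"""End-to-end orchestration: image -> features -> diagnosis."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cascade as _cascade
from . import features as _features
from . import layers as _layers
from . import preprocess as _pre
from . import tensor as _tensor
from .config import PipelineConfig
from .errors import OctoscopeError, SegmentationFailure
from .types import BScan


def preprocess_scan(image, config: PipelineConfig | None = None) -> BScan:
    """Channel selection, size normalization, Wiener denoising."""
    config = config or PipelineConfig()
    scan = image if isinstance(image, BScan) else _pre.to_gray(image)
    if config.axial_um_per_px is not None:
        scan.axial_um_per_px = config.axial_um_per_px
    if config.lateral_um_per_px is not None:
        scan.lateral_um_per_px = config.lateral_um_per_px
    scan = _pre.normalize_size(scan)
    wr, wc = config.wiener_window
    return _pre.wiener_denoise(scan, _pre.WienerParams(wr, wc))


def segment_scan(denoised: BScan, config: PipelineConfig | None = None) -> dict:
    """Structure-tensor segmentation stages of one denoised scan.

    Returns the intermediate artifacts keyed ``field``, ``coherent``,
    ``binmap``, ``edges`` and ``layers``.
    """
    config = config or PipelineConfig()
    ds, dt = _tensor.gradients(denoised, operator=config.gradient_operator)
    field = _tensor.structure_tensor(ds, dt, sigma=config.tensor_sigma)
    coherent = _tensor.coherent_image(field, mode=config.coherent_mode)
    binmap = _tensor.binarize_otsu(coherent)
    edges = _tensor.canny_edges(binmap, sigma=config.canny_sigma,
                                high_threshold=config.canny_high,
                                low_ratio=config.canny_low_ratio)
    layerset = _layers.trace_boundaries(edges, binmap, denoised,
                                        median_width=config.median_width,
                                        refine_window=config.refine_window)
    return {"field": field, "coherent": coherent, "binmap": binmap,
            "edges": edges, "layers": layerset}


def extract_features(image, config: PipelineConfig | None = None
                     ) -> tuple[_features.FeatureVector, dict]:
    """Run the full feature pipeline on an image or BScan."""
    config = config or PipelineConfig()
    denoised = preprocess_scan(image, config)
    arts = segment_scan(denoised, config)
    layerset = arts["layers"]
    thickness = _layers.thickness_profile(layerset)
    seg = _features.cyst_segmentation(layerset, arts["binmap"],
                                      min_size=config.min_cyst_px,
                                      fill_holes_px=config.fill_holes_px,
                                      fusion=config.cyst_fusion,
                                      lateral_um_per_px=denoised.lateral_um_per_px)
    rpe = _features.rpe_profile(layerset)
    fv = _features.feature_vector(thickness, seg, rpe)
    arts.update({"denoised": denoised, "thickness": thickness,
                 "cyst": seg, "rpe_profile": rpe})
    return fv, arts


def cohort_feature_table(scans, labels=None,
                         config: PipelineConfig | None = None) -> pd.DataFrame:
    """Feature table for a list of scans (f1..f9 [+ label])."""
    vectors = [extract_features(s, config)[0] for s in scans]
    if labels is None:
        labels = [""] * len(vectors)
    return _features.feature_table(vectors, list(labels))


def diagnose(image, model: _cascade.TrainedCascade,
             config: PipelineConfig | None = None, source: str = "") -> dict:
    """Classify one scan; returns a JSON-serializable report.

    A segmentation failure yields label ``undetermined`` with an ``error``
    field instead of raising, so batch screening can continue.
    """
    report: dict = {"source": source, "label": "undetermined",
                    "features": None, "stages": None, "error": None}
    try:
        fv, _ = extract_features(image, config)
        row = pd.Series(fv.to_dict())
        s1 = model._route1(row)
        stages = {"stage1": str(s1)}
        if s1 == "healthy":
            label = "healthy"
        else:
            s2 = model._route2(row)
            stages["stage2"] = str(s2)
            if s2 == "ARMD":
                label = "ARMD"
            else:
                label = model._route3(row)
                stages["stage3"] = str(label)
        report.update({"label": str(label), "features": fv.to_dict(),
                       "stages": stages})
    except SegmentationFailure as exc:
        report["error"] = str(exc)
    except OctoscopeError as exc:
        report["error"] = str(exc)
    return report
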