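"""Pipeline configuration with lossless JSON round-tripping."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .cascade import CascadeConfig


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, serializable as JSON."""

    wiener_window: tuple[int, int] = (5, 5)
    gradient_operator: str = "sobel"
    tensor_sigma: float = 2.0
    coherent_mode: str = "amplitude"
    canny_sigma: float = 1.0
    canny_high: float = 0.5
    canny_low_ratio: float = 0.4
    median_width: int = 15
    refine_window: int = 6
    min_cyst_px: int = 25
    fill_holes_px: int = 256
    cyst_fusion: str = "masked_complement"
    wavelet: str = "haar"
    wavelet_levels: int = 2
    axial_um_per_px: float | None = None
    lateral_um_per_px: float | None = None
    cascade: CascadeConfig = field(default_factory=CascadeConfig)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cascade"]["stage_features"] = {
            str(k): list(v) for k, v in d["cascade"]["stage_features"].items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        casc = data.pop("cascade", None)
        cfg = {}
        for key, val in data.items():
            if key == "wiener_window":
                val = tuple(val)
            cfg[key] = val
        if casc is not None:
            casc_known = {f.name for f in dataclasses.fields(CascadeConfig)}
            casc_unknown = set(casc) - casc_known
            if casc_unknown:
                raise ValueError(f"unknown cascade config keys: {sorted(casc_unknown)}")
            casc["stage_features"] = {int(k): tuple(v)
                                      for k, v in casc.get("stage_features", {}).items()}
            for grid in ("c_grid", "gamma_grid"):
                if grid in casc:
                    casc[grid] = tuple(casc[grid])
            cfg["cascade"] = CascadeConfig(**casc)
        return cls(**cfg)
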