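"""Strict pipeline configuration (YAML-backed, unknown keys rejected).

Silent misconfiguration is the dominant failure mode of multi-stage
pipelines, so every model forbids extra keys: a typo in a YAML file raises
a validation error naming the offending key instead of being ignored.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "PhantomConfig",
    "ReconConfig",
    "EnfaceConfig",
    "TractConfig",
    "CoregConfig",
    "RoiStatsConfig",
    "PipelineConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    """Synthetic specimen series: geometry, optics, noise, diffusion grid."""

    nx: int = 260
    ny: int = 260
    nz: int = 160
    lateral_pixel_um: float = 30.0
    axial_pixel_um: float = 4.2
    wavelength_um: float = 1.3
    noise_sd: float = 1e-3
    n_ages: int = 5
    dmri_grid_spacing_mm: float = 0.8
    tile_px: int = 150
    overlap_frac: float = 0.2


class ReconConfig(_Strict):
    tail_truncate_px: int = 0
    snr_floor: Optional[float] = None  # None: 3 * noise_sd when known


class EnfaceConfig(_Strict):
    bin_deg: float = 5.0
    depth_range: tuple[int, int] = (0, 80)


class TractConfig(_Strict):
    retardance_threshold: Optional[float] = None  # None: Otsu heuristic
    max_angle_deg: float = 45.0
    step_px: float = 0.5
    seed_spacing_px: int = 5
    min_len_px: float = 10.0
    max_len_px: float = 1e4
    mode: Literal["nearest", "bilinear"] = "nearest"


class CoregConfig(_Strict):
    levels: int = 3
    mask_method: Literal["otsu", "threshold"] = "otsu"
    mask_value: Optional[float] = None
    min_inplane: float = 0.1


class RoiStatsConfig(_Strict):
    roi_size_um: float = 900.0
    n_rois: Optional[int] = None
    min_wm_frac: float = 0.8
    polar_bin_deg: float = 10.0
    sd_ddof: int = 0


class PipelineConfig(_Strict):
    """Top-level configuration for the simulate -> report pipeline."""

    out_dir: str = "psoctpipe_out"
    seed: int = 0
    log_level: str = "INFO"
    save_raw: bool = False
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    recon: ReconConfig = Field(default_factory=ReconConfig)
    enface: EnfaceConfig = Field(default_factory=EnfaceConfig)
    tract: TractConfig = Field(default_factory=TractConfig)
    coreg: CoregConfig = Field(default_factory=CoregConfig)
    roistats: RoiStatsConfig = Field(default_factory=RoiStatsConfig)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config (or defaults) with optional dotted-key overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a YAML mapping")
            data = loaded
    for key, value in overrides.items():
        parts = key.split(".")
        node = data
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return PipelineConfig.model_validate(data)
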