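"""Pipeline configuration with validated defaults.

Every stage's tunable lives here with its published default; unknown keys
are rejected on load so typos cannot silently disable a stage.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VideoConfig(_Strict):
    target_width: int = Field(320, gt=0)
    target_height: int = Field(240, gt=0)


class LandmarksConfig(_Strict):
    provider: str = "synthetic"  # synthetic | facemesh
    reference_frames: int = Field(15, gt=0)


class StabConfig(_Strict):
    enabled: bool = True
    alpha_slow: float = Field(0.05, gt=0, le=1)
    alpha_fast: float = Field(0.8, gt=0, le=1)
    theta_threshold: float = Field(0.05, gt=0)  # radians
    alpha_step: float = Field(0.15, gt=0)
    refine: bool = True  # Stage-2 optical-flow translational refinement


class RoiConfig(_Strict):
    cluster: bool = True
    k: int = Field(2, ge=2)
    reference_u: float = 30.0
    reference_v: float = 45.0


class EvmConfig(_Strict):
    enabled: bool = True
    alpha: float = Field(50.0, ge=0)
    level: int = Field(3, ge=1)
    band_low: float = Field(0.8, gt=0)
    band_high: float = Field(3.0, gt=0)


class EpisodeConfig(_Strict):
    length: float = Field(30.0, gt=0)
    overlap: float = Field(15.0, ge=0)


class CleanConfig(_Strict):
    z_thresh: float = Field(3.0, gt=0)
    ratio_thresh: float = Field(0.4, gt=0, le=1)
    tau: float = Field(4.0, gt=0)


class HarmConfig(_Strict):
    sigma: float = Field(0.1, gt=0)  # Hz
    alpha: float = Field(0.7, ge=0, le=1)
    half_energy_frac: float = Field(0.4, gt=0, le=1)


class SepConfig(_Strict):
    window_pca: bool = True
    stride: int = Field(3, gt=0)
    n_pcs: int = Field(2, gt=0)
    corr_thresh: float = Field(0.5, ge=0, le=1)
    max_global: int = Field(10, gt=0)
    sobi_lags: int = Field(20, gt=0)


class SelectConfig(_Strict):
    p_thresh: float = Field(0.35, ge=0, le=1)
    power_ratio_thresh: float = Field(0.75, ge=0, le=1)
    fallback: bool = True


class HrConfig(_Strict):
    n_fft: int = Field(8192, gt=0)
    postprocess: bool = True  # full separation/selection chain


class PipelineConfig(_Strict):
    video: VideoConfig = Field(default_factory=VideoConfig)
    landmarks: LandmarksConfig = Field(default_factory=LandmarksConfig)
    stab: StabConfig = Field(default_factory=StabConfig)
    roi: RoiConfig = Field(default_factory=RoiConfig)
    evm: EvmConfig = Field(default_factory=EvmConfig)
    episode: EpisodeConfig = Field(default_factory=EpisodeConfig)
    clean: CleanConfig = Field(default_factory=CleanConfig)
    harm: HarmConfig = Field(default_factory=HarmConfig)
    sep: SepConfig = Field(default_factory=SepConfig)
    select: SelectConfig = Field(default_factory=SelectConfig)
    hr: HrConfig = Field(default_factory=HrConfig)
    seed: int = 0

    @property
    def band(self) -> tuple[float, float]:
        return (self.evm.band_low, self.evm.band_high)


def load_config(path=None) -> PipelineConfig:
    """Load a YAML configuration; an empty or missing body keeps every
    published default.  Unknown keys raise a validation error."""
    if path is None:
        return PipelineConfig()
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
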