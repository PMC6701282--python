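"""Pipeline configuration: dataclasses with YAML load/save.

A single config object records every tunable of a run — nuisance
settings, band list, GLM thresholds, seeds — so an output directory can
always be traced back to the exact parameters that produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from falffpipe.synth import SyntheticCohortSpec


@dataclass
class NuisanceConfig:
    despike_enabled: bool = True
    despike_clip_k: float = 4.0
    gsr_enabled: bool = True
    acompcor_n_components: int = 5
    erode_iterations: int = 2
    smooth_fwhm_mm: float = 6.0


@dataclass
class BandConfig:
    name: str
    lo_hz: float
    hi_hz: float


DEFAULT_BANDS = (
    BandConfig("broadband", 0.01, 0.08),
    BandConfig("slow5", 0.01, 0.027),
    BandConfig("slow4", 0.027, 0.07),
)


@dataclass
class GlmConfig:
    p_form: float = 0.001
    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    connectivity: int = 18
    one_sided: bool = True
    covariates: tuple[str, ...] = ()


@dataclass
class StatsConfig:
    n_reshuffles: int = 10_000
    seed: int = 0


@dataclass
class PipelineConfig:
    data_dir: str = "data"
    output_dir: str = "output"
    cohort_csv: str = "cohort.csv"
    label_volume: str | None = None
    nuisance: NuisanceConfig = field(default_factory=NuisanceConfig)
    bands: tuple[BandConfig, ...] = DEFAULT_BANDS
    glm: GlmConfig = field(default_factory=GlmConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    synthetic: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    kwargs = dict(raw)
    if "nuisance" in kwargs:
        kwargs["nuisance"] = NuisanceConfig(**kwargs["nuisance"])
    if "bands" in kwargs:
        kwargs["bands"] = tuple(BandConfig(**b) for b in kwargs["bands"])
    if "glm" in kwargs:
        glm = dict(kwargs["glm"])
        if "covariates" in glm:
            glm["covariates"] = tuple(glm["covariates"])
        kwargs["glm"] = GlmConfig(**glm)
    if "stats" in kwargs:
        kwargs["stats"] = StatsConfig(**kwargs["stats"])
    if "synthetic" in kwargs:
        synth = dict(kwargs["synthetic"])
        for key in ("grid_shape", "lesion_radius_range"):
            if key in synth:
                synth[key] = tuple(synth[key])
        if synth.get("effect_center") is not None:
            synth["effect_center"] = tuple(synth["effect_center"])
        kwargs["synthetic"] = SyntheticCohortSpec(**synth)
    return PipelineConfig(**kwargs)
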