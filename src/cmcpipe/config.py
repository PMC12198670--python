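"""Pipeline configuration: a single YAML file drives the whole study.

Unknown keys are rejected at load time so that typos fail before any
computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .coherence import BandDefinition, WindowingConfig
from .preprocess import PreprocessConfig
from .surrogates import SurrogateConfig
from .synthetic import CohortDesign, CouplingSpec

__all__ = ["PipelineConfig", "load_config", "default_config"]


def _build(cls, data: dict, context: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class DirectionalityConfig:
    max_lag_ms: float = 128.0
    smooth_span_ms: float = 16.0


@dataclass(frozen=True)
class StatsConfig:
    n_perm: int = 5000
    terms: tuple[str, ...] = (
        "band", "task", "group", "band:task", "band:group", "task:group",
        "band:task:group",
    )
    muscle_sets: dict = field(
        default_factory=lambda: {"trunk": ["ExO", "ES"], "leg": ["TA", "GM"]}
    )
    pairwise_direction: str = "efferent"
    run_nmds: bool = True
    nmds_restarts: int = 8


@dataclass(frozen=True)
class WaveletConfig:
    scale: float = 12.0
    q: float = 1.45
    r: float = 1.959
    j_range: tuple[int, int] = (1, 30)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    output_dir: str = "cmcpipe_out"
    synthetic: CohortDesign | None = None
    input_dir: str | None = None
    input_format: str = "delimited"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    wavelets: WaveletConfig = field(default_factory=WaveletConfig)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    bands: dict = field(
        default_factory=lambda: {"alpha": (8.0, 12.0), "beta": (13.0, 30.0),
                                 "low_gamma": (30.0, 45.0), "high_gamma": (45.0, 63.0)}
    )
    analysis_bands: tuple[str, ...] = ("alpha", "beta")
    surrogates: SurrogateConfig = field(default_factory=SurrogateConfig)
    directionality: DirectionalityConfig = field(default_factory=DirectionalityConfig)
    psd_window_s: float = 2.0
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        if self.synthetic is None and self.input_dir is None:
            raise ValueError("config needs either a 'synthetic' or an 'input' section")
        for b in self.analysis_bands:
            if b not in self.bands:
                raise ValueError(f"analysis band {b!r} not defined in 'bands'")

    def band_definitions(self) -> dict[str, BandDefinition]:
        return {
            name: BandDefinition(name, float(lo), float(hi))
            for name, (lo, hi) in self.bands.items()
        }


def _parse_synthetic(data: dict) -> CohortDesign:
    data = dict(data)
    base = data.pop("base_spec", {})
    effects_raw = data.pop("band_effects", {}) or {}
    effects = {}
    for key, gain in effects_raw.items():
        parts = tuple(str(key).split("/")) if isinstance(key, str) else tuple(key)
        if len(parts) != 4:
            raise ValueError(
                "band_effects keys must be 'group/task/band/direction'"
            )
        effects[parts] = float(gain)
    for tup_key in ("groups", "tasks", "bands"):
        if tup_key in data:
            data[tup_key] = tuple(data[tup_key])
    return _build(
        CohortDesign,
        {
            **data,
            "band_effects": effects,
            "base_spec": _build(CouplingSpec, base, "synthetic.base_spec"),
        },
        "synthetic",
    )


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    kwargs: dict = {}
    if "synthetic" in raw:
        kwargs["synthetic"] = _parse_synthetic(raw.pop("synthetic") or {})
    if "input" in raw:
        inp = raw.pop("input") or {}
        unknown = set(inp) - {"dir", "format"}
        if unknown:
            raise ValueError(f"input: unknown key(s) {sorted(unknown)}")
        kwargs["input_dir"] = inp.get("dir")
        kwargs["input_format"] = inp.get("format", "delimited")
    section_types = {
        "preprocess": PreprocessConfig,
        "wavelets": WaveletConfig,
        "windowing": WindowingConfig,
        "surrogates": SurrogateConfig,
        "directionality": DirectionalityConfig,
        "stats": StatsConfig,
    }
    for name, cls in section_types.items():
        if name in raw:
            data = raw.pop(name) or {}
            if name == "wavelets" and "j_range" in data:
                data["j_range"] = tuple(data["j_range"])
            if name == "stats" and "terms" in data:
                data["terms"] = tuple(data["terms"])
            kwargs[name] = _build(cls, data, name)
    for scalar in ("seed", "output_dir", "psd_window_s"):
        if scalar in raw:
            kwargs[scalar] = raw.pop(scalar)
    if "bands" in raw:
        kwargs["bands"] = {k: tuple(v) for k, v in raw.pop("bands").items()}
    if "analysis_bands" in raw:
        kwargs["analysis_bands"] = tuple(raw.pop("analysis_bands"))
    if raw:
        raise ValueError(f"config: unknown section(s) {sorted(raw)}")
    return PipelineConfig(**kwargs)


def default_config(**overrides) -> PipelineConfig:
    """A small synthetic-cohort configuration suitable for a demo run."""
    synthetic = overrides.pop(
        "synthetic",
        CohortDesign(n_per_group=3, trials_per_task=2),
    )
    return PipelineConfig(synthetic=synthetic, **overrides)
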