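"""Pipeline configuration and seed fan-out.

A configuration file (YAML) mirrors the parameters of each stage; unknown
keys are rejected before anything runs. One global seed is split into
per-stage seeds by hashing the stage name (CRC-32) against the global seed,
so any stage can be rerun in isolation and still see its own stream.
"""
from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError, MibciError


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {context}: {unknown}")
    return cls(**data)


@dataclass
class ProtocolSection:
    repetitions: int = 10
    segment_s: float = 5.0
    rest_s: float = 10.0
    module: str = "MI"


@dataclass
class SynthesisSection:
    n_subjects: int = 10
    erd_depth: float = 0.6
    fs: float = 250.0
    rms_uv: float = 10.0
    osc_power: dict = field(default_factory=lambda: {"alpha": 2.0, "beta": 2.0})
    window_s: float = 0.5
    step_s: float = 0.008


@dataclass
class FeatureSection:
    window_rows: int = 384
    hop_rows: int = 64
    wavelet: str = "db4"
    level: int = 4


@dataclass
class ModelSection:
    kind: str = "wpt_nn"
    n_search_iter: int = 6
    hyperparams: dict = field(default_factory=dict)


@dataclass
class StreamSection:
    min_dwell_windows: int = 2


@dataclass
class AnalysisSection:
    edge_trim_s: float = 0.25
    bands: list = field(default_factory=lambda: ["alpha", "beta"])


@dataclass
class PipelineConfig:
    protocol: ProtocolSection = field(default_factory=ProtocolSection)
    synthesis: SynthesisSection = field(default_factory=SynthesisSection)
    feature: FeatureSection = field(default_factory=FeatureSection)
    model: ModelSection = field(default_factory=ModelSection)
    stream: StreamSection = field(default_factory=StreamSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)
    seed: int = 0

    _SECTIONS = {
        "protocol": ProtocolSection,
        "synthesis": SynthesisSection,
        "feature": FeatureSection,
        "model": ModelSection,
        "stream": StreamSection,
        "analysis": AnalysisSection,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        unknown = sorted(set(data) - set(cls._SECTIONS) - {"seed"})
        if unknown:
            raise ConfigurationError(f"unknown top-level config key(s): {unknown}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            raw = data.get(name, {})
            if not isinstance(raw, dict):
                raise ConfigurationError(f"config section {name!r} must be a mapping")
            kwargs[name] = _from_mapping(section_cls, raw, context=f"section {name!r}")
        cfg = cls(seed=int(data.get("seed", 0)), **kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        # cross-checks that the per-stage constructors cannot see
        from .features import WPTSearchSpace
        from .models import ModelKind
        from .protocol import ProtocolSpec
        from .wavelets import WaveletSpec

        ProtocolSpec(
            self.protocol.repetitions,
            self.protocol.segment_s,
            self.protocol.rest_s,
            self.protocol.module,
        )
        if not -1 <= self.synthesis.erd_depth <= 1:
            raise ConfigurationError("synthesis.erd_depth must lie in [-1, 1]")
        try:
            WaveletSpec(self.feature.wavelet, self.feature.level).validate_for_length(
                self.feature.window_rows
            )
            WPTSearchSpace().validate_for_length(self.feature.window_rows)
        except MibciError as exc:
            raise ConfigurationError(
                f"feature.window_rows={self.feature.window_rows} too short: {exc}"
            ) from None
        try:
            ModelKind(self.model.kind)
        except ValueError:
            raise ConfigurationError(
                f"model.kind must be one of {[k.value for k in ModelKind]}"
            ) from None
        if self.model.n_search_iter < 1:
            raise ConfigurationError("model.n_search_iter must be >= 1")
        if self.stream.min_dwell_windows < 1:
            raise ConfigurationError("stream.min_dwell_windows must be >= 1")

    def to_dict(self) -> dict:
        return {
            **{name: asdict(getattr(self, name)) for name in self._SECTIONS},
            "seed": self.seed,
        }
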