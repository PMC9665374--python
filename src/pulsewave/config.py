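"""Run configuration: stage configs, YAML round-trip, named defaults.

All constants the pipeline treats as fixed defaults are surfaced here:
the signal-quality acceptance thresholds (57 dB powerline, 19 dB
high-frequency, 5% PPG saturation), the primary LVEDP definitions
(elevated >= 25 mmHg vs normal <= 12 mmHg), the 82%-sensitivity binary
operating point, and the 1000-iteration BNP simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .bnp import BoxplotSummary, NON_CARDIAC_SUMMARY, OBESE_HFPEF_SUMMARY
from .errors import ConfigurationError
from .features import FeatureConfig
from .quality import QualityConfig
from .synthetic import CohortConfig, SignalConfig, WaveSpec

__all__ = ["ModelingConfig", "EvaluationConfig", "BnpConfig", "RunConfig",
           "load_config", "save_config"]


@dataclass
class ModelingConfig:
    contamination: float = 0.05          # Isolation-Forest exclusion rate
    subset_range: tuple = (89, 194)      # nominal feature-subset sizes
    cv_folds: int = 5
    cv_iterations: int = 100


@dataclass
class EvaluationConfig:
    elevated_def: float = 25.0           # mmHg, primary elevated definition
    nonelevated_def: float = 12.0        # mmHg, primary normal definition
    target_sensitivity: float = 0.82     # binary operating point
    run_sweep: bool = False
    run_matching: bool = False
    subgroups: tuple = ()


@dataclass
class BnpConfig:
    non_elevated: BoxplotSummary = field(default_factory=lambda: NON_CARDIAC_SUMMARY)
    elevated: BoxplotSummary = field(default_factory=lambda: OBESE_HFPEF_SUMMARY)
    n_non: int = 258
    n_elev: int = 79
    thresholds: tuple = (50.0, 150.0)
    iterations: int = 1000
    ml_sens: float = 0.82
    ml_spec: float = 0.68


@dataclass
class RunConfig:
    n_dev: int = 300                     # development cohort size
    n_val: int = 150                     # blinded validation cohort size
    seed: int = 0
    out_dir: str = "pulsewave_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    modeling: ModelingConfig = field(default_factory=ModelingConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    bnp: BnpConfig = field(default_factory=BnpConfig)

    def to_dict(self) -> dict:
        return _to_plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return _from_dict(cls, d)


def _to_plain(obj):
    """asdict output with tuples rendered as lists (YAML-friendly)."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _coerce_like(template, value):
    """Coerce a YAML-decoded value to the shape of the default value."""
    if is_dataclass(template) and isinstance(value, dict):
        return _from_dict(type(template), value)
    if isinstance(template, tuple):
        return tuple(_coerce_like(t, v) for t, v in zip(template, value)) \
            if template and len(template) == len(value) \
            else tuple(value)
    if isinstance(template, dict) and isinstance(value, dict):
        sample = next(iter(template.values()), None)
        return {k: _coerce_like(sample, v) for k, v in value.items()}
    return value


def _from_dict(cls, d: dict):
    try:
        defaults = cls()
    except TypeError:
        # dataclasses without full defaults (WaveSpec, BoxplotSummary)
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in d.items()})
    kwargs = {}
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for f in fields(cls):
        if f.name not in d:
            continue
        kwargs[f.name] = _coerce_like(getattr(defaults, f.name), d[f.name])
    return cls(**kwargs)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ConfigurationError(f"{path}: not a mapping")
    return RunConfig.from_dict(d)
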