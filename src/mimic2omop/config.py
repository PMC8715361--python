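"""Configuration objects for the synthetic cohort generator and the pipeline.

The generator defaults describe the marginal statistics of the source ICU
population the transformation was designed around: gender split, the seven
age bands (with a distinct neonatal subpopulation), the emergency admission
share and per-admission event rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

AGE_BANDS = ("0-5", "6-15", "16-25", "26-45", "46-65", "66-80", ">80")

#: admission-level age-band shares of the source ICU population
DEFAULT_AGE_BAND_WEIGHTS = (0.1375, 0.0001, 0.0243, 0.1011, 0.2945,
                            0.2678, 0.1747)


class ConfigurationError(ValueError):
    """Invalid configuration; the message names the offending field."""


def _check_probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Controls for the synthetic source-database generator."""

    n_patients: int = 100
    seed: int = 0
    female_fraction: float = 0.4385
    age_band_weights: tuple[float, ...] = DEFAULT_AGE_BAND_WEIGHTS
    emergency_fraction: float = 0.7133
    mean_icu_stays_per_admission: float = 1.21
    mean_labs_per_admission: float = 478.0
    mean_drugs_per_admission: float = 82.8
    mean_diagnoses_per_admission: float = 11.0
    mean_chart_events_per_admission: float = 30.0
    mean_notes_per_admission: float = 1.5
    error_row_fraction: float = 0.0
    date_shift_window: tuple[int, int] = (2100, 2200)
    obfuscate_over_89: bool = True

    def validate(self) -> "GeneratorConfig":
        if self.n_patients < 0:
            raise ConfigurationError(
                f"n_patients must be >= 0, got {self.n_patients!r}")
        _check_probability("female_fraction", self.female_fraction)
        _check_probability("emergency_fraction", self.emergency_fraction)
        _check_probability("error_row_fraction", self.error_row_fraction)
        if len(self.age_band_weights) != len(AGE_BANDS):
            raise ConfigurationError(
                f"age_band_weights must have {len(AGE_BANDS)} entries")
        if any(w < 0 for w in self.age_band_weights):
            raise ConfigurationError("age_band_weights entries must be >= 0")
        if abs(sum(self.age_band_weights) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"age_band_weights must sum to 1, got {sum(self.age_band_weights)}")
        for name in ("mean_icu_stays_per_admission", "mean_labs_per_admission",
                     "mean_drugs_per_admission", "mean_diagnoses_per_admission",
                     "mean_chart_events_per_admission",
                     "mean_notes_per_admission"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.date_shift_window
        if not (1900 <= lo < hi <= 9999):
            raise ConfigurationError(
                f"date_shift_window must be an increasing year pair, got "
                f"{self.date_shift_window!r}")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_band_weights"] = list(self.age_band_weights)
        d["date_shift_window"] = list(self.date_shift_window)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        if "seed" not in data:
            raise ConfigurationError("seed is mandatory in generator config")
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(data)
        if "age_band_weights" in kwargs:
            kwargs["age_band_weights"] = tuple(kwargs["age_band_weights"])
        if "date_shift_window" in kwargs:
            kwargs["date_shift_window"] = tuple(kwargs["date_shift_window"])
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must be a mapping")
        return cls.from_dict(data)


STAGES = ("synth", "vocab", "etl", "derive", "nlp", "qa")

#: stages each stage depends on
STAGE_DEPENDENCIES = {
    "synth": (),
    "vocab": (),
    "etl": ("synth", "vocab"),
    "derive": ("etl",),
    "nlp": ("etl",),
    "qa": ("etl",),
}


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    concept_file: Path | None = None       # None -> packaged fixture
    relationship_file: Path | None = None
    output_dir: Path = Path("out")
    stages: tuple[str, ...] = STAGES
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        self.generator.validate()
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stages: {unknown}")
        return self
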