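"""Pipeline configuration: schema, defaults and YAML/JSON loading.

An empty config file resolves to the full default configuration, whose
rate-constant blocks reproduce the default parameter sets of
:mod:`recqcycle.scheme` exactly.  Unknown keys are rejected and validation
errors name the offending key and constraint (pydantic).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .scheme import RateConstantSet, default_rates

__all__ = ["PipelineConfig", "RatesBlock", "ConfigError", "load_and_validate",
           "dump_config"]


class ConfigError(ValueError):
    """Configuration failed schema validation."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RateSetConfig(_StrictModel):
    k1: float = Field(ge=0)
    k_m1: float = Field(ge=0)
    k2: float = Field(ge=0)
    k_m2: float = Field(ge=0)
    k3: float = Field(ge=0)
    k_m3: float = Field(ge=0)
    k4: float = Field(ge=0)
    k_m4: float = Field(ge=0)

    @classmethod
    def from_rates(cls, rates: RateConstantSet) -> "RateSetConfig":
        return cls(**rates.as_dict())

    def to_rates(self, condition: str, label: str) -> RateConstantSet:
        return RateConstantSet.from_dict(self.model_dump(), condition=condition,
                                         label=label)


class ConditionRates(_StrictModel):
    unlabeled: RateSetConfig
    md_analog: RateSetConfig


class RatesBlock(_StrictModel):
    dna_bound: ConditionRates
    dna_free: ConditionRates


class NoiseConfig(_StrictModel):
    md_fluorescence: float = Field(default=0.02, ge=0)
    fraction_cleaved: float = Field(default=0.02, ge=0)
    pi_released: float = Field(default=0.01, ge=0)


class TranslocationBlock(_StrictModel):
    atp: float = Field(default=100.0, gt=0)
    coupling_c: float = Field(default=1.1, gt=0)
    n_runs: int = Field(default=10000, ge=1)
    termination_fraction_D: float = Field(default=0.76, gt=0, lt=1)
    mean_cycles: float = Field(default=23.0, gt=0)
    # explicit off rates; if omitted they are solved from the two outputs above
    off_rates: dict[str, float] | None = None

    @field_validator("off_rates")
    @classmethod
    def _check_off(cls, v):
        if v is None:
            return v
        allowed = {"off_E", "off_T", "off_DPi", "off_D"}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown off-rate keys: {sorted(unknown)}")
        if any(x < 0 for x in v.values()):
            raise ValueError("off rates must be >= 0")
        return v


class ExchangeBlock(_StrictModel):
    f: float = Field(default=0.40, ge=0, lt=1)
    n_ions: int = Field(default=20000, ge=1)
    background_fraction: float = Field(default=0.0, ge=0, lt=1)


class PipelineConfig(_StrictModel):
    rates: RatesBlock
    noise: NoiseConfig = NoiseConfig()
    translocation: TranslocationBlock = TranslocationBlock()
    exchange: ExchangeBlock = ExchangeBlock()
    seed: int = 1
    output_dir: str = "out"

    def rate_set(self, condition: str, label: str = "unlabeled") -> RateConstantSet:
        block = getattr(self.rates, condition)
        return getattr(block, label).to_rates(condition, label)


def _default_rates_block() -> dict:
    return {
        cond: {
            label: default_rates(cond, label).as_dict()
            for label in ("unlabeled", "md_analog")
        }
        for cond in ("dna_bound", "dna_free")
    }


def default_config() -> PipelineConfig:
    return PipelineConfig(rates=RatesBlock.model_validate(_default_rates_block()))


def load_and_validate(path: Path | str | None) -> PipelineConfig:
    """Load a YAML or JSON config; missing keys fall back to defaults.

    An empty file (or ``path=None``) yields the full default config.
    Validation failures raise :class:`ConfigError` naming the offending
    key; a missing file raises ``FileNotFoundError``.
    """
    payload: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if text.strip():
            if path.suffix == ".json":
                payload = json.loads(text)
            else:
                payload = yaml.safe_load(text)
            if payload is None:
                payload = {}
            if not isinstance(payload, dict):
                raise ConfigError("config root must be a mapping")
    merged = {"rates": _default_rates_block()}
    merged.update({k: v for k, v in payload.items() if k != "rates"})
    if "rates" in payload:
        # deep-merge user rate overrides onto the defaults
        for cond, block in payload["rates"].items():
            if cond not in merged["rates"]:
                raise ConfigError(f"rates.{cond}: unknown condition")
            for label, values in block.items():
                if label not in merged["rates"][cond]:
                    raise ConfigError(f"rates.{cond}.{label}: unknown parameter-set label")
                merged["rates"][cond][label] = {**merged["rates"][cond][label], **values}
    try:
        return PipelineConfig.model_validate(merged)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: PipelineConfig) -> str:
    """Serialize a config to YAML; load(dump(load(x))) is idempotent."""
    return yaml.safe_dump(config.model_dump(), sort_keys=True)
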