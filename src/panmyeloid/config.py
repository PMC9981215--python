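"""Pipeline configuration: YAML round-trip with strict key validation.

Defaults are the study settings: DP concentration 1e-4 with 5,000 burn-in
and 500 retained sweeps, network widths (100, 65), 100 bootstrap
replicates, mutation-load threshold 2 and the eight-step filter
thresholds.  Unknown YAML keys are errors so that threshold typos cannot
pass silently.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .embedding import NetConfig
from .variant_filter import FilterThresholds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DPSettings:
    alpha: float = 1e-4
    burn_in: int = 5000
    n_samples: int = 500
    beta_a: float = 1.0
    beta_b: float = 1.0

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("DP concentration alpha must be > 0")
        if self.burn_in < 0 or self.n_samples < 1:
            raise ValueError("invalid sweep counts")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    dp: DPSettings = field(default_factory=DPSettings)
    net: NetConfig = field(default_factory=NetConfig)
    bootstrap_B: int = 100
    load_threshold: int = 2
    myeloid_rate_threshold: float = 0.01
    cohort_scale: float = 1.0  # synthetic cohort size multiplier

    def validate(self) -> None:
        self.dp.validate()
        if self.bootstrap_B < 2:
            raise ValueError("bootstrap_B must be >= 2")
        if self.load_threshold < 0:
            raise ValueError("load_threshold must be >= 0")


_SECTIONS = {
    "filter_thresholds": FilterThresholds,
    "dp": DPSettings,
    "net": NetConfig,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    kwargs = {}
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key, value in raw.items():
        if key not in top_fields:
            raise ValueError(f"unknown config key {key!r}")
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            section_fields = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - section_fields
            if unknown:
                raise ValueError(f"unknown keys in {key!r}: {sorted(unknown)}")
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            value = cls(**value)
        kwargs[key] = value
    config = PipelineConfig(**kwargs)
    config.validate()
    return config


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize the resolved config so a run can be reproduced."""
    out = dataclasses.asdict(config)
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
    logger.info("resolved config written to %s", path)
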