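"""YAML-backed pipeline configuration with explicit defaults.

Every analysis parameter is surfaced here with its conventional default:
the ±60-min protocol truncation margin, the 20/2/30-min non-wear rule, the
4-day/6-h validity criteria, the three toddler cut-point sets, and the
180-min TPA / 60-min sedentary-bout guideline thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .classification import CUT_POINT_SETS, CutPointSet
from .nonwear import NonwearParams
from .standardize import ValidityCriteria

__all__ = ["PipelineConfig", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    counts_dir: str = "cohort/counts"
    protocol_csv: str = "cohort/protocol.csv"
    out_dir: str = "out"
    margin_min: float = 60.0
    nonwear: NonwearParams = field(default_factory=NonwearParams)
    validity: ValidityCriteria = field(default_factory=ValidityCriteria)
    cutpoints: list = field(default_factory=lambda: ["costa_vm", "costa_va", "trost_va"])
    extra_cutpoints: dict = field(default_factory=dict)  # name -> CutPointSet
    tpa_threshold_min: float = 180.0
    sb_bout_limit_min: float = 60.0
    use_adjusted_adherence: bool = True
    seed: int = 0
    log_level: str = "INFO"
    # simulate-subcommand settings
    sim_n_subjects: int = 30
    sim_n_days: int = 7
    sim_ambiguity: float = 0.5

    def __post_init__(self) -> None:
        if not self.cutpoints:
            raise ConfigError("cutpoints: at least one cut-point set is required")
        for name in self.cutpoints:
            if name not in CUT_POINT_SETS and name not in self.extra_cutpoints:
                raise ConfigError(
                    f"cutpoints: unknown set {name!r}; built-ins are {sorted(CUT_POINT_SETS)}"
                )

    def cutpoint_sets(self) -> list[CutPointSet]:
        return [
            self.extra_cutpoints.get(name) or CUT_POINT_SETS[name] for name in self.cutpoints
        ]


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are an error, missing ones default."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    kwargs: dict = {}
    if "nonwear" in raw:
        kwargs["nonwear"] = NonwearParams(**raw.pop("nonwear"))
    if "validity" in raw:
        kwargs["validity"] = ValidityCriteria(**raw.pop("validity"))
    if "extra_cutpoints" in raw:
        kwargs["extra_cutpoints"] = {
            name: CutPointSet(name=name, **fields)
            for name, fields in raw.pop("extra_cutpoints").items()
        }
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs.update(raw)
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_default_config(path) -> None:
    """Write a fully explicit default config file."""
    cfg = PipelineConfig()
    data = asdict(cfg)
    data["nonwear"] = asdict(cfg.nonwear)
    data["validity"] = asdict(cfg.validity)
    data.pop("extra_cutpoints")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
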