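"""Configuration files and format-stable readers/writers.

All tabular outputs are CSV; results and metadata are JSON; configuration
is YAML or JSON.  A fully defaulted configuration reproduces the standard
scenario (25 µM IS, 1 mM albumin, fitted transporter parameters), so the
study scenarios run with zero configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import TimeSeriesDataset
from .model import (
    AlbuminParameters,
    CompartmentGeometry,
    EffluxParameters,
    TransportParameters,
    UremicFactors,
)
from .simulate import ModelSpec, scenario

__all__ = [
    "PipelineConfig",
    "build_spec",
    "load_config",
    "read_datasets_csv",
    "write_datasets_csv",
    "write_json",
]

#: Override keys accepted in a config file, grouped by the parameter block
#: they land in.
_TRANSPORT_KEYS = ("kf_uptake", "kf_dissociation", "oat1_density_0")
_EFFLUX_KEYS = ("vmax_efflux", "k_efflux")
_ALBUMIN_KEYS = ("hsa_0", "bmax", "kd_hsa")
_FACTOR_KEYS = ("f1", "f2")
_GEOMETRY_KEYS = (
    "well_or_blood_volume", "cell_volume", "dialysate_volume",
    "basolateral_area", "apical_area",
)
_STATE_KEYS = ("is_b",)
KNOWN_OVERRIDES = (
    _TRANSPORT_KEYS + _EFFLUX_KEYS + _ALBUMIN_KEYS + _FACTOR_KEYS
    + _GEOMETRY_KEYS + _STATE_KEYS
)


@dataclass
class PipelineConfig:
    """Run configuration shared by all pipeline stages."""

    scenario: str = "standard"
    overrides: dict[str, float] = field(default_factory=dict)
    output_dir: str = "oatkin-output"
    seed: int = 1
    verbosity: str = "INFO"
    clearance_threshold: float = 0.995
    endpoint_h: float = 17.5
    t_end_h: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - set(KNOWN_OVERRIDES)
        if unknown:
            raise ValueError(
                f"unknown override keys {sorted(unknown)}; known: {KNOWN_OVERRIDES}"
            )
        # YAML 1.1 reads "2.3e6" (no sign) as a string; be forgiving
        self.overrides = {k: float(v) for k, v in self.overrides.items()}


_CONFIG_FIELDS = {f for f in PipelineConfig.__dataclass_fields__}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML or JSON config; ``None`` returns the full defaults.

    Unknown top-level keys and unknown override keys are rejected.
    """
    if path is None:
        return PipelineConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    return PipelineConfig(**data)


def build_spec(config: PipelineConfig) -> ModelSpec:
    """Materialize the configured scenario with overrides applied."""
    ov = config.overrides
    pick = lambda keys, cls: cls(**{k: ov[k] for k in keys if k in ov})
    spec = scenario(
        config.scenario,
        transport=pick(_TRANSPORT_KEYS, TransportParameters),
        efflux=pick(_EFFLUX_KEYS, EffluxParameters),
        albumin=pick(_ALBUMIN_KEYS, AlbuminParameters),
        geometry=pick(_GEOMETRY_KEYS, CompartmentGeometry),
        factors=(
            UremicFactors(ov.get("f1", 1.0), ov.get("f2", 1.0))
            if any(k in ov for k in _FACTOR_KEYS) else None
        ),
    )
    if "is_b" in ov:
        spec = replace(spec, initial_state=replace(spec.initial_state, is_b=ov["is_b"]))
    return spec


def write_datasets_csv(datasets: list[TimeSeriesDataset], path: str | Path) -> None:
    pd.concat([d.to_frame() for d in datasets], ignore_index=True).to_csv(
        path, index=False
    )


def read_datasets_csv(path: str | Path) -> list[TimeSeriesDataset]:
    return TimeSeriesDataset.from_frame(pd.read_csv(path))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, cls=_NumpyEncoder) + "\n")
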