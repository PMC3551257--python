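"""Structured-text (YAML) run configuration.

One canonical nested mapping carries every tunable of the model: the cell
kinetic constants, injury parameters, sinusoid/lobule geometry, zonation,
the PBPK compartment table, the dose regimen and solver/simulation
settings. Unknown keys are rejected; value validation is delegated to the
domain dataclasses, which enforce positivity and consistency.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import fields
from pathlib import Path
from typing import Any

import yaml

from .cell_kinetics import EnzymeProfile
from .injury import InjuryParameters
from .lobule import ZonationProfile
from .sinusoid_transport import SinusoidGeometry
from .whole_body import CompartmentSpec, DoseRegimen, default_compartments

__all__ = ["RunConfig", "load_config", "default_config_dict", "config_hash"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _dataclass_dict(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in fields(obj)}


def default_config_dict() -> dict:
    """The full default configuration as a plain nested mapping."""
    comps = default_compartments()
    return {
        "cell": _dataclass_dict(EnzymeProfile()),
        "injury": _dataclass_dict(InjuryParameters()),
        "geometry": _dataclass_dict(SinusoidGeometry()),
        "zonation": {
            "boundaries": list(ZonationProfile().boundaries),
            "multipliers": list(ZonationProfile().multipliers),
        },
        "pbpk": {
            name: {"flow": c.flow, "volume": c.volume, "pc": c.pc}
            for name, c in comps.items()
        },
        "regimen": {
            "body_weight": 73.0,
            "doses": [],            # list of [time_min, dose_mg_per_kg]
            "fr_ing": 0.9,
            "k_gut": 0.025,
        },
        "simulation": {
            "duration": 2000.0,
            "seed": 0,
            "dt_macro": 0.5,
            "record_every": 2,
        },
    }


def _merge_strict(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {where}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge_strict(defaults[key], value, where)
        else:
            out[key] = value
    return out


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration; builds the domain objects on demand."""

    data: dict

    @classmethod
    def from_dict(cls, override: dict | None = None) -> "RunConfig":
        merged = _merge_strict(default_config_dict(), override or {})
        cfg = cls(merged)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        """Instantiate every section so the dataclass invariants run."""
        try:
            self.profile()
            self.injury()
            self.geometry()
            self.zonation()
            self.compartments()
            self.regimen()
        except (ValueError, TypeError) as err:
            raise ConfigError(str(err)) from err
        sim = self.data["simulation"]
        if sim["duration"] <= 0 or sim["dt_macro"] <= 0:
            raise ConfigError("simulation.duration and dt_macro must be > 0")

    def profile(self) -> EnzymeProfile:
        return EnzymeProfile(**self.data["cell"])

    def injury(self) -> InjuryParameters:
        return InjuryParameters(**self.data["injury"])

    def geometry(self) -> SinusoidGeometry:
        return SinusoidGeometry(**self.data["geometry"])

    def zonation(self) -> ZonationProfile:
        z = self.data["zonation"]
        return ZonationProfile(
            boundaries=tuple(z["boundaries"]),
            multipliers=tuple(z["multipliers"]),
        )

    def compartments(self) -> dict[str, CompartmentSpec]:
        return {
            name: CompartmentSpec(name=name, **params)
            for name, params in self.data["pbpk"].items()
        }

    def regimen(self, dose: float | None = None,
                body_weight: float | None = None) -> DoseRegimen:
        r = dict(self.data["regimen"])
        doses = [tuple(d) for d in r.pop("doses")]
        if dose is not None:
            doses = [(0.0, float(dose))]
        weight = body_weight if body_weight is not None else r.pop("body_weight")
        r.pop("body_weight", None)
        return DoseRegimen(body_weight=weight, doses=tuple(doses), **r)

    @property
    def simulation(self) -> dict:
        return self.data["simulation"]


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML configuration file (missing keys fall back to defaults),
    then apply flat overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("configuration root must be a mapping")
        data = loaded
    if overrides:
        data = _merge_strict(
            _merge_strict(default_config_dict(), data), overrides
        )
    return RunConfig.from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration (for run metadata)."""
    blob = json.dumps(cfg.data, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
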