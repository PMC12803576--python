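"""Plasma substrate / hormone / ion profiles defining physiological scenarios."""

from __future__ import annotations

from dataclasses import dataclass, replace, fields
from importlib import resources

import yaml

__all__ = ["PlasmaProfile", "preset_plasma", "available_presets"]


@dataclass(frozen=True)
class PlasmaProfile:
    """External concentrations clamping the boundary pools of the network.

    Concentrations are mmol/L; insulin and catecholamine are arbitrary units
    feeding the saturating regulation factors.  Sodium and calcium are carried
    for completeness but sarcolemmal Na/Ca handling is clamped in the model.
    """

    name: str = "custom"
    glucose: float = 5.0
    fatty_acids: float = 0.5
    lactate: float = 1.0
    pyruvate: float = 0.1
    beta_hydroxybutyrate: float = 0.15
    acetoacetate: float = 0.05
    bcaa: float = 0.4
    insulin: float = 40.0
    catecholamine: float = 10.0
    potassium: float = 4.5
    sodium: float = 140.0
    calcium: float = 1.2

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "name":
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"plasma {f.name} must be >= 0")

    @property
    def ketones(self) -> float:
        return self.beta_hydroxybutyrate + self.acetoacetate

    def override(self, **changes) -> "PlasmaProfile":
        """Field-wise merge; only the given fields differ from ``self``."""
        return replace(self, name=changes.pop("name", self.name), **changes)


def _load_presets() -> dict:
    ref = resources.files("myokin.data") / "plasma_presets.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def available_presets() -> list[str]:
    return sorted(_load_presets())


def preset_plasma(name: str, **overrides) -> PlasmaProfile:
    """Return a shipped preset (fasting / postprandial / diabetic_fasting),
    optionally with field-wise overrides."""
    presets = _load_presets()
    if name not in presets:
        raise KeyError(f"unknown plasma preset {name!r}; available: {sorted(presets)}")
    return PlasmaProfile(name=name, **presets[name]).override(**overrides)
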