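"""Shipped hierarchy presets: the flood configuration for Cork and the heat
configurations for Logroño and Milan, one YAML document each."""

from importlib import resources

from ..hierarchy import HierarchyConfig, load_hierarchy

PRESET_NAMES = ("cork_flood", "logrono_heat", "milan_heat")


def preset_text(name: str) -> str:
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return (resources.files(__package__) / f"{name}.yaml").read_text(encoding="utf-8")


def load_preset(name: str) -> HierarchyConfig:
    return load_hierarchy(preset_text(name))
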