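"""Flat key-value config files (YAML or JSON) mapped onto RunConfig.

Keys are dotted, one per leaf option, e.g.::

    detect.ang_min: 0.25
    detect.t_interval_s: 0.3
    preprocess.t_win_s: 0.3
    preprocess.normalize_for_dtw: true
    dtw.normalize_by_path_length: false
    train_fraction: 0.82
    seed: 1

Unknown keys are rejected so typos never silently fall back to defaults.
CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .activity_detection import DetectionConfig
from .dtw_classifier import DtwConfig
from .errors import ConfigError
from .pipeline import RunConfig
from .preprocessing import PreprocessConfig
from .synthetic import GeneratorConfig

_SECTIONS = {
    "preprocess": PreprocessConfig,
    "detect": DetectionConfig,
    "generator": GeneratorConfig,
    "dtw": DtwConfig,
}
_TOP_LEVEL = ("train_fraction", "seed", "log_level")


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat dotted-key YAML/JSON file into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a key-value mapping")

    overrides: dict[str, dict] = {name: {} for name in _SECTIONS}
    top: dict = {}
    for key, value in raw.items():
        if key in _TOP_LEVEL:
            top[key] = value
            continue
        if "." not in key:
            raise ConfigError(f"{path}: unknown config key {key!r}")
        section, _, option = key.partition(".")
        cls = _SECTIONS.get(section)
        if cls is None:
            raise ConfigError(f"{path}: unknown config section {section!r}")
        names = {f.name for f in dataclasses.fields(cls)}
        if option not in names:
            raise ConfigError(f"{path}: unknown option {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        overrides[section][option] = value

    return RunConfig(
        preprocess=PreprocessConfig(**overrides["preprocess"]),
        detect=DetectionConfig(**overrides["detect"]),
        generator=GeneratorConfig(**overrides["generator"]),
        dtw=DtwConfig(**overrides["dtw"]),
        **top,
    )
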