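"""YAML round-tripping of :class:`~comodal.experiments.ExperimentConfig`.

The file layout mirrors the parameter table of the model: a ``model``
section (N, S, p, tau, g, k, alpha, O, dt, force_interval), a ``teaching``
section (beta, gamma, T, delta), a ``stimulus`` section and a ``schedule``
section (C, m, d, use_separators, ...), plus top-level experiment fields
(variant, C_test, manipulate, scoring knobs).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .experiments import ExperimentConfig
from .params import ModelParams, ScheduleParams, StimulusParams, TeachingParams

_SECTIONS = {
    "model": ModelParams,
    "teaching": TeachingParams,
    "stimulus": StimulusParams,
    "schedule": ScheduleParams,
}


def load_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, cls in _SECTIONS.items():
        section = raw.pop(key, {}) or {}
        if key == "schedule" and "chunk_probabilities" in section:
            section["chunk_probabilities"] = tuple(section["chunk_probabilities"])
        kwargs[key] = cls(**section)
    kwargs.update(raw)
    return ExperimentConfig(**kwargs)


def save_config(config: ExperimentConfig, path) -> None:
    out = {}
    for key in _SECTIONS:
        out[key] = dataclasses.asdict(getattr(config, key))
        if key == "schedule":
            out[key]["chunk_probabilities"] = list(out[key]["chunk_probabilities"])
    for f in dataclasses.fields(config):
        if f.name not in _SECTIONS:
            out[f.name] = getattr(config, f.name)
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
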