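"""Structured run configuration: one YAML file, one block per stage.

Every tunable of the pipeline has a named default equal to the study's
processing parameters, so an empty configuration file reproduces them.
Unknown keys are rejected with a close-match suggestion rather than ignored.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .annotation import AnnotationConfig
from .crossmode import CrossModeConfig
from .networking import NetworkConfig
from .preprocess import PreprocessConfig
from .similarity import ScoreConfig
from .simgen import SimConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    similarity: ScoreConfig = field(default_factory=ScoreConfig)
    networking: NetworkConfig = field(default_factory=NetworkConfig)
    crossmode: CrossModeConfig = field(default_factory=CrossModeConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    simgen: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name))
                for name in _BLOCKS}


_BLOCKS = ("preprocess", "similarity", "networking", "crossmode",
           "annotation", "simgen")


def _suggest(key: str, valid) -> str:
    close = difflib.get_close_matches(key, list(valid), n=1)
    hint = f"; did you mean {close[0]!r}?" if close else ""
    return f"unknown configuration key {key!r}{hint}"


def _build_block(cls, data: dict, block: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = [k for k in data if k not in valid]
    if unknown:
        raise ConfigError(f"in block {block!r}: {_suggest(unknown[0], valid)}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"in block {block!r}: {exc}") from exc


def load_config(path: Optional[Any] = None, overrides: Optional[dict] = None
                ) -> RunConfig:
    """Load a run configuration; missing blocks/keys fall back to defaults."""
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        for block, vals in overrides.items():
            data.setdefault(block, {}).update(vals)

    unknown = [k for k in data if k not in _BLOCKS]
    if unknown:
        raise ConfigError(_suggest(unknown[0], _BLOCKS))

    kwargs = {}
    classes = {"preprocess": PreprocessConfig, "similarity": ScoreConfig,
               "networking": NetworkConfig, "crossmode": CrossModeConfig,
               "annotation": AnnotationConfig, "simgen": SimConfig}
    for block, cls in classes.items():
        kwargs[block] = _build_block(cls, data.get(block) or {}, block)
    return RunConfig(**kwargs)
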