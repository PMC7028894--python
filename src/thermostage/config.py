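"""Flat run configuration: one YAML file covering every pipeline stage.

Sections mirror the per-stage config dataclasses (``preprocess``, ``hog``,
``ann``, ``split``, ``synth``) plus a global ``seed`` and ``log_level``.
Every field has a documented default in code; unknown sections or keys are
rejected so typos fail loudly.  The global seed cascades into the ANN,
split and synthetic-generator seeds unless those are set explicitly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, replace

import yaml

from .classify import ANNConfig
from .evaluate import SplitSpec
from .features import HOGConfig
from .preprocess import PreprocessConfig
from .synthetic import SynthConfig

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "hog": HOGConfig,
    "ann": ANNConfig,
    "split": SplitSpec,
    "synth": SynthConfig,
}


@dataclass
class RunConfig:
    seed: int = 17
    log_level: str = "INFO"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hog: HOGConfig = field(default_factory=HOGConfig)
    ann: ANNConfig = field(default_factory=ANNConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def with_seed(self, seed: int) -> "RunConfig":
        """Cascade one global seed into every seeded section."""
        return replace(
            self,
            seed=seed,
            ann=replace(self.ann, seed=seed),
            split=replace(self.split, seed=seed),
            synth=replace(self.synth, seed=seed),
        )

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "log_level": self.log_level}
        for name in _SECTIONS:
            section = getattr(self, name)
            out[name] = {
                f.name: _plain(getattr(section, f.name)) for f in fields(section)
            }
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def digest(self) -> str:
        """Stable short hash of the full configuration."""
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    return v


def _build_section(cls, data: dict, where: str):
    allowed = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in allowed:
            raise ConfigError(f"unknown key {where}.{key}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where} section: {exc}") from exc


def load_run_config(path=None, seed: int | None = None) -> RunConfig:
    """Load a RunConfig from YAML (defaults when path is None).

    ``seed`` (e.g. from a CLI flag) overrides the file's global seed and
    cascades into every seeded section.
    """
    cfg = RunConfig()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        top_allowed = {"seed", "log_level", *_SECTIONS}
        for key in data:
            if key not in top_allowed:
                raise ConfigError(f"unknown config key {key!r}")
        sections = {}
        for name, cls in _SECTIONS.items():
            sec = data.get(name, {})
            if not isinstance(sec, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            sections[name] = _build_section(cls, sec, name)
        cfg = RunConfig(
            seed=int(data.get("seed", cfg.seed)),
            log_level=str(data.get("log_level", cfg.log_level)),
            **sections,
        )
        if "seed" in data:
            file_seed = int(data["seed"])
            cfg = _cascade_unset_seeds(cfg, data, file_seed)
    if seed is not None:
        cfg = cfg.with_seed(int(seed))
    return cfg


def _cascade_unset_seeds(cfg: RunConfig, data: dict, seed: int) -> RunConfig:
    updates = {}
    for name in ("ann", "split", "synth"):
        if "seed" not in data.get(name, {}):
            updates[name] = replace(getattr(cfg, name), seed=seed)
    return dataclasses.replace(cfg, **updates)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
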