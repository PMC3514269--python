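"""Run configuration: YAML loading with strict (unknown-key-rejecting)
validation against the parameter dataclasses."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._exceptions import InvalidInputError
from .baselines import GAParams, SAParams
from .gfa import GFAParams
from .simulator import SimParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config"]

_SECTION_TYPES = {"gfa": GFAParams, "ga": GAParams, "sa": SAParams, "sim": SimParams}
def _rank_tol_value(v):
    return "auto" if v == "auto" else float(v)


_SCALAR_KEYS = {
    "method": str,
    "seed": int,
    "tau": float,
    "rank_tol": _rank_tol_value,
    "force_null_k": int,
    "sparsity_lambda": float,
}


@dataclass
class RunConfig:
    """Fully resolved configuration of one run."""

    method: str = "gfa"
    seed: int = 0
    tau: float = 0.5
    rank_tol: float | str = 1e-10
    force_null_k: int = 0
    sparsity_lambda: float = 0.0
    gfa: GFAParams = field(default_factory=GFAParams)
    ga: GAParams = field(default_factory=GAParams)
    sa: SAParams = field(default_factory=SAParams)
    sim: SimParams = field(default_factory=SimParams)

    def log(self) -> None:
        """Log the fully resolved configuration (one line per field)."""
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


def _build_section(cls, raw: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(
            f"unknown keys in config section {section!r}: {sorted(unknown)}"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
    }
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig` (strict keys)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"{path}: config root must be a mapping")
    unknown = set(raw) - set(_SCALAR_KEYS) - set(_SECTION_TYPES)
    if unknown:
        raise InvalidInputError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for key, typ in _SCALAR_KEYS.items():
        if key in raw:
            kwargs[key] = typ(raw[key])
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            if not isinstance(raw[section], dict):
                raise InvalidInputError(f"{path}: section {section!r} must be a mapping")
            kwargs[section] = _build_section(cls, raw[section], section)
    return RunConfig(**kwargs)
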