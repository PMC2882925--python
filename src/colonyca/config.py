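"""Run configuration: YAML dialect, validation, and shipped defaults.

One config file fully determines one run.  The dialect is a YAML mapping
with three blocks::

    model:                 # every ModelParams field; max_generations optional
      N: 140
      P: 1.0
      ...
    inoculum:              # InoculumSpec fields; kind + positions mandatory
      kind: point
      positions: [175]
    output:                # optional
      thin: 1              # snapshot thinning interval for trace files
      plot: false

Unknown keys anywhere are an error — a misspelled parameter must never be
silently ignored.  Error messages name the offending key and constraint.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError, ValidationError
from .inoculation import InoculumKind, InoculumSpec
from .params import DEFAULT_MAX_GENERATIONS, ModelParams

CONFIG_VERSION = "colonyca-config-v1"

_MODEL_KEYS = {"N", "P", "S", "A", "O", "D", "G",
               "Qlim", "Olim1", "Olim2", "L", "max_generations"}
_MODEL_OPTIONAL = {"max_generations"}
_INOCULUM_KEYS = {"kind", "positions", "width", "gap",
                  "initial_thickness", "stride"}
_INOCULUM_OPTIONAL = _INOCULUM_KEYS - {"kind", "positions"}
_OUTPUT_KEYS = {"thin", "plot"}


@dataclass(frozen=True)
class OutputOptions:
    thin: int = 1
    plot: bool = False

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ConfigError(f"output.thin: must be >= 1, got {self.thin}")


@dataclass(frozen=True)
class RunConfig:
    """Validated model parameters, inoculum layout and output options."""

    params: ModelParams
    inoculum: InoculumSpec
    output: OutputOptions = OutputOptions()

    def to_mapping(self) -> dict:
        spec = dataclasses.asdict(self.inoculum)
        spec["kind"] = self.inoculum.kind.value
        spec["positions"] = list(spec["positions"])
        return {
            "model": self.params.to_dict(),
            "inoculum": spec,
            "output": {"thin": self.output.thin, "plot": self.output.plot},
        }


def _require_mapping(obj, name: str) -> dict:
    if not isinstance(obj, dict):
        raise ConfigError(f"{name}: expected a mapping, got {type(obj).__name__}")
    return obj


def _check_keys(block: dict, allowed: set, optional: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"{name}: unknown key(s) {sorted(unknown)}; allowed: "
            f"{sorted(allowed)}")
    missing = allowed - optional - set(block)
    if missing:
        raise ConfigError(f"{name}: missing mandatory key(s) {sorted(missing)}")


def config_from_mapping(mapping: dict) -> RunConfig:
    """Validate a parsed mapping into a :class:`RunConfig`."""
    mapping = _require_mapping(mapping, "config")
    unknown = set(mapping) - {"model", "inoculum", "output"}
    if unknown:
        raise ConfigError(
            f"config: unknown top-level key(s) {sorted(unknown)}; "
            f"allowed: ['model', 'inoculum', 'output']")
    if "model" not in mapping or "inoculum" not in mapping:
        missing = {"model", "inoculum"} - set(mapping)
        raise ConfigError(f"config: missing block(s) {sorted(missing)}")

    model = _require_mapping(mapping["model"], "model")
    _check_keys(model, _MODEL_KEYS, _MODEL_OPTIONAL, "model")
    model = dict(model)
    model.setdefault("max_generations", DEFAULT_MAX_GENERATIONS)
    params = ModelParams(**model)  # raises ConfigError naming the field

    ino = _require_mapping(mapping["inoculum"], "inoculum")
    _check_keys(ino, _INOCULUM_KEYS, _INOCULUM_OPTIONAL, "inoculum")
    try:
        kind = InoculumKind(ino["kind"])
    except ValueError:
        raise ConfigError(
            f"inoculum.kind: unknown kind {ino['kind']!r}; allowed: "
            f"{[k.value for k in InoculumKind]}") from None
    try:
        spec = InoculumSpec(kind=kind,
                            positions=tuple(ino.get("positions", ())),
                            width=ino.get("width", 1),
                            gap=ino.get("gap", 0),
                            initial_thickness=ino.get("initial_thickness", 1),
                            stride=ino.get("stride", 10))
    except ValidationError as exc:
        raise ConfigError(f"inoculum: {exc}") from exc

    out = _require_mapping(mapping.get("output", {}), "output")
    _check_keys(out, _OUTPUT_KEYS, _OUTPUT_KEYS, "output")
    output = OutputOptions(thin=out.get("thin", 1), plot=out.get("plot", False))
    return RunConfig(params, spec, output)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        mapping = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if mapping is None:
        raise ConfigError(f"{path}: empty config file")
    return config_from_mapping(mapping)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    header = f"# {CONFIG_VERSION}\n"
    Path(path).write_text(
        header + yaml.safe_dump(config.to_mapping(), sort_keys=False))


def builtin_config(name: str = "rimmed") -> RunConfig:
    """Load one of the configs shipped with the package.

    ``rimmed`` — reference rates with the tuned thresholds that develop a
    rimmed colony from a central point inoculum; ``rimless`` — identical
    except for the sensitivity thresholds.
    """
    ref = resources.files("colonyca").joinpath(f"data/{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ConfigError(f"no builtin config named {name!r}") from None
    return config_from_mapping(yaml.safe_load(text))
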