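"""Run configuration: parsing, validation, defaults, round-tripping."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .dataset import DatasetParams

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """A named, actionable configuration problem."""


_DEFAULTS = {
    "engine": "analytic",
    "depth": 2,
    "pi0": 1e-3,
    "rho": 0.005,
    "tau": 1.0,
    "generations": 10,
    "t_star": "auto",
    "learning_rate": None,
    "nh": None,
    "seed": 0,
    "outdir": "runs",
    "export": ["csv", "json"],
}


@dataclass(frozen=True)
class RunConfig:
    params: DatasetParams
    engine: str = "analytic"
    depth: int = 2
    pi0: float = 1e-3
    rho: float = 0.005
    tau: float = 1.0
    generations: int = 10
    t_star: float | str = "auto"
    learning_rate: float | None = None
    nh: int | None = None
    seed: int = 0
    outdir: str = "runs"
    export: tuple[str, ...] = ("csv", "json")
    injected_defaults: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        d["export"] = list(self.export)
        d["injected_defaults"] = list(self.injected_defaults)
        return d


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw mapping, injecting and recording defaults.

    Every violated invariant raises :class:`ConfigError` with the rule
    it breaks spelled out.
    """
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    raw = dict(raw)
    raw.pop("injected_defaults", None)  # provenance field from a dumped config
    praw = raw.pop("params", None)
    if praw is None:
        raise ConfigError("missing 'params': provide nx, ny, kx, ky, r")
    try:
        params = DatasetParams(**{k: int(v) for k, v in dict(praw).items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid dataset params: {exc}") from exc

    injected = []
    values = {}
    for key, default in _DEFAULTS.items():
        if key in raw:
            values[key] = raw.pop(key)
        else:
            values[key] = default
            injected.append(key)
    if raw:
        raise ConfigError(f"unknown configuration keys: {sorted(raw)}")

    if values["engine"] not in ("analytic", "simulated"):
        raise ConfigError("engine must be 'analytic' or 'simulated'")
    if int(values["depth"]) < 1:
        raise ConfigError("depth must be >= 1")
    if not (0 < float(values["pi0"]) < 1):
        raise ConfigError("pi0 must lie in (0, 1): training starts from small weights")
    if float(values["rho"]) <= 0:
        raise ConfigError("rho must be positive")
    if int(values["generations"]) < 1:
        raise ConfigError("generations must be >= 1")
    ts = values["t_star"]
    if ts != "auto":
        try:
            ts = float(ts)
        except (TypeError, ValueError):
            raise ConfigError("t_star must be a positive number or 'auto'") from None
        if ts <= 0:
            raise ConfigError("t_star must be positive")
        values["t_star"] = ts
    if values["learning_rate"] is not None and float(values["learning_rate"]) <= 0:
        raise ConfigError("learning_rate must be positive")

    return RunConfig(
        params=params,
        engine=values["engine"],
        depth=int(values["depth"]),
        pi0=float(values["pi0"]),
        rho=float(values["rho"]),
        tau=float(values["tau"]),
        generations=int(values["generations"]),
        t_star=values["t_star"],
        learning_rate=None if values["learning_rate"] is None else float(values["learning_rate"]),
        nh=None if values["nh"] is None else int(values["nh"]),
        seed=int(values["seed"]),
        outdir=str(values["outdir"]),
        export=tuple(values["export"]),
        injected_defaults=tuple(injected),
    )


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON, which YAML subsumes) config file."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable config file {path}: {exc}") from exc
    return validate_config(raw)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")
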