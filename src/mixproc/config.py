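"""YAML run configuration: schema validation and defaults.

Unknown keys are rejected at every nesting level so that typos fail loudly
before any computation starts.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import yaml

from .dataset import RESPONSES
from .design import MODEL_NAMES
from .desirability import DesirabilitySpec, default_specs
from .errors import ConfigError

__all__ = ["DesignConfig", "SimulateConfig", "SurfaceConfig", "RunConfig", "load_config"]

_TOP_KEYS = {
    "model",
    "responses",
    "desirability",
    "design",
    "grid_step",
    "seed",
    "output_dir",
    "simulate",
    "surface",
}
_DESIGN_KEYS = {"method", "p80_levels", "us_levels", "n_runs", "seed", "max_iter"}
_SIMULATE_KEYS = {"true_coeffs", "noise_sd"}
_SURFACE_KEYS = {"kind", "source", "setting", "blend", "resolution"}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _check_keys(section: Mapping, allowed: set, where: str) -> None:
    _require(isinstance(section, Mapping), f"{where} must be a mapping")
    extra = set(section) - allowed
    _require(not extra, f"unknown keys in {where}: {sorted(extra)}")


@dataclass(frozen=True)
class DesignConfig:
    method: str = "full_cross"
    p80_levels: tuple[float, ...] = (0.0, 50.0, 100.0)
    us_levels: tuple[float, ...] = (1.0, 5.0, 10.0)
    n_runs: int | None = None
    seed: int = 0
    max_iter: int = 100


@dataclass(frozen=True)
class SimulateConfig:
    true_coeffs: dict[str, tuple[float, ...]] = field(default_factory=dict)
    noise_sd: float | dict[str, float] = 0.0


@dataclass(frozen=True)
class SurfaceConfig:
    kind: str = "ternary"
    source: str = "desirability"
    setting: tuple[float, float] = (50.0, 5.5)
    blend: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    resolution: int = 50


@dataclass(frozen=True)
class RunConfig:
    model: str = "multiplicative_deg3"
    responses: tuple[str, ...] = RESPONSES
    desirability: dict[str, DesirabilitySpec] = field(default_factory=default_specs)
    design: DesignConfig = field(default_factory=DesignConfig)
    grid_step: float = 0.01
    seed: int = 0
    output_dir: str = "."
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)


def _parse_design(raw: Mapping) -> DesignConfig:
    _check_keys(raw, _DESIGN_KEYS, "design")
    method = raw.get("method", "full_cross")
    _require(method in ("full_cross", "d_optimal"), f"design.method {method!r} invalid")
    p80 = tuple(float(v) for v in raw.get("p80_levels", (0, 50, 100)))
    us = tuple(float(v) for v in raw.get("us_levels", (1, 5, 10)))
    _require(len(p80) > 0 and len(us) > 0, "design levels must be nonempty")
    n_runs = raw.get("n_runs")
    _require(
        n_runs is None or (isinstance(n_runs, int) and n_runs > 0),
        "design.n_runs must be a positive integer",
    )
    seed = raw.get("seed", 0)
    _require(isinstance(seed, int), "design.seed must be an integer")
    max_iter = raw.get("max_iter", 100)
    _require(isinstance(max_iter, int) and max_iter > 0, "design.max_iter must be positive")
    return DesignConfig(
        method=method, p80_levels=p80, us_levels=us, n_runs=n_runs, seed=seed, max_iter=max_iter
    )


def _parse_simulate(raw: Mapping) -> SimulateConfig:
    _check_keys(raw, _SIMULATE_KEYS, "simulate")
    coeffs_raw = raw.get("true_coeffs", {})
    _require(isinstance(coeffs_raw, Mapping), "simulate.true_coeffs must be a mapping")
    coeffs = {}
    for name, vec in coeffs_raw.items():
        _require(name in RESPONSES, f"simulate.true_coeffs: unknown response {name!r}")
        _require(isinstance(vec, Sequence), f"simulate.true_coeffs[{name!r}] must be a list")
        coeffs[name] = tuple(float(v) for v in vec)
    noise = raw.get("noise_sd", 0.0)
    if isinstance(noise, Mapping):
        noise = {str(k): float(v) for k, v in noise.items()}
        _require(
            set(noise) <= set(RESPONSES), "simulate.noise_sd names an unknown response"
        )
        _require(all(v >= 0 for v in noise.values()), "simulate.noise_sd must be >= 0")
    else:
        noise = float(noise)
        _require(noise >= 0, "simulate.noise_sd must be >= 0")
    return SimulateConfig(true_coeffs=coeffs, noise_sd=noise)


def _parse_surface(raw: Mapping) -> SurfaceConfig:
    _check_keys(raw, _SURFACE_KEYS, "surface")
    kind = raw.get("kind", "ternary")
    _require(kind in ("ternary", "process"), f"surface.kind {kind!r} invalid")
    source = raw.get("source", "desirability")
    _require(
        source == "desirability" or source in RESPONSES,
        f"surface.source {source!r} invalid",
    )
    setting = tuple(float(v) for v in raw.get("setting", (50.0, 5.5)))
    _require(len(setting) == 2, "surface.setting must be [p80, us]")
    blend = tuple(float(v) for v in raw.get("blend", (1 / 3, 1 / 3, 1 / 3)))
    _require(len(blend) == 3, "surface.blend must have three components")
    resolution = raw.get("resolution", 50)
    _require(
        isinstance(resolution, int) and resolution >= 2, "surface.resolution must be >= 2"
    )
    return SurfaceConfig(
        kind=kind, source=source, setting=setting, blend=blend, resolution=resolution
    )


def parse_config(raw: Mapping | None) -> RunConfig:
    """Validate a parsed YAML mapping into a :class:`RunConfig`."""
    if raw is None:
        raw = {}
    _check_keys(raw, _TOP_KEYS, "configuration")
    model = raw.get("model", "multiplicative_deg3")
    _require(model in MODEL_NAMES, f"model {model!r} not one of {list(MODEL_NAMES)}")
    responses = tuple(raw.get("responses", RESPONSES))
    _require(len(responses) > 0, "responses must be nonempty")
    for r in responses:
        _require(r in RESPONSES, f"unknown response {r!r}")
    des_raw = raw.get("desirability")
    if des_raw is None:
        desirability = default_specs()
    else:
        _require(isinstance(des_raw, Mapping), "desirability must be a mapping")
        desirability = {}
        for name, spec in des_raw.items():
            _require(name in RESPONSES, f"desirability: unknown response {name!r}")
            try:
                desirability[name] = DesirabilitySpec.from_dict(spec)
            except Exception as exc:
                raise ConfigError(f"desirability[{name!r}]: {exc}") from exc
    grid_step = float(raw.get("grid_step", 0.01))
    _require(0.0 < grid_step <= 0.25, "grid_step must lie in (0, 0.25]")
    seed = raw.get("seed", 0)
    _require(isinstance(seed, int), "seed must be an integer")
    return RunConfig(
        model=model,
        responses=responses,
        desirability=desirability,
        design=_parse_design(raw.get("design", {})),
        grid_step=grid_step,
        seed=seed,
        output_dir=str(raw.get("output_dir", ".")),
        simulate=_parse_simulate(raw.get("simulate", {})),
        surface=_parse_surface(raw.get("surface", {})),
    )


def load_config(path) -> RunConfig:
    """Read and validate a YAML configuration file."""
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"configuration file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if raw is not None and not isinstance(raw, Mapping):
        raise ConfigError("configuration must be a YAML mapping")
    return parse_config(raw)
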