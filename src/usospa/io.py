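"""Configuration files, trajectory serialization, and run manifests.

Trajectories round-trip through plain CSV (header exactly ``t,S,O,P,U``,
values at full double precision) with a JSON manifest alongside recording
the parameters, grid and model variant.  Run configurations are flat
JSON/YAML documents validated strictly: unknown keys fail before any
computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .integrate import DEFAULT_DT, DEFAULT_T_END, Trajectory
from .model import ModelParameters, PopulationState, preset

__all__ = [
    "ConfigError",
    "FormatError",
    "RunConfig",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "write_sweep",
    "write_threshold",
]

_HEADER = ["t", "S", "O", "P", "U"]

EXPERIMENTS = ("simulate", "sweep", "threshold", "compare", "figure")


class ConfigError(ValueError):
    """Configuration file is malformed or violates the schema."""


class FormatError(ValueError):
    """A serialized trajectory does not match the expected layout."""


def _params_hash(params: ModelParameters) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory CSV plus its ``.manifest.json`` sidecar.

    Values are printed with 17 significant digits so the round trip
    through text is exact for doubles.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = traj.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")
    manifest = {
        "params": traj.params.to_dict(),
        "params_hash": _params_hash(traj.params),
        "dt": traj.meta.get("dt"),
        "t_end": traj.meta.get("t_end"),
        "variant": traj.variant,
        "method": traj.meta.get("method"),
        "n_points": len(traj),
        "package_version": __version__,
    }
    manifest_path = path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV (and manifest, if present) back into memory."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if list(frame.columns) != _HEADER:
        raise FormatError(
            f"bad trajectory header {list(frame.columns)}; expected {_HEADER}"
        )
    manifest_path = path.with_suffix(".manifest.json")
    meta: dict = {}
    params = ModelParameters()
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        params = ModelParameters.from_dict(manifest["params"])
        meta = {
            "method": manifest.get("method"),
            "dt": manifest.get("dt"),
            "t_end": manifest.get("t_end"),
            "variant": manifest.get("variant", "full"),
        }
    return Trajectory(
        times=frame["t"].to_numpy(),
        states=frame[["S", "O", "P", "U"]].to_numpy(),
        params=params,
        meta=meta,
    )


def write_sweep(result, path: str | Path) -> Path:
    """Long-format CSV: one row per (grid value, metric record)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def write_threshold(estimate, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(estimate.to_dict(), indent=2) + "\n")
    return path


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_KEYS = {
    "experiment", "preset", "params", "initial", "variant", "dt", "t_end",
    "out_dir",
    # sweep
    "quantity", "grid",
    # threshold
    "target", "resolution", "slope_fraction",
    # figure
    "figure_id",
}


@dataclass(frozen=True)
class RunConfig:
    """One fully-resolved run of the tool."""

    experiment: str
    preset: str | None = "baseline_sec3"
    params: ModelParameters = field(default_factory=ModelParameters)
    initial: PopulationState | None = None
    variant: str = "full"
    dt: float = DEFAULT_DT
    t_end: float = DEFAULT_T_END
    out_dir: Path = Path("runs")
    quantity: str | None = None
    grid: tuple[float, ...] | None = None
    target: str | None = None
    resolution: float = 0.005
    slope_fraction: float = 0.1
    figure_id: str | None = None


def load_config(path: str | Path) -> RunConfig:
    """Parse and strictly validate a JSON or YAML run configuration.

    The document is a flat mapping.  ``params`` and ``initial`` are nested
    mappings of overrides applied on top of the chosen preset.  Any
    unknown key, unresolvable preset, or out-of-range value raises
    :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    unknown = sorted(set(doc) - _CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {unknown}")

    experiment = doc.get("experiment")
    if experiment not in EXPERIMENTS:
        raise ConfigError(
            f"{path}: experiment={experiment!r} must be one of {EXPERIMENTS}"
        )

    preset_name = doc.get("preset", "baseline_sec3")
    bundle = preset(preset_name)  # raises on unknown preset
    params = bundle.params
    initial = bundle.initial

    overrides = doc.get("params") or {}
    if not isinstance(overrides, dict):
        raise ConfigError(f"{path}: 'params' must be a mapping")
    try:
        params = params.replace(**{k: float(v) for k, v in overrides.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: params: {exc}") from exc

    init_over = doc.get("initial") or {}
    if not isinstance(init_over, dict):
        raise ConfigError(f"{path}: 'initial' must be a mapping")
    if init_over:
        bad = sorted(set(init_over) - {"S", "O", "P", "U"})
        if bad:
            raise ConfigError(f"{path}: initial: unknown compartment(s) {bad}")
        merged = {c: float(init_over.get(c, getattr(initial, c)))
                  for c in "SOPU"}
        try:
            initial = PopulationState(**merged).validate()
        except ValueError as exc:
            raise ConfigError(f"{path}: initial: {exc}") from exc

    variant = doc.get("variant", "full")
    if variant not in ("full", "reduced"):
        raise ConfigError(f"{path}: variant={variant!r}")

    grid = doc.get("grid")
    if grid is not None:
        grid = tuple(float(v) for v in grid)

    cfg = RunConfig(
        experiment=experiment,
        preset=preset_name,
        params=params,
        initial=initial,
        variant=variant,
        dt=float(doc.get("dt", DEFAULT_DT)),
        t_end=float(doc.get("t_end", DEFAULT_T_END)),
        out_dir=Path(doc.get("out_dir", "runs")),
        quantity=doc.get("quantity"),
        grid=grid,
        target=doc.get("target"),
        resolution=float(doc.get("resolution", 0.005)),
        slope_fraction=float(doc.get("slope_fraction", 0.1)),
        figure_id=doc.get("figure_id"),
    )
    if cfg.dt <= 0 or cfg.t_end <= 0 or cfg.dt > cfg.t_end:
        raise ConfigError(f"{path}: need 0 < dt <= t_end")
    if cfg.experiment == "sweep" and (cfg.quantity is None or cfg.grid is None):
        raise ConfigError(f"{path}: sweep requires 'quantity' and 'grid'")
    if cfg.experiment == "figure" and cfg.figure_id is None:
        raise ConfigError(f"{path}: figure requires 'figure_id'")
    return cfg
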