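"""Configuration handling, run manifests and serialization.

Conventions: long-format CSV (one observation per row), UTF-8, '.' decimal
separator.  Every output directory gets a ``manifest.json`` recording the
command, resolved parameters, master seed, package version and the files
written — enough to reproduce any artifact exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import yaml

from matesim.experiments import SweepResult, Trajectory
from matesim.lattice import Grid, LatticeConfig, SimParams

__all__ = [
    "ConfigError",
    "load_config",
    "params_from_config",
    "RunManifest",
    "write_trajectory_csv",
    "write_sweep_csv",
    "write_grid_text",
    "write_grid_png",
    "write_heatmap_png",
]

#: flat configuration keys accepted by config files and CLI overrides
CONFIG_KEYS = {
    "side_length": int,
    "boundary": str,
    "density": float,
    "growth_chance": float,
    "switching_cost": float,
    "intraclonal_cost": float,
    "mating_mode": str,
    "max_transfers": int,
    "initial_switcher_freq": float,
    "seed": int,
    "max_growth_rounds": int,
    "phase_rule": str,
}

_LATTICE_KEYS = ("side_length", "boundary", "density")


class ConfigError(ValueError):
    """Malformed configuration file or unknown/ill-typed key."""


def load_config(path) -> Dict[str, Any]:
    """Load a YAML or JSON config file into a validated flat dict.

    Unknown keys are rejected by name; values are coerced to the declared
    type (a type mismatch raises).  An empty file yields an empty dict (pure
    defaults downstream).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return validate_config(raw)


def validate_config(raw: Dict[str, Any]) -> Dict[str, Any]:
    out: Dict[str, Any] = {}
    for key, value in raw.items():
        if key not in CONFIG_KEYS:
            raise ConfigError(f"unknown configuration key {key!r}")
        if value is None:
            out[key] = None
            continue
        typ = CONFIG_KEYS[key]
        if typ is float and isinstance(value, (int, float)) and not isinstance(value, bool):
            out[key] = float(value)
        elif typ is int and isinstance(value, int) and not isinstance(value, bool):
            out[key] = int(value)
        elif typ is str and isinstance(value, str):
            out[key] = value
        else:
            raise ConfigError(
                f"configuration key {key!r} expects {typ.__name__}, got {value!r}"
            )
    return out


def params_from_config(
    config: Optional[Dict[str, Any]] = None, overrides: Optional[Dict[str, Any]] = None
) -> SimParams:
    """Resolve SimParams with precedence defaults < config file < overrides
    (CLI flags)."""
    merged: Dict[str, Any] = {}
    for layer in (config or {}, overrides or {}):
        for k, v in validate_config({k: v for k, v in layer.items() if v is not None}).items():
            merged[k] = v
    lat_kwargs = {k: merged.pop(k) for k in list(merged) if k in _LATTICE_KEYS}
    return SimParams(lattice=LatticeConfig(**lat_kwargs), **merged)


@dataclass
class RunManifest:
    """Reproducibility record written alongside every output set."""

    command: str
    parameters: Dict[str, Any]
    seed: Optional[int]
    version: str
    created: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))
    outputs: List[str] = field(default_factory=list)

    def write(self, directory) -> Path:
        path = Path(directory) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")
        return path

    @classmethod
    def read(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def params_to_dict(params: SimParams) -> Dict[str, Any]:
    d = dataclasses.asdict(params)
    lat = d.pop("lattice")
    d.update(lat)
    return d


def write_trajectory_csv(traj: Trajectory, path) -> Path:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False)
    return path


def write_sweep_csv(sweep: SweepResult, path) -> Path:
    """Long-format sweep endpoints: one replicate per row."""
    path = Path(path)
    cols = [
        "density",
        "cost",
        "replicate",
        "final_nonswitcher_ratio",
        "termination",
        "transfers",
        "seed",
    ]
    sweep.long[cols].to_csv(path, index=False)
    return path


def write_grid_text(grid: Grid, path) -> List[Path]:
    """Plain-text snapshot: coded matrix (0 empty, 1 P-switcher, 2 M-switcher,
    3 P-non-switcher, 4 M-non-switcher) plus a companion 0/1 mated matrix at
    ``<stem>.mated.txt``."""
    path = Path(path)
    np.savetxt(path, grid.to_coded_matrix(), fmt="%d")
    mated_path = path.with_suffix(".mated.txt")
    np.savetxt(mated_path, grid.mated_matrix(), fmt="%d")
    return [path, mated_path]


#: snapshot palette: empty, P-switcher, M-switcher, P-non-switcher,
#: M-non-switcher (warm hues for switchers, blues for non-switchers)
GRID_COLORS = ["#ffffff", "#d62728", "#ff7f0e", "#9ecae1", "#08519c"]


def write_grid_png(grid: Grid, path, show_mated: bool = False) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import pyplot as plt
    from matplotlib.colors import ListedColormap

    coded = grid.to_coded_matrix()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(coded, cmap=ListedColormap(GRID_COLORS), vmin=0, vmax=4, interpolation="nearest")
    if show_mated:
        ys, xs = np.nonzero(grid.mated_matrix())
        ax.plot(xs, ys, ".", color="black", markersize=1.5, alpha=0.6)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def write_heatmap_png(summary, path) -> Path:
    """Render a density × cost heat map (mean final non-switcher ratio, dot
    size ∝ SD) from an invasion-sweep summary table."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import pyplot as plt

    pivot = summary.pivot(index="density", columns="cost", values="mean_final_nonswitcher_ratio")
    sds = summary.pivot(index="density", columns="cost", values="sd")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        pivot.values, origin="lower", aspect="auto", cmap="RdBu_r", vmin=0.0, vmax=1.0
    )
    for yi, d in enumerate(pivot.index):
        for xi, c in enumerate(pivot.columns):
            sd = sds.loc[d, c]
            if np.isfinite(sd) and sd > 0:
                ax.plot(xi, yi, "o", color="black", markersize=2 + 20 * sd)
    ax.set_xticks(range(len(pivot.columns)), [f"{c:g}" for c in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{d:g}" for d in pivot.index])
    ax.set_xlabel("cost of switching s")
    ax.set_ylabel("population density")
    fig.colorbar(im, ax=ax, label="mean final non-switcher ratio")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
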