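"""Dataset, configuration and result I/O.

Datasets are flat CSV with a leading ``time`` column and one column per
observed species, plus a JSON sidecar (``<path>.meta.json``) recording the
seed, noise law, true parameters and model name so that synthetic datasets
round-trip losslessly.  Run configurations are YAML with strict schema
validation: unknown keys are rejected fail-fast with their key path.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .data import TimeSeriesDataset
from .models import get_model
from .optimize import EFAConfig

__all__ = [
    "read_dataset",
    "write_dataset",
    "RunConfig",
    "load_config",
    "dump_config",
    "write_trace",
]

_SIDECAR_SUFFIX = ".meta.json"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + _SIDECAR_SUFFIX)


def write_dataset(dataset: TimeSeriesDataset, path: str | Path) -> None:
    """Write CSV (+ JSON metadata sidecar); lossless at 17 significant digits."""
    path = Path(path)
    frame = pd.DataFrame(
        np.column_stack([dataset.times, dataset.observations]),
        columns=["time", *dataset.species],
    )
    frame.to_csv(path, index=False, float_format="%.17g")
    meta: dict[str, Any] = {
        "species": list(dataset.species),
        "seed": dataset.seed,
        "source": dataset.source,
        "noise_sd": None if dataset.noise_sd is None else dataset.noise_sd.tolist(),
        "real_variance": (
            None if dataset.real_variance is None else dataset.real_variance.tolist()
        ),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_dataset(path: str | Path, species: list[str] | None = None) -> TimeSeriesDataset:
    """Read a dataset CSV, re-aligning species columns by header name.

    ``species`` optionally fixes the column order expected by a model;
    otherwise the file's own order (after ``time``) is kept.  Non-monotone
    time raises a format error naming the offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if list(frame.columns).count("time") != 1 or frame.columns[0] != "time":
        raise ValueError(f"{path}: first column must be a single 'time' header")
    if len(set(frame.columns)) != len(frame.columns):
        raise ValueError(f"{path}: duplicate column headers")
    times = frame["time"].to_numpy(float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        # +2: one for the header line, one for the 0-based diff offset
        raise ValueError(f"{path}: non-increasing time at data row {bad[0] + 2}")
    cols = species if species is not None else [c for c in frame.columns if c != "time"]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing species columns {missing}")
    observations = frame[cols].to_numpy(float)

    noise_sd = real_variance = source = None
    seed = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        order = [meta["species"].index(c) for c in cols]
        if meta.get("noise_sd") is not None:
            noise_sd = np.asarray(meta["noise_sd"], float)[order]
        if meta.get("real_variance") is not None:
            real_variance = np.asarray(meta["real_variance"], float)[order]
        source = meta.get("source")
        seed = meta.get("seed")
    return TimeSeriesDataset(
        times=times,
        observations=observations,
        species=tuple(cols),
        noise_sd=noise_sd,
        real_variance=real_variance,
        source=source,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_OPTIMIZER_KEYS = {
    "algorithm", "np_size", "max_iter", "beta0", "phi", "alpha", "mr", "cr",
    "potential_fraction", "weak_width", "fitness_threshold", "eval_mode", "seed",
}
_DATA_KEYS = {"path", "noise_level", "n_points", "seed"}
_TOP_KEYS = {"model", "bounds", "optimizer", "data", "identifiability", "output_dir"}


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration for the CLI pipeline."""

    model: str
    optimizer: EFAConfig
    algorithm: str = "efa"
    data_path: str | None = None
    noise_level: float = 0.25
    n_points: int = 100
    data_seed: int = 0
    gamma: float = 0.95
    output_dir: str = "."


def _reject_unknown(section: dict, allowed: set[str], prefix: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"unknown configuration key {prefix}{key}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, filling defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "")
    if "model" not in raw:
        raise ValueError("missing required key: model")
    model_name = raw["model"]
    spec, _ = get_model(model_name)  # raises KeyError for unknown models

    bounds = raw.get("bounds")
    bounds = spec.default_bounds if bounds is None else np.asarray(bounds, float)

    opt_raw = dict(raw.get("optimizer") or {})
    _reject_unknown(opt_raw, _OPTIMIZER_KEYS, "optimizer.")
    algorithm = opt_raw.pop("algorithm", "efa")
    if algorithm not in ("efa", "fa"):
        raise ValueError("optimizer.algorithm must be 'efa' or 'fa'")
    optimizer = EFAConfig(bounds=bounds, **opt_raw)

    data_raw = dict(raw.get("data") or {})
    _reject_unknown(data_raw, _DATA_KEYS, "data.")

    ident_raw = dict(raw.get("identifiability") or {})
    _reject_unknown(ident_raw, {"gamma"}, "identifiability.")
    gamma = float(ident_raw.get("gamma", 0.95))
    if not (0.0 < gamma < 1.0):
        raise ValueError("identifiability.gamma must lie strictly in (0, 1)")

    return RunConfig(
        model=model_name,
        optimizer=optimizer,
        algorithm=algorithm,
        data_path=data_raw.get("path"),
        noise_level=float(data_raw.get("noise_level", 0.25)),
        n_points=int(data_raw.get("n_points", 100)),
        data_seed=int(data_raw.get("seed", 0)),
        gamma=gamma,
        output_dir=str(raw.get("output_dir", ".")),
    )


def dump_config(config: RunConfig) -> dict:
    """Canonical dictionary form of a run configuration (YAML-serializable).

    ``load_config`` of the dumped form reproduces the configuration, so
    write-then-load is idempotent.
    """
    opt = config.optimizer
    return {
        "model": config.model,
        "bounds": np.asarray(opt.bounds, float).tolist(),
        "optimizer": {
            "algorithm": config.algorithm,
            "np_size": opt.np_size,
            "max_iter": opt.max_iter,
            "beta0": opt.beta0,
            "phi": opt.phi,
            "alpha": opt.alpha,
            "mr": opt.mr,
            "cr": opt.cr,
            "potential_fraction": opt.potential_fraction,
            "weak_width": opt.weak_width,
            "fitness_threshold": opt.fitness_threshold,
            "eval_mode": opt.eval_mode,
            "seed": opt.seed,
        },
        "data": {
            "path": config.data_path,
            "noise_level": config.noise_level,
            "n_points": config.n_points,
            "seed": config.data_seed,
        },
        "identifiability": {"gamma": config.gamma},
        "output_dir": config.output_dir,
    }


def write_trace(trace: np.ndarray, evaluations: int, path: str | Path) -> None:
    """Per-iteration best-fitness trace as CSV (iteration, best_fitness)."""
    frame = pd.DataFrame(
        {"iteration": np.arange(1, len(trace) + 1), "best_fitness": trace}
    )
    frame.attrs["evaluations"] = evaluations
    frame.to_csv(path, index=False, float_format="%.17g")
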