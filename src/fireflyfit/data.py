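"""Synthetic time-series generation with the study's measurement model.

Observations are the model output sampled on a time grid, superimposed with
uncorrelated Gaussian noise.  "25% white Gaussian noise" is realized as a
per-species standard deviation of 0.25 times the RMS of that species'
noiseless trajectory, constant in time — a homoscedastic per-species noise
law, which is what yields a single real variance per species for the
identifiability test.  Negative noisy concentrations are kept as drawn
(no truncation); the choice is recorded in the dataset metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .models import ModelSpec, Trajectory, integrate_model

__all__ = ["TimeSeriesDataset", "noise_scale", "generate_dataset", "default_grid"]


@dataclass
class TimeSeriesDataset:
    """Sampled observations of a subset of species, with noise bookkeeping.

    ``real_variance`` is the per-species sample variance of the realized
    noise (observations minus the noiseless trajectory) — the quantity the
    study protocol computes "from the noisy experimental data" and feeds to
    the chi-square identifiability test.  ``noise_sd`` is the nominal noise
    law; both are recorded for synthetic data, neither for imported data.
    """

    times: np.ndarray
    observations: np.ndarray  # (N, K)
    species: tuple[str, ...]
    noise_sd: np.ndarray | None = None  # (K,) nominal sd
    real_variance: np.ndarray | None = None  # (K,) realized noise variance
    source: dict[str, Any] | None = None  # model name, true params, noise level
    seed: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.observations = np.asarray(self.observations, float)
        self.species = tuple(self.species)
        if self.noise_sd is not None:
            self.noise_sd = np.asarray(self.noise_sd, float)
        if self.real_variance is not None:
            self.real_variance = np.asarray(self.real_variance, float)
        if self.times.size < 2:
            raise ValueError("a dataset needs at least two sampling times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.observations.shape != (self.times.size, len(self.species)):
            raise ValueError(
                f"observations shape {self.observations.shape} does not match "
                f"{self.times.size} times x {len(self.species)} species"
            )
        if not np.all(np.isfinite(self.observations)):
            raise ValueError("observations contain non-finite values")
        if self.noise_sd is not None and np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def n_species(self) -> int:
        return len(self.species)


def default_grid(model: ModelSpec, n_points: int = 100) -> np.ndarray:
    """Equally spaced sampling grid over the model's default horizon.

    The grid starts just above zero so that the first sample is an actual
    measurement rather than the known initial condition.
    """
    h = model.default_horizon
    return np.linspace(h / n_points, h, n_points)


def noise_scale(trajectory: Trajectory, level: float) -> np.ndarray:
    """Per-species noise standard deviation: ``level`` x RMS of the signal.

    Constant over time within a species, so each species has a single
    noise variance sigma_k^2 = (level * RMS_k)^2.
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if trajectory.states.size == 0:
        raise ValueError("empty trajectory")
    return level * np.sqrt(np.mean(trajectory.states**2, axis=0))


def generate_dataset(
    model: ModelSpec,
    params: np.ndarray,
    times: np.ndarray | None = None,
    *,
    level: float = 0.25,
    seed: int = 0,
    n_points: int = 100,
) -> TimeSeriesDataset:
    """Simulate ``model`` at ``params`` and superimpose Gaussian noise.

    ``y[n, k] = s_hat[n, k] + eps[n, k]`` with ``eps`` i.i.d. Gaussian of
    standard deviation ``sigma_k`` from :func:`noise_scale`.  Identical
    seeds give identical datasets.
    """
    if times is None:
        times = default_grid(model, n_points)
    traj = integrate_model(model, params, np.asarray(times, float))
    sd = noise_scale(traj, level)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(traj.states.shape) * sd
    observations = traj.states + eps
    real_variance = np.mean(eps**2, axis=0)
    return TimeSeriesDataset(
        times=traj.times,
        observations=observations,
        species=model.observed_names,
        noise_sd=sd,
        real_variance=real_variance,
        source={
            "model": model.name,
            "true_params": np.asarray(params, float).tolist(),
            "noise_level": float(level),
            "truncated_negative": False,
        },
        seed=seed,
    )
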