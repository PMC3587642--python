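"""The nonlinear least-squares fitness J(x) minimized by every optimizer.

J(x) is the plain sum of squared residuals between the dataset and the
model prediction over all sampling times and observed species — no
normalization by N and no per-species weighting by default.  Failed
integrations are mapped to +inf so that population-based optimizers simply
discard the offending candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TimeSeriesDataset
from .models import IntegrationError, ModelSpec, integrate_model

__all__ = ["Objective", "evaluate_fitness"]


@dataclass
class Objective:
    """Callable fitness J(x) with evaluation counting and parameter masking.

    ``free`` selects which parameter indices the optimizer varies; the
    remaining entries are clamped to ``template``.  With ``free=None`` the
    full vector is free.  ``weights`` optionally scales each species'
    squared-residual contribution (default: all ones).
    """

    model: ModelSpec
    data: TimeSeriesDataset
    free: np.ndarray | None = None  # indices into the full parameter vector
    template: np.ndarray | None = None  # full-length clamp values
    weights: np.ndarray | None = None
    rtol: float = 1e-8
    atol: float = 1e-10
    evaluations: int = 0

    def __post_init__(self):
        if tuple(self.data.species) != self.model.observed_names:
            raise ValueError(
                f"dataset species {self.data.species} do not match model "
                f"observed species {self.model.observed_names}"
            )
        if self.free is not None:
            self.free = np.asarray(self.free, int)
            if self.template is None:
                raise ValueError("free-index masking requires a template vector")
            self.template = np.asarray(self.template, float)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            if self.weights.shape != (self.data.n_species,):
                raise ValueError("weights must have one entry per observed species")

    @property
    def n_free(self) -> int:
        return self.model.n_params if self.free is None else len(self.free)

    def full_params(self, x: np.ndarray) -> np.ndarray:
        """Expand an optimizer vector to the full model parameter vector."""
        x = np.asarray(x, float)
        if self.free is None:
            return x
        full = np.array(self.template, copy=True)
        full[self.free] = x
        return full

    def bounds(self, bounds: np.ndarray | None = None) -> np.ndarray:
        """Search bounds for the free parameters (defaults from the model)."""
        b = self.model.default_bounds if bounds is None else np.asarray(bounds, float)
        if b.shape == (self.n_free, 2):
            return b
        return b[self.free] if self.free is not None else b

    def __call__(self, x: np.ndarray) -> float:
        self.evaluations += 1
        params = self.full_params(x)
        try:
            traj = integrate_model(
                self.model, params, self.data.times, rtol=self.rtol, atol=self.atol
            )
        except IntegrationError:
            return np.inf
        resid2 = (self.data.observations - traj.states) ** 2
        if self.weights is not None:
            resid2 = resid2 * self.weights
        value = float(np.sum(resid2))
        return value if np.isfinite(value) else np.inf


def evaluate_fitness(
    params: np.ndarray, model: ModelSpec, data: TimeSeriesDataset
) -> float:
    """One-shot J(params) without evaluation bookkeeping."""
    return Objective(model, data)(params)
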