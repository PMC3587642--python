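"""Model selection: chi-square identifiability verdict plus per-species AIC.

Candidate model variants fitted on the *same* dataset are ranked with the
Gaussian-noise Akaike Information Criterion,

    AIC = N ln(RS / N) + 2 M,

computed per observed species (RS = residual sum of squares for that
species, M = the model's full parameter count), alongside the chi-square
variance test.  The selection rule: among candidates passing the test,
pick the smallest summed AIC; if no candidate passes, report that no
adequate model was found.  Candidates are nevertheless totally ordered —
passers first, then ascending summed AIC — so a ranking exists even when
every candidate fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import TimeSeriesDataset
from .identify import VarianceReport, compute_residuals, identifiability_report, model_passes
from .models import ModelSpec

__all__ = ["ModelScore", "compute_aic", "compare_models", "format_selection"]


@dataclass
class ModelScore:
    """Per-candidate selection summary."""

    name: str
    rs: np.ndarray  # per-species residual sum of squares
    aic: np.ndarray  # per-species AIC
    reports: list[VarianceReport]
    passed: bool
    params: np.ndarray

    @property
    def total_aic(self) -> float:
        return float(np.sum(self.aic))

    def to_dict(self) -> dict:
        return {
            "model": self.name,
            "rs": self.rs.tolist(),
            "aic": self.aic.tolist(),
            "total_aic": self.total_aic,
            "passed": self.passed,
            "species": [r.to_dict() for r in self.reports],
            "params": self.params.tolist(),
        }


def compute_aic(rs: float, n: int, m: int) -> float:
    """Gaussian-noise AIC = N ln(RS/N) + 2M; smaller is better."""
    if rs <= 0:
        raise ValueError("residual sum of squares must be positive "
                         "(a perfect fit has no finite AIC)")
    if n < 1 or m < 0:
        raise ValueError("need n >= 1 samples and m >= 0 parameters")
    return float(n * math.log(rs / n) + 2 * m)


def compare_models(
    candidates: list[tuple[ModelSpec, np.ndarray]],
    data: TimeSeriesDataset,
    *,
    gamma: float = 0.95,
    real_variance: np.ndarray | None = None,
) -> tuple[list[ModelScore], ModelScore | None]:
    """Score and rank fitted candidates on one shared dataset.

    Returns the ranked score list (chi-square passers first, then ascending
    summed AIC; deterministic) and the selected candidate, or ``None``
    when no candidate passes the identifiability test.
    """
    if len(candidates) < 2:
        raise ValueError("model selection needs at least two candidates")
    scores = []
    for spec, params in candidates:
        if spec.observed_names != tuple(data.species):
            raise ValueError(
                f"candidate {spec.name!r} observes {spec.observed_names}, "
                f"dataset has {tuple(data.species)}"
            )
        residuals = compute_residuals(params, spec, data)
        rs = np.sum(residuals**2, axis=0)
        aic = np.array(
            [compute_aic(float(r), data.n_samples, spec.n_params) for r in rs]
        )
        reports = identifiability_report(
            params, spec, data, gamma=gamma, real_variance=real_variance
        )
        scores.append(
            ModelScore(
                name=spec.name,
                rs=rs,
                aic=aic,
                reports=reports,
                passed=model_passes(reports),
                params=np.asarray(params, float),
            )
        )
    ranked = sorted(scores, key=lambda s: (not s.passed, s.total_aic, s.name))
    selected = ranked[0] if ranked[0].passed else None
    return ranked, selected


def format_selection(ranked: list[ModelScore]) -> str:
    """Table mirroring the study's selection layout, one block per model."""
    lines = []
    species = [r.species for r in ranked[0].reports]
    lines.append(f"{'':12s}{'':18s}" + "".join(f"{s:>26s}" for s in species))
    if all(r.real_variance is not None for r in ranked[0].reports):
        lines.append(
            f"{'':12s}{'Real Variance':18s}"
            + "".join(f"{r.real_variance:>26.3e}" for r in ranked[0].reports)
        )
    for score in ranked:
        lines.append(
            f"{score.name:12s}{'Point':18s}"
            + "".join(f"{r.variance_point:>26.3e}" for r in score.reports)
        )
        lines.append(
            f"{'':12s}{'Interval':18s}"
            + "".join(
                f"  [{r.interval[0]:.3e}, {r.interval[1]:.3e}]" for r in score.reports
            )
        )
        lines.append(
            f"{'':12s}{'AIC':18s}" + "".join(f"{a:>26.3e}" for a in score.aic)
        )
        lines.append(
            f"{'':12s}{'Chi2 Test':18s}{'Pass' if score.passed else 'Fail':>26s}"
        )
    return "\n".join(lines)
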