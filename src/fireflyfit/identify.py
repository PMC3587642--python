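"""A-posteriori practical-identifiability test via chi-square variance intervals.

After fitting, the residuals between data and the fitted model prediction
estimate the measurement noise.  Per observed species k, the variance point

    xi_k = (1/N) * sum_n resid_nk^2

is compared against the real noise variance sigma_k^2 through the
equal-tails chi-square interval for a Gaussian variance:

    [ N xi_k / chi2_{N, 1 - delta/2},  N xi_k / chi2_{N, delta/2} ]

with delta = 1 - gamma.  If sigma_k^2 falls outside the interval, the data
could not plausibly have been produced by the fitted parameters, and the
estimate is rejected with confidence 100*gamma%.  The default confidence
level is gamma = 0.95.  A model-level verdict passes only if every
observed species passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import TimeSeriesDataset
from .models import ModelSpec, integrate_model

__all__ = [
    "VarianceReport",
    "compute_residuals",
    "variance_point",
    "variance_interval",
    "chi2_identifiability_test",
    "identifiability_report",
    "format_report",
]

DEFAULT_GAMMA = 0.95


@dataclass(frozen=True)
class VarianceReport:
    """Per-species outcome of the chi-square identifiability test."""

    species: str
    variance_point: float
    interval: tuple[float, float]
    gamma: float
    n_samples: int
    chi2_quantiles: tuple[float, float]  # (upper-tail, lower-tail) divisors
    real_variance: float | None = None
    passed: bool | None = None

    @property
    def delta(self) -> float:
        return 1.0 - self.gamma

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "real_variance": self.real_variance,
            "variance_point": self.variance_point,
            "interval": list(self.interval),
            "gamma": self.gamma,
            "n_samples": self.n_samples,
            "passed": self.passed,
        }


def compute_residuals(
    params: np.ndarray, model: ModelSpec, data: TimeSeriesDataset
) -> np.ndarray:
    """Residual matrix eps_hat[n, k] = y[n, k] - y_hat[n, k].

    Integration failures propagate: the test is only meaningful for a
    successfully simulated fit.
    """
    traj = integrate_model(model, params, data.times)
    return data.observations - traj.states


def variance_point(residuals: np.ndarray) -> float:
    """xi = (1/N) * sum of squared residuals for one species."""
    residuals = np.asarray(residuals, float)
    if residuals.size < 2:
        raise ValueError("variance point needs at least two residuals")
    return float(np.mean(residuals**2))


def variance_interval(xi: float, n: int, gamma: float = DEFAULT_GAMMA) -> tuple[float, float]:
    """Equal-tails chi-square confidence interval for the noise variance.

    lower = N xi / chi2_{N, 1-delta/2}, upper = N xi / chi2_{N, delta/2};
    always lower <= xi <= upper, and width -> 0 as N -> infinity.
    """
    if n < 2:
        raise ValueError("interval needs at least two samples")
    if not (0.0 < gamma < 1.0):
        raise ValueError("gamma must lie strictly in (0, 1)")
    if xi < 0:
        raise ValueError("variance point must be non-negative")
    delta = 1.0 - gamma
    q_hi = stats.chi2.ppf(1.0 - delta / 2.0, df=n)
    q_lo = stats.chi2.ppf(delta / 2.0, df=n)
    return (n * xi / q_hi, n * xi / q_lo)


def chi2_identifiability_test(
    xi: float, interval: tuple[float, float], sigma2_real: float
) -> bool:
    """Pass iff the real variance lies inside the interval (inclusive)."""
    lower, upper = interval
    if not (0.0 <= lower <= upper):
        raise ValueError("malformed variance interval")
    return bool(lower <= sigma2_real <= upper)


def identifiability_report(
    params: np.ndarray,
    model: ModelSpec,
    data: TimeSeriesDataset,
    *,
    gamma: float = DEFAULT_GAMMA,
    real_variance: np.ndarray | None = None,
    ddof_correction: bool = False,
) -> list[VarianceReport]:
    """Run the full test for every observed species.

    ``real_variance`` defaults to the dataset's recorded realized noise
    variance (available for synthetic data).  With ``ddof_correction`` the
    variance point divides by N - M instead of N (off by default).
    """
    residuals = compute_residuals(params, model, data)
    n = data.n_samples
    if real_variance is None:
        real_variance = data.real_variance
    delta = 1.0 - gamma
    quantiles = (
        float(stats.chi2.ppf(1.0 - delta / 2.0, df=n)),
        float(stats.chi2.ppf(delta / 2.0, df=n)),
    )
    reports = []
    for k, species in enumerate(data.species):
        xi = variance_point(residuals[:, k])
        if ddof_correction:
            xi *= n / max(n - model.n_params, 1)
        interval = variance_interval(xi, n, gamma)
        sigma2 = None if real_variance is None else float(real_variance[k])
        passed = None
        if sigma2 is not None:
            passed = chi2_identifiability_test(xi, interval, sigma2)
        reports.append(
            VarianceReport(
                species=species,
                variance_point=xi,
                interval=interval,
                gamma=gamma,
                n_samples=n,
                chi2_quantiles=quantiles,
                real_variance=sigma2,
                passed=passed,
            )
        )
    return reports


def model_passes(reports: list[VarianceReport]) -> bool:
    """Model-level verdict: every observed species must pass."""
    return all(r.passed for r in reports)


def format_report(reports: list[VarianceReport]) -> str:
    """Human-readable table: real variance, point, interval, verdict."""
    lines = []
    header = f"{'':24s}" + "".join(f"{r.species:>24s}" for r in reports)
    lines.append(header)
    if all(r.real_variance is not None for r in reports):
        lines.append(
            f"{'Real Variance':24s}"
            + "".join(f"{r.real_variance:>24.3e}" for r in reports)
        )
    lines.append(
        f"{'Variance Point':24s}" + "".join(f"{r.variance_point:>24.3e}" for r in reports)
    )
    lines.append(
        f"{'Variance Interval':24s}"
        + "".join(f"  [{r.interval[0]:.3e}, {r.interval[1]:.3e}]" for r in reports)
    )
    if all(r.passed is not None for r in reports):
        verdict = "Pass" if model_passes(reports) else "Fail"
        lines.append(f"{'Chi2 Test':24s}{verdict:>24s}")
    return "\n".join(lines)
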