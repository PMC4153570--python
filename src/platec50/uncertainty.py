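"""Bootstrap confidence intervals, goodness of fit, and geometric-mean
aggregation of IC50s across independent assays.

The bootstrap is semi-parametric (residual resampling): fit the model once,
keep the fitted values, resample the residuals with replacement, rebuild
pseudo-responses fitted + resampled residual, refit, and record the IC50 of
each replicate.  The 95% CI is the (2.5, 97.5) percentile interval of the
successful replicates.  Residuals are resampled globally rather than within
each dose — with only three wells per dose, per-dose resampling would draw
from three values and badly understate variability.

Raw residuals from a p-parameter fit on n points understate the noise: the
i-th residual has variance (1 - h_ii) of the true noise variance, where
h_ii is the fit's leverage at that point.  The resampling pool therefore
uses modified residuals e_i / sqrt(1 - h_ii), centered, when the caller
supplies leverages (or the uniform approximation sqrt(n/(n-p)) when it
supplies only the parameter count).  This is the standard correction of the
residual bootstrap and it matters at microplate sample sizes: n=12, p=3
leaves raw residuals 13% too small in scale on average.

IC50s from repeated independent assays are summarized by their geometric
mean, the natural average for a log-normally distributed quantity, with a
t-based CI on the log scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

DEFAULT_B = 1000
DEFAULT_FAILURE_TOLERANCE = 0.2


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate count, seed and percentile pair for the bootstrap CI.

    The same seed and inputs always give bit-identical intervals: resampling
    uses a single generator owned by the run, no global RNG state.
    """

    n_replicates: int = DEFAULT_B
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)
    failure_tolerance: float = DEFAULT_FAILURE_TOLERANCE

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        lo, hi = self.percentiles
        if not 0 < lo < hi < 100:
            raise ValueError("percentiles must satisfy 0 < low < high < 100")

    def to_dict(self) -> dict:
        return {"n_replicates": self.n_replicates, "seed": self.seed,
                "percentiles": list(self.percentiles),
                "failure_tolerance": self.failure_tolerance}


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile CI plus replicate bookkeeping; unpacks as (low, high)."""

    low: float
    high: float
    n_success: int
    n_failed: int

    def __iter__(self):
        return iter((self.low, self.high))

    def to_dict(self) -> dict:
        return {"low": self.low, "high": self.high,
                "n_success": self.n_success, "n_failed": self.n_failed}


def bootstrap_ci(
    points: Sequence[tuple[float, float]],
    fit_and_extract: Callable[[list[tuple[float, float]]], tuple[float | None, np.ndarray]],
    config: BootstrapConfig = BootstrapConfig(),
    n_params: int | None = None,
    leverages: Sequence[float] | None = None,
) -> BootstrapResult | None:
    """Semi-parametric bootstrap CI for an IC50-producing fit.

    ``fit_and_extract(points)`` must return ``(ic50, fitted)`` where
    ``fitted`` aligns with ``points``; a refusing fit returns ``ic50=None``.
    The base fit must succeed (precondition).  ``leverages`` (per-point
    h_ii of the base fit) or ``n_params`` (the model's parameter count, for
    the uniform approximation) switch on the modified-residual correction.
    Replicates whose refit fails or refuses are dropped and counted; when
    more than the configured fraction fail the CI is reported absent, with
    a warning.
    """
    points = list(points)
    base_ic50, fitted = fit_and_extract(points)
    if base_ic50 is None:
        raise ValueError("base fit refused; bootstrap requires a successful base fit")
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape != (len(points),):
        raise ValueError("fitted values must align one-to-one with points")

    doses = np.array([d for d, _ in points], dtype=float)
    residuals = np.array([ip for _, ip in points], dtype=float) - fitted
    if leverages is not None:
        h = np.clip(np.asarray(leverages, dtype=float), 0.0, 0.95)
        if h.shape != residuals.shape:
            raise ValueError("leverages must align one-to-one with points")
        residuals = residuals / np.sqrt(1.0 - h)
        residuals = residuals - residuals.mean()
    elif n_params is not None and 0 < n_params < len(points):
        residuals = residuals * math.sqrt(len(points) / (len(points) - n_params))
        residuals = residuals - residuals.mean()

    rng = np.random.default_rng(config.seed)
    n = len(points)
    values: list[float] = []
    n_failed = 0
    for _ in range(config.n_replicates):
        idx = rng.integers(0, n, size=n)
        pseudo = fitted + residuals[idx]
        try:
            ic50, _ = fit_and_extract(list(zip(doses.tolist(), pseudo.tolist())))
        except Exception:
            ic50 = None
        if ic50 is None or not math.isfinite(ic50):
            n_failed += 1
        else:
            values.append(float(ic50))

    if n_failed > config.failure_tolerance * config.n_replicates:
        warnings.warn(
            f"bootstrap CI unavailable: {n_failed}/{config.n_replicates} "
            "replicate refits failed", stacklevel=2)
        return None

    low, high = np.percentile(values, config.percentiles)
    return BootstrapResult(low=float(low), high=float(high),
                           n_success=len(values), n_failed=n_failed)


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float | None:
    """Coefficient of determination 1 - SS_res/SS_tot; None when SS_tot = 0."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return None
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class AggregateEstimate:
    """Geometric mean of IC50s over independent assays, with a t-based CI."""

    geometric_mean: float
    ci_95: tuple[float, float] | None
    n_assays: int

    def to_dict(self) -> dict:
        return {"geometric_mean": self.geometric_mean,
                "ci_95": list(self.ci_95) if self.ci_95 else None,
                "n_assays": self.n_assays}


def geometric_mean_ic50(values: Sequence[float],
                        confidence: float = 0.95) -> AggregateEstimate:
    """exp(mean(ln IC50)) with a Student-t interval on the log scale.

    A single assay yields a point estimate with no CI.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one IC50")
    if np.any(vals <= 0):
        raise ValueError("IC50 values must be positive")
    logs = np.log(vals)
    gm = float(np.exp(logs.mean()))
    if vals.size == 1:
        return AggregateEstimate(geometric_mean=gm, ci_95=None, n_assays=1)
    se = logs.std(ddof=1) / math.sqrt(vals.size)
    t = stats.t.ppf(0.5 + confidence / 2.0, df=vals.size - 1)
    half = t * se
    ci = (float(np.exp(logs.mean() - half)), float(np.exp(logs.mean() + half)))
    return AggregateEstimate(geometric_mean=gm, ci_95=ci, n_assays=int(vals.size))
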