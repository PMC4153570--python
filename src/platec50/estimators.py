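"""IC50 estimation: two-point interpolation, transformed linear regression,
and Hill (logistic) nonlinear regression.

Axis transforms
---------------
The dose axis may be analyzed on a log2, log5, log10 (default) or linear
scale; the inhibition axis on a linear (default), probit, logit or log10
scale.  Probit and logit act on the inhibition *proportion* p = IP/100, so
both map 50% to 0; the log10 y-transform acts on IP as a percent.

Absolute vs relative IC50
-------------------------
Absolute IC50 is the concentration giving 50% inhibition on the
control-defined 0–100% scale.  Relative IC50 is the concentration giving half
of the compound's own maximum attainable inhibition I_max (the upper plateau).
For the zero-baseline Hill curve

    IP(C) = I_max * C^h / (C^h + K^h)

the relative IC50 is exactly the half-maximal concentration K, and the
absolute IC50 solves IP(C) = 50:

    C_abs = K * (50 / (I_max - 50))^(1/h),   defined only when I_max > 50.

The two-point method interpolates between the two adjacent triplicate-mean
inhibitions bracketing 50% (in transformed coordinates) and can only produce
an absolute IC50; it refuses rather than extrapolate or guess, and reports no
confidence interval.  The regression methods fit individual well points: the
linear method only those with 0 < IP < 100, the Hill fit all of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .inhibition import DoseResponseTable

DEFAULT_BAND = (48.0, 52.0)

X_TRANSFORMS = ("log10", "log2", "log5", "linear")
Y_TRANSFORMS = ("linear", "probit", "logit", "log10")

METHODS = ("two_point", "linear", "nonlinear")
IC50_TYPES = ("absolute", "relative")


class TransformDomainError(ValueError):
    """A value lies outside the domain of the requested axis transform."""


class FitError(RuntimeError):
    """The nonlinear optimizer failed to converge after restarts."""


@dataclass(frozen=True)
class TransformSpec:
    """Axis transforms for the x (dose) and y (percent inhibition) axes."""

    x: str = "log10"
    y: str = "linear"

    def __post_init__(self) -> None:
        if self.x not in X_TRANSFORMS:
            raise ValueError(f"unknown x transform {self.x!r}; choose from {X_TRANSFORMS}")
        if self.y not in Y_TRANSFORMS:
            raise ValueError(f"unknown y transform {self.y!r}; choose from {Y_TRANSFORMS}")

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y}


def transform(value, which: str):
    """Apply an axis transform elementwise.

    Log transforms require positive values; probit/logit act on p = value/100
    and require 0 < value < 100.
    """
    v = np.asarray(value, dtype=float)
    if which == "linear":
        out = v
    elif which in ("log10", "log2", "log5"):
        if np.any(v <= 0):
            raise TransformDomainError(f"{which} requires positive values, got {value!r}")
        base = {"log10": 10.0, "log2": 2.0, "log5": 5.0}[which]
        out = np.log(v) / np.log(base)
    elif which == "probit":
        p = v / 100.0
        if np.any((p <= 0) | (p >= 1)):
            raise TransformDomainError(f"probit requires 0 < IP < 100, got {value!r}")
        out = special.ndtri(p)
    elif which == "logit":
        p = v / 100.0
        if np.any((p <= 0) | (p >= 1)):
            raise TransformDomainError(f"logit requires 0 < IP < 100, got {value!r}")
        out = np.log(p / (1.0 - p))
    else:
        raise ValueError(f"unknown transform {which!r}")
    return float(out) if np.isscalar(value) else out


def inverse_transform(value, which: str):
    """Exact inverse of :func:`transform` on its domain."""
    v = np.asarray(value, dtype=float)
    if which == "linear":
        out = v
    elif which in ("log10", "log2", "log5"):
        base = {"log10": 10.0, "log2": 2.0, "log5": 5.0}[which]
        out = np.power(base, v)
    elif which == "probit":
        out = 100.0 * special.ndtr(v)
    elif which == "logit":
        out = 100.0 / (1.0 + np.exp(-v))
    else:
        raise ValueError(f"unknown transform {which!r}")
    return float(out) if np.isscalar(value) else out


@dataclass(frozen=True)
class HillParams:
    """Zero-baseline Hill curve parameters: upper plateau i_max (percent),
    Hill coefficient h (> 0), half-maximal concentration k (dose units)."""

    i_max: float
    h: float
    k: float

    def predict(self, dose):
        dose = np.asarray(dose, dtype=float)
        ch = np.power(dose, self.h)
        out = self.i_max * ch / (ch + self.k ** self.h)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {"i_max": self.i_max, "h": self.h, "k": self.k}


@dataclass(frozen=True)
class TwoPointBracket:
    """The adjacent dose pair whose mean inhibitions straddle 50%."""

    c_lower: float
    c_higher: float
    ip_lower: float
    ip_higher: float


@dataclass
class Ic50Estimate:
    """Result of one estimation attempt on one compound.

    Exactly one of ``value`` and ``refusal_reason`` is set.  ``gof`` is r^2
    for the linear method and R^2 for the nonlinear one; ``ci_95`` is filled
    by the bootstrap for regression methods only.
    """

    method: str
    ic50_type: str
    value: float | None = None
    ci_95: tuple[float, float] | None = None
    gof: float | None = None
    i_max: float | None = None
    refusal_reason: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.ic50_type not in IC50_TYPES:
            raise ValueError(f"unknown ic50_type {self.ic50_type!r}")
        if (self.value is None) == (self.refusal_reason is None):
            raise ValueError("exactly one of value and refusal_reason must be set")
        if self.method == "two_point":
            if self.ic50_type != "absolute":
                raise ValueError("two_point can only estimate absolute IC50")
            if self.ci_95 is not None:
                raise ValueError("two_point reports no confidence interval")

    @property
    def refused(self) -> bool:
        return self.refusal_reason is not None

    def to_dict(self) -> dict:
        return {"method": self.method, "ic50_type": self.ic50_type,
                "value": self.value,
                "ci_95": list(self.ci_95) if self.ci_95 else None,
                "gof": self.gof, "i_max": self.i_max,
                "refusal_reason": self.refusal_reason,
                "extra": dict(self.extra)}


def _refusal(method: str, ic50_type: str, reason: str, **extra) -> Ic50Estimate:
    return Ic50Estimate(method=method, ic50_type=ic50_type,
                        refusal_reason=reason, extra=extra)


# ---------------------------------------------------------------------------
# Two-point method
# ---------------------------------------------------------------------------

def find_bracket(dose_means: list[tuple[float, float]]) -> TwoPointBracket | None:
    """First adjacent pair (doses ascending) whose mean IPs bracket 50%.

    When the means are non-monotone several pairs may bracket; the pair at
    the lowest concentrations is chosen as the conservative first crossing.
    """
    for (c_lo, ip_lo), (c_hi, ip_hi) in zip(dose_means, dose_means[1:]):
        if ip_lo < 50.0 < ip_hi:
            return TwoPointBracket(c_lower=c_lo, c_higher=c_hi,
                                   ip_lower=ip_lo, ip_higher=ip_hi)
    return None


def two_point_ic50(table: DoseResponseTable,
                   transforms: TransformSpec = TransformSpec(),
                   band: tuple[float, float] = DEFAULT_BAND) -> Ic50Estimate:
    """Absolute IC50 by linear interpolation between the two triplicate means
    bracketing 50%, in transformed coordinates.

    Refuses (returning a reasoned estimate, never raising) when no adjacent
    pair brackets 50%, when a bracketing mean sits exactly at 0% or 100%
    (the estimate would be unbounded in uncertainty), or when a bracketing
    mean lies inside the near-50% exclusion band — too small a gradient to
    interpolate reliably; repeat the assay with a narrower dose range.
    """
    method, ic50_type = "two_point", "absolute"
    dose_means = table.dose_means()
    if len(dose_means) < 2:
        return _refusal(method, ic50_type,
                        f"insufficient data: {len(dose_means)} usable dose mean(s)")

    bracket = find_bracket(dose_means)
    if bracket is None:
        return _refusal(method, ic50_type, "no bracket: 50% never reached")

    for ip in (bracket.ip_lower, bracket.ip_higher):
        if ip == 0.0 or ip == 100.0:
            return _refusal(
                method, ic50_type,
                f"bracketing mean at {ip:g}%: estimate too uncertain",
            )
    lo, hi = band
    for ip in (bracket.ip_lower, bracket.ip_higher):
        if lo < ip < hi:
            return _refusal(
                method, ic50_type,
                f"bracketing point inside {lo:g}-{hi:g}% band (mean {ip:.4g}%)",
            )

    try:
        tx_lo = transform(bracket.c_lower, transforms.x)
        tx_hi = transform(bracket.c_higher, transforms.x)
        ty_lo = transform(bracket.ip_lower, transforms.y)
        ty_hi = transform(bracket.ip_higher, transforms.y)
        ty_50 = transform(50.0, transforms.y)
    except TransformDomainError as err:
        return _refusal(method, ic50_type, f"transform domain: {err}")

    frac = (ty_50 - ty_lo) / (ty_hi - ty_lo)
    value = inverse_transform(tx_lo + frac * (tx_hi - tx_lo), transforms.x)
    return Ic50Estimate(method=method, ic50_type=ic50_type, value=float(value),
                        extra={"bracket": {"c_lower": bracket.c_lower,
                                           "c_higher": bracket.c_higher,
                                           "ip_lower": bracket.ip_lower,
                                           "ip_higher": bracket.ip_higher}})


# ---------------------------------------------------------------------------
# Linear regression method
# ---------------------------------------------------------------------------

def _linear_filter(table: DoseResponseTable) -> list[tuple[float, float]]:
    """Individual usable points with 0 < IP < 100 (strict)."""
    return [(p.dose, p.ip) for p in table.usable_points() if 0.0 < p.ip < 100.0]


def linear_ic50(table: DoseResponseTable,
                transforms: TransformSpec = TransformSpec(),
                ic50_type: str = "absolute") -> Ic50Estimate:
    """IC50 from an ordinary least-squares line through the individual well
    points (only those with 0 < IP < 100) in transformed coordinates.

    The absolute IC50 inverts the fitted line at transformed 50%; the
    relative IC50 inverts it at transformed I_max/2, with I_max taken as the
    largest triplicate mean IP in the row (a line has no plateau of its own).
    Refuses on fewer than 3 usable points, a non-increasing fitted slope, or
    a crossing outside the representable dose range.
    """
    method = "linear"
    pts = _linear_filter(table)
    if len(pts) < 3:
        return _refusal(method, ic50_type,
                        f"insufficient data: {len(pts)} point(s) with 0 < IP < 100")

    doses = np.array([d for d, _ in pts])
    ips = np.array([ip for _, ip in pts])
    try:
        tx = transform(doses, transforms.x)
        ty = transform(ips, transforms.y)
    except TransformDomainError as err:
        return _refusal(method, ic50_type, f"transform domain: {err}")

    slope, intercept = np.polyfit(tx, ty, 1)
    ss_tot = float(np.sum((ty - ty.mean()) ** 2))
    ss_res = float(np.sum((ty - (intercept + slope * tx)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None

    if slope <= 0:
        return _refusal(method, ic50_type,
                        f"non-positive slope ({slope:.4g}) in transformed space",
                        slope=float(slope), intercept=float(intercept))

    if ic50_type == "absolute":
        target_ip = 50.0
        i_max = None
    else:
        means = [m for _, m in table.dose_means()]
        i_max = max(means) if means else None
        if i_max is None or i_max <= 0:
            return _refusal(method, ic50_type,
                            "relative IC50 undefined: no positive mean inhibition")
        target_ip = i_max / 2.0

    try:
        ty_target = transform(target_ip, transforms.y)
    except TransformDomainError as err:
        return _refusal(method, ic50_type, f"transform domain: {err}")

    x_cross = (ty_target - intercept) / slope
    with np.errstate(over="ignore"):
        value = inverse_transform(x_cross, transforms.x)
    if not math.isfinite(value) or value <= 0:
        return _refusal(method, ic50_type,
                        "crossing outside representable dose range",
                        slope=float(slope), intercept=float(intercept))

    return Ic50Estimate(method=method, ic50_type=ic50_type, value=float(value),
                        gof=r2, i_max=i_max,
                        extra={"slope": float(slope),
                               "intercept": float(intercept),
                               "n_points": len(pts)})


# ---------------------------------------------------------------------------
# Nonlinear (Hill) regression method
# ---------------------------------------------------------------------------

def _hill_ss(theta: np.ndarray, doses: np.ndarray, ips: np.ndarray) -> float:
    i_max, log_h, log_k = theta
    h = math.exp(log_h)
    k = math.exp(log_k)
    with np.errstate(over="ignore", invalid="ignore"):
        ch = np.power(doses, h)
        pred = i_max * ch / (ch + k ** h)
    resid = ips - pred
    ss = float(np.dot(resid, resid))
    if not math.isfinite(ss):
        return 1e300
    if i_max < 0:  # soft positivity penalty; h, k are positive by construction
        ss += 1e6 * i_max * i_max
    return ss


def default_hill_init(points: list[tuple[float, float]]) -> HillParams:
    """Heuristic start: i_max from the largest per-dose mean IP (clipped to
    [1, 150]), k at the dose whose mean IP is nearest half of that, h = 1."""
    by_dose: dict[float, list[float]] = {}
    for d, ip in points:
        by_dose.setdefault(d, []).append(ip)
    means = {d: float(np.mean(v)) for d, v in by_dose.items()}
    i_max0 = float(np.clip(max(means.values()), 1.0, 150.0))
    k0 = min(means, key=lambda d: abs(means[d] - i_max0 / 2.0))
    return HillParams(i_max=i_max0, h=1.0, k=float(k0))


def hill_fit(points: list[tuple[float, float]],
             init: HillParams | None = None,
             restarts: int = 3,
             xatol: float = 1e-8,
             fatol: float = 1e-8,
             maxiter: int = 2000) -> tuple[HillParams, float | None]:
    """Least-squares fit of the zero-baseline Hill curve by Nelder–Mead.

    h and k are optimized on the log scale so the simplex can never propose
    a non-positive value; i_max is unconstrained with a quadratic penalty
    below zero.  On non-convergence the fit restarts from k scaled by 0.5
    and 2 (and the best converged attempt wins on SS).  Returns the fitted
    parameters and R^2 (None when the points have zero spread, which leaves
    R^2 undefined).

    Raises :class:`FitError` if no attempt converges.
    """
    if len(points) < 4:
        raise ValueError(f"need >=4 points, got {len(points)}")
    doses = np.array([d for d, _ in points], dtype=float)
    ips = np.array([ip for _, ip in points], dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if len(set(doses.tolist())) < 2:
        raise ValueError("need >=2 distinct doses")

    start = init or default_hill_init(points)
    k_factors = [1.0, 0.5, 2.0, 0.25][: 1 + max(0, restarts)]

    options = {"xatol": xatol, "fatol": fatol, "maxiter": maxiter,
               "maxfev": maxiter}

    def _minimize(theta0):
        res = optimize.minimize(_hill_ss, theta0, args=(doses, ips),
                                method="Nelder-Mead", options=options)
        if not res.success:
            # A stalled simplex usually recovers when re-inflated at the
            # current best point; one chained restart rescues nearly all.
            res = optimize.minimize(_hill_ss, res.x, args=(doses, ips),
                                    method="Nelder-Mead", options=options)
        return res

    best = None
    for factor in k_factors:
        theta0 = np.array([start.i_max, math.log(start.h),
                           math.log(start.k * factor)])
        res = _minimize(theta0)
        if res.success and (best is None or res.fun < best.fun):
            best = res
        if best is not None and factor == 1.0 and res.success:
            break  # converged first try; restarts are for rescue only

    if best is None:
        raise FitError(
            f"Nelder-Mead failed to converge after {len(k_factors)} start(s) "
            f"({len(points)} points)")

    i_max, log_h, log_k = best.x
    params = HillParams(i_max=float(i_max), h=float(math.exp(log_h)),
                        k=float(math.exp(log_k)))
    ss_tot = float(np.sum((ips - ips.mean()) ** 2))
    r2 = 1.0 - best.fun / ss_tot if ss_tot > 0 else None
    return params, r2


def hill_leverages(doses, params: HillParams) -> np.ndarray:
    """Hat-matrix diagonal of the Hill fit at its optimum.

    Leverages come from the Jacobian J of the model in (i_max, h, k):
    h_ii = diag(J (J'J)^-1 J'), computed via the thin QR of J.  Used to
    form the modified residuals the bootstrap resamples.
    """
    c = np.asarray(doses, dtype=float)
    u = 1.0 / (1.0 + (params.k / c) ** params.h)  # pred = i_max * u
    d_imax = u
    d_h = params.i_max * u * (1.0 - u) * np.log(c / params.k)
    d_k = -params.i_max * u * (1.0 - u) * params.h / params.k
    J = np.column_stack([d_imax, d_h, d_k])
    q, r = np.linalg.qr(J)
    keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(r).max())
    return (q[:, keep] ** 2).sum(axis=1)


def hill_absolute_ic50(params: HillParams) -> float | None:
    """Dose where the Hill curve crosses 50%; None when i_max <= 50."""
    if params.i_max <= 50.0:
        return None
    return params.k * (50.0 / (params.i_max - 50.0)) ** (1.0 / params.h)


def nonlinear_ic50(table: DoseResponseTable, ic50_type: str = "relative",
                   init: HillParams | None = None,
                   fit_options: dict | None = None) -> Ic50Estimate:
    """IC50 from the Hill fit over *all* usable individual points (the
    0–100% filter does not apply to the nonlinear method).

    Relative IC50 is the fitted half-maximal concentration k; absolute IC50
    solves the curve for 50% and is refused when the plateau never reaches
    50%.  The estimate carries I_max and R^2.
    """
    method = "nonlinear"
    pts = [(p.dose, p.ip) for p in table.usable_points()]
    if len(pts) < 4:
        return _refusal(method, ic50_type,
                        f"insufficient data: {len(pts)} usable point(s), need >=4")
    try:
        params, r2 = hill_fit(pts, init=init, **(fit_options or {}))
    except (FitError, ValueError) as err:
        return _refusal(method, ic50_type, f"fit failure: {err}")

    if ic50_type == "relative":
        value = params.k
    else:
        value = hill_absolute_ic50(params)
        if value is None:
            return _refusal(
                method, ic50_type,
                f"curve never reaches 50% (I_max = {params.i_max:.4g}%)",
                params=params.to_dict(), r2=r2)

    return Ic50Estimate(method=method, ic50_type=ic50_type, value=float(value),
                        gof=r2, i_max=params.i_max,
                        extra={"params": params.to_dict(), "n_points": len(pts)})
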