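"""Richards growth model and quantitative maturity age (QMA).

The Richards sigmoid y(t) = a * (1 - exp(-b t))^c is fitted to volume-age
series; the quantitative maturity age is the stand age at which the mean
annual increment MAI(t) = y(t)/t intersects the current annual increment
CAI(t) = dy/dt (or the backward annual difference, for measured series) —
the classic harvest-age criterion for maximum sustained volume yield.

For the Richards form, MAI = CAI reduces to exp(u) = 1 + c*u with u = b*t,
so the maturity age depends only on the rate b and shape c, never on the
asymptote a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from .standtable import StandTrajectory, ValidationError
from .volume import stand_volume, stand_volume_with_thinned

__all__ = [
    "RichardsParams",
    "FitResult",
    "IncrementSeries",
    "richards",
    "richards_cai",
    "fit_richards",
    "qma_analytic",
    "qma_empirical",
    "volume_series",
    "stand_quantitative_maturity",
]


@dataclass(frozen=True)
class RichardsParams:
    """Richards curve parameters: asymptote a, rate b (1/yr), shape c."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValidationError(f"Richards parameters must be positive, got {self}")


@dataclass
class FitResult:
    params: RichardsParams | None
    r_squared: float
    rmse: float
    converged: bool
    n_points: int


@dataclass
class IncrementSeries:
    """An annual volume-age series with derived MAI and CAI."""

    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.size != self.values.size:
            raise ValidationError("ages and values must have equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValidationError("ages must be strictly increasing")

    @property
    def mai(self) -> np.ndarray:
        return self.values / self.ages

    @property
    def cai(self) -> np.ndarray:
        """Backward first differences; defined from the second age on."""
        return np.diff(self.values) / np.diff(self.ages)


def richards(t, params: RichardsParams):
    """Richards growth curve y = a (1 - e^{-bt})^c."""
    t = np.asarray(t, dtype=float)
    y = params.a * (1.0 - np.exp(-params.b * t)) ** params.c
    return float(y) if y.ndim == 0 else y


def richards_cai(t, params: RichardsParams):
    """Instantaneous current annual increment dy/dt of the Richards curve."""
    t = np.asarray(t, dtype=float)
    e = np.exp(-params.b * t)
    y = params.a * params.b * params.c * e * (1.0 - e) ** (params.c - 1.0)
    return float(y) if y.ndim == 0 else y


_A_STARTS = (1.0, 1.2, 1.5)
_B_STARTS = (0.05, 0.15, 0.3)
_C_STARTS = (1.5, 3.0, 6.0)


def fit_richards(ages, values) -> FitResult:
    """Nonlinear least-squares Richards fit with a 27-point multi-start.

    Starts span a0 in {1.0, 1.2, 1.5} * max(y), b0 in {0.05, 0.15, 0.3} and
    c0 in {1.5, 3, 6}; the best sum of squared residuals is kept.  Absolute
    residuals are minimized on the volume scale.  Non-convergence from every
    start yields a flagged result rather than an exception.
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValidationError(f"Richards fit needs >= 4 points, got {t.size}")
    if np.any(t <= 0) or np.any(y < 0):
        raise ValidationError("ages must be positive and values non-negative")

    def resid(p):
        a, b, c = p
        with np.errstate(over="ignore", invalid="ignore"):
            pred = a * (1.0 - np.exp(-b * t)) ** c
        return pred - y

    ymax = float(y.max())
    best = None
    lb = [1e-9, 1e-9, 1e-9]
    ub = [np.inf, 10.0, 100.0]
    for fa in _A_STARTS:
        for b0 in _B_STARTS:
            for c0 in _C_STARTS:
                x0 = [max(fa * ymax, 1e-6), b0, c0]
                try:
                    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf", max_nfev=2000)
                except Exception:
                    continue
                if not np.all(np.isfinite(sol.x)):
                    continue
                sse = float(np.sum(sol.fun**2))
                if best is None or sse < best[0]:
                    best = (sse, sol)
    if best is None:
        return FitResult(None, -np.inf, np.inf, False, int(t.size))
    sse, sol = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    rmse = math.sqrt(sse / t.size)
    params = RichardsParams(*(float(v) for v in sol.x))
    return FitResult(params, r2, rmse, bool(sol.success), int(t.size))


def qma_analytic(params: RichardsParams) -> float | None:
    """Maturity age where MAI(t) = CAI(t) for the fitted Richards curve.

    Solves exp(u) = 1 + c*u for the positive root u (u = b*t) by bracketed
    root finding.  For c <= 1 the only solution is u = 0: no maturity age
    exists and None is returned.  The result is independent of a.
    """
    c = params.c
    if c <= 1.0:
        return None

    def f(u):
        return math.exp(u) - 1.0 - c * u

    lo = math.log(c)  # minimum of f; f(lo) < 0 for c > 1
    hi = lo + 1.0
    while f(hi) < 0:
        hi *= 2.0
    u = brentq(f, lo, hi, xtol=1e-10, rtol=1e-14)
    return u / params.b


def qma_empirical(series: IncrementSeries) -> int | None:
    """First age at which MAI - CAI changes sign from negative to non-negative.

    CAI is the backward annual difference; the comparison starts at the
    second age.  A series whose first evaluable age already has CAI at or
    below MAI never entered the accelerating phase within the observation
    window, so a "crossing" there is spurious and None is returned.
    """
    if series.ages.size < 3:
        raise ValidationError("empirical QMA needs at least 3 ages")
    ages = series.ages[1:]
    d = series.mai[1:] - series.cai
    seen_negative = False
    for i, (age, di) in enumerate(zip(ages, d)):
        if di < 0:
            seen_negative = True
        elif seen_negative:
            # fractional crossing by linear interpolation between the last
            # negative difference and this one; reported as an integer year
            prev_age, prev_d = ages[i - 1], d[i - 1]
            frac = prev_age + (age - prev_age) * (-prev_d) / (di - prev_d) if di > prev_d else age
            return int(round(frac))
    return None


def volume_series(
    trajectory: StandTrajectory, basis: str = "existing_plus_thinned"
) -> IncrementSeries:
    """Stand-volume series (m3/ha) over all snapshot ages of a trajectory."""
    ages = np.array(trajectory.ages, dtype=float)
    if basis == "existing_plus_thinned":
        vals = np.array([stand_volume_with_thinned(trajectory, int(a)) for a in ages])
    elif basis == "existing":
        vals = np.array([stand_volume(s) for s in trajectory.snapshots])
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return IncrementSeries(ages, vals)


def stand_quantitative_maturity(
    trajectory: StandTrajectory, basis: str = "existing_plus_thinned"
) -> int | None:
    """QMA of a (possibly thinned) stand trajectory.

    The MAI/CAI intersection is sought on the volume series restricted to
    ages at and after the last thinning event, because the maturity of a
    managed stand is a property of the post-treatment growth course; MAI
    itself remains cumulative from planting.  For an unthinned stand the
    full series is used.  A stand whose CAI never re-exceeds MAI after a
    late heavy thinning (or never crosses within the window) returns None.
    """
    series = volume_series(trajectory, basis=basis)
    last = trajectory.last_event_age
    if last is not None:
        mask = series.ages >= last
        if mask.sum() < 3:
            return None
        series = IncrementSeries(series.ages[mask], series.values[mask])
    return qma_empirical(series)
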