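"""Deterministic growth models of cancer progression.

Three nested models of the size ``x(t)`` (cells) of a cluster of mutated
cells:

* **Richards** (generalized logistic): ``dx/dt = nu*r*x - nu*mu*x**((nu+1)/nu)``.
  Two equilibria, extinction ``x=0`` (unstable) and the carrying capacity
  ``K = (r/mu)**nu`` (stable).  Small clusters diverge at rate ``nu*r``; large
  clusters saturate at rate ``r``, so the growth/saturation asymmetry equals
  ``nu``.  No extinction threshold: any positive cluster grows.

* **ERM1** (Volterra-style threshold): Richards with reversed roles of the
  linear and power terms plus a second death term,
  ``dx/dt = -nu^2*r*x*(1-(x/A)**(1/nu))*(1-(x/K)**(1/nu))``.
  Introduces an unstable threshold ``0 < A < K`` below which clusters decay,
  but the asymmetry ratio is ``(A/K)**(1/nu) < 1``: small clusters always grow
  more slowly than large ones saturate, producing step-like trajectories
  unlike real tumour progression.

* **ERM2** (immune-response threshold): Richards minus a constant (or, in the
  complete model, time-varying) immune clearance ``s`` in cells/day, with the
  ``x=0`` state absorbing.  A threshold ``A`` and carrying capacity ``K``
  emerge as the two positive roots of the stationary drift, the asymmetry
  ratio is >= 1 for ``nu >= 1``, and sub-threshold clusters go extinct in
  finite time.

All rates are per day unless the caller chooses other units; the equations
are unit-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "GrowthParams",
    "StabilityReport",
    "DeterministicTrajectory",
    "GrowthConfigError",
    "DomainError",
    "IntegrationError",
    "ApproximationInvalidError",
    "rhs",
    "equilibria",
    "numerical_linearization",
    "erm2_threshold_approx",
    "integrate",
    "first_passage_time",
    "richards_closed_form",
    "asymmetry_curve",
    "OVERFLOW_GUARD",
    "EXTINCTION_FLOOR",
]

#: Abort integration if the population exceeds this many cells.
OVERFLOW_GUARD = 1e15
#: Populations below this many cells are clamped to zero by the integrator.
EXTINCTION_FLOOR = 1e-6

ModelId = Literal["richards", "erm1", "erm2"]


class GrowthConfigError(ValueError):
    """Invalid or inconsistent growth-model parameters."""


class DomainError(ValueError):
    """Input outside the model's domain (e.g. negative population)."""


class IntegrationError(RuntimeError):
    """Numerical integration failed or hit the overflow guard."""


class ApproximationInvalidError(ValueError):
    """The stationary-threshold approximation is not defined here."""


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one growth-model instance.

    Parameters
    ----------
    model_id : {"richards", "erm1", "erm2"}
    nu : float
        Shape parameter (dimensionless, > 0).  ``nu = 1`` is logistic growth,
        ``nu -> inf`` approaches Gompertz.
    r : float
        Per-capita rate scale (1/day, > 0).
    mu : float
        Death (Richards/ERM2) or birth (ERM1) rate parameter,
        1/day/cells**(1/nu), >= 0.
    gamma : float, optional
        Large-population death parameter (ERM1 only, >= 0).
    s : float, optional
        Constant immune response (ERM2 only, cells/day, >= 0).
    """

    model_id: ModelId
    nu: float
    r: float
    mu: float = 0.0
    gamma: float | None = None
    s: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in ("richards", "erm1", "erm2"):
            raise GrowthConfigError(f"unknown model_id {self.model_id!r}")
        if not (self.nu > 0 and math.isfinite(self.nu)):
            raise GrowthConfigError("nu must be finite and > 0")
        if not (self.r > 0 and math.isfinite(self.r)):
            raise GrowthConfigError("r must be finite and > 0")
        if not (self.mu >= 0 and math.isfinite(self.mu)):
            raise GrowthConfigError("mu must be finite and >= 0")
        if self.model_id == "erm1":
            if self.gamma is None:
                raise GrowthConfigError("gamma is required for erm1")
            if not (self.gamma >= 0 and math.isfinite(self.gamma)):
                raise GrowthConfigError("gamma must be finite and >= 0")
        if self.model_id == "erm2":
            if self.s is None:
                raise GrowthConfigError("s is required for erm2")
            if not (self.s >= 0 and math.isfinite(self.s)):
                raise GrowthConfigError("s must be finite and >= 0")

    # ---------------------------------------------------------------- helpers
    @classmethod
    def richards(cls, nu: float, r: float, mu: float) -> "GrowthParams":
        return cls("richards", nu=nu, r=r, mu=mu)

    @classmethod
    def richards_from_capacity(cls, nu: float, r: float, K: float) -> "GrowthParams":
        """Richards parameters with carrying capacity ``K = (r/mu)**nu``."""
        mu = r / K ** (1.0 / nu)
        return cls("richards", nu=nu, r=r, mu=mu)

    @classmethod
    def erm1(cls, nu: float, r: float, mu: float, gamma: float) -> "GrowthParams":
        return cls("erm1", nu=nu, r=r, mu=mu, gamma=gamma)

    @classmethod
    def erm1_from_thresholds(cls, nu: float, r: float, A: float, K: float) -> "GrowthParams":
        """ERM1 parameters from the factorized form with threshold A, capacity K.

        Matching ``-nu^2*r*x*(1-(x/A)**(1/nu))*(1-(x/K)**(1/nu))`` against the
        polynomial form gives ``mu = r*(A**(-1/nu) + K**(-1/nu))`` and
        ``gamma = r*(A*K)**(-1/nu)``.  For ``nu = 1`` this reduces to the
        config-interface conversion ``mu = r*(1/A + 1/K)``, ``gamma = r/(A*K)``.
        """
        if not (0 < A < K):
            raise GrowthConfigError("need 0 < A < K")
        a = A ** (-1.0 / nu)
        k = K ** (-1.0 / nu)
        return cls("erm1", nu=nu, r=r, mu=r * (a + k), gamma=r * a * k)

    @classmethod
    def erm2(cls, nu: float, r: float, mu: float, s: float) -> "GrowthParams":
        return cls("erm2", nu=nu, r=r, mu=mu, s=s)

    @classmethod
    def erm2_from_thresholds(cls, nu: float, r: float, A: float, K: float) -> "GrowthParams":
        """ERM2 (constant s) parameters whose stationary drift vanishes at A and K.

        Solving ``nu*r*x - nu*mu*x**((nu+1)/nu) - s = 0`` at both targets is
        linear in (mu, s):
        ``mu = r*(K - A) / (K**((nu+1)/nu) - A**((nu+1)/nu))`` and
        ``s = nu*r*A - nu*mu*A**((nu+1)/nu)``.
        """
        if not (0 < A < K):
            raise GrowthConfigError("need 0 < A < K")
        e = (nu + 1.0) / nu
        mu = r * (K - A) / (K**e - A**e)
        s = nu * r * A - nu * mu * A**e
        if s <= 0:
            raise GrowthConfigError("targets (A, K) not reachable with s > 0")
        return cls("erm2", nu=nu, r=r, mu=mu, s=s)


def _power_term(x, nu: float):
    """x**((nu+1)/nu), safe for x = 0 and vectorized."""
    return np.power(x, (nu + 1.0) / nu)


def rhs(x, params: GrowthParams):
    """Instantaneous rate of change dx/dt (cells/day) at population ``x``.

    Vectorized over ``x``.  Negative populations are a domain error.  For the
    ERM2 model the absorbing branch applies: the rate at exactly ``x = 0`` is
    0, not ``-s``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("population x must be >= 0")
    nu, r, mu = params.nu, params.r, params.mu
    if params.model_id == "richards":
        out = nu * r * x - nu * mu * _power_term(x, nu)
    elif params.model_id == "erm1":
        g = params.gamma
        out = (
            -(nu**2) * r * x
            + nu**2 * mu * _power_term(x, nu)
            - nu**2 * g * np.power(x, (nu + 2.0) / nu)
        )
    else:  # erm2
        drift = nu * r * x - nu * mu * _power_term(x, nu) - params.s
        out = np.where(x > 0, drift, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def drift_rate(x, params: GrowthParams):
    """ERM2-style drift without the absorbing branch (used by the daily map)."""
    nu, r, mu = params.nu, params.r, params.mu
    s = params.s or 0.0
    return nu * r * x - nu * mu * _power_term(np.asarray(x, dtype=float), nu) - s


@dataclass(frozen=True)
class StabilityReport:
    """Equilibria of a growth model with their linearization rates.

    ``equilibria`` are sorted ascending and always include 0.  ``rates`` are
    the signed linearization rates (1/day; positive = unstable).  For ERM2
    with s > 0 the origin is absorbing and reached with non-zero speed, so its
    "rate" is reported as ``-inf``.  ``defining_feature`` is the asymmetry
    ratio |lambda_grow / lambda_sat| quantifying how fast small clusters grow
    relative to how fast large ones saturate at K; known cancers have >= 1.
    """

    equilibria: tuple[float, ...]
    rates: tuple[float, ...]
    lambda_grow: float | None
    lambda_sat: float | None
    defining_feature: float | None

    @property
    def threshold(self) -> float | None:
        """Extinction threshold A, when three equilibria exist."""
        return self.equilibria[1] if len(self.equilibria) == 3 else None

    @property
    def carrying_capacity(self) -> float | None:
        return self.equilibria[-1] if len(self.equilibria) >= 2 else None


def _erm1_thresholds(params: GrowthParams) -> tuple[float, float] | None:
    """Closed-form (A, K) for ERM1, or None when no threshold exists.

    The per-capita factor is quadratic in ``y = x**(1/nu)``:
    ``gamma*y**2 - mu*y + r = 0``; a threshold exists iff ``mu**2 > 4*r*gamma``
    (two distinct positive roots).  ``A`` takes the smaller root.
    """
    mu, r, g, nu = params.mu, params.r, params.gamma, params.nu
    disc = mu * mu - 4.0 * r * g
    if disc <= 0 or g == 0 or mu <= 0:
        return None
    root = math.sqrt(disc)
    # the textbook (mu - sqrt(disc))/(2 gamma) form cancels badly when A << K;
    # use the algebraically identical, numerically stable companion form
    yA = 2.0 * r / (mu + root)
    yK = (mu + root) / (2.0 * g)
    return yA**nu, yK**nu


def erm2_stationary_roots(params: GrowthParams) -> tuple[float, float] | None:
    """Positive roots (A, K) of the ERM2 stationary drift, or None.

    ``g(x) = nu*r*x - nu*mu*x**((nu+1)/nu) - s`` is unimodal on x > 0 with its
    maximum at ``x* = (nu*r/((nu+1)*mu))**nu``; when ``g(x*) > 0`` the roots
    bracket x* and are located by Brent's method (robust, derivative-free).
    ``g(s/(nu*r)) < 0`` and ``g(K_richards) = -s < 0`` supply the outer
    brackets.
    """
    nu, r, mu, s = params.nu, params.r, params.mu, params.s
    if s == 0:
        return None  # reduces to Richards; no threshold
    if mu == 0:
        return None  # no saturation: at most one root; treat as no (A, K) pair
    log_xstar = nu * math.log(nu * r / ((nu + 1.0) * mu))
    if log_xstar > math.log(OVERFLOW_GUARD) * 2:
        raise GrowthConfigError("stationary analysis overflows; rescale parameters")
    xstar = math.exp(log_xstar)

    def g(x: float) -> float:
        return nu * r * x - nu * mu * x ** ((nu + 1.0) / nu) - s

    if g(xstar) <= 0:
        return None  # immune response too strong: extinction only
    lo = s / (nu * r)  # g(lo) = -nu*mu*lo**e < 0 in exact arithmetic
    for _ in range(60):  # guard against rounding at the bracket edge
        if g(lo) < 0:
            break
        lo *= 1.0 - 1e-9
    # upper bracket: Richards capacity, where g = -s < 0
    hi = math.exp(min(nu * math.log(r / mu), math.log(1e300)))
    for _ in range(60):
        if g(hi) < 0:
            break
        hi *= 1.0 + 1e-9
    A = brentq(g, lo, xstar, xtol=1e-300, rtol=8.9e-16)
    K = brentq(g, xstar, hi, xtol=1e-300, rtol=8.9e-16)
    return A, K


def _erm2_rate(x: float, params: GrowthParams) -> float:
    """Analytic derivative of the ERM2 stationary drift at x > 0."""
    nu, r, mu = params.nu, params.r, params.mu
    return nu * r - (nu + 1.0) * mu * x ** (1.0 / nu)


def equilibria(params: GrowthParams) -> StabilityReport:
    """Equilibria, linearization rates and the asymmetry ratio of a model.

    Richards: {0, K} with rates (nu*r, -r) and ratio nu.  ERM1: {0, A, K} with
    the closed-form threshold and ratio (A/K)**(1/nu).  ERM2 (constant s):
    {0, A, K} with numerically located roots; the ratio comes from the
    analytic linearization at A and K.  Degenerate cases (no threshold,
    extinction only) shrink the equilibria list rather than failing.
    """
    nu, r = params.nu, params.r
    if params.model_id == "richards":
        if params.mu <= 0:
            return StabilityReport((0.0,), (nu * r,), nu * r, None, None)
        K = math.exp(nu * math.log(r / params.mu))
        return StabilityReport((0.0, K), (nu * r, -r), nu * r, r, nu)
    if params.model_id == "erm1":
        pair = _erm1_thresholds(params)
        if pair is None:
            # no threshold: only extinction (stable, rate -nu^2 r)
            return StabilityReport((0.0,), (-(nu**2) * r,), None, None, None)
        A, K = pair
        ratio = (A / K) ** (1.0 / nu)
        lam_grow = nu * r * (1.0 - (A / K) ** (1.0 / nu))
        lam_sat = nu * r * ((K / A) ** (1.0 / nu) - 1.0)
        return StabilityReport(
            (0.0, A, K), (-(nu**2) * r, lam_grow, -lam_sat), lam_grow, lam_sat, ratio
        )
    # erm2
    if params.s == 0:
        rep = equilibria(GrowthParams("richards", nu=nu, r=r, mu=params.mu))
        return rep
    pair = erm2_stationary_roots(params)
    if pair is None:
        return StabilityReport((0.0,), (-math.inf,), None, None, None)
    A, K = pair
    lam_grow = _erm2_rate(A, params)
    lam_sat = -_erm2_rate(K, params)
    return StabilityReport(
        (0.0, A, K),
        (-math.inf, lam_grow, -lam_sat),
        lam_grow,
        lam_sat,
        lam_grow / lam_sat,
    )


def numerical_linearization(params: GrowthParams, x: float, step: float | None = None) -> float:
    """Central-difference derivative of the right-hand side at ``x``.

    Independent numerical check of the analytic linearization rates; the step
    defaults to ``1e-6 * max(1, x)``.  At ``x = 0`` a one-sided difference is
    used (negative populations are out of the domain).
    """
    h = step if step is not None else 1e-6 * max(1.0, x)
    if x - h < 0:
        return (rhs(x + h, params) - rhs(x, params)) / h
    return (rhs(x + h, params) - rhs(x - h, params)) / (2.0 * h)


def erm2_threshold_approx(
    params: GrowthParams,
    a: float | None = None,
    *,
    tol: float = 1e-3,
    max_iter: int = 50,
) -> float:
    """Approximate stationary extinction threshold of ERM2 with constant s.

    ``A ~ 10**a`` is approximated by ``A = s / (nu*r - mu*(nu + a*ln 10))``,
    from expanding ``A**(1/nu) = exp(a*ln10/nu)`` to first order in the
    stationary condition.  When ``a`` is not supplied it is resolved
    self-consistently: starting from a = 2, iterate ``a <- log10(A)`` until
    |delta a| < tol (raises on non-convergence).
    """
    nu, r, mu, s = params.nu, params.r, params.mu, params.s
    if s is None:
        raise GrowthConfigError("threshold approximation requires an erm2 s")
    if s == 0:
        return 0.0

    def approx(a_val: float) -> float:
        denom = nu * r - mu * (nu + a_val * math.log(10.0))
        if denom <= 0:
            raise ApproximationInvalidError(
                "non-positive denominator in threshold approximation"
            )
        return s / denom

    if a is not None:
        return approx(a)
    a_val = 2.0
    for _ in range(max_iter):
        A = approx(a_val)
        a_new = math.log10(A)
        if abs(a_new - a_val) < tol:
            return approx(a_new)
        a_val = a_new
    raise ApproximationInvalidError("self-consistent exponent a did not converge")


@dataclass(frozen=True)
class DeterministicTrajectory:
    """Solution x(t) of one deterministic growth model.

    ``values`` are non-negative everywhere and identically zero from
    ``extinct_at`` onward (when extinction occurred within the window).
    """

    times: np.ndarray
    values: np.ndarray
    extinct_at: float | None = None
    params: GrowthParams | None = field(default=None, compare=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "x": self.values})


def _solve(params: GrowthParams, x0: float, t_end: float, rtol: float, t_eval=None):
    if x0 < 0:
        raise DomainError("x0 must be >= 0")

    def f(t, y):
        return [rhs(max(y[0], 0.0), params)]

    def hit_floor(t, y):
        return y[0] - EXTINCTION_FLOOR

    hit_floor.terminal = True
    hit_floor.direction = -1

    def overflow(t, y):
        return y[0] - OVERFLOW_GUARD

    overflow.terminal = True
    overflow.direction = 1

    atol = max(min(x0, 1.0), EXTINCTION_FLOOR) * 1e-12
    sol = solve_ivp(
        f,
        (0.0, t_end),
        [x0],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        t_eval=t_eval,
        events=[hit_floor, overflow],
    )
    if not sol.success and sol.status != 1:
        raise IntegrationError(f"integration failed: {sol.message}")
    if sol.t_events[1].size:
        raise IntegrationError(
            f"overflow guard: x exceeded {OVERFLOW_GUARD:g} cells at "
            f"t = {sol.t_events[1][0]:g} (params: {params})"
        )
    return sol


def integrate(
    params: GrowthParams,
    x0: float,
    t_end: float,
    grid: int | Sequence[float] | None = None,
    rtol: float = 1e-9,
) -> DeterministicTrajectory:
    """Integrate a growth model from ``x0`` over ``[0, t_end]``.

    ``grid`` may be None (solver-chosen points), an integer (that many evenly
    spaced points) or an explicit array of times.  Trajectories are clamped to
    zero after crossing the extinction floor (1e-6 cells); the crossing time
    is reported as ``extinct_at``.  Adaptive LSODA with a tight default
    relative tolerance resolves the near-vertical ERM1 step.
    """
    if t_end <= 0:
        raise DomainError("t_end must be > 0")
    if grid is None:
        t_eval = None
    elif isinstance(grid, int):
        t_eval = np.linspace(0.0, t_end, grid)
    else:
        t_eval = np.asarray(grid, dtype=float)

    if x0 == 0.0:
        times = t_eval if t_eval is not None else np.array([0.0, t_end])
        return DeterministicTrajectory(np.asarray(times), np.zeros(len(times)), None, params)

    sol = _solve(params, x0, t_end, rtol, t_eval)
    extinct_at = float(sol.t_events[0][0]) if sol.t_events[0].size else None

    if t_eval is None:
        times, values = sol.t, sol.y[0].copy()
    else:
        times = t_eval
        values = np.empty_like(t_eval)
        reached = t_eval <= sol.t[-1]
        values[reached] = sol.sol(t_eval[reached])[0]
        values[~reached] = 0.0 if extinct_at is not None else sol.y[0][-1]
    if extinct_at is not None:
        values[times >= extinct_at] = 0.0
    values = np.maximum(values, 0.0)
    return DeterministicTrajectory(np.asarray(times), values, extinct_at, params)


def first_passage_time(
    params: GrowthParams,
    x0: float,
    target: float,
    t_max: float,
    rtol: float = 1e-11,
) -> float | None:
    """First time x(t) reaches ``target`` from ``x0``, via event detection.

    Returns None if the target is not reached within ``t_max``.  Uses the
    integrator's dense output root finding, which resolves passage times that
    differ by several orders of magnitude (the ERM1 step).
    """
    if x0 < 0 or target <= 0:
        raise DomainError("x0 >= 0 and target > 0 required")
    if x0 == target:
        return 0.0

    def f(t, y):
        return [rhs(max(y[0], 0.0), params)]

    def hit(t, y):
        return y[0] - target

    hit.terminal = True

    sol = solve_ivp(
        f,
        (0.0, t_max),
        [x0],
        method="LSODA",
        rtol=rtol,
        atol=min(x0, target) * 1e-12,
        events=[hit],
    )
    if not sol.success and sol.status != 1:
        raise IntegrationError(f"integration failed: {sol.message}")
    if sol.t_events[0].size:
        return float(sol.t_events[0][0])
    return None


def richards_closed_form(params: GrowthParams, x0: float, t) -> np.ndarray:
    """Closed-form Richards solution (the model is explicitly solvable).

    With ``u = (x/K)**(1/nu)``, u follows plain logistic growth at rate r, so
    ``x(t) = K * (u0 / (u0 + (1 - u0) * exp(-r t)))**nu``.
    """
    if params.model_id != "richards":
        raise GrowthConfigError("closed form applies to the richards model")
    if params.mu <= 0:
        return np.asarray(x0 * np.exp(params.nu * params.r * np.asarray(t, dtype=float)))
    K = math.exp(params.nu * math.log(params.r / params.mu))
    u0 = (x0 / K) ** (1.0 / params.nu)
    t = np.asarray(t, dtype=float)
    u = u0 / (u0 + (1.0 - u0) * np.exp(-params.r * t))
    return K * u**params.nu


def asymmetry_curve(
    model_id: ModelId,
    nu_grid: Sequence[float],
    r: float,
    A: float = 1.0,
    K: float = 100.0,
) -> np.ndarray:
    """Asymmetry ratio |lambda_grow/lambda_sat| versus nu at fixed (r, A, K).

    For ERM1 and ERM2 the remaining parameters are re-solved at every nu so
    the threshold and capacity stay at the targets (A, K); for Richards only K
    is matched (it has no threshold).  Unreachable targets yield NaN at that
    grid point rather than a global failure.
    """
    out = np.empty(len(nu_grid), dtype=float)
    for i, nu in enumerate(nu_grid):
        try:
            if model_id == "richards":
                p = GrowthParams.richards_from_capacity(nu, r, K)
            elif model_id == "erm1":
                p = GrowthParams.erm1_from_thresholds(nu, r, A, K)
            else:
                p = GrowthParams.erm2_from_thresholds(nu, r, A, K)
            rep = equilibria(p)
            out[i] = rep.defining_feature if rep.defining_feature is not None else np.nan
        except (GrowthConfigError, ApproximationInvalidError):
            out[i] = np.nan
    return out
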