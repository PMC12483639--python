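"""Fitting growth models to tumour-progression time series.

The fit is a *shooting* fit: the model trajectory is integrated forward from
the first observation (t = 0 at the first data point) and squared residuals
to the remaining observations are minimized.  Residuals are taken on
log-transformed sizes by default — tumour sizes span decades, and a linear
loss would let the largest points dominate — with a linear-scale option.

Measured volumes are converted to cell counts assuming a cancer cell density
of 1e9 cells per cm^3.

Multi-start initialization covers the very wide plausible range of the shape
parameter (symmetric logistic nu = 1 up to practically-Gompertzian nu ~ 1e5),
with the rate seeded from the early-time log-slope of the data and the
(mu, s) pair from threshold/capacity re-parameterizations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import growth as gm
from .growth import GrowthConfigError, GrowthParams, IntegrationError

__all__ = [
    "CELLS_PER_CM3",
    "TumourDataset",
    "FitResult",
    "volume_to_cells",
    "cells_to_volume",
    "model_curve",
    "fit_growth_model",
    "compare_models",
]

CELLS_PER_CM3 = 1e9

_UNIT_TO_CM3 = {"cm3": 1.0, "mm3": 1e-3, "cells": None}


def volume_to_cells(volume, unit: str = "cm3"):
    """Convert tumour volume to a cell count (1e9 cells/cm^3)."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be >= 0")
    if unit not in ("cm3", "mm3"):
        raise ValueError("unit must be cm3 or mm3")
    out = v * _UNIT_TO_CM3[unit] * CELLS_PER_CM3
    return float(out) if out.ndim == 0 else out


def cells_to_volume(cells, unit: str = "cm3"):
    """Inverse of :func:`volume_to_cells`."""
    c = np.asarray(cells, dtype=float)
    if np.any(c < 0):
        raise ValueError("cell count must be >= 0")
    if unit not in ("cm3", "mm3"):
        raise ValueError("unit must be cm3 or mm3")
    out = c / CELLS_PER_CM3 / _UNIT_TO_CM3[unit]
    return float(out) if out.ndim == 0 else out


@dataclass
class TumourDataset:
    """Tumour-progression observations.

    ``times`` are days from the first observation (first time must be 0);
    ``sizes`` are strictly positive, in the unit given by ``size_kind``
    ('cells', 'cm3' or 'mm3').  ``replicate`` optionally identifies the
    animal for individual-measurement datasets; per-day mean datasets leave
    it None.
    """

    times: np.ndarray
    sizes: np.ndarray
    size_kind: str = "cells"
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.times.size != self.sizes.size:
            raise ValueError("times and sizes must have equal length")
        if self.times.min() != 0.0 or np.any(self.times < 0):
            raise ValueError("times must be >= 0 with the first observation at 0")
        if np.any(self.sizes <= 0):
            raise ValueError("sizes must be > 0")
        if self.size_kind not in ("cells", "cm3", "mm3"):
            raise ValueError("size_kind must be cells, cm3 or mm3")

    @property
    def cells(self) -> np.ndarray:
        if self.size_kind == "cells":
            return self.sizes
        return volume_to_cells(self.sizes, self.size_kind)

    @classmethod
    def from_csv(cls, path, size_unit: str | None = None) -> "TumourDataset":
        """Read columns day, size[, replicate]; unit from arg or '# size_unit=' header."""
        unit = size_unit
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "size_unit=" in line and unit is None:
                    unit = line.split("size_unit=")[1].strip()
        df = pd.read_csv(path, comment="#")
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(
            times=df["day"].to_numpy(float),
            sizes=df["size"].to_numpy(float),
            size_kind=unit or "cells",
            replicate=rep,
        )


@dataclass
class FitResult:
    """Best-fit parameters and derived quantities for one model/dataset."""

    params: GrowthParams
    fixed: dict
    sse: float
    K: float | None
    A: float | None
    flags: dict = field(default_factory=dict)
    n_starts: int = 0
    model_id: str = ""

    def to_json(self) -> str:
        d = {
            "model_id": self.params.model_id,
            "nu": self.params.nu,
            "r": self.params.r,
            "mu": self.params.mu,
            "gamma": self.params.gamma,
            "s": self.params.s,
            "fixed": self.fixed,
            "sse": self.sse,
            "K": self.K,
            "A": self.A,
            "flags": self.flags,
        }
        return json.dumps(d, indent=2)


_PARAM_NAMES = {
    "richards": ("nu", "r", "mu"),
    "erm1": ("nu", "r", "mu", "gamma"),
    "erm2": ("nu", "r", "mu", "s"),
}

_DEFAULT_BOUNDS = {
    "nu": (0.1, 1e6),
    "r": (1e-8, 1e3),
    "mu": (1e-20, 1e3),
    "gamma": (1e-30, 1e3),
    "s": (1e-12, 1e12),
}


def model_curve(params: GrowthParams, x0: float, times: np.ndarray) -> np.ndarray:
    """Model trajectory (cells) at the observation times, shot from x0 at t=0.

    Replicated datasets repeat observation times; the ODE is solved once on
    the unique sorted times and mapped back.
    """
    times = np.asarray(times, dtype=float)
    if params.model_id == "richards":
        return gm.richards_closed_form(params, x0, times)
    uniq, inverse = np.unique(times, return_inverse=True)
    traj = gm.integrate(params, x0, float(uniq.max()) * (1 + 1e-9), grid=uniq, rtol=1e-8)
    return traj.values[inverse]


def _residuals(theta_log, data_t, data_x, x0, model_id, free, fixed_vals, log_scale, floor):
    vals = dict(fixed_vals)
    for name, v in zip(free, theta_log):
        vals[name] = 10.0**v
    try:
        p = GrowthParams(model_id, **vals)
        model = model_curve(p, x0, data_t)
    except (GrowthConfigError, IntegrationError, ValueError):
        return np.full(data_x.size, 1e6)
    model = np.maximum(model, floor)
    if log_scale:
        return np.log(model) - np.log(data_x)
    return model - data_x


def _early_slope(t: np.ndarray, x: np.ndarray) -> float:
    """Log-slope over the first few observations (per-capita growth guess)."""
    order = np.argsort(t)
    t, x = t[order], x[order]
    k = max(2, min(5, t.size))
    tt, xx = t[:k], np.log(x[:k])
    if np.ptp(tt) == 0:
        return 0.1
    slope = np.polyfit(tt, xx, 1)[0]
    return float(abs(slope)) or 0.1


def _initial_grid(model_id: str, free, data_t, data_x, nu_fixed: float | None):
    """Multi-start initial points spanning decades of nu and threshold scales."""
    slope = _early_slope(data_t, data_x)
    K_guess = 2.0 * float(data_x.max())
    nus = [1.0, 10.0, 1e3, 1e5] if "nu" in free else [nu_fixed or 1.0]
    A_guesses = [1e2, 1e4]
    starts = []
    for nu in nus:
        r = max(slope / nu, 1e-8)
        for A in A_guesses:
            if A >= K_guess:
                continue
            try:
                if model_id == "erm2":
                    p = GrowthParams.erm2_from_thresholds(nu, r, A, K_guess)
                    cand = {"nu": nu, "r": r, "mu": p.mu, "s": p.s}
                elif model_id == "erm1":
                    p = GrowthParams.erm1_from_thresholds(nu, r, A, K_guess)
                    cand = {"nu": nu, "r": r, "mu": p.mu, "gamma": p.gamma}
                else:
                    p = GrowthParams.richards_from_capacity(nu, r, K_guess)
                    cand = {"nu": nu, "r": r, "mu": p.mu}
            except (GrowthConfigError, OverflowError):
                continue
            starts.append(tuple(math.log10(cand[name]) for name in free))
            if model_id == "richards":
                break  # A plays no role
    # dedupe
    starts = sorted(set(starts))
    return starts


def fit_growth_model(
    data: TumourDataset,
    model_id: str,
    free: tuple[str, ...] | None = None,
    bounds: dict | None = None,
    init: list[dict] | None = None,
    log_scale: bool = True,
    x0: float | None = None,
) -> FitResult:
    """Shooting + least-squares fit of a growth model to tumour data.

    The trajectory is shot from ``x0`` when supplied (e.g. a known injected
    cell count) and from the first observation otherwise.

    Parameters in ``free`` are optimized (in log10 space, bounded); the rest
    are held at values supplied via ``init[0]`` or model defaults.  Multiple
    starts are tried and the best converged one returned.  ``K_below_data``
    is flagged when the fitted carrying capacity falls below the largest
    observation — biologically inconsistent, since patients die before the
    tumour reaches its carrying capacity.

    Deterministic: a fixed init grid and dataset give an identical result.
    """
    if model_id not in _PARAM_NAMES:
        raise ValueError(f"unknown model_id {model_id!r}")
    names = _PARAM_NAMES[model_id]
    free = tuple(free) if free is not None else names
    for f in free:
        if f not in names:
            raise ValueError(f"{f!r} is not a parameter of {model_id}")
    data_t = data.times
    data_x = data.cells
    if data_t.size < len(free) + 1:
        raise ValueError("need more observations than free parameters")
    if x0 is None:
        x0 = float(data_x[np.argmin(data_t)])
    floor = 1e-6 * float(data_x.min())

    fixed_vals = {}
    explicit = init[0] if init else {}
    for name in names:
        if name not in free:
            if name in explicit:
                fixed_vals[name] = explicit[name]
            elif name == "nu":
                fixed_vals[name] = 1.0
            else:
                raise ValueError(f"fixed parameter {name!r} needs an initial value")

    if init:
        starts = [
            tuple(math.log10(d[name]) for name in free) for d in init if all(n in d for n in free)
        ]
        if not starts:
            starts = _initial_grid(model_id, free, data_t, data_x, fixed_vals.get("nu"))
    else:
        starts = _initial_grid(model_id, free, data_t, data_x, fixed_vals.get("nu"))

    bnds = dict(_DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = [math.log10(bnds[f][0]) for f in free]
    hi = [math.log10(bnds[f][1]) for f in free]

    best = None
    diagnostics = []
    for start in starts:
        start = tuple(min(max(v, l), h) for v, l, h in zip(start, lo, hi))
        try:
            res = least_squares(
                _residuals,
                start,
                bounds=(lo, hi),
                args=(data_t, data_x, x0, model_id, free, fixed_vals, log_scale, floor),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            diagnostics.append(f"start {start}: {exc}")
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
        diagnostics.append(f"start {start}: sse={sse:.3e}")
    if best is None:
        raise RuntimeError("no start converged:\n" + "\n".join(diagnostics))

    sse, theta = best
    vals = dict(fixed_vals)
    for name, v in zip(free, theta):
        vals[name] = 10.0**v
    params = GrowthParams(model_id, **vals)
    rep = gm.equilibria(params)
    K = rep.carrying_capacity
    A = rep.threshold
    flags = {"K_below_data": bool(K is not None and K < float(data_x.max()))}
    return FitResult(
        params=params,
        fixed={k: v for k, v in fixed_vals.items()},
        sse=sse,
        K=K,
        A=A,
        flags=flags,
        n_starts=len(starts),
        model_id=model_id,
    )


def compare_models(
    data: TumourDataset,
    candidates: list[tuple[str, tuple[str, ...] | None]],
    **kwargs,
) -> list[FitResult]:
    """Fit several model/free-set candidates and rank them by sse.

    Failed fits are excluded from the ranking (with a console note) rather
    than aborting the comparison.
    """
    results = []
    for model_id, free in candidates:
        try:
            results.append(fit_growth_model(data, model_id, free=free, **kwargs))
        except Exception as exc:
            print(f"fit failed for {model_id} (free={free}): {exc}")
    results.sort(key=lambda fr: fr.sse)
    return results
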