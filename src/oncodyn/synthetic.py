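"""Synthetic fixtures: mouse-like tumour curves and registry-like incidence.

Every other module is testable without downloads.  Generators are fully
specified by a serializable :class:`SyntheticSpec` (seed mandatory), so any
fixture can be regenerated bit-exactly from its provenance header.

Two canned tumour specs emulate the shapes of published mouse experiments:

* ``dataset1_like``  — dense individual measurements (many mice, ~583 points
  over 38 days) following a strongly asymmetric (large-nu) ERM2 curve,
* ``dataset2_like``  — eight per-day mean points over 33 days following a
  symmetric (nu = 1) ERM2 curve.

Measurement noise is multiplicative lognormal: caliper-style tumour-volume
error scales with size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import growth as gm
from .fitting import TumourDataset, cells_to_volume
from .growth import GrowthParams
from .risk import IncidenceTable

__all__ = [
    "SyntheticSpec",
    "make_tumour_dataset",
    "make_incidence_table",
    "dataset1_like",
    "dataset2_like",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete recipe for one synthetic fixture.

    ``generator`` is 'tumour' or 'incidence'; ``params`` holds the true
    model/shape parameters; ``noise_sigma`` the lognormal sigma (0 = exact);
    ``grid`` the sampling times (days) or age-band edges (years).
    """

    generator: str
    seed: int
    params: dict
    grid: tuple
    noise_sigma: float = 0.0
    n_replicates: int = 1
    size_kind: str = "cells"

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        d["grid"] = tuple(d["grid"])
        return cls(**d)


def _growth_params(d: dict) -> GrowthParams:
    if {"A", "K"} <= d.keys():
        ctor = {
            "erm2": GrowthParams.erm2_from_thresholds,
            "erm1": GrowthParams.erm1_from_thresholds,
        }[d["model_id"]]
        return ctor(d["nu"], d["r"], d["A"], d["K"])
    kwargs = {k: v for k, v in d.items() if k in ("nu", "r", "mu", "gamma", "s")}
    return GrowthParams(d["model_id"], **kwargs)


def make_tumour_dataset(spec: SyntheticSpec) -> TumourDataset:
    """Integrate the true model, sample the grid, apply noise, set units.

    With several replicates, each gets independent noise around the common
    true curve (individual-mouse style); a flagged error is raised if the
    true trajectory goes extinct before the grid ends (useless fixture).
    """
    if spec.generator != "tumour":
        raise ValueError("spec.generator must be 'tumour'")
    rng = np.random.default_rng(spec.seed)
    p = _growth_params(spec.params)
    times = np.asarray(spec.grid, dtype=float)
    x0 = float(spec.params["x0"])
    traj = gm.integrate(p, x0, float(times.max()) * (1 + 1e-9), grid=times)
    if traj.extinct_at is not None and traj.extinct_at <= times.max():
        raise ValueError(
            f"true trajectory extinct at t={traj.extinct_at:.3g}, before the grid ends"
        )
    cells = traj.values
    n_rep = spec.n_replicates
    all_t = np.tile(times, n_rep)
    all_x = np.tile(cells, n_rep)
    rep = np.repeat(np.arange(n_rep), times.size) if n_rep > 1 else None
    if spec.noise_sigma > 0:
        noise = rng.lognormal(0.0, spec.noise_sigma, size=all_x.size)
        all_x = all_x * noise
    if spec.size_kind != "cells":
        all_x = cells_to_volume(all_x, spec.size_kind)
    return TumourDataset(times=all_t, sizes=all_x, size_kind=spec.size_kind, replicate=rep)


def dataset1_like(seed: int = 0, noise_sigma: float = 0.15) -> SyntheticSpec:
    """Dense, individual, strongly asymmetric (large-nu) tumour fixture.

    65 replicates on a 9-day grid (585 points) over 38 days; volumes reach
    ~1 cm^3 (1e9 cells).
    """
    return SyntheticSpec(
        generator="tumour",
        seed=seed,
        params={
            "model_id": "erm2",
            "nu": 1e3,
            "r": 2.6e-2,
            "A": 2e2,
            "K": 2e9,
            "x0": 1e6,
        },
        grid=tuple(np.linspace(0.0, 38.0, 9)),
        noise_sigma=noise_sigma,
        n_replicates=65,
        size_kind="mm3",
    )


def dataset2_like(seed: int = 1, noise_sigma: float = 0.0) -> SyntheticSpec:
    """Sparse per-day-mean, symmetric (nu = 1) tumour fixture: 8 points, 33 days."""
    return SyntheticSpec(
        generator="tumour",
        seed=seed,
        params={
            "model_id": "erm2",
            "nu": 1.0,
            "r": 0.35,
            "A": 3e5,
            "K": 1e9,
            "x0": 5e6,
        },
        grid=tuple(np.linspace(0.0, 33.0, 8)),
        noise_sigma=noise_sigma,
        n_replicates=1,
        size_kind="mm3",
    )


def make_incidence_table(spec: SyntheticSpec) -> IncidenceTable:
    """Registry-like 5-year incidence bands following a chosen shape.

    ``params['shape']``: 'exponential' (log-rate linear in age — the typical
    cancer pattern), 'breast' (steep polynomial rise that flattens near the
    menopausal age, emulating the atypical breast-cancer pattern) or 'zero'.
    ``params['peak_rate']`` sets the rate per person-year in the last band.
    """
    if spec.generator != "incidence":
        raise ValueError("spec.generator must be 'incidence'")
    edges = np.asarray(spec.grid, dtype=float)
    lo, hi = edges[:-1], edges[1:]
    mid = 0.5 * (lo + hi)
    shape = spec.params.get("shape", "exponential")
    peak = float(spec.params.get("peak_rate", 3e-3))
    if shape == "zero":
        rate = np.zeros_like(mid)
    elif shape == "exponential":
        b = float(spec.params.get("log_slope", 0.09))  # per year of age
        rate = peak * np.exp(b * (mid - mid[-1]))
    elif shape == "breast":
        change = float(spec.params.get("change_age", 47.5))
        rate = np.where(
            mid <= change,
            (mid / change) ** 6,
            1.0 + 0.05 * (mid - change),
        )
        rate = peak * rate / rate[-1]
    else:
        raise ValueError(f"unknown incidence shape {shape!r}")
    return IncidenceTable(age_lo=lo, age_hi=hi, rate=rate)
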