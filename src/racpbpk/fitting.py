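"""Parameter estimation against multi-matrix concentration data.

Observed residue data span three decades (plasma in hundreds of μg/L down to
tissue residues near the LOQ), so the default objective works on the log
scale: residuals are log(pred + ε) − log(obs + ε) with ε = LOQ/2, pooled over
all matrices and animals, minimised by bounded trust-region nonlinear least
squares (``scipy.optimize.least_squares``).  Per-parameter standard
deviations come from the Jacobian at the optimum (linearisation) and are
approximate by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .parameters import DoseEvent, DrugParams, PhysioProfile, resolve
from .simulate import predicted_at, simulate

log = logging.getLogger(__name__)

LOQ_EPSILON = 0.25  # LOQ/2 with LOQ = 0.5 μg/L
PENALTY = 1e6       # residual magnitude when a simulation fails


@dataclass(frozen=True)
class FitDataset:
    """One observed profile: a matrix, its sampling times/values and the
    regimen that produced it."""

    matrix: str
    times: np.ndarray           # h
    observed: np.ndarray        # μg/L or μg/kg
    regimen: tuple[DoseEvent, ...]

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "observed",
                           np.asarray(self.observed, dtype=float))
        if self.times.shape != self.observed.shape:
            raise ValueError("times and observed must have matching shapes")


@dataclass(frozen=True)
class FitSpec:
    """What to fit: free parameter paths into :class:`DrugParams` (dotted for
    maps, e.g. ``partition.liver``), their bounds and initial values, the
    objective flavour, and the datasets."""

    free_parameters: Sequence[str]
    bounds: Mapping[str, tuple[float, float]]
    initial: Mapping[str, float]
    datasets: Sequence[FitDataset]
    objective: str = "log_ssr"          # or "weighted_ssr" (1/obs weights)
    epsilon: float = LOQ_EPSILON
    weights: Mapping[str, float] = field(default_factory=dict)  # per matrix

    def __post_init__(self):
        for name in self.free_parameters:
            if name not in self.initial:
                raise ValueError(f"no initial value for {name!r}")
            lo, hi = self.bounds.get(name, (-np.inf, np.inf))
            if not (lo <= self.initial[name] <= hi):
                raise ValueError(
                    f"initial value for {name!r} outside bounds ({lo}, {hi})")
        if self.objective not in ("log_ssr", "weighted_ssr"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass(frozen=True)
class FitResult:
    estimates: Mapping[str, float]
    std: Mapping[str, float]
    objective_value: float
    converged: bool
    n_evaluations: int
    message: str


def _apply(drug: DrugParams, names: Sequence[str],
           values: np.ndarray) -> DrugParams:
    for name, value in zip(names, values):
        drug = drug.set_param(name, float(value))
    return drug


def residuals(values: np.ndarray, spec: FitSpec, base_drug: DrugParams,
              profile: PhysioProfile) -> np.ndarray:
    """Stacked residual vector at one parameter point.

    A failed simulation contributes a large-but-finite constant residual so
    the optimiser can back away rather than crash; the event is logged.
    """
    drug = _apply(base_drug, list(spec.free_parameters), values)
    physiology = resolve(profile)
    out = []
    cache: dict[tuple, object] = {}
    for ds in spec.datasets:
        try:
            key = ds.regimen
            if key not in cache:
                t_end = float(ds.times.max()) + 1.0
                grid = np.unique(np.concatenate(
                    [[0.0], ds.times, [t_end],
                     [e.time for e in key if e.time <= t_end]]))
                cache[key] = simulate(physiology, drug, list(key), t_end,
                                      output_grid=grid,
                                      check_mass_balance=False)
            pred = predicted_at(cache[key], ds.matrix, ds.times)
            w = spec.weights.get(ds.matrix, 1.0)
            if spec.objective == "log_ssr":
                res = np.log(pred + spec.epsilon) \
                    - np.log(ds.observed + spec.epsilon)
            else:
                res = (pred - ds.observed) / np.maximum(ds.observed,
                                                        spec.epsilon)
            out.append(np.sqrt(w) * res)
        except Exception:
            log.exception("simulation failed for matrix %s; penalising",
                          ds.matrix)
            out.append(np.full(len(ds.times), PENALTY))
    return np.concatenate(out)


def objective(values: np.ndarray, spec: FitSpec, base_drug: DrugParams,
              profile: PhysioProfile) -> float:
    """Scalar loss: sum of squared residuals."""
    r = residuals(np.asarray(values, dtype=float), spec, base_drug, profile)
    return float(np.sum(r ** 2))


def fit(spec: FitSpec, profile: PhysioProfile,
        base_drug: DrugParams | None = None) -> FitResult:
    """Bounded nonlinear least squares from the spec's initial point.

    Deterministic given the spec (trust-region reflective, analytic-free
    finite-difference Jacobian).  Non-convergence returns the best point
    found, flagged rather than raised.
    """
    base_drug = base_drug if base_drug is not None else DrugParams()
    names = list(spec.free_parameters)
    x0 = np.array([spec.initial[n] for n in names])
    lo = np.array([spec.bounds.get(n, (0.0, np.inf))[0] for n in names])
    hi = np.array([spec.bounds.get(n, (0.0, np.inf))[1] for n in names])
    x_scale = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
    sol = least_squares(
        residuals, x0, bounds=(lo, hi), args=(spec, base_drug, profile),
        method="trf", x_scale=x_scale, xtol=1e-10, ftol=1e-10, gtol=1e-10)

    # linearised covariance: s² (JᵀJ)⁻¹ with s² = 2·cost / (m − n)
    m, n = sol.jac.shape
    std = np.full(n, np.nan)
    dof = m - n
    if dof > 0:
        try:
            jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
            s2 = 2.0 * sol.cost / dof
            std = np.sqrt(np.maximum(np.diag(jtj_inv) * s2, 0.0))
        except np.linalg.LinAlgError:
            pass
    return FitResult(
        estimates=dict(zip(names, (float(v) for v in sol.x))),
        std=dict(zip(names, (float(v) for v in std))),
        objective_value=2.0 * float(sol.cost),
        converged=bool(sol.success),
        n_evaluations=int(sol.nfev),
        message=str(sol.message),
    )


def fit_stages(stages: Sequence[FitSpec], profile: PhysioProfile,
               base_drug: DrugParams | None = None
               ) -> tuple[DrugParams, list[FitResult]]:
    """Sequential multi-stage fitting: each stage's estimates are fixed into
    the base parameters before the next stage runs (e.g. absorption from
    plasma first, tissue partitions second)."""
    drug = base_drug if base_drug is not None else DrugParams()
    results = []
    for spec in stages:
        result = fit(spec, profile, drug)
        results.append(result)
        for name, value in result.estimates.items():
            drug = drug.set_param(name, value)
    return drug, results
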