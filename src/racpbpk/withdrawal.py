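"""Monte Carlo withdrawal-time estimation against maximum residue limits.

A population of virtual animals is generated by sampling the sensitive drug
parameters from truncated lognormal distributions around the reference
values.  Each individual is simulated through the dosing scenario (default:
28 daily oral gavages of 1 mg/kg), the per-tissue withdrawal time is read off
as the last down-crossing of the tissue concentration below its MRL after the
final dose, and the population is summarised by a distribution-free one-sided
95th-percentile/95%-confidence upper tolerance bound (order statistic),
rounded up to whole days for reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .parameters import (
    DoseEvent, DrugParams, PhysioProfile, daily_oral_regimen, resolve,
)
from .simulate import TimeCourse, simulate

log = logging.getLogger(__name__)

#: Codex Alimentarius MRLs for ractopamine in edible tissues, μg/kg
DEFAULT_MRLS: Mapping[str, float] = {
    "muscle": 10.0, "fat": 10.0, "liver": 40.0, "kidney": 90.0,
}

#: drug parameters varied by default: the |NSC| ≥ 0.25 set restricted to
#: DrugParams fields (physiology is held at its reference values)
DEFAULT_VARIED = (
    "cl_hepatic", "k_absorption", "k_gut",
    "permeability_fraction.rest", "partition.rest",
    "partition.muscle", "partition.fat", "partition.liver",
    "partition.kidney",
)


class WithdrawalError(RuntimeError):
    pass


@dataclass(frozen=True)
class PopulationSpec:
    """How to generate the virtual population.

    Parameters are drawn lognormally with median at the reference value and
    coefficient of variation ``cv`` (per parameter, default 0.2), truncated
    at ±3 SD on the log scale by redrawing.
    """

    n_individuals: int = 500
    varied_parameters: Sequence[str] = DEFAULT_VARIED
    cv: Mapping[str, float] | float = 0.2
    truncation_sd: float = 3.0
    seed: int = 0

    def cv_for(self, name: str) -> float:
        if isinstance(self.cv, Mapping):
            return float(self.cv.get(name, 0.2))
        return float(self.cv)

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        cvs = (self.cv.values() if isinstance(self.cv, Mapping)
               else [self.cv])
        if any(c < 0 for c in cvs):
            raise ValueError("cv must be >= 0")


@dataclass(frozen=True)
class WTResult:
    tissue: str
    mrl: float                      # μg/kg
    wts: np.ndarray                 # per-individual withdrawal times, h
    wt_95_95: float                 # h
    wt_days: int                    # ceil(wt_95_95 / 24)

    @property
    def median(self) -> float:
        return float(np.median(self.wts))


def sample_population(drug: DrugParams, spec: PopulationSpec
                      ) -> list[DrugParams]:
    """Draw ``n_individuals`` parameter sets; deterministic under the seed.

    Truncation is by rejection; exceeding 10× the requested draws for any
    parameter raises (it would mean the truncation band is pathological).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    draws: dict[str, np.ndarray] = {}
    for name in spec.varied_parameters:
        cv = spec.cv_for(name)
        if cv == 0.0:
            draws[name] = np.full(n, drug.get_param(name))
            continue
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        mu = math.log(drug.get_param(name))
        z = np.empty(0)
        attempts = 0
        while len(z) < n:
            batch = rng.standard_normal(n)
            z = np.concatenate([z, batch[np.abs(batch) <= spec.truncation_sd]])
            attempts += n
            if attempts > 10 * n and len(z) < n:
                raise WithdrawalError(
                    f"truncation rejection for {name!r} exceeded 10x n draws")
        draws[name] = np.exp(mu + sigma * z[:n])
    population = []
    for i in range(n):
        individual = drug
        for name, values in draws.items():
            individual = individual.set_param(name, float(values[i]))
        population.append(individual)
    return population


def withdrawal_time_curve(timecourse: TimeCourse, tissue: str, mrl: float,
                          t_last_dose: float) -> float:
    """Withdrawal time (h after the last dose) from one simulated curve.

    The WT is the time of the *last* down-crossing below the MRL: the first
    time after the last dose at which the concentration is below the MRL and
    stays below for the rest of the simulated horizon.  The crossing is
    located by log-linear interpolation between the bracketing grid points.
    A concentration already (and permanently) below the MRL at the last dose
    gives WT = 0.
    """
    if mrl <= 0:
        raise ValueError("mrl must be positive")
    t = timecourse.times
    c = timecourse.concentration(tissue)
    post = t >= t_last_dose - 1e-9
    t, c = t[post], c[post]
    if len(t) < 2:
        raise WithdrawalError("timecourse does not extend past the last dose")
    above = c >= mrl
    if above[-1]:
        raise WithdrawalError(
            f"{tissue} concentration still >= MRL at t = {t[-1]:.1f} h; "
            "extend t_end")
    if not above.any():
        return 0.0
    i = int(np.flatnonzero(above)[-1])     # last point at/above the MRL
    t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
    if c1 > 0 and c2 > 0 and c2 < c1:
        frac = (math.log(c1) - math.log(mrl)) / (math.log(c1) - math.log(c2))
    else:
        frac = (c1 - mrl) / (c1 - c2)
    return float(t1 + frac * (t2 - t1) - t_last_dose)


def tolerance_bound_index(n: int, p: float = 0.95,
                          confidence: float = 0.95) -> int:
    """1-based order-statistic index k such that X_(k) is a distribution-free
    one-sided upper tolerance bound covering the p-th percentile with the
    given confidence: the smallest k with P[Binomial(n, p) ≤ k−1] ≥ conf."""
    n_min = math.ceil(math.log(1.0 - confidence) / math.log(p))
    if n < n_min:
        raise ValueError(
            f"n = {n} too small for a {p:.0%}/{confidence:.0%} order-statistic "
            f"bound; need n >= {n_min}")
    k = int(binom.ppf(confidence, n, p)) + 1
    while binom.cdf(k - 1, n, p) < confidence:   # guard against ppf edge cases
        k += 1
    return k


def wt_95_95(per_individual_wts: Sequence[float], p: float = 0.95,
             confidence: float = 0.95) -> float:
    """Nonparametric 95/95 upper tolerance bound of the WT sample (hours)."""
    wts = np.sort(np.asarray(per_individual_wts, dtype=float))
    k = tolerance_bound_index(len(wts), p, confidence)
    return float(wts[k - 1])


def regression_tolerance_wt(times: np.ndarray, log_concs: np.ndarray,
                            mrl: float, p: float = 0.95,
                            confidence: float = 0.95) -> float:
    """Alternative 95/95: log-linear regression tolerance-limit on a terminal
    phase (regulatory depletion-curve style).  ``times`` are hours after the
    last dose for pooled individual observations; returns the time at which
    the one-sided upper tolerance limit of the fitted line crosses log(mrl).
    """
    from scipy.stats import nct
    t = np.asarray(times, dtype=float)
    y = np.asarray(log_concs, dtype=float)
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 observations")
    slope, intercept = np.polyfit(t, y, 1)
    if slope >= 0:
        raise ValueError("no depletion: non-negative terminal slope")
    resid = y - (slope * t + intercept)
    s = math.sqrt(float(resid @ resid) / (n - 2))
    sxx = float(np.sum((t - t.mean()) ** 2))
    zp = 1.6448536269514722          # standard normal 95th percentile
    log_mrl = math.log(mrl)

    def upper(tq: float) -> float:
        d = zp / math.sqrt(1.0 / n + (tq - t.mean()) ** 2 / sxx)
        k = nct.ppf(confidence, n - 2, d) \
            * math.sqrt(1.0 / n + (tq - t.mean()) ** 2 / sxx)
        return slope * tq + intercept + k * s

    lo, hi = 0.0, float(t.max()) * 10 + 24.0
    if upper(lo) <= log_mrl:
        return 0.0
    while upper(hi) > log_mrl:
        hi *= 2
        if hi > 1e6:
            raise ValueError("tolerance limit never crosses the MRL")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if upper(mid) > log_mrl:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def withdrawal_report(profile: PhysioProfile, drug: DrugParams,
                      regimen: Sequence[DoseEvent] | None = None,
                      population: PopulationSpec | None = None,
                      mrls: Mapping[str, float] = DEFAULT_MRLS, *,
                      t_washout: float = 45.0 * 24.0,
                      grid_step: float = 1.0) -> list[WTResult]:
    """Full Monte Carlo withdrawal-time analysis.

    Simulates every sampled individual through the regimen (default: the
    28-day daily 1 mg/kg oral scenario) plus ``t_washout`` hours, computes
    per-tissue withdrawal times and their 95/95 bounds.  Individuals whose
    simulation fails are dropped with a logged count, provided they are fewer
    than 1% of the population.
    """
    if regimen is None:
        regimen = daily_oral_regimen(1.0, profile.body_mass, 28)
    population = population or PopulationSpec()
    physiology = resolve(profile)
    t_last = max(e.time for e in regimen)
    t_end = t_last + t_washout
    grid = np.arange(0.0, t_end + 0.5 * grid_step, grid_step)
    individuals = sample_population(drug, population)

    per_tissue: dict[str, list[float]] = {tissue: [] for tissue in mrls}
    failures = 0
    for individual in individuals:
        try:
            tc = simulate(physiology, individual, list(regimen), t_end,
                          output_grid=grid, check_mass_balance=False)
            wts = {tissue: withdrawal_time_curve(tc, tissue, mrl, t_last)
                   for tissue, mrl in mrls.items()}
        except Exception:
            failures += 1
            log.exception("individual simulation failed (%d so far)", failures)
            continue
        for tissue, wt in wts.items():
            per_tissue[tissue].append(wt)
    if failures:
        if failures > 0.01 * len(individuals):
            raise WithdrawalError(
                f"{failures}/{len(individuals)} individual simulations failed")
        log.warning("dropped %d failed individuals", failures)

    results = []
    for tissue, mrl in mrls.items():
        wts = np.asarray(per_tissue[tissue])
        bound = wt_95_95(wts) if len(wts) >= 59 else float(wts.max())
        results.append(WTResult(tissue=tissue, mrl=mrl, wts=wts,
                                wt_95_95=bound,
                                wt_days=int(math.ceil(bound / 24.0 - 1e-9))))
    return results
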