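"""Synthetic observed datasets with the statistical structure of residue
study data: per-animal multiplicative assay noise, LOQ censoring and LOD
drop-out on top of the model's own noise-free predictions.

The noise-free mean is produced by the very simulator the rest of the package
uses — there is no second model — so these tables exercise NCA, fitting and
validation exactly the way a real study would, while remaining reproducible
from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    DoseEvent, DrugParams, PhysioProfile, daily_oral_regimen, resolve,
)
from .simulate import MATRICES, predicted_at, simulate

#: default plasma sampling schedule (h) for single-dose kinetics
ORAL_SAMPLING = (1 / 12, 1 / 6, 1 / 3, 0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48,
                 72, 96)
IV_SAMPLING = (1 / 60, 1 / 12, 1 / 6, 1 / 3, 0.5, 1, 2, 4, 6, 8, 12, 24, 36,
               48, 60, 72, 84, 96)
#: withdrawal-day schedule of the multi-tissue depletion study
DEPLETION_DAYS = (1, 3, 5, 7, 14, 21)
DEPLETION_MATRICES = ("liver", "kidney", "spleen", "lung", "heart", "muscle",
                      "fat", "brain", "plasma")


@dataclass(frozen=True)
class NoiseSpec:
    """Assay-noise model: proportional lognormal error with CV
    ``proportional_cv``; values below the LOQ are flagged censored, values
    below the LOD are dropped entirely."""

    proportional_cv: float = 0.15
    loq: float = 0.5        # μg/kg or μg/L
    lod: float = 0.15
    n_animals: int = 6
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.proportional_cv < 1.0):
            raise ValueError("proportional_cv must be in [0, 1)")
        if not (0.0 < self.lod < self.loq):
            raise ValueError("need 0 < lod < loq")


def generate_observed(profile: PhysioProfile, drug: DrugParams,
                      regimen: Sequence[DoseEvent],
                      sampling_times: Sequence[float],
                      matrices: Sequence[str],
                      noise: NoiseSpec = NoiseSpec()) -> pd.DataFrame:
    """Synthetic observed table (animal_id, time_h, matrix, concentration,
    unit, status) for one regimen.

    Each animal's observations are the model mean times a lognormal factor
    with median 1; cv = 0 reproduces the model exactly.  Deterministic under
    the seed.
    """
    rng = np.random.default_rng(noise.seed)
    t_end = float(max(sampling_times)) + 1.0
    tc = simulate(resolve(profile), drug, list(regimen), t_end)
    sigma = np.sqrt(np.log(1.0 + noise.proportional_cv ** 2))
    rows = []
    times = np.asarray(sampling_times, dtype=float)
    for matrix in matrices:
        mean = predicted_at(tc, matrix, times)
        unit = "ug/L" if matrix == "plasma" else "ug/kg"
        for animal in range(1, noise.n_animals + 1):
            factors = (np.exp(sigma * rng.standard_normal(len(times)))
                       if sigma > 0 else np.ones(len(times)))
            values = mean * factors
            for t, v in zip(times, values):
                if v < noise.lod:
                    continue        # below detection: not reported at all
                status = "<LOQ" if v < noise.loq else "ok"
                rows.append((f"goat{animal:02d}", t, matrix, v, unit, status))
    return pd.DataFrame(rows, columns=["animal_id", "time_h", "matrix",
                                       "concentration", "unit", "status"])


def generate_validation_set(profile: PhysioProfile, drug: DrugParams,
                            noise: NoiseSpec = NoiseSpec(n_animals=3),
                            dose_mg_per_kg: float = 1.0,
                            n_days: int = 28,
                            withdrawal_days: Sequence[int] = DEPLETION_DAYS,
                            matrices: Sequence[str] = DEPLETION_MATRICES
                            ) -> pd.DataFrame:
    """Multi-tissue depletion table after repeated daily oral dosing, sampled
    at fixed withdrawal days across nine matrices."""
    regimen = daily_oral_regimen(dose_mg_per_kg, profile.body_mass, n_days)
    t_last = max(e.time for e in regimen)
    times = [t_last + 24.0 * d for d in withdrawal_days]
    return generate_observed(profile, drug, regimen, times, matrices, noise)


def cumulative_urine_observed(profile: PhysioProfile, drug: DrugParams,
                              regimen: Sequence[DoseEvent],
                              sampling_times: Sequence[float],
                              noise: NoiseSpec = NoiseSpec(n_animals=4)
                              ) -> pd.DataFrame:
    """Cumulative urinary excretion table (μg); noise multiplies the
    increments so each animal's curve stays non-decreasing."""
    rng = np.random.default_rng(noise.seed)
    t_end = float(max(sampling_times)) + 1.0
    tc = simulate(resolve(profile), drug, list(regimen), t_end)
    times = np.asarray(sampling_times, dtype=float)
    mean = np.interp(times, tc.times, tc.cumulative_urine)
    increments = np.diff(np.concatenate([[0.0], mean]))
    sigma = np.sqrt(np.log(1.0 + noise.proportional_cv ** 2))
    rows = []
    for animal in range(1, noise.n_animals + 1):
        factors = (np.exp(sigma * rng.standard_normal(len(times)))
                   if sigma > 0 else np.ones(len(times)))
        values = np.cumsum(increments * factors)
        rows += [(f"goat{animal:02d}", t, "urine_cumulative", v, "ug", "ok")
                 for t, v in zip(times, values)]
    return pd.DataFrame(rows, columns=["animal_id", "time_h", "matrix",
                                       "concentration", "unit", "status"])


def validate_predictions(observed: pd.DataFrame, predicted: pd.DataFrame
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed-vs-predicted regression per matrix.

    ``predicted`` must carry matching (matrix, time_h) rows with a
    ``concentration`` column.  Returns (regression table with slope,
    intercept, r2, n per matrix; residual table with observed − predicted).
    A matrix with fewer than 3 matched pairs is skipped.
    """
    from scipy.stats import linregress
    merged = observed.merge(
        predicted[["matrix", "time_h", "concentration"]],
        on=["matrix", "time_h"], suffixes=("_obs", "_pred"))
    merged["residual"] = merged["concentration_obs"] \
        - merged["concentration_pred"]
    stats = []
    for matrix, group in merged.groupby("matrix"):
        if len(group) < 3:
            continue
        x = group["concentration_pred"].to_numpy()
        y = group["concentration_obs"].to_numpy()
        if np.allclose(x, x[0]):
            continue
        fit = linregress(x, y)
        stats.append((matrix, fit.slope, fit.intercept, fit.rvalue ** 2,
                      len(group)))
    table = pd.DataFrame(stats, columns=["matrix", "slope", "intercept",
                                         "r2", "n"])
    return table, merged


def scenario_table(name: str, profile: PhysioProfile, drug: DrugParams,
                   noise: NoiseSpec) -> pd.DataFrame:
    """Named study scenarios used by the CLI: ``iv-plasma``, ``oral-plasma``,
    ``urine`` and ``depletion``."""
    amount = 1.0 * profile.body_mass * 1000.0
    if name == "iv-plasma":
        return generate_observed(profile, drug,
                                 [DoseEvent(0.0, "iv", amount)],
                                 IV_SAMPLING, ["plasma"], noise)
    if name == "oral-plasma":
        return generate_observed(profile, drug,
                                 [DoseEvent(0.0, "oral", amount)],
                                 ORAL_SAMPLING, ["plasma"], noise)
    if name == "urine":
        return cumulative_urine_observed(
            profile, drug, [DoseEvent(0.0, "iv", amount)],
            [24.0 * d for d in range(1, 8)], noise)
    if name == "depletion":
        return generate_validation_set(profile, drug, noise)
    raise ValueError(f"unknown scenario {name!r}")
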