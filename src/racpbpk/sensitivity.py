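"""Local sensitivity analysis: sensitivity coefficients and elasticities.

For a scalar model functional f and parameter x, the sensitivity coefficient
is the forward finite difference SC = (f(x+Δx) − f(x))/Δx with Δx a fixed
fraction of x (default 1%), and the normalised coefficient (elasticity)
NSC = SC·x/f(x).  Parameters with |NSC| ≥ 0.25 are flagged sensitive.

The default functional is the residue level that the analysis is meant to
protect: the output concentration at a fixed time into the post-exposure
(washout) period, 120 h after the last dose — the midpoint of the window in
which the withdrawal-time decisions fall.  AUC over the exposure window and
Cmax are available alternatives (note that total AUC in a linear,
clearance-limited model is nearly flow-independent, which hides exactly the
distribution parameters a residue analysis cares about).

Parameter semantics worth spelling out:

* ``qclu`` is cardiac output (= lung blood flow).  Perturbing it scales every
  organ flow and, under the flow-scaled permeability convention, every
  membrane conductance.
* ``qcli``/``qcki``/... perturb one organ's absolute flow; venous return (and
  hence lung flow) is recomputed as the sum, keeping the circulation balanced.
* ``bw`` perturbs body mass at *fixed absolute cardiac output* (per-kg
  perfusion falls as the animal grows) with the mg/kg dose scaling along —
  the scenario in which body weight has a pharmacokinetic effect at all; with
  per-kg physiology held, the whole system would merely rescale.
* ``pcv`` (hematocrit) only reaches the observables through the blood:plasma
  ratio and is included only when that pathway is active.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .parameters import DoseEvent, DrugParams, PhysioProfile, resolve
from .simulate import simulate

log = logging.getLogger(__name__)

SENSITIVE_THRESHOLD = 0.25
DEFAULT_DELTA = 0.01
DEFAULT_POST_EXPOSURE_OFFSET = 120.0   # h after the last dose

#: drug-parameter paths by their conventional short names
DRUG_PARAMS = {
    "clhe": "cl_hepatic", "clre": "cl_renal", "kst": "k_stomach",
    "ka": "k_absorption", "kint": "k_gut", "pfree": "free_fraction",
    "pli": "partition.liver", "pki": "partition.kidney",
    "psp": "partition.spleen", "phe": "partition.heart",
    "plu": "partition.lung", "pmu": "partition.muscle",
    "pfa": "partition.fat", "pbr": "partition.brain",
    "pre": "partition.rest",
    "ppmu": "permeability_fraction.muscle",
    "ppfa": "permeability_fraction.fat",
    "ppbr": "permeability_fraction.brain",
    "ppre": "permeability_fraction.rest",
}
#: organ flows perturbed individually (absolute L/h, venous return recomputed)
FLOW_PARAMS = {
    "qcli": "liver", "qcki": "kidney", "qcmu": "muscle", "qcfa": "fat",
    "qche": "heart", "qcbr": "brain",
}
PHYSIO_PARAMS = ("bw", "qclu")

# pfree sits at its default upper bound 1.0 (no plasma binding) where an
# upward relative perturbation is undefined; like pcv it joins the table only
# when its pathway is configured active
DEFAULT_PARAMETERS = tuple(PHYSIO_PARAMS) + tuple(FLOW_PARAMS) \
    + tuple(p for p in DRUG_PARAMS if p != "pfree")
DEFAULT_OUTPUTS = ("plasma", "liver", "kidney")


@dataclass(frozen=True)
class SensitivityResult:
    output_id: str
    parameter: str
    base_value: float
    f_base: float
    sc: float
    nsc: float
    sensitive: bool
    delta_fraction: float


def sensitivity_coefficient(f: Callable[[float], float], x: float,
                            delta_fraction: float = DEFAULT_DELTA, *,
                            scheme: str = "forward") -> float:
    """Finite-difference SC of a scalar function at x (Δx = δ·x)."""
    if delta_fraction <= 0:
        raise ValueError("delta_fraction must be positive")
    if x == 0:
        raise ValueError("cannot take a relative perturbation at x = 0")
    dx = delta_fraction * x
    if scheme == "forward":
        return (f(x + dx) - f(x)) / dx
    if scheme == "central":
        return (f(x + dx) - f(x - dx)) / (2.0 * dx)
    raise ValueError(f"unknown scheme {scheme!r}")


def nsc(f: Callable[[float], float], x: float,
        delta_fraction: float = DEFAULT_DELTA, *,
        scheme: str = "forward") -> float:
    """Normalised sensitivity coefficient (elasticity) SC·x/f(x)."""
    fx = f(x)
    if fx == 0:
        raise ZeroDivisionError("f(x) = 0: NSC undefined at this point")
    return sensitivity_coefficient(f, x, delta_fraction, scheme=scheme) \
        * x / fx


def _functional(values: np.ndarray, times: np.ndarray, kind: str,
                t_eval: float) -> float:
    if kind == "conc_at_time":
        return float(np.interp(t_eval, times, values))
    if kind == "auc":
        return float(np.trapezoid(values, times))
    if kind == "cmax":
        return float(values.max())
    raise ValueError(f"unknown functional {kind!r}")


def _evaluate(profile: PhysioProfile, drug: DrugParams,
              regimen: Sequence[DoseEvent], outputs: Sequence[str],
              t_end: float, kind: str, t_eval: float,
              flow_scale: tuple[str, float] | None = None,
              dose_scale: float = 1.0) -> dict[str, float]:
    """Simulate one parameter point and reduce each output to its functional."""
    physiology = resolve(profile)
    if flow_scale is not None:
        organ, factor = flow_scale
        flows = dict(physiology.flows)
        flows[organ] *= factor
        flows["lung"] = sum(flows[o] for o in
                            ("liver", "kidney", "muscle", "fat", "heart",
                             "brain", "rest"))
        physiology = dataclasses.replace(physiology, flows=flows)
    if dose_scale != 1.0:
        regimen = [DoseEvent(e.time, e.route, e.amount * dose_scale)
                   for e in regimen]
    grid = np.arange(0.0, t_end + 0.5, 1.0)
    tc = simulate(physiology, drug, list(regimen), t_end, output_grid=grid,
                  check_mass_balance=False)
    return {out: _functional(tc.concentration(out), tc.times, kind, t_eval)
            for out in outputs}


def sensitivity_table(profile: PhysioProfile, drug: DrugParams,
                      regimen: Sequence[DoseEvent], *,
                      outputs: Sequence[str] = DEFAULT_OUTPUTS,
                      parameters: Sequence[str] = DEFAULT_PARAMETERS,
                      delta_fraction: float = DEFAULT_DELTA,
                      functional: str = "conc_at_time",
                      post_exposure_offset: float =
                      DEFAULT_POST_EXPOSURE_OFFSET
                      ) -> list[SensitivityResult]:
    """NSC for the full cross of outputs × parameters, sorted by |NSC|.

    One simulation per perturbed parameter (all outputs share it).  A failed
    entry is logged and skipped rather than aborting the table.
    """
    t_last = max(e.time for e in regimen)
    t_eval = t_last + post_exposure_offset
    t_end = t_eval + 24.0 if functional == "conc_at_time" else t_eval
    base = _evaluate(profile, drug, regimen, outputs, t_end, functional,
                     t_eval)
    results: list[SensitivityResult] = []
    for name in parameters:
        try:
            x, perturbed = _perturbed_point(profile, drug, name,
                                            delta_fraction)
            f_pert = _evaluate(**perturbed, regimen=regimen, outputs=outputs,
                               t_end=t_end, kind=functional, t_eval=t_eval)
        except Exception:
            log.exception("sensitivity entry for %r failed; skipped", name)
            continue
        dx = delta_fraction * x
        for out in outputs:
            f0 = base[out]
            sc = (f_pert[out] - f0) / dx
            value = sc * x / f0 if f0 != 0 else np.nan
            results.append(SensitivityResult(
                output_id=out, parameter=name, base_value=x, f_base=f0,
                sc=sc, nsc=value,
                sensitive=bool(abs(value) >= SENSITIVE_THRESHOLD),
                delta_fraction=delta_fraction))
    results.sort(key=lambda r: -abs(r.nsc))
    return results


def _perturbed_point(profile: PhysioProfile, drug: DrugParams, name: str,
                     delta: float):
    """Base value of parameter ``name`` and the (profile, drug, extras) at
    x(1+δ), encoded as keyword arguments for ``_evaluate``."""
    if name in DRUG_PARAMS:
        path = DRUG_PARAMS[name]
        x = drug.get_param(path)
        return x, dict(profile=profile, drug=drug.set_param(path, x * (1 + delta)))
    if name in FLOW_PARAMS:
        organ = FLOW_PARAMS[name]
        x = resolve(profile).flows[organ]
        return x, dict(profile=profile, drug=drug,
                       flow_scale=(organ, 1.0 + delta))
    if name == "qclu":
        x = profile.cardiac_output * profile.body_mass
        pert = dataclasses.replace(
            profile, cardiac_output=profile.cardiac_output * (1 + delta))
        return x, dict(profile=pert, drug=drug)
    if name == "bw":
        x = profile.body_mass
        # grow the animal, hold absolute cardiac output, scale the mg/kg dose
        pert = dataclasses.replace(
            profile, body_mass=x * (1 + delta),
            cardiac_output=profile.cardiac_output / (1 + delta))
        return x, dict(profile=pert, drug=drug, dose_scale=1.0 + delta)
    if name == "pcv":
        x = profile.hematocrit
        pert = dataclasses.replace(profile, hematocrit=x * (1 + delta))
        return x, dict(profile=pert, drug=drug)
    raise KeyError(f"unknown sensitivity parameter {name!r}")


def sensitive_parameters(results: Sequence[SensitivityResult]) -> list[str]:
    """Parameters flagged sensitive for at least one output, table order."""
    seen: list[str] = []
    for r in results:
        if r.sensitive and r.parameter not in seen:
            seen.append(r.parameter)
    return seen
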