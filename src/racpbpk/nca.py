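"""Non-compartmental pharmacokinetic analysis of plasma profiles.

Implements the industry-standard NCA conventions: terminal slope λz by
log-linear regression over the best terminal window (maximum adjusted R²,
at least three points, Cmax excluded), linear-up/log-down trapezoidal AUC and
AUMC with Clast/λz tail extrapolation, and the derived dose-normalised
parameters (Cl, Vz, Vss, MRT, F).  Concentrations below the assay LOQ are
excluded from the λz fit and treated as missing — never as zero — in the
area calculations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_LOQ = 0.5  # μg/L


class NCAError(ValueError):
    pass


@dataclass(frozen=True)
class NCAResult:
    """Summary parameters for one concentration–time profile.

    Volume/clearance terms are dose-per-kg normalised (L/kg, L/h/kg).  The
    IV-only fields (``c0``, ``vz``, ``vss``) are ``None`` for oral profiles.
    """

    route: str
    lambda_z: float                 # 1/h
    t_half: float                   # h
    r2_adj_lambda: float
    n_lambda_points: int
    auc_last: float                 # h·μg/L
    auc_inf: float
    aumc_inf: float                 # h²·μg/L
    mrt: float                      # h
    c0: float | None = None         # μg/L
    cl: float | None = None         # L/h/kg
    vz: float | None = None         # L/kg
    vss: float | None = None        # L/kg


def _clean_profile(times, concentrations, loq: float | None):
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise NCAError("times and concentrations must be matching 1-D arrays")
    order = np.argsort(t)
    t, c = t[order], c[order]
    keep = np.isfinite(c)
    if loq is not None:
        keep &= (c >= loq)
    return t, c, keep


def fit_lambda_z(times, concentrations, *, loq: float | None = DEFAULT_LOQ
                 ) -> tuple[float, float, int]:
    """Terminal elimination rate constant by best-window log-linear regression.

    Candidate windows run from each post-peak start index to the last
    quantifiable point; the window maximising adjusted R² wins, with ties
    (within 1e-4) broken toward more points.  Returns
    ``(lambda_z, r2_adj, n_points)``.
    """
    t, c, keep = _clean_profile(times, concentrations, loq)
    t, c = t[keep], c[keep]
    if len(c) < 3:
        raise NCAError("need at least 3 quantifiable concentrations")
    i_max = int(np.argmax(c))
    best = None
    for start in range(i_max + 1, len(c) - 2):
        tt, cc = t[start:], np.log(c[start:])
        n = len(tt)
        slope, intercept = np.polyfit(tt, cc, 1)
        resid = cc - (slope * tt + intercept)
        ss_tot = float(np.sum((cc - cc.mean()) ** 2))
        if ss_tot == 0.0:
            r2 = 1.0 if np.allclose(resid, 0) else 0.0
        else:
            r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if slope >= 0:
            continue
        if best is None or r2_adj > best[0] + 1e-4 or \
                (abs(r2_adj - best[0]) <= 1e-4 and n > best[2]):
            best = (r2_adj, -slope, n)
    if best is None:
        raise NCAError("no terminal decay: every candidate window has a "
                       "non-negative slope")
    r2_adj, lam, n = best
    return lam, r2_adj, n


def _segment_areas(t1, t2, c1, c2, rule: str) -> tuple[float, float]:
    """AUC and AUMC contribution of one interval."""
    dt = t2 - t1
    log_down = rule == "linear-log" and c2 < c1 and c2 > 0 and c1 > 0
    if log_down:
        k = math.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k ** 2
    else:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def auc_aumc(times, concentrations, lambda_z: float | None = None, *,
             rule: str = "linear-log", loq: float | None = DEFAULT_LOQ
             ) -> tuple[float, float, float]:
    """Trapezoidal areas to the last quantifiable point plus tail extrapolation.

    ``rule`` is ``linear-log`` (linear up, logarithmic down; default) or
    ``linear``.  Returns ``(auc_last, auc_inf, aumc_inf)``; the extrapolated
    values require ``lambda_z`` and equal the *_last values plus Clast/λz and
    Clast·tlast/λz + Clast/λz² respectively.
    """
    if rule not in ("linear-log", "linear"):
        raise NCAError(f"unknown trapezoid rule {rule!r}")
    t, c, keep = _clean_profile(times, concentrations, loq)
    t, c = t[keep], c[keep]   # sub-LOQ points are missing, not zero
    if len(c) < 2:
        raise NCAError("need at least 2 quantifiable concentrations")
    auc = aumc = 0.0
    for i in range(len(t) - 1):
        a, m = _segment_areas(t[i], t[i + 1], c[i], c[i + 1], rule)
        auc += a
        aumc += m
    if auc <= 0:
        raise NCAError("non-positive AUC to t_last")
    if lambda_z is None:
        raise NCAError("lambda_z required for extrapolation to infinity")
    c_last, t_last = c[-1], t[-1]
    auc_inf = auc + c_last / lambda_z
    aumc_inf = aumc + c_last * t_last / lambda_z + c_last / lambda_z ** 2
    return auc, auc_inf, aumc_inf


def back_extrapolate_c0(times, concentrations) -> float:
    """IV C0 by log-linear back-extrapolation through the first two positive
    concentrations."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    pos = c > 0
    t, c = t[pos], c[pos]
    if len(c) < 2:
        raise NCAError("need two positive concentrations to back-extrapolate")
    if c[1] >= c[0]:
        return float(c[0])  # no initial decline; use the first observation
    slope = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
    return float(math.exp(math.log(c[0]) - slope * t[0]))


def nca_summary(times, concentrations, route: str, dose_per_kg: float, *,
                rule: str = "linear-log", loq: float | None = DEFAULT_LOQ
                ) -> NCAResult:
    """Full NCA of one profile.  ``dose_per_kg`` is in μg/kg so that Cl and
    the volume terms come out in L/h/kg and L/kg.

    For IV profiles whose first sample is after t=0, the back-extrapolated C0
    closes the initial area.  Oral profiles report MRT as AUMC/AUC without IV
    correction and omit C0/Vz/Vss.
    """
    if route not in ("oral", "iv"):
        raise NCAError(f"route must be 'oral' or 'iv', got {route!r}")
    lam, r2_adj, n_pts = fit_lambda_z(times, concentrations, loq=loq)
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    c0 = None
    if route == "iv":
        c0 = back_extrapolate_c0(t, c)
        if t.min() > 0:
            t = np.concatenate(([0.0], t))
            c = np.concatenate(([c0], c))
    auc_last, auc_inf, aumc_inf = auc_aumc(t, c, lam, rule=rule, loq=loq)
    mrt = aumc_inf / auc_inf
    result = dict(route=route, lambda_z=lam, t_half=math.log(2) / lam,
                  r2_adj_lambda=r2_adj, n_lambda_points=n_pts,
                  auc_last=auc_last, auc_inf=auc_inf, aumc_inf=aumc_inf,
                  mrt=mrt, c0=c0)
    if route == "iv":
        cl = dose_per_kg / auc_inf
        result.update(cl=cl, vz=dose_per_kg / (lam * auc_inf), vss=cl * mrt)
    return NCAResult(**result)


def bioavailability_from_auc(auc_oral: float, auc_iv: float,
                             dose_ratio: float = 1.0) -> float:
    """Absolute oral bioavailability in percent:
    100 · (AUC_oral / AUC_iv) / (dose_oral / dose_iv)."""
    if auc_iv <= 0 or dose_ratio <= 0:
        raise NCAError("auc_iv and dose_ratio must be positive")
    if auc_oral < 0:
        raise NCAError("auc_oral must be non-negative")
    return 100.0 * (auc_oral / auc_iv) / dose_ratio
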