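"""Mass-balance right-hand side of the goat ractopamine PBPK model.

The state is a vector of compartment *amounts* in μg (never concentrations),
so that conservation — Σ amounts = Σ doses administered — is assertable to
machine precision.  Because every transfer is first order, the whole system
is linear and time-invariant between dosing events:

    dA/dt = M · A

``system_matrix`` builds M once per parameter set; ``rhs`` is the matching
callable for ODE integrators.  Every column of M sums to zero (whatever
leaves one compartment arrives in another or in a cumulative sink), which is
the conservation identity the tests lean on.

Circulation layout: arterial blood perfuses liver (minus the splenic share),
spleen (draining into the liver), kidney, heart and the four membrane-limited
tissue pairs (muscle, fat, brain, rest); venous blood collects every tissue
outflow and passes through the lung back to the arterial side.  Flow-limited
organs return venous blood at C/P equilibrium; membrane-limited tissues
exchange between a vascular and a cellular sub-compartment across a
permeability–area conductance Pa.  The liver clears drug at Clhe·Pfree acting
on its venous-equilibrium concentration C_li/P_li, the kidney at Clre·Pfree
on C_ki/P_ki into cumulative urine.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    AbsolutePhysiology, DoseEvent, DrugParams, MEMBRANE_TISSUES,
)

#: state-vector layout (amounts, μg)
STATE_NAMES = (
    "gastric_contents", "intestinal_contents", "fecal_cumulative",
    "liver", "spleen", "kidney", "heart", "lung",
    "arterial_blood", "venous_blood",
    "muscle_blood", "muscle_tissue", "fat_blood", "fat_tissue",
    "brain_blood", "brain_tissue", "rest_blood", "rest_tissue",
    "hepatic_eliminated_cumulative", "renal_eliminated_cumulative",
)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATE = len(STATE_NAMES)

#: indices of cumulative sinks (never flow back out)
SINKS = ("fecal_cumulative", "hepatic_eliminated_cumulative",
         "renal_eliminated_cumulative")


def permeability_area(physiology: AbsolutePhysiology,
                      drug: DrugParams) -> dict[str, float]:
    """Permeability–area conductance Pa_i (L/h) for each membrane tissue.

    Default convention: the configured permeability value scales the tissue's
    blood flow (Pa = fraction × Q).  With ``permeability_absolute`` the value
    is an absolute conductance in L/h per kg BW instead.
    """
    if drug.permeability_absolute:
        return {t: drug.permeability_fraction[t] * physiology.body_mass
                for t in MEMBRANE_TISSUES}
    return {t: drug.permeability_fraction[t] * physiology.flows[t]
            for t in MEMBRANE_TISSUES}


def bioavailability(drug: DrugParams) -> float:
    """Oral bioavailability F = Ka / (Ka + Kgut): the absorbed share of the
    intestinal first-order race between uptake and fecal transit."""
    total = drug.k_absorption + drug.k_gut
    if total <= 0:
        raise ValueError("Ka + Kgut must be positive to define bioavailability")
    return drug.k_absorption / total


def system_matrix(physiology: AbsolutePhysiology, drug: DrugParams,
                  absorption_form: str = "standard") -> np.ndarray:
    """Build the constant rate matrix M with dA/dt = M·A.

    ``absorption_form`` selects how the intestinal absorption terms are
    written.  ``standard`` (default) absorbs Ka·Ainc into the liver and loses
    Kgut·Ainc to feces, so the fraction absorbed equals Ka/(Ka+Kgut) exactly.
    ``as_printed`` keeps the literal published coefficients, with the
    bioavailability factor F multiplying Ka in both the intestinal loss and
    the hepatic uptake term.
    """
    if absorption_form not in ("standard", "as_printed"):
        raise ValueError(f"unknown absorption_form {absorption_form!r}")

    V = physiology.volumes
    Q = physiology.flows
    P = drug.partition
    Pa = permeability_area(physiology, drug)
    bw = physiology.body_mass
    fu = drug.free_fraction
    cl_he = drug.cl_hepatic * bw * fu    # L/h acting on C_li/P_li
    cl_re = drug.cl_renal * bw * fu      # L/h acting on C_ki/P_ki

    ka_eff = drug.k_absorption
    if absorption_form == "as_printed":
        ka_eff *= bioavailability(drug)

    M = np.zeros((N_STATE, N_STATE))

    def move(src: str, dst: str | None, rate: float) -> None:
        """First-order transfer: rate × A_src leaves src (and enters dst)."""
        i = IDX[src]
        M[i, i] -= rate
        if dst is not None:
            M[IDX[dst], i] += rate

    # GI tract: gastric emptying, then the absorption / fecal-loss race
    move("gastric_contents", "intestinal_contents", drug.k_stomach)
    move("intestinal_contents", "liver", ka_eff)
    move("intestinal_contents", "fecal_cumulative", drug.k_gut)

    # liver: arterial inflow is the hepatic total minus the splenic share;
    # the spleen drains into the liver at its venous equilibrium C_sp/P_sp
    move("arterial_blood", "liver",
         (Q["liver"] - Q["spleen"]) / V["arterial_blood"])
    move("spleen", "liver", Q["spleen"] / (V["spleen"] * P["spleen"]))
    move("liver", "venous_blood", Q["liver"] / (V["liver"] * P["liver"]))
    move("liver", "hepatic_eliminated_cumulative",
         cl_he / (V["liver"] * P["liver"]))

    # spleen arterial inflow (published row's "Q·+(Cab − C/P)" read as
    # Q·(Cab − C/P), as for kidney and heart)
    move("arterial_blood", "spleen", Q["spleen"] / V["arterial_blood"])

    # kidney: flow-limited with renal excretion into cumulative urine
    move("arterial_blood", "kidney", Q["kidney"] / V["arterial_blood"])
    move("kidney", "venous_blood", Q["kidney"] / (V["kidney"] * P["kidney"]))
    move("kidney", "renal_eliminated_cumulative",
         cl_re / (V["kidney"] * P["kidney"]))

    # heart
    move("arterial_blood", "heart", Q["heart"] / V["arterial_blood"])
    move("heart", "venous_blood", Q["heart"] / (V["heart"] * P["heart"]))

    # lung: fed by the entire venous return, releases to arterial blood
    move("venous_blood", "lung", Q["lung"] / V["venous_blood"])
    move("lung", "arterial_blood", Q["lung"] / (V["lung"] * P["lung"]))

    # membrane-limited tissue pairs (published brain row's stray fat/muscle
    # symbols read as the brain analogues, mirroring the muscle row)
    for t in MEMBRANE_TISSUES:
        vb = physiology.blood_sub_volume[t]
        vt = physiology.tissue_sub_volume[t]
        move("arterial_blood", f"{t}_blood", Q[t] / V["arterial_blood"])
        move(f"{t}_blood", "venous_blood", Q[t] / vb)
        move(f"{t}_blood", f"{t}_tissue", Pa[t] / vb)
        move(f"{t}_tissue", f"{t}_blood", Pa[t] / (vt * P[t]))

    return M


def rhs(state: np.ndarray, t: float, physiology: AbsolutePhysiology,
        drug: DrugParams, absorption_form: str = "standard") -> np.ndarray:
    """Time-derivative of the amount vector (μg/h). ``t`` is unused — the
    system is autonomous; doses are applied as state jumps, never as forcing."""
    matrix = system_matrix(physiology, drug, absorption_form)
    deriv = matrix @ np.asarray(state, dtype=float)
    if not np.all(np.isfinite(deriv)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(deriv))]
        raise FloatingPointError(f"non-finite derivative in {bad}")
    return deriv


def apply_dose(state: np.ndarray, event: DoseEvent) -> np.ndarray:
    """Return the state after an instantaneous bolus."""
    out = np.array(state, dtype=float)
    target = "gastric_contents" if event.route == "oral" else "venous_blood"
    out[IDX[target]] += event.amount
    return out


def total_amount(state: np.ndarray) -> float:
    """Drug inventory: compartments plus cumulative sinks (μg)."""
    return float(np.sum(state))
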