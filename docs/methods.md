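# Methods

## Model structure

`racpbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model for ractopamine (RAC), a β-adrenoceptor agonist growth
promoter, in the ~30 kg meat goat. The body is a set of organ compartments
connected by the blood circulation:

* **GI tract** — an oral bolus lands in a single gastric compartment
  (the ruminant forestomachs lumped together), empties into the intestine at
  the first-order rate K_st, and from there races between absorption (K_a,
  into the liver) and fecal transit (K_gut). Oral bioavailability is
  therefore F = K_a/(K_a + K_gut).
* **Flow-limited organs** — liver, spleen, kidney, heart, lung: a single
  well-stirred compartment whose venous outflow leaves at the equilibrium
  concentration C/P, with P the tissue:plasma partition coefficient.
* **Membrane-limited tissues** — muscle, fat, brain and the lumped
  "remaining tissue": each is split into a vascular sub-compartment (a
  fraction of tissue volume) and a cellular sub-compartment, exchanging
  across a permeability–area conductance Pa. Whole-tissue concentration is
  reported as (A_blood + A_tissue)/V.
* **Elimination** — linear hepatic clearance Cl_he acting on the liver's
  venous-equilibrium concentration C_li/P_li (metabolism) and linear renal
  clearance Cl_re on C_ki/P_ki (cumulative urine). Feces collects the
  unabsorbed intestinal fraction.
* **Circulation** — arterial blood perfuses all tissues (the spleen drains
  through the liver, so hepatic inflow is the splenic flow plus the
  remaining arterial share); venous blood collects every outflow and passes
  through the lung. "Plasma" is reported as the venous-blood concentration
  divided by a configurable blood:plasma ratio, 1.0 by default.

The state is kept in amounts (μg), never concentrations, so total drug
inventory (compartments + cumulative sinks) must equal the administered dose
exactly; the tests assert this to 1e-6 relative and the rate matrix is
constructed so that every column sums to zero.

Three published transcription glitches in the mass-balance table are
repaired in the obvious way (a "VB" volume symbol in the liver row read as
V_li; "Q·+(Cab − C/P)" in the spleen/kidney/heart rows read as
Q·(Cab − C/P); stray fat/muscle symbols in the brain row read as their brain
analogues, mirroring the muscle row). The literal published absorption terms
carry the factor F on K_a in both the intestinal-loss and hepatic-uptake
terms; because that makes the absorbed fraction F·K_a/(K_gut + F·K_a) rather
than the F the source text itself states, the default `absorption_form =
"standard"` absorbs K_a·A_inc and loses K_gut·A_inc, so the absorbed
fraction is exactly K_a/(K_a+K_gut); the literal form remains available as
`"as_printed"`.

## Parameters and defaults

Organ mass fractions, flow fractions, partition coefficients, permeability
fractions, clearances and GI rate constants are the model's reference values
for the goat (see `src/racpbpk/data/goat_default.yaml`). Several quantities
any such model needs are not part of that reference set and carry package
defaults, all configurable:

| parameter | default | rationale |
|---|---|---|
| cardiac output | 5.97 L/h/kg BW | small-ruminant PBPK literature value |
| brain flow | 0.02 of CO | carved out of the remaining-tissue flow so perfusion still sums to CO |
| spleen flow | 0.02 of CO | carved out of the total hepatic inflow (anatomical drainage) |
| blood volume | 0.07 of BW, 1/3 arterial | standard ruminant values; taken out of the remaining-tissue mass |
| vascular fraction of membrane tissues | muscle 0.04, fat 0.02, brain 0.04, rest 0.04 | standard PBPK vascular spaces |
| plasma free fraction | 1.0 | no binding correction unless configured |
| blood:plasma ratio | 1.0 | plasma ≡ venous blood concentration |

Permeability values for the membrane-limited tissues are interpreted as
fractions of the tissue's blood flow (Pa = fraction × Q, the common PBPK
convention); a config switch (`permeability_absolute`) treats them as
absolute conductances in L/h/kg instead. Tissue density is fixed at 1 kg/L
so μg/kg and μg/L interconvert trivially. A "liver tissue uptake rate
constant" named in the source material has no governing equation and is not
implemented, and the "central compartment volume" appearing in its
sensitivity table has no home in the mass balances and is likewise omitted.

## Numerical integration

Every transfer in the model is first order, so between dosing events the
system is linear and time-invariant: dA/dt = M·A with a constant 20×20 rate
matrix. The default integration path propagates the state with matrix
exponentials (`scipy.linalg.expm`), cached per distinct step length —
exact for this model to machine precision, and fast enough that a
56-day simulation costs ~10 ms. Doses are hard state jumps with the
propagation restarted at each event time, never forcing pulses. A stiff
`solve_ivp` path (LSODA or BDF, rtol 1e-8 / atol 1e-10 μg) is retained and
cross-checked against the propagator in the test suite as an independent
integration route. The default output grid is 0.1 h for 24 h after any dose
and 1 h elsewhere; interpolation between grid points is linear by default
(monotone cubic available).

## Non-compartmental analysis

λz is fitted by log-linear regression over the best terminal window
(maximum adjusted R², at least three points, Cmax excluded — the usual
"best-fit" convention, since the original software settings are not
recorded). AUC/AUMC use the linear-up/log-down trapezoid with Clast/λz tail
extrapolation (all-linear available). Concentrations below the LOQ
(0.5 μg/L) are excluded from the λz fit and treated as missing, not zero.
IV C0 is back-extrapolated through the first two positive samples and closes
the initial area when sampling starts after t=0. Cl = dose/AUC∞,
Vz = Cl/λz, Vss = Cl·MRT are reported for IV profiles only; oral MRT is
AUMC/AUC without IV correction. Per-animal NCA is averaged arithmetically
(mean ± SD), which is why dose/mean-AUC need not equal mean Cl.

Note one structural property verified in the tests: because oral absorption
enters the liver directly, the oral/IV AUC ratio equals
F × Q_li/(Q_li + Cl_he·BW·Pfree) — the GI-absorbed fraction times hepatic
first-pass availability (≈0.98 at the reference parameters) — not F alone.

## Parameter fitting

Observed residue data span three decades, so the default objective is the
log-residual sum of squares, Σ(log(pred+ε) − log(obs+ε))² with ε = LOQ/2,
pooled over matrices and animals and minimised by bounded trust-region
nonlinear least squares from the published starting values. A relative
(1/obs-weighted) alternative is available. Per-parameter standard deviations
come from the Jacobian at the optimum (linearisation) and are approximate;
the near-zero SDs printed for the original fit are not reproducible without
the original objective and are treated as qualitative. A sequential
multi-stage interface (`fit_stages`) supports fitting absorption from plasma
first and tissue partitions second, since joint fitting of all 18 drug
parameters from sparse data is ill-conditioned.

## Sensitivity analysis

SC = (f(x+Δx) − f(x))/Δx with Δx = 1% of x (forward difference as the
method is conventionally printed; central available), NSC = SC·x/f(x), and
|NSC| ≥ 0.25 flags a sensitive parameter. The output functional defaults to
the concentration at 120 h after the last dose of the exposure scenario —
the midpoint of the 1–13 day window in which the withdrawal-time decisions
fall, consistent with evaluating sensitivity "during the post-exposure
period". AUC-over-exposure and Cmax are available, with the caveat that
total AUC of a linear, clearance-limited model is nearly flow-independent
and therefore blind to the distribution parameters a residue analysis cares
about. Perturbation semantics: cardiac output scales every organ flow (and,
under the flow-scaled convention, every membrane conductance); individual
organ flows are perturbed with venous return recomputed as the sum; body
weight is perturbed at fixed absolute cardiac output with the mg/kg dose
scaling along (with per-kg physiology held fixed, a body-weight change would
merely rescale the whole system and have no effect at all). Elasticities
below ~1e-3 in magnitude are numerically zero and their sign carries no
information.

## Withdrawal-time estimation

The exposure scenario is 28 daily oral gavages of 1.0 mg/kg BW. A
population of 500 virtual animals is built by sampling the sensitive drug
parameters independently from lognormal distributions with median at the
reference value, CV 0.20, truncated at ±3 SD on the log scale (the original
variability settings are unpublished; all of this is configurable). Each
individual is simulated through dosing plus a 45-day washout on a 1 h grid;
the per-tissue withdrawal time is the last down-crossing below the MRL
(muscle 10, fat 10, liver 40, kidney 90 μg/kg — CAC limits), located by
log-linear interpolation between grid points. The population is summarised
by the distribution-free one-sided 95th-percentile/95%-confidence upper
tolerance bound: the k-th order statistic with k the smallest integer such
that the Binomial(n, 0.95) CDF at k−1 reaches 0.95 (k = 484 at n = 500;
n ≥ 59 required). Hours are reported alongside whole days (ceiling of
h/24). An FDA-style log-linear regression tolerance-limit alternative is
provided (`regression_tolerance_wt`).

## Synthetic observed data

The fixtures module emulates the statistical structure of a residue study:
the noise-free mean is the simulator's own prediction (one shared code
path, no second model), multiplied per animal/time/matrix by lognormal
noise with CV 0.15 (the scale of typical residue-assay relative SDs);
values below the LOQ (0.5 μg/kg or μg/L) are flagged `<LOQ` rather than
substituted, and values below the LOD (0.15) are dropped. Scenarios cover
single-dose IV and oral plasma kinetics, cumulative urinary excretion
(noise applied to increments so curves stay non-decreasing), and the
nine-matrix tissue-depletion study at withdrawal days 1–21 after 28-day
dosing. What these fixtures deliberately do not emulate: between-animal
kinetic variability (every animal shares the generating parameter set —
only assay noise varies), assay recovery bias, and any model misspecification.
Tests that pass on them therefore demonstrate self-consistency of the
pipeline and its statistics, not predictive accuracy for real goats.

## Known limitations

* The model is linear throughout: no saturable clearance, no enterohepatic
  recirculation, no metabolite kinetics, no receptor binding.
* With the reference partition coefficients, washout tissue concentrations
  track plasma, so the order in which tissues cross their MRLs is fixed by
  MRL_i/P_i: kidney (90/1.77) crosses first and muscle (10/1.07) last, and
  the model consequently predicts the *shortest* withdrawal time for kidney
  among the four edible tissues. Field residue data for RAC show marked
  renal accumulation that a partition coefficient of 1.77 cannot represent;
  reproducing kidney-limited withdrawal times would require a larger
  effective kidney partition (or an explicit intrarenal urine pool), which
  the reference parameter set does not contain.
* The deep "remaining tissue" depot (P = 9.09, very low permeability) gives
  plasma a months-long shallow terminal phase; quantities that integrate to
  infinity (AUC∞, Vss) depend on how this tail is handled.
* Reported problem sizes: the Monte Carlo uses 500 individuals on a 1 h
  grid over 63 days; the fitting demonstrations use single-dose multi-matrix
  profiles with 4 free parameters. Both complete in seconds on one core
  thanks to the matrix-exponential propagator.
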