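# Methods

## Flux balance analysis and shadow prices

The FBA problem is `max c'v` subject to `S v = 0` and bounds `lb <= v <= ub`,
solved with HiGHS (through scipy). Exchange fluxes are negative for uptake;
setting an uptake rate r places the exchange lower bound at -r (a capacity,
not an equality — the optimum may leave substrate unused).

Metabolite shadow prices follow

    lambda_i = - dZ / d(eps_i),

where `eps_i` is the rate of a hypothetical free source of metabolite i.
`lambda_i < 0` marks a limiting metabolite (a free source would raise the
objective), `> 0` one in excess, `0` no effect. The mapping from the
solver's equality-row duals to this convention is fixed by a
finite-difference oracle (`finite_difference_duals`), which perturbs each
balance row by ±1e-4 and compares two-sided difference quotients against
the reported dual at tolerance 1e-3 — the sign convention is *measured*,
never assumed from solver documentation.

Duals are not unique at degenerate vertices. Two systematic cases arise and
are flagged rather than silently passed:

* **Conserved-moiety pairs.** Every reaction that touches NADH also touches
  NAD+ with the opposite coefficient, so the two balance rows are exact
  negatives and a single-row perturbation is infeasible; only the
  *difference* of the two duals is determined. The same holds for
  NADP(H) and the quinone/quinol pair. This is precisely why the pair
  index lambda_ARC (below) is the meaningful quantity.
* **Alternate optima**, detected as disagreeing left/right difference
  quotients.

## ARC sensitivity

The available-reducing-capacity index of an objective Z is

    lambda_ARC^Z = lambda_NADH^Z - lambda_NAD^Z,

the response of Z to converting one unit of NAD+ into NADH at constant
pool size (equivalently, a joint +NADH source / +NAD+ sink perturbation,
which is always feasible even when the single rows are degenerate). It is
computed per compartment; the headline scalar uses the cytosolic pool
(fermentative NADH turnover is cytosolic), with mitochondrial and summed
variants always reported alongside, since published figures rarely state
which pool they used.

The ethanol sensitivity at a metabolic state is bi-level: (1) maximise
biomass at the given uptake bounds; (2) maximise ethanol export with the
biomass flux pinned to its step-1 optimum within a relative tolerance of
1e-6 and the same uptake bounds, reading sensitivities from the step-2
duals. Pinning *all* fluxes would collapse step 2 to a single point with
meaningless duals; pinning only biomass keeps the state while leaving a
non-trivial LP. The 1e-6 pinning band admits a secondary-objective leak of
order 1e-5 flux units; assertions about "zero ethanol" use a 5e-5 band.
If the tight pinning is numerically infeasible it is retried once at 1e-4.

## Loop removal

`enforce_loopless` returns a flux distribution with the same objective
value and exchange fluxes but no circulation around internal
stoichiometrically balanced cycles. Networks up to 500 reactions use the
mixed-integer formulation (binary direction indicators, potential
variables constrained to the null space of the internal stoichiometry);
larger networks use l1 cycle-flux minimisation at fixed exchanges, which
removes every removable cycle. Duals are always reported from the plain
LP: a MILP has no meaningful duals, and the loop constraints do not alter
the optimal value.

## Phase planes

`compute_phpp` scans a 2-D grid of carbon and oxygen uptake capacities
(defaults 41x41 over 0-20 and 0-25 mmol/gDW/h; tests and the acceptance
analysis use 11x13 over 0-10 x 0-12 to keep LP counts small). Each point
stores the growth optimum, the bi-level ethanol optimum, molar yield, the
ethanol ARC sensitivity and the extracellular carbon/oxygen duals.
Phases are connected regions of constant marginal behaviour: adjacent
points share a phase iff their carbon and oxygen duals agree after
rounding to 1e-6; labels are ordered by first appearance in a row-major
scan. A numerical-gradient break detector is used as a test oracle for the
phase boundaries, not as the classifier. The biomass line of optimality
takes, per carbon value, the smallest oxygen uptake attaining the maximal
biomass-per-carbon ratio (ties resolve toward cheaper oxygen).

## The synthetic core network

A ~29-reaction lumped model of a Crabtree-negative xylose-fermenting
yeast. Design choices that carry the analysis:

* **Xylose reductase with dual cofactor linkage.** The enzyme accepts
  NADPH and NADH; both activities are present (`xr_cofactor="dual"`),
  strictly-NADPH and strictly-NADH variants are available. Because xylitol
  dehydrogenase is strictly NAD+-linked, any NADPH-linked XR flux leaves a
  net cytosolic NADH surplus — the xylose-specific redox burden. Cofactor
  flexibility is also what makes the NADH pool more valuable on xylose
  than on glucose (extra NADH substitutes the NADPH demand and spares
  oxidative-PPP carbon), widening the limiting (lambda<0) region of the
  xylose plane relative to the glucose plane.
* **Finite fermentative capacity.** Pyruvate decarboxylase is capped at
  3 mmol/gDW/h — the low fermentative capacity characteristic of
  Crabtree-negative yeasts. The cap produces the zero-sensitivity band of
  the phase plane (where ethanol is enzyme-pinned, marginal reducing
  capacity has no effect) and the zero plane under partial respiratory
  inhibition.
* **Capacity-limited glycerol branch** (2 mmol/gDW/h glycerol export, via
  a lumped G3P shunt costing ATP and carbon) as the only anaerobic
  cytosolic NADH sink. It permits slow growth when the respiratory chain
  is deleted (making the knockout plane non-degenerate) while keeping
  anaerobic growth collapsed to ~5% of the aerobic maximum.
* **Respiratory chain with explicit proton motive force.** CINADH (complex
  I) pumps, COX pumps, AOX does not; ATP synthase converts pmf to ATP. The
  default P/O ratios are 2.0 through CINADH+COX and 4/3 through the
  non-pumping alternative branch, so losing CINADH (rotenone) or routing
  through AOX lowers the ATP yield per NADH — the mechanism the inhibition
  analysis exploits.
* **ATP-expensive biomass** (60 mmol ATP, 13.67 mmol pyruvate, 8 mmol
  NADPH per gDW). Oxygen-limited growth is then ATP-limited, which makes
  respiro-fermentative overflow optimal left of the biomass line; with a
  cheaper biomass the optimum never ferments and the fermentative region
  is empty.

Carbon bookkeeping of every lump is checked at construction against
declared per-metabolite carbon counts (the biomass equation rounds to
41 mmol C/gDW within 0.05).

What the toy does *not* emulate: genome-scale pathway redundancy, polyol
(arabitol/ribitol/xylitol) by-products, gene regulation, and the numeric
flux magnitudes of any published reconstruction. Tests passing on this
network establish that the *methods* behave as described on a network with
the right redox topology, not that a particular organism's fluxes are
reproduced.

### Known boundary behaviour

At exactly zero oxygen uptake the optimum is growth-arrested and the
ethanol optimum is pinned at the PDC capacity, so the ethanol ARC
sensitivity is 0 there even where the adjacent microaerobic cells are
positive. Region-structure checks therefore scan from the biomass line
down to the smallest positive oxygen uptake. Similarly, the
zero-sensitivity plane under 80% COX+AOX inhibition holds across the
fermentation-saturated regime (carbon uptake >= ~6 mmol/gDW/h on the
default axes); at strongly carbon-limited states a marginal unit of NADH
still trades against carbon and the sensitivity is non-zero.

## Inhibition semantics

`inhibit(network, reaction, fraction, reference_flux)` caps the reaction at
(1-fraction) x reference_flux. The reference is an explicit argument
because percent inhibition is ambiguous: relative to the *flux in the
uninhibited optimum* (used for the trajectory simulations, recomputed per
time point) or relative to the *capacity* (maximum feasible flux at the
state — the Vmax reading, used for the plane experiments). The capacity
reading matters for AOX, which carries zero flux in unstressed optima: an
optimum-flux reference would silently turn an 80% inhibition into a
knockout, erasing the distinction between the two experiments.

## Batch-culture model

State (x, S, P, C_L) in g/L with

    dx/dt = mu x,   dS/dt = -qS x,   dP/dt = qP x,
    mu = mu_max S/(S+Ks) f1(t),  qP = (alpha mu + beta) f2(t),
    qS = mu/Yo + m + qP/YP,      f = q/(q + e^{-v t}).

Under oxygen limitation all transferred oxygen is consumed: C_L sits at
quasi-steady zero and qO2 = kLa C*/x; the full dC_L/dt equation is
integrated only when the limitation flag is off. Integration is adaptive
(LSODA) with an event that terminates at substrate depletion, after which
the state is held constant; this avoids right-hand-side chatter at the
S = 0 kink. Defaults (mu_max 0.12 1/h, Ks 1.5 g/L, Yo 0.28, YP fixed at
the theoretical 0.511 g/g, m 0.02, alpha 2.2, beta 0.01, q1 = q2 = 0.05,
v1 0.25, v2 0.2 1/h, C* 7.5 mg/L, S0 15 g/L, x0 0.25 g/L) describe a
microaerobic xylose batch finishing in ~40-50 h with specific xylose
uptake 0.7-1.0 g/g/h, inside the range reported for xylose-fermenting
yeast, so the converted molar rates land in the responsive part of the
toy phase plane. The growth delay can be written q1 = k mu_max; q1 is the
fitted quantity and k is derived afterwards.

Fitting minimises per-variable range-normalised least squares over
(mu_max, Ks, Yo, m, alpha, beta, q1, q2, v1, v2) with YP fixed, via
trust-region reflective least squares. Multi-start: a data-driven
heuristic first guess (log-slope for mu_max, overall yields for Yo and
alpha) plus seeded log-uniform draws within bounds. The fitting residuals
use a fixed-step RK4 integration (step 0.125 h, error ~1e-6 relative to
the adaptive solver — far below data noise) because the optimiser calls
the model thousands of times. Trajectory-level agreement is the contract;
individual parameters (notably Ks and the delay constants) are weakly
identifiable from a single batch and are reported with that caveat.

## Culture-to-FBA coupling

Mass-specific rates convert to molar with MW xylose 150.13, O2 32.00,
ethanol 46.07 g/mol; biomass is dry weight. Each time point is an
independent steady-state LP (quasi-static coupling; no dynamic feedback).
Rate points are dropped once the substrate falls below a threshold
(tests and examples use Ks): after depletion the specific rates vanish
and a steady-state interpretation no longer applies. Inhibition caps the
target reaction at (1-fraction) of its flux in the uninhibited optimum at
the same time point, for points past the start time; a zero fraction adds
no constraint at all (a cap sitting exactly on the optimal flux would
leave the optimum unchanged but perturb degenerate duals). The
flux-carrying-set report compares matched uninhibited/inhibited solutions
at the point of maximal ethanol flux past the inhibition start; shift
magnitudes reflect the lumped stoichiometry (pmf-aggregating steps such as
ATP synthase show the largest absolute shifts, with complex I always among
the top decreases).

## Numerical conventions

Feasibility 1e-9, duality/flux-carrying tolerance 1e-6, loop-removal
objective preservation 1e-8, sensitivity zero-band 1e-6 — all configurable.
LP solves use one fixed HiGHS configuration and the network's declared
variable order, so repeated solves are bit-identical. All randomness
(dataset noise, multi-start draws) flows from explicit integer seeds.

## Limitations

* The toy network's absolute fluxes and yields are not calibrated to any
  organism; only the qualitative geometry is designed.
* Individual shadow prices of conserved-pair metabolites are reported as
  the solver returns them but are meaningful only as differences.
* The ethanol sensitivity depends on which pool (cytosolic,
  mitochondrial, summed) is read; all are reported, the cytosolic value
  is the default.
* The kinetic model has no direct oxygen effect on growth; oxygen enters
  only through the transfer-limited uptake used by the FBA coupling.
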