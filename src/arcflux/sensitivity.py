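"""Shadow-price sensitivity of the NAD(H/+) redox pair (ARC).

The available reducing capacity (ARC) of the NAD(H/+) pair affects an FBA
objective Z through the difference of the two species' shadow prices,

    lambda_ARC^Z = lambda_NADH^Z - lambda_NAD^Z,

which measures the response of Z to converting one unit of NAD+ into NADH
(a net gain of reducing capacity at constant pool size). lambda_ARC < 0
means ARC limits the objective, > 0 means ARC is in excess, 0 means no
effect. In networks where every reaction touches NADH and NAD+ together the
two balance rows are linearly dependent and only this difference is
well-defined — which is why the pair index, not the individual shadow
prices, is the meaningful quantity.

The ethanol sensitivity at a metabolic state is computed with a bi-level
procedure: (1) maximise biomass at the given uptake bounds — this selects
the physiological state; (2) re-optimise for ethanol with the biomass flux
pinned at its step-1 optimum (within a relative tolerance) and read the
sensitivities from the duals of this second LP. Only the biomass flux and
the uptake bounds are carried into step 2; pinning every flux would leave a
single feasible point with meaningless duals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import FBASolution, solve_fba
from .network import MetabolicNetwork

__all__ = [
    "SensitivityRecord",
    "arc_sensitivity",
    "objective_sensitivity_at_state",
    "biomass_arc_sensitivity",
    "DEFAULT_COMPARTMENT",
]

DEFAULT_COMPARTMENT = "c"  # cytosolic pool is the headline lambda_ARC
ZERO_BAND = 1e-6

_NADH_BASE = "nadh"
_NAD_BASE = "nad"


def _cofactor_ids(network: MetabolicNetwork, compartment: str) -> tuple[str, str]:
    nadh = f"{_NADH_BASE}_{compartment}"
    nad = f"{_NAD_BASE}_{compartment}"
    have = set(network.metabolite_ids)
    if nadh not in have or nad not in have:
        cands = sorted(m for m in have if m.startswith(("nad", "nadh")))
        raise KeyError(
            f"NAD(H) pair not found in compartment {compartment!r}; "
            f"available cofactor ids: {cands}"
        )
    return nadh, nad


def classify(value: float, zero_band: float = ZERO_BAND) -> str:
    if value < -zero_band:
        return "limiting"
    if value > zero_band:
        return "excess"
    return "no_effect"


@dataclass
class SensitivityRecord:
    """Per-compartment NAD(H) shadow prices and the ARC index for one state."""

    objective_id: str
    lambda_nadh: dict[str, float]
    lambda_nad: dict[str, float]
    lambda_arc: dict[str, float]
    classification: dict[str, str]
    default_compartment: str = DEFAULT_COMPARTMENT
    extras: dict = field(default_factory=dict)

    @property
    def arc(self) -> float:
        """The declared-default scalar: lambda_ARC of the default compartment.

        NaN when the network carries no NAD(H) pair at all.
        """
        return self.lambda_arc.get(self.default_compartment, float("nan"))

    @property
    def arc_summed(self) -> float:
        """Pooled variant: sum of per-compartment lambda_ARC values."""
        return float(sum(self.lambda_arc.values()))

    def to_row(self) -> dict:
        row = {"objective_id": self.objective_id}
        for comp, val in self.lambda_arc.items():
            row[f"lambda_nadh_{comp}"] = self.lambda_nadh[comp]
            row[f"lambda_nad_{comp}"] = self.lambda_nad[comp]
            row[f"lambda_arc_{comp}"] = val
            row[f"class_{comp}"] = self.classification[comp]
        return row


def arc_sensitivity(
    solution: FBASolution,
    network: MetabolicNetwork,
    compartment: str | None = None,
    zero_band: float = ZERO_BAND,
) -> SensitivityRecord:
    """Build a :class:`SensitivityRecord` from an optimal solution's duals.

    With ``compartment=None`` every compartment holding an NAD(H) pair is
    reported; the record's scalar ``arc`` uses the default (cytosolic) pool.
    """
    if not solution.ok:
        raise ValueError("arc_sensitivity requires an optimal solution with duals")
    comps = (
        [compartment]
        if compartment
        else sorted(
            {
                m.compartment
                for m in network.metabolites
                if m.id.startswith((_NADH_BASE + "_", _NAD_BASE + "_"))
            }
        )
    )
    lam_nadh, lam_nad, lam_arc, cls = {}, {}, {}, {}
    for comp in comps:
        nadh, nad = _cofactor_ids(network, comp)
        lh = solution.duals[nadh]
        ln = solution.duals[nad]
        lam_nadh[comp] = lh
        lam_nad[comp] = ln
        lam_arc[comp] = lh - ln
        cls[comp] = classify(lh - ln, zero_band)
    default = compartment or DEFAULT_COMPARTMENT
    if default not in lam_arc and comps:
        default = comps[0]
    return SensitivityRecord(
        objective_id=solution.objective_id,
        lambda_nadh=lam_nadh,
        lambda_nad=lam_nad,
        lambda_arc=lam_arc,
        classification=cls,
        default_compartment=default,
    )


def biomass_arc_sensitivity(
    network: MetabolicNetwork,
    uptakes: dict[str, float],
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> SensitivityRecord:
    """Single-level ARC sensitivity of biomass at the given uptake bounds.

    ``uptakes`` maps exchange ids to uptake capacities (>= 0).
    """
    eb = dict(extra_bounds or {})
    for ex, rate in uptakes.items():
        if rate < 0:
            raise ValueError(f"uptake rate for {ex!r} must be >= 0")
        eb[ex] = (-float(rate), network.get_reaction(ex).upper_bound)
    sol = solve_fba(network, extra_bounds=eb)
    if not sol.ok:
        raise ValueError(f"biomass FBA {sol.status} at uptakes {uptakes}")
    rec = arc_sensitivity(sol, network)
    rec.extras["mu"] = sol.objective_value
    rec.extras["solution"] = sol
    return rec


def objective_sensitivity_at_state(
    network: MetabolicNetwork,
    uptakes: dict[str, float],
    secondary_objective_id: str = "EX_etoh",
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    fix_rel_tol: float = 1e-6,
) -> SensitivityRecord:
    """Bi-level sensitivity of a secondary objective at a biomass-optimal state.

    Step 1 maximises biomass under the uptake bounds; step 2 maximises the
    secondary objective (ethanol exchange by default) with the biomass flux
    fixed at its step-1 optimum within ``fix_rel_tol``. If the numerically
    tight fixing makes step 2 infeasible it is retried once at 1e-4 before
    raising.
    """
    eb = dict(extra_bounds or {})
    for ex, rate in uptakes.items():
        if rate < 0:
            raise ValueError(f"uptake rate for {ex!r} must be >= 0")
        eb[ex] = (-float(rate), network.get_reaction(ex).upper_bound)
    step1 = solve_fba(network, extra_bounds=eb)
    if not step1.ok:
        raise ValueError(f"step-1 biomass FBA {step1.status} at uptakes {uptakes}")
    mu = step1.objective_value
    bio = step1.objective_id

    for tol in (fix_rel_tol, 1e-4):
        eb2 = dict(eb)
        pad = abs(mu) * tol + 1e-12
        eb2[bio] = (mu - pad, mu + pad)
        step2 = solve_fba(network, objective_id=secondary_objective_id, extra_bounds=eb2)
        if step2.ok:
            break
    else:  # pragma: no cover - loop always breaks or falls through to raise
        pass
    if not step2.ok:
        raise RuntimeError(
            f"step-2 LP {step2.status} even after relaxing the biomass fixing; "
            f"state uptakes {uptakes}"
        )
    rec = arc_sensitivity(step2, network)
    rec.extras["mu"] = mu
    rec.extras["secondary_optimum"] = step2.objective_value
    rec.extras["solution"] = step2
    rec.extras["step1_solution"] = step1
    return rec
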