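"""Metabolic network data model, SBML I/O and constraint editing.

The network is a plain stoichiometric model: metabolites with compartments,
reactions with signed stoichiometry and flux bounds, and a designated
objective reaction. All editing operations (:func:`set_uptake`,
:func:`knockout`, :func:`inhibit`) return modified copies; a network is never
mutated in place, so grid scans and trajectory loops are side-effect free.

Sign convention: exchange flux < 0 is uptake, > 0 is secretion. Setting an
uptake rate *r* therefore sets the exchange lower bound to ``-r``.

SBML read/write goes through cobrapy (Level 3 + fbc on write; fbc or
note-encoded bounds accepted on read).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetworkError",
    "load_sbml",
    "write_sbml",
    "set_uptake",
    "knockout",
    "inhibit",
]

_BOUND_INF = 1000.0


class NetworkError(ValueError):
    """Raised for malformed networks or invalid edits."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry (metabolite id -> coefficient).

    Bounds are in mmol gDW^-1 h^-1 (the biomass reaction's flux is h^-1 by
    the usual convention of precursor coefficients in mmol/gDW).
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = _BOUND_INF
    name: str = ""
    is_exchange: bool = False
    subsystem: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )


@dataclass
class MetabolicNetwork:
    """An ordered collection of metabolites and reactions plus an objective.

    ``stoichiometric_matrix()`` returns the dense m x n matrix S with one row
    per metabolite (in list order) and one column per reaction.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str | None = None
    compartments: dict[str, str] = field(
        default_factory=lambda: {"c": "cytosol", "m": "mitochondrion", "e": "extracellular"}
    )

    def __post_init__(self):
        self.validate()

    # -- indexing ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    def get_reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index()[rid]]
        except KeyError:
            raise NetworkError(f"unknown reaction id {rid!r}") from None

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        mids = self.metabolite_ids
        if len(set(mids)) != len(mids):
            raise NetworkError("duplicate metabolite ids")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            raise NetworkError("duplicate reaction ids")
        known = set(mids)
        for m in self.metabolites:
            if m.compartment not in self.compartments:
                raise NetworkError(
                    f"metabolite {m.id!r}: compartment {m.compartment!r} not declared"
                )
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise NetworkError(f"reaction {r.id!r}: unknown metabolites {sorted(missing)}")
            if r.is_exchange and len(r.stoichiometry) != 1:
                raise NetworkError(
                    f"exchange reaction {r.id!r} must touch exactly one metabolite"
                )
        if self.objective_id is not None and self.objective_id not in set(rids):
            raise NetworkError(f"objective_id {self.objective_id!r} does not resolve")

    # -- matrix view ------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        midx = self.metabolite_index()
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                S[midx[mid], j] = coef
        return S

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            objective_id=self.objective_id,
            compartments=dict(self.compartments),
        )

    # -- summaries --------------------------------------------------------
    def summary_json(self) -> str:
        return json.dumps(
            {
                "n_metabolites": len(self.metabolites),
                "n_reactions": len(self.reactions),
                "objective_id": self.objective_id,
                "reactions": {
                    r.id: {"lb": r.lower_bound, "ub": r.upper_bound, "exchange": r.is_exchange}
                    for r in self.reactions
                },
            },
            indent=1,
        )

    def _replace_reaction(self, rid: str, **changes) -> "MetabolicNetwork":
        net = self.copy()
        j = net.reaction_index()[rid]
        net.reactions[j] = replace(net.reactions[j], **changes)
        return net


# -- constraint editing ----------------------------------------------------

def set_uptake(network: MetabolicNetwork, exchange_id: str, rate: float) -> MetabolicNetwork:
    """Return a copy permitting uptake of at most ``rate`` through an exchange.

    ``rate`` is a non-negative uptake capacity (mmol gDW^-1 h^-1); the
    exchange lower bound becomes ``-rate`` (uptake = negative exchange flux).
    """
    rxn = network.get_reaction(exchange_id)
    if not rxn.is_exchange:
        raise NetworkError(f"{exchange_id!r} is not an exchange reaction")
    if rate < 0:
        raise NetworkError(f"uptake rate must be >= 0, got {rate}")
    return network._replace_reaction(exchange_id, lower_bound=-float(rate))


def knockout(network: MetabolicNetwork, reaction_ids) -> MetabolicNetwork:
    """Return a copy with both bounds of every listed reaction set to zero."""
    rids = list(reaction_ids)
    known = set(network.reaction_ids)
    unknown = [r for r in rids if r not in known]
    if unknown:
        raise NetworkError(f"unknown reaction ids: {unknown}")
    net = network.copy()
    idx = net.reaction_index()
    for rid in rids:
        j = idx[rid]
        net.reactions[j] = replace(net.reactions[j], lower_bound=0.0, upper_bound=0.0)
    return net


def inhibit(
    network: MetabolicNetwork,
    reaction_id: str,
    fraction: float,
    reference_flux: float,
) -> MetabolicNetwork:
    """Return a copy with the reaction capped at ``(1 - fraction) * reference_flux``.

    ``fraction`` is the inhibited fraction in [0, 1]; ``reference_flux`` is
    the flux (>= 0) the cap is taken relative to — typically the reaction's
    flux in the uninhibited optimum at the same uptake constraints, or its
    maximum feasible flux if the inhibition is read as a capacity (Vmax)
    reduction. For reversible reactions the lower bound is symmetrically
    tightened.
    """
    if not 0.0 <= fraction <= 1.0:
        raise NetworkError(f"inhibition fraction must be in [0, 1], got {fraction}")
    if reference_flux < 0:
        raise NetworkError(f"reference_flux must be >= 0, got {reference_flux}")
    rxn = network.get_reaction(reaction_id)
    cap = (1.0 - fraction) * float(reference_flux)
    new_ub = min(rxn.upper_bound, cap)
    new_lb = max(rxn.lower_bound, -cap) if rxn.lower_bound < 0 else rxn.lower_bound
    new_lb = min(new_lb, new_ub)
    return network._replace_reaction(reaction_id, lower_bound=new_lb, upper_bound=new_ub)


# -- SBML I/O via cobrapy ---------------------------------------------------

def _to_cobra(network: MetabolicNetwork):
    import cobra

    model = cobra.Model("arcflux_model")
    mets = {}
    for m in network.metabolites:
        cm = cobra.Metabolite(m.id, name=m.name or m.id, compartment=m.compartment)
        mets[m.id] = cm
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in network.reactions:
        cr = cobra.Reaction(r.id, name=r.name or r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        cr.subsystem = r.subsystem
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in network.reactions:
        model.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coef for mid, coef in r.stoichiometry.items()}
        )
    if network.objective_id is not None:
        model.objective = network.objective_id
    return model


def _from_cobra(model) -> MetabolicNetwork:
    comps = dict(model.compartments) or {}
    metabolites = []
    for m in model.metabolites:
        comp = m.compartment or "c"
        comps.setdefault(comp, comp)
        metabolites.append(Metabolite(id=m.id, name=m.name or "", compartment=comp))
    reactions = []
    for r in model.reactions:
        reactions.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                is_exchange=len(r.metabolites) == 1,
                subsystem=r.subsystem or "",
            )
        )
    objective_id = None
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(model)
        if coeffs:
            objective_id = max(coeffs, key=lambda k: abs(coeffs[k])).id
    except Exception:
        pass
    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        compartments=comps,
    )


def load_sbml(path: str, objective_id: str | None = None) -> MetabolicNetwork:
    """Read an SBML (Level 2/3, fbc or note-encoded bounds) file.

    Raises :class:`NetworkError` for unreadable files. If the file carries no
    objective and ``objective_id`` is not given, an error instructs the
    caller to set one.
    """
    import cobra.io

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parser errors
        raise NetworkError(f"cannot read SBML file {path!r}: {exc}") from exc
    net = _from_cobra(model)
    if objective_id is not None:
        net.objective_id = objective_id
        net.validate()
    if net.objective_id is None:
        raise NetworkError(
            f"SBML file {path!r} declares no objective; "
            "pass objective_id= or set network.objective_id"
        )
    return net


def write_sbml(network: MetabolicNetwork, path: str) -> None:
    """Write the network as SBML Level 3 + fbc."""
    import cobra.io

    cobra.io.write_sbml_model(_to_cobra(network), str(path))
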