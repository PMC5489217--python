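"""Phenotypic phase planes: optimal growth over a 2-D grid of carbon and
oxygen uptake rates, phase detection, lines of optimality and attached
ARC-sensitivity surfaces.

At each grid point the biomass-maximising FBA gives the growth surface; the
bi-level procedure (ethanol maximised at fixed optimal biomass) gives the
ethanol surface, the molar ethanol yield and the ethanol ARC sensitivity.
Phases are regions of constant marginal behaviour: two adjacent grid points
share a phase iff the quantised shadow prices of the extracellular carbon
and oxygen metabolites match. The biomass line of optimality is, per carbon
value, the smallest oxygen uptake reaching the maximal biomass-per-carbon
ratio; ties resolve toward cheaper oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import MetabolicNetwork
from .sensitivity import objective_sensitivity_at_state
from .fba import solve_fba

__all__ = ["PhPPGrid", "compute_phpp", "detect_phases", "line_of_optimality"]


@dataclass
class PhPPGrid:
    carbon_axis: np.ndarray
    o2_axis: np.ndarray
    carbon_exchange_id: str
    o2_exchange_id: str
    mu_surface: np.ndarray          # h^-1; NaN where infeasible
    qetoh_surface: np.ndarray       # mmol gDW^-1 h^-1 (bi-level optimum)
    yield_surface: np.ndarray       # mol ethanol per mol carbon source
    arc_surface: np.ndarray         # lambda_ARC^etoh (default compartment)
    carbon_dual: np.ndarray         # shadow price of extracellular carbon
    o2_dual: np.ndarray             # shadow price of extracellular oxygen
    phase_labels: np.ndarray | None = None
    optimality_line_biomass: list[tuple[float, float]] = field(default_factory=list)
    optimality_line_ethanol: list[tuple[float, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def yield_mass(self, mw_carbon: float = 150.13, mw_etoh: float = 46.07) -> np.ndarray:
        """g ethanol per g carbon source view of the yield surface."""
        return self.yield_surface * mw_etoh / mw_carbon

    def to_tsv(self, directory: str) -> None:
        import json
        import os

        import pandas as pd

        os.makedirs(directory, exist_ok=True)
        surfaces = {
            "mu": self.mu_surface, "qetoh": self.qetoh_surface,
            "yield": self.yield_surface, "arc_etoh": self.arc_surface,
        }
        if self.phase_labels is not None:
            surfaces["phases"] = self.phase_labels
        for name, surf in surfaces.items():
            pd.DataFrame(surf, index=self.carbon_axis, columns=self.o2_axis).to_csv(
                os.path.join(directory, f"phpp_{name}.tsv"), sep="\t"
            )
        manifest = {
            "carbon_axis": list(map(float, self.carbon_axis)),
            "o2_axis": list(map(float, self.o2_axis)),
            "carbon_exchange_id": self.carbon_exchange_id,
            "o2_exchange_id": self.o2_exchange_id,
            "optimality_line_biomass": self.optimality_line_biomass,
            "optimality_line_ethanol": self.optimality_line_ethanol,
            "meta": {k: v for k, v in self.meta.items() if isinstance(v, (int, float, str))},
        }
        with open(os.path.join(directory, "phpp_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)


def compute_phpp(
    network: MetabolicNetwork,
    carbon_exchange_id: str,
    o2_exchange_id: str = "EX_o2",
    carbon_axis=None,
    o2_axis=None,
    loopless: bool = False,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    detect: bool = True,
    secondary_objective_id: str = "EX_etoh",
) -> PhPPGrid:
    """Scan the uptake grid; infeasible points are recorded as NaN, not dropped.

    Default axes: 41 x 41 over carbon 0-20 and oxygen 0-25 mmol gDW^-1 h^-1.
    """
    carbon_axis = np.asarray(
        carbon_axis if carbon_axis is not None else np.linspace(0.0, 20.0, 41), dtype=float
    )
    o2_axis = np.asarray(
        o2_axis if o2_axis is not None else np.linspace(0.0, 25.0, 41), dtype=float
    )
    for ax, nm in ((carbon_axis, "carbon"), (o2_axis, "o2")):
        if len(ax) == 0 or np.any(ax < 0) or np.any(np.diff(ax) <= 0):
            raise ValueError(f"{nm} axis must be non-empty, non-negative, increasing")

    nc, no = len(carbon_axis), len(o2_axis)
    shape = (nc, no)
    mu = np.full(shape, np.nan)
    qe = np.full(shape, np.nan)
    arc = np.full(shape, np.nan)
    cdual = np.full(shape, np.nan)
    odual = np.full(shape, np.nan)

    carbon_met = next(iter(network.get_reaction(carbon_exchange_id).stoichiometry))
    o2_met = next(iter(network.get_reaction(o2_exchange_id).stoichiometry))
    network.get_reaction(secondary_objective_id)  # fail fast on a bad id

    for i, qc in enumerate(carbon_axis):
        for j, qo in enumerate(o2_axis):
            uptakes = {carbon_exchange_id: float(qc), o2_exchange_id: float(qo)}
            try:
                rec = objective_sensitivity_at_state(
                    network, uptakes, secondary_objective_id=secondary_objective_id,
                    extra_bounds=extra_bounds,
                )
            except (ValueError, RuntimeError):
                continue
            mu[i, j] = rec.extras["mu"]
            qe[i, j] = rec.extras["secondary_optimum"]
            arc[i, j] = rec.arc
            step1 = rec.extras["step1_solution"]
            cdual[i, j] = step1.duals[carbon_met]
            odual[i, j] = step1.duals[o2_met]

    with np.errstate(invalid="ignore", divide="ignore"):
        yld = np.where(carbon_axis[:, None] > 0, qe / carbon_axis[:, None], 0.0)

    grid = PhPPGrid(
        carbon_axis=carbon_axis, o2_axis=o2_axis,
        carbon_exchange_id=carbon_exchange_id, o2_exchange_id=o2_exchange_id,
        mu_surface=mu, qetoh_surface=qe, yield_surface=yld, arc_surface=arc,
        carbon_dual=cdual, o2_dual=odual,
        meta={"loopless": loopless},
    )
    if detect:
        detect_phases(grid)
        grid.optimality_line_biomass = line_of_optimality(grid, "biomass")
        grid.optimality_line_ethanol = line_of_optimality(grid, "ethanol_yield")
    return grid


def detect_phases(grid: PhPPGrid, quantum: float = 1e-6) -> np.ndarray:
    """Label connected regions of equal quantised (carbon, O2) dual signature.

    Labels are contiguous positive integers ordered by first occurrence in a
    row-major scan; infeasible cells get label 0.
    """
    sig_c = np.round(grid.carbon_dual / quantum).astype(object)
    sig_o = np.round(grid.o2_dual / quantum).astype(object)
    nc, no = grid.mu_surface.shape
    labels = np.zeros((nc, no), dtype=int)
    next_label = 1
    for i in range(nc):
        for j in range(no):
            if labels[i, j] or not np.isfinite(grid.mu_surface[i, j]):
                continue
            # BFS flood fill over 4-neighbours with identical signatures
            sig = (sig_c[i, j], sig_o[i, j])
            stack = [(i, j)]
            labels[i, j] = next_label
            while stack:
                a, b = stack.pop()
                for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    u, v = a + da, b + db
                    if 0 <= u < nc and 0 <= v < no and not labels[u, v]:
                        if np.isfinite(grid.mu_surface[u, v]) and (
                            sig_c[u, v], sig_o[u, v]
                        ) == sig:
                            labels[u, v] = next_label
                            stack.append((u, v))
            next_label += 1
    grid.phase_labels = labels
    return labels


def line_of_optimality(grid: PhPPGrid, quantity: str = "biomass") -> list[tuple[float, float]]:
    """Locus of (carbon, O2) grid points optimising a yield.

    ``biomass``: per carbon value, the smallest O2 achieving the maximal
    biomass yield mu/q_carbon. ``ethanol_yield``: per carbon value, the
    smallest O2 maximising the ethanol yield surface. Columns that are
    entirely infeasible are omitted.
    """
    if quantity not in ("biomass", "ethanol_yield"):
        raise ValueError(f"unknown quantity {quantity!r}")
    pts: list[tuple[float, float]] = []
    for i, qc in enumerate(grid.carbon_axis):
        if qc == 0:
            continue
        row = grid.mu_surface[i] / qc if quantity == "biomass" else grid.yield_surface[i]
        if not np.any(np.isfinite(row)):
            continue
        best = np.nanmax(row)
        if not np.isfinite(best):
            continue
        j = int(np.argmax(np.isfinite(row) & (row >= best - 1e-9)))
        pts.append((float(qc), float(grid.o2_axis[j])))
    return pts
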