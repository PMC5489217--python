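"""Coupling fitted batch-culture rate trajectories to FBA.

Each culture time point supplies specific uptake rates (xylose from the
substrate mass balance, oxygen from the transfer-limited balance
qO2 = kLa C*/x) that become uptake bounds of independent steady-state FBA
problems — the quasi-static approximation: metabolic states along the
culture are successive optima, with no dynamic feedback. Respiratory
inhibition is simulated by capping the proton-pumping NADH dehydrogenase
(CINADH) at a fraction of its flux in the uninhibited optimum at the same
time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import FBASolution, FCSDiff, compare_fcs, solve_fba
from .network import MetabolicNetwork
from .sensitivity import biomass_arc_sensitivity, objective_sensitivity_at_state
from .phpp import PhPPGrid

__all__ = [
    "RatePoint",
    "InhibitionSpec",
    "SensitivityTrajectory",
    "rates_to_constraints",
    "trajectory_rate_points",
    "overlay_trajectory",
    "sensitivity_trajectory",
    "inhibition_flux_report",
    "MW",
]

MW = {"xylose": 150.13, "o2": 32.00, "ethanol": 46.07}


@dataclass(frozen=True)
class RatePoint:
    """Specific rates at one culture time point, in mmol gDW^-1 h^-1."""

    t: float
    q_xyl: float
    q_O2: float
    mu_obs: float = np.nan     # h^-1, from the kinetic model
    qP_obs: float = np.nan     # mmol gDW^-1 h^-1

    def __post_init__(self):
        if self.q_xyl < 0 or self.q_O2 < 0:
            raise ValueError("uptake rates must be >= 0")


@dataclass(frozen=True)
class InhibitionSpec:
    reaction_id: str = "CINADH"
    fraction: float = 0.8
    start_time: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("inhibition fraction must be in [0, 1]")


def rates_to_constraints(qS_g: float, qO2_g: float) -> tuple[float, float]:
    """Convert mass-specific rates (g gDW^-1 h^-1) to mmol gDW^-1 h^-1."""
    if qS_g < 0 or qO2_g < 0:
        raise ValueError("specific rates must be >= 0")
    return qS_g / MW["xylose"] * 1000.0, qO2_g / MW["o2"] * 1000.0


def trajectory_rate_points(trajectory, times=None, min_substrate: float = 1e-6) -> list[RatePoint]:
    """Build :class:`RatePoint` series from a kinetic CultureTrajectory.

    Points where the substrate has fallen to ``min_substrate`` (g/L) are
    dropped: once xylose is gone the specific rates vanish and a
    steady-state metabolic interpretation no longer applies. Pass the Monod
    Ks to restrict to the actively fermenting window.
    """
    t = trajectory.t if times is None else np.asarray(times, dtype=float)
    if times is not None:
        qS = np.interp(t, trajectory.t, trajectory.qS)
        qO2 = np.interp(t, trajectory.t, trajectory.qO2)
        mu = np.interp(t, trajectory.t, trajectory.mu)
        qP = np.interp(t, trajectory.t, trajectory.qP)
        S = np.interp(t, trajectory.t, trajectory.S)
    else:
        qS, qO2, mu, qP, S = (trajectory.qS, trajectory.qO2, trajectory.mu,
                              trajectory.qP, trajectory.S)
    pts = []
    for ti, qsi, qoi, mui, qpi, si in zip(t, qS, qO2, mu, qP, S):
        if si <= min_substrate:
            continue
        qx_m, qo_m = rates_to_constraints(max(qsi, 0.0), max(qoi, 0.0))
        pts.append(RatePoint(float(ti), qx_m, qo_m, float(mui),
                             float(qpi / MW["ethanol"] * 1000.0)))
    return pts


@dataclass
class SensitivityTrajectory:
    """Time series of ARC sensitivities along a culture rate trajectory."""

    points: list[dict] = field(default_factory=list)
    inhibition: InhibitionSpec | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.points)

    def column(self, name: str) -> np.ndarray:
        return np.array([p.get(name, np.nan) for p in self.points])


def overlay_trajectory(grid: PhPPGrid, rates: list[RatePoint]) -> dict:
    """Map rate points onto the nearest PhPP grid cells.

    Returns the mapped path (with each cell's mu, q_etoh and phase label),
    clip flags for points outside the grid ranges, and a Spearman rank
    correlation between grid-predicted and kinetic-model growth rates.
    """
    if not rates:
        raise ValueError("empty rate trajectory")
    path = []
    clipped = 0
    for p in rates:
        qc = float(np.clip(p.q_xyl, grid.carbon_axis[0], grid.carbon_axis[-1]))
        qo = float(np.clip(p.q_O2, grid.o2_axis[0], grid.o2_axis[-1]))
        was_clipped = (qc != p.q_xyl) or (qo != p.q_O2)
        clipped += was_clipped
        i = int(np.argmin(np.abs(grid.carbon_axis - qc)))
        j = int(np.argmin(np.abs(grid.o2_axis - qo)))
        path.append(
            {
                "t": p.t,
                "q_xyl": p.q_xyl, "q_O2": p.q_O2,
                "grid_q_xyl": float(grid.carbon_axis[i]),
                "grid_q_O2": float(grid.o2_axis[j]),
                "mu_grid": float(grid.mu_surface[i, j]),
                "qetoh_grid": float(grid.qetoh_surface[i, j]),
                "phase": int(grid.phase_labels[i, j]) if grid.phase_labels is not None else -1,
                "mu_obs": p.mu_obs, "qP_obs": p.qP_obs,
                "clipped": bool(was_clipped),
            }
        )
    mu_grid = np.array([c["mu_grid"] for c in path])
    mu_obs = np.array([c["mu_obs"] for c in path])
    ok = np.isfinite(mu_grid) & np.isfinite(mu_obs)
    spearman = np.nan
    if ok.sum() >= 3 and np.ptp(mu_grid[ok]) > 0 and np.ptp(mu_obs[ok]) > 0:
        from scipy.stats import spearmanr

        spearman = float(spearmanr(mu_grid[ok], mu_obs[ok]).statistic)
    return {"path": path, "n_clipped": int(clipped), "spearman_mu": spearman}


def _uptake_bounds(network: MetabolicNetwork, p: RatePoint, carbon_ex: str, o2_ex: str):
    return {
        carbon_ex: (-p.q_xyl, network.get_reaction(carbon_ex).upper_bound),
        o2_ex: (-p.q_O2, network.get_reaction(o2_ex).upper_bound),
    }


def _inhibition_caps(
    network: MetabolicNetwork, p: RatePoint, spec: InhibitionSpec,
    carbon_ex: str, o2_ex: str,
) -> dict[str, tuple[float, float]] | None:
    """Cap the inhibited reaction at (1-fraction) x its uninhibited optimal flux."""
    if p.t < spec.start_time or spec.fraction == 0.0:
        # a zero-fraction cap sits exactly on the optimal flux: it leaves the
        # optimum unchanged but would perturb degenerate duals, so add nothing
        return None
    ref_sol = solve_fba(network, extra_bounds=_uptake_bounds(network, p, carbon_ex, o2_ex))
    if not ref_sol.ok:
        return None
    ref = abs(ref_sol.fluxes.get(spec.reaction_id, 0.0))
    cap = (1.0 - spec.fraction) * ref
    rxn = network.get_reaction(spec.reaction_id)
    return {spec.reaction_id: (max(rxn.lower_bound, -cap) if rxn.lower_bound < 0 else rxn.lower_bound,
                               min(rxn.upper_bound, cap))}


def sensitivity_trajectory(
    network: MetabolicNetwork,
    rates: list[RatePoint],
    inhibition: InhibitionSpec | None = None,
    carbon_exchange_id: str = "EX_xyl",
    o2_exchange_id: str = "EX_o2",
) -> SensitivityTrajectory:
    """ARC sensitivities (biomass, single-level; ethanol, bi-level) per point.

    Each time point is an independent LP; with ``inhibition`` given, points
    at t >= start_time are solved with the inhibited reaction capped at
    (1 - fraction) of its flux in the uninhibited optimum at the same
    uptakes. Infeasible points are recorded with their status and skipped.
    """
    traj = SensitivityTrajectory(inhibition=inhibition)
    for p in rates:
        row = {"t": p.t, "q_xyl": p.q_xyl, "q_O2": p.q_O2, "status": "optimal",
               "inhibited": False}
        caps = None
        if inhibition is not None:
            caps = _inhibition_caps(network, p, inhibition, carbon_exchange_id, o2_exchange_id)
            row["inhibited"] = caps is not None
        eb = caps or {}
        uptakes = {carbon_exchange_id: p.q_xyl, o2_exchange_id: p.q_O2}
        try:
            rec_bio = biomass_arc_sensitivity(network, uptakes, extra_bounds=eb)
            rec_eth = objective_sensitivity_at_state(network, uptakes, extra_bounds=eb)
        except (ValueError, RuntimeError) as exc:
            row["status"] = f"infeasible ({exc})"
            traj.points.append(row)
            continue
        row.update(
            lambda_arc_bio=rec_bio.arc,
            lambda_arc_etoh=rec_eth.arc,
            mu_fba=rec_bio.extras["mu"],
            qetoh_fba=rec_eth.extras["secondary_optimum"],
        )
        traj.points.append(row)
    return traj


def inhibition_flux_report(
    network: MetabolicNetwork,
    rates: list[RatePoint],
    inhibition: InhibitionSpec,
    at_time: float | None = None,
    carbon_exchange_id: str = "EX_xyl",
    o2_exchange_id: str = "EX_o2",
) -> tuple[FCSDiff, dict]:
    """Flux-carrying-set diff between matched uninhibited/inhibited states.

    The representative time point defaults to the one with maximal
    uninhibited bi-level ethanol flux among points past the inhibition
    start (mid-fermentation); pass ``at_time`` to override.
    """
    candidates = [p for p in rates if p.t >= inhibition.start_time] or list(rates)
    if at_time is not None:
        point = min(rates, key=lambda p: abs(p.t - at_time))
    else:
        best, point = -np.inf, candidates[0]
        for p in candidates:
            try:
                rec = objective_sensitivity_at_state(
                    network, {carbon_exchange_id: p.q_xyl, o2_exchange_id: p.q_O2}
                )
            except (ValueError, RuntimeError):
                continue
            if rec.extras["secondary_optimum"] > best:
                best, point = rec.extras["secondary_optimum"], p
    bounds = _uptake_bounds(network, point, carbon_exchange_id, o2_exchange_id)
    sol_ref = solve_fba(network, extra_bounds=bounds)
    caps = _inhibition_caps(
        network, point, InhibitionSpec(inhibition.reaction_id, inhibition.fraction, -np.inf),
        carbon_exchange_id, o2_exchange_id,
    )
    eb = dict(bounds)
    if caps:
        eb.update(caps)
    sol_inh = solve_fba(network, extra_bounds=eb)
    if not (sol_ref.ok and sol_inh.ok):
        raise RuntimeError("reference or inhibited solve failed at the report point")
    diff = compare_fcs(sol_ref, sol_inh)
    info = {"t": point.t, "q_xyl": point.q_xyl, "q_O2": point.q_O2,
            "mu_ref": sol_ref.objective_value, "mu_inh": sol_inh.objective_value}
    return diff, info


def fcs_report_frame(network: MetabolicNetwork, diff: FCSDiff):
    """Tabulate an FCS diff in descending absolute-flux-shift order."""
    import pandas as pd

    rows = []
    for rid, shift, direction in diff.sorted_shifts():
        rxn = network.get_reaction(rid)
        formula = " + ".join(
            f"{-c:g} {m}" for m, c in rxn.stoichiometry.items() if c < 0
        ) + " --> " + " + ".join(
            f"{c:g} {m}" for m, c in rxn.stoichiometry.items() if c > 0
        )
        rows.append({"flux_shift": shift, "direction": direction,
                     "reaction": rxn.name or rid, "formula": formula,
                     "subsystem": rxn.subsystem})
    for rid in sorted(diff.turned_on):
        rows.append({"flux_shift": np.nan, "direction": "turned_on",
                     "reaction": network.get_reaction(rid).name or rid,
                     "formula": "", "subsystem": network.get_reaction(rid).subsystem})
    for rid in sorted(diff.turned_off):
        rows.append({"flux_shift": np.nan, "direction": "turned_off",
                     "reaction": network.get_reaction(rid).name or rid,
                     "formula": "", "subsystem": network.get_reaction(rid).subsystem})
    return pd.DataFrame(rows)
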