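"""Synthetic inputs: a core yeast-like metabolic network and batch-culture data.

The network generator builds a lumped (~30 reaction) core model of a
Crabtree-negative, xylose-fermenting yeast with the redox and respiratory
structure that the sensitivity analysis probes:

* xylose assimilation through xylose reductase (XR) and xylitol
  dehydrogenase (XDH). XR is modelled as two parallel activities, one
  NADPH-linked and one NADH-linked (the enzyme accepts both cofactors);
  XDH is strictly NAD+-linked, so the pathway carries a net NADH surplus
  whenever the NADPH-linked activity is used.
* lumped glycolysis (xylulose -> pyruvate + ATP + NADH), an oxidative
  pentose-phosphate lump supplying NADPH at a carbon cost, and a
  capacity-limited glycerol branch as cytosolic NADH overflow.
* pyruvate decarboxylase (PDC) and alcohol dehydrogenase to ethanol.
  PDC capacity is finite — the low fermentative capacity characteristic
  of Crabtree-negative yeasts — which bounds ethanol production at
  carbon-rich states.
* mitochondrial pyruvate oxidation (PDH + lumped TCA), a cytosolic->
  mitochondrial NADH shuttle, and a respiratory chain with a
  proton-pumping NADH dehydrogenase (CINADH), a pumping cytochrome
  oxidase (COX) and a non-pumping alternative oxidase (AOX); proton
  motive force is an explicit pseudo-metabolite consumed by ATP synthase.
* a biomass reaction consuming pyruvate, ATP and NADPH.

Every reaction's carbon bookkeeping is checked at construction time
against declared per-metabolite carbon counts.

The culture generator samples the kinetic batch model (Monod growth,
Luedeking–Piret ethanol production, growth/production delay factors) at
given times and adds independent Gaussian noise, clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MetabolicNetwork, Metabolite, NetworkError, Reaction

__all__ = [
    "ToyNetworkOptions",
    "make_core_network",
    "CultureDatasetSpec",
    "make_culture_dataset",
    "write_culture_tsv",
    "read_culture_tsv",
    "CARBON_COUNTS",
]

UNBOUNDED = 1000.0

# carbon atoms per metabolite unit (biomass: 41 mmol C per gDW)
CARBON_COUNTS = {
    "xyl": 5.0, "xlt": 5.0, "xu": 5.0, "glc": 6.0,
    "pyr": 3.0, "acald": 2.0, "etoh": 2.0, "co2": 1.0,
    "accoa": 2.0, "glycerol": 3.0, "biomass": 41.0,
}


@dataclass(frozen=True)
class ToyNetworkOptions:
    """Construction options for the core network.

    ``xr_cofactor`` selects the xylose-reductase cofactor wiring: ``"dual"``
    (default; both NADPH- and NADH-linked activities, the NADH-linked one
    capacity-limited by ``xr_nadh_capacity``), ``"NADPH"`` or ``"NADH"``
    (single activity). P/O ratios are ATP per NADH oxidised through the
    proton-pumping CINADH+COX branch and through the non-pumping
    alternative (CINADH+AOX) branch.
    """

    carbon_source: str = "xylose"  # "xylose" | "glucose"
    include_cinadh: bool = True
    include_cox: bool = True
    include_aox: bool = True
    xr_cofactor: str = "dual"  # "dual" | "NADPH" | "NADH"
    p_o_ratio_cinadh: float = 2.0
    p_o_ratio_alternative: float = 4.0 / 3.0
    xr_nadh_capacity: float = UNBOUNDED
    pdc_capacity: float = 3.0
    glycerol_capacity: float = 2.0
    biomass_pyr: float = 13.67     # mmol pyruvate / gDW
    biomass_atp: float = 60.0      # mmol ATP / gDW (growth-associated maintenance included)
    biomass_nadph: float = 8.0     # mmol NADPH / gDW
    default_uptake: float = 10.0   # mmol gDW^-1 h^-1 carbon-source uptake bound

    def __post_init__(self):
        if self.carbon_source not in ("xylose", "glucose"):
            raise NetworkError(f"unknown carbon source {self.carbon_source!r}")
        if self.xr_cofactor not in ("dual", "NADPH", "NADH"):
            raise NetworkError(f"unknown xr_cofactor {self.xr_cofactor!r}")
        if self.p_o_ratio_cinadh <= 0 or self.p_o_ratio_alternative <= 0:
            raise NetworkError("P/O ratios must be positive")
        if not (self.include_cox or self.include_aox) and self.glycerol_capacity <= 0:
            raise NetworkError(
                "contradictory options: no terminal oxidase and no glycerol "
                "overflow leaves the network without any net NADH sink"
            )


def _carbon(met_id: str) -> float:
    return CARBON_COUNTS.get(met_id.rsplit("_", 1)[0], 0.0)


def make_core_network(options: ToyNetworkOptions | None = None) -> MetabolicNetwork:
    """Build the core network; raises :class:`NetworkError` on bad options."""
    opt = options or ToyNetworkOptions()

    mets: list[Metabolite] = []
    def M(mid, comp, name=""):
        mets.append(Metabolite(mid, name or mid, comp))

    for mid in ("o2_e", "co2_e", "etoh_e", "glycerol_e", "biomass_e"):
        M(mid, "e")
    for mid in ("o2_c", "co2_c", "etoh_c", "glycerol_c", "pyr_c", "acald_c",
                "nad_c", "nadh_c", "nadp_c", "nadph_c", "atp_c"):
        M(mid, "c")
    for mid in ("pyr_m", "accoa_m", "nad_m", "nadh_m", "q_m", "qh2_m", "pmf_m"):
        M(mid, "m")

    rxns: list[Reaction] = []
    def R(rid, st, lb=0.0, ub=UNBOUNDED, name="", exchange=False, subsystem=""):
        rxns.append(Reaction(rid, dict(st), lb, ub, name or rid, exchange, subsystem))

    # Proton pumping derived from the requested P/O ratios: ATP synthase uses
    # `s` pmf per ATP; CINADH pumps ci, COX pumps cx with
    # (ci+cx)/s = P/O(CINADH branch) and ci/s = P/O(alternative branch).
    s = 3.0
    ci = s * opt.p_o_ratio_alternative
    cx = s * opt.p_o_ratio_cinadh - ci
    if cx < 0:
        raise NetworkError("p_o_ratio_alternative may not exceed p_o_ratio_cinadh")

    if opt.carbon_source == "xylose":
        M("xyl_e", "e"); M("xyl_c", "c"); M("xlt_c", "c"); M("xu_c", "c")
        R("EX_xyl", {"xyl_e": -1}, -opt.default_uptake, UNBOUNDED,
          "xylose exchange", exchange=True)
        R("XYLt", {"xyl_e": -1, "xyl_c": 1}, name="xylose transport", subsystem="Transport")
        if opt.xr_cofactor in ("dual", "NADPH"):
            R("XR", {"xyl_c": -1, "nadph_c": -1, "xlt_c": 1, "nadp_c": 1},
              name="xylose reductase (NADPH)", subsystem="Xylose assimilation")
        if opt.xr_cofactor in ("dual", "NADH"):
            R("XR_NADH", {"xyl_c": -1, "nadh_c": -1, "xlt_c": 1, "nad_c": 1},
              0.0, opt.xr_nadh_capacity if opt.xr_cofactor == "dual" else UNBOUNDED,
              name="xylose reductase (NADH)", subsystem="Xylose assimilation")
        R("XDH", {"xlt_c": -1, "nad_c": -1, "xu_c": 1, "nadh_c": 1},
          name="xylitol dehydrogenase", subsystem="Xylose assimilation")
        # xylulose -> 5/3 pyruvate; net 5/3 ATP after the xylulokinase and
        # phosphofructokinase investments
        R("GLYC", {"xu_c": -1, "nad_c": -5/3, "pyr_c": 5/3, "nadh_c": 5/3, "atp_c": 5/3},
          name="glycolysis (lumped, from xylulose)", subsystem="Glycolysis")
        R("OXPPP", {"xu_c": -1, "nadp_c": -10, "co2_c": 5, "nadph_c": 10},
          name="oxidative pentose phosphate (lumped)", subsystem="Pentose phosphate")
        R("GPD", {"xu_c": -1, "atp_c": -5/3, "nadh_c": -5/3, "nad_c": 5/3,
                  "glycerol_c": 5/3},
          name="glycerol branch (lumped G3P shunt)", subsystem="Glycerolipid")
        carbon_ex = "EX_xyl"
    else:
        M("glc_e", "e"); M("glc_c", "c")
        R("EX_glc", {"glc_e": -1}, -opt.default_uptake, UNBOUNDED,
          "glucose exchange", exchange=True)
        R("GLCt", {"glc_e": -1, "glc_c": 1}, name="glucose transport", subsystem="Transport")
        R("GLYC", {"glc_c": -1, "nad_c": -2, "pyr_c": 2, "nadh_c": 2, "atp_c": 2},
          name="glycolysis (lumped)", subsystem="Glycolysis")
        R("OXPPP", {"glc_c": -1, "nadp_c": -12, "co2_c": 6, "nadph_c": 12},
          name="oxidative pentose phosphate (lumped)", subsystem="Pentose phosphate")
        R("GPD", {"glc_c": -1, "atp_c": -2, "nadh_c": -2, "nad_c": 2, "glycerol_c": 2},
          name="glycerol branch (lumped G3P shunt)", subsystem="Glycerolipid")
        carbon_ex = "EX_glc"

    R("GLYCEROLt", {"glycerol_c": -1, "glycerol_e": 1}, name="glycerol export",
      subsystem="Transport")
    R("EX_glycerol", {"glycerol_e": -1}, 0.0, opt.glycerol_capacity,
      "glycerol exchange", exchange=True)
    R("PDC", {"pyr_c": -1, "acald_c": 1, "co2_c": 1}, 0.0, opt.pdc_capacity,
      "pyruvate decarboxylase", subsystem="Fermentation")
    R("ADH", {"acald_c": -1, "nadh_c": -1, "etoh_c": 1, "nad_c": 1},
      name="alcohol dehydrogenase", subsystem="Fermentation")
    R("ETOHt", {"etoh_c": -1, "etoh_e": 1}, name="ethanol export", subsystem="Transport")
    R("EX_etoh", {"etoh_e": -1}, 0.0, UNBOUNDED, "ethanol exchange", exchange=True)
    R("PYRtm", {"pyr_c": -1, "pyr_m": 1}, name="pyruvate mitochondrial transport",
      subsystem="Transport")
    R("PDH", {"pyr_m": -1, "nad_m": -1, "accoa_m": 1, "co2_c": 1, "nadh_m": 1},
      name="pyruvate dehydrogenase", subsystem="TCA")
    R("TCA", {"accoa_m": -1, "nad_m": -3, "q_m": -1, "co2_c": 2, "nadh_m": 3,
              "qh2_m": 1, "atp_c": 1},
      name="TCA cycle (lumped)", subsystem="TCA")
    R("SHUTTLE", {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1},
      name="NADH shuttle (cytosol to mitochondrion)", subsystem="Transport")
    if opt.include_cinadh:
        R("CINADH", {"nadh_m": -1, "q_m": -1, "nad_m": 1, "qh2_m": 1, "pmf_m": ci},
          name="NADH dehydrogenase with H+ transport (complex I)",
          subsystem="Oxidative phosphorylation")
    if opt.include_cox:
        R("COX", {"qh2_m": -1, "o2_c": -0.5, "q_m": 1, "pmf_m": cx},
          name="cytochrome oxidase", subsystem="Oxidative phosphorylation")
    if opt.include_aox:
        R("AOX", {"qh2_m": -1, "o2_c": -0.5, "q_m": 1},
          name="alternative oxidase", subsystem="Oxidative phosphorylation")
    R("ATPS", {"pmf_m": -s, "atp_c": 1}, name="ATP synthase",
      subsystem="Oxidative phosphorylation")
    R("ATPM", {"atp_c": -1}, 0.0, UNBOUNDED, "ATP maintenance", subsystem="Maintenance")
    R("O2t", {"o2_e": -1, "o2_c": 1}, name="oxygen transport", subsystem="Transport")
    R("EX_o2", {"o2_e": -1}, -UNBOUNDED, UNBOUNDED, "oxygen exchange", exchange=True)
    R("CO2t", {"co2_c": -1, "co2_e": 1}, name="CO2 transport", subsystem="Transport")
    R("EX_co2", {"co2_e": -1}, 0.0, UNBOUNDED, "CO2 exchange", exchange=True)
    R("BIOMASS", {"pyr_c": -opt.biomass_pyr, "atp_c": -opt.biomass_atp,
                  "nadph_c": -opt.biomass_nadph, "nadp_c": opt.biomass_nadph,
                  "biomass_e": 1},
      name="biomass synthesis", subsystem="Biomass")
    R("EX_biomass", {"biomass_e": -1}, 0.0, UNBOUNDED, "biomass exchange", exchange=True)

    net = MetabolicNetwork(metabolites=mets, reactions=rxns, objective_id="BIOMASS")
    _check_carbon_balance(net)
    net.carbon_exchange_id = carbon_ex  # convenience attribute
    return net


def _check_carbon_balance(net: MetabolicNetwork, tol: float = 1e-9) -> None:
    """Assert the declared per-reaction carbon balance of every lump."""
    for r in net.reactions:
        if r.is_exchange:
            continue
        balance = sum(coef * _carbon(mid) for mid, coef in r.stoichiometry.items())
        # biomass locks 41 C per unit by construction: pyr 13.67 * 3 = 41.01;
        # allow the rounding of the declared composition
        tol_r = 0.05 if r.id == "BIOMASS" else tol
        if abs(balance) > tol_r:
            raise NetworkError(f"reaction {r.id!r} violates carbon balance by {balance:.3g}")


# -- synthetic batch-culture data -------------------------------------------

@dataclass(frozen=True)
class CultureDatasetSpec:
    """Sampling plan for a noisy synthetic batch culture.

    ``noise_sd`` gives additive Gaussian standard deviations for
    (biomass, xylose, ethanol) in g/L. Deterministic given ``seed``.
    """

    params: "CultureParams" = None  # type: ignore[assignment]
    initial_state: tuple[float, float, float, float] = (0.25, 15.0, 0.0, 0.0075)
    sample_times: tuple[float, ...] = tuple(np.linspace(0.0, 48.0, 25))
    noise_sd: tuple[float, float, float] = (0.05, 0.25, 0.08)
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be >= 0")


def make_culture_dataset(spec: CultureDatasetSpec) -> pd.DataFrame:
    """Simulate the batch model at ``spec.sample_times`` and add noise.

    Returns a DataFrame with columns ``t_h, biomass_gL, xylose_gL,
    ethanol_gL``; values are clipped at zero.
    """
    from .kinetics import CultureParams, simulate_culture

    params = spec.params or CultureParams()
    times = np.asarray(spec.sample_times, dtype=float)
    traj = simulate_culture(params, spec.initial_state, t_eval=times)
    rng = np.random.default_rng(spec.seed)
    sds = np.asarray(spec.noise_sd, dtype=float)
    clean = np.column_stack([traj.x, traj.S, traj.P])
    noisy = clean + rng.normal(0.0, 1.0, clean.shape) * sds
    noisy = np.clip(noisy, 0.0, None)
    return pd.DataFrame(
        {
            "t_h": times,
            "biomass_gL": noisy[:, 0],
            "xylose_gL": noisy[:, 1],
            "ethanol_gL": noisy[:, 2],
        }
    )


def write_culture_tsv(data: pd.DataFrame, path: str) -> None:
    data.to_csv(path, sep="\t", index=False)


def read_culture_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"t_h", "biomass_gL", "xylose_gL", "ethanol_gL"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"culture TSV {path!r} missing columns {sorted(missing)}")
    return df
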