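"""Configuration-driven pipeline tying the analysis stages together.

``run(config)`` executes the requested stages on either a user-supplied
SBML model or the synthetic core network, writing TSV/JSON outputs and a
reproducible run manifest (config hash, package version, seed, per-stage
status). Stages: ``phpp`` (phase plane + ethanol ARC map), ``sens-map``
(knockout / 80%-inhibition sensitivity planes), ``fit`` (batch-culture
parameter estimation), ``traj`` (sensitivity trajectories with and without
CINADH inhibition), ``fcs`` (flux-carrying-set report at a representative
inhibited state). ``demo`` runs all of them on synthetic inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .network import MetabolicNetwork, knockout, load_sbml
from .fba import max_feasible_flux, solve_fba
from .phpp import compute_phpp
from .synthetic import (
    CultureDatasetSpec, ToyNetworkOptions, make_core_network, make_culture_dataset,
    read_culture_tsv,
)
from .kinetics import CultureParams, fit_parameters, simulate_culture
from .coupling import (
    InhibitionSpec, fcs_report_frame, inhibition_flux_report, sensitivity_trajectory,
    trajectory_rate_points,
)
from .sensitivity import objective_sensitivity_at_state

log = logging.getLogger("arcflux")

STAGES = ("phpp", "sens-map", "fit", "traj", "fcs")


@dataclass
class RunConfig:
    """Validated pipeline configuration (see :data:`CONFIG_SCHEMA`)."""

    stages: tuple[str, ...] = STAGES
    out_dir: str = "arcflux_out"
    seed: int = 0
    sbml_path: str | None = None
    network_options: dict = field(default_factory=dict)
    culture_tsv: str | None = None
    culture_spec: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)      # carbon_max, o2_max, n
    inhibition: dict = field(default_factory=dict)  # reaction_id, fraction, start_time
    fit_n_starts: int = 8

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")
        if self.sbml_path is not None and not os.path.exists(self.sbml_path):
            raise FileNotFoundError(f"SBML file not found: {self.sbml_path}")
        if self.culture_tsv is not None and not os.path.exists(self.culture_tsv):
            raise FileNotFoundError(f"culture TSV not found: {self.culture_tsv}")
        for key in self.grid:
            if key not in ("carbon_max", "o2_max", "n"):
                raise ValueError(f"unknown grid key {key!r}")


CONFIG_SCHEMA = {
    "stages": "list of stage names drawn from %s" % (STAGES,),
    "out_dir": "output directory (created if absent)",
    "seed": "integer seed for every stochastic step",
    "sbml_path": "optional SBML model; default: synthetic core network",
    "network_options": "ToyNetworkOptions fields (synthetic network only)",
    "culture_tsv": "optional culture data (t_h, biomass_gL, xylose_gL, ethanol_gL)",
    "culture_spec": "CultureDatasetSpec overrides for synthetic culture data",
    "grid": "phase-plane grid: carbon_max, o2_max, n",
    "inhibition": "InhibitionSpec fields (reaction_id, fraction, start_time)",
    "fit_n_starts": "multi-start count for parameter fitting",
}


def _axes(cfg: RunConfig):
    g = cfg.grid
    n = int(g.get("n", 21))
    return (np.linspace(0.0, float(g.get("carbon_max", 10.0)), n),
            np.linspace(0.0, float(g.get("o2_max", 12.0)), n))


def _network(cfg: RunConfig) -> tuple[MetabolicNetwork, str]:
    if cfg.sbml_path:
        net = load_sbml(cfg.sbml_path)
        carbon_ex = cfg.network_options.get("carbon_exchange_id", "EX_xyl")
        return net, carbon_ex
    opts = ToyNetworkOptions(**cfg.network_options)
    net = make_core_network(opts)
    return net, net.carbon_exchange_id


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Raises on schema violations; a stage failure aborts with prior outputs
    retained on disk.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
        "outputs": [],
    }

    net, carbon_ex = _network(config)
    carbon_axis, o2_axis = _axes(config)
    state: dict = {}

    for stage in config.stages:
        t0 = time.monotonic()
        log.info("stage %s: start", stage)
        try:
            outputs = _STAGE_FNS[stage](config, net, carbon_ex, carbon_axis, o2_axis,
                                        state, rng)
        except Exception as exc:
            manifest["stages"][stage] = {"status": f"failed: {exc}"}
            _write_manifest(config, manifest)
            raise
        dt = time.monotonic() - t0
        manifest["stages"][stage] = {"status": "ok", "wall_s": round(dt, 2)}
        manifest["outputs"].extend(outputs)
        log.info("stage %s: done in %.1fs", stage, dt)

    _write_manifest(config, manifest)
    return manifest


def _write_manifest(cfg: RunConfig, manifest: dict) -> None:
    path = os.path.join(cfg.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def _stage_phpp(cfg, net, carbon_ex, carbon_axis, o2_axis, state, rng):
    grid = compute_phpp(net, carbon_ex, "EX_o2", carbon_axis, o2_axis)
    d = os.path.join(cfg.out_dir, "phpp")
    grid.to_tsv(d)
    state["grid"] = grid
    return [os.path.join(d, f) for f in sorted(os.listdir(d))]


def _stage_sens_map(cfg, net, carbon_ex, carbon_axis, o2_axis, state, rng):
    import pandas as pd

    out = []
    # knockout plane: COX + AOX removed
    ko = knockout(net, [r for r in ("COX", "AOX") if r in set(net.reaction_ids)])
    rows = []
    for qc in carbon_axis[carbon_axis > 0]:
        for qo in o2_axis:
            try:
                rec = objective_sensitivity_at_state(ko, {carbon_ex: qc, "EX_o2": qo})
                rows.append({"q_carbon": qc, "q_O2": qo, "lambda_arc_etoh": rec.arc,
                             "mu": rec.extras["mu"], "mode": "knockout"})
            except (ValueError, RuntimeError):
                continue
    # capacity-referenced 80% inhibition plane of COX + AOX
    frac = float(cfg.inhibition.get("fraction", 0.8))
    for qc in carbon_axis[carbon_axis > 0]:
        for qo in o2_axis[o2_axis > 0]:
            eb = {carbon_ex: (-qc, 1000.0), "EX_o2": (-qo, 1000.0)}
            caps = {}
            for rid in ("COX", "AOX"):
                if rid in set(net.reaction_ids):
                    caps[rid] = (0.0, (1 - frac) * max_feasible_flux(net, rid, eb))
            try:
                rec = objective_sensitivity_at_state(
                    net, {carbon_ex: qc, "EX_o2": qo}, extra_bounds=caps
                )
                rows.append({"q_carbon": qc, "q_O2": qo, "lambda_arc_etoh": rec.arc,
                             "mu": rec.extras["mu"], "mode": "inhibition80"})
            except (ValueError, RuntimeError):
                continue
    path = os.path.join(cfg.out_dir, "sensitivity_map.tsv")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return [path]


def _culture_data(cfg, rng):
    if cfg.culture_tsv:
        return read_culture_tsv(cfg.culture_tsv)
    spec_kw = dict(cfg.culture_spec)
    params_kw = spec_kw.pop("params", {})
    spec = CultureDatasetSpec(params=CultureParams(**params_kw),
                              seed=int(spec_kw.pop("seed", cfg.seed)), **spec_kw)
    return make_culture_dataset(spec)


def _stage_fit(cfg, net, carbon_ex, carbon_axis, o2_axis, state, rng):
    data = _culture_data(cfg, rng)
    fit = fit_parameters(data, n_starts=cfg.fit_n_starts, seed=cfg.seed)
    state["fit"] = fit
    path = os.path.join(cfg.out_dir, "fit.json")
    with open(path, "w") as fh:
        json.dump({"params": asdict(fit.params), "rmse": fit.rmse,
                   "cost": fit.cost, "converged": fit.converged}, fh, indent=1)
    dpath = os.path.join(cfg.out_dir, "culture_data.tsv")
    data.to_csv(dpath, sep="\t", index=False)
    return [path, dpath]


def _fit_params(cfg, state, rng):
    if "fit" in state:
        return state["fit"].params
    # traj/fcs without a prior fit stage: use generator defaults
    return CultureParams(**cfg.culture_spec.get("params", {}))


def _stage_traj(cfg, net, carbon_ex, carbon_axis, o2_axis, state, rng):
    params = _fit_params(cfg, state, rng)
    traj = simulate_culture(params, t_eval=np.linspace(0.5, 48.0, 30))
    pts = trajectory_rate_points(traj)
    inh = InhibitionSpec(
        reaction_id=cfg.inhibition.get("reaction_id", "CINADH"),
        fraction=float(cfg.inhibition.get("fraction", 0.8)),
        start_time=float(cfg.inhibition.get("start_time", 16.0)),
    )
    out = []
    for name, spec in (("control", None), ("inhibited", inh)):
        st = sensitivity_trajectory(net, pts, spec, carbon_ex, "EX_o2")
        path = os.path.join(cfg.out_dir, f"sensitivity_trajectory_{name}.tsv")
        st.to_frame().to_csv(path, sep="\t", index=False)
        state[f"traj_{name}"] = (pts, st)
        out.append(path)
    return out


def _stage_fcs(cfg, net, carbon_ex, carbon_axis, o2_axis, state, rng):
    params = _fit_params(cfg, state, rng)
    traj = simulate_culture(params, t_eval=np.linspace(0.5, 48.0, 30))
    pts = trajectory_rate_points(traj)
    inh = InhibitionSpec(
        reaction_id=cfg.inhibition.get("reaction_id", "CINADH"),
        fraction=float(cfg.inhibition.get("fraction", 0.8)),
        start_time=float(cfg.inhibition.get("start_time", 16.0)),
    )
    diff, info = inhibition_flux_report(net, pts, inh, carbon_exchange_id=carbon_ex)
    frame = fcs_report_frame(net, diff)
    path = os.path.join(cfg.out_dir, "fcs_report.tsv")
    frame.to_csv(path, sep="\t", index=False)
    with open(os.path.join(cfg.out_dir, "fcs_state.json"), "w") as fh:
        json.dump(info, fh, indent=1)
    return [path, os.path.join(cfg.out_dir, "fcs_state.json")]


_STAGE_FNS = {
    "phpp": _stage_phpp,
    "sens-map": _stage_sens_map,
    "fit": _stage_fit,
    "traj": _stage_traj,
    "fcs": _stage_fcs,
}


def demo_config(out_dir: str = "arcflux_demo", seed: int = 0) -> RunConfig:
    """Small full-pipeline configuration on synthetic inputs."""
    return RunConfig(
        stages=STAGES,
        out_dir=out_dir,
        seed=seed,
        grid={"carbon_max": 10.0, "o2_max": 12.0, "n": 13},
        fit_n_starts=4,
    )
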