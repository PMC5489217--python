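"""Phase-plane geometry: monotone concave growth surface, fermentative
region left of the biomass line, phase count, lines of optimality."""

import numpy as np
import pytest

from arcflux import compute_phpp, detect_phases, line_of_optimality, solve_fba
from arcflux.network import MetabolicNetwork, Metabolite, Reaction


def _line_lookup(grid):
    return {qc: qo for qc, qo in grid.optimality_line_biomass}


def test_surfaces_share_shape(toy_grid):
    shape = (len(toy_grid.carbon_axis), len(toy_grid.o2_axis))
    for surf in (toy_grid.mu_surface, toy_grid.qetoh_surface, toy_grid.yield_surface,
                 toy_grid.arc_surface, toy_grid.phase_labels):
        assert surf.shape == shape
    assert np.nanmin(toy_grid.mu_surface) >= -1e-9


def test_zero_carbon_column_zero_growth(toy_grid):
    assert np.allclose(toy_grid.mu_surface[0], 0.0, atol=1e-9)


def test_growth_monotone_and_concave_along_axes(toy_grid):
    mu = toy_grid.mu_surface
    assert np.all(np.diff(mu, axis=0) >= -1e-7)
    assert np.all(np.diff(mu, axis=1) >= -1e-7)
    for axis in (0, 1):
        m = np.moveaxis(mu, axis, 0)
        mid = 0.5 * (m[:-2] + m[2:])
        assert np.all(m[1:-1] >= mid - 1e-7)


def test_ethanol_zero_right_of_biomass_line(toy_grid):
    """States with oxygen above the line's requirement are fully aerobic."""
    line = _line_lookup(toy_grid)
    for i, qc in enumerate(toy_grid.carbon_axis):
        if qc not in line:
            continue
        for j, qo in enumerate(toy_grid.o2_axis):
            if qo > line[qc] + 1e-9:
                # the 1e-6 relative biomass-fixing band admits a ~1e-5 leak
                assert toy_grid.qetoh_surface[i, j] == pytest.approx(0.0, abs=5e-5)


def test_ethanol_produced_left_of_line(toy_grid):
    line = _line_lookup(toy_grid)
    produced = 0
    for i, qc in enumerate(toy_grid.carbon_axis):
        if qc not in line or qc == 0:
            continue
        for j, qo in enumerate(toy_grid.o2_axis):
            if 0 < qo < line[qc]:
                produced += toy_grid.qetoh_surface[i, j] > 1e-6
    assert produced > 10


def test_yield_surface_bookkeeping(toy_grid):
    qc = toy_grid.carbon_axis[:, None]
    recon = np.where(qc > 0, toy_grid.yield_surface * qc, 0.0)
    mask = np.isfinite(toy_grid.qetoh_surface) & (qc > 0)
    np.testing.assert_allclose(recon[mask], toy_grid.qetoh_surface[mask], atol=1e-9)


def test_at_least_three_phases(toy_grid):
    labels = toy_grid.phase_labels
    n_phases = len(set(labels[labels > 0].ravel()))
    assert n_phases >= 3


def test_phase_boundaries_match_growth_gradient_breaks(toy_grid):
    """Phase changes along a carbon row coincide (within one cell) with
    discontinuities in the numerical gradient of the growth surface."""
    mu = toy_grid.mu_surface
    labels = toy_grid.phase_labels
    i = len(toy_grid.carbon_axis) - 1  # top carbon row crosses several phases
    row_mu = mu[i]
    row_lab = labels[i]
    grad = np.diff(row_mu)
    grad_breaks = {j for j in range(1, len(grad)) if abs(grad[j] - grad[j - 1]) > 1e-6}
    label_changes = {j for j in range(1, len(row_lab)) if row_lab[j] != row_lab[j - 1]}
    for j in label_changes:
        assert any(abs(j - b) <= 1 for b in grad_breaks), (
            f"phase change at column {j} without a growth-gradient break nearby"
        )


def test_biomass_line_is_ray_through_origin(toy_grid):
    pts = [(qc, qo) for qc, qo in toy_grid.optimality_line_biomass if qc > 0]
    ratios = [qo / qc for qc, qo in pts]
    # fixed stoichiometric O2:carbon proportion, up to grid resolution
    step = toy_grid.o2_axis[1] - toy_grid.o2_axis[0]
    expected = np.median(ratios)
    for (qc, qo), r in zip(pts, ratios):
        assert abs(qo - expected * qc) <= step + 1e-9


def test_ethanol_yield_line_left_of_biomass_line(toy_grid):
    bio = _line_lookup(toy_grid)
    eth = {qc: qo for qc, qo in toy_grid.optimality_line_ethanol}
    below = 0
    for qc in eth:
        if qc in bio and bio[qc] > 0:
            assert eth[qc] <= bio[qc] + 1e-9
            below += eth[qc] < bio[qc] - 1e-9
    assert below >= len(eth) // 2


def test_grid_points_match_fresh_solves(toy, toy_grid):
    rng = np.random.default_rng(42)
    nc, no = toy_grid.mu_surface.shape
    for _ in range(10):
        i, j = rng.integers(nc), rng.integers(no)
        qc, qo = toy_grid.carbon_axis[i], toy_grid.o2_axis[j]
        sol = solve_fba(toy, extra_bounds={"EX_xyl": (-qc, 1000.0), "EX_o2": (-qo, 1000.0)})
        assert toy_grid.mu_surface[i, j] == pytest.approx(sol.objective_value, abs=1e-7)


def _two_reaction_network():
    """A single-phase degenerate plane: one substrate, one linear objective."""
    mets = [Metabolite("s_e", "", "e"), Metabolite("s_c", "", "c"),
            Metabolite("o_e", "", "e"), Metabolite("bio_e", "", "e")]
    rxns = [
        Reaction("EX_s", {"s_e": -1}, -10, 1000, is_exchange=True),
        Reaction("EX_o", {"o_e": -1}, -10, 1000, is_exchange=True),
        Reaction("St", {"s_e": -1, "s_c": 1}),
        Reaction("GROW", {"s_c": -1, "bio_e": 1}),
        Reaction("EX_bio", {"bio_e": -1}, 0, 1000, is_exchange=True),
        Reaction("Osink", {"o_e": -1}, 0, 1000),
    ]
    return MetabolicNetwork(mets, rxns, objective_id="GROW")


def test_single_phase_synthetic_grid():
    net = _two_reaction_network()
    grid = compute_phpp(net, "EX_s", "EX_o",
                        np.linspace(0.5, 5.0, 6), np.linspace(0.0, 5.0, 6),
                        secondary_objective_id="EX_bio")
    labels = grid.phase_labels
    assert len(set(labels[labels > 0].ravel())) == 1
    # both optimality lines collapse onto the O2 = 0 grid edge
    assert all(qo == grid.o2_axis[0] for _, qo in grid.optimality_line_biomass)


def test_axis_validation(toy):
    with pytest.raises(ValueError):
        compute_phpp(toy, "EX_xyl", "EX_o2", np.array([2.0, 1.0]), np.array([0.0, 1.0]))
    with pytest.raises(ValueError):
        compute_phpp(toy, "EX_xyl", "EX_o2", np.array([]), np.array([0.0, 1.0]))


def test_grid_export(tmp_path, toy_grid):
    toy_grid.to_tsv(str(tmp_path))
    import os
    assert {"phpp_mu.tsv", "phpp_arc_etoh.tsv", "phpp_manifest.json"} <= set(os.listdir(tmp_path))
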