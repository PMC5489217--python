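"""Network data model, constraint editing and SBML round-trips."""

import numpy as np
import pytest

from arcflux import (
    MetabolicNetwork,
    NetworkError,
    inhibit,
    knockout,
    load_sbml,
    set_uptake,
    solve_fba,
    write_sbml,
)
from arcflux.network import Metabolite, Reaction


def test_invariants_rejected():
    m = [Metabolite("a", "", "c")]
    with pytest.raises(NetworkError):
        Reaction("r", {})  # empty stoichiometry
    with pytest.raises(NetworkError):
        Reaction("r", {"a": -1}, lower_bound=1.0, upper_bound=0.0)
    with pytest.raises(NetworkError):
        MetabolicNetwork(m, [Reaction("r", {"missing": -1})])
    with pytest.raises(NetworkError):
        MetabolicNetwork(m, [Reaction("r", {"a": -1})], objective_id="nope")
    with pytest.raises(NetworkError):
        # exchange must touch exactly one metabolite
        MetabolicNetwork(
            m + [Metabolite("b", "", "c")],
            [Reaction("EX", {"a": -1, "b": 1}, is_exchange=True)],
        )


def test_stoichiometric_matrix_shape(toy):
    S = toy.stoichiometric_matrix()
    assert S.shape == (len(toy.metabolites), len(toy.reactions))
    j = toy.reaction_index()["ADH"]
    i = toy.metabolite_index()["etoh_c"]
    assert S[i, j] == 1.0


def test_set_uptake_sets_lower_bound(toy):
    net = set_uptake(toy, "EX_xyl", 10.0)
    assert net.get_reaction("EX_xyl").lower_bound == -10.0
    # copy contract: original untouched
    assert toy.get_reaction("EX_xyl").lower_bound == -10.0  # builder default
    net2 = set_uptake(toy, "EX_xyl", 3.5)
    assert net2.get_reaction("EX_xyl").lower_bound == -3.5
    assert toy.get_reaction("EX_xyl").lower_bound == -10.0


def test_set_uptake_rejects_internal_and_negative(toy):
    with pytest.raises(NetworkError):
        set_uptake(toy, "GLYC", 5.0)
    with pytest.raises(NetworkError):
        set_uptake(toy, "EX_xyl", -1.0)


def test_set_uptake_zero_oxygen_gives_anaerobic_state(toy):
    net = set_uptake(toy, "EX_o2", 0.0)
    sol = solve_fba(net)
    assert sol.ok
    assert sol.fluxes["EX_o2"] == pytest.approx(0.0, abs=1e-9)
    aerobic = solve_fba(toy).objective_value
    # growth collapses; any ethanol comes from the redox-balanced route
    assert sol.objective_value < 0.15 * aerobic


def test_knockout_zeroes_bounds_and_preserves_input(toy):
    ko = knockout(toy, ["AOX", "COX"])
    for rid in ("AOX", "COX"):
        r = ko.get_reaction(rid)
        assert r.lower_bound == r.upper_bound == 0.0
        assert toy.get_reaction(rid).upper_bound > 0
    assert knockout(toy, []).get_reaction("COX").upper_bound == toy.get_reaction("COX").upper_bound
    with pytest.raises(NetworkError, match="NOPE"):
        knockout(toy, ["NOPE"])


def test_knockout_never_improves_objective(toy):
    base = solve_fba(toy, extra_bounds={"EX_xyl": (-8, 1000), "EX_o2": (-6, 1000)})
    ko = knockout(toy, ["COX"])
    capped = solve_fba(ko, extra_bounds={"EX_xyl": (-8, 1000), "EX_o2": (-6, 1000)})
    assert capped.objective_value <= base.objective_value + 1e-9


@pytest.mark.parametrize("fraction,expect_cap", [(1.0, 0.0), (0.5, 2.5), (0.0, 5.0)])
def test_inhibit_caps_upper_bound(toy, fraction, expect_cap):
    net = inhibit(toy, "CINADH", fraction, reference_flux=5.0)
    assert net.get_reaction("CINADH").upper_bound == pytest.approx(expect_cap)
    assert toy.get_reaction("CINADH").upper_bound == 1000.0


def test_inhibit_fraction_zero_at_reference_is_nonbinding(toy):
    bounds = {"EX_xyl": (-8, 1000.0), "EX_o2": (-4, 1000.0)}
    base = solve_fba(toy, extra_bounds=bounds)
    ref = base.fluxes["CINADH"]
    net = inhibit(toy, "CINADH", 0.0, reference_flux=ref)
    again = solve_fba(net, extra_bounds=bounds)
    assert again.objective_value == pytest.approx(base.objective_value, abs=1e-8)


def test_inhibit_validates_fraction(toy):
    with pytest.raises(NetworkError):
        inhibit(toy, "CINADH", 1.5, 1.0)
    with pytest.raises(NetworkError):
        inhibit(toy, "CINADH", 0.5, -1.0)


def test_sbml_round_trip(tmp_path, toy):
    path = tmp_path / "toy.xml"
    write_sbml(toy, path)
    rt = load_sbml(str(path))
    assert sorted(rt.metabolite_ids) == sorted(toy.metabolite_ids)
    assert sorted(rt.reaction_ids) == sorted(toy.reaction_ids)
    assert rt.objective_id == toy.objective_id
    idx = rt.reaction_index()
    for r in toy.reactions:
        r2 = rt.reactions[idx[r.id]]
        assert r2.lower_bound == pytest.approx(r.lower_bound, abs=1e-9)
        assert r2.upper_bound == pytest.approx(r.upper_bound, abs=1e-9)
        assert set(r2.stoichiometry) == set(r.stoichiometry)
        for mid, coef in r.stoichiometry.items():
            assert r2.stoichiometry[mid] == pytest.approx(coef, abs=1e-9)


def test_sbml_round_trip_preserves_custom_bounds(tmp_path, toy):
    net = set_uptake(toy, "EX_xyl", 10.0)
    path = tmp_path / "net.xml"
    write_sbml(net, path)
    assert load_sbml(str(path)).get_reaction("EX_xyl").lower_bound == pytest.approx(-10.0)


def test_load_sbml_missing_file_raises():
    with pytest.raises(NetworkError, match="no/such"):
        load_sbml("no/such/file.xml")


IBB814_PATH = "tests/data/iBB814.xml"


@pytest.mark.skipif(not __import__("os").path.exists(IBB814_PATH),
                    reason="user-supplied genome-scale reconstruction not present")
def test_user_supplied_genome_scale_model_dimensions():
    net = load_sbml(IBB814_PATH)
    assert len(net.reactions) == 1371
    assert len(net.metabolites) == 971
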