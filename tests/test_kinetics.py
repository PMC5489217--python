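"""Batch-culture model: delay factors, rate algebra, simulation limits,
mass bookkeeping, fitting, and yield arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arcflux import (
    CultureDatasetSpec,
    CultureParams,
    delay_factor,
    fit_parameters,
    make_culture_dataset,
    otr,
    oxygen_limited_qO2,
    relative_change,
    simulate_culture,
    specific_rates,
    yield_and_productivity,
)


def test_delay_factor_closed_form():
    assert delay_factor(1.0, 1.0, np.log(3.0)) == pytest.approx(0.75, abs=1e-12)
    assert delay_factor(0.05, 0.3, 0.0) == pytest.approx(0.05 / 1.05)
    assert delay_factor(0.05, 0.3, 1e4) == pytest.approx(1.0)


@given(q=st.floats(0.01, 5.0), v=st.floats(0.01, 2.0),
       t1=st.floats(0.0, 50.0), t2=st.floats(0.0, 50.0))
@settings(max_examples=50, deadline=None)
def test_delay_factor_monotone_and_bounded(q, v, t1, t2):
    lo, hi = sorted((t1, t2))
    f_lo, f_hi = delay_factor(q, v, lo), delay_factor(q, v, hi)
    assert f_lo <= f_hi + 1e-15
    assert q / (q + 1) - 1e-15 <= f_lo <= 1.0


def test_specific_rates_limits(params):
    mu, qP, qS = specific_rates(params, 0.0, 10.0)
    f2 = delay_factor(params.q2, params.v2, 10.0)
    assert mu == 0.0
    assert qP == pytest.approx(params.beta * f2)
    assert qS == pytest.approx(params.m + qP / params.YP)
    # half saturation at long times
    mu, _, _ = specific_rates(params, params.Ks, 1e5)
    assert mu == pytest.approx(params.mu_max / 2, rel=1e-9)


def test_specific_rates_no_production_term(params):
    from dataclasses import replace

    p = replace(params, alpha=0.0, beta=0.0)
    mu, qP, qS = specific_rates(p, 10.0, 1e5)
    assert qP == 0.0
    assert qS == pytest.approx(mu / p.Yo + p.m)


def test_simulate_no_biomass_is_inert(params):
    tr = simulate_culture(params, initial_state=(0.0, 15.0, 0.0, 0.0075),
                          t_eval=np.linspace(0, 20, 9))
    assert np.allclose(tr.S, 15.0)
    assert np.allclose(tr.P, 0.0)
    assert np.allclose(tr.x, 0.0)


def test_simulate_exponential_growth_limit():
    """Without delays and maintenance, x grows as x0*exp(mu_max t) while S >> Ks."""
    p = CultureParams(mu_max=0.1, Ks=0.01, Yo=0.5, m=0.0, alpha=0.0, beta=0.0,
                      q1=1e3, q2=1e3, v1=2.0, v2=2.0)
    t = np.linspace(0.0, 10.0, 11)
    tr = simulate_culture(p, initial_state=(0.1, 500.0, 0.0, 0.0), t_eval=t)
    expected = 0.1 * np.exp(p.mu_max * t)
    np.testing.assert_allclose(tr.x, expected, rtol=1e-4)


def test_substrate_bookkeeping_identity(params):
    """Consumed substrate covers growth and product demands (integrated balance)."""
    tr = simulate_culture(params, t_eval=np.linspace(0, 48, 49))
    consumed = tr.S[0] - tr.S[-1]
    need = (tr.x[-1] - tr.x[0]) / params.Yo + (tr.P[-1] - tr.P[0]) / params.YP
    assert consumed >= need - 1e-6
    # and exactly covers growth + maintenance + product; the maintenance
    # draw stops at substrate depletion
    alive = tr.S > 1e-9
    stop = len(tr.t) if alive.all() else int(np.argmin(alive)) + 1
    maint = np.trapezoid(params.m * tr.x[:stop], tr.t[:stop])
    assert consumed == pytest.approx(need + maint, rel=3e-3)


def test_state_nonnegative_and_substrate_monotone(params):
    tr = simulate_culture(params, t_eval=np.linspace(0, 60, 61))
    assert (tr.x >= 0).all() and (tr.S >= 0).all() and (tr.P >= 0).all()
    assert np.all(np.diff(tr.S) <= 1e-9)
    assert np.all(np.diff(tr.x) >= -1e-9)


def test_oxygen_limited_qO2_algebra():
    assert oxygen_limited_qO2(25.0, 0.0075, 1.0) == pytest.approx(0.1875)
    # qO2 * x independent of x; linear in kLa
    assert oxygen_limited_qO2(25.0, 0.0075, 2.0) * 2.0 == pytest.approx(0.1875)
    assert oxygen_limited_qO2(50.0, 0.0075, 1.0) == pytest.approx(2 * 0.1875)
    with pytest.raises(ValueError):
        oxygen_limited_qO2(25.0, 0.0075, 0.0)


def test_otr_values():
    assert otr(25.0, 0.0075) == pytest.approx(5.86, abs=0.005)
    assert otr(15.0, 0.0075) == pytest.approx(3.52, abs=0.005)
    assert otr(0.0, 0.0075) == 0.0


def test_fit_noiseless_self_consistency(params):
    times = tuple(np.linspace(0.0, 48.0, 50))
    ds = make_culture_dataset(CultureDatasetSpec(params=params, noise_sd=(0, 0, 0),
                                                 sample_times=times, seed=0))
    fit = fit_parameters(ds, n_starts=1, seed=0)
    assert fit.converged
    for v, rmse in fit.rmse.items():
        assert rmse <= 1e-3, f"{v} RMSE {rmse} above 1e-3 of range"


def test_fit_all_fixed_returns_inputs(params):
    times = tuple(np.linspace(0.0, 40.0, 20))
    ds = make_culture_dataset(CultureDatasetSpec(params=params, noise_sd=(0, 0, 0),
                                                 sample_times=times, seed=0))
    from arcflux.kinetics import FITTED_PARAM_NAMES

    fixed = {n: getattr(params, n) for n in FITTED_PARAM_NAMES}
    fit = fit_parameters(ds, fixed=fixed)
    for n in FITTED_PARAM_NAMES:
        assert getattr(fit.params, n) == getattr(params, n)
    assert max(fit.rmse.values()) < 1e-3  # residuals are pure integration error


def test_fit_requires_enough_points(params):
    ds = make_culture_dataset(
        CultureDatasetSpec(params=params, sample_times=(0.0, 5.0, 10.0), seed=0)
    )
    with pytest.raises(ValueError):
        fit_parameters(ds)


def test_param_validation():
    with pytest.raises(ValueError):
        CultureParams(mu_max=-0.1)
    with pytest.raises(ValueError):
        CultureParams(YP=0.6)
    with pytest.raises(ValueError):
        CultureParams(m=-0.01)
    p = CultureParams(q1=0.06, mu_max=0.12)
    assert p.k == pytest.approx(0.5)


def test_yield_and_productivity(params):
    tr = simulate_culture(params, t_eval=np.linspace(0, 48, 49))
    Y, Q = yield_and_productivity(tr)
    assert 0 < Y <= 0.511
    assert Q > 0
    # constant product: zero yield and productivity
    flat = simulate_culture(CultureParams(alpha=0.0, beta=0.0),
                            t_eval=np.linspace(0, 20, 21))
    Y0, Q0 = yield_and_productivity(flat)
    assert Y0 == 0.0 and Q0 == 0.0


def test_relative_change():
    assert relative_change(0.3812, 0.3207) == pytest.approx(18.86, abs=0.01)
    with pytest.raises(ValueError):
        relative_change(1.0, 0.0)
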