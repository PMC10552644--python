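import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from psorqsp import pbpk
from psorqsp.pbpk import DoseEvent, PKParameters, Regimen


@pytest.mark.parametrize("tmax,expected", [(3.0, math.log(2)), (6.0, 3 * math.log(2) / 6)])
def test_absorption_constant_from_tmax(tmax, expected):
    assert pbpk.absorption_constant(tmax) == pytest.approx(expected, rel=1e-12)


@given(st.floats(0.5, 50), st.floats(0.5, 50))
def test_absorption_constant_strictly_decreases_with_tmax(t1, t2):
    if t1 == t2:
        return
    lo, hi = sorted([t1, t2])
    assert pbpk.absorption_constant(hi) < pbpk.absorption_constant(lo)


def test_absorption_constant_rejects_nonpositive_tmax():
    with pytest.raises(ValueError):
        pbpk.absorption_constant(0.0)


def test_czp_regimen_schedules():
    r200 = pbpk.czp_regimen(200)
    assert [e.amount for e in r200.events] == [400] * 3 + [200] * 6
    assert [e.time for e in r200.events] == [14.0 * i for i in range(9)]
    assert all(e.route == "sc" for e in r200.events)
    assert r200.total_dose == 2400
    r400 = pbpk.czp_regimen(400)
    assert [e.amount for e in r400.events] == [400] * 9
    with pytest.raises(ValueError):
        pbpk.czp_regimen(300)
    assert len(pbpk.czp_regimen(300, allow_any=True).events) == 9


def test_empty_regimen_gives_zero_profile():
    params = PKParameters(ka=0.35, kel=0.05, v_blood=5.0)
    prof = pbpk.simulate(params, Regimen((), "none"), t_end=10)
    assert np.all(prof.concentrations == 0)
    m = pbpk.pk_metrics(prof)
    assert m.cmax == 0 and m.auc == 0


def test_single_dose_matches_bateman_closed_form():
    params = PKParameters(ka=0.35, kel=0.05, v_blood=5.0, f_bio=1.0)
    reg = Regimen((DoseEvent(0.0, 200.0, "sc"),), "single")
    prof = pbpk.simulate(params, reg, t_end=60)
    t = prof.times
    expected = 200 * 0.35 / (5 * 0.30) * (np.exp(-0.05 * t) - np.exp(-0.35 * t))
    assert np.max(np.abs(prof.concentrations - expected)) <= 1e-6 * expected.max()


def test_rk4_agrees_with_analytic_superposition_on_multidose():
    params = pbpk.CZP_REFERENCE
    for maintenance in (200, 400):
        reg = pbpk.czp_regimen(maintenance)
        a = pbpk.simulate(params, reg, method="analytic")
        n = pbpk.simulate(params, reg, method="rk4")
        rel = np.max(np.abs(a.concentrations - n.concentrations))
        assert rel <= 1e-6 * a.concentrations.max()


def test_linearity_of_the_dose_response():
    params = PKParameters(ka=0.4, kel=0.06, v_blood=6.0)
    reg1 = Regimen((DoseEvent(0, 100, "sc"), DoseEvent(7, 50, "iv")), "a")
    reg2 = Regimen((DoseEvent(0, 200, "sc"), DoseEvent(7, 100, "iv")), "b")
    c1 = pbpk.simulate(params, reg1, t_end=30).concentrations
    c2 = pbpk.simulate(params, reg2, t_end=30).concentrations
    assert np.allclose(2 * c1, c2, rtol=1e-12, atol=1e-12)

    reg3 = Regimen((DoseEvent(3, 75, "sc"),), "c")
    c3 = pbpk.simulate(params, reg3, t_end=30).concentrations
    combined = Regimen((DoseEvent(0, 100, "sc"), DoseEvent(3, 75, "sc"),
                        DoseEvent(7, 50, "iv")), "d")
    c13 = pbpk.simulate(params, combined, t_end=30).concentrations
    assert np.allclose(c1 + c3, c13, rtol=1e-12, atol=1e-12)


def test_mass_balance_within_point_one_percent():
    params = pbpk.CZP_REFERENCE
    reg = pbpk.czp_regimen(200)
    prof = pbpk.simulate(params, reg, method="rk4", t_end=400)
    assert pbpk.mass_balance_error(prof, params, reg) < 1e-3


def test_off_grid_dose_event_is_rejected_by_name():
    params = PKParameters(ka=0.35, kel=0.05, v_blood=5.0)
    reg = Regimen((DoseEvent(0.05, 100, "sc"),), "offgrid")
    with pytest.raises(ValueError, match="t=0.05"):
        pbpk.simulate(params, reg, t_end=10, dt=0.1)


def test_ka_equal_kel_is_perturbed_not_singular():
    params = PKParameters(ka=0.1, kel=0.1, v_blood=5.0)
    assert params.ka != params.kel
    prof = pbpk.simulate(params, Regimen((DoseEvent(0, 100, "sc"),), "s"), t_end=30)
    assert np.all(np.isfinite(prof.concentrations))


def _synthetic_points(kel, noise=0.0, seed=0):
    params = PKParameters(ka=0.35, kel=kel, v_blood=5.0)
    reg = Regimen((DoseEvent(0.0, 200.0, "sc"),), "single")
    prof = pbpk.simulate(params, reg, t_end=50)
    t_obs = np.array([2.0, 5.0, 8.0, 12.0, 20.0, 30.0, 45.0])
    c = np.interp(t_obs, prof.times, prof.concentrations)
    if noise:
        c = c * (1 + np.random.default_rng(seed).normal(0, noise, len(c)))
    return pd.DataFrame({"time_day": t_obs, "conc_mg_per_L": c}), reg


def test_clearance_fit_recovers_noise_free_kel():
    points, reg = _synthetic_points(0.08)
    guess = PKParameters(ka=0.35, kel=0.05, v_blood=5.0)
    fit = pbpk.fit_clearance(points, guess, reg)
    assert abs(fit.kel - 0.08) < 1e-4
    assert fit.r_squared > 1 - 1e-9


def test_clearance_fit_matches_brute_force_grid_search():
    points, reg = _synthetic_points(0.11, noise=0.03, seed=4)
    guess = PKParameters(ka=0.35, kel=0.05, v_blood=5.0)
    fit = pbpk.fit_clearance(points, guess, reg)
    grid = np.arange(1e-3, 1.0, 1e-4)
    t_obs = points["time_day"].to_numpy()
    c_obs = points["conc_mg_per_L"].to_numpy()
    sses = []
    for kel in grid:
        p = PKParameters(ka=0.35, kel=kel, v_blood=5.0)
        pred = pbpk._bateman(p, reg, t_obs)[0]
        sses.append(np.sum((pred - c_obs) ** 2))
    assert abs(fit.kel - grid[int(np.argmin(sses))]) <= 1e-4


def test_clearance_fit_r2_with_five_percent_noise():
    points, reg = _synthetic_points(0.08, noise=0.05, seed=1)
    guess = PKParameters(ka=0.35, kel=0.05, v_blood=5.0)
    fit = pbpk.fit_clearance(points, guess, reg)
    assert fit.r_squared >= 0.95


def test_clearance_fit_rejects_degenerate_points():
    pts = pd.DataFrame({"time_day": [5.0, 5.0, 5.0], "conc_mg_per_L": [1, 2, 3]})
    guess = PKParameters(ka=0.35, kel=0.05, v_blood=5.0)
    with pytest.raises(ValueError, match="identifiable"):
        pbpk.fit_clearance(pts, guess, Regimen((DoseEvent(0, 100, "sc"),), "s"))


class _P:
    def __init__(self, sex, height, weight):
        self.sex, self.height, self.weight = sex, height, weight


def test_individualization_reference_identity_and_monotonicity():
    ref = pbpk.individualize(_P("male", 170.0, 75.0), volume_adjustment=1.0)
    assert ref.v_blood == pytest.approx(pbpk.CZP_REFERENCE.v_blood, rel=1e-12)
    assert ref.v_skin == pytest.approx(pbpk.CZP_REFERENCE.v_skin, rel=1e-12)
    weights = [50, 70, 90, 110, 130]
    volumes = [pbpk.individualize(_P("female", 165.0, w)).v_blood for w in weights]
    assert all(b > a for a, b in zip(volumes, volumes[1:]))


def test_patients_differing_in_weight_get_different_cmax():
    reg = pbpk.czp_regimen(200)
    light = pbpk.individualize(_P("male", 175.0, 60.0))
    heavy = pbpk.individualize(_P("male", 175.0, 120.0))
    c_light = pbpk.pk_metrics(pbpk.simulate(light, reg), reg, light).cmax
    c_heavy = pbpk.pk_metrics(pbpk.simulate(heavy, reg), reg, heavy).cmax
    assert c_light > c_heavy  # larger distribution volume dilutes the dose


def test_pk_metrics_closed_form_tmax_and_auc():
    params = PKParameters(ka=0.35, kel=0.05, v_blood=5.0)
    reg = Regimen((DoseEvent(0.0, 200.0, "sc"),), "single")
    prof = pbpk.simulate(params, reg, t_end=250)
    m = pbpk.pk_metrics(prof, reg, params)
    tmax_expected = math.log(0.35 / 0.05) / 0.30
    assert abs(m.tmax - tmax_expected) <= 0.1  # one grid step
    auc_inf = 200 / (5.0 * 0.05)
    assert abs(m.auc - auc_inf) / auc_inf < 0.01
    assert m.half_life == pytest.approx(math.log(2) / 0.05)


def test_terminal_half_life_estimated_from_slope():
    params = PKParameters(ka=0.5, kel=0.07, v_blood=5.0)
    reg = Regimen((DoseEvent(0.0, 100.0, "sc"),), "single")
    prof = pbpk.simulate(params, reg, t_end=150)
    m = pbpk.pk_metrics(prof, reg, None)
    assert m.half_life == pytest.approx(math.log(2) / 0.07, rel=0.05)


def test_steady_state_trough_stabilizes_under_q2w_dosing():
    params = pbpk.CZP_REFERENCE  # half-life 14 d -> steady by dose 5
    n_doses = 14
    reg = Regimen(tuple(DoseEvent(14.0 * i, 400.0, "sc") for i in range(n_doses)), "q2w")
    prof = pbpk.simulate(params, reg, t_end=14.0 * n_doses)
    troughs = []
    for i in range(1, n_doses):
        idx = int(round(14.0 * i / 0.1)) - 1  # grid point just before each dose
        troughs.append(prof.concentrations[idx])
    n_ss = math.ceil(5 * (math.log(2) / params.kel) / 14)
    for i in range(n_ss, len(troughs) - 1):
        assert abs(troughs[i + 1] - troughs[i]) / troughs[i] < 0.01


def test_iv_and_oral_route_variants():
    params = PKParameters(ka=0.8, kel=0.2, v_blood=4.0)
    iv = pbpk.iv_bolus_regimen([0.0], 100.0)
    prof = pbpk.simulate(params, iv, t_end=20)
    assert prof.concentrations[0] == pytest.approx(25.0)  # D/V at t=0
    oral = pbpk.oral_regimen([0.0], 100.0)
    prof_o = pbpk.simulate(params, oral, t_end=20)
    assert prof_o.concentrations[0] == 0.0
    assert oral.label == "oral-liver-clearance"
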