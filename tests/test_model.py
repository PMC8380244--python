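"""Core model: rate expressions, ODE invariants, closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alumtk.physiology import InvalidInputError, TISSUES
from alumtk.model import (DoseEvent, PBTKParameters, STATE_NAMES,
                          default_parameters, effective_fu, empirical_retention,
                          ode_rhs, release_rate_constant, renal_clearance,
                          retention_fraction, simulate, tissue_blood_ratio,
                          tissue_half_life, uptake_rate_constant)

IDX = {name: i for i, name in enumerate(STATE_NAMES)}


# ---------------------------------------------------------------------------
# elementary rate expressions


def test_uptake_rate_constant():
    # human male bone: I=0.01920, Q=19.5 L/h, V_blo=5.30 L
    assert uptake_rate_constant(0.01920, 19.5, 5.30) == pytest.approx(0.0706415, rel=1e-5)
    assert uptake_rate_constant(0.0, 19.5, 5.30) == 0.0
    assert uptake_rate_constant(0.5, 2.0, 1.0) == 2 * uptake_rate_constant(0.5, 1.0, 1.0)
    with pytest.raises(InvalidInputError):
        uptake_rate_constant(0.5, -1.0, 1.0)


def test_release_rate_constant():
    # human male muscle: Q=66.3, K=116, V=29.0
    assert release_rate_constant(116.0, 29.0, 66.3) == pytest.approx(66.3 / 3364.0, rel=1e-12)
    assert release_rate_constant(116.0, 29.0, 66.3) == pytest.approx(0.01971, abs=1e-5)
    assert release_rate_constant(math.inf, 1.45, 46.8) == 0.0  # brain sink
    assert release_rate_constant(1.0, 1.0, 1.0) == 1.0
    with pytest.raises(InvalidInputError):
        release_rate_constant(-1.0, 1.0, 1.0)


def test_tissue_half_life_examples():
    # human male muscle ~35 h, bone ~198 weeks
    assert tissue_half_life(116.0, 29.0, 66.3) == pytest.approx(35.17, abs=0.01)
    assert tissue_half_life(1.16e5, 8.07, 19.5) / 168.0 == pytest.approx(198.07, abs=0.01)
    assert math.isinf(tissue_half_life(math.inf, 1.45, 46.8))


def test_tissue_blood_ratio():
    # equals uptake/release rate-constant quotient and the bone example ~3391
    assert tissue_blood_ratio(0.01920, 1.16e5, 8.07, 5.30) == pytest.approx(3391.4, rel=1e-3)
    kin = uptake_rate_constant(0.01920, 19.5, 5.30)
    kout = release_rate_constant(1.16e5, 8.07, 19.5)
    assert tissue_blood_ratio(0.01920, 1.16e5, 8.07, 5.30) == pytest.approx(kin / kout)
    assert tissue_blood_ratio(0.0, 116.0, 1.0, 1.0) == 0.0
    assert math.isinf(tissue_blood_ratio(0.1, math.inf, 1.0, 1.0))


@given(st.floats(1e-4, 1.0), st.floats(1e-4, 1.0), st.floats(0.01, 100.0),
       st.floats(0.01, 100.0))
@settings(max_examples=50, deadline=None)
def test_tissue_blood_ratio_identity(I, K_scale, V, Vb):
    K = 10.0 + K_scale * 1e4
    ratio = tissue_blood_ratio(I, K, V, Vb)
    quotient = uptake_rate_constant(I, 1.7, Vb) / release_rate_constant(K, V, 1.7)
    assert ratio == pytest.approx(quotient, rel=1e-12)


def test_effective_fu():
    assert effective_fu(1.0, 0.0, 1.0, 0.1) == 1.0       # all citrate
    assert effective_fu(0.0, 1.0, 1.0, 0.1) == 0.1       # all mixed species
    assert effective_fu(0.5, 0.5, 1.0, 0.1) == pytest.approx(0.55)
    assert effective_fu(0.0, 0.0, 1.0, 0.1) == 0.1       # empty blood convention
    with pytest.raises(InvalidInputError):
        effective_fu(-0.1, 0.5, 1.0, 0.1)


def test_renal_clearance():
    # human male mixed species: Q_kid=74.1, fu=0.1, GFR=6.92
    cl = renal_clearance(0.1, 6.92, 74.1)
    assert cl == pytest.approx(0.6857, abs=2e-4)
    assert cl < 74.1 and cl < 0.1 * 6.92
    assert renal_clearance(0.0, 6.92, 74.1) == 0.0        # fu -> 0 limit
    assert renal_clearance(1.0, 1e12, 74.1) == pytest.approx(74.1, rel=1e-9)  # flow limited
    with pytest.raises(InvalidInputError):
        renal_clearance(0.5, 6.92, 0.0)
    with pytest.raises(InvalidInputError):
        renal_clearance(1.5, 6.92, 74.1)


# ---------------------------------------------------------------------------
# ODE right-hand side


def test_rhs_zero_state_and_conservation(hm_params, human_male, rng):
    zero = np.zeros(len(STATE_NAMES))
    assert np.allclose(ode_rhs(zero, hm_params, human_male), 0.0)
    for _ in range(20):
        y = rng.exponential(0.1, len(STATE_NAMES))
        dy = ode_rhs(y, hm_params, human_male)
        assert abs(dy.sum()) < 1e-12 * max(1.0, np.abs(dy).max())


def test_rhs_rejects_negative_state(hm_params, human_male):
    y = np.zeros(len(STATE_NAMES))
    y[IDX["Mix"]] = -0.1
    with pytest.raises(InvalidInputError):
        ode_rhs(y, hm_params, human_male)


def test_rhs_single_species_urine_flux(hm_params, human_male):
    # with only the mixed pool populated, urine flux is CL(fu_Mix) * A_Mix / V_blo
    y = np.zeros(len(STATE_NAMES))
    y[IDX["Mix"]] = 0.3
    dy = ode_rhs(y, hm_params, human_male)
    cl = renal_clearance(hm_params.fu_Mix, hm_params.GFR, human_male.Q_kid)
    assert dy[IDX["uri"]] == pytest.approx(cl * 0.3 / human_male.V_blo, rel=1e-12)


# ---------------------------------------------------------------------------
# simulation invariants


def _grid(t_end, n=120):
    return np.concatenate([[0.0], np.geomspace(min(0.25, t_end / 100), t_end, n)])


@pytest.mark.parametrize("route,salt", [("iv", "citrate"), ("iv", "chloride"),
                                        ("po", "citrate"), ("po", "chloride")])
def test_mass_balance_and_monotonicity(route, salt, hm_params, human_male):
    res = simulate(hm_params, human_male, [DoseEvent(0.0, route, salt)], _grid(25200.0))
    total = res.states.sum(axis=1)
    assert np.all(np.abs(total - 1.0) < 1e-8)
    assert np.all(res.states >= 0.0)
    assert np.all(np.diff(res.amount("uri")) >= -1e-12)   # urine non-decreasing
    assert np.all(np.diff(res.amount("bra")) >= -1e-12)   # brain is a sink
    assert np.allclose(res.A_pla, res.A_blo)              # BP = 1 - Hct
    assert np.allclose(res.A_blo, res.amount("addCit") + res.amount("Mix"))


def test_mass_balance_random_scenarios(all_references, rng):
    for _ in range(5):
        ref = all_references[rng.integers(len(all_references))]
        params = default_parameters(
            ref,
            k_gut2blo=float(rng.uniform(0.5, 5.0)),
            F=float(rng.uniform(1e-4, 0.05)),
            K_bon=float(np.exp(rng.normal(np.log(1.16e5), 0.5))),
            I_bon=float(rng.uniform(0.005, 0.05)),
        )
        route = ("iv", "po")[rng.integers(2)]
        salt = ("citrate", "chloride")[rng.integers(2)]
        doses = [DoseEvent(0.0, route, salt, 1.0),
                 DoseEvent(float(rng.uniform(1.0, 24.0)), route, salt,
                           float(rng.uniform(0.1, 2.0)))]
        t_end = float(rng.uniform(500.0, 5000.0))
        grid = np.unique(np.concatenate([_grid(t_end), [d.time for d in doses]]))
        res = simulate(params, ref, doses, grid)
        total_dose = sum(d.amount for d in doses)
        assert np.all(np.abs(res.states.sum(axis=1)
                             - np.where(grid >= doses[1].time, total_dose, 1.0))
                      < 1e-8 * total_dose)
        assert np.all(res.states >= 0.0)


def test_zero_dose_trajectory(hm_params, human_male):
    res = simulate(hm_params, human_male, [DoseEvent(0.0, "iv", "citrate", 0.0)],
                   _grid(100.0))
    assert np.all(res.states == 0.0)


def test_po_absorption_limit(hm_params, human_male):
    # long after an oral dose, (1-F) sits in the unabsorbed sink and F has
    # passed through the body into urine/tissues
    res = simulate(hm_params, human_male, [DoseEvent(0.0, "po", "chloride")],
                   _grid(5000.0))
    F = hm_params.F
    assert res.amount("unabs")[-1] == pytest.approx(1.0 - F, rel=1e-6)
    absorbed = res.A_blo[-1] + res.states[:, IDX["liv"]:IDX["rob"] + 1].sum(axis=1)[-1] \
        + res.amount("uri")[-1]
    assert absorbed == pytest.approx(F, rel=1e-6)
    assert res.amount("gut")[-1] < 1e-12


def test_speciation_decay_bound(hm_params, human_male):
    # injected citrate cannot outlive its first-order equilibration envelope
    res = simulate(hm_params, human_male, [DoseEvent(0.0, "iv", "citrate")], _grid(120.0))
    envelope = np.exp(-hm_params.k_Cit2Mix * res.t)
    assert np.all(res.amount("addCit") <= envelope * (1.0 + 1e-9) + 1e-15)


def test_auto_and_ode_routes_agree(hm_params, human_male):
    grid = _grid(3024.0, 60)
    ra = simulate(hm_params, human_male, [DoseEvent(0.0, "iv", "citrate")], grid)
    ro = simulate(hm_params, human_male, [DoseEvent(0.0, "iv", "citrate")], grid,
                  method="ode", rtol=1e-10, atol=1e-14)
    rel = np.abs(ra.states - ro.states) / np.maximum(ro.states, 1e-6)
    assert rel.max() < 1e-4


def test_two_compartment_closed_form_oracle(human_male):
    """Blood + muscle only, no speciation: simulation matches the hand-derived
    bi-exponential solution of the 2x2 linear system."""
    ref = human_male
    params = default_parameters(ref, I_lsk=0.0, I_bon=0.0, I_bra=0.0, I_rob=0.0)
    kin = params.I_mus * ref.Q_tis["mus"] / ref.V_blo
    kout = ref.Q_tis["mus"] / (params.K_mus * ref.V_tis["mus"])
    cl = renal_clearance(params.fu_Mix, params.GFR, ref.Q_kid) / ref.V_blo
    a = cl + kin
    tr, det = -(a + kout), cl * kout
    disc = math.sqrt(tr * tr - 4 * det)
    lam1, lam2 = (tr + disc) / 2, (tr - disc) / 2
    c1 = (-a - lam2) / (lam1 - lam2)
    c2 = 1.0 - c1

    t = _grid(2000.0, 80)
    blood = c1 * np.exp(lam1 * t) + c2 * np.exp(lam2 * t)
    muscle = (c1 * (lam1 + a) * np.exp(lam1 * t)
              + c2 * (lam2 + a) * np.exp(lam2 * t)) / kout

    res = simulate(params, ref, [DoseEvent(0.0, "iv", "chloride")], t,
                   method="ode", rtol=1e-10, atol=1e-14)
    assert np.allclose(res.A_blo, blood, rtol=1e-6, atol=1e-12)
    assert np.allclose(res.amount("mus"), muscle, rtol=1e-6, atol=1e-12)


def test_steady_state_tissue_blood_ratio(human_male):
    # zero clearance, single exchanging tissue: long-time ratio -> I*K*V_tis/V_blo
    ref = human_male
    params = default_parameters(ref, GFR=0.0, I_lsk=0.0, I_bon=0.0, I_bra=0.0,
                                I_rob=0.0, K_mus=5.0)
    kout = ref.Q_tis["mus"] / (params.K_mus * ref.V_tis["mus"])
    t_end = 30.0 / kout
    res = simulate(params, ref, [DoseEvent(0.0, "iv", "chloride")], _grid(t_end))
    expected = tissue_blood_ratio(params.I_mus, params.K_mus, ref.V_tis["mus"], ref.V_blo)
    assert res.amount("mus")[-1] / res.A_blo[-1] == pytest.approx(expected, rel=1e-6)


def test_retention_fraction(hm_params, human_male):
    res = simulate(hm_params, human_male, [DoseEvent(0.0, "iv", "citrate")], _grid(25200.0))
    assert retention_fraction(res, 1e-3) == pytest.approx(1.0, abs=1e-3)
    for t in (24.0, 504.0, 25200.0):
        ret = retention_fraction(res, t)
        uri = float(np.interp(t, res.t, res.amount("uri")))
        assert ret + uri == pytest.approx(1.0, abs=1e-8)
    with pytest.raises(InvalidInputError):
        retention_fraction(res, 30000.0)


def test_empirical_retention():
    assert empirical_retention(0.0) == pytest.approx(46.9)
    assert empirical_retention(1.0) == pytest.approx(32.09, abs=0.01)
    assert empirical_retention(1e6) == pytest.approx(0.0, abs=1e-6)
    assert np.all(np.diff(empirical_retention(np.linspace(0, 100, 50))) < 0)
    with pytest.raises(InvalidInputError):
        empirical_retention(-1.0)


def test_dose_event_validation():
    with pytest.raises(InvalidInputError):
        DoseEvent(0.0, "sc", "citrate")
    with pytest.raises(InvalidInputError):
        DoseEvent(0.0, "iv", "hydroxide")
    with pytest.raises(InvalidInputError):
        DoseEvent(-1.0, "iv", "citrate")
    assert DoseEvent(0.0, "iv", "citrate").target_state == "addCit"
    assert DoseEvent(0.0, "iv", "chloride").target_state == "Mix"
    assert DoseEvent(0.0, "po", "citrate").target_state == "gut"
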