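"""Equilibrium binding models: isotherms, species solver, ITC, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from coopbind import binding_models as bm
from coopbind import synthetic_data as sd

conc = st.floats(1e-3, 1e3)


# --------------------------------------------------------------------------
# 1:1 depletion isotherm


def numeric_fraction_bound(pt, dt, kd):
    """Independent oracle: solve the 1:1 mass balance for free ligand."""

    def f(d_free):
        p_free = pt / (1.0 + d_free / kd)
        return d_free + p_free * d_free / kd - dt

    d_free = optimize.brentq(f, 0.0, dt, rtol=1e-14) if dt > 0 else 0.0
    p_free = pt / (1.0 + d_free / kd)
    return (pt - p_free) / pt


def test_fraction_bound_zero_titrant():
    assert bm.fraction_bound_1to1(0.05, 0.0, 1.0) == 0.0


def test_fraction_bound_stoichiometric_limit():
    assert bm.fraction_bound_1to1(0.05, 0.05, 1e-12) == pytest.approx(1.0, abs=1e-5)


def test_fraction_bound_against_mass_balance_oracle():
    got = bm.fraction_bound_1to1(0.05, 0.27, 0.27)
    assert got == pytest.approx(0.477, abs=0.001)
    assert got == pytest.approx(numeric_fraction_bound(0.05, 0.27, 0.27), rel=1e-10)


@given(pt=conc, kd=conc, dt1=conc, dt2=conc)
def test_fraction_bound_monotone_in_titrant(pt, kd, dt1, dt2):
    lo, hi = sorted([dt1, dt2])
    f_lo = bm.fraction_bound_1to1(pt, lo, kd)
    f_hi = bm.fraction_bound_1to1(pt, hi, kd)
    assert f_hi >= f_lo - 1e-12


@given(pt=conc, dt=conc, kd1=conc, kd2=conc)
def test_fraction_bound_decreasing_in_kd(pt, dt, kd1, kd2):
    lo, hi = sorted([kd1, kd2])
    assert bm.fraction_bound_1to1(pt, dt, lo) >= bm.fraction_bound_1to1(pt, dt, hi) - 1e-12


def test_fraction_bound_rejects_invalid():
    with pytest.raises(ValueError):
        bm.fraction_bound_1to1(-1, 1, 1)
    with pytest.raises(ValueError):
        bm.fraction_bound_1to1(1, -1, 1)
    with pytest.raises(ValueError):
        bm.fraction_bound_1to1(1, 1, 0)


def test_predict_mst_signal_affine():
    dt = np.logspace(-3, 2, 16)
    flat = bm.predict_mst_signal(0.05, dt, 1.0, baseline=0.3, amplitude=0.0)
    assert np.allclose(flat, 0.3)
    up = bm.predict_mst_signal(0.05, dt, 1.0, baseline=0.1, amplitude=2.0)
    assert np.all(np.diff(up) >= -1e-12)
    f = bm.fraction_bound_1to1(0.05, dt, 1.0)
    assert np.allclose(up, 0.1 + 2.0 * f)


def test_fit_one_to_one_noiseless_self_consistency():
    series = sd.simulate_mst_titration(1.0, noise_cv=0.0, baseline=0.2, amplitude=0.8)
    fit = bm.fit_one_to_one(series)
    assert fit.kd == pytest.approx(1.0, rel=1e-6)
    assert fit.baseline == pytest.approx(0.2, abs=1e-6)
    assert fit.amplitude == pytest.approx(0.8, rel=1e-6)
    assert fit.kd_ci95[0] <= fit.kd <= fit.kd_ci95[1]


def test_fit_one_to_one_flat_signal_unidentifiable():
    series = sd.simulate_mst_titration(1.0, noise_cv=0.0, baseline=0.5, amplitude=0.0)
    with pytest.raises(bm.FitError):
        bm.fit_one_to_one(series)


@pytest.mark.parametrize("truth", [0.06, 1.0, 10.6])
def test_fit_one_to_one_low_bias_at_3pct_noise(truth):
    recovered = []
    for seed in range(25):
        series = sd.simulate_mst_titration(truth, noise_cv=0.03, seed=seed)
        recovered.append(bm.fit_one_to_one(series).kd)
    assert np.median(recovered) == pytest.approx(truth, rel=0.05)


# --------------------------------------------------------------------------
# Sequential two-event species solver


def grid_oracle_species(pt, dt, kd1, kd2, n=400_001):
    """Two-stage fine-grid search over free protein for the mass-balance root."""

    def best_on(grid):
        z = 1.0 + grid / kd1 + grid * grid / (kd1 * kd2)
        dp = dt * (grid / kd1) / z
        dp2 = dt * (grid * grid / (kd1 * kd2)) / z
        i = np.argmin(np.abs(grid + dp + 2 * dp2 - pt))
        return i, {"free_P": grid[i], "DP": dp[i], "DP2": dp2[i], "D": dt / z[i]}

    coarse = np.linspace(0.0, pt, n)
    i, _ = best_on(coarse)
    step = coarse[1] - coarse[0]
    lo = max(coarse[i] - 2 * step, 0.0)
    hi = min(coarse[i] + 2 * step, pt)
    _, species = best_on(np.linspace(lo, hi, n))
    return species


def test_species_no_protein():
    sp = bm.solve_sequential_species(0.0, 7.0, 1.0, 1.0)
    assert sp == {"free_P": 0.0, "D": 7.0, "DP": 0.0, "DP2": 0.0}


def test_species_weak_binding_limit():
    sp = bm.solve_sequential_species(5.0, 5.0, 1e9, 1e9)
    assert sp["free_P"] == pytest.approx(5.0, rel=1e-6)
    assert sp["DP2"] == pytest.approx(0.0, abs=1e-6)


def test_species_match_grid_oracle_at_measured_kds():
    got = bm.solve_sequential_species(30.0, 30.0, 1.24, 0.82)
    want = grid_oracle_species(30.0, 30.0, 1.24, 0.82)
    for key in ("free_P", "D", "DP", "DP2"):
        assert got[key] == pytest.approx(want[key], rel=1e-6, abs=1e-6)


@given(pt=conc, dt=conc, kd1=conc, kd2=conc)
def test_species_mass_conservation(pt, dt, kd1, kd2):
    sp = bm.solve_sequential_species(pt, dt, kd1, kd2)
    assert sp["free_P"] + sp["DP"] + 2 * sp["DP2"] == pytest.approx(pt, rel=1e-8)
    assert sp["D"] + sp["DP"] + sp["DP2"] == pytest.approx(dt, rel=1e-8)


@given(pt=conc, dt=conc, kd=conc)
def test_single_site_limit_agrees_with_1to1_isotherm(pt, dt, kd):
    sp = bm.solve_sequential_species(pt, dt, kd, 1e12)
    f_seq = sp["DP"] / pt
    assert f_seq == pytest.approx(bm.fraction_bound_1to1(pt, dt, kd), abs=1e-6)


# --------------------------------------------------------------------------
# ITC forward model


ITC_TRUTH = bm.SequentialBindingParams(1.24, 0.82, -3.0, -17.0)


def default_exp(heats=None, n=19):
    return bm.ITCExperiment(200.0, 30.0, 450.0, np.full(n, 2.0), heats if heats is not None else np.zeros(n))


def test_itc_zero_enthalpy_gives_pure_dilution():
    exp = default_exp()
    q = bm.predict_itc_heats(exp, bm.SequentialBindingParams(1.0, 1.0, 0.0, 0.0), dilution_offset=0.5)
    assert np.allclose(q, 0.5 * 2.0)


def test_itc_zero_syringe_protein_gives_pure_dilution():
    exp = bm.ITCExperiment(200.0, 30.0, 0.0, np.full(19, 2.0), np.zeros(19))
    q = bm.predict_itc_heats(exp, ITC_TRUTH, dilution_offset=-0.3)
    assert np.allclose(q, -0.3 * 2.0)


def test_itc_heats_approach_dilution_past_saturation():
    # long injection series: protein far in excess of the 2x DNA sites, so
    # late injections carry almost no binding heat (a small second-order
    # displacement term remains in the exact forward model)
    exp = bm.ITCExperiment(200.0, 30.0, 450.0, np.full(45, 2.0), np.zeros(45))
    q = bm.predict_itc_heats(exp, ITC_TRUTH, dilution_offset=0.1)
    excess = np.abs(q - 0.1 * 2.0)
    assert np.all(excess[-15:] < 0.01 * np.abs(q).max())
    # newly formed complex per injection decays monotonically once saturated
    dt, pt = bm._itc_concentrations(200.0, 30.0, 450.0, exp.injection_volumes)
    bound = np.array(
        [bm.solve_sequential_species(p, d, ITC_TRUTH.kd1, ITC_TRUTH.kd2)["DP2"] / d for d, p in zip(dt, pt)]
    )
    increments = np.diff(bound)  # occupancy gain per injection
    assert np.all(np.diff(increments[-15:]) <= 1e-12)  # tail increments shrink
    assert increments[-1] < 1e-3


def test_itc_rejects_overfilled_cell():
    with pytest.raises(ValueError):
        bm.ITCExperiment(200.0, 30.0, 450.0, np.full(101, 2.0), np.zeros(101))


def test_fit_itc_noiseless_recovery():
    exp = sd.simulate_itc_experiment(ITC_TRUTH, noise_sd=0.0)
    fit = bm.fit_itc(exp, "two_event_sequential")
    assert fit.params.kd1 == pytest.approx(1.24, rel=1e-4)
    assert fit.params.kd2 == pytest.approx(0.82, rel=1e-4)
    assert fit.params.dh1 == pytest.approx(-3.0, rel=1e-4)
    assert fit.params.dh2 == pytest.approx(-17.0, rel=1e-4)


def one_event_experiment(noise_sd=0.0, seed=0):
    exp = default_exp()
    heats = bm.predict_itc_heats_one_event(exp, bm.OneEventParams(1.0, -10.0))
    if noise_sd:
        heats = heats + np.random.default_rng(seed).normal(0, noise_sd, heats.size)
    return default_exp(heats=heats)


def test_aicc_prefers_one_event_on_one_event_data():
    exp = one_event_experiment(noise_sd=0.05, seed=1)
    sel = bm.select_binding_events(exp)
    assert sel.events == 1


def test_aicc_selects_two_events_on_two_event_data():
    clean = sd.simulate_itc_experiment(ITC_TRUTH, noise_sd=0.0)
    peak = np.abs(clean.heats).max()
    exp = sd.simulate_itc_experiment(ITC_TRUTH, noise_sd=0.02 * peak, seed=3)
    sel = bm.select_binding_events(exp)
    assert sel.events == 2
    assert sel.stoichiometry == "2:1"
    assert sel.reliable


def test_pure_noise_selection_flagged_unreliable():
    heats = np.random.default_rng(0).normal(0, 0.5, 19)
    sel = bm.select_binding_events(default_exp(heats=heats))
    assert not sel.reliable


def test_fit_itc_needs_enough_injections():
    with pytest.raises(ValueError):
        bm.fit_itc(default_exp(n=5), "one_event")


# --------------------------------------------------------------------------
# Cooperativity and fold changes


def test_statistical_factor_identity_is_not_cooperative():
    rep = bm.cooperativity_factor(0.5, 2.0)
    assert rep.omega == pytest.approx(1.0)
    assert rep.classification == "none"


def test_measured_kds_show_positive_cooperativity():
    rep = bm.cooperativity_factor(1.24, 0.82)
    assert rep.omega == pytest.approx(6.05, abs=0.01)
    assert rep.classification == "positive"


def test_negative_cooperativity():
    assert bm.cooperativity_factor(1.0, 100.0).classification == "negative"


def test_fold_change_examples():
    assert bm.fold_change(0.12, 0.06) == pytest.approx(2.0)
    assert bm.fold_change(11.00, 0.27) == pytest.approx(40.7, abs=0.1)
    assert bm.fold_change(3.3, 3.3) == 1.0
    with pytest.raises(ValueError):
        bm.fold_change(0.0, 1.0)
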