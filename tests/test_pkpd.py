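"""PK-PD layer: UGT sigmoid, death rate, protein translation/rescaling,
treatment simulation and toxicity profiles."""

import numpy as np
import pytest

import chronotox as ct
from chronotox.pkpd import (TreatmentProtocol, _alpha_fn, death_rate,
                            phase_adapt, rescale_protein, simulate_treatment,
                            toxicity_profile, translate_proteins,
                            ugt_treatment_factor)
from chronotox.simulate import Trajectory


# --- UGT sigmoid ------------------------------------------------------------

def test_ugt_factor_identity_at_zero_magnitude():
    t = np.linspace(-10, 100, 23)
    assert np.allclose(ugt_treatment_factor(t, 0.0, -0.5), 1.0)


def test_ugt_factor_midpoint_and_asymptote():
    k, M = -0.5, 2.0
    t_mid = -4.0 / k  # k t + 4 = 0
    assert ugt_treatment_factor(t_mid, M, k) == pytest.approx(1 + M / 2)
    assert ugt_treatment_factor(1e6, M, k) == pytest.approx(1 + M)
    # monotone increasing for negative slope
    t = np.linspace(0, 60, 100)
    assert np.all(np.diff(ugt_treatment_factor(t, M, k)) >= 0)


# --- death rate -------------------------------------------------------------

def test_death_rate_constant_without_modulation(pkpd_params):
    p = pkpd_params.replace(A_circ=0.0, A_alpha=0.0)
    proto = TreatmentProtocol(10.0, 1.0)
    t = np.linspace(0, 100, 50)
    assert np.allclose(death_rate(t, p, proto), p["d0"])


def test_alpha_function_peaks_at_tau():
    A, tau = 0.5, 6.0
    s = np.linspace(0, 60, 6001)
    vals = _alpha_fn(s, A, tau)
    assert vals.max() == pytest.approx(A, rel=1e-4)
    assert s[np.argmax(vals)] == pytest.approx(tau, abs=0.02)


def test_no_alpha_before_treatment(pkpd_params):
    proto = TreatmentProtocol(24.0, 1.0)
    before = death_rate(23.9, pkpd_params, proto)
    base = death_rate(23.9, pkpd_params.replace(A_alpha=0.0), proto)
    assert before == pytest.approx(base)


def test_alpha_requires_positive_tau(pkpd_params):
    with pytest.raises(ValueError):
        death_rate(1.0, pkpd_params.replace(tau_alpha=0.0),
                   TreatmentProtocol(0.0, 1.0))


# --- protein layer ----------------------------------------------------------

def _const_mrna_traj(level=2.0, t_end=200.0):
    t = np.arange(0.0, t_end + 0.05, 0.1)
    vals = np.tile(np.full(t.size, level), (4, 1))
    return Trajectory(t, vals, ["CES2", "UGT1A1", "ABCB", "ABCC"])


def test_translation_reaches_closed_form_steady_state(pkpd_params):
    p = pkpd_params.replace(**{f"ampp_{g}": 0.0 for g in
                               ("CES2", "UGT1A1", "ABCB", "ABCC")})
    traj = translate_proteins(_const_mrna_traj(2.0), p)
    expect = p["ktlp_CES2"] * 2.0 / p["dpp_CES2"]
    tail = traj.get("CES2_p")[traj.t > 150]
    assert np.allclose(tail, expect, rtol=1e-4)


def test_zero_mrna_protein_decays_to_zero(pkpd_params):
    traj = translate_proteins(_const_mrna_traj(0.0), pkpd_params)
    p = traj.get("UGT1A1_p")
    assert p[0] == pytest.approx(0.0, abs=1e-12)
    assert np.all(np.diff(p) <= 1e-12)


def test_circadian_degradation_matches_euler_oracle(pkpd_params):
    """Translation with circadian degradation against a fine-step explicit
    Euler integration of the same scalar ODE."""
    traj = translate_proteins(_const_mrna_traj(2.0, t_end=72.0), pkpd_params)
    ktl, d0 = pkpd_params["ktlp_CES2"], pkpd_params["dpp_CES2"]
    amp, ph = pkpd_params["ampp_CES2"], pkpd_params["php_CES2"]
    dt = 1e-3
    tt = np.arange(0.0, 72.0 + dt / 2, dt)
    p = np.empty(tt.size)
    p[0] = ktl * 2.0 / d0
    for i in range(1, tt.size):
        d = d0 * (1 + amp * np.cos(2 * np.pi * (tt[i - 1] - ph) / 24.0))
        p[i] = p[i - 1] + dt * (ktl * 2.0 - d * p[i - 1])
    ours = traj.interp("CES2_p", tt[::1000])
    assert np.max(np.abs(ours - p[::1000]) / np.max(p)) < 1e-3


def test_rescale_protein_examples():
    out = rescale_protein(np.array([1.0, 5.0, 2.0]), target_max=2.0)
    assert np.allclose(out, [0.4, 2.0, 0.8])
    # 10-fold UGT reduction for HCT116-like lines
    out = rescale_protein(np.array([1.0, 5.0]), 2.0, scale_factor=0.1)
    assert out.max() == pytest.approx(0.2)
    # zero UGT course passes through as zero in UGT-null lines
    z = rescale_protein(np.zeros(5), 2.0, allow_zero=True)
    assert np.all(z == 0)
    with pytest.raises(ValueError):
        rescale_protein(np.zeros(5), 2.0)


# --- treatment dynamics -----------------------------------------------------

def test_dose_zero_equals_control(drug_proteins, pkpd_params):
    t0 = drug_proteins.t[0]
    a = simulate_treatment(drug_proteins, pkpd_params,
                           TreatmentProtocol(t0, 0.0, horizon=48.0))
    b = simulate_treatment(drug_proteins, pkpd_params,
                           TreatmentProtocol(t0, 0.0, horizon=48.0))
    assert np.array_equal(a.values, b.values)
    assert np.all(a.get("SN38") == 0)


def test_negative_dose_rejected():
    with pytest.raises(ValueError):
        TreatmentProtocol(0.0, -1.0)


def test_dead_cells_non_decreasing(drug_proteins, pkpd_params):
    t0 = drug_proteins.t[0]
    traj = simulate_treatment(drug_proteins, pkpd_params,
                              TreatmentProtocol(t0, 1.0, horizon=72.0))
    assert np.all(np.diff(traj.get("D")) >= -1e-9)


def test_monotone_dose_response(drug_proteins, pkpd_params):
    t0 = drug_proteins.t[0]
    aucs = []
    for dose in (0.5, 1.0, 2.0):
        tr = simulate_treatment(drug_proteins, pkpd_params,
                                TreatmentProtocol(t0, dose, horizon=48.0))
        ctrl = simulate_treatment(drug_proteins, pkpd_params,
                                  TreatmentProtocol(t0, 0.0, horizon=48.0))
        aucs.append(np.trapezoid(tr.get("D"), tr.t)
                    / np.trapezoid(ctrl.get("D"), ctrl.t))
    assert aucs[0] <= aucs[1] <= aucs[2]


def test_control_profile_is_exactly_one(drug_proteins, pkpd_params):
    tt = drug_proteins.t[0] + np.arange(0.0, 24.1, 6.0)
    prof = toxicity_profile(drug_proteins, pkpd_params, tt, dose=0.0,
                            horizon=48.0)
    assert np.allclose(prof.auc, 1.0, atol=1e-12)


def test_profile_invariant_under_joint_rescaling(drug_proteins, pkpd_params):
    """Doubling the initial living pool doubles D in treated and control
    alike and leaves the normalized profile unchanged."""
    from chronotox.pkpd import CellPopulationState
    tt = drug_proteins.t[0] + np.arange(0.0, 24.1, 8.0)
    t0 = tt[0]
    for t_tr in tt:
        for dose in (1.0, 0.0):
            a = simulate_treatment(drug_proteins, pkpd_params,
                                   TreatmentProtocol(t_tr, dose, horizon=36.0),
                                   CellPopulationState(1.0, 0.0))
            b = simulate_treatment(drug_proteins, pkpd_params,
                                   TreatmentProtocol(t_tr, dose, horizon=36.0),
                                   CellPopulationState(2.0, 0.0))
            assert np.allclose(2 * a.get("D")[1:], b.get("D")[1:], rtol=1e-3)


def test_lower_ugt_scale_increases_toxicity(wt_cycle, pkpd_params):
    traj, _ = wt_cycle
    tt = traj.t[0] + np.arange(0.0, 24.1, 6.0)
    aucs = {}
    for scale in (1.0, 0.1):
        p = pkpd_params.replace(ugt_scale=scale)
        prot = ct.pkpd.rescaled_drug_proteins(translate_proteins(traj, p), p)
        prof = toxicity_profile(prot, p, tt, horizon=48.0)
        aucs[scale] = prof.auc
    assert np.all(aucs[0.1] >= aucs[1.0])


def test_treatment_run_matches_tight_tolerance_oracle(drug_proteins,
                                                      pkpd_params):
    """Dead-cell course at working tolerance versus an independent
    high-order integration at much tighter tolerance."""
    from scipy.integrate import solve_ivp
    t0 = drug_proteins.t[0]
    proto = TreatmentProtocol(t0, 1.0, exposure=100.0, horizon=48.0)
    ours = simulate_treatment(drug_proteins, pkpd_params, proto)

    tp = drug_proteins.t
    curves = {n: drug_proteins.get(n) for n in drug_proteins.names}
    p = pkpd_params

    def rhs(t, y):
        cpt, sn, c, living, dead = np.maximum(y, 0.0)
        ces = np.interp(t, tp, curves["CES2_p"])
        ugt = np.interp(t, tp, curves["UGT1A1_p"]) * ugt_treatment_factor(
            t - t0, p["M_UGT"], p["k_UGT"])
        abcb = np.interp(t, tp, curves["ABCB_p"])
        abcc = np.interp(t, tp, curves["ABCC_p"])
        dcpt = p["k_upt"] * 1.0 - (p["k_act"] * ces + p["k_eff_B"] * abcb) * cpt
        dsn = (p["k_act"] * ces * cpt
               - (p["k_deact"] * ugt + p["k_eff_C"] * abcc
                  + p["k_dna"] * p["TOP1"]) * sn)
        dc = p["k_dna"] * p["TOP1"] * sn - p["k_rep"] * c
        delta = death_rate(t, p, proto) + p["k_kill"] * c
        return [dcpt, dsn, dc, p["g_L"] * living - delta * living,
                delta * living]

    oracle = solve_ivp(rhs, (t0, t0 + 48.0), [0, 0, 0, 1.0, 0.0],
                       method="DOP853", rtol=1e-9, atol=1e-12,
                       t_eval=ours.t)
    assert oracle.success
    d_ref = oracle.y[4]
    dev = np.max(np.abs(ours.get("D") - d_ref)) / np.max(np.abs(d_ref))
    assert dev < 1e-3


# --- phase adaptation -------------------------------------------------------

def test_phase_adapt_identity_cases(pkpd_params):
    assert phase_adapt(pkpd_params, 0.0) == pkpd_params
    shifted = phase_adapt(pkpd_params, 24.0)
    for n in pkpd_params.names:
        assert shifted[n] == pytest.approx(pkpd_params[n] % 24.0
                                           if n.startswith("php_") or n == "phi_circ"
                                           else pkpd_params[n])


def test_phase_adapt_shifts_degradation_minima(pkpd_params):
    """A +3 h phase adaptation moves the protein course of a constant-mRNA
    gene (pure circadian degradation) by +3 h."""
    base = translate_proteins(_const_mrna_traj(2.0, 200.0), pkpd_params)
    shifted = translate_proteins(_const_mrna_traj(2.0, 200.0),
                                 phase_adapt(pkpd_params, 3.0))
    t = base.t
    w = (t > 150) & (t < 198)
    tb = t[w][np.argmin(base.get("CES2_p")[w])]
    ts = t[w][np.argmin(shifted.get("CES2_p")[w])]
    dt = (ts - tb) % 24.0
    assert dt == pytest.approx(3.0, abs=0.15)
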