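"""Synthetic expression and cytotoxicity generators."""

import numpy as np
import pytest

import chronotox as ct
from chronotox.synthetic import (GeneSpec, SyntheticSpec,
                                 default_synthetic_spec,
                                 generate_clock_expression,
                                 generate_cytotoxicity, generate_knockout)


def _cosinor_fit(t, y, period):
    """Least-squares cosinor: returns (mesor, amplitude, peak phase)."""
    X = np.column_stack([np.ones_like(t),
                         np.cos(2 * np.pi * t / period),
                         np.sin(2 * np.pi * t / period)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, a, b = beta
    amp = np.hypot(a, b)
    phase = (np.arctan2(b, a) * period / (2 * np.pi)) % period
    return m, amp, phase


def test_noiseless_cosinor_recovery():
    spec = SyntheticSpec(genes={"G": GeneSpec(10.0, 0.3, 5.0)},
                         noise_sd=0.0, seed=1, t_step=1.5, duration=48.0)
    ds = generate_clock_expression(spec)
    m, amp, phase = _cosinor_fit(ds.times, ds.series("G"), 24.0)
    assert m == pytest.approx(10.0, abs=1e-6)
    assert amp == pytest.approx(3.0, abs=1e-6)
    assert phase == pytest.approx(5.0, abs=1e-6)


def test_drift_detrended_series_matches_pure_cosine():
    g = GeneSpec(10.0, 0.3, 5.0, drift=0.2)
    spec = SyntheticSpec(genes={"G": g}, noise_sd=0.0, seed=1,
                         t_step=1.5, duration=48.0)
    ds = generate_clock_expression(spec)
    t, y = ds.times, ds.series("G")
    # detrend: subtract the linear component, then cosinor
    slope = np.polyfit(t, y - 10.0 * (1 + 0.3 * np.cos(2 * np.pi * (t - 5.0) / 24.0)), 1)[0]
    assert slope == pytest.approx(0.2, abs=1e-9)
    detrended = y - 0.2 * t
    m, amp, phase = _cosinor_fit(t, detrended, 24.0)
    assert amp == pytest.approx(3.0, abs=1e-6)
    assert phase == pytest.approx(5.0, abs=1e-6)


def test_same_seed_bitwise_reproducible():
    a = generate_clock_expression(default_synthetic_spec(seed=7))
    b = generate_clock_expression(default_synthetic_spec(seed=7))
    assert np.array_equal(a.values, b.values)
    c = generate_clock_expression(default_synthetic_spec(seed=8))
    assert not np.array_equal(a.values, c.values)


def test_spec_validation():
    with pytest.raises(ValueError):
        GeneSpec(-1.0)
    with pytest.raises(ValueError):
        GeneSpec(1.0, rel_amp=1.0)
    with pytest.raises(ValueError, match="24"):
        SyntheticSpec(genes={"G": GeneSpec(1.0)}, duration=12.0, seed=0)


def test_per2_ko_preserves_family_sum(synthetic_spec):
    wt = generate_clock_expression(synthetic_spec)
    ko = generate_knockout(synthetic_spec, "PER2")
    fam = ["PER1", "PER2", "PER3"]
    s_wt = sum(wt.series(g) for g in fam)
    s_ko = sum(ko.series(g) for g in fam)
    assert np.all(np.abs(s_ko / s_wt - 1.0) < 0.05)
    # the knocked-out gene itself is near zero
    assert ko.series("PER2").max() < 0.01 * wt.series("PER2").mean()
    # compensation raised PER1 (the strongest remaining paralog)
    assert ko.series("PER1").mean() > wt.series("PER1").mean()


def test_nr1d1_ko_compensated_by_nr1d2(synthetic_spec):
    wt = generate_clock_expression(synthetic_spec)
    ko = generate_knockout(synthetic_spec, "NR1D1")
    assert ko.series("NR1D2").mean() > wt.series("NR1D2").mean()


def test_arntl_ko_co_reduces_arntl2(synthetic_spec):
    wt = generate_clock_expression(synthetic_spec)
    ko = generate_knockout(synthetic_spec, "ARNTL")
    assert ko.series("ARNTL2").mean() < wt.series("ARNTL2").mean()


def test_ko_without_rule_errors(synthetic_spec):
    with pytest.raises(ValueError, match="rule"):
        generate_knockout(synthetic_spec, "CES2")
    with pytest.raises(ValueError, match="unknown"):
        generate_knockout(synthetic_spec, "NOSUCH")


def test_hct116_like_ugt_near_zero():
    ds = generate_clock_expression(default_synthetic_spec(seed=1,
                                                          hct116_like=True))
    assert ds.series("UGT1A1").max() < 0.05


def test_cytotox_noiseless_equals_simulation(drug_proteins, pkpd_params):
    t0 = drug_proteins.t[0]
    tt = t0 + np.array([0.0, 12.0, 24.0])
    curves, truth = generate_cytotoxicity(drug_proteins, pkpd_params, tt,
                                          noise_sd=0.0, seed=0,
                                          horizon=36.0, measurement_step=6.0)
    from chronotox.pkpd import TreatmentProtocol, simulate_treatment
    traj = simulate_treatment(drug_proteins, pkpd_params,
                              TreatmentProtocol(tt[1], 1.0, 48.0, 36.0))
    sub = curves[curves.treatment_time_h == tt[1]]
    expect = traj.interp("D", tt[1] + sub.measurement_time_h.to_numpy())
    assert np.allclose(sub.cytotox_signal.to_numpy(), expect, atol=1e-12)
    # attached truth equals an independent profile recomputation
    from chronotox.pkpd import toxicity_profile
    prof = toxicity_profile(drug_proteins, pkpd_params, tt, horizon=36.0)
    assert np.allclose(truth.auc, prof.auc, atol=1e-12)


def test_cytotox_empty_grid_errors(drug_proteins, pkpd_params):
    with pytest.raises(ValueError, match="empty"):
        generate_cytotoxicity(drug_proteins, pkpd_params, [], seed=0)
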