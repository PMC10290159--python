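"""Integration correctness: closed forms, determinism, non-negativity,
limit-cycle detection."""

import numpy as np
import pytest

import chronotox as ct
from chronotox.simulate import Trajectory, find_maxima


def _decay_topology(d=0.3):
    return {"mrnas": [{"name": "X", "vmax": ["V_X", 0.0],
                       "regulation": [], "degradation": ["dm_X", d]}],
            "proteins": []}


def test_single_species_decay_matches_closed_form():
    d, x0 = 0.3, 2.0
    sys1 = ct.build_network(_decay_topology(d))
    traj = ct.simulate(sys1, sys1.default_parameters, [x0], (0.0, 20.0),
                       t_step=0.5, rtol=1e-8, atol=1e-12)
    expected = x0 * np.exp(-d * traj.t)
    assert np.allclose(traj.get("X"), expected, rtol=1e-6)


def test_simulation_deterministic(system, wt_params):
    y0 = ct.default_initial_state(system)
    a = ct.simulate(system, wt_params, y0, (0.0, 48.0))
    b = ct.simulate(system, wt_params, y0, (0.0, 48.0))
    assert np.array_equal(a.t, b.t)
    assert np.array_equal(a.values, b.values)


def test_trivial_schedule_equals_no_schedule(system, wt_params):
    y0 = ct.default_initial_state(system)
    sch = ct.ZeitgeberSchedule(f_light=1.0,
                               pulses=[ct.PulseSpec(10.0, 1.0, 1.0)])
    a = ct.simulate(system, wt_params, y0, (0.0, 48.0), schedule=sch)
    b = ct.simulate(system, wt_params, y0, (0.0, 48.0))
    assert np.array_equal(a.values, b.values)


def test_non_negative_over_ten_days(system, wt_params):
    y0 = ct.default_initial_state(system)
    traj = ct.simulate(system, wt_params, y0, (0.0, 240.0))
    assert traj.values.min() >= 0.0
    assert np.all(np.isfinite(traj.values))


def test_limit_cycle_period_and_flags(wt_cycle):
    traj, period = wt_cycle
    assert period == pytest.approx(23.8, abs=0.05)
    assert traj.meta["reference"] == "ARNTL"


def test_constructed_oscillation_period_recovered():
    """Peak detection on a known 24 h harmonic signal."""
    t = np.arange(0.0, 120.0, 0.05)
    y = 2.0 + np.cos(2 * np.pi * (t - 3.0) / 24.0)
    peaks, heights = find_maxima(t, y)
    assert np.allclose(np.diff(peaks), 24.0, atol=0.05)
    assert peaks[0] == pytest.approx(3.0, abs=0.05)


def test_fixed_point_parameters_raise_damped_error(system, wt_params):
    # removing PER:CRY complex formation destroys the negative feedback
    damped = wt_params.replace(kass_PC_c=0.0)
    with pytest.raises(ct.DampedOscillationError):
        ct.limit_cycle(system, damped, transient=120.0, window=96.0)


def test_trajectory_validation():
    with pytest.raises(ValueError, match="increasing"):
        Trajectory(np.array([0.0, 0.0, 1.0]), np.zeros((1, 3)), ["A"])
    with pytest.raises(ValueError, match="finite"):
        Trajectory(np.array([0.0, 1.0]), np.array([[np.nan, 1.0]]), ["A"])


def test_init_state_validation(system, wt_params):
    with pytest.raises(ValueError, match="non-negative"):
        ct.simulate(system, wt_params, -np.ones(system.n_species), (0, 1))
    with pytest.raises(ValueError, match="entries"):
        ct.simulate(system, wt_params, [1.0], (0, 1))


def test_tidy_export_round_trip(tmp_path, system, wt_params):
    y0 = ct.default_initial_state(system)
    traj = ct.simulate(system, wt_params, y0, (0.0, 5.0), t_step=1.0)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    import pandas as pd
    df = pd.read_csv(path)
    assert set(df.columns) == {"time", "species", "value"}
    sub = df[df.species == "ARNTL"].sort_values("time")
    assert np.allclose(sub.value.to_numpy(), traj.get("ARNTL"), atol=1e-12)
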