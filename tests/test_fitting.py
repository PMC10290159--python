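"""Cost functions, constraints and fit bookkeeping (fast paths).

The expensive CMA-ES recovery and regularization-path checks live in
test_acceptance.py; here the cost terms are verified against independent
brute-force oracles and hand-computed values.
"""

import numpy as np
import pytest

import chronotox as ct
from chronotox.datasets import ExpressionDataset
from chronotox.fitting import (FitConfig, amplitude_constraint,
                               coefficient_of_determination,
                               cost_squared_error, divergent_parameters,
                               lasso_cost, model_generated_dataset)
from chronotox.params import ParameterSet
from chronotox.simulate import Trajectory


def _traj(genes, times, values):
    return Trajectory(np.asarray(times, float), np.asarray(values, float),
                      list(genes))


def test_cost_zero_when_sim_equals_data():
    ds = ExpressionDataset(["A"], [0.0, 3.0], [[2.0, 4.0]])
    sim = _traj(["A"], [0.0, 3.0], [[2.0, 4.0]])
    assert cost_squared_error(ds, sim) == 0.0


def test_cost_single_gene_hand_value():
    # x=[2,4], s=[2,2]: (0/4)^2 + (2/4)^2 = 0.25
    ds = ExpressionDataset(["A"], [0.0, 3.0], [[2.0, 4.0]])
    sim = _traj(["A"], [0.0, 3.0], [[2.0, 2.0]])
    assert cost_squared_error(ds, sim) == pytest.approx(0.25)


def test_cost_matches_double_loop_oracle():
    """Vector implementation against a naive per-gene, per-timepoint loop
    on 20 random multi-gene toys."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        n_g, n_t = rng.integers(2, 6), rng.integers(3, 8)
        times = np.sort(rng.uniform(0, 48, n_t))
        times += np.arange(n_t) * 1e-3  # ensure strictly increasing
        x = rng.uniform(0.5, 10, (n_g, n_t))
        s = rng.uniform(0.0, 10, (n_g, n_t))
        genes = [f"G{i}" for i in range(n_g)]
        ds = ExpressionDataset(genes, times, x)
        sim = _traj(genes, times, s)
        expected = 0.0
        for j in range(n_g):
            mx = max(x[j])
            for i in range(n_t):
                expected += ((x[j, i] - s[j, i]) / mx) ** 2
        assert cost_squared_error(ds, sim) == pytest.approx(expected)


def test_lasso_cost_arithmetic():
    wt = ParameterSet(["a", "b", "c", "d"], [1.0, 1.0, 1.0, 1.0])
    p = wt.replace(a=2.0)  # one parameter at 2x WT
    assert lasso_cost(3.0, wt, wt, lam=8.0, n_par=4) == pytest.approx(3.0)
    assert lasso_cost(3.0, p, wt, lam=0.0, n_par=4) == pytest.approx(3.0)
    # 8 * (1/4) * |2-1|/1 = 2
    assert lasso_cost(3.0, p, wt, lam=8.0, n_par=4) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        lasso_cost(3.0, p, wt, lam=1.0, n_par=0)


def test_lasso_matches_loop_oracle_on_random_toys():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n = int(rng.integers(2, 9))
        names = [f"p{i}" for i in range(n)]
        wt = ParameterSet(names, rng.uniform(0.1, 5, n))
        p = ParameterSet(names, rng.uniform(0.1, 5, n))
        lam = float(rng.uniform(0, 10))
        cse = float(rng.uniform(0, 5))
        expected = cse + lam / n * sum(
            abs((p[k] - wt[k]) / wt[k]) for k in names)
        assert lasso_cost(cse, p, wt, lam) == pytest.approx(expected)


def test_lasso_excludes_near_zero_wt_entries():
    wt = ParameterSet(["a", "b"], [1.0, 0.0])
    p = ParameterSet(["a", "b"], [1.0, 5.0])
    # entry b has wt ~ 0: excluded from the sum, not a division by zero
    assert lasso_cost(1.0, p, wt, lam=4.0) == pytest.approx(1.0)


def test_amplitude_constraint_rules():
    t = np.linspace(0, 48, 49)
    flat = np.full(t.size, 1.0)
    osc6 = 1.0 - 0.06 * (t % 24 > 12)  # max 1.0, min 0.94
    osc4 = 1.0 - 0.04 * (t % 24 > 12)
    sim = Trajectory(t, np.array([flat, osc6, osc4]), ["F", "S", "W"])
    out = amplitude_constraint(sim, ["F", "S", "W"], threshold=0.05)
    assert out == {"F": False, "S": True, "W": False}
    # exemption (UGT1A1 in HCT116-like lines) always passes
    out = amplitude_constraint(sim, ["F"], threshold=0.05, exempt=("F",))
    assert out["F"] is True


def test_r2_trivial_values():
    ds = ExpressionDataset(["A", "B"], [0.0, 3.0, 6.0],
                           [[1.0, 2.0, 3.0], [4.0, 6.0, 8.0]])
    perfect = _traj(["A", "B"], ds.times, ds.values)
    assert coefficient_of_determination(ds, perfect) == pytest.approx(1.0)
    means = _traj(["A", "B"], ds.times,
                  [[2.0] * 3, [6.0] * 3])
    assert coefficient_of_determination(ds, means) == pytest.approx(0.0)


def test_r2_pooled_two_gene_hand_value():
    ds = ExpressionDataset(["A", "B"], [0.0, 3.0],
                           [[1.0, 2.0], [2.0, 4.0]])
    sim = _traj(["A", "B"], ds.times, [[1.0, 1.0], [4.0, 4.0]])
    # normalized: A: x=(.5,1) s=(.5,.5); B: x=(.5,1) s=(1,1)
    ss_res = 0.0 + 0.5 ** 2 + 0.5 ** 2 + 0.0
    ss_tot = 4 * 0.25 ** 2  # each series (.5,1) about its mean .75
    expected = 1 - ss_res / ss_tot
    assert coefficient_of_determination(ds, sim) == pytest.approx(expected)


def test_r2_zero_variance_errors():
    ds = ExpressionDataset(["A"], [0.0, 3.0], [[2.0, 2.0]])
    sim = _traj(["A"], ds.times, [[2.0, 2.0]])
    with pytest.raises(ValueError, match="variance"):
        coefficient_of_determination(ds, sim)


def test_divergent_parameter_threshold():
    wt = ParameterSet(["a", "b", "c"], [1.0, 1.0, 1.0])
    assert divergent_parameters(wt, wt) == []
    p = ParameterSet(["a", "b", "c"], [1.04, 1.10, 1.0])
    out = divergent_parameters(p, wt, threshold=0.05)
    assert out == [("b", pytest.approx(0.10))]
    with pytest.raises(ValueError, match="aligned"):
        divergent_parameters(ParameterSet(["x"], [1.0]), wt)


def test_budget_zero_returns_initial_guess(system, model_dataset):
    cfg = FitConfig(free_names=["V_PER"], max_evals=0, seed=3)
    res = ct.fit_wildtype(model_dataset, system, cfg)
    assert res.n_evals == 0
    assert res.params["V_PER"] == system.default_parameters["V_PER"]
    assert res.cost_se == pytest.approx(0.0, abs=1e-8)


def test_infeasible_bounds_rejected(system, model_dataset):
    cfg = FitConfig(free_names=["V_PER"], bounds={"V_PER": (2.0, 1.0)},
                    max_evals=10, seed=0)
    with pytest.raises(ValueError, match="bounds"):
        ct.fit_wildtype(model_dataset, system, cfg)


def test_model_generated_dataset_is_self_consistent(system, wt_params,
                                                    model_dataset):
    """Refitting convention: simulating the generating parameters under
    the fitting initial-state convention reproduces the dataset."""
    sim = ct.fitting.simulate_for_data(system, wt_params, model_dataset)
    assert cost_squared_error(model_dataset, sim) < 1e-8


def test_penalty_sweep_validates_grid(system, model_dataset):
    from chronotox.fitting import FitResult, penalty_sweep
    wt_res = FitResult(system.default_parameters, 0.0, None, None, [],
                       0, 0, True)
    cfg = FitConfig(free_names=["V_PER"], max_evals=0, seed=0)
    with pytest.raises(ValueError, match="empty"):
        penalty_sweep(model_dataset, system, wt_res, [], cfg)
    with pytest.raises(ValueError, match="non-negative"):
        penalty_sweep(model_dataset, system, wt_res, [-1.0], cfg)
    df = penalty_sweep(model_dataset, system, wt_res, [0.0], cfg)
    assert len(df) == 1 and df["lambda"].iloc[0] == 0.0


def test_cytotoxicity_rescaling_requires_control():
    import pandas as pd
    from chronotox.fitting import rescale_cytotoxicity
    df = pd.DataFrame({"treatment_time_h": [0.0, 0.0],
                       "measurement_time_h": [0.0, 4.0],
                       "cytotox_signal": [1.0, 2.0]})
    with pytest.raises(ValueError, match="control"):
        rescale_cytotoxicity(df)


def test_cytotoxicity_rescaling_aligns_start_values():
    import pandas as pd
    from chronotox.fitting import rescale_cytotoxicity
    df = pd.DataFrame({
        "treatment_time_h": ["control"] * 3 + [0.0] * 3,
        "measurement_time_h": [0.0, 4.0, 8.0] * 2,
        "cytotox_signal": [1.0, 1.5, 2.0, 5.0, 7.0, 9.0],
    })
    out = rescale_cytotoxicity(df)
    treated = out[out.condition == "T0"].sort_values("measurement_time_h")
    assert treated["cytotox_signal"].iloc[0] == pytest.approx(1.0)
    # temporal development preserved
    assert np.allclose(np.diff(treated["cytotox_signal"]), [2.0, 2.0])
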