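"""Parameter estimation for the clock network and the PK-PD layer.

The squared-error cost normalizes each gene's residuals by the gene's
data maximum so every mRNA carries equal weight regardless of its
expression level. Fits run CMA-ES in log-parameter space with restarts;
the minimum-relative-amplitude requirement (5%) enters as a large
additive penalty so the optimizer keeps a gradient signal. Knock-out
cell lines are fitted with a LASSO penalty on the relative divergence of
each parameter from its wild-type value, which concentrates the
divergence on few parameters; the penalty weight lambda trades fit
quality (R^2) against the number of divergent parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmaes import cma_es_minimize
from .datasets import ExpressionDataset
from .network import ODESystem
from .params import ParameterSet
from .pkpd import (PKPDParameters, TreatmentProtocol, rescaled_drug_proteins,
                   simulate_treatment, translate_proteins)
from .simulate import (IntegrationError, Trajectory, default_initial_state,
                       relative_amplitude, simulate)

__all__ = [
    "FitConfig",
    "FitResult",
    "cost_squared_error",
    "lasso_cost",
    "amplitude_constraint",
    "coefficient_of_determination",
    "simulate_for_data",
    "fit_wildtype",
    "fit_knockout",
    "penalty_sweep",
    "divergent_parameters",
    "fit_pkpd",
]

WT_EPS = 1e-9          # |p_WT| below this is excluded from relative terms
AMPLITUDE_PENALTY = 1e4
FAILURE_COST = 1e12


@dataclass
class FitConfig:
    """Settings shared by all fitting routines.

    ``free_names`` selects the fitted subset of the parameter vector;
    bounds default to [bound_lo_factor, bound_hi_factor] times the
    initial value of each free parameter. ``seed`` controls the CMA-ES
    sampling and is recorded in every result.
    """

    free_names: list = field(default_factory=list)
    bound_lo_factor: float = 0.01
    bound_hi_factor: float = 100.0
    bounds: dict = field(default_factory=dict)   # name -> (lo, hi) overrides
    sigma0: float = 0.3                          # in log10-parameter units
    popsize: int | None = None
    max_evals: int = 5000
    restarts: int = 3
    seed: int = 0
    amplitude_threshold: float = 0.05
    amplitude_exempt: tuple = ()
    divergence_threshold: float = 0.05

    def __post_init__(self):
        if self.bound_lo_factor <= 0 or self.bound_hi_factor <= self.bound_lo_factor:
            raise ValueError("bound factors must satisfy 0 < lo < hi")


@dataclass
class FitResult:
    """Best-of-run parameter estimate with its diagnostics."""

    params: ParameterSet
    cost_se: float
    cost_lasso: float | None
    r2: float | None
    divergent: list
    seed: int
    n_evals: int
    success: bool
    message: str = ""
    trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(), "cost_se": self.cost_se,
                "cost_lasso": self.cost_lasso, "r2": self.r2,
                "divergent": self.divergent, "seed": self.seed,
                "n_evals": self.n_evals, "success": self.success,
                "message": self.message}


# ---------------------------------------------------------------------------
# cost terms
# ---------------------------------------------------------------------------

def _predictions(data: ExpressionDataset, sim: Trajectory) -> np.ndarray:
    return np.array([sim.interp(g, data.times) for g in data.genes])


def cost_squared_error(data: ExpressionDataset, sim: Trajectory,
                       exempt=()) -> float:
    """Sum over genes and timepoints of ((x - s(t)) / max_t x)^2.

    The per-gene normalizer gives every mRNA equal weight independent of
    its concentration. The sum runs over the data genes the simulation
    models (data-only genes are ignored). Genes with an all-zero data
    series are skipped if listed in ``exempt`` (UGT1A1 in UGT-null
    lines), otherwise an error.
    """
    total = 0.0
    for gene in (g for g in data.genes if g in sim.names):
        x = data.series(gene)
        mx = x.max()
        if mx <= 0:
            if gene in exempt:
                continue
            raise ValueError(
                f"gene {gene!r} has an all-zero series and is not "
                f"amplitude-exempt")
        s = sim.interp(gene, data.times)
        total += float(np.sum(((x - s) / mx) ** 2))
    return total


def lasso_cost(cost_se: float, params: ParameterSet, wt_params: ParameterSet,
               lam: float, n_par: int | None = None,
               names=None) -> float:
    """cost_SE + lambda (1/n_par) sum_i |(p_i - p_i^WT) / p_i^WT|.

    The sum runs over ``names`` (default: all shared parameters); entries
    whose wild-type value is below ``WT_EPS`` are excluded (relative
    deviation undefined).
    """
    if names is None:
        names = [n for n in params.names if n in wt_params]
    used = [n for n in names if abs(wt_params[n]) > WT_EPS]
    if n_par is None:
        n_par = len(names)
    if n_par == 0:
        raise ValueError("n_par must be positive")
    pen = sum(abs((params[n] - wt_params[n]) / wt_params[n]) for n in used)
    return float(cost_se + lam * pen / n_par)


def amplitude_constraint(sim: Trajectory, genes, threshold: float = 0.05,
                         exempt=()) -> dict:
    """Per-gene pass/fail of the minimum relative amplitude
    (max - min)/max > threshold; exempt genes always pass."""
    out = {}
    for g in genes:
        if g in exempt:
            out[g] = True
            continue
        out[g] = relative_amplitude(sim.get(g)) > threshold
    return out


def coefficient_of_determination(data: ExpressionDataset,
                                 sim: Trajectory, exempt=()) -> float:
    """Pooled R^2 = 1 - SS_res/SS_tot over max-normalized gene series.

    May be negative when the simulation fits the data worse than the
    per-gene mean (e.g. a knock-out fit evaluated against wild-type data).
    """
    ss_res = 0.0
    ss_tot = 0.0
    for gene in (g for g in data.genes if g in sim.names):
        x = data.series(gene)
        mx = x.max()
        if mx <= 0:
            if gene in exempt:
                continue
            raise ValueError(f"gene {gene!r} has an all-zero series")
        xn = x / mx
        s = sim.interp(gene, data.times) / mx
        ss_res += float(np.sum((xn - s) ** 2))
        ss_tot += float(np.sum((xn - xn.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("zero total variance; R^2 undefined")
    return 1.0 - ss_res / ss_tot


def divergent_parameters(fit_params: ParameterSet, wt_params: ParameterSet,
                         threshold: float = 0.05, names=None) -> list:
    """Parameters with |p/p_WT - 1| > threshold, as (name, deviation).

    Parameter sets must align on ``names`` (default: the full wild-type
    name list); near-zero wild-type entries are excluded.
    """
    if names is None:
        names = wt_params.names
        if fit_params.names != wt_params.names:
            raise ValueError("parameter sets are not aligned")
    missing = [n for n in names if n not in fit_params or n not in wt_params]
    if missing:
        raise ValueError(f"parameters missing from one set: {missing}")
    out = []
    for n in names:
        wt = wt_params[n]
        if abs(wt) <= WT_EPS:
            continue
        dev = abs(fit_params[n] / wt - 1.0)
        if dev > threshold:
            out.append((n, float(dev)))
    out.sort(key=lambda kv: -kv[1])
    return out


# ---------------------------------------------------------------------------
# clock-network fitting
# ---------------------------------------------------------------------------

def simulate_for_data(system: ODESystem, params, data: ExpressionDataset,
                      t_step: float = 0.25) -> Trajectory:
    """Simulate the network over the data window (t = 0 at synchronization),
    starting from the first data timepoint for fitted species."""
    y0 = default_initial_state(system, data)
    t1 = float(data.times[-1])
    return simulate(system, params, y0, (0.0, max(t1, data.times[0]) + 1e-6),
                    t_step=t_step)


def model_generated_dataset(system: ODESystem, params, times,
                            cell_line: str = "model",
                            n_iter: int = 3) -> ExpressionDataset:
    """Expression dataset generated by the model itself, for recovery tests.

    Iterates the fitting initial-state convention (mRNAs at the first data
    timepoint, proteins at a small data-derived floor) to a fixed point so
    that refitting the generating parameters yields (near-)zero cost.
    """
    times = np.asarray(times, float)
    y0 = default_initial_state(system)
    ds = None
    for _ in range(n_iter):
        traj = simulate(system, params, y0, (0.0, float(times[-1]) + 1e-6),
                        t_step=0.25)
        vals = np.array([traj.interp(g, times) for g in system.mrna_names])
        ds = ExpressionDataset(system.mrna_names, times, vals,
                               cell_line=cell_line)
        y0 = default_initial_state(system, ds)
    return ds


def _objective_factory(system, data, base_params, config,
                       wt_params=None, lam: float = 0.0):
    free = list(config.free_names)
    if not free:
        raise ValueError("config.free_names must list the fitted parameters")
    for n in free:
        if n not in base_params:
            raise ValueError(f"unknown free parameter: {n!r}")
    x0 = base_params.subset_array(free)
    if np.any(x0 <= 0):
        raise ValueError("free parameters must be strictly positive to fit "
                         "in log space")
    lo = np.empty(len(free))
    hi = np.empty(len(free))
    for i, n in enumerate(free):
        l, h = config.bounds.get(
            n, (config.bound_lo_factor * x0[i], config.bound_hi_factor * x0[i]))
        if not (0 < l < h):
            raise ValueError(f"infeasible bounds for {n!r}: ({l}, {h})")
        lo[i], hi[i] = np.log10(l), np.log10(h)
    z0 = np.log10(x0)
    genes = [g for g in data.genes if g in system.species]

    def unpack(z):
        return base_params.updated_from(free, 10.0 ** np.asarray(z))

    def objective(z):
        p = unpack(z)
        try:
            sim = simulate_for_data(system, p, data)
        except (IntegrationError, ValueError):
            return FAILURE_COST
        try:
            c = cost_squared_error(data, sim, exempt=config.amplitude_exempt)
        except ValueError:
            return FAILURE_COST
        ok = amplitude_constraint(sim, genes, config.amplitude_threshold,
                                  config.amplitude_exempt)
        n_bad = sum(not v for v in ok.values())
        c += AMPLITUDE_PENALTY * n_bad
        if lam > 0 and wt_params is not None:
            c = lasso_cost(c, p, wt_params, lam, n_par=len(free), names=free)
        return c

    return objective, unpack, z0, (lo, hi), free


def _run_cma(objective, z0, bounds, config):
    """Best-of-restarts CMA-ES; restarts double the population (IPOP) and
    jitter the start mean to escape local optima of the rugged phase
    landscape."""
    best = None
    evals_total = 0
    per_run = max(1, config.max_evals // max(1, config.restarts))
    traces = []
    rng = np.random.default_rng(config.seed)
    n = len(z0)
    base_pop = config.popsize or (4 + int(3 * np.log(n)))
    for k in range(max(1, config.restarts)):
        zk = z0 if k == 0 else np.clip(
            z0 + config.sigma0 * rng.standard_normal(n), *bounds)
        res = cma_es_minimize(objective, zk, config.sigma0, bounds=bounds,
                              max_evals=per_run, popsize=base_pop * (2 ** k),
                              seed=config.seed + k)
        evals_total += res.n_evals
        traces.append(res.trace)
        if best is None or res.fun < best.fun:
            best = res
    return best, evals_total, traces


def fit_wildtype(data: ExpressionDataset, system: ODESystem,
                 config: FitConfig) -> FitResult:
    """Fit the clock network to wild-type expression (squared-error cost,
    amplitude constraint as additive penalty, CMA-ES with restarts)."""
    objective, unpack, z0, bounds, _ = _objective_factory(
        system, data, system.default_parameters, config)
    if config.max_evals == 0:
        p0 = unpack(z0)
        sim = simulate_for_data(system, p0, data)
        c = cost_squared_error(data, sim, exempt=config.amplitude_exempt)
        return FitResult(p0, c, None,
                         coefficient_of_determination(
                             data, sim, exempt=config.amplitude_exempt),
                         [], config.seed, 0, True, "initial guess (0 evals)")
    best, n_evals, traces = _run_cma(objective, z0, bounds, config)
    p = unpack(best.x)
    try:
        sim = simulate_for_data(system, p, data)
        cost = cost_squared_error(data, sim, exempt=config.amplitude_exempt)
        r2 = coefficient_of_determination(data, sim,
                                          exempt=config.amplitude_exempt)
    except (IntegrationError, ValueError) as exc:
        return FitResult(p, FAILURE_COST, None, None, [], config.seed,
                         n_evals, False, f"best candidate unusable: {exc}")
    success = best.fun < AMPLITUDE_PENALTY  # no amplitude violation survived
    msg = "" if success else ("no feasible oscillatory solution within "
                              "budget (amplitude constraint violated)")
    return FitResult(p, cost, None, r2, [], config.seed, n_evals, success,
                     msg, trace=traces)


def fit_knockout(data: ExpressionDataset, system: ODESystem,
                 wt_result: FitResult, lam: float,
                 config: FitConfig) -> FitResult:
    """LASSO-regularized fit of a knock-out line around the wild-type
    parameters; reports the divergent-parameter list at the 5% threshold.

    The knocked-out paralog is removed from the lumped data sum on the
    data side (see :func:`chronotox.datasets.lump_paralogs`); the lumped
    species itself stays in the model.
    """
    if not wt_result.success:
        raise ValueError("wild-type fit is not valid")
    wt = wt_result.params
    objective, unpack, z0, bounds, free = _objective_factory(
        system, data, wt, config, wt_params=wt, lam=lam)
    if config.max_evals == 0:
        p0 = unpack(z0)
        sim = simulate_for_data(system, p0, data)
        c = cost_squared_error(data, sim, exempt=config.amplitude_exempt)
        return FitResult(p0, c, lasso_cost(c, p0, wt, lam, n_par=len(free),
                                           names=free),
                         None, [], config.seed, 0, True, "initial guess")
    best, n_evals, traces = _run_cma(objective, z0, bounds, config)
    p = unpack(best.x)
    try:
        sim = simulate_for_data(system, p, data)
        cost = cost_squared_error(data, sim, exempt=config.amplitude_exempt)
        r2 = coefficient_of_determination(data, sim,
                                          exempt=config.amplitude_exempt)
    except (IntegrationError, ValueError) as exc:
        return FitResult(p, FAILURE_COST, None, None, [], config.seed,
                         n_evals, False, f"best candidate unusable: {exc}")
    classo = lasso_cost(cost, p, wt, lam, n_par=len(free), names=free)
    div = divergent_parameters(p, wt, config.divergence_threshold, names=free)
    success = best.fun < AMPLITUDE_PENALTY
    return FitResult(p, cost, classo, r2, div, config.seed, n_evals, success,
                     "" if success else "amplitude constraint violated",
                     trace=traces)


def penalty_sweep(data: ExpressionDataset, system: ODESystem,
                  wt_result: FitResult, lambda_grid,
                  config: FitConfig) -> pd.DataFrame:
    """One KO fit per lambda (same seed across the grid so only lambda
    varies); returns a table of (lambda, cost_SE, R^2, n_divergent)."""
    grid = list(lambda_grid)
    if not grid:
        raise ValueError("lambda grid must not be empty")
    if any(l < 0 for l in grid):
        raise ValueError("lambda values must be non-negative")
    rows = []
    results = {}
    for lam in grid:
        r = fit_knockout(data, system, wt_result, lam, config)
        results[lam] = r
        rows.append({"lambda": lam, "cost_se": r.cost_se, "r2": r.r2,
                     "n_divergent": len(r.divergent)})
    df = pd.DataFrame(rows)
    df.attrs["results"] = results
    return df


# ---------------------------------------------------------------------------
# PK-PD fitting to cytotoxicity curves
# ---------------------------------------------------------------------------

def rescale_cytotoxicity(curves: pd.DataFrame) -> pd.DataFrame:
    """Shift each treated curve so it starts at the control's start value
    (the profile must depend on the temporal development, not the level at
    treatment onset). Expects columns (treatment_time_h, measurement_time_h,
    cytotox_signal) with the control flagged as treatment_time_h = NaN or
    the string 'control'."""
    df = curves.copy()
    is_ctrl = df["treatment_time_h"].apply(
        lambda v: (isinstance(v, str) and v.lower() == "control")
        or (isinstance(v, float) and np.isnan(v)))
    if not is_ctrl.any():
        raise ValueError("cytotoxicity table lacks a control condition")
    ctrl = df[is_ctrl].sort_values("measurement_time_h")
    c0 = float(ctrl["cytotox_signal"].iloc[0])
    out = [ctrl.assign(condition="control")]
    for tt, grp in df[~is_ctrl].groupby("treatment_time_h"):
        g = grp.sort_values("measurement_time_h").copy()
        g["cytotox_signal"] += c0 - float(g["cytotox_signal"].iloc[0])
        g["condition"] = f"T{float(tt):g}"
        out.append(g)
    return pd.concat(out, ignore_index=True)


def fit_pkpd(curves: pd.DataFrame, protein_trajs: Trajectory,
             base_params: PKPDParameters, config: FitConfig,
             dose: float = 1.0, exposure: float = 48.0) -> FitResult:
    """Fit the free PK-PD parameters so the dead-cell variable D matches
    the rescaled cytotoxicity curves (squared error, CMA-ES).

    ``curves`` must contain a control condition; each treated condition's
    measurement times define where D is evaluated.
    """
    df = rescale_cytotoxicity(curves)
    conds = []
    treated_tts = [float(c[1:]) for c in df["condition"].unique()
                   if c != "control"]
    if not treated_tts:
        raise ValueError("no treated condition in cytotoxicity table")
    for cond, grp in df.groupby("condition"):
        g = grp.sort_values("measurement_time_h")
        # measurement times are hours since the condition's start
        times = g["measurement_time_h"].to_numpy(float)
        if times.size < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 timepoints")
        tt = min(treated_tts) if cond == "control" else float(cond[1:])
        conds.append((cond, tt, times, g["cytotox_signal"].to_numpy(float)))
    n_t = {len(c[2]) for c in conds}
    if len(n_t) > 1:
        raise ValueError("conditions have inconsistent measurement grids "
                         "(missing timepoints)")

    free = list(config.free_names)
    x0 = base_params.subset_array(free)
    if np.any(x0 <= 0):
        raise ValueError("free parameters must be strictly positive")
    lo = np.array([np.log10(config.bounds.get(n, (config.bound_lo_factor * v,))[0])
                   for n, v in zip(free, x0)])
    hi = np.array([np.log10(config.bounds.get(
        n, (None, config.bound_hi_factor * v))[-1]) for n, v in zip(free, x0)])
    z0 = np.log10(x0)

    def unpack(z):
        return base_params.updated_from(free, 10.0 ** np.asarray(z))

    def simulate_all(p):
        out = {}
        for cond, tt, times, _ in conds:
            proto = TreatmentProtocol(tt, 0.0 if cond == "control" else dose,
                                      exposure, max(times.max(), 1.0))
            traj = simulate_treatment(protein_trajs, p, proto)
            out[cond] = traj.interp("D", tt + times)
        return out

    def objective(z):
        p = unpack(z)
        try:
            sims = simulate_all(p)
        except (IntegrationError, ValueError):
            return FAILURE_COST
        c = 0.0
        for cond, tt, times, ydata in conds:
            mx = ydata.max()
            if mx <= 0:
                mx = 1.0
            c += float(np.sum(((ydata - sims[cond]) / mx) ** 2))
        return c

    if config.max_evals == 0:
        return FitResult(base_params, objective(z0), None, None, [],
                         config.seed, 0, True, "initial guess")
    best, n_evals, traces = _run_cma(objective, z0, (lo, hi), config)
    p = unpack(best.x)
    return FitResult(p, float(best.fun), None, None, [], config.seed,
                     n_evals, best.fun < FAILURE_COST, "", trace=traces)
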