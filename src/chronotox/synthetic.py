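"""Synthetic circadian expression and cytotoxicity generators.

The generators emulate the statistical structure of synchronized CRC
cell-line time courses: ~24 h cosine oscillations on a positive mesor,
superimposed linear drift (pronounced for PPARA and CES2 in RNA-seq
series), multiplicative log-normal noise, paralog families with
compensation structure, and near-zero UGT1A1 for HCT116-like lines.
Knock-out datasets implement the observed compensation rules: a PER2 or
NR1D1 knock-out is compensated by the strongest remaining paralog so the
family sum is preserved, whereas an ARNTL knock-out co-reduces ARNTL2.

Cytotoxicity curves are forward-simulated from a known PK-PD truth so
that fitting can be validated against an attached ground-truth profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .pkpd import (PKPDParameters, TreatmentProtocol, simulate_treatment,
                   toxicity_profile)
from .simulate import Trajectory

__all__ = [
    "GeneSpec",
    "SyntheticSpec",
    "default_synthetic_spec",
    "generate_clock_expression",
    "generate_knockout",
    "generate_cytotoxicity",
]

KO_RESIDUAL_FRAC = 1e-3  # KO expression floor, as a fraction of the gene mesor


@dataclass(frozen=True)
class GeneSpec:
    """Cosinor description of one gene: x(t) = mesor (1 + amp cos(...)) + drift t."""

    mesor: float
    rel_amp: float = 0.3
    phase: float = 0.0        # peak time, h
    period: float = 24.0
    drift: float = 0.0        # CPM per hour

    def __post_init__(self):
        if self.mesor < 0:
            raise ValueError("mesor must be non-negative")
        if not 0.0 <= self.rel_amp < 1.0:
            raise ValueError("relative amplitude must be in [0, 1)")


@dataclass
class SyntheticSpec:
    """Study conditions for the expression generator.

    Defaults mimic the study design: sampling every 3 h over 45 h,
    multiplicative log-normal noise of sd 0.1, and a seeded RNG.
    """

    genes: dict                      # name -> GeneSpec
    t_start: float = 0.0
    t_step: float = 3.0
    duration: float = 45.0
    noise_sd: float = 0.1
    seed: int = 0
    families: dict = field(default_factory=dict)  # family -> rule dict
    cell_line: str = "synthetic"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.duration < 24.0:
            raise ValueError("sampling must cover at least 24 h")
        if self.t_step <= 0:
            raise ValueError("t_step must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_start + self.duration + 1e-9,
                         self.t_step)


def default_synthetic_spec(seed: int = 0, hct116_like: bool = False,
                           arntl_phase_shift: float = 0.0,
                           noise_sd: float = 0.1) -> SyntheticSpec:
    """Paralog-resolved wild-type spec with study-like structure.

    ``arntl_phase_shift`` shifts every gene's peak phase (a cell line
    whose clock runs earlier/later); ``hct116_like`` sets UGT1A1 to
    near-zero expression.
    """
    s = arntl_phase_shift
    genes = {
        "ARNTL":  GeneSpec(30, 0.35, 7.0 + s),
        "ARNTL2": GeneSpec(5, 0.30, 7.5 + s),
        "CLOCK":  GeneSpec(20, 0.20, 20.0 + s),
        "PER1":   GeneSpec(15, 0.40, 0.5 + s),
        "PER2":   GeneSpec(25, 0.40, 1.0 + s),
        "PER3":   GeneSpec(5, 0.40, 1.5 + s),
        "CRY1":   GeneSpec(20, 0.35, 0.5 + s),
        "CRY2":   GeneSpec(15, 0.35, 2.0 + s),
        "NR1D1":  GeneSpec(10, 0.60, 23.0 + s),
        "NR1D2":  GeneSpec(8, 0.50, 1.0 + s),
        "ROR":    GeneSpec(12, 0.40, 0.2 + s, drift=0.05),
        "PAR":    GeneSpec(14, 0.50, 0.2 + s),
        "NFIL3":  GeneSpec(6, 0.30, 8.0 + s),
        "PPARA":  GeneSpec(10, 0.15, 1.0 + s, drift=0.08),
        "CES2":   GeneSpec(8, 0.25, 9.0 + s, drift=0.06),
        "ABCB":   GeneSpec(10, 0.25, 6.0 + s),
        "ABCC":   GeneSpec(12, 0.20, 6.0 + s),
        "UGT1A1": GeneSpec(0.01 if hct116_like else 5, 0.30, 9.0 + s),
    }
    families = {
        "PER": {"members": ["PER1", "PER2", "PER3"], "rule": "compensate"},
        "NR1D": {"members": ["NR1D1", "NR1D2"], "rule": "compensate"},
        "CRY": {"members": ["CRY1", "CRY2"], "rule": "compensate"},
        "ARNTL": {"members": ["ARNTL", "ARNTL2"], "rule": "co_reduce",
                  "factor": 0.5},
    }
    return SyntheticSpec(genes=genes, seed=seed, families=families,
                         noise_sd=noise_sd,
                         cell_line="HCT116-like" if hct116_like else "synthetic")


def _clean_signal(g: GeneSpec, t: np.ndarray) -> np.ndarray:
    osc = g.mesor * (1.0 + g.rel_amp * np.cos(2 * np.pi * (t - g.phase)
                                              / g.period))
    return np.maximum(osc + g.drift * t, 0.0)


def _apply_noise(values: np.ndarray, sd: float, rng) -> np.ndarray:
    if sd == 0:
        return values
    return values * rng.lognormal(mean=0.0, sigma=sd, size=values.shape)


def generate_clock_expression(spec: SyntheticSpec) -> ExpressionDataset:
    """Wild-type expression dataset; bit-reproducible under a fixed seed."""
    t = spec.times
    names = list(spec.genes)
    clean = np.array([_clean_signal(spec.genes[g], t) for g in names])
    rng = np.random.default_rng(spec.seed)
    values = _apply_noise(clean, spec.noise_sd, rng)
    return ExpressionDataset(names, t, values, cell_line=spec.cell_line,
                             meta={"seed": spec.seed,
                                   "noise_sd": spec.noise_sd})


def generate_knockout(spec: SyntheticSpec, ko_gene: str) -> ExpressionDataset:
    """Knock-out dataset per the family's compensation rule.

    ``compensate``: the knocked-out gene drops to a residual
    (1e-3 of its mesor) and the strongest remaining paralog absorbs the
    difference, so the family's per-timepoint sum is preserved.
    ``co_reduce``: the other family members are scaled down by the
    family's factor (no compensation, as for ARNTL/ARNTL2).
    """
    if ko_gene not in spec.genes:
        raise ValueError(f"unknown gene: {ko_gene!r}")
    family = None
    for fam, rule in spec.families.items():
        if ko_gene in rule["members"]:
            family = (fam, rule)
            break
    if family is None:
        raise ValueError(f"no compensation rule declared for {ko_gene!r}")
    fam, rule = family

    wt = generate_clock_expression(spec)
    values = wt.values.copy()
    names = wt.genes
    i_ko = names.index(ko_gene)
    residual = KO_RESIDUAL_FRAC * spec.genes[ko_gene].mesor
    ko_series = np.full(wt.times.size, residual)
    removed = values[i_ko] - ko_series
    values[i_ko] = ko_series

    others = [g for g in rule["members"] if g != ko_gene and g in names]
    if rule["rule"] == "compensate":
        if others:
            comp = max(others, key=lambda g: spec.genes[g].mesor)
            values[names.index(comp)] += removed
    elif rule["rule"] == "co_reduce":
        f = float(rule.get("factor", 0.5))
        for g in others:
            values[names.index(g)] *= f
    else:
        raise ValueError(f"unknown compensation rule {rule['rule']!r}")
    return ExpressionDataset(names, wt.times.copy(), values,
                             cell_line=f"{spec.cell_line}-{ko_gene}KO",
                             meta={**wt.meta, "ko": ko_gene,
                                   "family": fam, "rule": rule["rule"]})


def generate_cytotoxicity(protein_trajs: Trajectory,
                          pkpd_truth: PKPDParameters,
                          treatment_times,
                          dose: float = 1.0,
                          exposure: float = 48.0,
                          horizon: float = 72.0,
                          measurement_step: float = 4.0,
                          noise_sd: float = 0.0,
                          seed: int = 0):
    """Forward-simulated cytotoxicity curves with attached ground truth.

    Returns ``(curves, truth_profile)``: a long-format table of
    (treatment_time_h, measurement_time_h, cytotox_signal) including a
    control condition, and the noiseless normalized-AUC profile of the
    generating parameters.
    """
    tt = np.asarray(treatment_times, float)
    if tt.size == 0:
        raise ValueError("treatment-time grid must not be empty")
    rng = np.random.default_rng(seed)
    rows = []

    t_ctrl0 = float(tt.min())
    ctrl = simulate_treatment(protein_trajs, pkpd_truth,
                              TreatmentProtocol(t_ctrl0, 0.0, exposure, horizon))
    mt = np.arange(0.0, horizon + 1e-9, measurement_step)
    d = ctrl.interp("D", t_ctrl0 + mt)
    d = _apply_noise(d, noise_sd, rng)
    for m, v in zip(mt, d):
        rows.append({"treatment_time_h": "control",
                     "measurement_time_h": float(m), "cytotox_signal": float(v)})

    for t_tr in tt:
        traj = simulate_treatment(protein_trajs, pkpd_truth,
                                  TreatmentProtocol(t_tr, dose, exposure,
                                                    horizon))
        d = traj.interp("D", t_tr + mt)
        d = _apply_noise(d, noise_sd, rng)
        for m, v in zip(mt, d):
            rows.append({"treatment_time_h": float(t_tr),
                         "measurement_time_h": float(m),
                         "cytotox_signal": float(v)})

    truth = None
    if tt.size >= 2 and (tt.max() - tt.min()) >= 24.0 - 3.0:
        truth = toxicity_profile(protein_trajs, pkpd_truth, tt, dose=dose,
                                 exposure=exposure, horizon=horizon)
    return pd.DataFrame(rows), truth
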