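"""Irinotecan pharmacokinetics/-dynamics driven by clock-network output.

The transcription-translation network hands four mRNA time courses to
this layer — CES2 (activates the prodrug CPT-11 to SN-38), UGT1A1
(deactivates SN-38), and the export pumps ABCB and ABCC. Each is
translated with a circadian protein-degradation rate, rescaled to a
reference maximal protein concentration, and drives a small intracellular
PK model: CPT-11 uptake and activation, SN-38 deactivation and efflux,
and formation of SN-38/TOP1/DNA cleavage complexes (TOP1 protein is
constant; SN-38 is shared between nucleus and cytoplasm). Cleavage
complexes raise the death rate of the living-cell pool L; dead cells
accumulate in D. The circadian toxicity readout is the area under D,
normalized to an untreated control, as a function of treatment time.

Treatment-specific refinements: UGT is multiplied by a sigmoid
``1 + M_UGT / (1 + exp(k_UGT t + 4))`` of time after treatment, and the
death rate gains a transient alpha-function surge
``A (s/tau) exp(1 - s/tau)`` (unit-peak scaling: maximum A at s = tau)
on top of a treatment-independent circadian modulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ParameterSet
from .simulate import IntegrationError, Trajectory, _quad_refine

__all__ = [
    "PKPDParameters",
    "CellPopulationState",
    "TreatmentProtocol",
    "ToxicityProfile",
    "default_pkpd_parameters",
    "translate_proteins",
    "rescale_protein",
    "ugt_treatment_factor",
    "death_rate",
    "simulate_treatment",
    "toxicity_profile",
    "phase_adapt",
]

DRUG_GENES = ("CES2", "UGT1A1", "ABCB", "ABCC")
CIRC_PERIOD = 24.0
PKPD_RTOL = 1e-4
PKPD_ATOL = 1e-7


class PKPDParameters(ParameterSet):
    """Transport/activation/death parameters of the PK-PD layer.

    All entries are non-negative except ``k_UGT`` (the sigmoid slope,
    negative for a post-treatment *increase* in UGT).
    """

    SIGNED = frozenset({"k_UGT"})

    def __init__(self, names, values):
        names = list(names)
        vals = np.asarray(values, dtype=float)
        shift = np.array([n in self.SIGNED for n in names])
        # temporarily zero the signed entries for the base-class check
        ParameterSet.__init__(self, names, np.where(shift, 0.0, vals))
        self._values = vals.copy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("parameter values must be finite")
        if "ugt_scale" in self:
            s = self["ugt_scale"]
            if not 0.0 < s <= 1.0:
                raise ValueError("ugt_scale must be in (0, 1]")


def default_pkpd_parameters() -> PKPDParameters:
    """Package defaults for the PK-PD layer (rates per hour).

    Transport/activation magnitudes are order-one against the unit
    rescaled protein maxima; death rates are small against 1/h so the
    living pool decays over days, not hours.
    """
    d = {
        # CPT-11 / SN-38 kinetics
        "k_upt": 0.5,       # CPT-11 uptake from the medium
        "k_act": 0.4,       # CES2-mediated activation CPT-11 -> SN-38
        "k_eff_B": 0.3,     # ABCB-mediated CPT-11 efflux
        "k_deact": 1.2,     # UGT1A1-mediated SN-38 deactivation
        "k_eff_C": 0.3,     # ABCC-mediated SN-38 efflux
        "TOP1": 1.0,        # constant TOP1 protein concentration
        "k_dna": 0.6,       # SN-38/TOP1/DNA cleavage-complex formation
        "k_rep": 0.25,      # complex resolution
        # death dynamics
        "k_kill": 0.12,     # death-rate gain per cleavage complex
        "d0": 0.010,        # baseline death rate
        "A_circ": 0.004,    # circadian death-modulation amplitude
        "phi_circ": 6.0,    # circadian death-modulation phase (h)
        "A_alpha": 0.03,    # alpha-function peak height
        "tau_alpha": 8.0,   # alpha-function time constant (h)
        "g_L": 0.005,       # slow proliferation of the living pool
        # UGT treatment sigmoid (Eq. form 1 + M/(1+exp(k t + 4)))
        "M_UGT": 1.0,
        "k_UGT": -0.25,
        # translation with circadian protein degradation, per drug gene
        "ktlp_CES2": 0.5, "dpp_CES2": 0.15, "ampp_CES2": 0.3, "php_CES2": 4.0,
        "ktlp_UGT1A1": 0.5, "dpp_UGT1A1": 0.15, "ampp_UGT1A1": 0.3, "php_UGT1A1": 8.0,
        "ktlp_ABCB": 0.5, "dpp_ABCB": 0.15, "ampp_ABCB": 0.3, "php_ABCB": 12.0,
        "ktlp_ABCC": 0.5, "dpp_ABCC": 0.15, "ampp_ABCC": 0.3, "php_ABCC": 12.0,
        # rescaling targets (reference maximal protein concentrations)
        "max_CES2": 1.0, "max_UGT1A1": 1.0, "max_ABCB": 1.0, "max_ABCC": 1.0,
        "ugt_scale": 1.0,   # 0.1 for HCT116-like (UGT1A1-low) lines
    }
    return PKPDParameters(list(d), list(d.values()))


@dataclass
class CellPopulationState:
    """Living (L) and dead (D) cell counts, assay-scale arbitrary units."""

    living: float
    dead: float

    def __post_init__(self):
        if self.living < 0 or self.dead < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass(frozen=True)
class TreatmentProtocol:
    """One treatment condition: when, how much, how long, observed how long.

    ``t_treat`` is in circadian/Zeitgeber hours; the drug is present in
    the medium at concentration ``dose`` for ``exposure`` hours; L and D
    are followed for ``horizon`` hours after treatment start.
    """

    t_treat: float
    dose: float
    exposure: float = 48.0
    horizon: float = 72.0

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")


# ---------------------------------------------------------------------------
# protein layer
# ---------------------------------------------------------------------------

def translate_proteins(mrna_traj: Trajectory,
                       params: PKPDParameters,
                       clock_phase: float = 0.0,
                       genes=DRUG_GENES) -> Trajectory:
    """Translate drug-metabolism mRNAs with circadian protein degradation.

    For each gene, dP/dt = ktl m(t) - d(t) P with
    d(t) = dpp (1 + amp cos(2 pi (t - phase - clock_phase)/24)); the mRNA
    course m(t) is interpolated from ``mrna_traj``. The initial protein
    level is the quasi-steady state at the window start.
    """
    t = mrna_traj.t
    out = np.empty((len(genes), t.size))
    for gi, gene in enumerate(genes):
        m = mrna_traj.get(gene)
        ktl = params[f"ktlp_{gene}"]
        d0 = params[f"dpp_{gene}"]
        amp = params[f"ampp_{gene}"]
        ph = params[f"php_{gene}"] + clock_phase
        if d0 <= 0:
            raise ValueError(f"degradation rate for {gene} must be positive")
        if amp >= 1.0:
            raise ValueError(f"circadian degradation amplitude for {gene} "
                             "must be < 1 to keep the rate positive")

        def deg(tt):
            return d0 * (1.0 + amp * np.cos(2 * np.pi * (tt - ph) / CIRC_PERIOD))

        def rhs(tt, y):
            return [ktl * np.interp(tt, t, m) - deg(tt) * y[0]]

        p0 = ktl * m[0] / d0
        sol = solve_ivp(rhs, (t[0], t[-1]), [p0], t_eval=t, method="LSODA",
                        rtol=1e-6, atol=1e-10)
        if not sol.success:
            raise IntegrationError("protein translation failed",
                                   float(sol.t[-1]) if sol.t.size else t[0])
        out[gi] = np.maximum(sol.y[0], 0.0)
    return Trajectory(t.copy(), out, [f"{g}_p" for g in genes],
                      {"clock_phase": clock_phase})


def rescale_protein(values, target_max: float, scale_factor: float = 1.0,
                    allow_zero: bool = False) -> np.ndarray:
    """Rescale a protein time course so its maximum is
    ``target_max * scale_factor``, preserving shape.

    An all-zero course with a nonzero target is an error unless
    ``allow_zero`` (UGT in UGT1A1-null lines passes through as zero).
    """
    values = np.asarray(values, float)
    mx = float(values.max()) if values.size else 0.0
    if mx <= 0:
        if allow_zero:
            return np.zeros_like(values)
        raise ValueError("cannot rescale an all-zero trajectory")
    return values * (target_max * scale_factor / mx)


def rescaled_drug_proteins(protein_traj: Trajectory,
                           params: PKPDParameters) -> Trajectory:
    """Apply the reference-maximum rescaling (and the UGT cell-line scale
    factor) to all four drug proteins."""
    out = []
    for gene in DRUG_GENES:
        v = protein_traj.get(f"{gene}_p")
        if gene == "UGT1A1":
            v = rescale_protein(v, params["max_UGT1A1"], params["ugt_scale"],
                                allow_zero=True)
        else:
            v = rescale_protein(v, params[f"max_{gene}"])
        out.append(v)
    return Trajectory(protein_traj.t.copy(), np.array(out),
                      [f"{g}_p" for g in DRUG_GENES], dict(protein_traj.meta))


def ugt_treatment_factor(t_after_treatment, M_UGT: float, k_UGT: float):
    """Sigmoidal post-treatment UGT multiplier
    ``1 + M_UGT / (1 + exp(k_UGT t + 4))``; >= 1 for M_UGT >= 0 and
    monotone in t with the sign of ``-k_UGT``."""
    t = np.asarray(t_after_treatment, float)
    out = 1.0 + M_UGT / (1.0 + np.exp(np.clip(k_UGT * t + 4.0, -500, 500)))
    return float(out) if out.ndim == 0 else out


def _alpha_fn(s, A: float, tau: float):
    """Alpha function A (s/tau) exp(1 - s/tau): 0 at s<=0, peak A at s=tau."""
    if tau <= 0:
        raise ValueError("alpha-function time constant must be positive")
    s = np.asarray(s, float)
    out = np.where(s > 0, A * (s / tau) * np.exp(1.0 - s / tau), 0.0)
    return float(out) if out.ndim == 0 else out


def death_rate(t, params: PKPDParameters,
               protocol: TreatmentProtocol | None = None):
    """Drug-independent death rate: baseline + circadian modulation, plus
    the treatment-triggered alpha surge (only when a treated protocol with
    positive dose is given and t >= treatment start). Clipped at zero.
    The cleavage-complex contribution is added by the full simulation."""
    t = np.asarray(t, float)
    rate = (params["d0"]
            + params["A_circ"] * np.cos(2 * np.pi * (t - params["phi_circ"])
                                        / CIRC_PERIOD))
    if protocol is not None and protocol.dose > 0:
        rate = rate + _alpha_fn(t - protocol.t_treat, params["A_alpha"],
                                params["tau_alpha"])
    out = np.maximum(rate, 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# population dynamics
# ---------------------------------------------------------------------------

def simulate_treatment(protein_trajs: Trajectory,
                       params: PKPDParameters,
                       protocol: TreatmentProtocol,
                       init_state: CellPopulationState | None = None,
                       t_step: float = 0.1) -> Trajectory:
    """Integrate drug and cell-population dynamics for one treatment.

    ``protein_trajs`` must contain the rescaled CES2_p, UGT1A1_p, ABCB_p
    and ABCC_p courses covering [t_treat, t_treat + horizon]. Returns a
    trajectory of (CPT11, SN38, DNAC, L, D) on the protocol window;
    deterministic for fixed inputs. With dose 0, D reflects baseline
    death only.
    """
    t0 = protocol.t_treat
    t1 = t0 + protocol.horizon
    if protein_trajs.t[0] > t0 + 1e-9 or protein_trajs.t[-1] < t1 - 1e-9:
        raise ValueError("protein trajectories do not cover the protocol window")
    init = init_state or CellPopulationState(living=1.0, dead=0.0)

    tp = protein_trajs.t
    ces = protein_trajs.get("CES2_p")
    ugt = protein_trajs.get("UGT1A1_p")
    abcb = protein_trajs.get("ABCB_p")
    abcc = protein_trajs.get("ABCC_p")
    treated = protocol.dose > 0

    k_upt, k_act = params["k_upt"], params["k_act"]
    k_eff_B, k_deact, k_eff_C = params["k_eff_B"], params["k_deact"], params["k_eff_C"]
    top1, k_dna, k_rep = params["TOP1"], params["k_dna"], params["k_rep"]
    k_kill, g_l = params["k_kill"], params["g_L"]
    m_ugt, k_ugt = params["M_UGT"], params["k_UGT"]

    def rhs(t, y):
        cpt, sn, c, living, dead = np.maximum(y, 0.0)
        ext = protocol.dose if (treated and t < t0 + protocol.exposure) else 0.0
        ces_t = np.interp(t, tp, ces)
        ugt_t = np.interp(t, tp, ugt)
        if treated and t >= t0:
            ugt_t = ugt_t * ugt_treatment_factor(t - t0, m_ugt, k_ugt)
        abcb_t = np.interp(t, tp, abcb)
        abcc_t = np.interp(t, tp, abcc)
        dcpt = k_upt * ext - (k_act * ces_t + k_eff_B * abcb_t) * cpt
        dsn = k_act * ces_t * cpt - (k_deact * ugt_t + k_eff_C * abcc_t
                                     + k_dna * top1) * sn
        dc = k_dna * top1 * sn - k_rep * c
        delta = death_rate(t, params, protocol) + k_kill * c
        dliving = g_l * living - delta * living
        ddead = delta * living
        return [dcpt, dsn, dc, dliving, ddead]

    n_pts = int(round(protocol.horizon / t_step)) + 1
    t_eval = t0 + t_step * np.arange(n_pts)
    t_eval = t_eval[t_eval <= t1 + 1e-12]
    # the exposure end is a forcing discontinuity: integrate piecewise
    cuts = [t0 + protocol.exposure] if treated and t0 + protocol.exposure < t1 else []
    edges = [t0, *cuts, t1]
    y = np.array([0.0, 0.0, 0.0, init.living, init.dead])
    ts, ys = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (t_eval >= a - 1e-12) & (t_eval <= b + 1e-12)
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=PKPD_RTOL,
                        atol=PKPD_ATOL, t_eval=t_eval[mask])
        if not sol.success:
            raise IntegrationError(f"PK-PD integration failed: {sol.message}",
                                   float(sol.t[-1]) if sol.t.size else a)
        ts.append(sol.t)
        ys.append(sol.y)
        if sol.t.size and abs(sol.t[-1] - b) < 1e-9:
            y = sol.y[:, -1]
        else:
            full = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=PKPD_RTOL,
                             atol=PKPD_ATOL, t_eval=[b])
            y = full.y[:, -1]
    t = np.concatenate(ts)
    vals = np.concatenate(ys, axis=1)
    t, keep = np.unique(np.round(t, 9), return_index=True)
    vals = np.maximum(vals[:, keep], 0.0)
    return Trajectory(t, vals, ["CPT11", "SN38", "DNAC", "L", "D"],
                      {"protocol": protocol})


# ---------------------------------------------------------------------------
# toxicity profiles
# ---------------------------------------------------------------------------

@dataclass
class ToxicityProfile:
    """Normalized dead-cell AUC per treatment time over one circadian cycle."""

    treatment_times: np.ndarray
    auc: np.ndarray                  # AUC(D treated) / AUC(D control)
    peak_time: float
    peak_value: float
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"treatment_time_h": self.treatment_times,
                             "normalized_AUC": self.auc})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {"peak_time_h": self.peak_time, "peak_value": self.peak_value}


def _auc(traj: Trajectory, species: str = "D", grid_step: float = 0.1) -> float:
    """Trapezoidal AUC on a uniform resampled grid."""
    t = traj.t
    tt = np.arange(t[0], t[-1] + grid_step / 2, grid_step)
    return float(np.trapezoid(traj.interp(species, tt), tt))


def toxicity_profile(protein_trajs: Trajectory,
                     params: PKPDParameters,
                     treatment_times,
                     dose: float = 1.0,
                     exposure: float = 48.0,
                     horizon: float = 72.0) -> ToxicityProfile:
    """Circadian toxicity profile: normalized AUC of D per treatment time.

    For each treatment time the dead-cell course is simulated for the
    treated condition and an untreated control (dose 0), AUC is taken by
    the trapezoidal rule on a uniform 0.1 h grid, and the ratio is
    reported. The peak time is refined by quadratic interpolation around
    the discrete maximum (ties broken by earliest time).
    """
    tt = np.asarray(treatment_times, float)
    if tt.size < 2 or (tt.max() - tt.min()) < CIRC_PERIOD - 3.0 - 1e-9:
        raise ValueError("treatment times must span a circadian cycle")
    aucs = np.empty(tt.size)
    for i, t_tr in enumerate(tt):
        treated = simulate_treatment(
            protein_trajs, params,
            TreatmentProtocol(t_tr, dose, exposure, horizon))
        control = simulate_treatment(
            protein_trajs, params,
            TreatmentProtocol(t_tr, 0.0, exposure, horizon))
        denom = _auc(control)
        if denom <= 0:
            raise ValueError("control AUC is zero; cannot normalize")
        aucs[i] = _auc(treated) / denom
    i_max = int(np.argmax(aucs))  # argmax returns the earliest tie
    pk_t, pk_v = _quad_refine(tt, aucs, i_max)
    return ToxicityProfile(tt, aucs, pk_t, pk_v,
                           {"dose": dose, "exposure": exposure,
                            "horizon": horizon})


def phase_adapt(params: PKPDParameters, delta_phase: float) -> PKPDParameters:
    """Shift all circadian phases (protein degradation of the four drug
    proteins and the death-rate modulation) by ``delta_phase`` modulo 24 h.

    Used to transfer a fitted PK-PD layer between cell lines whose clock
    phase (read from ARNTL) differs by ``delta_phase``.
    """
    if not np.isfinite(delta_phase):
        raise ValueError("delta_phase must be finite")
    upd = {}
    for gene in DRUG_GENES:
        upd[f"php_{gene}"] = (params[f"php_{gene}"] + delta_phase) % CIRC_PERIOD
    upd["phi_circ"] = (params["phi_circ"] + delta_phase) % CIRC_PERIOD
    return params.replace(**upd)
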