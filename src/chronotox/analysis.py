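"""Entrainment, Zeitgeber pulses, phase-response scans and pulse-shifted
toxicity.

Sign convention (stated in all outputs): a **positive** phase shift is a
phase *advance* — the pulsed oscillation reaches its reference maximum
earlier than the unpulsed one. Shifts are reported modulo the cycle in
(-12, 12] h. Pulse responses are measured on the entrained system as the
time difference of the reference gene's (default ARNTL) second maximum
after the pulse, pulsed versus unpulsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ODESystem
from .pkpd import (PKPDParameters, ToxicityProfile, rescaled_drug_proteins,
                   toxicity_profile, translate_proteins)
from .simulate import (DampedOscillationError, Trajectory,
                       default_initial_state, find_maxima, limit_cycle,
                       relative_amplitude, simulate)
from .zeitgeber import PulseSpec, ZeitgeberSchedule

__all__ = [
    "PhaseShiftMeasurement",
    "PRCTable",
    "entrain",
    "minimal_entrainment_strength",
    "pulse_response",
    "prc_scan",
    "toxicity_under_pulse",
]

PERIOD_TOL_H = 0.1      # |period - 24| tolerance for the entrainment verdict
AMP_TOL = 0.05          # relative-amplitude tolerance ("at least similarly strong")
AMP_WINDOW_H = 64.0     # amplitude comparison window
DRIFT_TOL_H = 0.02      # max peak-phase drift per cycle for true locking
DEFAULT_TRANSIENT_H = 240.0


@dataclass
class PhaseShiftMeasurement:
    """Phase shift of the reference gene caused by one pulse.

    ``shift`` > 0 means phase advance (pulsed peak earlier than the
    unpulsed reference); reported in (-12, 12] h.
    """

    pulse: PulseSpec
    reference_gene: str
    shift: float
    t_max_reference: float      # unpulsed second post-pulse maximum (abs. h)
    t_max_pulsed: float
    relaxation: dict = field(default_factory=dict)
    sign_convention: str = "positive = advance (pulsed peak earlier)"


@dataclass
class PRCTable:
    """Grid of phase shifts over (T_pulse, strength, duration, gene)."""

    table: pd.DataFrame          # columns: zt, strength, duration, gene, shift
    meta: dict = field(default_factory=dict)

    def argmax_shift(self, gene: str | None = None) -> dict:
        df = self.table.dropna(subset=["shift"])
        if gene is not None:
            df = df[df["gene"] == gene]
        if df.empty:
            raise ValueError("no successful PRC entries")
        row = df.loc[df["shift"].abs().idxmax()]
        return {"zt": float(row["zt"]), "strength": float(row["strength"]),
                "duration": float(row["duration"]), "gene": row["gene"],
                "shift": float(row["shift"])}

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _wrap_shift(shift: float, period: float = 24.0) -> float:
    """Wrap into (-period/2, period/2]."""
    s = (shift + period / 2) % period - period / 2
    return period / 2 if s == -period / 2 else s


# ---------------------------------------------------------------------------
# entrainment
# ---------------------------------------------------------------------------

ENTRAIN_TRANSIENT_H = 480.0  # locking converges slowly near threshold


def entrain(system: ODESystem, params, schedule: ZeitgeberSchedule,
            reference: str = "ARNTL",
            transient: float = ENTRAIN_TRANSIENT_H,
            free_running=None):
    """Entrainment verdict: 24 h period within tolerance, a stationary
    peak phase (mean drift below 0.02 h per cycle — a slowly drifting
    quasiperiodic state can show a near-24 h mean period without being
    locked), AND a relative amplitude over a 64 h window at least as
    large as free-running (within 5%). Returns
    ``(entrained Trajectory, verdict bool)``.

    ``free_running`` may pass a precomputed ``(trajectory, period)`` pair
    to avoid re-simulating the unforced system.
    """
    if free_running is None:
        free_running = limit_cycle(system, params, schedule=None,
                                   reference=reference)
    fr_traj, _ = free_running
    fr_amp = relative_amplitude(
        fr_traj.window(fr_traj.t[0], fr_traj.t[0] + AMP_WINDOW_H).get(reference))

    traj, period = limit_cycle(system, params, schedule=schedule,
                               reference=reference, transient=transient,
                               window=5 * schedule.period)
    amp = relative_amplitude(
        traj.window(traj.t[0], traj.t[0] + AMP_WINDOW_H).get(reference))
    peaks = traj.meta.get("peak_times", np.array([]))
    drift = np.inf
    if peaks.size >= 3:
        drift = abs(np.polyfit(np.arange(peaks.size),
                               peaks - np.arange(peaks.size) * schedule.period,
                               1)[0])
    verdict = (abs(period - schedule.period) <= PERIOD_TOL_H
               and drift <= DRIFT_TOL_H
               and amp >= fr_amp * (1.0 - AMP_TOL))
    traj.meta.update({"entrained": verdict, "period": period,
                      "rel_amp": amp, "free_running_rel_amp": fr_amp,
                      "phase_drift_h_per_cycle": drift})
    return traj, verdict


def minimal_entrainment_strength(system: ODESystem, params,
                                 schedule: ZeitgeberSchedule,
                                 f_grid, **kwargs):
    """Smallest forcing strength on an ascending grid that entrains the
    oscillator; None if no grid value does."""
    f_grid = list(f_grid)
    if not f_grid:
        raise ValueError("f_grid must not be empty")
    if any(b < a for a, b in zip(f_grid, f_grid[1:])):
        raise ValueError("f_grid must be ascending")
    free_running = limit_cycle(system, params, schedule=None)
    for f in f_grid:
        sch = ZeitgeberSchedule(period=schedule.period,
                                light_fraction=schedule.light_fraction,
                                f_light=f, ld_target=schedule.ld_target,
                                pulse_mode=schedule.pulse_mode)
        try:
            _, ok = entrain(system, params, sch, free_running=free_running,
                            **kwargs)
        except DampedOscillationError:
            ok = False
        if ok:
            return float(f)
    return None


# ---------------------------------------------------------------------------
# pulse responses
# ---------------------------------------------------------------------------

def _entrained_state(system: ODESystem, params, schedule: ZeitgeberSchedule,
                     transient: float):
    traj = simulate(system, params, default_initial_state(system),
                    (0.0, transient), schedule=schedule, t_step=0.5)
    return traj.values[:, -1]


def _second_max_after(traj: Trajectory, gene: str, t_after: float) -> float:
    peaks, _ = find_maxima(traj.t, traj.get(gene))
    peaks = peaks[peaks > t_after]
    if peaks.size < 2:
        raise DampedOscillationError(
            "fewer than two post-pulse maxima in the simulation window")
    return float(peaks[1])


def pulse_response(system: ODESystem, params,
                   schedule: ZeitgeberSchedule, pulse: PulseSpec,
                   reference_gene: str = "ARNTL",
                   transient: float = DEFAULT_TRANSIENT_H,
                   window: float = 168.0,
                   t_step: float = 0.01,
                   _shared_state=None,
                   _shared_reference=None) -> PhaseShiftMeasurement:
    """Phase shift of one pulse on the entrained system.

    Shift = t(second post-pulse maximum, no pulse) - t(same maximum,
    pulsed); positive = advance. The private ``_shared_*`` hooks let
    :func:`prc_scan` reuse the transient state and reference run.
    """
    if pulse.t_start < transient:
        raise ValueError("pulse must start after the entrainment transient")
    y0 = (_shared_state if _shared_state is not None
          else _entrained_state(system, params, schedule, transient))
    t_end = pulse.t_end + window
    if _shared_reference is not None:
        ref_traj = _shared_reference
        if ref_traj.t[-1] < t_end - 1e-9:
            raise ValueError("shared reference does not cover the window")
    else:
        ref_traj = simulate(system, params, y0, (transient, t_end),
                            schedule=schedule, t_step=t_step)
    pulsed = simulate(system, params, y0, (transient, t_end),
                      schedule=schedule.with_pulse(pulse), t_step=t_step)
    t_ref = _second_max_after(ref_traj, reference_gene, pulse.t_end)
    t_pul = _second_max_after(pulsed, reference_gene, pulse.t_end)
    shift = _wrap_shift(t_ref - t_pul, schedule.period)

    # relaxation: residual phase offset at later reference maxima
    ref_peaks, _ = find_maxima(ref_traj.t, ref_traj.get(reference_gene))
    pul_peaks, _ = find_maxima(pulsed.t, pulsed.get(reference_gene))
    ref_peaks = ref_peaks[ref_peaks > pulse.t_end]
    pul_peaks = pul_peaks[pul_peaks > pulse.t_end]
    n = min(ref_peaks.size, pul_peaks.size)
    offsets = [_wrap_shift(r - p, schedule.period)
               for r, p in zip(ref_peaks[:n], pul_peaks[:n])]
    return PhaseShiftMeasurement(
        pulse=pulse, reference_gene=reference_gene, shift=shift,
        t_max_reference=t_ref, t_max_pulsed=t_pul,
        relaxation={"peak_offsets_h": offsets})


def prc_scan(system: ODESystem, params, schedule: ZeitgeberSchedule,
             zt_grid, strengths=(1.75,), durations=(1.0,),
             target: str = "PER", reference_gene: str = "ARNTL",
             transient: float = DEFAULT_TRANSIENT_H,
             window: float = 168.0, t_step: float = 0.01,
             pulse_day: int | None = None) -> PRCTable:
    """Phase-response scan over a (T_pulse x strength x duration) grid.

    A failing cell (e.g. no detectable post-pulse maxima) is recorded as a
    missing entry, not a global failure. Strength-1 pulses have zero
    shift by construction of the forcing.
    """
    if target not in ("PER", "NR1D"):
        raise ValueError("pulse target must be PER or NR1D")
    day = (int(np.ceil(transient / schedule.period)) + 1
           if pulse_day is None else pulse_day)
    y0 = _entrained_state(system, params, schedule, transient)
    t_end = ((day + 2) * schedule.period + max(durations)) + window
    ref_traj = simulate(system, params, y0, (transient, t_end),
                        schedule=schedule, t_step=t_step)
    rows = []
    for zt in zt_grid:
        for f in strengths:
            for dur in durations:
                pulse = PulseSpec.at_zt(float(zt), day, schedule.period,
                                        duration=float(dur), strength=float(f),
                                        gene=target)
                try:
                    m = pulse_response(system, params, schedule, pulse,
                                       reference_gene=reference_gene,
                                       transient=transient, window=window,
                                       t_step=t_step, _shared_state=y0,
                                       _shared_reference=ref_traj)
                    shift = m.shift
                except (DampedOscillationError, ValueError):
                    shift = np.nan
                rows.append({"zt": float(zt), "strength": float(f),
                             "duration": float(dur), "gene": target,
                             "shift": shift})
    return PRCTable(pd.DataFrame(rows),
                    {"reference_gene": reference_gene,
                     "sign_convention": "positive = advance"})


def gene_relaxation(system: ODESystem, params, schedule: ZeitgeberSchedule,
                    pulse: PulseSpec, genes,
                    transient: float = DEFAULT_TRANSIENT_H,
                    window: float = 240.0, t_step: float = 0.02) -> dict:
    """Per-cycle relaxation of each gene back to the unpulsed reference.

    For every full cycle after the pulse the RMS deviation between pulsed
    and reference course is normalized by the reference's own RMS
    amplitude in that cycle. ``cycles_to_half`` counts cycles from the
    deviation's early peak (the perturbation reaches downstream genes
    with a delay) until it first halves; core-clock genes (PER) relax
    faster than clock-controlled outputs (CES2).
    """
    y0 = _entrained_state(system, params, schedule, transient)
    t_end = pulse.t_end + window
    ref = simulate(system, params, y0, (transient, t_end), schedule=schedule,
                   t_step=t_step)
    pul = simulate(system, params, y0, (transient, t_end),
                   schedule=schedule.with_pulse(pulse), t_step=t_step)
    n_cycles = int((t_end - pulse.t_end) // schedule.period)
    out = {}
    for gene in genes:
        r = ref.get(gene)
        q = pul.get(gene)
        devs = []
        for k in range(n_cycles):
            m = ((ref.t >= pulse.t_end + k * schedule.period)
                 & (ref.t < pulse.t_end + (k + 1) * schedule.period))
            amp = float(np.sqrt(np.mean((r[m] - r[m].mean()) ** 2)))
            devs.append(float(np.sqrt(np.mean((q[m] - r[m]) ** 2)))
                        / max(amp, 1e-12))
        devs = np.array(devs)
        k0 = int(np.argmax(devs[:2])) if devs.size >= 2 else 0
        init = devs[k0] if devs.size else 0.0
        if init <= 0:
            cycles = 0.0
        else:
            below = np.nonzero(devs[k0:] <= 0.5 * init)[0]
            cycles = float(below[0]) if below.size else float("inf")
        out[gene] = {"rms_per_cycle": devs.tolist(),
                     "cycles_to_half": cycles}
    return out


# ---------------------------------------------------------------------------
# pulse-shifted toxicity
# ---------------------------------------------------------------------------

def toxicity_under_pulse(system: ODESystem, clock_params,
                         pkpd_params: PKPDParameters,
                         schedule: ZeitgeberSchedule,
                         pulse: PulseSpec | None,
                         treatment_times,
                         dose: float = 1.0, exposure: float = 48.0,
                         horizon: float = 72.0,
                         transient: float = DEFAULT_TRANSIENT_H,
                         t_step: float = 0.05) -> ToxicityProfile:
    """Circadian toxicity profile computed from the (optionally pulsed)
    entrained clock. ``treatment_times`` are absolute simulation hours;
    pass ``pulse=None`` (or a strength-1 pulse) for the unperturbed
    reference profile."""
    sch = schedule if pulse is None else schedule.with_pulse(pulse)
    tt = np.asarray(treatment_times, float)
    t_end = float(tt.max() + horizon + 1.0)
    y0 = _entrained_state(system, clock_params, schedule, transient)
    traj = simulate(system, clock_params, y0, (transient, t_end),
                    schedule=sch, t_step=t_step)
    prot = translate_proteins(traj, pkpd_params)
    prot = rescaled_drug_proteins(prot, pkpd_params)
    prof = toxicity_profile(prot, pkpd_params, tt, dose=dose,
                            exposure=exposure, horizon=horizon)
    prof.meta["pulse"] = pulse
    return prof
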