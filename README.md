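# chronotox

Coupled circadian-clock / irinotecan PK-PD modelling for chronotherapy:
fit a transcription-translation model of the extended core clock to
circadian gene-expression time series, predict circadian toxicity
profiles of irinotecan treatment from the fitted network, and simulate
how external Zeitgebers (light-dark cycles, light or pharmacological
pulses on *PER*/*NR1D*) entrain the clock and shift both gene expression
and toxicity.

**Who it is for.** Systems biologists and chronotherapy modellers who
want a self-contained, testable pipeline for the question: *given a cell
line's circadian expression profile, when during the day is irinotecan
most (or least) toxic, and how can external cues move that time?*

## The model

A Hill-kinetics transcription-translation network of the core clock
(*ARNTL*, *CLOCK*, *PER*, *CRY*, *NR1D*, *ROR*, *PAR*/DBP, *NFIL3*,
*PPARA*; *PER*, *CRY* and *NR1D* lumped over their paralogs) drives four
drug-metabolism mRNAs (*CES2*, *ABCB*, *ABCC*, *UGT1A1*). Their proteins
(translated with circadian degradation and rescaled to reference maxima)
feed an intracellular irinotecan PK-PD layer: CES2 activates CPT-11 to
SN-38, UGT1A1 deactivates it, ABCB/ABCC export it, and SN-38/TOP1/DNA
cleavage complexes raise the death rate of the living-cell pool L;
dead cells accumulate in D. The circadian toxicity profile is

    AUC(D, treated) / AUC(D, untreated control)   per treatment time,

over one circadian cycle. Fitting minimizes the max-normalized squared
error cost_SE = Σ_{i,j} ((x_i^j − s^j(t_i))/max_k x_k^j)² with CMA-ES
under a 5% minimum-relative-amplitude constraint; knock-out lines are
fitted with a LASSO penalty λ/n_par · Σ_i |(p_i − p_i^WT)/p_i^WT| that
concentrates parameter divergence from the wild type on few parameters.
Light multiplies the maximal *PER* transcription rate while on
(V1max → f·V1max); pulses on *PER* or *NR1D* shift the entrained phase,
measured at the second post-pulse *ARNTL* maximum.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and known limitations.

## Worked example

```python
import numpy as np
import chronotox as ct

system = ct.build_network()                       # default WT topology
traj, period = ct.limit_cycle(system, system.default_parameters)
print(f"free-running period: {period:.2f} h")

pp = ct.default_pkpd_parameters().replace(ugt_scale=0.1)  # HCT116-like
proteins = ct.pkpd.rescaled_drug_proteins(
    ct.translate_proteins(traj, pp), pp)
times = traj.t[0] + np.arange(0, 24.1, 3.0)
profile = ct.toxicity_profile(proteins, pp, times)
for t, a in zip(profile.treatment_times - traj.t[0], profile.auc):
    print(f"treatment at {t:4.0f} h: normalized AUC = {a:.3f}")
print(f"toxicity peak at {profile.peak_time - traj.t[0]:.1f} h "
      f"(value {profile.peak_value:.3f})")
```

prints

```
free-running period: 23.80 h
treatment at    0 h: normalized AUC = 2.635
treatment at    3 h: normalized AUC = 2.663
treatment at    6 h: normalized AUC = 2.729
treatment at    9 h: normalized AUC = 2.796
treatment at   12 h: normalized AUC = 2.822
treatment at   15 h: normalized AUC = 2.790
treatment at   18 h: normalized AUC = 2.721
treatment at   21 h: normalized AUC = 2.658
treatment at   24 h: normalized AUC = 2.635
toxicity peak at 11.8 h (value 2.822)
```

Every AUC is well above 1 — treatment kills cells at any hour — but the
~6% circadian modulation means a cell population treated ~12 h after
synchronization accumulates the most dead cells, and the profile repeats
with the clock. Lowering `ugt_scale` (less SN-38 deactivation) raises
the whole profile.

A command-line interface wraps the same library:

```bash
chronotox synth expression --seed 1 --out expr.tsv   # synthetic dataset
chronotox toxicity --ugt-scale 0.1                   # profile + summary
chronotox entrain --f-light 1.5                      # entrainment verdict
chronotox prc --target PER --strength 1.75           # phase-response scan
chronotox fit-wt --data expr.tsv --config fit.yaml   # CMA-ES fit
```

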