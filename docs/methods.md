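# Methods

## Model overview

`chronotox` couples two layers:

1. **A transcription-translation network of the extended core clock.**
   Thirteen mRNA species — the core-clock genes *ARNTL*, *CLOCK*, *PER*,
   *CRY*, *NR1D*, *ROR*, *PAR* (DBP), *NFIL3*, *PPARA* and the four
   irinotecan-metabolism genes *CES2*, *ABCB*, *ABCC*, *UGT1A1* — plus
   eleven protein species (cytoplasmic monomers, the nuclear CLOCK:ARNTL
   and PER:CRY complexes with explicit nuclear-import steps, and nuclear
   NR1D/ROR/PAR/NFIL3/PPARA). *PER*, *CRY* and *NR1D* are lumped
   variables fitted to the summed expression of their paralogs, because
   single-paralog knock-outs are compensated within the family; *ARNTL*
   shows no compensation and is fitted alone. TOP1 is not transcribed in
   the model (constant protein in the PK-PD layer).

2. **An intracellular irinotecan PK-PD layer.** CES2, UGT1A1, ABCB and
   ABCC mRNA courses are translated with circadian protein degradation,
   rescaled to reference maximal protein concentrations (10-fold reduced
   UGT for UGT1A1-low HCT116-like lines), and drive CPT-11 uptake and
   activation to SN-38, SN-38 deactivation and efflux, and formation of
   SN-38/TOP1/DNA cleavage complexes. Complexes raise the death rate of
   the living-cell pool; dead cells accumulate without clearance. The
   toxicity readout is the AUC of the dead-cell course normalized to an
   untreated control, as a function of treatment time over one circadian
   cycle.

### Kinetic forms

Transcription uses Hill-type regulation. For gene *j* with maximal rate
V_j, activators A (Hill term h_A = (A/k)^n), inhibitors I and basal
fraction b_j:

    dm_j/dt = V_j · (b_j + (1 − b_j) · Π_A h_A/(1+h_A)) · Π_I 1/(1+h_I) − d_j m_j

D-box regulation of the ABC transporters uses a competitive form in
which the activator PAR and the repressor NFIL3 share binding sites:
h_PAR / (1 + h_PAR + h_NFIL3). The basal fraction prevents a
near-extinction attractor in which all E-box genes shut down jointly.
*NFIL3* inhibits *NR1D* at the D-box, which makes NFIL3 an *indirect*
activator of *CES2* (relief of NR1D repression); there is no direct
NFIL3→CES2 edge. PER/CRY inhibition is modelled as blocking of DNA-bound
CLOCK:ARNTL (Hill factors on the E-box terms), not sequestration.

The topology is declarative (YAML-compatible config of species, edges
and kinetic-law parameters); `build_network` validates it and compiles a
fast scalar right-hand side. Every rate constant is a named entry of a
flat `ClockParameters` vector.

### Default parameterization

The default rate constants are the package's own. They were chosen once
to give a robust self-sustained oscillator: the PER/CRY arm forms a
four-stage delayed negative feedback (mRNA → cytoplasmic protein →
cytoplasmic complex → nuclear complex), which oscillates at moderate
Hill coefficients (n = 6 for PER:CRY repression, n = 2 elsewhere).
Because autonomous ODEs rescale exactly in time, all rate-dimension
parameters were scaled so the free-running period is 23.8 h — slightly
short of 24 h, in the typical range of human peripheral clocks, so that
entrainment to a 24 h light-dark cycle is a real locking phenomenon
rather than a coincidence of periods. All 13 mRNAs oscillate with
relative amplitudes between 8% and 92%, above the 5% amplitude floor
used in fitting.

Published parameterizations of this model family, fitted to CRC
cell-line data, exist but are not bundled; they are treated as external
inputs a user can load. Quantitative simulation outcomes that depend on
the parameterization (entrainment threshold, pulse phase-response
timing and range) therefore differ between such a fitted set and the
defaults here. The package reports its own measured values; see "Known
limitations".

## Zeitgeber forcing

Light multiplies the maximal transcription rate of *PER* while on
(factor f ≥ 1); pharmacological cues do the same for *NR1D*. A schedule
combines a periodic light-dark baseline (default 12:12, ZT 0 =
lights-on) with transient pulses. During a pulse window on the LD target
the pulse factor *replaces* the baseline factor (configurable to
multiply); a strength-1 pulse is a no-op. Simulations integrate
piecewise between on/off and pulse boundaries so the solver never steps
across a forcing discontinuity.

**Entrainment verdict.** Entrained means: mean inter-peak interval of
the reference gene (ARNTL) within ±0.1 h of the cycle length over the
last five cycles, peak-phase drift at most 0.02 h per cycle, and
relative amplitude over a 64 h window at least 95% of the free-running
value. The drift bound matters: near the locking threshold a
quasiperiodic state can show a near-24 h *mean* period over five cycles
while its phase drifts steadily; pulse-response measurements in such a
state are meaningless (offsets grow instead of relaxing). The verdict is
evaluated after a 20-day transient because convergence to the locked
state is slow near threshold; the measured minimal entraining strength
is therefore an upper bound on the true threshold.

**Phase shifts.** A pulse response is the time difference of the
reference gene's second post-pulse maximum, pulsed versus unpulsed, on
the entrained system, wrapped to (−12, 12] h. Positive = phase advance
(pulsed peak earlier). Peaks are located on a fine resampled grid
(0.01-0.02 h) with three-point quadratic refinement.

**Relaxation.** Relaxation back to the reference is quantified per cycle
as the RMS difference between pulsed and reference course, normalized by
the reference's own RMS amplitude in that cycle; `cycles_to_half` counts
cycles from the deviation's early peak until it halves. Peak-time
offsets are not used for this: in the first post-pulse cycle the
deviation has not yet reached downstream genes, which makes peak-offset
ratios artifact-dominated. Under this measure core-clock genes (PER)
relax faster than clock-controlled outputs (CES2), as expected.

## Fitting

The cost is the squared error between data and simulation at the data
timepoints, normalized per gene by the gene's data maximum so every mRNA
carries equal weight. Fitted mRNA courses must oscillate with relative
amplitude (max−min)/max > 0.05, enforced as a large additive penalty
(1e4 per violating gene) so the optimizer retains a gradient signal;
*UGT1A1* is exempt for HCT116-like lines where it is not expressed.

Optimization uses an in-package (mu/mu_w, lambda)-CMA-ES (canonical
weights and learning rates, cumulative step-size adaptation, box
constraints by reflection), run in log10-parameter space with restarts
that double the population and jitter the start mean. Bounds default to
[0.01x, 100x] of each free parameter's initial value. Initial state:
first data timepoint for fitted mRNAs, a small data-derived floor for
unobserved proteins (optionally fitted). For recovery tests,
`model_generated_dataset` iterates this convention to a fixed point so
that the generating parameters are an exact optimum of the refit.

Knock-out lines are fitted with a LASSO penalty on relative parameter
divergence from the wild-type fit,
cost_SE + λ/n_par · Σ|p_i − p_i^WT|/p_i^WT, the knocked-out paralog
being removed from the lumped data sum (the lumped model species is kept).
Parameters with near-zero wild-type values (<1e-9) are excluded from the
penalty and the divergence report. The penalty sweep runs one fit per λ
with the same seed so only λ varies; the 50%-of-R² rule for choosing λ
is reported as a diagnostic, not automated.

PK-PD fitting matches the dead-cell variable D to cytotoxicity curves
(each treated curve shifted to start at the control's start value); the
free set defaults to the death/cell-count parameters plus the CES2
activation rate, and is config-driven.

## Synthetic data

The expression generator produces cosinor signals
x(t) = mesor·(1 + amp·cos(2π(t−phase)/24)) + drift·t with multiplicative
log-normal noise (sd 0.1 by default), sampled every 3 h over 45 h —
mimicking the study design of synchronized CRC cell-line time series
with superimposed linear drifts (pronounced for *PPARA* and *CES2*) and
near-zero *UGT1A1* in HCT116-like lines. Knock-outs set the gene to a
1e-3-of-mesor residual and either transfer the removed expression to the
strongest remaining paralog (PER, NR1D, CRY families: sum-preserving
compensation) or co-reduce the family (ARNTL: ARNTL2 halved). What the
generator does *not* emulate: count noise (negative binomial), gene-gene
correlation beyond the shared clock phase, batch effects, or any
read-level structure — so passing recovery tests demonstrate correctness
of the estimation machinery under the model's own assumptions, not
robustness to real RNA-seq artifacts.

Cytotoxicity curves are forward-simulated from known PK-PD parameters
with optional multiplicative noise and carry their noiseless
normalized-AUC profile as an attached ground truth.

## Cell-line scenarios

The phase-adaptation procedure transfers one fitted model between cell
lines: each line's clock phase is measured from its expression data as
the cosinor peak phase of *ARNTL* (with a linear drift term), and all
circadian phases of the PK-PD layer (the four protein-degradation phases
and the death-modulation phase) are shifted by the measured difference;
UGT1A1-low lines get the 10-fold UGT reduction. The packaged scenarios
encode per-line ARNTL phase offsets reproducing the qualitative
relations reported for HCT116 WT, its PER2/NR1D1/ARNTL knock-outs and
SW480; the toxicity-peak differences are then *computed* through
measurement → adaptation → simulation, and come out close to but not
identical with the encoded offsets (the alpha-function death surge and
the finite observation horizon deform the profile).

## Numerical choices

- Clock integration: LSODA, rtol 1e-4, atol 1e-12, step cap 0.25 h (the
  cap keeps the accumulated error of a 48 h run within 1e-3 of a DOP853
  rtol 1e-7 reference). PK-PD integration: LSODA, rtol 1e-4, atol 1e-7.
- Concentrations are clipped to zero within 1e-6 (solver undershoot);
  kinetic terms evaluate max(y, 0) so fractional Hill powers are safe.
- AUC by trapezoid on a uniform 0.1 h grid; toxicity-profile peak time
  by quadratic interpolation around the discrete maximum, earliest-time
  tie-break.
- Transient discard before phase/amplitude readouts: 10 simulated days
  (20 for entrainment verdicts); configurable.
- Default problem sizes in tests and the acceptance script are desk
  scale: 6-8 free parameters per fit, ~4000 CMA-ES evaluations with two
  restarts, 1 h phase-response grids, 1.5-3 h treatment-time grids.

## Known limitations

- The default parameterization is the package's own, not one fitted to
  measured CRC expression and cytotoxicity data. Consequences measured
  by the acceptance suite: minimal entraining light strength 1.34
  (fitted parameterizations report values as low as 1.07); largest
  PER-pulse phase shift at ZT 23 rather than midday, with a ±0.1-0.3 h
  shift range at strength 1.75 rather than ±2 h. The cell-line
  toxicity-peak relations and the bounded pulse effect on toxicity
  peaks do reproduce.
- The clock model is autonomous apart from Zeitgeber forcing; no
  cell-division, temperature or metabolic coupling.
- Light enters as a single multiplicative factor on *PER* transcription;
  no photoreceptor or SCN-periphery signalling.
- LASSO divergence reporting is a parameter-selection heuristic, not an
  identifiability analysis.
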