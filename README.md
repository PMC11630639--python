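# tirftrace

Two-color single-molecule TIRF analysis for immobilized multi-subunit
molecules probed with a labeled ligand: spot detection and colocalization,
stepwise-photobleaching subunit counting, signed residence-time kinetics
with photobleaching correction, and Poisson occupancy modeling — plus a
virtual-movie simulator that provides ground truth for every stage.

## The problem

In a typical experiment, a Venus-tagged multi-subunit enzyme (e.g. a
12–14-subunit CaMKII holoenzyme) is sparsely immobilized on a coverslip
and imaged by TIRF microscopy while rhodamine-labeled calmodulin binds and
unbinds its subunits. Two EMCCD cameras record interleaved frames under
alternating blue/olive laser excitation, yielding four logical channels
(Venus, rhodamine, a leakage/FRET "mixed" channel, and a discarded blank).
From each diffraction-limited spot's intensity trace one wants:

- **S**, the subunit stoichiometry, from counting downward photobleaching
  steps in the Venus channel;
- **N(t)**, the bound-ligand occupancy, from signed steps in the rhodamine
  channel;
- **fON, fOFF** — up/down step counts per unit record time;
- **kτ**, the decay rate of the residence-time (|τ| ≤ 30 s) distribution,
  and **kτ−corr = kτ − kPB** after removing the photobleaching hazard
  (independent competing exponential risks);
- the **affinity index Ai = [ligand]·kτ/fON**, a heuristic stand-in for a
  dissociation constant;
- population occupancy histograms with Poisson / two-Poisson /
  geometric fits (independent per-subunit binding predicts Poisson).

Steps are found with a four-pass detector: running-average smoothing
(window *b*), a rolling-window first derivative (window *a*) with
prominence threshold *q* in units of the trace's noise, amplitude
acceptance within ±1 SD of the calibrated single-fluorophore step
distribution (integer multiples are scored as multi-step "bunching"), and
level refitting with a minimum dwell of 0.3 s and a Welch *t*-test between
adjacent levels.

Raw movies for this kind of study are rarely deposited, so the package
ships a first-class simulator: exact continuous-time Markov binding
trajectories per subunit, exponential photobleaching, a Gaussian PSF
rendered onto a 512×512 / 100 nm-per-pixel field, dual-exponential
autofluorescence decay, uneven illumination, spectral leakage (10% of
Venus into the mixed channel), and EMCCD noise
(Poisson → Gamma gain register → Gaussian read noise).

## Worked example

Count the subunits of one simulated 14-fluorophore spot whose
photobleaching staircase is recorded at the calibrated single-step
signal-to-noise ratio (single-fluorophore step 100 ± 15 ADU, per-frame
noise 15 ADU):

```python
from tirftrace.simulate import simulate_bleach_staircase
from tirftrace.stepfind import StepParams, find_steps, count_bleach_steps
from tirftrace.kinetics import affinity_index

trace = simulate_bleach_staircase(
    n_fluor=14, kpb=0.04, step_mean=100.0, step_sd=15.0,
    noise_sd=15.0, duration=100.0, dt=0.2, seed=11,
)
model = find_steps(trace, StepParams(step_mean=100.0, step_sd=15.0))
print("detected steps :", model.n_steps)
print("subunit count  :", count_bleach_steps(model))
print("first level    : %.1f ADU" % model.levels[0].mean_intensity)
print("last level     : %.1f ADU" % model.levels[-1].mean_intensity)
print("affinity index : %.1f uM" % (1e6 * affinity_index(300e-9, 0.7, 0.0512)))
```

prints

```
detected steps : 6
subunit count  : 12
first level    : 1430.4 ADU
last level     : 0.2 ADU
affinity index : 4.1 uM
```

The trace starts at ~14 step units and bleaches to zero, but only 12
subunits are counted from 6 step events: early bleaching events crowd
together and are scored as double/triple steps ("bunching"), and noise
hides a couple entirely. Across many spots this undercount averages about
2 of 14 subunits — the known resolution limit of step counting at this
noise level. The affinity-index line evaluates Ai for a monomer-like
condition (300 nM ligand, kτ = 0.7 s⁻¹, fON = 0.0512 s⁻¹) and returns
4.1 µM.

End-to-end runs (simulate → preprocess → detect → step-fit → kinetics →
occupancy, with CSV/JSON reports and a config-hash manifest) go through
`tirftrace.pipeline.run_pipeline` or the CLI:

```bash
tirftrace run --out myrun --seed 1          # end-to-end on a simulated movie
tirftrace simulate --out sim --seed 1       # movie + ground-truth tables only
tirftrace steps traces.csv --step-mean 100 --step-sd 15 --out stepdir
```

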