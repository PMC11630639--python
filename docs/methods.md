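# Methods

## Scope and data model

The package analyzes interleaved two-camera TIRF recordings of surface-
immobilized multi-subunit molecules (the "green"/Venus channel) exchanging
a fluorescently labeled ligand (the "red"/rhodamine channel). Recorded
camera frames alternate between blue and olive excitation at 0.1 s per
frame; after deinterleaving, each logical channel is sampled at 0.2 s.
All stages operate on a `MovieStack` (time × rows × cols, float64, with
frame-interval metadata and an optional invalid-pixel mask) and on
per-spot `Trace` objects (5×5-pixel ROI sums per frame).

## Simulator

The simulator is first-class, tested code: it defines the study
conditions under which every downstream claim is validated.

**Binding.** Each of the S subunits binds ligand independently at
`kon·C` and releases at `koff` (identical rates; cooperativity is out of
scope). Trajectories are exact continuous-time Markov (Gillespie) paths,
sampled onto the frame grid only afterwards, so residence-time
distributions carry no time-discretization bias. The initial state is
drawn from the stationary law in the dark (Binomial(S, konC/(konC+koff)));
the photobleaching hazard applies only for t ≥ 0, when the laser is on.
A bound ligand whose fluorophore bleaches still occupies its subunit,
invisibly, until it dissociates; the solution pool is treated as
unbleached. Every visible transition is logged as (time, ±1, cause ∈
{bind, unbind, photobleach}).

**Photobleaching staircases.** Each Venus fluorophore has an amplitude
drawn from the single-fluorophore intensity distribution
N(step_mean, step_sd) and bleaches once at an exponential time; an
optional dark fraction (default 0.20, the literature estimate for
GFP-family tags) removes fluorophores before t = 0.

**Rendering.** Spots are placed uniformly with a minimum separation
(default 20 px = 2 µm) and rendered as symmetric Gaussian PSFs with
σ = 74 nm (0.21·λ/NA at λ = 525 nm, NA = 1.5) on a 100 nm/px grid.
Backgrounds follow a dual-exponential + offset decay multiplied by a
smooth vignette (1.0 at center → 0.7 at corners). Camera counts are
Poisson photons → Gamma(shape = n, scale = gain) EM register → Gaussian
read noise → 16-bit quantization, with gain 30 ADU/photon and read noise
10 ADU: these are not measured quantities but chosen so a single
fluorophore's per-frame SNR matches the monomer calibration regime.
Spectral leakage adds `leak_fraction` (default 0.10) of the Venus signal
to the red camera on blue-excited frames; an optional per-bound-ligand
FRET term is off by default. Identical seed and config give bit-identical
stacks.

**What the simulator does not emulate:** diffusing-ligand background
beyond a uniform term, aggregation, drift, focus fluctuations, and
nonuniform PSFs. Passing tests therefore demonstrate correctness of the
analysis chain under the stated stochastic model, not robustness to every
artifact of real recordings.

## Preprocessing

Registration applies a pre-calibrated rotation/translation (bead
calibration is an input, not a fit) with bilinear interpolation and an
out-of-field mask. Leakage is estimated on ligand-free records as the
median over spots × frames of the ratio of ROI-integrated mixed to Venus
intensity; each ROI sum is first corrected by the mean pixel value of the
surrounding 9×9-minus-5×5 annulus. The annulus statistic is the mean, not
the median, because EMCCD pixel noise is right-skewed and the median
would systematically under-subtract background (a ~+0.01 bias on a 0.10
leakage fraction). The FRET channel is mixed − leak_fraction × Venus,
frame by frame.

Uneven illumination is removed from projections with a rolling-ball
background (radius 100 px). Because that background is smooth by
construction, it is computed on a 4× block-averaged image with the radius
scaled down and resampled up — indistinguishable from the full-resolution
ball on gradients (<0.5% residual) and ~100× faster; `downsample=1`
restores the exact ball. Autofluorescence decay is fitted per channel to
A1·e^(−k1 t) + A2·e^(−k2 t) + C on the per-frame mean over non-ROI pixels
(initialized from log-linear fits to the early/late thirds, rates bounded
at 0, single-exponential fallback on non-convergence) and subtracted from
all pixels.

## Spot detection and traces

Detection runs on the temporal mean projection: a 7×7 negated
Laplacian-of-Gaussian kernel matched to the PSF (σ = 0.74 px), local
maxima above median + k·MAD (k = 5) of the filtered image, merge-to-
brighter within 5 px (flagged `overlap`), `edge` and `aggregate` flags.
ROI centers are integer pixels; the sub-pixel centroid is stored for QC
only. A centered 5×5 ROI holds 99.8% of the default PSF analytically,
comfortably above the ≥80% capture the ROI size is meant to guarantee. Traces are per-frame 5×5 sums;
for pipeline use they are local-background-corrected with the same
annulus rule as the leakage estimator, which removes camera baseline and
diffuse background (~1.2 step units if left in, enough to shift occupancy
anchoring by +1).

## Four-pass step detection

The four passes: (1) running-average smoothing, window b = 3 frames;
(2) rolling first derivative over a = 5 frames, peak calling on |d| with
prominence ≥ q = 3 in units of the derivative's noise scale — the robust
SD of first differences of the raw trace divided by √(a/2) — not of the
derivative distribution itself, which is step-bearing on busy traces;
each peak is refined to the exact change point by a local two-segment
least-squares split; (3) amplitude acceptance: ΔI measured between
neighboring candidates on the raw trace, multiplicity m = round(|ΔI| /
step_mean), accepted when |ΔI − m·step_mean| ≤ m·step_sd (the ±1 SD rule,
extended to integer multiples to score "bunched" double steps); (4) level
refitting with iterative merging of levels shorter than 0.3 s or not
separated at α = 0.05 by Welch's unequal-variance t-test (weakest
boundary first). Final step amplitudes, signs, multiplicities and
p-values are recomputed from the refitted levels. Stoichiometry is the
summed downward multiplicity; records whose terminal level exceeds half a
step are flagged `censored_stoichiometry`.

**Self-calibration.** A population-level step calibration is broadened by
illumination inhomogeneity across the field, while within one spot the
unit amplitude is essentially fixed. `find_steps_selfcalibrated`
therefore runs a loose first pass (band SD = 0.35 × mean), takes the
spot's unit as the median |ΔI|/multiplicity of its own steps (clamped to
±2.5 population SD), and refits with a band combining the intrinsic
per-spot spread (CV 0.15) with the ΔI measurement noise. The pipeline
uses this variant for both channels.

**Temporal resolution.** The derivative window blurs events over ~a
frames: measured detection is ≈99% for dwells >5 s, ≈92% at 2–5 s, and
falls to ≈40% below 1 s, because opposite-sign events inside the window
cancel. This dead time (~1 s) is intrinsic to the derivative design and
is the mechanism behind the stoichiometry undercount quantified in the
acceptance suite; tests that assert frame-level or rate-level recovery
state their resolvability premise explicitly and, for end-to-end
kinetics, compare against resolution-matched truth (ground-truth
trajectories with sub-1.2 s excursions merged).

## Kinetics

fON/fOFF are multiplicity-weighted up/down step counts divided by record
duration, computed per spot and averaged; residence intervals are pooled
across spots per condition. Each stationary nonzero-occupancy level
yields one interval, signed by its entering transition (up → τ+, down →
τ−): this is the only sign convention consistent with monomers producing
only τ+ intervals, saturated dimers alternating symmetrically, and
holoenzymes showing a τ− excess under photobleaching. Zero-occupancy
intervals are not scored; record-boundary intervals are censored and
excluded from fits. Occupancy labels come from cumulative signed
multiplicities anchored by frame-weighted least squares against the
spot's own unit amplitude, so records that never visit zero occupancy are
still labeled correctly and a single misread level cannot shift the whole
trajectory.

The |τ| histogram (bin width 2 × frame interval, τ ≤ 30 s; the >30 s
fraction is reported but not fitted, as it is photobleaching-dominated)
is fitted by unweighted least squares with A·e^(−kτ) and with a
two-exponential sum, selected by AIC; a degenerate biexponential
(rates within 1.5×) collapses to single. An optional `tau_min` drops
bins below the detector's dwell resolution from the fit (dead-time
handling; an exponential rate is shift-invariant under truncation from
the left). Photobleaching correction subtracts the control hazard,
kτ−corr = kτ − kPB (independent competing exponential risks), clamped at
zero with a warning. The affinity index is Ai = C·kτ/fON in the
concentration's units.

## Occupancy

Per-spot initial occupancy N(0) is the anchored trajectory's first frame
(steady state is reached in the dark, and photobleaching only lowers
occupancy afterwards). Population histograms are fitted by maximum
likelihood: single Poisson (λ = histogram mean, an identity the tests
assert exactly), a two-component Poisson mixture by EM with 10 seeded
restarts (degenerate weights or coincident means fall back to single,
flagged), and a geometric law as the discrete single-exponential
candidate; models are compared by AIC and goodness-of-fit is a χ² with
tail bins pooled to expected ≥5. The zero- versus nonzero-occupancy
subpopulations are compared on their subunit counts with an F-test for
variance equality followed by Welch's t-test. Intensity filtration keeps
spots within a configurable monomer-unit band (default 6–28 units) to
separate holoenzymes from dimers below and aggregates above.

## Pipeline

`run_pipeline` sequences simulate/load → deinterleave → leakage → field
correction → detection → trace extraction → colocalization (9×9 shifted
Pearson CC on projections, ties broken toward smaller |shift|) →
self-calibrated step fitting → kinetics → occupancy, writing CSV/JSON
artifacts and a manifest with config hash, version, seed, stage timings
and counts. All randomness flows from one seed; identical configs and
seeds give byte-identical summaries.

## Validation conditions and problem sizes

The test and acceptance suites run on deliberately scaled problems:
staircase ensembles of 100–120 traces of 500 frames; leakage calibration
on a 192² field with 8 holoenzyme spots over 120 recorded frames;
colocalization baselines on twenty 512² projection pairs with 50–150
spots per channel; and end-to-end kinetics on three 320² fields of 40
holoenzyme spots over 600 recorded frames (60 s per channel). The
end-to-end exchange parameters (per-subunit association 0.0035 s⁻¹ at
30 nM ligand, koff = 0.015 s⁻¹, ligand photobleaching 0.02 s⁻¹) were
chosen to match the assay regime the method is designed for: mean
occupancy ≈ 2.6 on a 14-mer with per-spot event frequencies of a few
times 0.01 s⁻¹, so that most dwells are resolvable at the 0.2 s channel
frame interval.

## Known limitations

- The step detector's ~1 s dead time biases apparent fOFF, kτ and
  stoichiometry when true dwells approach the frame interval; the
  acceptance suite quantifies the stoichiometry consequence (≈2 of 14
  subunits missed) rather than hiding it.
- Histogram least squares is the default τ fit for parity with common
  practice; it is less efficient than censored MLE, which is the natural
  extension point.
- The per-level photobleaching hazard scales with occupancy (n·kPB), but
  the default correction subtracts a single control rate; the refined
  per-level mode is intentionally minimal.
- Occupancy reconstruction is cumulative: a wrong multiplicity propagates
  until the anchor re-synchronizes it; the intensity anchor bounds, but
  does not eliminate, this failure mode.
- Registration assumes calibration inputs; there is no sub-pixel
  refinement, tracking, or drift correction (molecules are immobilized).
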