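# Methods

`spt` analyses intracellular single-particle tracking data of the kind
produced by stroboscopic live-cell imaging of fluorescently labeled proteins
and tRNAs in bacteria: short 2D trajectories (tens of frames at millisecond
frame times) of molecules that switch between a small number of diffusive
states — e.g. a translation factor alternating between a slowly diffusing
ribosome-bound state and fast free diffusion. This note records the model,
its assumptions, the numerical choices, and the limits of what the synthetic
data can demonstrate.

## Observation model

A trajectory is an ordered list of localizations (x, y, frame). The analysis
operates on displacements. For a molecule in diffusion state k with
coefficient D_k, the displacement across a span of n frames (n = 1 + number
of missed detections) is modeled as an isotropic bivariate Gaussian with
per-dimension variance

    v_k(n) = 2 D_k (n Δt) (1 − 2R/n) + 2 σ²,

where Δt is the frame interval, σ the localization error SD, and
R = t_E / (6 Δt) the motion-blur coefficient for a uniform laser pulse of
length t_E at the start of each frame. The two correction terms are standard:
averaging the Brownian path over the pulse shortens apparent displacements
(the −2R/n term, exact for free diffusion under uniform exposure), and
localization noise adds 2σ² per displacement. The blur-and-noise-induced
*covariance between consecutive displacements* is deliberately neglected
(diagonal emission approximation). This keeps the EM exact and fast; the
recovery tests, which run against a simulator that includes the full
physics, quantify the residual bias (bound/free dwell times come out
roughly 5–15% high under the default acquisition conditions; diffusion
coefficients and occupancies are essentially unbiased).

## Hidden Markov model and fitting

Hidden states switch between consecutive displacements with a per-frame
transition matrix A; across a detection gap of g frames the transition
operator is A^(g+1). The state of a displacement is identified with the
physical state at its first frame. All trajectories of a dataset are fitted
jointly (global maximum likelihood) by expectation–maximization:

* **Initial distribution.** Tied to the stationary vector π(A) of the
  transition matrix — the tracked system is in steady state, and each
  trajectory's first localization samples that steady state. Because of the
  tie, the M-step for A is not closed-form: it maximizes
  Q(A) = Σ C_ij log A_ij + Σ_j G0_j log π_j(A) directly (L-BFGS on row
  logits, with the closed-form stationary gradient via the fundamental
  matrix). This matters in practice: treating the initial distribution as a
  free parameter and recomputing π(A) afterwards discards the initial-state
  observations and measurably degrades occupancy estimates when transitions
  are rare relative to trajectories.
* **Gaps.** The expected per-frame transition counts through the unobserved
  frames of a gap are computed exactly by the path-sum over matrix powers
  (exact EM on the augmented chain), not by treating a gapped transition as
  a single step.
* **Diffusion coefficients.** The M-step per state is closed-form when all
  spans are 1 and a bounded 1-D search over D otherwise (spans give the
  variance different intercept/slope, so no joint closed form exists).
* **Localization error.** One global σ is fitted by default (conditional
  1-D maximization after the D updates — ECM). When per-point uncertainties
  are present in the data they are used as fixed per-step noise instead.
  Note the practical identifiability limit: for a noise-dominated slow state
  (2DΔt ≪ 2σ²), D and σ trade off along a ridge that only the span
  heterogeneity of gapped steps breaks, so fitted-σ runs show inflated
  scatter in the slowest D. Recovery tests therefore fix σ at its known
  simulated value; real-data analyses should prefer per-point uncertainties
  from the localization step when available.
* **Initialization and convergence.** Default 10 random starts (D
  log-uniform on [0.005, 20] µm²/s, self-transitions uniform on
  [0.8, 0.99]), relative log-likelihood tolerance 1e-8, 500 iterations cap;
  the best converged start is kept. States are reported sorted by ascending
  D (ties: occupancy descending). Heavy test scenarios use documented
  scaled-down settings (4 starts, tol 1e-7, 250 iterations), which suffice
  for well-separated two-state data.
* **Model size.** K is fixed per fit; `model_scan` fits K = 1..9 and
  reports AIC = 2p − 2 logL with p = K + K(K−1) (+1 when σ is fitted); the
  stationarity tie means the initial distribution adds no parameters.

Confinement is *not* modeled in the likelihood. In a 0.8 µm-wide cell the
apparent D of a fast state (≈3 µm²/s) is depressed by ≈20% relative to its
free-space value; fitted states are therefore apparent (confined) diffusion
states, which is also how the experimental numbers should be read.
Recovery tests run the simulator without confinement to isolate estimator
correctness; a separate simulation quantifies the confinement bias.

## Coarse-graining and kinetics

Fitted states are lumped into classes by thresholds on D (defaults 1 and
8 µm²/s: ribosome-bound / free / fast cleavage-product artifact; finer
splits at 0.25 and 0.05 µm²/s resolve mRNA-engaged sub-states). A state
exactly at a threshold goes to the slower class. Class occupancy sums member
π_i; the class-to-class flux is Σ π_i A_ij / Δt over member pairs; and the
mean dwell time of a class is occupancy / total outflux. This flux-based
dwell equals the mean sojourn per visit at stationarity and — unlike a
segment-duration average over observed binding events — remains unbiased
when dwells exceed typical trajectory lengths (a deliberately biased
segment-duration estimator is included for comparison).

Replicate experiments are aggregated with means and between-experiment
sample SDs (never pooled-step SDs). The factor cycle time is
τ_bound / occ_bound (= τ_bound + τ_free at stationarity), computed from the
pooled mean occupancy and dwell rather than averaging per-experiment cycle
times (ratios of means, not means of ratios; the difference is second order
in the between-experiment spread). Cycle-time thresholds scale a reference
ribosome translation-cycle time (default window 10–17 s; the conservative
10 s lower bound is used) by the factor-to-ribosome concentration ratio; a
measured cycle below the threshold implies more than one ribosome binding
per translation cycle. Conditions are compared with a two-sided unpaired
Student t-test on per-experiment values (Welch variant by flag), with the
conventional star coding.

## Synthetic data

The simulator emulates the acquisition physics the fitter assumes, plus the
pieces it does not model:

* 3D Brownian motion inside a spherocylinder (default 0.8 µm wide, mean
  length 3 µm, lognormal CV 0.15) with reflecting walls, propagated at 50
  sub-steps per frame; Markov switching with exponential waiting times,
  frozen within a sub-step (a warning fires if rate × sub-step > 0.1);
* stroboscopic exposure: the emitted position is the average of sub-step
  positions within the pulse window (default 3 ms of a 5 ms frame) at the
  start of the frame, projected to 2D (z discarded), plus isotropic Gaussian
  localization noise (default 30 nm);
* geometric trajectory lengths (photobleaching; default mean 30 frames,
  truncated at 500) and independent missed detections (default p = 0.1)
  constrained so no gap exceeds 3 frames and endpoints are detected;
* several independent "experiments" (default 3) with their own cells.

Defaults mirror the acquisition conditions of stroboscopic initiation-factor
tracking in E. coli (3 ms pulses / 5 ms frames, D between 0.01 and
10 µm²/s, dwell times 0.03–1 s, ~30-frame trajectories). The simulator does
*not* emulate camera noise models, PSF shape, z-dependent localization
error, molecule misassignment during tracking, or cell growth during
imaging — passing recovery tests therefore demonstrates estimator
correctness under the stated physics, not robustness to detection and
linking artifacts, which are upstream of this package.

## Spatial maps

Localizations are mapped into normalized cell coordinates (rotate by the
cell orientation about its center; long axis u ∈ [−1, 1], short axis
v ∈ [−1, 1]; points beyond 1.05 are excluded and counted) and accumulated
into a 2D histogram, each point weighted by its posterior probability of
belonging to the selected diffusion class (soft assignment; a Viterbi-style
hard mode is available, but posterior weighting is more robust at 5 ms
frames where state segments are short). Default grid 50 × 25 (u × v),
normalized to unit mass; raw-mass mode makes maps of nested classes exactly
additive. Quadrant folding is off by default. Size-based cell sorting by a
length window stands in for nucleoid-count-based sorting; nucleoid imaging
is out of scope.

## Degenerate inputs and tie-breaks

Trajectories with fewer than two localizations are skipped with a warning;
an empty coarse class reports NaN dwell and is flagged (never infinite); a
zero-occupancy bound class makes the cycle time NaN with a flag; groups
without within-group variance get the exact degenerate t-test limits (t = 0,
p = 1 for equal means). Gap violations on read either reject (default) or
split trajectories — which of the two the original pipeline used is not
documented, so both are provided.

## Problem sizes

The test suite runs the full recovery surface at the study's own scale
(1000 trajectories × ~30 frames per replicate; 20 replicates for the
recovery sweep; model sizes 2–6 for the robustness scan) with the
scaled-down fit settings noted above. The likelihood oracle enumerates all
hidden paths for K ≤ 3 and ≤ 8 steps; the dwell oracle simulates a
10⁶-step Markov chain.
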