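# Methods

This note documents the models, conventions, parameter choices and known
limitations of the `placecode` pipeline, in the order data flow through it.

## Recording model and conventions

A session is 10 minutes of foraging in a 62-cm cylindrical arena. Positions
are arena-centred Cartesian centimetres at a nominal 50 Hz; spikes, LFP and
position share one per-session clock (alignment is validated, never
repaired — spikes more than 1 s outside the tracked window raise). The LFP is
one channel at a nominal 4.8 kHz; any rate above twice the highest analysed
frequency (102 Hz) is accepted.

All rate and spatial metrics use only locomotion periods: running speed is the
path length per 500-ms epoch divided by 0.5 s, and movement is a strict
`speed > 3 cm/s`. Immobility is defined as the complement (speed ≤ 3 cm/s);
a post-immobility activity epoch is the first 4 s of a supra-threshold run of
at least 4 s preceded by at least one immobile epoch (0.5 s) — the minimum
immobility duration is a choice, as no convention fixes it.

## Rate maps and spatial metrics

Occupancy and rate use a square grid of 2.5-cm bins anchored at the arena
centre; bins whose centre falls outside the disc, or that are occupied for
less than 100 ms, carry no rate. The smoothed rate at a bin centre x is the
kernel density ratio λ(x) = Σ spikes g(‖Sᵢ − x‖/h) / ∫ g(‖y(t) − x‖/h) dt with
g(u) = exp(−u²/2) and h = 2.5 cm; the denominator integral is a Riemann sum
over the 50-Hz position samples (dt = 0.02 s), which agrees with a 10×
oversampled quadrature to within 1 % (tested). The denominator depends only on
the trajectory, so it is computed once per session and shared across cells.

Occupancy probabilities Pᵢ are raw (unsmoothed) dwell times normalised over
valid bins; the overall rate is R = Σ PᵢRᵢ. Spatial information uses the
x log x → 0 limit convention for silent bins and is undefined (an error, not
zero) for a silent cell. Percent active bins deliberately uses raw
spike-containing bins over visited bins, not the smoothed map. Place fields
are 4-connected components (8-connectivity is a config option) of bins above
20 % of the map peak with at least 9 members; the "main" field is the
component containing the global peak bin (a largest-area rule would be the
alternative). Map stability is the Pearson r over bins valid in both sessions,
Fisher-z transformed with |r| clipped at 1 − 10⁻⁷; pairs are excluded — not
scored 0 — when either session's SI is ≤ 0.5 bits/spike or fewer than 10
joint bins exist.

Open choices resolved here: rate-map occupancy is movement-masked (the spike
filter is explicit in the protocol, the occupancy filter is not; masking both
keeps numerator and denominator consistent), and classification rates are
computed per session.

## Cluster quality and burst statistics

Isolation distance is the squared Mahalanobis distance (cluster mean and
covariance) of the n_c-th closest non-cluster spike; it is undefined (NaN,
logged, never auto-rejecting) when fewer non-cluster spikes than cluster
spikes exist. L-ratio sums the χ² upper-tail mass of all non-cluster spikes
and divides by n_c; the degrees of freedom default to the feature
dimensionality, with 8 the conventional value for 4-channel × 2-feature
reductions. A singular or ill-conditioned cluster covariance raises rather
than being silently ridge-regularised (an explicit ridge is available).

Bursts are maximal groups of ≥ 2 spikes whose consecutive ISIs are all below
10 ms (strict); burst probability is N_B/(N_B + N_S) and the
spikes-in-bursts/total-spikes alternative is reported alongside. The 6/9/12-ms
variants rank a simulated population consistently with the 10-ms definition
(Spearman ρ > 0.9, tested).

## LFP analysis

Band definitions: theta 6–12 Hz, slow gamma 30–45 Hz, medium gamma 55–100 Hz
for power; phase extraction filters with passbands 4–14, 28–47 and 58–102 Hz
and stop bands 2 Hz beyond each passband edge. The printed medium-gamma
filter passband clips the bottom 3 Hz of its analysis band; we keep both
definitions as printed rather than reconciling them.

Session power z-scores the trace, concatenates the post-immobility activity
epochs, and averages a DPSS multitaper spectrogram (20-s windows, 10-s steps,
time-bandwidth 3, 5 tapers — conventional defaults, configurable) over each
band. Windows are longer than single 4-s epochs, so concatenation is the only
workable reading; join artefacts are accepted as part of the estimator.
Per-epoch power uses Welch periodograms (Hamming, 50 % overlap) on 500-ms
bins, integrating the PSD over each band with linear interpolation at the
exact band edges so coarse frequency grids do not truncate the integral.

The band-pass filter is a Kaiser-window FIR designed for ≥ 40 dB stop-band
attenuation and ≤ 1 dB passband ripple (no convention fixes the filter
family; phase fidelity is the binding requirement). The symmetric odd-length
kernel is applied centred, so the net phase response is exactly zero. Phase
comes from the Hilbert analytic signal shifted by π, putting the oscillation
trough at 0/360°. Strong-oscillation epochs are 500-ms bins whose mean squared
analytic amplitude exceeds the session mean + 2 SD (power, not amplitude — an
option switches). Phase locking uses only spikes inside those bins; results
with fewer than 30 spikes (configurable) are flagged insufficient rather than
reported.

## Circular and group statistics

Rayleigh p-values use Zar's corrected approximation
p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)); it matches an independent
permutation null to < 0.005 at n = 20 (tested). Watson–Williams uses the
standard κ̂-based correction factor (Fisher/Best approximation with the
small-sample adjustment); low pooled concentration is warned about, not
enforced. Harrison–Kanji is the two-factor resultant-length decomposition
with the 1/(1 − 1/(5κ) − 1/(10κ²)) bias correction for main effects; it
assumes concentrated data (warning below κ̂ = 2) and its type-I error
calibrates to 0.02–0.09 at κ = 4 in simulation (tested). Two-proportion
z-tests and Benjamini–Hochberg FDR delegate to statsmodels behind the module
surface. Mixed-effects models are deliberately out of scope: the pipeline
exports tidy long-format tables for lme4-style software, where the intended
models are of the form `metric ~ genotype * day * session_in_day +
(1|animal) + (1|cell)` with likelihood-ratio model reduction.

## Down-sampling control

Subsamples of 30 cells (the approximate per-animal yield) are drawn uniformly
with replacement until 1000 draws satisfy the mean-rate constraint
(target ± 5 %); the sampler is plain rejection with a budget of 10⁶ attempts
per accepted subsample, after which a feasibility error reports the achieved
acceptance rate. "Statistically different from the overall population" is a
Welch two-sample t-test of the subsample's metric values against all cells'
values at α = 0.05 (Watson–Williams for preferred phase); the full population
is used as-is, including the drawn duplicates. The session-3/4 variant
constrains the mean rate decrease instead, either to a reference decrease or
to zero (both ± 5 % of the reference magnitude), and tests the Fisher-z
between-day stability distribution.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, not
the biophysics. Foraging is an Ornstein–Uhlenbeck velocity process (mean
speed 10 cm/s, relaxation 1 s, Rayleigh stationary speed distribution)
reflected at the wall, with optional Markov pause bouts (default rate
0.05 s⁻¹, mean 2 s in experiment simulation) so post-immobility epochs exist;
600-s sessions cover > 93 % of the arena. Place cells are inhomogeneous
Poisson processes thinned on a 1-ms grid with Gaussian spatial tuning
(fields drawn inside 0.85 × the arena radius, σ 5–12 cm, peak 2–8 Hz,
baseline 0.02–0.15 Hz — yielding mean rates inside the 0.1–5 Hz activity
band); burstiness is doublet injection at 4–8 ms ISI, which directly controls
the burst-probability statistic; theta phase locking multiplies the rate by a
mean-one von-Mises factor exp(κ cos(φ − μ))/I₀(κ) with κ drawn from 0.1–0.5,
placing per-cell MVLs mostly in the realistic 0–0.2 range. The LFP is 8-, 38-
and 75-Hz carriers (clear of the 48–52-Hz mains-notch region) with slow OU
frequency jitter over 1/f noise, optionally speed-coupled. Phase-locked spike
trains for calibration are rejection-sampled against the analyser's own
filtered phase, so generator and analyser share one phase convention.

Across-day effects are injected per genotype as day-2 multipliers. The rate
multiplier targets the session mean rate: because the in-field contribution
scales with the tuning bump's mass inside the arena, the tuning-curve gain is
compensated by the ratio of truncated-Gaussian masses, decoupling the rate
and tuning-width knobs (injected ×0.7 is recovered as 0.69–0.72 over ~200
cells). A remap fraction redraws field centres on day 2 for stability tests.

What the generator does not emulate — and hence what passing tests do not
establish about real data: theta phase precession, speed/acceleration rate
modulation, interneurons, cluster drift and sorting errors, non-Poisson
refractory structure beyond doublets, cross-frequency coupling, and
behavioural state changes within sessions.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled problem sizes chosen for quick,
stable runs: effect recovery uses 8 animals × 25 cells × 600-s sessions
(~30 s), calibration suites use 1000–2000 replicates, and LFP tests run at
1200 Hz (ample for a 102-Hz analysis ceiling) while the generator's default
remains 4.8 kHz. Determinism: every stochastic routine takes a seed or
Generator; experiment simulation derives independent per-animal streams from
one master seed. Degenerate inputs raise typed errors (`ValidationError`,
`FormatError`, `FeasibilityError`) rather than returning silent zeros; the
few places a quantity is legitimately undefined (isolation distance with too
few non-cluster spikes, phase locking with too few spikes) return flagged
NaN/insufficient results so downstream tables stay rectangular.
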