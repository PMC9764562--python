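# placecode

Analysis pipeline for hippocampal CA1 place-cell and local-field-potential
recordings from repeated sessions in a novel open-field environment, together
with a synthetic-session generator that provides ground truth for every stage.

It is written for in vivo electrophysiologists who record foraging rodents
with tetrodes: the inputs are per-session position samples (50 Hz), sorted
spike trains with per-spike waveform features, and one LFP channel (4.8 kHz);
the outputs are tidy per-cell metric tables ready for mixed-model software.

## What it computes

**Spatial tuning.** Firing-rate maps on 2.5-cm bins by Gaussian-kernel density
ratio, λ(x) = Σᵢ g(‖Sᵢ − x‖/h) / ∫ g(‖y(t) − x‖/h) dt with g(u) = exp(−u²/2)
and h = 2.5 cm; Skaggs spatial information SI = Σ Pᵢ (Rᵢ/R) log₂(Rᵢ/R)
bits/spike; sparsity (ΣPᵢRᵢ)²/ΣPᵢRᵢ²; place fields (≥ 9 contiguous bins above
20 % of the map peak); percent active bins; and between-session map stability
as Fisher-z-transformed Pearson correlations, restricted to cells with
SI > 0.5 bits/spike in both sessions.

**Unit metrics.** Isolation distance (squared Mahalanobis distance of the
n_c-th closest non-cluster spike), L-ratio (χ² tail mass of non-cluster
spikes / n_c), pyramidal classification (Iso-D > 15, L-ratio < 0.2, waveform
width > 250 µs, movement-masked rate < 5 Hz), the 0.1–5 Hz activity criterion,
and burst probability N_B/(N_B + N_S) with bursts defined by ISIs < 10 ms.

**LFP.** Theta (6–12 Hz), slow-gamma (30–45 Hz) and medium-gamma (55–100 Hz)
power from a DPSS multitaper spectrogram of post-immobility activity epochs,
Welch band power per 500-ms epoch stratified by running speed, and spike–LFP
phase locking: zero-phase FIR band-pass, Hilbert phase referenced to the
oscillation trough (0°), spikes restricted to strong-oscillation epochs
(> mean + 2 SD of band power), mean resultant vector length r = |Σⱼ e^{iθⱼ}|/N
with a Rayleigh uniformity test.

**Statistics.** Watson–Williams and Harrison–Kanji circular tests,
two-proportion z-tests with Benjamini–Hochberg FDR correction, and the
firing-rate-constrained down-sampling control: 1000 thirty-cell subsamples
matched to a target mean rate (±5 %), with the fraction differing from the
full population reported as the probability that a metric change is secondary
to a rate change.

## Worked example

```python
import numpy as np
from placecode.synth import EffectSpec, simulate_experiment
from placecode.pipeline import run_experiment

datasets, truth = simulate_experiment(
    [EffectSpec("WT", rate_multiplier_day2=0.7, sigma_multiplier_day2=0.7)],
    n_animals_per_genotype=2, cells_per_animal=12,
    session_duration=300.0, include_lfp=False, seed=2024)
res = run_experiment(datasets, compute_lfp=False)
m = res["cells"][res["cells"].is_active].groupby("day")[
    ["rate_hz", "si_bits_per_spike"]].mean()
print(m)
```

prints

```
      rate_hz  si_bits_per_spike
day
1    0.903209           1.318470
2    0.647489           1.924808
```

i.e. the pipeline recovers the injected day-2 structure: the mean firing rate
drops by the injected ×0.7 (0.647/0.903 ≈ 0.72) while spatial information
rises by ~0.6 bits/spike, because narrower place fields concentrate the same
spikes in fewer bins. The numbered drivers under `analysis/` run the same
machinery step by step (simulation, behaviour, unit quality, spatial tuning,
LFP/phase locking, down-sampling control) and write their tables under
`results/`.

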