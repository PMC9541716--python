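# pacemap

Analysis of spontaneous electrical activity and stretch responses in
cardiomyocyte monolayer cultures recorded on stretchable microelectrode
arrays (sMEAs).

Disc-shaped monolayers of ventricular myocytes beat spontaneously, like a
natural cardiac pacemaker: excitations originate at shifting peripheral
foci and propagate across the culture, and the interbeat-interval (IBI)
series shows power-law (fractal) beat-rate variability resembling heart
rate variability in vivo. `pacemap` implements the complete analysis chain
for 12-electrode sMEA recordings of such preparations — and a
ground-truthed simulator of the same recordings — for electrophysiologists
and biosignal analysts who want to quantify pacemaker complexity and
mechano-electrical feedback without hand-curating events.

## What it computes

* **Activation detection** — each unipolar electrogram is median-filtered
  (3 samples), AC-coupled (first-order high pass, τ = 3 ms) and low-pass
  filtered with a zero-phase Kaiser FIR; local activation is the minimum of
  the centred-difference first derivative, with fractionated downstrokes
  fused by a derivative-magnitude-weighted mean within 1 ms.
* **Beats and rates** — events cluster into beats by a maximal-gap rule;
  the per-beat mean activation time mᵢ = (1/N) Σⱼ tᵢⱼ defines the IBI
  series; the instantaneous beat rate (IBR) is resampled at 2 Hz by exact
  integration of f(t) = 1/(mᵢ₊₁ − mᵢ), so that Σ rᵢ·Δt counts the IBIs.
* **Spatial patterns** — per beat, the slowness vector s⃗ = (sₓ, s_y) is
  the least-squares plane fit tᵢⱼ = tᵢ₀ + sₓxⱼ + s_y yⱼ; conduction
  velocity is v⃗ = s⃗/‖s⃗‖². Pattern variability is quantified by Shannon
  entropy of the 2-D slowness-tip histogram (0.005 s/cm bins) and by PCA
  of the mean-offset activation times.
* **Temporal fractality** — detrended fluctuation analysis (DFA) of the
  IBI series over segment lengths 4–128; α = 0.5 for white noise, ≈1 for
  1/f noise, 1.5 for Brownian noise.
* **Stretch response** — motor pulses on the event channel time-stamp each
  stretch/release; the IBR is aligned on motor start, normalised to the
  mean rate in the 5 s before the movement and averaged over repeats; the
  peak is the bin ending at the first bin edge at/after motor end.
  Strain-geometry arithmetic (areal strain 100·((1+εₓₓ)(1+ε_yy)−1)) is
  included.
* **Statistics** — Shapiro–Wilk-gated paired/one-sample t or Wilcoxon
  signed-rank tests (normal approximation, no continuity correction), and
  Spearman rank correlations with a quantile–quantile density map.
* **Simulator** — competing peripheral pacemaker foci modelled as phase
  clocks with winner-resets-all entrainment, 1/f-family log-period noise
  with a tunable DFA exponent, radial propagation, biphasic electrogram
  templates with a sub-millisecond downstroke, noise floor, drift and
  stretch-protocol modulation — with full ground truth for validation.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from pacemap import (SimulationConfig, StretchProtocolSpec,
                     simulate_recording, analyze_recording)

prot = StretchProtocolSpec(n_repeats=2, hold_duration=30.0,
                           release_duration=30.0, start_offset=20.0)
cfg = SimulationConfig(duration=150.0, stretch_protocol=prot, seed=0)
rec, truth = simulate_recording(cfg)
report = analyze_recording(rec)

print(f"beats detected        : {report.n_beats} (simulated: {len(truth.beat_times)})")
print(f"mean IBI              : {report.mean_ibi:.3f} s")
print(f"DFA alpha             : {report.dfa_alpha:.2f}")
print(f"slowness entropy      : {report.entropy:.2f} nats over {report.entropy_occupied_bins} bins")
print(f"PCA var (2 components): {100*report.pca_cumulative_two:.1f} %")
print(f"stretch peak response : {report.epochs['stretch']['mean_peak']:.2f}-fold")
print(f"release peak response : {report.epochs['release']['mean_peak']:.2f}-fold")
```

prints

```
beats detected        : 244 (simulated: 221)
mean IBI              : 0.614 s
DFA alpha             : 0.85
slowness entropy      : 1.74 nats over 10 bins
PCA var (2 components): 99.4 %
stretch peak response : 1.79-fold
release peak response : 1.28-fold
```

Every simulated beat is recovered as a spatially *eligible* beat (≥4
electrodes); the surplus over the simulated count are rare
threshold-grazing noise detections that appear as single-electrode beats —
the automated stand-in for what manual curation would delete. The DFA
exponent above 0.5 reflects the fractal log-period noise driving the
simulated foci; the two leading principal components carry nearly all
pattern variance because wavefronts are planar at the array scale; and the
stretch/release peaks approach the simulator's rate gains (2.0 and 1.4),
reduced by bin-averaging over the 2-s motor ramp.

The same chain is scriptable from a shell:

```bash
pacemap simulate --seed 1 --duration 120 --stretch --out rec.h5
pacemap detect   --in rec.h5 --out events.csv
pacemap beats    --events events.csv --out beats.csv --ibr ibr.csv
pacemap dfa      --ibi beats.csv --out dfa.json
pacemap stretch  --in rec.h5 --kind stretch --out epoch.json
```

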