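# opcephys

Analysis of the passive bioelectrical properties of oligodendrocyte
precursor cells (OPCs) from whole-cell voltage-clamp recordings, together
with a matched biophysical simulator.

Cortical OPCs split into two electrophysiological states: a
low-conductance state and a high-conductance state dominated by inwardly
rectifying K⁺ (Kir) channels. High-state cells sit near dense clusters of
neuronal somata, are hyperpolarized, have low membrane resistance, and
respond to activity-driven rises in extracellular K⁺ with slow inward
currents (SLICs) whose amplitude is set by the cell's own membrane
resistance rather than by the size of the K⁺ transient. This package
implements the complete quantitative chain behind those observations, for
electrophysiologists who want a tested, scriptable version of it:

- **Passive-property extraction** (`opcephys.traces`): series resistance
  Rs and capacitance Cm from the capacitive transient (single-exponential
  fit with back-extrapolated peak), steady-state I/V curves, resting
  membrane potential by zero-current interpolation, and the *inward
  conductance* g_in — the slope of the I/V between the most hyperpolarized
  tested potential and the K⁺ equilibrium potential
  E_K = (RT/F)·ln([K⁺]ₑ/[K⁺]ᵢ). Recording inclusion criteria (leak
  < 500 pA, Rs bounds) are applied as QC.
- **Conductance-state classification** (`opcephys.population`): histogram
  of log₁₀ g_in fitted with one vs two Gaussian curves (weighted least
  squares), compared by the extra-sum-of-squares F-test and AICc; the
  state boundary is the low component's 90th percentile (≈2.35 nS in the
  reference cortical cohort).
- **SLIC analysis** (`opcephys.slic`): detection by low-pass filter +
  rolling-median baseline + MAD threshold, duration-based separation from
  fast synaptic-like currents, the Nernst prediction
  ΔI = (1/Rm)·(RT/F)·ln([K⁺]′ₑ/[K⁺]ₑ), amplitude regressions on cell
  covariates, OPC–field-potential latency pairing, and percent-block
  statistics for pharmacology.
- **K⁺-selective microelectrodes** (`opcephys.kism`): log-linear
  calibration (Nernstian acceptance at >50 mV/decade), reference-electrode
  subtraction and voltage→[K⁺]ₑ inversion, and Henderson liquid-junction
  potentials from built-in ionic mobilities.
- **Simulator** (`opcephys.simulate`): an RC + Kir + delayed-rectifier
  membrane model integrated by exponential Euler at 50 kHz under the
  −134…+26 mV step protocol; cohort generation from a two-component
  log-normal conductance mixture with conductance-linked cell-cycle,
  proliferation and neuron-density labels; three-channel SLIC sessions
  (holding current, field potential, ISM voltage) with ground truth.

## Worked example

```python
import numpy as np
from opcephys.simulate import (PopulationSpec, iter_population, ActivityScenario,
                               session_cell, simulate_slic_session, draw_conductances)
from opcephys.traces import analyze_bundle
from opcephys.slic import detect_events
from opcephys.population import fit_conductance_mixture, state_threshold

for bundle, gt in iter_population(PopulationSpec(n_cells=4), seed=42):
    p = analyze_bundle(bundle)
    print(f"{p.cell_id}: RMP {p.rmp_mv:6.1f} mV  Rm {p.rm_mohm:6.1f} MOhm  "
          f"g_in {p.g_in_ns:5.2f} nS (true {gt['g_in_true_ns']:5.2f})")

rng = np.random.default_rng(42)
g, _ = draw_conductances(PopulationSpec(), rng, 264)
fit = fit_conductance_mixture(g)
thr, _ = state_threshold(fit)
print(f"two-Gaussian preferred: F={fit.f_statistic:.1f}, p={fit.p_value:.2e}")
print(f"state threshold: {thr:.2f} nS")

scenario = ActivityScenario.cortical(180.0, seed=rng)
sess = simulate_slic_session(session_cell(rm_mohm=185.0), scenario, 180.0, seed=rng)
series = detect_events(sess.current_pa, sess.sampling_rate_hz)
amps = [e.amplitude_pa for e in series.slics]
print(f"SLICs: {len(series.slics)} in 180 s ({series.rate_hz:.3f} Hz), "
      f"mean amplitude {np.mean(amps):.1f} pA")
```

prints

```
cortex-0000: RMP  -91.6 mV  Rm  220.1 MOhm  g_in  3.91 nS (true  3.91)
cortex-0001: RMP  -92.9 mV  Rm  144.0 MOhm  g_in  5.80 nS (true  5.79)
cortex-0002: RMP  -78.3 mV  Rm 1077.9 MOhm  g_in  0.89 nS (true  0.88)
cortex-0003: RMP  -94.0 mV  Rm  107.6 MOhm  g_in  7.00 nS (true  6.99)
two-Gaussian preferred: F=10.8, p=1.32e-03
state threshold: 2.61 nS
SLICs: 11 in 180 s (0.061 Hz), mean amplitude 34.7 pA
```

The extracted g_in matches each cell's generative value (the estimator is
validated to <1% at zero noise); the mixture comparison rejects the
single-Gaussian model on a 264-cell cohort and places the state boundary
near the 2.35 nS anchor; and the detected SLICs have the slow (~0.06 Hz)
low-amplitude (tens of pA) character expected of K⁺-driven inward currents
in a 185 MΩ cell.

Every stage is also available from the shell:

```bash
opcephys simulate --n-cells 24 --out cohort/
opcephys analyze-traces cohort/* --out properties.csv
opcephys classify-population properties.csv
opcephys report --out run/       # full simulate→analyze→classify→report run
```

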