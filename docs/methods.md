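# Methods

This note documents the models, estimators and numerical choices behind
`opcephys`, and what the synthetic validation does and does not establish.

## Membrane model and integration

A recorded OPC is modeled as a single compartment seen through an access
resistance Rs:

    Cm dVm/dt = (Vcmd − Vm)/Rs − Im(Vm)
    Im(V) = g_leak (V − E_leak)
          + g_kir f_kir(V) (V − E_K)
          + g_out f_out(V) (V − E_K)

with instantaneous Boltzmann gates
f_kir(V) = 1/(1 + exp((V − E_K − V½)/k_kir)) and a rising f_out for the
delayed-rectifier component. The recorded current is (Vcmd − Vm)/Rs.

Units are chosen to be mutually consistent (mV, pA, nS, pF, ms), so
τ = Cm/g_total falls out in ms with no conversion factors.

**Kir gate convention.** The default gate half-point sits at +300 mV
relative to E_K, far above the tested voltage range, so the gate is open
throughout and the K⁺ current is passive/ohmic — the phenotype of
high-conductance OPCs, whose inward currents scale linearly with voltage.
A gate centered at E_K would sit near f ≈ 0.5 across the inward limb and
the measured slope could never report g_leak + g_kir. Classic inward
rectification (inward-limb conductance ≫ outward) is obtained by moving
V½ toward 0 and steepening k_kir (e.g. V½ = +10 mV, k = 8 mV), and is
exercised in the tests.

**Integration.** Exponential Euler at the 20 µs sampling interval: at each
step the gates are frozen at the current Vm, giving a locally linear ODE
that is propagated exactly. For the pure RC cell the scheme is exact to
rounding (validated against the two-resistor closed form at <10⁻⁶
relative error), and it is unconditionally stable for this stiff,
linear-dominated system. Non-finite state aborts with an explicit error.

**SLIC sessions** are computed quasi-statically: the membrane time
constant (a few ms) is far below the K⁺-transient timescales (≥50 ms), so
the holding current follows the instantaneous clamp solution with
E_K(t) = (RT/F)·ln([K⁺]ₑ(t)/[K⁺]ᵢ). By default the series resistance is
treated as fully compensated (`ideal_clamp=True`), which is what allows
detected amplitudes to be compared against the Rs-free ΔI formula; an
uncompensated quasi-static solve is available.

## Synthetic cohorts: what they emulate

The generator reproduces the statistical structure the analysis assumes,
with these study conditions as defaults:

- **Conductance mixture**: log₁₀ g_in from two Gaussian components,
  σ = 0.20/0.20 (log₁₀ nS), the low component anchored so its 90th
  percentile is 2.35 nS (μ₁ ≈ 0.115) and the high component at μ₂ = 0.80
  (median ≈ 6.3 nS), i.e. ≈3.4 pooled-σ separation — a clearly bimodal
  population curve. Equal weights.
- **Per-cell calibration**: g_kir is solved (bracketed root find on the
  analytic steady-state I/V, including Rs loading) so that the *measured*
  inward-limb slope equals the drawn g_in; infeasible draws are rejected
  and redrawn with a count.
- **Recording parameters**: Rs ~ N(32, 5) MΩ (uncompensated), Cm ~ N(42.1, 6)
  pF for cells in high neuron-density territory and N(26, 6) pF otherwise,
  leak g_leak = 0.2 + 0.1·g_in nS reversing at −30 mV, current noise
  5 pA RMS.
- **Labels**: neuron counts in an 80 µm territory are Poisson with mean 3
  (low component) or 9 (high); P(G1/G0) rises logistically with log g_in
  from 0.3 to 0.9; P(proliferation-marker⁺) is 0.25 in the low state and
  0.08 in the high state.
- **Activity**: K⁺ transients as difference-of-exponentials (rise 50 ms /
  decay 500 ms cortical; 0.5 s / 5 s hippocampal — the paperless kinetics
  are tunable assumptions), peak Δ[K⁺]ₑ uniform on 0.14–1.32 mM, Poisson
  times at 0.09 Hz with a 3 s dead time (network discharges are followed
  by seconds of recovery; overlapping transients would also make
  event-level ground truth ill-defined). Field-potential deflections
  precede each K⁺ peak by 20 ms. The ISM channel carries the
  calibration-forward voltage *plus* the field potential, so reference
  subtraction is required downstream. Sessions default to 10 kHz.
- **Amplitude cohorts** (for the regression analyses): per-cell Rm
  log-uniform on 50–1000 MΩ; the K⁺ rise reaching the cell differs from
  the ISM reading by a log-normal coupling factor (σ_ln = 0.5; electrodes
  sit 30–180 µm from the soma), and measured amplitudes carry 2 pA
  additive noise. Default: 16 cells, 180 s sessions.

What passing tests do **not** show about real data: the generator has no
electrode drift, no seal instability, no space-clamp error, no K⁺
diffusion or spatial structure, white (not 1/f) noise, and exactly
Gaussian mixture components. Estimator accuracy on real recordings will
be bounded below by these effects.

## Estimators

- **Capacitive transient**: the decay after the step closest to 20 mV
  below holding is fitted with I(t) = I_ss + A·e^(−t/τ) (Levenberg–
  Marquardt; the decay tail is decimated to ≈2500 points for speed, which
  leaves the least-squares solution unchanged at zero noise). The peak is
  back-extrapolated to onset: Rs = ΔV/I_peak, R_input = ΔV/I_ss − Rs,
  Cm = τ(Rs + R_in)/(Rs·R_in). Non-decaying or negative-resistance fits
  return flags, not numbers.
- **Steady-state I/V**: mean current over the last 50 ms of each step
  (≫ τ for all plausible cells). Command potentials are shifted by the
  −14 mV junction correction only when a bundle is marked uncorrected.
- **RMP**: linear interpolation between the I/V points bracketing zero
  current; a current-clamp baseline, when present, takes precedence
  upstream. No crossing → QC flag.
- **Inward conductance**: least-squares slope over points in
  [v_min, E_K), v_min defaulting to the most hyperpolarized sampled
  potential. With the default protocol and E_K ≈ −100.8 mV only two
  sampled potentials lie below E_K, so the window is extended upward to
  the nearest potential above E_K to reach three points (recorded in the
  output); for near-ohmic cells this leaves the slope unchanged. E_K
  always comes from solution metadata via the Nernst relation, never a
  constant.
- **SLIC detector**: 4th-order zero-phase Butterworth low-pass (20 Hz),
  rolling-median baseline (10 s window, computed on a ~50 Hz decimated
  copy), noise σ = 1.4826·MAD of the residual, threshold 4σ below
  baseline with half-threshold hysteresis (a decaying tail hovering at
  threshold is not split), 200 ms merge gap, and a 200 ms half-amplitude
  duration separating SLICs from synaptic-like events. Amplitudes are
  baseline-to-peak on the filtered trace (primary) with the raw-trace
  value reported alongside.
- **Amplitude regressions** are performed across cells: per-event Δ[K⁺]ₑ
  values (nearest ISM peak) are averaged within cell, and mean SLIC
  amplitude is regressed on Rm, g_in and mean Δ[K⁺]ₑ by OLS. The
  cohort-level question is whether amplitude tracks the cell or the K⁺
  rise; a pooled per-event regression of amplitude on Δ[K⁺]ₑ is
  significantly positive *by construction* whenever amplitudes follow the
  ΔI model, so it cannot distinguish the two hypotheses.

## Mixture-model comparison

log₁₀ g_in is histogrammed with √n bins. Freedman–Diaconis binning was
rejected: on bimodal cohorts of n ≈ 264 the IQR spans both modes and
yields only 8–10 bins, leaving 2–4 denominator degrees of freedom and
roughly 60% power. One- and two-Gaussian curves are fitted by weighted
least squares (per-bin σ = √max(count, 1), the Poisson scale), the
two-Gaussian fit from three starting points keeping the best; component σ
is bounded below by one bin width so a component cannot collapse onto a
single bin. Models are compared with the extra-sum-of-squares F-test
(3 numerator df, n_bins − 6 denominator df) at α = 0.05, and by AICc on
the same weighted sums. Calibration measured by simulation: null
rejection ≈ 0.05–0.06, power ≈ 0.99 at the default separation, median
threshold-recovery error ≈ 8% of the 2.35 nS anchor.

The printed threshold statement ("the 90th percentile where the two
curves merge") is read as the low component's 90th percentile,
10^(μ₁ + z₀.₉σ₁); the high component's symmetric reading
10^(μ₂ − z₀.₉σ₂) is computed alongside and the discrepancy reported, since
the two coincide only when the components are percentile-symmetric about
the boundary. R² is reported unweighted for comparability with
curve-fitting software output.

## Junction potentials

The Henderson equation is evaluated over explicit ion lists with a
built-in table of limiting equivalent conductivities (25 °C scale;
organic anions use conventional junction-calculator values), overridable
per solution. Sign convention: pipette minus bath, validated against the
Lewis–Sargent closed form for single-salt junctions. Recipe conventions
for the standard solutions: HEPES 50% anionic near its pKa, BAPTA fully
tetra-anionic, MgATP as free Mg²⁺ + ATP²⁻, GTP²⁻, Lucifer yellow²⁻, and
the KOH/NaOH titration recovered by charge balance. Under these
conventions the K-gluconate internal against HEPES-aCSF computes to
−15.7 mV at 295 K; the temperature for the conventional −14 mV correction
is not pinned down, and the computed value is insensitive (±0.1 mV) to
the HEPES ionization fraction and the ATP charge convention.

## Degenerate inputs and tie-breaks

Identical solutions give exactly 0 mV (the Henderson prefactor is taken
as 0/0 → 0). Calibration fits refuse duplicate-only concentration sets;
voltage inversion refuses |slope| < 1 mV/decade and warns below the
Nernstian criterion. Mixture components are ordered μ₁ < μ₂ after
fitting. Event series with no supra-threshold samples return an empty
series, and percent block with a zero pre-rate is flagged undefined
rather than clipped. QC thresholds are strict inequalities on the printed
bounds (leak 499 pA passes, 501 fails).

## Problem sizes

Validation runs use 100-cell cohorts for parameter recovery, 500/200/100
replicates for mixture calibration/power/threshold recovery, 8 × 150 s
sessions for detector sensitivity, and 100 seeded 16-cell cohorts for the
regression pattern — sizes at which the Monte-Carlo error is small
relative to each acceptance band.

## Known limitations

- The transient-fit algorithm reconstructs a standard single-exponential
  procedure; the original acquisition scripts it stands in for are not
  publicly specified, so agreement is established only against the
  simulator.
- The detector is tuned for slow, sparse events on stationary baselines;
  dense event trains or strong drift would require different baseline
  tracking.
- Junction potentials ignore activity coefficients and temperature
  dependence of mobilities.
- The FP channel is phenomenological (Gaussian deflections); no spike
  content or waveform analysis is supported.
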