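"""Biophysical simulator for OPC voltage-clamp data with known ground truth.

The membrane model is a single-compartment cell recorded through an access
resistance Rs:

    Cm dVm/dt = (Vcmd - Vm)/Rs - Im(Vm)
    Im(V) = g_leak (V - E_leak) + g_kir f_kir(V) (V - E_K) + g_out f_out(V) (V - E_K)

with an inward-rectifier gate f_kir(V) = 1/(1 + exp((V - E_K - V_half)/k))
and a rising Boltzmann f_out for the delayed-rectifier component. The gates
are instantaneous, so with g_kir = g_out = 0 the cell is a plain RC circuit
and the integrator (exponential Euler at the sampling interval) is exact.
A large rectification slope k (default 50 mV) produces the near-ohmic
"passive" K+ current phenotype of high-conductance OPCs.

Population, SLIC-session and electrode-calibration generators emulate the
measured statistical structure of cortical OPC cohorts: a two-component
log-normal mixture of inward conductances meeting at ~2.35 nS, extracellular
K+ transients of 0.14-1.32 mM driving slow inward currents at ~0.09 Hz with
~35 pA mean amplitude, and conductance-correlated cell-cycle, proliferation
and neuron-density labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .bundles import StepProtocol, SweepBundle
from .constants import (
    DEFAULT_K_IN_MM,
    DEFAULT_K_OUT_MM,
    ROOM_TEMPERATURE_K,
    thermal_voltage_mv,
)
from .kism import KismCalibration, theoretical_nernst_slope

__all__ = [
    "MembraneModelParams",
    "ActivityScenario",
    "PopulationSpec",
    "SlicSession",
    "SimulationError",
    "simulate_voltage_clamp",
    "simulate_population",
    "iter_population",
    "simulate_slic_session",
    "simulate_kism_calibration",
    "simulate_amplitude_cohort",
    "draw_conductances",
]


class SimulationError(RuntimeError):
    """Raised when an integration produces non-finite state."""


def _nernst_mv(k_out_mm, k_in_mm, temperature_k):
    return thermal_voltage_mv(temperature_k) * np.log(np.asarray(k_out_mm) / k_in_mm)


@dataclass(frozen=True)
class MembraneModelParams:
    """Parameters of the recorded-cell model (units per :mod:`.constants`)."""

    rs_mohm: float = 15.0
    cm_pf: float = 30.0
    g_leak_ns: float = 0.5
    e_leak_mv: float = -30.0
    g_kir_ns: float = 3.0
    # Kir gate half-point relative to E_K. The default sits far positive of
    # the tested voltage range, leaving the gate open throughout and giving
    # the passive (ohmic) K+ current of high-conductance OPCs; moving it
    # toward 0 with a small k_kir produces classic inward rectification.
    v_half_kir_mv: float = 300.0
    k_kir_mv: float = 50.0
    g_out_ns: float = 0.0
    v_half_out_mv: float = -20.0
    k_out_mv: float = 12.0
    e_k_mv: float = -100.8

    def __post_init__(self) -> None:
        if self.rs_mohm <= 0 or self.cm_pf <= 0:
            raise ValueError("Rs and Cm must be positive")
        if min(self.g_leak_ns, self.g_kir_ns, self.g_out_ns) < 0:
            raise ValueError("conductances must be non-negative")
        if self.k_kir_mv <= 0 or self.k_out_mv <= 0:
            raise ValueError("Boltzmann slopes must be positive")

    def f_kir(self, v_mv):
        return 1.0 / (1.0 + np.exp((np.asarray(v_mv) - self.e_k_mv - self.v_half_kir_mv) / self.k_kir_mv))

    def f_out(self, v_mv):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v_mv) - self.v_half_out_mv) / self.k_out_mv))

    def membrane_current(self, v_mv, e_k_mv=None):
        """Instantaneous membrane current Im(V) in pA (outward positive)."""
        e_k = self.e_k_mv if e_k_mv is None else e_k_mv
        v = np.asarray(v_mv, dtype=float)
        i = self.g_leak_ns * (v - self.e_leak_mv)
        i = i + self.g_kir_ns * self.f_kir(v) * (v - e_k)
        i = i + self.g_out_ns * self.f_out(v) * (v - e_k)
        return i

    def resting_potential(self) -> float:
        """Zero of Im(V), mV."""
        return float(brentq(lambda v: self.membrane_current(v), -250.0, 150.0))

    def clamp_steady_state(self, v_cmd_mv: float) -> tuple[float, float]:
        """(Vm, recorded current) at steady state under command ``v_cmd_mv``."""
        g_s = 1000.0 / self.rs_mohm
        f = lambda v: g_s * (v_cmd_mv - v) - self.membrane_current(v)
        vm = brentq(f, -400.0, 300.0)
        return vm, g_s * (v_cmd_mv - vm)


def _integrate_clamp(params_list, cmds, dt_ms):
    """Exponential-Euler integration of the clamp equation.

    params_list : list of MembraneModelParams, one per batch row
    cmds : (B, T) command waveforms, mV
    Returns recorded currents (B, T) in pA.
    """
    B, T = cmds.shape
    get = lambda attr: np.array([getattr(p, attr) for p in params_list])
    g_s = 1000.0 / get("rs_mohm")
    cm = get("cm_pf")
    g_leak, e_leak = get("g_leak_ns"), get("e_leak_mv")
    g_kir, vh_kir, k_kir = get("g_kir_ns"), get("v_half_kir_mv"), get("k_kir_mv")
    g_out, vh_out, k_out = get("g_out_ns"), get("v_half_out_mv"), get("k_out_mv")
    e_k = get("e_k_mv")

    # start from the true steady state at the initial command
    v = np.array([p.clamp_steady_state(c)[0] for p, c in zip(params_list, cmds[:, 0])])
    out = np.empty((B, T))
    out[:, 0] = g_s * (cmds[:, 0] - v)
    for n in range(1, T):
        drive = cmds[:, n - 1]
        fk = 1.0 / (1.0 + np.exp((v - e_k - vh_kir) / k_kir))
        fo = 1.0 / (1.0 + np.exp(-(v - vh_out) / k_out))
        g_k = g_kir * fk + g_out * fo
        gtot = g_s + g_leak + g_k
        vinf = (g_s * drive + g_leak * e_leak + g_k * e_k) / gtot
        v = vinf + (v - vinf) * np.exp(-dt_ms * gtot / cm)
        out[:, n] = g_s * (cmds[:, n] - v)
    if not np.all(np.isfinite(out)):
        raise SimulationError("voltage-clamp integration produced non-finite currents")
    return out


def simulate_voltage_clamp(
    params: MembraneModelParams,
    protocol: StepProtocol | None = None,
    noise_rms_pa: float = 0.0,
    seed: int | np.random.Generator = 0,
    cell_id: str = "sim-cell",
    metadata: dict | None = None,
) -> SweepBundle:
    """Simulate one cell's current sweeps under a step protocol.

    Gaussian white noise of the given RMS (pA) is added per sample. The
    ground truth (model parameters, resting potential) is attached to the
    returned bundle.
    """
    protocol = protocol or StepProtocol()
    if noise_rms_pa < 0:
        raise ValueError("noise_rms_pa must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cmds = protocol.command_waveforms()
    n_sweeps = cmds.shape[0]
    sweeps = _integrate_clamp([params] * n_sweeps, cmds, protocol.dt_ms)
    if noise_rms_pa > 0:
        sweeps = sweeps + rng.normal(0.0, noise_rms_pa, sweeps.shape)
    gt = {
        "params": asdict(params),
        "rmp_mv": params.resting_potential(),
        "noise_rms_pa": noise_rms_pa,
    }
    return SweepBundle(
        protocol=protocol,
        sweeps_pa=sweeps,
        cell_id=cell_id,
        metadata={"junction_corrected": True, **(metadata or {})},
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# population generator
# ---------------------------------------------------------------------------

_Z90 = 1.2815515655446004  # standard-normal 90th percentile

# Default mixture in log10 nS, anchored so that the low component's 90th
# percentile equals 2.35 nS, the conductance at which the fitted population
# curves meet and the state boundary of the reference cortical cohort. The
# high component (median ~6.3 nS) sits ~3.4 pooled-sigma above the low one,
# giving the clearly bimodal population curve seen in that cohort.
_BOUNDARY_NS = 2.35
_SIGMA_LOW, _SIGMA_HIGH = 0.20, 0.20
_MU_LOW = math.log10(_BOUNDARY_NS) - _Z90 * _SIGMA_LOW
_MU_HIGH = 0.80


@dataclass
class PopulationSpec:
    """Generative model for a cohort of OPCs.

    The inward conductance g_in is drawn from a two-component Gaussian
    mixture on log10 nS; membrane parameters are then derived so that the
    slope measured from the simulated steady-state I/V equals the drawn
    g_in. Cell-cycle state (G1/G0 vs G2/M), proliferation-marker
    positivity and surrounding neuron counts are drawn from g_in-dependent
    conditional models, emulating the coupling between conductance state,
    cell cycle and neuronal density.
    """

    n_cells: int = 264
    weights: tuple = (0.5, 0.5)
    mu_log10: tuple = (_MU_LOW, _MU_HIGH)
    sigma_log10: tuple = (_SIGMA_LOW, _SIGMA_HIGH)
    region: str = "cortex"
    age_days: int = 30
    # access resistance and capacitance (means match the recorded cohorts:
    # uncompensated Rs ~32 MOhm; Cm ~42 pF near high neuron density, ~26 pF
    # in low-density territory)
    rs_mean_mohm: float = 32.0
    rs_sd_mohm: float = 5.0
    cm_high_density_pf: float = 42.1
    cm_low_density_pf: float = 26.0
    cm_sd_pf: float = 6.0
    # leak model: g_leak = leak_base + leak_frac * g_in
    leak_base_ns: float = 0.2
    leak_frac: float = 0.1
    e_leak_mv: float = -30.0
    k_kir_mv: float = 50.0
    v_half_kir_mv: float = 300.0
    g_out_ns: float = 0.5
    # conditional label models
    p_g1g0_low: float = 0.3
    p_g1g0_high: float = 0.9
    cycle_scale_log10: float = 0.2
    p_edu_low_state: float = 0.25
    p_edu_high_state: float = 0.08
    neuron_lambda: tuple = (3.0, 9.0)  # Poisson mean per mixture component
    territory_diameter_um: float = 80.0
    noise_rms_pa: float = 5.0
    k_out_mm: float = DEFAULT_K_OUT_MM
    k_in_mm: float = DEFAULT_K_IN_MM
    temperature_k: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if min(self.sigma_log10) < 0:
            raise ValueError("mixture sigmas must be non-negative")

    @property
    def e_k_mv(self) -> float:
        return float(_nernst_mv(self.k_out_mm, self.k_in_mm, self.temperature_k))

    @property
    def analytic_boundary_ns(self) -> float:
        """Conductance where the low component's 90th percentile meets the
        high component's 10th percentile (the state threshold the mixture
        analysis should recover)."""
        return 10.0 ** (self.mu_log10[0] + _Z90 * self.sigma_log10[0])


def draw_conductances(spec: PopulationSpec, rng: np.random.Generator, n: int | None = None):
    """Draw (g_in nS, component index) from the mixture."""
    n = spec.n_cells if n is None else n
    comp = rng.choice(len(spec.weights), size=n, p=np.asarray(spec.weights))
    mu = np.asarray(spec.mu_log10)[comp]
    sd = np.asarray(spec.sigma_log10)[comp]
    g = 10.0 ** rng.normal(mu, sd)
    return g, comp


def _measured_inward_slope(params: MembraneModelParams, potentials, e_k: float) -> float:
    """Slope (nS) the steady-state I/V analysis would report for this cell."""
    from .traces import inward_window_mask  # late import; traces has no dep on simulate

    potentials = np.asarray(potentials, dtype=float)
    currents = np.array([params.clamp_steady_state(v)[1] for v in potentials])
    mask = inward_window_mask(potentials, e_k, potentials.min())
    return float(np.polyfit(potentials[mask], currents[mask], 1)[0])


def _calibrate_cell(
    g_target_ns: float, spec: PopulationSpec, rs: float, cm: float, protocol: StepProtocol
) -> MembraneModelParams | None:
    """Find g_kir so the measured inward-limb slope equals the drawn g_in.

    Returns None when no non-negative g_kir can reach the target (the
    caller then rejects and redraws).
    """
    e_k = spec.e_k_mv
    g_leak = spec.leak_base_ns + spec.leak_frac * g_target_ns

    def make(g_kir):
        return MembraneModelParams(
            rs_mohm=rs, cm_pf=cm, g_leak_ns=g_leak, e_leak_mv=spec.e_leak_mv,
            g_kir_ns=g_kir, k_kir_mv=spec.k_kir_mv, v_half_kir_mv=spec.v_half_kir_mv,
            g_out_ns=spec.g_out_ns, e_k_mv=e_k,
        )

    pots = protocol.step_potentials_mv
    f = lambda g_kir: _measured_inward_slope(make(g_kir), pots, e_k) - g_target_ns
    lo, hi = 0.0, 2.0 * g_target_ns
    if f(lo) > 0:
        return None
    for _ in range(12):
        if f(hi) >= 0:
            return make(brentq(f, lo, hi, xtol=1e-6))
        lo, hi = hi, 2.0 * hi
    return None


def iter_population(spec: PopulationSpec, seed: int, chunk: int = 32):
    """Yield (SweepBundle, ground_truth dict) per cell, in chunks internally
    so that large cohorts never hold all sweeps in memory at once."""
    rng = np.random.default_rng(seed)
    protocol = StepProtocol()
    boundary = spec.analytic_boundary_ns
    n_rejected = 0
    produced = 0
    while produced < spec.n_cells:
        m = min(chunk, spec.n_cells - produced)
        cells = []
        while len(cells) < m:
            g, comp = draw_conductances(spec, rng, 1)
            g, comp = float(g[0]), int(comp[0])
            rs = float(np.clip(rng.normal(spec.rs_mean_mohm, spec.rs_sd_mohm), 5.0, 60.0))
            neuron_count = int(rng.poisson(spec.neuron_lambda[comp]))
            density = "high" if neuron_count > 5 else "low"
            cm_mean = spec.cm_high_density_pf if density == "high" else spec.cm_low_density_pf
            cm = float(np.clip(rng.normal(cm_mean, spec.cm_sd_pf), 8.0, 120.0))
            params = _calibrate_cell(g, spec, rs, cm, protocol)
            if params is None:
                n_rejected += 1
                continue
            lg = math.log10(g)
            center = 0.5 * (spec.mu_log10[0] + spec.mu_log10[-1])
            p_g1g0 = spec.p_g1g0_low + (spec.p_g1g0_high - spec.p_g1g0_low) / (
                1.0 + math.exp(-(lg - center) / spec.cycle_scale_log10)
            )
            cycle = "G1/G0" if rng.random() < p_g1g0 else "G2/M"
            state = "high" if g > boundary else "low"
            p_edu = spec.p_edu_high_state if state == "high" else spec.p_edu_low_state
            gt = {
                "params": asdict(params),
                "g_in_true_ns": g,
                "component": comp,
                "state": state,
                "boundary_ns": boundary,
                "cycle_label": cycle,
                "edu_positive": bool(rng.random() < p_edu),
                "neuron_count": neuron_count,
                "density_class": density,
                "territory_diameter_um": spec.territory_diameter_um,
                "rmp_mv": params.resting_potential(),
                "rm_true_mohm": 1000.0 * 20.0 / (
                    params.membrane_current(protocol.holding_mv)
                    - params.membrane_current(protocol.holding_mv - 20.0)
                ),
                "region": spec.region,
                "age_days": spec.age_days,
                "n_rejected_so_far": n_rejected,
            }
            cells.append((params, gt))
        cmds = protocol.command_waveforms()
        n_sweeps = cmds.shape[0]
        plist = [p for p, _ in cells for _ in range(n_sweeps)]
        big_cmds = np.tile(cmds, (len(cells), 1))
        currents = _integrate_clamp(plist, big_cmds, protocol.dt_ms)
        if spec.noise_rms_pa > 0:
            currents = currents + rng.normal(0.0, spec.noise_rms_pa, currents.shape)
        for i, (params, gt) in enumerate(cells):
            bundle = SweepBundle(
                protocol=protocol,
                sweeps_pa=currents[i * n_sweeps : (i + 1) * n_sweeps],
                cell_id=f"{spec.region}-{produced:04d}",
                metadata={
                    "junction_corrected": True,
                    "region": spec.region,
                    "age_days": spec.age_days,
                    "k_out_mm": spec.k_out_mm,
                    "k_in_mm": spec.k_in_mm,
                    "temperature_k": spec.temperature_k,
                },
                ground_truth=gt,
            )
            produced += 1
            yield bundle, gt


def simulate_population(spec: PopulationSpec, seed: int):
    """Materialize the whole cohort as a list of (SweepBundle, ground truth)."""
    return list(iter_population(spec, seed))


# ---------------------------------------------------------------------------
# SLIC sessions
# ---------------------------------------------------------------------------


@dataclass
class ActivityScenario:
    """Phenomenological description of network activity during a session.

    K+ transients are difference-of-exponential waveforms added to the
    baseline [K+]e; field-potential deflections precede each K+ peak by
    ``latency_offset_s``; fast synaptic-like currents arrive as an
    independent Poisson process.
    """

    baseline_k_mm: float = DEFAULT_K_OUT_MM
    event_peak_times_s: tuple = ()
    event_dk_mm: tuple = ()
    rise_s: float = 0.05
    decay_s: float = 0.5
    pattern: str = "cortical-fast"
    syn_rate_hz: float = 0.1
    syn_amp_pa: float = 20.0
    syn_decay_s: float = 0.010
    fp_amp_mv: float = 0.5
    fp_width_s: float = 0.05
    latency_offset_s: float = 0.020

    def __post_init__(self) -> None:
        if len(self.event_peak_times_s) != len(self.event_dk_mm):
            raise ValueError("event times and amplitudes must have equal length")
        if any(a < 0 for a in self.event_dk_mm):
            raise ValueError("K+ transient amplitudes must be non-negative")
        if self.latency_offset_s <= 0:
            raise ValueError("latency offset must be positive (FP precedes the OPC event)")
        if self.baseline_k_mm <= 0:
            raise ValueError("baseline [K+]e must be positive")

    @classmethod
    def cortical(
        cls,
        duration_s: float,
        seed: int | np.random.Generator,
        rate_hz: float = 0.09,
        dk_range_mm: tuple = (0.14, 1.32),
        min_separation_s: float = 3.0,
        **kwargs,
    ) -> "ActivityScenario":
        """Fast cortical pattern: K+ transients at ~0.09 Hz with peak
        amplitudes uniform over the detectable 0.14-1.32 mM range.

        Event times follow a Poisson process with a ``min_separation_s``
        dead time: synchronized network discharges are followed by seconds
        of recovery, and the K+ transient itself outlasts the burst.
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n = rng.poisson(rate_hz * duration_s)
        margin = 3.0 * kwargs.get("decay_s", 0.5) + 1.0
        hi = max(duration_s - margin, margin + 1e-6)
        times: list[float] = []
        for _ in range(50 * max(n, 1)):
            if len(times) >= n:
                break
            t = float(rng.uniform(margin, hi))
            if all(abs(t - u) >= min_separation_s for u in times):
                times.append(t)
        times = np.sort(times)
        dk = rng.uniform(*dk_range_mm, len(times))
        return cls(
            event_peak_times_s=tuple(times), event_dk_mm=tuple(dk),
            pattern="cortical-fast", **kwargs,
        )

    @classmethod
    def hippocampal(cls, duration_s, seed, rate_hz=0.05, dk_range_mm=(0.14, 1.32), **kwargs):
        """Slow, sustained hippocampal pattern (rise 0.5 s, decay 5 s)."""
        kwargs.setdefault("rise_s", 0.5)
        kwargs.setdefault("decay_s", 5.0)
        sc = cls.cortical(duration_s, seed, rate_hz, dk_range_mm, **kwargs)
        sc.pattern = "hippocampal-slow"
        return sc


@dataclass
class SlicSession:
    """Aligned three-channel recording plus generator ground truth."""

    time_s: np.ndarray
    current_pa: np.ndarray
    fp_mv: np.ndarray
    ism_mv: np.ndarray
    sampling_rate_hz: float
    holding_mv: float
    calibration: KismCalibration
    ground_truth: dict = field(default_factory=dict)


def _doe_kernel(t_s, rise_s, decay_s):
    """Difference-of-exponentials normalized to unit peak; zero for t<0."""
    if decay_s <= rise_s:
        raise ValueError("decay must exceed rise time constant")
    t = np.asarray(t_s)
    y = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_s) - np.exp(-np.maximum(t, 0) / rise_s), 0.0)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * math.log(decay_s / rise_s)
    peak = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
    return y / peak, t_peak


def simulate_slic_session(
    params: MembraneModelParams,
    scenario: ActivityScenario,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    *,
    sampling_rate_hz: float = 10_000.0,
    holding_mv: float = -74.0,
    noise_rms_pa: float = 5.0,
    fp_noise_rms_mv: float = 0.02,
    calibration: KismCalibration | None = None,
    k_in_mm: float = DEFAULT_K_IN_MM,
    temperature_k: float = ROOM_TEMPERATURE_K,
    ideal_clamp: bool = True,
) -> SlicSession:
    """Simulate a gap-free co-recording: holding current, FP, and ISM voltage.

    Each K+ transient raises [K+]e, shifts E_K via the Nernst relation, and
    deflects the holding current through the full membrane model. The
    membrane time constant (a few ms) is far below the transient
    timescales, so the current follows the quasi-static clamp solution;
    with ``ideal_clamp`` the series resistance is treated as fully
    compensated. The ISM channel carries the calibration-forward transform
    of [K+]e *plus* the field potential, so downstream analysis must
    subtract the reference channel.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / sampling_rate_hz
    t = np.arange(int(round(duration_s / dt))) * dt

    k_e = np.full_like(t, scenario.baseline_k_mm)
    peak_times = np.asarray(scenario.event_peak_times_s, dtype=float)
    dk = np.asarray(scenario.event_dk_mm, dtype=float)
    for t_pk, a in zip(peak_times, dk):
        kern, t_peak = _doe_kernel(t - (t_pk - t_peak_offset(scenario)), scenario.rise_s, scenario.decay_s)
        k_e += a * kern
    if np.any(k_e <= 0):
        raise ValueError("[K+]e must stay positive throughout the session")

    e_k_t = _nernst_mv(k_e, k_in_mm, temperature_k)
    if ideal_clamp:
        current = params.membrane_current(holding_mv, e_k_mv=e_k_t)
    else:
        # quasi-static solve of Vm = Vh - Rs*Im(Vm) by damped fixed-point
        g_s = 1000.0 / params.rs_mohm
        v = np.full_like(t, holding_mv)
        for _ in range(60):
            v_new = holding_mv - params.membrane_current(v, e_k_mv=e_k_t) / g_s
            if np.max(np.abs(v_new - v)) < 1e-10:
                v = v_new
                break
            v = 0.5 * (v + v_new)
        current = g_s * (holding_mv - v)
    baseline_current = float(current[0]) if len(current) else 0.0

    # per-event true amplitude: baseline-to-peak of the noiseless deflection
    true_amp = np.empty(len(peak_times))
    for j, t_pk in enumerate(peak_times):
        idx = np.searchsorted(t, t_pk)
        lo = max(idx - int(0.2 / dt), 0)
        hi = min(idx + int(0.2 / dt) + 1, len(t))
        true_amp[j] = baseline_current - current[lo:hi].min() if hi > lo else np.nan

    # fast synaptic-like inward currents (phenomenological, single exponential)
    n_syn = rng.poisson(scenario.syn_rate_hz * duration_s)
    syn_times = np.sort(rng.uniform(0.0, duration_s, n_syn))
    syn = np.zeros_like(t)
    for ts in syn_times:
        kern, _ = _doe_kernel(t - ts, scenario.syn_decay_s / 10.0, scenario.syn_decay_s)
        syn -= scenario.syn_amp_pa * kern
    current = current + syn

    fp_times = peak_times - scenario.latency_offset_s
    fp = np.zeros_like(t)
    for tf in fp_times:
        fp -= scenario.fp_amp_mv * np.exp(-0.5 * ((t - tf) / scenario.fp_width_s) ** 2)

    cal = calibration or KismCalibration(
        slope=theoretical_nernst_slope(temperature_k), intercept=0.0,
        concentrations_mm=np.array([1.0, 2.0, 10.0, 20.0]),
        voltages_mv=np.array([]), residual_sd=0.0,
    )
    ism = cal.forward(k_e) + fp

    if noise_rms_pa > 0:
        current = current + rng.normal(0.0, noise_rms_pa, current.shape)
    if fp_noise_rms_mv > 0:
        fp = fp + rng.normal(0.0, fp_noise_rms_mv, fp.shape)
        ism = ism + rng.normal(0.0, fp_noise_rms_mv, ism.shape)

    gt = {
        "event_peak_times_s": peak_times.tolist(),
        "event_dk_mm": dk.tolist(),
        "event_amplitude_pa": true_amp.tolist(),
        "fp_peak_times_s": fp_times.tolist(),
        "k_e_baseline_mm": scenario.baseline_k_mm,
        "k_e_series_mm": k_e,
        "syn_times_s": syn_times.tolist(),
        "rm_mohm": 1000.0 / max(params.g_leak_ns + params.g_kir_ns * float(params.f_kir(holding_mv)) + params.g_out_ns * float(params.f_out(holding_mv)), 1e-12),
        "params": asdict(params),
        "baseline_current_pa": baseline_current,
    }
    return SlicSession(t, current, fp, ism, sampling_rate_hz, holding_mv, cal, gt)


def t_peak_offset(scenario: ActivityScenario) -> float:
    """Time from transient onset to its peak for the scenario kinetics."""
    r, d = scenario.rise_s, scenario.decay_s
    return r * d / (d - r) * math.log(d / r)


def session_cell(rm_mohm: float = 185.0, cm_pf: float = 42.0, **overrides) -> MembraneModelParams:
    """Convenience: a near-ohmic high-conductance cell with input resistance
    ``rm_mohm``, the phenotype in which SLICs are recorded."""
    defaults = dict(
        rs_mohm=12.0, cm_pf=cm_pf, g_leak_ns=0.0,
        g_kir_ns=1000.0 / rm_mohm, k_kir_mv=50.0, v_half_kir_mv=500.0,
        g_out_ns=0.0, e_k_mv=-100.8,
    )
    defaults.update(overrides)
    return MembraneModelParams(**defaults)


# ---------------------------------------------------------------------------
# electrode calibration and amplitude cohorts
# ---------------------------------------------------------------------------


def simulate_kism_calibration(
    true_slope_mv: float,
    intercept_mv: float,
    concentrations_mm=(1.0, 2.0, 10.0, 20.0),
    noise_sd_mv: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Synthetic calibration points V = slope*log10(c) + intercept + noise."""
    c = np.asarray(list(concentrations_mm), dtype=float)
    if len(c) == 0:
        raise ValueError("concentration list must not be empty")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = true_slope_mv * np.log10(c) + intercept_mv
    if noise_sd_mv > 0:
        v = v + rng.normal(0.0, noise_sd_mv, v.shape)
    return list(zip(c.tolist(), v.tolist()))


def simulate_amplitude_cohort(
    n_cells: int = 16,
    seed: int | np.random.Generator = 0,
    *,
    rm_range_mohm: tuple = (50.0, 1000.0),
    dk_range_mm: tuple = (0.14, 1.32),
    baseline_k_mm: float = DEFAULT_K_OUT_MM,
    rate_hz: float = 0.09,
    duration_s: float = 180.0,
    coupling_sigma: float = 0.5,
    meas_noise_pa: float = 2.0,
    temperature_k: float = ROOM_TEMPERATURE_K,
):
    """Per-event SLIC amplitudes for a cohort of cells, without traces.

    Each cell has one membrane resistance (log-uniform over the observed
    50-1000 MOhm span) and experiences Poisson K+ transients whose
    ISM-measured peak dK is uniform over the detectable range. The K+ rise
    actually reaching the cell differs from the ISM reading by a log-normal
    coupling factor (electrodes sit 30-180 um from the soma), and the
    measured amplitude carries additive detection noise. Returns a pandas
    DataFrame with one row per event (cell, rm_mohm, g_in_ns, dk_mm,
    amplitude_pa).
    """
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rtf = thermal_voltage_mv(temperature_k)
    rows = []
    for c in range(n_cells):
        rm = float(np.exp(rng.uniform(np.log(rm_range_mohm[0]), np.log(rm_range_mohm[1]))))
        n_ev = max(2, int(rng.poisson(rate_hz * duration_s)))
        dk_ism = rng.uniform(*dk_range_mm, n_ev)
        coupling = np.exp(rng.normal(0.0, coupling_sigma, n_ev))
        dk_cell = dk_ism * coupling
        de_k = rtf * np.log((baseline_k_mm + dk_cell) / baseline_k_mm)
        amp = de_k / rm * 1000.0 + rng.normal(0.0, meas_noise_pa, n_ev)
        for a, k in zip(amp, dk_ism):
            rows.append({"cell": c, "rm_mohm": rm, "g_in_ns": 1000.0 / rm,
                         "dk_mm": float(k), "amplitude_pa": float(a)})
    return pd.DataFrame(rows)
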