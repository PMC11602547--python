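"""Passive-property extraction from voltage-step sweeps.

Implements the whole-cell analysis chain for OPC recordings: capacitive
transient fitting (Rs, Cm, input resistance), steady-state I/V curves,
resting membrane potential by zero-current interpolation, the
inward-conductance slope between the most hyperpolarized potential and the
K⁺ equilibrium potential, and the recording inclusion criteria (leak
current < 500 pA, Rs bounds, baseline stability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .bundles import StepProtocol, SweepBundle
from .constants import thermal_voltage_mv

__all__ = [
    "IVCurve",
    "PassiveProperties",
    "QcCriteria",
    "TransientFit",
    "fit_capacitive_transient",
    "steady_state_iv",
    "resting_potential",
    "inward_conductance",
    "inward_window_mask",
    "apply_qc",
    "nernst_potential",
    "analyze_bundle",
]

#: junction potential applied when a bundle is marked uncorrected, mV
DEFAULT_JUNCTION_OFFSET_MV = -14.0


@dataclass
class IVCurve:
    """Steady-state current/voltage relation (junction-corrected potentials)."""

    potentials_mv: np.ndarray
    currents_pa: np.ndarray
    window_ms: float

    def __post_init__(self) -> None:
        self.potentials_mv = np.asarray(self.potentials_mv, dtype=float)
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        if self.potentials_mv.shape != self.currents_pa.shape:
            raise ValueError("potentials and currents must have equal length")
        if np.any(np.diff(self.potentials_mv) <= 0):
            raise ValueError("potentials must be strictly increasing")


@dataclass
class PassiveProperties:
    """Per-cell passive record: the pipeline's central result row."""

    cell_id: str
    rmp_mv: float | None
    rm_mohm: float | None
    cm_pf: float | None
    rs_mohm: float | None
    leak_pa: float | None
    g_in_ns: float | None
    e_k_mv: float
    baseline_drift_pa_per_min: float | None = None
    qc_flags: list = field(default_factory=list)
    qc_passed: bool | None = None


@dataclass
class QcCriteria:
    """Inclusion criteria. A recording fails when any bound is violated;
    the leak bound is the printed 500 pA criterion."""

    max_leak_pa: float = 500.0
    rs_min_mohm: float = 2.0
    rs_max_mohm: float = 60.0
    max_baseline_drift_pa_per_min: float = 50.0

    def __post_init__(self) -> None:
        if min(self.max_leak_pa, self.rs_min_mohm, self.rs_max_mohm,
               self.max_baseline_drift_pa_per_min) <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class TransientFit:
    rs_mohm: float
    cm_pf: float
    tau_ms: float
    r_input_mohm: float
    i_peak_pa: float
    i_ss_pa: float
    flags: list = field(default_factory=list)


def _single_exp(t, i_ss, a, tau):
    return i_ss + a * np.exp(-t / tau)


def fit_capacitive_transient(
    sweep_pa: np.ndarray,
    protocol: StepProtocol,
    step_potential_mv: float,
    *,
    fit_window_ms: float | None = None,
) -> TransientFit:
    """Estimate Rs, Cm and input resistance from one step's transient.

    A single exponential is fitted to the current decay after step onset;
    the peak is back-extrapolated to the onset, giving
    Rs = ΔV/I_peak, R_input = ΔV/I_ss − Rs and Cm = τ·(Rs+R_in)/(Rs·R_in).
    Raises ValueError when no resolvable transient exists; implausible
    results (negative resistances, non-decaying fit) come back flagged
    with no numeric output.
    """
    sweep = np.asarray(sweep_pa, dtype=float)
    t = protocol.time_ms()
    dv = step_potential_mv - protocol.holding_mv
    if dv == 0:
        raise ValueError("step must differ from the holding potential")
    onset = int(round(protocol.step_start_ms / protocol.dt_ms))
    base_lo = max(onset - int(20 / protocol.dt_ms), 0)
    baseline = float(np.mean(sweep[base_lo:onset])) if onset > base_lo else 0.0
    end = int(round(protocol.step_end_ms / protocol.dt_ms))
    if fit_window_ms is not None:
        end = min(end, onset + int(round(fit_window_ms / protocol.dt_ms)))
    seg = sweep[onset:end] - baseline
    ts = t[onset:end] - t[onset]
    if len(seg) < 10:
        raise ValueError("step transient too short to fit (< 10 samples)")
    if len(seg) > 4000:  # decimate the decay tail; keeps the fit well posed
        stride = len(seg) // 2000
        keep = np.concatenate([np.arange(min(500, len(seg))), np.arange(500, len(seg), stride)])
        keep = np.unique(keep[keep < len(seg)])
        seg, ts = seg[keep], ts[keep]

    i_ss0 = float(np.mean(seg[int(0.8 * len(seg)) :]))
    a0 = float(seg[0] - i_ss0)
    # crude tau guess: first crossing of a0/e
    rel = np.abs(seg - i_ss0)
    below = np.nonzero(rel < abs(a0) / np.e)[0]
    tau0 = ts[below[0]] if len(below) else ts[len(ts) // 4]
    tau0 = max(float(tau0), protocol.dt_ms)
    try:
        popt, _ = curve_fit(
            _single_exp, ts, seg, p0=[i_ss0, a0, tau0],
            bounds=([-np.inf, -np.inf, protocol.dt_ms / 10], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as err:
        return TransientFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                            flags=[f"transient fit failed: {err}"])
    i_ss, a, tau = popt
    flags: list = []
    i_peak = i_ss + a
    if a * dv < 0 or i_peak * dv <= 0:
        flags.append("non-decaying transient")
    r_total = 1000.0 * dv / i_ss if i_ss * dv > 0 else np.nan
    rs = 1000.0 * dv / i_peak if i_peak * dv > 0 else np.nan
    r_input = r_total - rs
    if not np.isfinite(r_input) or r_input <= 0 or not np.isfinite(rs) or rs <= 0:
        flags.append("negative derived resistance")
        return TransientFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, flags=flags)
    cm = 1000.0 * tau * (rs + r_input) / (rs * r_input)
    return TransientFit(float(rs), float(cm), float(tau), float(r_input),
                        float(i_peak), float(i_ss), flags=flags)


def steady_state_iv(
    bundle: SweepBundle,
    window_ms: float = 50.0,
    junction_offset_mv: float = DEFAULT_JUNCTION_OFFSET_MV,
) -> IVCurve:
    """Mean current over the final ``window_ms`` of each step.

    When the bundle metadata marks the recording as not junction-corrected,
    ``junction_offset_mv`` is added to the command potentials (simulated
    bundles are generated in corrected coordinates and pass through
    unchanged).
    """
    proto = bundle.protocol
    if not 0 < window_ms <= proto.step_end_ms - proto.step_start_ms:
        raise ValueError(
            f"window of {window_ms} ms does not fit inside the "
            f"{proto.step_end_ms - proto.step_start_ms} ms step"
        )
    t = proto.time_ms()
    mask = (t >= proto.step_end_ms - window_ms) & (t < proto.step_end_ms)
    currents = bundle.sweeps_pa[:, mask].mean(axis=1)
    pots = np.asarray(proto.step_potentials_mv, dtype=float)
    if not bundle.metadata.get("junction_corrected", True):
        pots = pots + junction_offset_mv
    return IVCurve(pots, currents, window_ms)


def resting_potential(iv: IVCurve) -> tuple[float | None, list]:
    """Zero-current potential by linear interpolation between the bracketing
    I/V points. Returns (RMP, flags); RMP is None when the curve does not
    cross zero."""
    i = iv.currents_pa
    sign_change = np.nonzero(np.diff(np.signbit(i)))[0]
    if len(sign_change) == 0:
        return None, ["no zero-current crossing in I/V"]
    k = sign_change[0]
    v0, v1 = iv.potentials_mv[k], iv.potentials_mv[k + 1]
    i0, i1 = i[k], i[k + 1]
    return float(v0 - i0 * (v1 - v0) / (i1 - i0)), []


def inward_window_mask(
    potentials_mv: np.ndarray, e_k_mv: float, v_min_mv: float, min_points: int = 3
) -> np.ndarray:
    """Boolean mask of I/V points used for the inward-conductance slope:
    potentials in [v_min, E_K). When fewer than ``min_points`` sampled
    potentials fall below E_K, the window is extended upward to the nearest
    potentials above it, so the slope stays defined for protocols whose
    spacing leaves only two points below the equilibrium potential."""
    pots = np.asarray(potentials_mv, dtype=float)
    mask = (pots >= v_min_mv) & (pots < e_k_mv)
    if mask.sum() < min_points:
        candidates = np.nonzero(pots >= v_min_mv)[0]
        if len(candidates) < min_points:
            raise ValueError(
                f"only {len(candidates)} I/V points at or above {v_min_mv} mV; "
                f"need {min_points} for the inward slope"
            )
        mask = np.zeros_like(mask)
        mask[candidates[:min_points]] = True
    return mask


def inward_conductance(
    iv: IVCurve,
    e_k_mv: float,
    v_min_mv: float | None = None,
) -> tuple[float, dict]:
    """Slope (nS) of the least-squares line through the inward-limb points.

    ``v_min_mv`` defaults to the most hyperpolarized sampled potential.
    Returns (g_in, info) where info records the window actually used.
    """
    v_min = float(iv.potentials_mv.min()) if v_min_mv is None else v_min_mv
    mask = inward_window_mask(iv.potentials_mv, e_k_mv, v_min)
    v, i = iv.potentials_mv[mask], iv.currents_pa[mask]
    slope, intercept = np.polyfit(v, i, 1)
    info = {
        "v_min_mv": v_min,
        "e_k_mv": e_k_mv,
        "potentials_used_mv": v.tolist(),
        "extended_above_e_k": bool(v.max() >= e_k_mv),
        "intercept_pa": float(intercept),
    }
    return float(slope), info


def apply_qc(props: PassiveProperties, criteria: QcCriteria) -> tuple[bool, list]:
    """Evaluate inclusion criteria; returns (passed, reasons)."""
    reasons = list(props.qc_flags)
    if props.leak_pa is None or not np.isfinite(props.leak_pa):
        reasons.append("leak current unavailable")
    elif abs(props.leak_pa) >= criteria.max_leak_pa:
        reasons.append(
            f"leak current {abs(props.leak_pa):.0f} pA >= {criteria.max_leak_pa:.0f} pA"
        )
    if props.rs_mohm is None or not np.isfinite(props.rs_mohm):
        reasons.append("series resistance unavailable")
    elif not criteria.rs_min_mohm <= props.rs_mohm <= criteria.rs_max_mohm:
        reasons.append(
            f"Rs {props.rs_mohm:.1f} MOhm outside "
            f"[{criteria.rs_min_mohm}, {criteria.rs_max_mohm}] MOhm"
        )
    if (
        props.baseline_drift_pa_per_min is not None
        and abs(props.baseline_drift_pa_per_min) > criteria.max_baseline_drift_pa_per_min
    ):
        reasons.append(
            f"baseline drift {abs(props.baseline_drift_pa_per_min):.0f} pA/min exceeds "
            f"{criteria.max_baseline_drift_pa_per_min:.0f} pA/min"
        )
    return len(reasons) == 0, reasons


def nernst_potential(k_out_mm: float, k_in_mm: float, temperature_k: float) -> float:
    """K⁺ equilibrium potential E_K = (RT/F)·ln([K⁺]ₒ/[K⁺]ᵢ) in mV."""
    if k_out_mm <= 0 or k_in_mm <= 0:
        raise ValueError("concentrations must be positive")
    return thermal_voltage_mv(temperature_k) * float(np.log(k_out_mm / k_in_mm))


def analyze_bundle(
    bundle: SweepBundle,
    *,
    criteria: QcCriteria | None = None,
    window_ms: float = 50.0,
    v_min_mv: float | None = None,
    junction_offset_mv: float = DEFAULT_JUNCTION_OFFSET_MV,
) -> PassiveProperties:
    """Run the full per-cell chain: transient fit → I/V → RMP → g_in → QC.

    E_K is computed from the bundle's solution metadata (``k_out_mm``,
    ``k_in_mm``, ``temperature_k``) rather than hard-coded. The transient is
    fitted on the sweep whose step lies closest to 20 mV below holding.
    """
    meta = bundle.metadata
    e_k = nernst_potential(
        meta.get("k_out_mm", 2.5), meta.get("k_in_mm", 132.0),
        meta.get("temperature_k", 295.0),
    )
    pots = np.asarray(bundle.protocol.step_potentials_mv, dtype=float)
    idx = int(np.argmin(np.abs(pots - (bundle.protocol.holding_mv - 20.0))))
    flags: list = []
    try:
        tf = fit_capacitive_transient(bundle.sweeps_pa[idx], bundle.protocol, pots[idx])
        flags.extend(tf.flags)
        rs, cm, r_in = tf.rs_mohm, tf.cm_pf, tf.r_input_mohm
    except ValueError as err:
        flags.append(str(err))
        rs = cm = r_in = np.nan

    iv = steady_state_iv(bundle, window_ms, junction_offset_mv)
    rmp, rmp_flags = resting_potential(iv)
    flags.extend(rmp_flags)
    try:
        g_in, _ = inward_conductance(iv, e_k, v_min_mv)
    except ValueError as err:
        flags.append(str(err))
        g_in = np.nan
    # leak: holding current magnitude, interpolated from the I/V at V_h
    leak = float(np.interp(bundle.protocol.holding_mv, iv.potentials_mv, iv.currents_pa))
    props = PassiveProperties(
        cell_id=bundle.cell_id,
        rmp_mv=rmp,
        rm_mohm=float(r_in) if np.isfinite(r_in) else None,
        cm_pf=float(cm) if np.isfinite(cm) else None,
        rs_mohm=float(rs) if np.isfinite(rs) else None,
        leak_pa=leak,
        g_in_ns=float(g_in) if np.isfinite(g_in) else None,
        e_k_mv=e_k,
        qc_flags=flags,
    )
    if criteria is not None:
        passed, reasons = apply_qc(props, criteria)
        props.qc_flags = reasons
        props.qc_passed = passed
    return props
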