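"""Detection and quantification of spontaneous long inward currents (SLICs).

SLICs are slow (hundreds of ms), small (tens of pA) inward currents in
OPCs driven by activity-dependent rises in extracellular K⁺. The detector
low-pass filters the holding-current trace, tracks a rolling-median
baseline, thresholds negative deflections at k robust standard deviations,
and separates SLICs from fast synaptic-like currents by their duration at
half amplitude. Companion routines predict event amplitudes from the
Nernst ΔI model, ΔI = (1/Rm)·(RT/F)·ln([K⁺]'ₑ/[K⁺]ₑ), regress amplitudes
on cell covariates, pair OPC events with field-potential events, and
quantify pharmacological block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .constants import thermal_voltage_mv
from .traces import IVCurve, inward_conductance

__all__ = [
    "SlicEvent",
    "EventSeries",
    "DetectorParams",
    "NernstDeltaIParams",
    "detect_events",
    "predicted_delta_I",
    "amplitude_regressions",
    "pair_event_latencies",
    "percent_block",
    "block_of_inward_current",
]


@dataclass
class SlicEvent:
    onset_s: float
    peak_s: float
    amplitude_pa: float  # positive magnitude of the inward deflection
    raw_amplitude_pa: float
    half_width_s: float
    event_class: str  # "SLIC" | "synaptic-like"
    depolarization_mv: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude_pa <= 0 or self.half_width_s <= 0:
            raise ValueError("amplitude and duration must be positive")
        if self.onset_s > self.peak_s:
            raise ValueError("onset must not follow the peak")


@dataclass
class EventSeries:
    events: list
    duration_s: float
    noise_sd_pa: float

    @property
    def slics(self) -> list:
        return [e for e in self.events if e.event_class == "SLIC"]

    @property
    def rate_hz(self) -> float:
        """SLIC frequency over the full epoch duration."""
        return len(self.slics) / self.duration_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "onset_s": e.onset_s,
                    "peak_s": e.peak_s,
                    "amplitude_pa": e.amplitude_pa,
                    "raw_amplitude_pa": e.raw_amplitude_pa,
                    "half_width_s": e.half_width_s,
                    "class": e.event_class,
                }
                for e in self.events
            ]
        )


@dataclass
class DetectorParams:
    """Detection settings; defaults suit slow sub-0.1 Hz, tens-of-pA events
    riding on whole-cell noise."""

    lowpass_hz: float = 20.0
    baseline_window_s: float = 10.0
    threshold_k: float = 4.0
    min_slic_duration_s: float = 0.2
    merge_gap_s: float = 0.2

    def __post_init__(self) -> None:
        if min(self.lowpass_hz, self.baseline_window_s, self.threshold_k,
               self.min_slic_duration_s, self.merge_gap_s) <= 0:
            raise ValueError("all detector parameters must be positive")


def _rolling_median_baseline(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Rolling median on a ~50 Hz decimated copy, interpolated back."""
    stride = max(int(fs / 50.0), 1)
    coarse = x[::stride]
    win = max(int(round(window_s * fs / stride)) | 1, 3)  # odd
    med = (
        pd.Series(coarse)
        .rolling(win, center=True, min_periods=max(win // 4, 1))
        .median()
        .to_numpy()
    )
    t_coarse = np.arange(len(coarse)) * stride
    return np.interp(np.arange(len(x)), t_coarse, med)


def detect_events(
    trace_pa: np.ndarray,
    sampling_rate_hz: float,
    params: DetectorParams | None = None,
) -> EventSeries:
    """Detect inward (negative-going) events in a holding-current trace.

    Pipeline: zero-phase low-pass Butterworth filter → rolling-median
    baseline → MAD-scaled noise estimate → threshold at k·σ below baseline
    → merge supra-threshold stretches across short gaps → classify by
    half-amplitude duration. Amplitudes are baseline-to-peak on the
    filtered trace (primary) and on the raw trace (reported alongside).
    """
    params = params or DetectorParams()
    x = np.asarray(trace_pa, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    fs = sampling_rate_hz
    n_baseline = int(params.baseline_window_s * fs)
    if len(x) < n_baseline:
        raise ValueError("trace shorter than the baseline window")

    sos = signal.butter(4, params.lowpass_hz, btype="low", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    baseline = _rolling_median_baseline(filt, fs, params.baseline_window_s)
    resid = filt - baseline
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    sigma = max(sigma, 1e-12)
    thresh = -params.threshold_k * sigma

    below = resid < thresh
    if not below.any():
        return EventSeries([], len(x) / fs, sigma)
    # hysteresis: grow each supra-threshold region while the residual stays
    # below half threshold, so a slowly decaying tail hovering around the
    # detection level is not split into spurious extra events
    half_mask = resid < thresh / 2.0
    edges_h = np.flatnonzero(np.diff(np.concatenate(([0], half_mask.view(np.int8), [0]))))
    h_starts, h_ends = edges_h[0::2], edges_h[1::2]
    region_of = np.searchsorted(h_starts, np.flatnonzero(below), side="right") - 1
    keep = np.unique(region_of)
    below = np.zeros_like(below)
    for r in keep:
        below[h_starts[r] : h_ends[r]] = True
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    starts, ends = edges[0::2], edges[1::2]
    gap = int(params.merge_gap_s * fs)
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events: list[SlicEvent] = []
    for s, e in merged:
        seg = resid[s:e]
        k = int(np.argmin(seg))
        peak_idx = s + k
        amplitude = -float(seg[k])
        if amplitude <= 0:
            continue
        # half-amplitude width around the peak
        half = -amplitude / 2.0
        lo = peak_idx
        while lo > 0 and resid[lo - 1] < half:
            lo -= 1
        hi = peak_idx
        while hi < len(resid) - 1 and resid[hi + 1] < half:
            hi += 1
        half_width = (hi - lo + 1) / fs
        raw_amp = float(baseline[peak_idx] - x[max(peak_idx - int(0.005 * fs), 0) : peak_idx + int(0.005 * fs) + 1].min())
        cls = "SLIC" if half_width >= params.min_slic_duration_s else "synaptic-like"
        events.append(
            SlicEvent(
                onset_s=s / fs,
                peak_s=peak_idx / fs,
                amplitude_pa=amplitude,
                raw_amplitude_pa=max(raw_amp, amplitude),
                half_width_s=half_width,
                event_class=cls,
            )
        )
    return EventSeries(events, len(x) / fs, sigma)


@dataclass(frozen=True)
class NernstDeltaIParams:
    """Inputs of the ΔI prediction for a K⁺-driven current deflection."""

    rm_mohm: float
    v_h_mv: float
    k_e_mm: float
    k_e_evoked_mm: float
    k_i_mm: float = 132.0
    temperature_k: float = 295.0

    def __post_init__(self) -> None:
        if self.rm_mohm <= 0:
            raise ValueError("Rm must be positive")
        if min(self.k_e_mm, self.k_e_evoked_mm, self.k_i_mm) <= 0:
            raise ValueError("concentrations must be positive")


def predicted_delta_I(p: NernstDeltaIParams) -> float:
    """Current change (pA) for a [K⁺]ₑ step, ΔI = (1/Rm)(RT/F)ln(K'ₑ/Kₑ).

    Positive for a K⁺ rise (growth of the inward-going deflection
    magnitude); algebraically identical to (E_K' − E_K)/Rm.
    """
    rtf = thermal_voltage_mv(p.temperature_k)
    de_mv = rtf * np.log(p.k_e_evoked_mm / p.k_e_mm)
    return float(de_mv / p.rm_mohm * 1000.0)


@dataclass
class RegressionReport:
    covariate: str
    slope: float
    r_squared: float
    p_value: float
    n: int
    direction: str

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def amplitude_regressions(
    cell_table: pd.DataFrame | None = None, event_table: pd.DataFrame | None = None
) -> dict:
    """OLS regressions of SLIC amplitude on cell covariates.

    ``cell_table`` has one row per cell with columns ``amplitude_pa`` (mean
    SLIC amplitude) and any of ``rm_mohm``, ``g_in_ns``, ``dk_mm`` (mean
    peak Δ[K⁺]ₑ paired to that cell's events). When a per-event table is
    supplied instead of per-cell aggregates, it is aggregated here: the
    Δ[K⁺]ₑ nearest each event is paired first, then averaged per cell, so
    the comparisons are across cells, matching the cohort-level question
    (does amplitude track the cell, or the K⁺ rise?).
    """
    import statsmodels.api as sm

    if event_table is not None:
        agg = event_table.groupby("cell").agg(
            amplitude_pa=("amplitude_pa", "mean"),
            **{c: (c, "mean") for c in ("rm_mohm", "g_in_ns", "dk_mm") if c in event_table},
        )
        cell_table = agg.reset_index()
    if cell_table is None:
        raise ValueError("provide a per-cell table or a per-event table")
    if len(cell_table) < 3:
        raise ValueError("need at least 3 cells for regression")
    out = {}
    y = cell_table["amplitude_pa"].to_numpy(dtype=float)
    for cov in ("rm_mohm", "g_in_ns", "dk_mm"):
        if cov not in cell_table:
            continue
        x = cell_table[cov].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"covariate {cov} has zero variance")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        out[cov] = RegressionReport(
            covariate=cov,
            slope=float(model.params[1]),
            r_squared=float(model.rsquared),
            p_value=float(model.pvalues[1]),
            n=len(y),
            direction="positive" if model.params[1] > 0 else "negative",
        )
    return out


@dataclass
class LatencyPairing:
    latencies_s: np.ndarray
    n_unmatched_opc: int
    n_unmatched_partner: int

    @property
    def median_latency_s(self) -> float:
        return float(np.median(self.latencies_s)) if len(self.latencies_s) else np.nan


def pair_event_latencies(opc_times_s, partner_times_s, max_lag_s: float = 0.5) -> LatencyPairing:
    """Match each OPC event to the nearest partner (FP or neuronal) event
    within ``max_lag_s``; latency = OPC peak − partner peak (positive when
    the partner precedes)."""
    opc = np.sort(np.asarray(opc_times_s, dtype=float))
    partner = np.sort(np.asarray(partner_times_s, dtype=float))
    if len(partner) == 0:
        return LatencyPairing(np.array([]), len(opc), 0)
    lat = []
    used = set()
    for t in opc:
        j = int(np.clip(np.searchsorted(partner, t), 0, len(partner) - 1))
        cand = [j - 1, j] if j > 0 else [j]
        best = min(cand, key=lambda k: abs(t - partner[k]))
        if abs(t - partner[best]) <= max_lag_s:
            lat.append(t - partner[best])
            used.add(best)
    return LatencyPairing(np.asarray(lat), len(opc) - len(lat), len(partner) - len(used))


@dataclass
class BlockResult:
    percent: float  # clipped to [0, 100]
    raw_percent: float
    pre_rate_hz: float | None = None
    post_rate_hz: float | None = None
    undefined: bool = False


def percent_block(
    pre_events: EventSeries,
    post_events: EventSeries,
    pre_duration_s: float | None = None,
    post_duration_s: float | None = None,
) -> BlockResult:
    """Percentage of SLICs blocked: 100·(1 − post rate/pre rate)."""
    pre_d = pre_duration_s if pre_duration_s is not None else pre_events.duration_s
    post_d = post_duration_s if post_duration_s is not None else post_events.duration_s
    if pre_d <= 0 or post_d <= 0:
        raise ValueError("durations must be positive")
    pre_rate = len(pre_events.slics) / pre_d
    post_rate = len(post_events.slics) / post_d
    if pre_rate == 0:
        return BlockResult(np.nan, np.nan, pre_rate, post_rate, undefined=True)
    raw = 100.0 * (1.0 - post_rate / pre_rate)
    return BlockResult(float(np.clip(raw, 0.0, 100.0)), float(raw), pre_rate, post_rate)


def block_of_inward_current(iv_pre: IVCurve, iv_post: IVCurve, e_k_mv: float) -> float:
    """Percent reduction of the inward-conductance slope after a blocker:
    100·(1 − g_in(post)/g_in(pre))."""
    if not np.array_equal(iv_pre.potentials_mv, iv_post.potentials_mv):
        raise ValueError("pre and post I/V curves must share potentials")
    g_pre, _ = inward_conductance(iv_pre, e_k_mv)
    g_post, _ = inward_conductance(iv_post, e_k_mv)
    if g_pre <= 0:
        raise ValueError("pre-block inward conductance must be positive")
    return 100.0 * (1.0 - g_post / g_pre)
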