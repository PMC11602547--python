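"""SLIC detection, the Nernst ΔI model, pairing and block quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from opcephys.constants import thermal_voltage_mv
from opcephys.simulate import (
    ActivityScenario,
    session_cell,
    simulate_amplitude_cohort,
    simulate_slic_session,
)
from opcephys.slic import (
    DetectorParams,
    NernstDeltaIParams,
    amplitude_regressions,
    block_of_inward_current,
    detect_events,
    pair_event_latencies,
    percent_block,
    predicted_delta_I,
    EventSeries,
    SlicEvent,
)
from opcephys.traces import IVCurve, nernst_potential


def _series(times, duration, cls="SLIC"):
    events = [SlicEvent(t, t, 30.0, 30.0, 0.5, cls) for t in times]
    return EventSeries(events, duration, 1.0)


class TestDetector:
    def test_noise_only_trace_yields_no_events(self, rng):
        fs = 2000.0
        trace = rng.normal(0.0, 5.0, int(fs * 300))
        series = detect_events(trace, fs)
        fp_per_min = len(series.slics) / (300 / 60)
        assert fp_per_min < 0.01 or len(series.slics) == 0

    def test_ground_truth_events_recovered(self):
        """10 events ≥5× noise RMS: ≥9 detected, no false SLICs, onset
        within 50 ms of the K transient onset."""
        times = tuple(10.0 + 11.0 * np.arange(10))
        sc = ActivityScenario(event_peak_times_s=times, event_dk_mm=(1.0,) * 10,
                              syn_rate_hz=0.0)
        sess = simulate_slic_session(session_cell(150.0), sc, 125.0, seed=2,
                                     noise_rms_pa=5.0)
        series = detect_events(sess.current_pa, sess.sampling_rate_hz)
        det = np.array([e.peak_s for e in series.slics])
        matched = [np.min(np.abs(det - t)) < 0.5 for t in times]
        assert sum(matched) >= 9
        assert len(det) <= 10  # no false positives
        onsets = np.array([e.onset_s for e in series.slics])
        from opcephys.simulate import t_peak_offset

        true_onsets = np.asarray(times) - t_peak_offset(sc)
        for o in onsets:
            assert np.min(np.abs(true_onsets - o)) < 0.05

    def test_sensitivity_monotone_in_amplitude(self):
        detected = []
        for dk in (0.05, 0.4, 1.2):
            sc = ActivityScenario(event_peak_times_s=tuple(10.0 + 10.0 * np.arange(8)),
                                  event_dk_mm=(dk,) * 8, syn_rate_hz=0.0)
            sess = simulate_slic_session(session_cell(250.0), sc, 95.0, seed=4,
                                         noise_rms_pa=5.0)
            series = detect_events(sess.current_pa, sess.sampling_rate_hz)
            detected.append(len(series.slics))
        assert detected[0] <= detected[1] <= detected[2]

    def test_fast_events_classified_synaptic_like(self):
        sc = ActivityScenario(syn_rate_hz=0.3, syn_amp_pa=60.0)
        sess = simulate_slic_session(session_cell(), sc, 60.0, seed=9, noise_rms_pa=2.0)
        series = detect_events(sess.current_pa, sess.sampling_rate_hz)
        syn = [e for e in series.events if e.event_class == "synaptic-like"]
        assert len(syn) >= 1
        assert all(e.half_width_s < 0.2 for e in syn)

    def test_non_finite_trace_rejected(self):
        trace = np.zeros(50_000)
        trace[100] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            detect_events(trace, 1000.0)


class TestDeltaI:
    def test_no_change_gives_zero(self):
        p = NernstDeltaIParams(rm_mohm=100.0, v_h_mv=-74.0, k_e_mm=2.5, k_e_evoked_mm=2.5)
        assert predicted_delta_I(p) == 0.0

    @pytest.mark.parametrize(
        "rm,k0,k1,expected",
        [(100.0, 2.5, 5.0, 176.2), (400.0, 2.5, 3.0, 11.6)],
    )
    def test_printed_examples(self, rm, k0, k1, expected):
        p = NernstDeltaIParams(rm_mohm=rm, v_h_mv=-74.0, k_e_mm=k0, k_e_evoked_mm=k1)
        assert predicted_delta_I(p) == pytest.approx(expected, abs=0.2)

    @given(
        rm=st.floats(min_value=20.0, max_value=2000.0),
        k0=st.floats(min_value=0.5, max_value=10.0),
        dk=st.floats(min_value=-0.4, max_value=5.0),
    )
    def test_identity_with_nernst_potential_difference(self, rm, k0, dk):
        k1 = k0 + dk
        if k1 <= 0:
            return
        p = NernstDeltaIParams(rm_mohm=rm, v_h_mv=-74.0, k_e_mm=k0, k_e_evoked_mm=k1)
        via_e_k = (nernst_potential(k1, 132.0, 295.0) - nernst_potential(k0, 132.0, 295.0)) / rm * 1000.0
        assert predicted_delta_I(p) == pytest.approx(via_e_k, rel=1e-12, abs=1e-12)

    def test_zero_noise_detection_matches_prediction(self):
        sc = ActivityScenario(event_peak_times_s=(15.0,), event_dk_mm=(0.5,), syn_rate_hz=0.0)
        sess = simulate_slic_session(session_cell(100.0), sc, 30.0, noise_rms_pa=0.0,
                                     fp_noise_rms_mv=0.0)
        series = detect_events(sess.current_pa, sess.sampling_rate_hz)
        pred = predicted_delta_I(
            NernstDeltaIParams(rm_mohm=100.0, v_h_mv=-74.0, k_e_mm=2.5, k_e_evoked_mm=3.0))
        assert series.slics[0].amplitude_pa == pytest.approx(pred, rel=0.01)


class TestRegressions:
    def test_deterministic_rm_dependence_gives_unit_r2(self):
        rm = np.linspace(50, 1000, 12)
        amp = thermal_voltage_mv(295.0) * np.log(3.0 / 2.5) / rm * 1000.0
        cells = pd.DataFrame({"amplitude_pa": amp, "g_in_ns": 1000.0 / rm})
        rep = amplitude_regressions(cells)
        assert rep["g_in_ns"].r_squared == pytest.approx(1.0, abs=1e-9)
        assert rep["g_in_ns"].direction == "positive"

    def test_cohort_mirrors_rm_but_not_k_dependence(self):
        df = simulate_amplitude_cohort(16, seed=0)
        rep = amplitude_regressions(event_table=df)
        assert rep["rm_mohm"].significant
        assert rep["rm_mohm"].direction == "negative"
        assert not rep["dk_mm"].significant

    def test_shuffled_covariates_reject_at_nominal_rate(self, rng):
        rejections = 0
        n_shuffles = 60
        df = simulate_amplitude_cohort(16, seed=1)
        agg = df.groupby("cell").agg(amplitude_pa=("amplitude_pa", "mean"),
                                     rm_mohm=("rm_mohm", "first")).reset_index()
        for _ in range(n_shuffles):
            shuffled = agg.copy()
            shuffled["rm_mohm"] = rng.permutation(shuffled["rm_mohm"].to_numpy())
            rep = amplitude_regressions(shuffled)
            rejections += rep["rm_mohm"].significant
        assert rejections / n_shuffles < 0.15

    def test_degenerate_covariate_rejected(self):
        cells = pd.DataFrame({"amplitude_pa": [1.0, 2.0, 3.0], "rm_mohm": [100.0] * 3})
        with pytest.raises(ValueError, match="zero variance"):
            amplitude_regressions(cells)


class TestLatencyPairing:
    def test_identical_series_zero_latency(self):
        t = [1.0, 2.0, 3.0]
        pairing = pair_event_latencies(t, t)
        assert np.allclose(pairing.latencies_s, 0.0)
        assert pairing.n_unmatched_opc == 0

    def test_constant_offset_recovered(self):
        partner = np.arange(10, 100, 10.0)
        pairing = pair_event_latencies(partner + 0.02, partner)
        assert pairing.median_latency_s == pytest.approx(0.02, abs=1e-12)

    def test_empty_partner_all_unmatched(self):
        pairing = pair_event_latencies([1.0, 2.0], [])
        assert pairing.n_unmatched_opc == 2
        assert len(pairing.latencies_s) == 0


class TestBlock:
    def test_complete_block(self):
        res = percent_block(_series(np.arange(12) * 10.0, 120.0), _series([], 120.0))
        assert res.percent == 100.0

    def test_identical_rates_zero(self):
        a = _series([1.0, 2.0], 100.0)
        res = percent_block(a, _series([5.0, 6.0], 100.0))
        assert res.percent == 0.0

    def test_zero_pre_rate_flagged(self):
        res = percent_block(_series([], 100.0), _series([1.0], 100.0))
        assert res.undefined

    def test_thinning_recovered_within_binomial_error(self, rng):
        keep = 0.3
        n = 400
        pre_times = np.sort(rng.uniform(0, 4000, n))
        post_times = pre_times[rng.random(n) < keep]
        res = percent_block(_series(pre_times, 4000.0), _series(post_times, 4000.0))
        se = 100 * np.sqrt(keep * (1 - keep) / n)
        assert res.percent == pytest.approx(70.0, abs=3 * se)

    def test_time_rescaling_invariance(self):
        pre, post = _series([1.0, 2.0, 3.0], 10.0), _series([5.0], 10.0)
        r1 = percent_block(pre, post)
        r2 = percent_block(_series([2.0, 4.0, 6.0], 20.0), _series([10.0], 20.0))
        assert r1.percent == pytest.approx(r2.percent, abs=1e-12)

    def test_inward_current_block_identity_and_residual(self):
        v = np.arange(-134.0, 27.0, 20.0)
        pre = IVCurve(v, 8.0 * (v + 100.0), 50.0)
        assert block_of_inward_current(pre, pre, -100.8) == pytest.approx(0.0, abs=1e-9)
        post = IVCurve(v, 0.4 * (v + 100.0), 50.0)
        assert block_of_inward_current(pre, post, -100.8) == pytest.approx(95.0, abs=1e-9)

    def test_simulated_kir_block_fraction(self):
        """Zeroing the Kir component blocks g_kir/(g_leak+g_kir) of the slope."""
        from opcephys.simulate import MembraneModelParams, simulate_voltage_clamp
        from opcephys.traces import steady_state_iv

        p_pre = MembraneModelParams(rs_mohm=2.0, g_leak_ns=1.0, e_leak_mv=-74.0,
                                    g_kir_ns=4.0, g_out_ns=0.0)
        p_post = MembraneModelParams(rs_mohm=2.0, g_leak_ns=1.0, e_leak_mv=-74.0,
                                     g_kir_ns=0.0, g_out_ns=0.0)
        iv_pre = steady_state_iv(simulate_voltage_clamp(p_pre, noise_rms_pa=0.0))
        iv_post = steady_state_iv(simulate_voltage_clamp(p_post, noise_rms_pa=0.0))
        block = block_of_inward_current(iv_pre, iv_post, p_pre.e_k_mv)
        assert block == pytest.approx(100.0 * 4.0 / 5.0, abs=2.0)
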