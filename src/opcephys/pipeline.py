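"""Reproducible simulate → analyze → classify → report runs.

A run is governed by one RunConfig (readable from YAML), executes stages
in order, writes delimited-text outputs plus a JSON manifest, and is
deterministic under its seed: per-stage random generators are spawned
from a single SeedSequence, so re-running an identical config reproduces
identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bundles import read_bundle
from .kism import fit_calibration, theoretical_nernst_slope
from .population import classify_cells, fit_conductance_mixture, state_threshold
from .simulate import (
    ActivityScenario,
    PopulationSpec,
    SlicSession,
    iter_population,
    session_cell,
    simulate_kism_calibration,
    simulate_slic_session,
)
from .slic import DetectorParams, amplitude_regressions, detect_events, pair_event_latencies
from .traces import QcCriteria, analyze_bundle

log = logging.getLogger("opcephys")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_bundle"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "opcephys-run"
    n_cells: int = 264
    n_sessions: int = 8
    session_duration_s: float = 180.0
    temperature_k: float = 295.0
    junction_offset_mv: float = -14.0
    mixture_percentile: float = 0.90
    write_bundles: bool = False
    population: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict
    timing_s: dict
    completed: bool
    failed_stage: str | None = None


def _stage(name, timing, fn, *args, **kwargs):
    t0 = time.perf_counter()
    log.info("stage %s ...", name)
    result = fn(*args, **kwargs)
    timing[name] = round(time.perf_counter() - t0, 3)
    return result


def run_pipeline(config: RunConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_of = lambda i: int(seeds[i].generate_state(1)[0] % (2**31))
    timing: dict = {}
    outputs: dict = {}
    failed = None
    try:
        spec = PopulationSpec(
            n_cells=config.n_cells, temperature_k=config.temperature_k,
            **config.population,
        )
        criteria = QcCriteria(**config.qc)

        def analyze_cohort():
            rows = []
            for bundle, gt in iter_population(spec, seed_of(0)):
                props = analyze_bundle(
                    bundle, criteria=criteria,
                    junction_offset_mv=config.junction_offset_mv,
                )
                rows.append({
                    "cell_id": props.cell_id,
                    "region": gt["region"], "age_days": gt["age_days"],
                    "rmp_mv": props.rmp_mv, "rm_mohm": props.rm_mohm,
                    "cm_pf": props.cm_pf, "rs_mohm": props.rs_mohm,
                    "leak_pa": props.leak_pa, "g_in_ns": props.g_in_ns,
                    "e_k_mv": props.e_k_mv,
                    "qc_passed": props.qc_passed,
                    "qc_reasons": "; ".join(props.qc_flags),
                    "g_in_true_ns": gt["g_in_true_ns"],
                    "true_state": gt["state"],
                    "cycle_label": gt["cycle_label"],
                    "edu_positive": gt["edu_positive"],
                    "neuron_count": gt["neuron_count"],
                    "density_class": gt["density_class"],
                })
                if config.write_bundles:
                    from .bundles import write_bundle

                    write_bundle(bundle, out / "bundles" / bundle.cell_id)
            return pd.DataFrame(rows)

        props_df = _stage("analyze_traces", timing, analyze_cohort)
        props_path = out / "properties.csv"
        props_df.to_csv(props_path, index=False)
        outputs["properties"] = str(props_path)
        n_fail = int((~props_df["qc_passed"].astype(bool)).sum())
        if n_fail:
            log.warning("%d/%d cells excluded by QC", n_fail, len(props_df))

        passed = props_df[props_df["qc_passed"].astype(bool)]
        g = passed["g_in_ns"].dropna().to_numpy()

        def mixture_stage():
            if len(g) < 10:
                log.warning("too few QC-passing cells (%d) for a mixture fit", len(g))
                return None, None, None
            try:
                fit = fit_conductance_mixture(g)
            except ValueError as err:
                log.warning("mixture fit unavailable: %s", err)
                return None, None, None
            if fit.preferred == "double":
                thr, info = state_threshold(fit, config.mixture_percentile)
            else:
                thr, info = None, {}
                log.warning("single-Gaussian model preferred; no state threshold")
            return fit, thr, info

        fit, threshold, thr_info = _stage("mixture", timing, mixture_stage)
        mix_path = out / "mixture_report.json"
        with open(mix_path, "w") as fh:
            if fit is None:
                json.dump({"n": len(g), "fit": None}, fh, indent=2)
            else:
                json.dump({
                    "n": int(len(g)),
                    "single_params": fit.single_params,
                    "double_params": fit.double_params,
                    "r2_single": fit.r2_single, "r2_double": fit.r2_double,
                    "f_statistic": fit.f_statistic, "f_df": fit.f_df,
                    "p_value": fit.p_value,
                    "aic_single": fit.aic_single, "aic_double": fit.aic_double,
                    "preferred": fit.preferred,
                    "threshold_ns": threshold,
                    **{k: v for k, v in (thr_info or {}).items()},
                }, fh, indent=2)
        outputs["mixture_report"] = str(mix_path)

        def classify_stage():
            if threshold is None:
                return passed.copy()
            return classify_cells(passed, threshold)

        cohort = _stage("classify", timing, classify_stage)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        outputs["cohort"] = str(cohort_path)

        def sessions_stage():
            rng = np.random.default_rng(seed_of(1))
            cal = fit_calibration(simulate_kism_calibration(
                theoretical_nernst_slope(config.temperature_k), 5.0,
                noise_sd_mv=0.5, seed=rng,
            ))
            if not cal.is_nernstian:
                log.warning("calibrated electrode is sub-Nernstian (%.1f mV/decade)", cal.slope)
            det = DetectorParams(**config.detector)
            ev_rows, cell_rows, lat = [], [], []
            for s in range(config.n_sessions):
                rm = float(np.exp(rng.uniform(np.log(80), np.log(400))))
                scenario = ActivityScenario.cortical(config.session_duration_s, rng)
                sess = simulate_slic_session(
                    session_cell(rm), scenario, config.session_duration_s,
                    seed=rng, calibration=cal, temperature_k=config.temperature_k,
                )
                series = detect_events(sess.current_pa, sess.sampling_rate_hz, det)
                slics = series.slics
                pairing = pair_event_latencies(
                    [e.peak_s for e in slics], sess.ground_truth["fp_peak_times_s"])
                lat.extend(pairing.latencies_s.tolist())
                from .kism import voltage_to_concentration

                k_e = voltage_to_concentration(sess.ism_mv, sess.fp_mv, cal)
                for e in slics:
                    idx = slice(max(int((e.peak_s - 1) * sess.sampling_rate_hz), 0),
                                int((e.peak_s + 1) * sess.sampling_rate_hz))
                    dk = float(np.max(k_e[idx]) - np.median(k_e))
                    ev_rows.append({"session": s, "cell": s, "rm_mohm": rm,
                                    "onset_s": e.onset_s, "peak_s": e.peak_s,
                                    "amplitude_pa": e.amplitude_pa,
                                    "half_width_s": e.half_width_s, "dk_mm": dk})
                if slics:
                    cell_rows.append({"cell": s, "rm_mohm": rm,
                                      "g_in_ns": 1000.0 / rm,
                                      "amplitude_pa": float(np.mean([e.amplitude_pa for e in slics])),
                                      "dk_mm": float(np.mean([r["dk_mm"] for r in ev_rows if r["cell"] == s])),
                                      "rate_hz": series.rate_hz})
            events = pd.DataFrame(ev_rows)
            cells = pd.DataFrame(cell_rows)
            reg = amplitude_regressions(cells) if len(cells) >= 3 else {}
            return events, cells, reg, lat

        events, sess_cells, reg, latencies = _stage("sessions", timing, sessions_stage)
        ev_path = out / "events.csv"
        events.to_csv(ev_path, index=False)
        outputs["events"] = str(ev_path)
        reg_path = out / "regressions.json"
        with open(reg_path, "w") as fh:
            json.dump({k: asdict(v) for k, v in reg.items()}
                      | {"median_latency_s": float(np.median(latencies)) if latencies else None},
                      fh, indent=2)
        outputs["regressions"] = str(reg_path)

        def summary_stage():
            from .population import group_summaries

            if "state" not in cohort.columns:
                return None
            summary, tests = group_summaries(cohort, "state")
            return summary, tests

        res = _stage("summaries", timing, summary_stage)
        if res is not None:
            summary, tests = res
            summary.to_csv(out / "state_summary.csv")
            tests.to_csv(out / "state_tests.csv", index=False)
            outputs["state_summary"] = str(out / "state_summary.csv")
            outputs["state_tests"] = str(out / "state_tests.csv")
        completed = True
    except Exception:
        log.exception("pipeline failed")
        failed = sorted(set(["analyze_traces", "mixture", "classify", "sessions", "summaries"])
                        - set(timing))[0] if len(timing) < 5 else "unknown"
        completed = False
        raise
    finally:
        manifest = RunManifest(
            config=asdict(config), version=__version__,
            outputs=outputs, timing_s=timing,
            completed=len(timing) >= 5, failed_stage=failed,
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(asdict(manifest), fh, indent=2)
        log.removeHandler(handler)
        handler.close()
    return manifest


def validate_bundle(path: str | Path) -> dict:
    """Schema/consistency report for a sweep-bundle directory; read-only."""
    path = Path(path)
    report = {"path": str(path), "valid": True, "problems": []}
    if not path.exists():
        return {"path": str(path), "valid": False, "problems": ["path does not exist"]}
    try:
        bundle = read_bundle(path)
    except Exception as err:  # noqa: BLE001 - itemized report is the contract
        report["valid"] = False
        report["problems"].append(str(err))
        return report
    if not np.all(np.isfinite(bundle.sweeps_pa)):
        report["valid"] = False
        report["problems"].append("non-finite samples in sweeps")
    report["n_sweeps"] = bundle.sweeps_pa.shape[0]
    report["n_samples"] = bundle.sweeps_pa.shape[1]
    report["cell_id"] = bundle.cell_id
    return report
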