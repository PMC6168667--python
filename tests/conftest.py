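"""Shared fixtures.

``noisy_batch`` is the workhorse: 20 seeded replicates of the full study
(8 simulated subjects each, default noise) run end to end through both
pipeline branches, with ground-truth recovery and ICA-cleaning metrics per
subject.  It is session-scoped because several recovery, efficacy and
statistics tests all consume the same replicates.
"""

from __future__ import annotations

import numpy as np
import pytest

from ppigate import (PipelineConfig, SimulationConfig, SubjectResult,
                     average_erp, cleaning_metrics, condition_recording,
                     epoch_eeg, lowpass_epochs, measure_peaks, percent_ppi,
                     run_eeg_branch, run_emg_branch, run_group,
                     simulate_session, subject_seeds)

N_SEEDS = 20
N_SUBJECTS = 8
BATCH_SEEDS = list(range(1, N_SEEDS + 1))


def run_subject_with_truth(sim_cfg: SimulationConfig, pcfg: PipelineConfig,
                           sseed: int, subject: str):
    """Full two-branch pipeline on one simulated subject, returning the
    pipeline result plus ground-truth comparison metrics."""
    rec, events, truth = simulate_session(sim_cfg, sseed)
    rec = condition_recording(rec, pcfg)
    asr, responder = run_emg_branch(rec, events, pcfg, subject)
    raw = lowpass_epochs(
        epoch_eeg(rec, events, None, pcfg.eeg_epoch_ms, pcfg.eeg_baseline_ms),
        pcfg.eeg_lp_hz, pcfg.eeg_lp_order)
    cleaned, scores, dec = run_eeg_branch(rec, events, pcfg)
    metrics = cleaning_metrics(truth, raw, cleaned, dec, scores)
    erps = average_erp(cleaned)
    peaks = measure_peaks(erps, pcfg.n1_window_ms, pcfg.p2_window_ms,
                          list(pcfg.analysis_channels))
    result = SubjectResult(subject, asr, responder, peaks, scores, {})
    return result, truth, metrics


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def noisy_batch(sim_config, pipeline_config):
    """20 seeded 8-subject replicates of the default-noise study.

    Per seed: the group report, per-subject ICA metrics, recovered group
    %PPI means per modality, and the planted values.
    """
    batch = []
    for seed in BATCH_SEEDS:
        results, metrics = [], []
        for j, sseed in enumerate(subject_seeds(seed, N_SUBJECTS)):
            res, truth, m = run_subject_with_truth(sim_config, pipeline_config,
                                                   sseed, f"s{j:02d}")
            results.append(res)
            metrics.append(m)
        report = run_group(results, pipeline_config)
        recovered = {}
        for mod in ("ASR", "p2n1@Fz", "p2n1@Cz", "p2n1@Pz"):
            d = report["modalities"][mod]["percent_ppi"]
            recovered[mod] = {iv: d[f"ppi_{iv}"]["mean"] for iv in (30, 60, 120)}
        amp_means = {
            mod: {c: report["modalities"][mod]["amplitude_uv"][f"amp_{c}"]["mean"]
                  for c in ("P", "P30", "P60", "P120")}
            for mod in ("ASR", "p2n1@Fz")
        }
        batch.append({
            "seed": seed,
            "report": report,
            "subject_metrics": metrics,
            "recovered_ppi": recovered,
            "amplitude_means": amp_means,
            "planted_muscular": dict(sim_config.ppi_muscular),
            "planted_neural": dict(sim_config.ppi_neural),
        })
    return batch


@pytest.fixture(scope="session")
def noiseless_recovery(sim_config, pipeline_config):
    """One zero-noise subject through the EMG branch: recovered muscular
    %PPI vs planted, plus the tables for exactness checks.

    The session has no mains interference, so the mains notch is switched
    off (its own ±2 Hz ring-down couples adjacent trials at the 1e-6
    level, which would blur the exact identity the zero-noise session is
    designed to expose).
    """
    cfg = sim_config.noiseless()
    pcfg = pipeline_config.replace(notch_enabled=False)
    rec, events, truth = simulate_session(cfg, 42)
    rec = condition_recording(rec, pcfg)
    asr, responder = run_emg_branch(rec, events, pcfg, "noiseless")
    means = asr.condition_means().set_index("condition")["mean_asr_uv"]
    recovered = {iv: percent_ppi(means["P"], means[f"P{iv}"]) for iv in (30, 60, 120)}
    return {"asr": asr, "responder": responder, "recovered": recovered,
            "planted": dict(cfg.ppi_muscular)}
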