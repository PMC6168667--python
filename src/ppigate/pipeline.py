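"""End-to-end orchestration: raw recording(s) → per-subject measures →
group report.

Per subject the chain is: earlobe re-reference → 0.25 Hz high-pass →
mains notch, then two branches over the *same* trials:

* EMG: bipolar derivation → 24–200 Hz band-pass → rectified 15.9 Hz
  envelope → −300…300 ms segments → ASR scoring → outlier rejection →
  responder classification;
* EEG: −1…1 s scalp epochs, −650…−150 ms baseline → 40 Hz low-pass →
  Infomax ICA → automated component classification → artifact removal →
  per-condition ERP averaging → N1/P2 peaks at Fz/Cz/Pz.

EMG-rejected trials are *not* removed from the EEG branch (no statistical
epoch thresholding), so both modalities score the same trial set; a config
switch enables synchronized rejection for methodological comparison.
Non-responders complete the chain but are excluded from group statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from .io_events import (CONDITIONS, PPI_INTERVALS, EventList, PipelineConfig,
                        Recording, rereference, logger)
from .filters import FilterSpec, zero_phase_filter, notch_mains
from .emg import (ASRTable, ResponderStatus, classify_responder, derive_emg_channel,
                  emg_envelope, reject_trials, score_asr, segment_envelope)
from .erp import EpochSet, PeakMeasure, average_erp, epoch_eeg, lowpass_epochs, measure_peaks
from .ica import (ClassifierConfig, ComponentScores, ICADecomposition, fit_ica,
                  remove_components, score_components)
from .stats import (PPITable, build_ppi_table, condition_battery,
                    cross_modality_correlation)


@dataclass
class SubjectResult:
    subject: str
    asr: ASRTable
    responder: ResponderStatus
    peaks: PeakMeasure
    ic_scores: ComponentScores
    manifest: dict
    cleaned_epochs: EpochSet | None = None


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(repr(sorted(asdict(cfg).items())).encode()).hexdigest()[:16]


def condition_recording(rec: Recording, cfg: PipelineConfig) -> Recording:
    """Shared conditioning: earlobe re-reference, 0.25 Hz high-pass, mains
    notch — applied to the continuous recording before either branch."""
    rec = rereference(rec)
    data = zero_phase_filter(rec.data, FilterSpec("highpass", (cfg.hp_cutoff_hz,), cfg.hp_order),
                             rec.rate)
    if cfg.notch_enabled:
        data = notch_mains(data, rec.rate, cfg.notch_base_hz,
                           cfg.notch_halfwidth_hz, cfg.notch_order)
    return Recording(data, rec.rate, list(rec.channels), rec.adc_resolution)


def run_emg_branch(rec: Recording, events: EventList, cfg: PipelineConfig,
                   subject: str = "s01") -> tuple[ASRTable, ResponderStatus]:
    """Startle branch on a conditioned recording: envelope → segments →
    ASR scores → outlier rejection → responder status."""
    emg = derive_emg_channel(rec, cfg.emg_bipolar)
    env = emg_envelope(emg, rec.rate, cfg.emg_band_hz, cfg.emg_band_order,
                       cfg.emg_envelope_lp_hz, cfg.emg_envelope_lp_order)
    trials = segment_envelope(env, events, rec.rate, cfg.emg_window_ms, cfg.emg_baseline_ms)
    asr = score_asr(trials, cfg.asr_window_ms, cfg.asr_baseline_subtract)
    asr = reject_trials(asr, cfg.rejection_sd, cfg.rejection_conjunctive)
    responder = classify_responder(asr, rec.adc_resolution,
                                   cfg.responder_digital_units, subject)
    return asr, responder


def run_eeg_branch(rec: Recording, events: EventList, cfg: PipelineConfig
                   ) -> tuple[EpochSet, ComponentScores, "ICADecomposition"]:
    """Neural branch on a conditioned recording: scalp epochs → 40 Hz
    low-pass → ICA → automated classification → component removal.
    Returns the cleaned epochs, component scores and the decomposition."""
    epochs = epoch_eeg(rec, events, None, cfg.eeg_epoch_ms, cfg.eeg_baseline_ms)
    epochs = lowpass_epochs(epochs, cfg.eeg_lp_hz, cfg.eeg_lp_order)
    dec = fit_ica(epochs, cfg.ica_seed, cfg.ica_max_iter, cfg.ica_w_change,
                  cfg.ica_extended, cfg.ica_train_decim, cfg.ica_block)
    ref_names = [rec.channels[i].name for i in rec.picks("eog") + rec.picks("emg")]
    ref_epochs = epoch_eeg(rec, events, ref_names, cfg.eeg_epoch_ms,
                           cfg.eeg_baseline_ms)
    ref_epochs = lowpass_epochs(ref_epochs, cfg.eeg_lp_hz, cfg.eeg_lp_order)
    refs = {n: ref_epochs.data[:, i, :] for i, n in enumerate(ref_names)}
    scores = score_components(dec, refs, ClassifierConfig.from_pipeline(cfg))
    cleaned = remove_components(epochs, dec, scores)
    return cleaned, scores, dec


def run_subject(rec: Recording, events: EventList, cfg: PipelineConfig | None = None,
                subject: str = "s01", keep_epochs: bool = False) -> SubjectResult:
    """Run the full two-branch pipeline on one subject."""
    cfg = cfg or PipelineConfig()
    rec = condition_recording(rec, cfg)
    asr, responder = run_emg_branch(rec, events, cfg, subject)
    cleaned, scores, dec = run_eeg_branch(rec, events, cfg)

    if cfg.synchronized_rejection:
        rejected_events = set(asr.per_trial.loc[asr.per_trial["rejected"], "trial"])
        keep = np.array([i not in rejected_events for i in cleaned.event_index])
        logger.info("synchronized rejection drops %d EEG epoch(s)", int((~keep).sum()))
        cleaned = cleaned.select_epochs(keep)

    erp = average_erp(cleaned)
    peaks = measure_peaks(erp, cfg.n1_window_ms, cfg.p2_window_ms,
                          [c for c in cfg.analysis_channels if c in erp.channel_names])

    manifest = {
        "subject": subject,
        "software_version": __version__,
        "config_hash": _config_hash(cfg),
        "ica_seed": cfg.ica_seed,
        "ica_iterations": dec.n_iter,
        "n_events": len(events),
        "n_emg_trials": len(asr.per_trial),
        "n_emg_rejected": int(asr.per_trial["rejected"].sum()),
        "n_eeg_epochs": len(cleaned),
        "emg_trial_indices": sorted(int(i) for i in asr.per_trial["trial"]),
        "eeg_trial_indices": sorted(int(i) for i in cleaned.event_index),
        "n_components_removed": int(scores.final_artifact.sum()),
        "responder": bool(responder.is_responder),
        "mean_p_asr_uv": responder.mean_p_asr_uv,
    }
    return SubjectResult(subject, asr, responder, peaks, scores, manifest,
                         cleaned if keep_epochs else None)


# ---------------------------------------------------------------------------
# Group aggregation
# ---------------------------------------------------------------------------

def amplitudes_long(results: list[SubjectResult],
                    electrodes: tuple[str, ...] = ("Fz", "Cz", "Pz"),
                    responders_only: bool = True) -> pd.DataFrame:
    """Long-format per-subject condition amplitudes for every modality
    (ASR mean over kept trials; P2−N1 per electrode)."""
    rows = []
    for res in results:
        if responders_only and not res.responder.is_responder:
            continue
        means = res.asr.condition_means()
        for _, r in means.iterrows():
            rows.append({"subject": res.subject, "modality": "ASR",
                         "condition": r["condition"], "amplitude": r["mean_asr_uv"]})
        for _, r in res.peaks.table.iterrows():
            if r["channel"] in electrodes:
                rows.append({"subject": res.subject,
                             "modality": f"p2n1@{r['channel']}",
                             "condition": r["condition"], "amplitude": r["p2n1_uv"]})
    return pd.DataFrame(rows)


def run_group(results: list[SubjectResult], cfg: PipelineConfig | None = None) -> dict:
    """Aggregate responders, run the statistical battery, and build the
    Table-1-shaped report (JSON-serialisable dict)."""
    cfg = cfg or PipelineConfig()
    responders = [r for r in results if r.responder.is_responder]
    if len(responders) < 3:
        raise ValueError(f"need at least 3 responders for group statistics, "
                         f"have {len(responders)} of {len(results)}")
    amps = amplitudes_long(responders, cfg.analysis_channels)
    ppi = build_ppi_table(amps)

    amp_pairs = [("amp_P", f"amp_P{iv}") for iv in PPI_INTERVALS]
    ppi_pairs = [(f"ppi_{a}", f"ppi_{b}") for a, b in ((30, 60), (30, 120), (60, 120))]

    report = {
        "n_subjects": len(results),
        "n_responders": len(responders),
        "non_responders": [r.subject for r in results if not r.responder.is_responder],
        "modalities": {},
        "cross_modality_kendall": None,
    }
    for modality in ppi.modalities:
        amp_frame = ppi.amplitude_frame(modality)
        ppi_frame = ppi.ppi_frame(modality)
        entry = {"amplitude_uv": _describe(amp_frame),
                 "percent_ppi": _describe(ppi_frame),
                 "amplitude_test": _report_dict(condition_battery(amp_frame, amp_pairs, cfg.alpha)),
                 "ppi_test": _report_dict(condition_battery(ppi_frame, ppi_pairs, cfg.alpha))}
        report["modalities"][modality] = entry

    kendall = cross_modality_correlation(ppi, cfg.analysis_channels)
    report["cross_modality_kendall"] = kendall.to_dict(orient="records")
    report["ppi_table"] = ppi.table.to_dict(orient="records")
    return report


def _describe(frame: pd.DataFrame) -> dict:
    out = {}
    for col in frame.columns:
        x = frame[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        out[col] = {
            "mean": float(np.mean(x)) if x.size else None,
            "se": float(np.std(x, ddof=1) / np.sqrt(len(x))) if x.size > 1 else None,
            "median": float(np.median(x)) if x.size else None,
            "n": int(x.size),
        }
    return out


def _report_dict(rep) -> dict:
    d = {"test": rep.test, "statistic": _jsonable(rep.statistic),
         "df": [_jsonable(v) for v in rep.df], "p_value": _jsonable(rep.p_value),
         "parametric": rep.parametric, "n_subjects": rep.n_subjects,
         "normality": {k: [_jsonable(w), _jsonable(p)] for k, (w, p) in rep.normality.items()}}
    if rep.posthoc is not None:
        d["posthoc"] = rep.posthoc.to_dict(orient="records")
    return d


def _jsonable(v):
    v = float(v)
    return None if not np.isfinite(v) else v


def write_report(report: dict, results: list[SubjectResult], out_dir) -> None:
    """Write report.json plus per-trial/per-component TSVs and the run
    manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    asr_rows, erp_rows, ic_rows = [], [], []
    for res in results:
        t = res.asr.per_trial.copy()
        t.insert(0, "subject", res.subject)
        asr_rows.append(t)
        p = res.peaks.table.copy()
        p.insert(0, "subject", res.subject)
        erp_rows.append(p)
        s = res.ic_scores.table.copy()
        s.insert(0, "subject", res.subject)
        ic_rows.append(s)
    pd.concat(asr_rows).to_csv(out / "asr.tsv", sep="\t", index=False,
                               float_format="%.6g")
    pd.concat(erp_rows).to_csv(out / "erp.tsv", sep="\t", index=False,
                               float_format="%.6g")
    pd.concat(ic_rows).to_csv(out / "ic_scores.tsv", sep="\t", index=False,
                              float_format="%.6g")
    manifests = {res.subject: res.manifest for res in results}
    (out / "manifest.json").write_text(json.dumps(manifests, indent=1, sort_keys=True))
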