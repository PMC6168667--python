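"""Muscular PPI branch: orbicularis EMG envelope, per-trial startle (ASR)
scoring, outlier trial rejection, and responder classification.

The acoustic startle reflex (ASR) is scored per trial as the maximum of the
rectified, smoothed EMG envelope in the 20–120 ms post-pulse window, minus
the 50 ms pre-stimulus baseline mean (floored at zero; a config switch
yields the raw maximum instead).  Trials are rejected when either their
in-window maximum exceeds the condition's mean + 3 SD, or their baseline
exceeds the subject's baseline mean + 3 SD — one pass, strict inequality,
so a zero-variance set rejects nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import FilterSpec, zero_phase_filter
from .io_events import CONDITIONS, EventList, Recording, ms_window_to_samples, logger


@dataclass
class EnvelopeTrialSet:
    """Per-trial EMG envelope segments (μV, nonnegative) with baselines."""

    trials: np.ndarray                       # n_trials x n_samples
    conditions: np.ndarray                   # condition label per trial
    baseline_mean: np.ndarray                # μV per trial
    trial_index: np.ndarray                  # index into the source EventList
    window_ms: tuple[float, float]
    baseline_window_ms: tuple[float, float]
    rate: float

    def __post_init__(self):
        if self.trials.ndim != 2:
            raise ValueError("trials must be a trials x samples matrix")
        if np.any(self.trials < 0):
            raise ValueError("envelope must be nonnegative")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"invalid condition labels {sorted(bad)}")

    def __len__(self) -> int:
        return self.trials.shape[0]


@dataclass
class ASRTable:
    """Per-trial ASR scores plus rejection flags.

    ``per_trial`` columns: trial, condition, baseline_uv, max_uv (raw
    in-window maximum, the rejection statistic), asr_uv, rejected, reason.
    """

    per_trial: pd.DataFrame

    def condition_means(self) -> pd.DataFrame:
        """Mean ASR (μV) over non-rejected trials and n_kept, per condition."""
        kept = self.per_trial[~self.per_trial["rejected"]]
        rows = []
        for cond in CONDITIONS:
            sub = kept[kept["condition"] == cond]
            rows.append({
                "condition": cond,
                "mean_asr_uv": float(sub["asr_uv"].mean()) if len(sub) else np.nan,
                "n_kept": int(len(sub)),
            })
        return pd.DataFrame(rows)


@dataclass
class ResponderStatus:
    subject: str
    mean_p_asr_uv: float
    threshold_uv: float
    is_responder: bool


def derive_emg_channel(rec: Recording, bipolar: bool = True) -> np.ndarray:
    """Combine the two periocular EMG electrodes into one series (μV).

    Default is the bipolar derivation EMG1 − EMG2 (standard orbicularis
    montage); ``bipolar=False`` averages the pair instead.
    """
    picks = rec.picks("emg")
    if len(picks) != 2:
        raise ValueError(f"expected exactly 2 EMG channels, found {len(picks)}")
    a, b = rec.data[picks[0]], rec.data[picks[1]]
    return a - b if bipolar else (a + b) / 2.0


def emg_envelope(emg: np.ndarray, rate: float,
                 band_hz: tuple[float, float] = (24.0, 200.0), band_order: int = 4,
                 lp_hz: float = 15.9, lp_order: int = 4) -> np.ndarray:
    """Band-pass (24–200 Hz), rectify, low-pass (15.9 Hz) → EMG envelope.

    Low-pass ringing can dip below zero; the envelope is clamped at 0.
    """
    if not rate > 2 * band_hz[1]:
        raise ValueError(
            f"rate {rate} Hz too low for a {band_hz[1]} Hz band edge (need > {2 * band_hz[1]})"
        )
    bp = zero_phase_filter(emg, FilterSpec("bandpass", band_hz, band_order), rate)
    env = zero_phase_filter(np.abs(bp), FilterSpec("lowpass", (lp_hz,), lp_order), rate)
    return np.maximum(env, 0.0)


def segment_envelope(env: np.ndarray, events: EventList, rate: float,
                     window_ms: tuple[float, float] = (-300.0, 300.0),
                     baseline_ms: tuple[float, float] = (-50.0, 0.0)) -> EnvelopeTrialSet:
    """Cut the envelope into per-trial segments around each pulse onset and
    store the pre-stimulus baseline mean.

    Events without the full window margin are excluded and logged.  No
    usable trials is an error.
    """
    start, stop = ms_window_to_samples(window_ms, rate)
    b0, b1 = ms_window_to_samples(baseline_ms, rate)
    ok = events.in_bounds(len(env), window_ms, rate)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("no events with sufficient margin for EMG segmentation")
    trials = np.stack([env[events.onsets[i] + start: events.onsets[i] + stop] for i in idx])
    baselines = np.array([env[events.onsets[i] + b0: events.onsets[i] + b1].mean() for i in idx])
    if idx.size < len(events):
        logger.info("EMG segmentation excluded %d trial(s) near recording edges",
                    len(events) - idx.size)
    return EnvelopeTrialSet(trials, events.conditions[idx], baselines, idx,
                            tuple(window_ms), tuple(baseline_ms), rate)


def score_asr(trials: EnvelopeTrialSet,
              asr_window_ms: tuple[float, float] = (20.0, 120.0),
              baseline_subtract: bool = True) -> ASRTable:
    """Score the ASR per trial: maximum envelope in the 20–120 ms window
    (endpoints inclusive after ms→sample rounding), baseline-subtracted and
    floored at 0 by default."""
    rate = trials.rate
    seg_start, seg_stop = ms_window_to_samples(trials.window_ms, rate)
    lo = int(np.round(asr_window_ms[0] * rate / 1000.0))
    hi = int(np.round(asr_window_ms[1] * rate / 1000.0))
    i0, i1 = lo - seg_start, hi - seg_start + 1
    if i0 < 0 or i1 > trials.trials.shape[1]:
        raise ValueError("trial window does not cover the ASR scoring window")
    win_max = trials.trials[:, i0:i1].max(axis=1)
    if baseline_subtract:
        asr = np.maximum(win_max - trials.baseline_mean, 0.0)
    else:
        asr = win_max
    df = pd.DataFrame({
        "trial": trials.trial_index,
        "condition": trials.conditions,
        "baseline_uv": trials.baseline_mean,
        "max_uv": win_max,
        "asr_uv": asr,
        "rejected": False,
        "reason": "",
    })
    return ASRTable(df)


def reject_trials(table: ASRTable, sd_factor: float = 3.0,
                  conjunctive: bool = False) -> ASRTable:
    """Flag outlier trials in one pass.

    A trial is an ``amplitude_outlier`` when its in-window maximum exceeds
    mean + ``sd_factor``·SD of its condition's maxima, and a
    ``baseline_outlier`` when its baseline exceeds mean + ``sd_factor``·SD
    of all the subject's baselines.  Both statistics are computed before any
    removal; strict ``>`` so identical trials are never rejected.  Default
    is disjunctive rejection (either criterion suffices).
    """
    def outliers(vals: np.ndarray) -> np.ndarray:
        thr = vals.mean() + sd_factor * (vals.std(ddof=1) if len(vals) > 1 else 0.0)
        # strict ">" with a small numerical guard (1e-6 relative) so trials
        # identical up to IIR filtering round-off are never rejected; real
        # trial-to-trial variability is orders of magnitude larger
        return vals > thr + 1e-6 * max(1.0, abs(vals.mean()))

    df = table.per_trial.copy()
    amp_flag = np.zeros(len(df), dtype=bool)
    for cond in CONDITIONS:
        m = (df["condition"] == cond).to_numpy()
        if m.sum() == 0:
            continue
        if m.sum() < 3:
            logger.warning("condition %s has %d trial(s); rejection statistics unreliable",
                           cond, int(m.sum()))
        amp_flag[m] = outliers(df.loc[m, "max_uv"].to_numpy())
    base_flag = outliers(df["baseline_uv"].to_numpy())
    rejected = (amp_flag & base_flag) if conjunctive else (amp_flag | base_flag)
    reasons = []
    for a, b in zip(amp_flag, base_flag):
        tags = ([
            t for t, on in (("amplitude_outlier", a), ("baseline_outlier", b)) if on
        ])
        reasons.append("+".join(tags))
    df["rejected"] = rejected
    df["reason"] = np.where(rejected, reasons, "")
    return ASRTable(df)


def classify_responder(table: ASRTable, adc_resolution: float,
                       digital_units: float = 20.0,
                       subject: str = "") -> ResponderStatus:
    """A subject is a responder when the mean ASR over kept pulse-alone
    trials reaches ``digital_units × adc_resolution`` μV (≥, boundary
    inclusive; 0.976 μV at the default resolution)."""
    kept = table.per_trial[(~table.per_trial["rejected"])
                           & (table.per_trial["condition"] == "P")]
    if len(kept) == 0:
        raise ValueError("no kept pulse-alone trials; cannot classify responder")
    mean_p = float(kept["asr_uv"].mean())
    thr = digital_units * adc_resolution
    return ResponderStatus(subject, mean_p, thr, mean_p >= thr)
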