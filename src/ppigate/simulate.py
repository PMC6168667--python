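"""Synthetic PPI session generator with full ground truth.

Each simulated session reproduces the experiment's structure — two blocks
of 20 pseudorandomly ordered trials per condition (pulse alone and
prepulse+pulse at 30/60/120 ms lead intervals) flanked by five leading and
five trailing pulse-alone trials, 512 Hz, 11 scalp channels (10–20),
EOG, a bipolar EMG pair and two earlobe references — and plants:

* a condition-scaled orbicularis EMG burst (band-limited noise carrier
  under a gamma-shaped envelope peaking ~55 ms post pulse); trial-to-trial
  variability is a lognormal amplitude jitter on a fixed per-subject
  carrier, so the muscular ground truth is exactly the configured %PPI
  factors when the jitter is disabled,
* a blink artifact (smooth unimodal wave peaking ~100 ms post pulse) mixed
  into EOG and scalp through a fixed rank-1 frontal-dominant gain vector,
  its amplitude coupled to the trial's startle amplitude — the very
  confound that motivates ICA cleaning before neural PPI scoring,
* a genuine N1/P2 ERP (two Gaussian deflections at ~100 and ~200 ms with
  fronto-central topographies) scaled per condition by the neural %PPI
  factors,
* 1/f background EEG noise, white sensor noise and coherent mains
  interference (60 Hz plus decaying harmonics).

Every random quantity comes from one seeded generator, so identical seeds
give bit-identical sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import h5py
import numpy as np

from .filters import FilterSpec, zero_phase_filter
from .io_events import (ChannelInfo, EventList, Recording, write_brainvision,
                        write_events_tsv, PPI_INTERVALS)

SCALP_CHANNELS = ("Fp1", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")


@dataclass
class SimulationConfig:
    """All planted quantities of a synthetic session (amplitudes in μV,
    latencies in ms, rates in Hz)."""

    n_subjects: int = 8
    rate: float = 512.0
    trials_per_condition_per_block: int = 20
    n_blocks: int = 2
    n_edge_pulse_trials: int = 5           # leading and trailing P trials
    iti_s: tuple[float, float] = (2.5, 3.5)

    # muscular ground truth
    a_p_uv: float = 50.0                   # pulse-alone startle burst amplitude
    ppi_muscular: dict = field(default_factory=lambda: {30: 35.0, 60: 55.0, 120: 35.0})
    startle_jitter_sigma: float = 0.3      # lognormal sigma; 0 = deterministic
    emg_burst_band_hz: tuple[float, float] = (24.0, 200.0)
    emg_burst_peak_ms: float = 55.0
    emg_burst_dur_ms: float = 300.0

    # neural ground truth
    n1_amp_uv: float = -12.0
    n1_latency_ms: float = 100.0
    n1_sigma_ms: float = 15.0
    p2_amp_uv: float = 18.0
    p2_latency_ms: float = 200.0
    p2_sigma_ms: float = 24.0
    ppi_neural: dict = field(default_factory=lambda: {30: 40.0, 60: 55.0, 120: 40.0})
    n1_gains: tuple = (0.40, 0.40, 0.80, 1.00, 0.80, 0.85, 1.00, 0.85, 0.55, 0.70, 0.55)
    p2_gains: tuple = (0.30, 0.30, 0.70, 0.90, 0.70, 0.90, 1.10, 0.90, 0.65, 0.80, 0.65)
    eog_neural_gain: float = 0.15

    # blink artifact (rank-1 source, amplitude coupled to the startle)
    blink_gain_uv: float = 120.0           # amplitude at the EOG for a pulse-alone trial
    blink_peak_ms: float = 100.0
    blink_sigma_ms: float = 60.0
    blink_scalp_gains: tuple = (0.45, 0.45, 0.32, 0.32, 0.32,
                                0.18, 0.18, 0.18, 0.07, 0.07, 0.07)

    # background noise
    eeg_onef_sd_uv: float = 8.0
    eeg_white_sd_uv: float = 2.0
    eog_noise_sd_uv: float = 3.0
    emg_noise_sd_uv: float = 2.0
    ref_noise_sd_uv: float = 0.5
    mains_amp_uv: float = 5.0
    mains_hz: float = 60.0

    def __post_init__(self):
        if not 0 < self.iti_s[0] <= self.iti_s[1]:
            raise ValueError("iti_s must be a positive ascending pair")
        if self.iti_s[0] < 2.0 * 1.0 + 0.2:
            raise ValueError("inter-trial interval too short for ±1 s epochs")
        for d in (self.ppi_muscular, self.ppi_neural):
            if set(d) != set(PPI_INTERVALS):
                raise ValueError(f"PPI factors must cover intervals {PPI_INTERVALS}")
            if any(not 0 <= v <= 100 for v in d.values()):
                raise ValueError("%PPI factors must lie in [0, 100]")
        for name in ("a_p_uv", "blink_gain_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def noiseless(self, **overrides) -> "SimulationConfig":
        """A copy with every stochastic nuisance disabled (noise SDs, mains,
        amplitude jitter); the deterministic burst/ERP/blink remain."""
        kw = dict(startle_jitter_sigma=0.0, eeg_onef_sd_uv=0.0,
                  eeg_white_sd_uv=0.0, eog_noise_sd_uv=0.0, emg_noise_sd_uv=0.0,
                  ref_noise_sd_uv=0.0, mains_amp_uv=0.0)
        kw.update(overrides)
        return replace(self, **kw)

    def condition_factor(self, cond: str, which: str) -> float:
        """Planted amplitude factor 1 − %PPI/100 for a condition label."""
        if cond == "P":
            return 1.0
        table = self.ppi_muscular if which == "muscular" else self.ppi_neural
        return 1.0 - table[int(cond[1:])] / 100.0


@dataclass
class GroundTruth:
    """Everything planted in one session, for known-answer testing."""

    muscular_ppi: dict                     # interval -> planted %PPI
    neural_ppi: dict
    conditions: np.ndarray                 # per trial
    onsets: np.ndarray                     # per trial, samples
    startle_amp: np.ndarray                # per trial, μV (burst scale incl. jitter)
    blink_amp: np.ndarray                  # per trial, μV at the EOG
    blink_scalp_gains: np.ndarray          # per scalp channel (EOG = 1)
    blink_source: np.ndarray               # 1-D series, μV at the EOG
    neural_source: np.ndarray              # 1-D series, unit-topography ERP drive
    clean_scalp: np.ndarray                # scalp channels x samples, artifact-free μV


def _one_over_f_noise(rng: np.random.Generator, n: int, rate: float, sd: float) -> np.ndarray:
    """Spectrally shaped (1/f amplitude) Gaussian noise with the given SD."""
    if sd == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    freqs[0] = freqs[1] if n > 1 else 1.0
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec /= np.sqrt(freqs)
    x = np.fft.irfft(spec, n)
    return x / x.std() * sd


def _gamma_envelope(t_s: np.ndarray, peak_s: float, shape: float = 3.0) -> np.ndarray:
    """Unit-peak gamma-shaped envelope with mode at ``peak_s``."""
    theta = peak_s / (shape - 1.0)
    env = np.where(t_s > 0, (t_s / theta) ** (shape - 1.0) * np.exp(-(t_s - peak_s) / theta), 0.0)
    return env / env.max() if env.max() > 0 else env


def simulate_session(cfg: SimulationConfig, subject_seed: int
                     ) -> tuple[Recording, EventList, GroundTruth]:
    """Generate one subject's continuous recording, its event list, and the
    planted ground truth.  Deterministic given ``(cfg, subject_seed)``."""
    rng = np.random.default_rng(subject_seed)
    rate = cfg.rate

    # --- trial sequence ------------------------------------------------
    block = (["P"] * cfg.trials_per_condition_per_block
             + [f"P{iv}" for iv in PPI_INTERVALS
                for _ in range(cfg.trials_per_condition_per_block)])
    conditions, block_tag = [], []
    conditions += ["P"] * cfg.n_edge_pulse_trials
    block_tag += [0] * cfg.n_edge_pulse_trials
    for b in range(cfg.n_blocks):
        order = rng.permutation(len(block))
        conditions += [block[i] for i in order]
        block_tag += [b + 1] * len(block)
    conditions += ["P"] * cfg.n_edge_pulse_trials
    block_tag += [cfg.n_blocks + 1] * cfg.n_edge_pulse_trials
    conditions = np.array(conditions, dtype=object)
    n_trials = len(conditions)

    itis = rng.uniform(cfg.iti_s[0], cfg.iti_s[1], size=n_trials)
    onset_times = 2.0 + np.cumsum(itis) - itis[0]
    onsets = np.round(onset_times * rate).astype(np.int64)
    n_samples = int(onsets[-1] + round(2.0 * rate))

    # --- channel layout -------------------------------------------------
    n_scalp = len(SCALP_CHANNELS)
    channels = ([ChannelInfo(n, "scalp", n) for n in SCALP_CHANNELS]
                + [ChannelInfo("EOG", "eog"), ChannelInfo("EMG1", "emg"),
                   ChannelInfo("EMG2", "emg"), ChannelInfo("A1", "reference"),
                   ChannelInfo("A2", "reference")])
    i_eog, i_emg1, i_emg2, i_a1, i_a2 = n_scalp, n_scalp + 1, n_scalp + 2, n_scalp + 3, n_scalp + 4
    data = np.zeros((len(channels), n_samples))

    # --- deterministic waveform templates -------------------------------
    # EMG burst: a fixed per-subject band-limited carrier under a gamma
    # envelope, normalised to unit peak; per-trial scaling only.
    n_burst = int(round(cfg.emg_burst_dur_ms / 1000.0 * rate))
    t_burst = np.arange(n_burst) / rate
    carrier = rng.standard_normal(n_burst)
    carrier = zero_phase_filter(carrier, FilterSpec("bandpass", cfg.emg_burst_band_hz, 4), rate)
    burst = carrier * _gamma_envelope(t_burst, cfg.emg_burst_peak_ms / 1000.0)
    burst /= np.abs(burst).max()

    # blink: truncated Gaussian, ±4 sigma support
    sig = cfg.blink_sigma_ms / 1000.0
    peak = cfg.blink_peak_ms / 1000.0
    b0 = int(round((peak - 4 * sig) * rate))
    b1 = int(round((peak + 4 * sig) * rate))
    t_blink = np.arange(b0, b1) / rate
    blink_wave = np.exp(-0.5 * ((t_blink - peak) / sig) ** 2)

    # neural ERP template per scalp channel (unit condition factor)
    n_erp = int(round(0.4 * rate))
    t_erp = np.arange(n_erp) / rate
    g1 = np.exp(-0.5 * ((t_erp - cfg.n1_latency_ms / 1000.0) / (cfg.n1_sigma_ms / 1000.0)) ** 2)
    g2 = np.exp(-0.5 * ((t_erp - cfg.p2_latency_ms / 1000.0) / (cfg.p2_sigma_ms / 1000.0)) ** 2)
    erp_templates = (np.outer(np.array(cfg.n1_gains), cfg.n1_amp_uv * g1)
                     + np.outer(np.array(cfg.p2_gains), cfg.p2_amp_uv * g2))
    erp_drive = cfg.n1_amp_uv * g1 + cfg.p2_amp_uv * g2   # unit-topography course

    # --- per-trial planted amplitudes -----------------------------------
    if cfg.startle_jitter_sigma > 0:
        jitter = np.exp(rng.normal(-cfg.startle_jitter_sigma ** 2 / 2.0,
                                   cfg.startle_jitter_sigma, size=n_trials))
    else:
        jitter = np.ones(n_trials)
    musc_factor = np.array([cfg.condition_factor(c, "muscular") for c in conditions])
    neur_factor = np.array([cfg.condition_factor(c, "neural") for c in conditions])
    startle_amp = cfg.a_p_uv * musc_factor * jitter
    blink_amp = cfg.blink_gain_uv * musc_factor * jitter

    blink_source = np.zeros(n_samples)
    neural_source = np.zeros(n_samples)
    clean_scalp = np.zeros((n_scalp, n_samples))
    blink_gains = np.asarray(cfg.blink_scalp_gains, dtype=float)

    for k in range(n_trials):
        o = onsets[k]
        data[i_emg1, o: o + n_burst] += 0.6 * startle_amp[k] * burst
        data[i_emg2, o: o + n_burst] += -0.4 * startle_amp[k] * burst
        blink_source[o + b0: o + b1] += blink_amp[k] * blink_wave
        neural_source[o: o + n_erp] += neur_factor[k] * erp_drive
        clean_scalp[:, o: o + n_erp] += neur_factor[k] * erp_templates

    data[:n_scalp] += clean_scalp
    data[:n_scalp] += np.outer(blink_gains, blink_source)
    data[i_eog] += blink_source + cfg.eog_neural_gain * neural_source

    # --- noise -----------------------------------------------------------
    for c in range(n_scalp):
        data[c] += _one_over_f_noise(rng, n_samples, rate, cfg.eeg_onef_sd_uv)
        if cfg.eeg_white_sd_uv > 0:
            data[c] += rng.standard_normal(n_samples) * cfg.eeg_white_sd_uv
    if cfg.eog_noise_sd_uv > 0:
        data[i_eog] += rng.standard_normal(n_samples) * cfg.eog_noise_sd_uv
    if cfg.emg_noise_sd_uv > 0:
        data[i_emg1] += rng.standard_normal(n_samples) * cfg.emg_noise_sd_uv
        data[i_emg2] += rng.standard_normal(n_samples) * cfg.emg_noise_sd_uv
    if cfg.ref_noise_sd_uv > 0:
        data[i_a1] += rng.standard_normal(n_samples) * cfg.ref_noise_sd_uv
        data[i_a2] += rng.standard_normal(n_samples) * cfg.ref_noise_sd_uv
    if cfg.mains_amp_uv > 0:
        t = np.arange(n_samples) / rate
        phase = rng.uniform(0, 2 * np.pi)
        gains = rng.uniform(0.5, 1.5, size=len(channels))
        mains = np.zeros(n_samples)
        for h, rel in ((1, 1.0), (2, 0.4), (3, 0.2)):
            if cfg.mains_hz * h < rate / 2:
                mains += rel * np.sin(2 * np.pi * cfg.mains_hz * h * t + phase * h)
        data += np.outer(gains * cfg.mains_amp_uv, mains)

    rec = Recording(data, rate, channels)
    events = EventList(onsets, conditions, np.array(block_tag))
    truth = GroundTruth(dict(cfg.ppi_muscular), dict(cfg.ppi_neural),
                        conditions, onsets, startle_amp, blink_amp,
                        blink_gains, blink_source, neural_source, clean_scalp)
    return rec, events, truth


def epoch_series(series: np.ndarray, onsets: np.ndarray,
                 window_ms: tuple[float, float], rate: float) -> np.ndarray:
    """Cut a 1-D ground-truth series into stimulus-locked segments
    (``trials × samples``); onsets must have full margins."""
    from .io_events import ms_window_to_samples

    start, stop = ms_window_to_samples(window_ms, rate)
    return np.stack([series[o + start: o + stop] for o in onsets])


def cleaning_metrics(truth: GroundTruth, raw_epochs, cleaned_epochs, dec,
                     scores, channel: str = "Fz") -> dict:
    """Ground-truth evaluation of one subject's ICA cleaning.

    Compares the raw and cleaned ERPs (grand average over all epochs) at
    one channel against the planted artifact-free ERP, and matches the
    decomposition's components to the planted blink and neural sources by
    absolute correlation of their concatenated stimulus-locked activations.

    Returns rms_raw / rms_cleaned (μV, vs the planted ERP), the index and
    flag status of the best-matching blink component, and the indices and
    flagged count of neural components (|r| > 0.5 with the planted drive).
    """
    rate = raw_epochs.rate
    window = raw_epochs.window_ms
    onsets = truth.onsets[np.asarray(raw_epochs.event_index)]
    ch = list(raw_epochs.channel_names).index(channel)

    from .erp import EpochSet, apply_baseline

    truth_ep = epoch_series(truth.clean_scalp[ch], onsets, window, rate)
    truth_ep = EpochSet(truth_ep[:, None, :], raw_epochs.conditions, [channel],
                        rate, window, raw_epochs.baseline_window_ms)
    truth_erp = apply_baseline(truth_ep).data[:, 0, :].mean(axis=0)

    raw_erp = raw_epochs.data[:, ch, :].mean(axis=0)
    cleaned_erp = cleaned_epochs.data[:, ch, :].mean(axis=0)
    rms_raw = float(np.sqrt(np.mean((raw_erp - truth_erp) ** 2)))
    rms_cleaned = float(np.sqrt(np.mean((cleaned_erp - truth_erp) ** 2)))

    def match(source: np.ndarray) -> np.ndarray:
        seg = epoch_series(source, onsets, window, rate).reshape(-1)
        seg = seg - seg.mean()
        sd = seg.std()
        if sd == 0:
            return np.zeros(dec.n_components)
        acts = dec.activations - dec.activations.mean(axis=1, keepdims=True)
        return np.abs((acts * (seg / sd)).mean(axis=1) / acts.std(axis=1))

    blink_corr = match(truth.blink_source)
    neural_corr = match(truth.neural_source)
    blink_idx = int(np.argmax(blink_corr))
    flagged = scores.final_artifact
    neural_idx = [int(i) for i in np.flatnonzero(neural_corr > 0.5) if i != blink_idx]
    return {
        "rms_raw": rms_raw,
        "rms_cleaned": rms_cleaned,
        "blink_component": blink_idx,
        "blink_corr": float(blink_corr[blink_idx]),
        "blink_flagged": bool(flagged[blink_idx]),
        "neural_components": neural_idx,
        "n_neural": len(neural_idx),
        "n_neural_flagged": int(sum(bool(flagged[i]) for i in neural_idx)),
    }


def subject_seeds(master_seed: int, n_subjects: int) -> list[int]:
    """Deterministic per-subject seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n_subjects)]


def write_fixture(rec: Recording, events: EventList, truth: GroundTruth, out_dir,
                  name: str = "session") -> dict[str, Path]:
    """Write a session as a BrainVision triplet + events.tsv, the planted
    %PPI and per-trial amplitudes as ground_truth.json, and the bulky clean
    signals as ground_truth.h5.  The triplet round-trips through
    :func:`ppigate.io_events.read_recording`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vhdr = write_brainvision(rec, out_dir / name, events)
    tsv = write_events_tsv(events, out_dir / "events.tsv", rec.rate)
    gt_json = out_dir / "ground_truth.json"
    gt_json.write_text(json.dumps({
        "muscular_ppi": {str(k): v for k, v in truth.muscular_ppi.items()},
        "neural_ppi": {str(k): v for k, v in truth.neural_ppi.items()},
        "conditions": list(truth.conditions),
        "onsets": truth.onsets.tolist(),
        "startle_amp_uv": truth.startle_amp.tolist(),
        "blink_amp_uv": truth.blink_amp.tolist(),
        "blink_scalp_gains": truth.blink_scalp_gains.tolist(),
    }, indent=1))
    gt_h5 = out_dir / "ground_truth.h5"
    with h5py.File(gt_h5, "w") as f:
        f.create_dataset("clean_scalp", data=truth.clean_scalp)
        f.create_dataset("blink_source", data=truth.blink_source)
        f.create_dataset("neural_source", data=truth.neural_source)
    return {"vhdr": vhdr, "events": tsv, "ground_truth": gt_json, "signals": gt_h5}
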