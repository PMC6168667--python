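"""Neural PPI branch: EEG epoching, baseline correction, per-condition ERP
averaging and N1/P2 peak measurement.

Epochs span −1…+1 s around pulse onset and are baselined to the mean of the
−650…−150 ms pre-stimulus interval (chosen upstream of the prepulse so the
baseline is identical across conditions).  N1 is the most negative sample
in 60–165 ms, P2 the most positive in 165–275 ms (endpoints inclusive after
ms→sample rounding, ties to the earliest sample); the neural startle
measure is the peak-to-peak amplitude P2 − N1.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .filters import FilterSpec, zero_phase_filter
from .io_events import CONDITIONS, EventList, Recording, ms_window_to_samples, logger


@dataclass
class EpochSet:
    """Stimulus-locked epochs: ``epochs × channels × samples`` (μV)."""

    data: np.ndarray
    conditions: np.ndarray
    channel_names: list[str]
    rate: float
    window_ms: tuple[float, float] = (-1000.0, 1000.0)
    baseline_window_ms: tuple[float, float] = (-650.0, -150.0)
    event_index: np.ndarray | None = None   # indices into the source EventList

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("one condition label per epoch required")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match the channel axis")
        if self.event_index is None:
            self.event_index = np.arange(self.data.shape[0])

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        start, stop = ms_window_to_samples(self.window_ms, self.rate)
        return np.arange(start, stop) * 1000.0 / self.rate

    def select_epochs(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(self.data[mask], self.conditions[mask], list(self.channel_names),
                        self.rate, self.window_ms, self.baseline_window_ms,
                        self.event_index[mask])


@dataclass
class ERP:
    """Per-condition, per-channel averaged waveforms."""

    waveforms: dict[str, np.ndarray]        # condition -> channels x samples
    n_epochs: dict[str, int]
    channel_names: list[str]
    rate: float
    window_ms: tuple[float, float]


@dataclass
class PeakMeasure:
    """N1/P2 peak amplitudes and latencies, and P2−N1, per condition and
    channel (long-format DataFrame: condition, channel, n1_uv, n1_ms,
    p2_uv, p2_ms, p2n1_uv, n_epochs)."""

    table: pd.DataFrame

    def p2n1(self, condition: str, channel: str) -> float:
        sub = self.table[(self.table["condition"] == condition)
                         & (self.table["channel"] == channel)]
        if sub.empty:
            raise KeyError(f"no measure for {condition}/{channel}")
        return float(sub["p2n1_uv"].iloc[0])


def epoch_eeg(rec: Recording, events: EventList,
              channel_names: list[str] | None = None,
              window_ms: tuple[float, float] = (-1000.0, 1000.0),
              baseline_ms: tuple[float, float] = (-650.0, -150.0),
              baseline: bool = True) -> EpochSet:
    """Cut epochs around each pulse onset and subtract the pre-stimulus
    baseline mean per epoch and channel.

    ``channel_names`` defaults to the scalp channels.  Events without the
    full margin are excluded and logged; zero usable epochs is an error.
    """
    if channel_names is None:
        picks = rec.picks("scalp")
    else:
        picks = [rec.channel_index(n) for n in channel_names]
    if not picks:
        raise ValueError("no channels to epoch")
    names = [rec.channels[i].name for i in picks]

    start, stop = ms_window_to_samples(window_ms, rec.rate)
    ok = events.in_bounds(rec.n_samples, window_ms, rec.rate)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("no events with sufficient margin for epoching")
    if idx.size < len(events):
        logger.info("epoching excluded %d event(s) near recording edges",
                    len(events) - idx.size)
    data = np.stack([rec.data[np.ix_(picks, range(events.onsets[i] + start,
                                                  events.onsets[i] + stop))]
                     for i in idx])
    epochs = EpochSet(data, events.conditions[idx], names, rec.rate,
                      tuple(window_ms), tuple(baseline_ms), idx)
    return apply_baseline(epochs) if baseline else epochs


def apply_baseline(epochs: EpochSet) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    start, _ = ms_window_to_samples(epochs.window_ms, epochs.rate)
    b0, b1 = ms_window_to_samples(epochs.baseline_window_ms, epochs.rate)
    i0, i1 = b0 - start, b1 - start
    if i0 < 0 or i1 > epochs.n_samples:
        raise ValueError("baseline window outside the epoch window")
    base = epochs.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return EpochSet(epochs.data - base, epochs.conditions, list(epochs.channel_names),
                    epochs.rate, epochs.window_ms, epochs.baseline_window_ms,
                    epochs.event_index)


def lowpass_epochs(epochs: EpochSet, cutoff_hz: float = 40.0, order: int = 4) -> EpochSet:
    """Zero-phase low-pass of every epoch and channel (default 40 Hz)."""
    spec = FilterSpec("lowpass", (cutoff_hz,), order)
    out = zero_phase_filter(epochs.data.reshape(-1, epochs.n_samples), spec, epochs.rate)
    return EpochSet(out.reshape(epochs.data.shape), epochs.conditions,
                    list(epochs.channel_names), epochs.rate, epochs.window_ms,
                    epochs.baseline_window_ms, epochs.event_index)


def average_erp(epochs: EpochSet) -> ERP:
    """Arithmetic mean across epochs of each condition, per channel."""
    waveforms, counts = {}, {}
    for cond in CONDITIONS:
        mask = epochs.conditions == cond
        n = int(mask.sum())
        if n == 0:
            logger.warning("condition %s has no epochs; omitted from ERP", cond)
            continue
        waveforms[cond] = epochs.data[mask].mean(axis=0)
        counts[cond] = n
    if not waveforms:
        raise ValueError("no epochs in any condition")
    return ERP(waveforms, counts, list(epochs.channel_names), epochs.rate,
               epochs.window_ms)


def measure_peaks(erp: ERP,
                  n1_window_ms: tuple[float, float] = (60.0, 165.0),
                  p2_window_ms: tuple[float, float] = (165.0, 275.0),
                  channels: list[str] | None = None) -> PeakMeasure:
    """Find N1 (most negative) and P2 (most positive) peaks in their search
    windows and the peak-to-peak P2−N1 per condition and channel."""
    rate = erp.rate
    start, stop = ms_window_to_samples(erp.window_ms, rate)
    if channels is None:
        channels = list(erp.channel_names)

    def win_idx(w):
        lo = int(np.round(w[0] * rate / 1000.0)) - start
        hi = int(np.round(w[1] * rate / 1000.0)) - start + 1  # inclusive
        if lo < 0 or hi > stop - start:
            raise ValueError(f"peak window {w} ms outside the ERP window")
        return lo, hi

    n1_lo, n1_hi = win_idx(n1_window_ms)
    p2_lo, p2_hi = win_idx(p2_window_ms)

    rows = []
    for cond, wf in erp.waveforms.items():
        for ch in channels:
            c = erp.channel_names.index(ch)
            seg1 = wf[c, n1_lo:n1_hi]
            seg2 = wf[c, p2_lo:p2_hi]
            i1 = int(np.argmin(seg1))    # ties -> earliest sample
            i2 = int(np.argmax(seg2))
            rows.append({
                "condition": cond,
                "channel": ch,
                "n1_uv": float(seg1[i1]),
                "n1_ms": (n1_lo + i1 + start) * 1000.0 / rate,
                "p2_uv": float(seg2[i2]),
                "p2_ms": (p2_lo + i2 + start) * 1000.0 / rate,
                "p2n1_uv": float(seg2[i2] - seg1[i1]),
                "n_epochs": erp.n_epochs[cond],
            })
    return PeakMeasure(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Hierarchical container for intermediate epoch arrays
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("conditions", data=np.array(epochs.conditions, dtype="S8"))
        f.create_dataset("event_index", data=epochs.event_index)
        f.attrs["channel_names"] = [n.encode() for n in epochs.channel_names]
        f.attrs["rate"] = epochs.rate
        f.attrs["window_ms"] = epochs.window_ms
        f.attrs["baseline_window_ms"] = epochs.baseline_window_ms


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            f["data"][()],
            np.array([c.decode() for c in f["conditions"][()]], dtype=object),
            [n.decode() if isinstance(n, bytes) else str(n)
             for n in f.attrs["channel_names"]],
            float(f.attrs["rate"]),
            tuple(f.attrs["window_ms"]),
            tuple(f.attrs["baseline_window_ms"]),
            f["event_index"][()],
        )
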