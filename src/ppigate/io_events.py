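"""Recording and event I/O, experimental configuration, re-referencing.

This module is the only place with file-format knowledge: BrainVision
(.vhdr/.vmrk/.eeg triplets) and EDF are read through :mod:`mne`'s bundled
readers, stimulus events come either from .vmrk marker files or from a
BIDS-style tab-separated events table, and minimal BrainVision/EDF writers
are provided so the simulator can emit fixtures that round-trip through the
same readers.  Everything downstream consumes only :class:`Recording` /
:class:`EventList`.

All signal data are held in microvolts (μV) as ``channels × samples``
float64 arrays.  Event onsets are 0-based sample indices.  Millisecond
windows are converted to half-open sample windows with
:func:`ms_window_to_samples`.
"""

from __future__ import annotations

import configparser
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ppigate")

#: Valid stimulus condition labels: pulse alone and prepulse+pulse with
#: 30/60/120 ms lead intervals.
CONDITIONS = ("P", "P30", "P60", "P120")

#: Prepulse-to-pulse lead intervals (ms) indexed like the PP conditions.
PPI_INTERVALS = (30, 60, 120)

ROLES = ("scalp", "emg", "eog", "reference")

#: Amplifier digitisation step in μV per digital unit.
DEFAULT_ADC_RESOLUTION_UV = 0.0488


def ms_window_to_samples(window_ms: tuple[float, float], rate: float) -> tuple[int, int]:
    """Convert an ``(start_ms, end_ms)`` window into ``(start, stop)`` sample
    offsets forming a half-open interval ``[start, stop)``.

    ``start`` is the nearest sample to ``start_ms``; the window *length* is
    the nearest sample count to the window span, so a (−300, 300) ms window
    at 512 Hz yields 307 samples.  Ties round to even (numpy convention).
    """
    start_ms, end_ms = window_ms
    if not end_ms > start_ms:
        raise ValueError(f"window must satisfy start < end, got {window_ms}")
    start = int(np.round(start_ms * rate / 1000.0))
    length = int(np.round((end_ms - start_ms) * rate / 1000.0))
    return start, start + length


@dataclass(frozen=True)
class ChannelInfo:
    """A channel label, its role in the montage, and its 10–20 position."""

    name: str
    role: str
    position_label: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {ROLES}")


@dataclass
class Recording:
    """Continuous multichannel recording in μV.

    Parameters
    ----------
    data
        ``channels × samples`` array, μV.
    rate
        Sampling rate in Hz.
    channels
        One :class:`ChannelInfo` per data row, unique names.
    adc_resolution
        μV per digital unit of the acquisition ADC; only used by the
        EMG non-responder threshold.
    """

    data: np.ndarray
    rate: float
    channels: list[ChannelInfo]
    adc_resolution: float = DEFAULT_ADC_RESOLUTION_UV

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} channels declared"
            )
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if not self.adc_resolution > 0:
            raise ValueError("adc_resolution must be positive")
        if not any(c.role == "scalp" for c in self.channels):
            raise ValueError("at least one scalp channel is required")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def picks(self, role: str) -> list[int]:
        """Indices of channels with the given role."""
        return [i for i, c in enumerate(self.channels) if c.role == role]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None


@dataclass
class EventList:
    """Stimulus onsets (0-based sample indices) with condition labels.

    ``n_excluded`` counts rows of the source table whose trial type was not
    one of :data:`CONDITIONS`; they are reported, never silently dropped.
    """

    onsets: np.ndarray
    conditions: np.ndarray
    block_tag: np.ndarray | None = None
    n_excluded: int = 0

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.onsets.shape != self.conditions.shape:
            raise ValueError("onsets and conditions must have equal length")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("event onsets must be strictly ascending")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"invalid condition labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.onsets)

    def in_bounds(self, n_samples: int, window_ms: tuple[float, float], rate: float) -> np.ndarray:
        """Boolean mask of events whose ``window_ms`` epoch fits the data.

        Out-of-bounds events are flagged (mask False) and logged, not
        dropped; epoching operations exclude them explicitly.
        """
        start, stop = ms_window_to_samples(window_ms, rate)
        ok = (self.onsets + start >= 0) & (self.onsets + stop <= n_samples)
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning("%d event(s) fall outside the recording for window %s ms", n_bad, window_ms)
        return ok

    def select(self, mask: np.ndarray) -> "EventList":
        return EventList(
            self.onsets[mask],
            self.conditions[mask],
            None if self.block_tag is None else self.block_tag[mask],
            self.n_excluded,
        )


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every numeric parameter of the analysis chain, defaulted to the
    published protocol values.

    Filters are Butterworth designs applied forward-backward (zero phase);
    ``*_order`` is the design order of a single pass.  Windows are in ms
    relative to pulse onset.
    """

    # continuous-signal conditioning
    hp_cutoff_hz: float = 0.25
    hp_order: int = 4
    notch_enabled: bool = True
    notch_base_hz: float = 60.0
    notch_halfwidth_hz: float = 2.0
    notch_order: int = 4

    # EMG branch
    emg_band_hz: tuple[float, float] = (24.0, 200.0)
    emg_band_order: int = 4
    emg_envelope_lp_hz: float = 15.9
    emg_envelope_lp_order: int = 4
    emg_window_ms: tuple[float, float] = (-300.0, 300.0)
    emg_baseline_ms: tuple[float, float] = (-50.0, 0.0)
    asr_window_ms: tuple[float, float] = (20.0, 120.0)
    emg_bipolar: bool = True          # EMG1 - EMG2; False -> mean of the pair
    asr_baseline_subtract: bool = True
    rejection_sd: float = 3.0
    rejection_conjunctive: bool = False  # default: either criterion rejects
    responder_digital_units: float = 20.0

    # EEG branch
    eeg_epoch_ms: tuple[float, float] = (-1000.0, 1000.0)
    eeg_baseline_ms: tuple[float, float] = (-650.0, -150.0)
    eeg_lp_hz: float = 40.0
    eeg_lp_order: int = 4
    n1_window_ms: tuple[float, float] = (60.0, 165.0)
    p2_window_ms: tuple[float, float] = (165.0, 275.0)
    analysis_channels: tuple[str, ...] = ("Fz", "Cz", "Pz")

    # ICA + component classifier
    ica_seed: int = 0
    ica_max_iter: int = 512
    ica_w_change: float = 1e-7
    ica_extended: bool = False
    ica_train_decim: int = 4
    ica_block: int = 1024
    autocorr_lag_ms: float = 20.0
    autocorr_threshold: float | str = "auto"
    focal_topo_z_threshold: float = 3.5
    focal_trial_z_threshold: float = 10.0
    snr_ratio_threshold: float = 1.0
    ref_corr_threshold: float = 0.2
    classifier_combine: str = "union"  # or "vote"

    # statistics
    alpha: float = 0.05
    # remove EMG-rejected trials from the EEG branch as well (off: the two
    # modalities keep the same trial set, EMG rejection stays EMG-only)
    synchronized_rejection: bool = False

    def __post_init__(self):
        for name in ("emg_window_ms", "emg_baseline_ms", "asr_window_ms",
                     "eeg_epoch_ms", "eeg_baseline_ms", "n1_window_ms", "p2_window_ms"):
            a, b = getattr(self, name)
            if not a < b:
                raise ValueError(f"{name} must satisfy start < end, got {(a, b)}")
        lo, hi = self.emg_band_hz
        if not 0 < lo < hi:
            raise ValueError("emg_band_hz must be ascending and positive")
        for name in ("hp_cutoff_hz", "notch_base_hz", "notch_halfwidth_hz",
                     "emg_envelope_lp_hz", "eeg_lp_hz", "rejection_sd",
                     "responder_digital_units", "focal_topo_z_threshold",
                     "focal_trial_z_threshold", "snr_ratio_threshold",
                     "ref_corr_threshold", "alpha"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.classifier_combine not in ("union", "vote"):
            raise ValueError("classifier_combine must be 'union' or 'vote'")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f: v for f, v in d.items()}
        for k, v in list(fields.items()):
            if isinstance(v, list):
                fields[k] = tuple(v)
        return cls(**fields)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_KNOWN_UNITS = {"µV": 1.0, "uV": 1.0, "μV": 1.0, "mV": 1e3, "V": 1e6}


def _validate_brainvision(vhdr: Path) -> None:
    """Check the header's companion files and channel units before handing
    the triplet to mne, so failures name the offending member."""
    cp = configparser.ConfigParser(strict=False)
    text = vhdr.read_text(errors="replace")
    # strip the non-INI banner line
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("Brain Vision"))
    cp.read_string(body)
    common = cp["Common Infos"]
    for key in ("DataFile", "MarkerFile"):
        if key in common:
            member = vhdr.parent / common[key]
            if not member.exists():
                raise FileNotFoundError(
                    f"BrainVision header {vhdr} references missing {key} {member}"
                )
    if "Channel Infos" in cp:
        for key, val in cp["Channel Infos"].items():
            parts = val.split(",")
            if len(parts) >= 4 and parts[3] and parts[3] not in _KNOWN_UNITS:
                raise ValueError(f"unknown unit {parts[3]!r} for channel entry {key}")


def _validate_edf_units(path: Path) -> None:
    with open(path, "rb") as f:
        header = f.read(256)
        ns = int(header[252:256].decode("ascii").strip())
        f.seek(256 + ns * (16 + 80))
        dims = f.read(8 * ns).decode("ascii", errors="replace")
    for i in range(ns):
        dim = dims[8 * i: 8 * (i + 1)].strip()
        if dim and dim not in _KNOWN_UNITS:
            raise ValueError(f"unknown unit {dim!r} in EDF signal {i}")


def read_recording(path, format: str | None = None, role_map: dict[str, str] | None = None,
                   adc_resolution: float = DEFAULT_ADC_RESOLUTION_UV) -> Recording:
    """Read a BrainVision or EDF recording into a μV :class:`Recording`.

    Parameters
    ----------
    path
        The .vhdr file (BrainVision) or .edf file.
    format
        ``"brainvision"`` or ``"edf"``; inferred from the suffix if None.
    role_map
        Mapping channel name → role (scalp/emg/eog/reference).  Roles are
        explicit rather than guessed from names; every channel in the file
        must be mapped.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = {".vhdr": "brainvision", ".edf": "edf"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if role_map is None:
        raise ValueError("a role_map (channel name -> role) is required")

    if format == "brainvision":
        _validate_brainvision(path)
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif format == "edf":
        _validate_edf_units(path)
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown format {format!r}")

    names = raw.ch_names
    missing = [n for n in names if n not in role_map]
    if missing:
        raise ValueError(f"role_map does not cover channels {missing}")
    channels = [ChannelInfo(n, role_map[n], n if role_map[n] == "scalp" else "") for n in names]
    data_uv = raw.get_data() * 1e6  # mne holds SI volts
    return Recording(data_uv, float(raw.info["sfreq"]), channels, adc_resolution)


def read_events(path, rate: float) -> EventList:
    """Read stimulus events from a .vmrk marker file or a tab-separated
    events table (columns ``onset`` [s], ``duration``, ``trial_type``).

    Unknown trial types are excluded and counted; non-monotonic onsets are
    sorted with a warning; an empty table is an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".vmrk":
        rows = _parse_vmrk(path)
    else:
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise ValueError(f"events table {path} is empty")
        for col in ("onset", "trial_type"):
            if col not in df.columns:
                raise ValueError(f"events table must have an {col!r} column")
        rows = [(int(np.round(float(t) * rate)), str(tt)) for t, tt in
                zip(df["onset"], df["trial_type"])]
    if not rows:
        raise ValueError(f"no events in {path}")

    kept = [(o, c) for o, c in rows if c in CONDITIONS]
    n_excluded = len(rows) - len(kept)
    if n_excluded:
        logger.warning("excluded %d event(s) with unknown trial types", n_excluded)
    if not kept:
        raise ValueError("no events with recognised condition labels")
    onsets = np.array([o for o, _ in kept], dtype=np.int64)
    conds = np.array([c for _, c in kept], dtype=object)
    order = np.argsort(onsets, kind="stable")
    if np.any(np.diff(onsets) < 0):
        warnings.warn("event onsets were not monotonic; sorted ascending")
    return EventList(onsets[order], conds[order], n_excluded=n_excluded)


def _parse_vmrk(path: Path) -> list[tuple[int, str]]:
    rows = []
    for line in path.read_text().splitlines():
        if not line.startswith("Mk"):
            continue
        _, _, value = line.partition("=")
        parts = value.split(",")
        if len(parts) < 3 or parts[0] != "Stimulus":
            continue
        # marker positions are 1-based data points
        rows.append((int(parts[2]) - 1, parts[1].strip()))
    return rows


# ---------------------------------------------------------------------------
# Re-referencing
# ---------------------------------------------------------------------------

def rereference(rec: Recording) -> Recording:
    """Re-reference all non-reference channels to the mean of the two
    earlobe reference channels.  Reference channels are retained unchanged
    for provenance."""
    refs = rec.picks("reference")
    if len(refs) != 2:
        raise ValueError(f"expected exactly 2 reference channels, found {len(refs)}")
    ref_mean = rec.data[refs].mean(axis=0)
    out = rec.data.copy()
    for i in range(out.shape[0]):
        if i not in refs:
            out[i] -= ref_mean
    return Recording(out, rec.rate, list(rec.channels), rec.adc_resolution)


# ---------------------------------------------------------------------------
# Writers (fixture emission; formats kept deliberately minimal)
# ---------------------------------------------------------------------------

def write_brainvision(rec: Recording, base, events: EventList | None = None) -> Path:
    """Write ``base``.vhdr/.vmrk/.eeg (binary IEEE float32, multiplexed, μV).

    Returns the .vhdr path.  The triplet reads back through
    :func:`read_recording`.
    """
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    name = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(rec.channels)}",
        f"SamplingInterval={1e6 / rec.rate:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.channels, start=1):
        lines.append(f"Ch{i}={ch.name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    if events is not None:
        for k, (onset, cond) in enumerate(zip(events.onsets, events.conditions), start=2):
            mlines.append(f"Mk{k}=Stimulus,{cond},{onset + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    eeg.write_bytes(np.ascontiguousarray(rec.data.T, dtype="<f4").tobytes())
    return vhdr


def write_edf(rec: Recording, path) -> Path:
    """Write a minimal EDF file (16-bit, 1-second records, unit uV).

    The last record is zero-padded when the recording length is not a whole
    number of seconds; readers will return the padded length.  Requires an
    integer sampling rate.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if abs(rec.rate - round(rec.rate)) > 1e-9:
        raise ValueError("EDF writing requires an integer sampling rate")
    spr = int(round(rec.rate))  # samples per 1 s record
    n_ch = len(rec.channels)
    n_rec = math.ceil(rec.n_samples / spr)

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate 01-JAN-2000 X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8), pad(str(256 * (n_ch + 1)), 8),
        pad("", 44), pad(str(n_rec), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    labels = b"".join(pad(ch.name, 16) for ch in rec.channels)
    transducers = b"".join(pad("", 80) for _ in rec.channels)
    dims = b"".join(pad("uV", 8) for _ in rec.channels)

    def fmt8(v: float) -> str:
        for spec in (".6g", ".4g", ".2g", ".1g"):
            s = format(v, spec)
            if len(s) <= 8:
                return s
        return format(v, ".0e")

    pmins, pmaxs, scaled = [], [], []
    dmin, dmax = -32768, 32767
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data
    for c in range(n_ch):
        lo, hi = padded[c].min(), padded[c].max()
        margin = max(1e-6, (hi - lo) * 1e-4, abs(hi) * 1e-4, abs(lo) * 1e-4)
        lo, hi = lo - margin, hi + margin
        # scale against the header's (8-char) representation so the
        # round-trip is exact to quantisation
        lo, hi = float(fmt8(lo)), float(fmt8(hi))
        if not lo < hi:
            lo, hi = lo - 1.0, hi + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
        dig = np.clip(np.round((padded[c] - lo) / (hi - lo) * (dmax - dmin) + dmin), dmin, dmax)
        scaled.append(dig.astype("<i2"))

    phys_min = b"".join(pad(fmt8(v), 8) for v in pmins)
    phys_max = b"".join(pad(fmt8(v), 8) for v in pmaxs)
    dig_min = b"".join(pad(str(dmin), 8) for _ in rec.channels)
    dig_max = b"".join(pad(str(dmax), 8) for _ in rec.channels)
    prefilter = b"".join(pad("", 80) for _ in rec.channels)
    spr_f = b"".join(pad(str(spr), 8) for _ in rec.channels)
    reserved = b"".join(pad("", 32) for _ in rec.channels)

    with open(path, "wb") as f:
        f.write(header + labels + transducers + dims + phys_min + phys_max
                + dig_min + dig_max + prefilter + spr_f + reserved)
        for r in range(n_rec):
            for c in range(n_ch):
                f.write(scaled[c][r * spr: (r + 1) * spr].tobytes())
    return path


def write_events_tsv(events: EventList, path, rate: float,
                     duration_s: float = 0.04) -> Path:
    """Write a BIDS-style events table (onset in seconds)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "onset": events.onsets / rate,
        "duration": duration_s,
        "trial_type": events.conditions,
    })
    df.to_csv(path, sep="\t", index=False)
    return path
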