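"""Zero-phase Butterworth conditioning and mains-notch filtering.

All filtering in the pipeline is Butterworth, applied forward-backward
(``scipy.signal.sosfiltfilt``) so the output has no phase lag.  "Order"
always means the design order of one pass; the effective magnitude response
is that order squared.  Edges are handled with odd-reflection padding of up
to three times a nominal impulse length (``order / lowest cutoff``), which
keeps slow high-pass transients out of the analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

_KINDS = {"highpass", "lowpass", "bandpass", "bandstop"}


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth design: kind, cutoff(s) in Hz, single-pass order."""

    kind: str
    cutoffs_hz: tuple[float, ...]
    order: int = 4

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        cut = tuple(float(c) for c in self.cutoffs_hz)
        object.__setattr__(self, "cutoffs_hz", cut)
        n_expected = 2 if self.kind in ("bandpass", "bandstop") else 1
        if len(cut) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} cutoff(s), got {cut}")
        if any(c <= 0 for c in cut):
            raise ValueError("cutoffs must be positive")
        if n_expected == 2 and not cut[0] < cut[1]:
            raise ValueError("band cutoffs must be ascending")
        if self.order < 1:
            raise ValueError("order must be a positive integer")


def _design(spec: FilterSpec, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    if max(spec.cutoffs_hz) >= nyq:
        raise ValueError(
            f"cutoff {max(spec.cutoffs_hz)} Hz is at or above Nyquist ({nyq} Hz)"
        )
    wn = spec.cutoffs_hz[0] if len(spec.cutoffs_hz) == 1 else list(spec.cutoffs_hz)
    return signal.butter(spec.order, wn, btype=spec.kind, fs=rate, output="sos")


def _padlen(spec: FilterSpec, rate: float, n: int) -> int:
    nominal = spec.order * rate / min(spec.cutoffs_hz)
    return int(min(n - 1, max(3 * (2 * spec.order + 1), np.round(3 * nominal))))


def zero_phase_filter(x: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Forward-backward Butterworth filter of a 1-D series or a
    ``channels × samples`` matrix (filtered along the last axis).

    Raises if a cutoff reaches Nyquist or the signal is too short for the
    filter's edge padding.
    """
    x = np.asarray(x, dtype=np.float64)
    sos = _design(spec, rate)
    n = x.shape[-1]
    min_len = 3 * (2 * spec.order + 1)
    if n <= min_len:
        raise ValueError(
            f"signal of {n} samples is too short for a zero-phase order-"
            f"{spec.order} filter; need more than {min_len} samples"
        )
    return signal.sosfiltfilt(sos, x, axis=-1, padtype="odd",
                              padlen=_padlen(spec, rate, n))


def notch_mains(x: np.ndarray, rate: float, base_hz: float = 60.0,
                halfwidth_hz: float = 2.0, order: int = 4) -> np.ndarray:
    """Cascaded zero-phase band-stops at the mains frequency and every
    integer harmonic below Nyquist (60, 120, 180, 240 Hz at 512 Hz)."""
    nyq = rate / 2.0
    if base_hz >= nyq:
        raise ValueError(f"mains base {base_hz} Hz is at or above Nyquist ({nyq} Hz)")
    out = np.asarray(x, dtype=np.float64)
    k = 1
    while True:
        f = base_hz * k
        hi = min(f + halfwidth_hz, nyq * 0.999)
        if f >= nyq or f - halfwidth_hz >= hi:
            break
        spec = FilterSpec("bandstop", (f - halfwidth_hz, hi), order)
        out = zero_phase_filter(out, spec, rate)
        k += 1
        if base_hz * k - halfwidth_hz >= nyq:
            break
    return out
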