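"""Denoising and standardisation of raw EEG segments.

Content above ~50 Hz carries little of the rhythmic activity the five
conventional EEG bands describe, so segments are band-limited with a
zero-phase Butterworth filter to an effective 0-50 Hz range and then
z-scored per segment.  The zero-phase (forward-backward) application keeps
spike transients aligned in time, which matters once wavelet coefficients
are interpreted band by band.

Statistics here and everywhere downstream use the population convention
(1/n), stated once and applied consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .bonn_io import EEGSegment


@dataclass
class PreprocessConfig:
    """Band-pass and normalisation settings.

    ``low_cut=0`` selects a pure low-pass; otherwise a band-pass with
    edges (low_cut, high_cut) Hz.  ``order`` is the Butterworth order of
    the underlying one-direction filter (effective order doubles under
    the zero-phase forward-backward pass).
    """

    low_cut: float = 0.5
    high_cut: float = 50.0
    order: int = 4
    normalize: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not 0 <= self.low_cut < self.high_cut:
            raise ValueError(
                f"need 0 <= low_cut < high_cut, got ({self.low_cut}, {self.high_cut})"
            )
        if self.high_cut >= nyq:
            raise ValueError(
                f"high_cut {self.high_cut} Hz must lie below Nyquist {nyq} Hz"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")


def bandpass(segment: EEGSegment, cfg: PreprocessConfig | None = None) -> EEGSegment:
    """Zero-phase Butterworth band-pass (or low-pass when ``low_cut == 0``).

    Forward-backward filtering removes group delay, so the output has the
    same length as, and is time-aligned with, the input.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(segment.fs)
    nyq = segment.fs / 2.0
    if cfg.low_cut == 0:
        sos = butter(cfg.order, cfg.high_cut / nyq, btype="low", output="sos")
    else:
        sos = butter(cfg.order, [cfg.low_cut / nyq, cfg.high_cut / nyq],
                     btype="band", output="sos")
    filtered = sosfiltfilt(sos, segment.samples)
    return segment.with_samples(filtered)


def normalize(segment: EEGSegment) -> EEGSegment:
    """Per-segment z-score: subtract the mean, divide by the population std."""
    x = segment.samples
    mu = x.mean()
    sd = x.std()  # population (1/n)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"segment {segment.id!r} is constant; cannot normalize")
    return segment.with_samples((x - mu) / sd)


def preprocess(segment: EEGSegment, cfg: PreprocessConfig | None = None) -> EEGSegment:
    """Band-pass then (optionally) normalise one segment."""
    cfg = cfg or PreprocessConfig()
    out = bandpass(segment, cfg)
    if cfg.normalize:
        out = normalize(out)
    return out
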