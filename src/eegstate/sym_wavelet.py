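"""Four-level discrete wavelet decomposition with the Symlet-4 filter bank.

The Symlet family is the near-symmetric variant of the Daubechies
orthogonal wavelets; with N = 4 vanishing moments the filters have 2N = 8
taps and the detail branch annihilates polynomials up to degree 3.  A
four-level cascade of a 0-50 Hz signal splits it dyadically into the five
conventional EEG rhythms:

    d1 -> gamma (25-50 Hz)     d2 -> beta (12.5-25 Hz)
    d3 -> alpha (6.25-12.5 Hz) d4 -> theta (3.125-6.25 Hz)
    a4 -> delta (0-3.125 Hz)

The transform is implemented from first principles (cascaded filtering and
dyadic downsampling) with two boundary policies:

``symmetric``
    Half-sample symmetric extension, the production default for EEG —
    avoids the edge spikes a periodic wrap would introduce.  Coefficient
    lengths follow the "full" convention floor((n + taps - 1) / 2).
``periodization``
    Circular extension producing an orthogonal transform (length
    ceil(n/2) per branch), under which Parseval's identity holds exactly;
    used by the energy-conservation checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .bonn_io import EEGSegment

BoundaryMode = Literal["symmetric", "periodization"]

#: Detail/approximation tags in decomposition order and their band names.
BAND_LABELS = {"d1": "gamma", "d2": "beta", "d3": "alpha", "d4": "theta",
               "a4": "delta"}

#: Fixed band order used for feature vectors: gamma, beta, alpha, theta, delta.
BAND_ORDER = ("d1", "d2", "d3", "d4", "a4")

# Standard Symlet-4 low-pass decomposition taps (orthonormal: sum = sqrt(2),
# sum of squares = 1), least-asymmetric length-8 solution.
_SYM4_DEC_LO = np.array([
    -0.07576571478927333,
    -0.02963552764599851,
    0.49761866763201545,
    0.8037387518059161,
    0.29785779560527736,
    -0.09921954357684722,
    -0.012603967262037833,
    0.0322231006040427,
])


@dataclass
class WaveletFilterBank:
    """Orthogonal two-channel filter bank (decomposition + reconstruction taps).

    The high-pass branch is the alternating-sign mirror of the low-pass:
    ``dec_hi[k] = (-1)^(k+1) dec_lo[L-1-k]``, and the reconstruction taps
    are the time-reversed decomposition taps, the standard arrangement for
    orthogonal wavelets.
    """

    name: str
    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray
    vanishing_moments: int

    @property
    def taps(self) -> int:
        return len(self.dec_lo)


def sym4_filter_bank() -> WaveletFilterBank:
    """The 8-tap Symlet-4 filter bank (N = 4 vanishing moments)."""
    lo = _SYM4_DEC_LO.copy()
    L = len(lo)
    hi = np.array([(-1) ** (k + 1) * lo[L - 1 - k] for k in range(L)])
    return WaveletFilterBank(name="sym4", dec_lo=lo, dec_hi=hi,
                             rec_lo=lo[::-1].copy(), rec_hi=hi[::-1].copy(),
                             vanishing_moments=4)


@dataclass
class DecompositionResult:
    """Coefficients of a four-level cascade: details d1..d4 and approximation a4."""

    details: dict[str, np.ndarray]
    approximation: np.ndarray
    band_labels: dict[str, str] = field(default_factory=lambda: dict(BAND_LABELS))
    levels: int = 4
    #: input lengths at each cascade stage, needed for exact inversion
    input_lengths: tuple[int, ...] = ()
    mode: str = "symmetric"

    def coefficient_sets(self) -> list[np.ndarray]:
        """The five coefficient arrays in fixed band order d1, d2, d3, d4, a4."""
        return [self.details["d1"], self.details["d2"], self.details["d3"],
                self.details["d4"], self.approximation]


def _dwt_symmetric(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    L = len(f)
    ext = np.pad(x, (L - 1, L - 1), mode="symmetric")
    return np.convolve(ext, f, mode="valid")[1::2]


def _dwt_periodized(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    L = len(f)
    if len(x) % 2:
        x = np.concatenate([x, x[-1:]])  # repeat last sample to even length
    ext = np.pad(x, (L // 2 - 1, L // 2 - 1), mode="wrap")
    return np.convolve(ext, f, mode="valid")[0::2]


def dwt_level(signal: np.ndarray, fb: WaveletFilterBank,
              mode: BoundaryMode = "symmetric") -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: filter with the low/high-pass pair, downsample by 2.

    Returns ``(approximation, detail)``.  Under symmetric extension each
    output has length floor((n + taps - 1)/2); under periodization,
    ceil(n/2).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) < fb.taps:
        raise ValueError(
            f"signal length {len(x)} shorter than filter length {fb.taps}"
        )
    if mode == "symmetric":
        return _dwt_symmetric(x, fb.dec_lo), _dwt_symmetric(x, fb.dec_hi)
    elif mode == "periodization":
        return _dwt_periodized(x, fb.dec_lo), _dwt_periodized(x, fb.dec_hi)
    raise ValueError(f"unknown boundary mode {mode!r}")


def idwt_level(approx: np.ndarray, detail: np.ndarray, fb: WaveletFilterBank,
               output_length: int, mode: BoundaryMode = "symmetric") -> np.ndarray:
    """One synthesis step: upsample, filter with reconstruction taps, merge.

    ``output_length`` is the length of the signal that produced the two
    coefficient arrays (the synthesis result is trimmed to it, mirroring
    the analysis-side extension).
    """
    a = np.asarray(approx, dtype=float)
    d = np.asarray(detail, dtype=float)
    if len(a) != len(d):
        raise ValueError(f"approx/detail length mismatch: {len(a)} vs {len(d)}")
    L = fb.taps
    m = len(a)
    up_a = np.zeros(2 * m)
    up_a[::2] = a
    up_d = np.zeros(2 * m)
    up_d[::2] = d
    full = np.convolve(up_a, fb.rec_lo) + np.convolve(up_d, fb.rec_hi)
    if mode == "symmetric":
        y = full[L - 2: L - 2 + 2 * m - L + 2]
        return y[:output_length]
    elif mode == "periodization":
        shift = L // 2 - 1
        acc = np.zeros(2 * m)
        idx = (np.arange(len(full)) - shift) % (2 * m)
        np.add.at(acc, idx, full)
        return acc[:output_length]
    raise ValueError(f"unknown boundary mode {mode!r}")


def wavedec4(segment, fb: WaveletFilterBank | None = None,
             mode: BoundaryMode = "symmetric") -> DecompositionResult:
    """Four-level cascade d1..d4, a4 with EEG band labels.

    Accepts an :class:`~eegstate.bonn_io.EEGSegment` or a bare array.  The
    approximation branch is re-decomposed at each level, so d1 covers the
    top half of the spectrum and a4 the lowest sixteenth.
    """
    fb = fb or sym4_filter_bank()
    x = segment.samples if isinstance(segment, EEGSegment) else np.asarray(
        segment, dtype=float)
    levels = 4
    min_len = fb.taps * 2 ** levels
    if len(x) < min_len:
        feasible = max(0, int(np.floor(np.log2(len(x) / fb.taps))))
        raise ValueError(
            f"signal length {len(x)} supports at most {feasible} levels; "
            f"{levels} levels need >= {min_len} samples"
        )
    details: dict[str, np.ndarray] = {}
    lengths = []
    cur = x
    for p in range(1, levels + 1):
        lengths.append(len(cur))
        cur, det = dwt_level(cur, fb, mode=mode)
        details[f"d{p}"] = det
    return DecompositionResult(details=details, approximation=cur,
                               input_lengths=tuple(lengths), mode=mode)


def waverec4(dec: DecompositionResult,
             fb: WaveletFilterBank | None = None) -> np.ndarray:
    """Invert :func:`wavedec4`, reproducing the input signal exactly."""
    fb = fb or sym4_filter_bank()
    cur = dec.approximation
    for p in range(dec.levels, 0, -1):
        n_out = dec.input_lengths[p - 1]
        cur = idwt_level(cur, dec.details[f"d{p}"], fb, n_out,
                         mode=dec.mode)  # type: ignore[arg-type]
    return cur


def band_edges(level_tag: str, effective_bandwidth: float = 50.0
               ) -> tuple[float, float]:
    """Dyadic frequency edges (low, high) in Hz for a coefficient set.

    Detail p covers (B/2^p, B/2^(p-1)); the final approximation covers
    (0, B/2^4).  With B = 50 Hz, d1 is the 25-50 Hz gamma band and a4 the
    0-3.125 Hz delta band (the literature rounds these edges to 12-25,
    6-12, 3-6 and 0-3 Hz).
    """
    if effective_bandwidth <= 0:
        raise ValueError("effective_bandwidth must be positive")
    B = effective_bandwidth
    if level_tag in ("d1", "d2", "d3", "d4"):
        p = int(level_tag[1])
        return (B / 2 ** p, B / 2 ** (p - 1))
    if level_tag == "a4":
        return (0.0, B / 2 ** 4)
    raise ValueError(f"unknown level tag {level_tag!r}; expected d1..d4 or a4")
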