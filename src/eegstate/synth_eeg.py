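"""Seeded three-class surrogate EEG generator.

Real epilepsy archives cannot ship with a library, so this module
synthesises single-channel segments whose gross statistics mirror the
three clinical states the classifier separates:

* healthy {OZ}: broadband, low amplitude (std ~ 4.6 uV);
* interictal {FN}: mid amplitude (std ~ 13.1 uV), slowing toward
  theta/delta, occasional isolated sharp transients;
* ictal {S}: high amplitude (std ~ 38.6 uV), dominant theta/delta
  rhythm, dense spike-wave discharges.

Each segment is a sum of band-limited Gaussian noise processes — one per
dyadic EEG band, weighted to a requested band-power profile — plus
randomly placed spike-wave transients (a 70 ms biphasic spike followed by
a 3 Hz half-wave, 3x the background amplitude) emulating ictal
morphology.  The final signal is rescaled to the class's target standard
deviation.  Band shaping uses ordinary Butterworth filtering of white
noise, deliberately independent of the wavelet module it helps test.

Everything is deterministic given a seed; datasets derive one child seed
per segment from a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .bonn_io import BONN_FS, EEGSegment, LabeledDataset

#: Dyadic band edges (Hz) over the 0-50 Hz effective range:
#: gamma, beta, alpha, theta, delta.
BAND_EDGES_HZ = ((25.0, 50.0), (12.5, 25.0), (6.25, 12.5),
                 (3.125, 6.25), (0.0, 3.125))


@dataclass
class ClassProfile:
    """Spectral and amplitude recipe for one synthetic class."""

    class_code: int
    band_power: tuple[float, float, float, float, float]
    target_std: float
    spike_rate: float = 0.0

    def validate(self) -> None:
        if self.class_code not in (-1, 0, 1):
            raise ValueError(f"class_code must be -1, 0 or 1, got {self.class_code}")
        bp = np.asarray(self.band_power, dtype=float)
        if bp.shape != (5,) or (bp < 0).any():
            raise ValueError("band_power must be 5 nonnegative fractions")
        if abs(bp.sum() - 1.0) > 1e-9:
            raise ValueError(f"band_power must sum to 1, sums to {bp.sum()}")
        if not self.target_std > 0:
            raise ValueError("target_std must be positive")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")


def default_profiles() -> dict[int, ClassProfile]:
    """The three stock profiles keyed by class code.

    Dispersions (4.6 / 13.1 / 38.6) reproduce the ordering
    std(S) > std(FN) > std(OZ) observed between ictal, interictal and
    healthy recordings; band-power profiles shift mass toward theta/delta
    with disease severity, and spike rates grow from none (healthy)
    through sporadic (interictal) to ~2/s (ictal).
    """
    return {
        -1: ClassProfile(class_code=-1, target_std=4.6, spike_rate=0.0,
                         band_power=(0.20, 0.25, 0.30, 0.15, 0.10)),
        0: ClassProfile(class_code=0, target_std=13.1, spike_rate=0.2,
                        band_power=(0.08, 0.15, 0.22, 0.25, 0.30)),
        1: ClassProfile(class_code=1, target_std=38.6, spike_rate=2.0,
                        band_power=(0.03, 0.07, 0.12, 0.28, 0.50)),
    }


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float, high: float) -> np.ndarray:
    """Unit-std Gaussian noise band-limited to (low, high) Hz."""
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    high = min(high, nyq * 0.99)
    if low <= 0:
        sos = butter(4, high / nyq, btype="low", output="sos")
    else:
        sos = butter(4, [low / nyq, high / nyq], btype="band", output="sos")
    x = sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _spike_wave(fs: float) -> np.ndarray:
    """Unit-amplitude spike-wave template: 70 ms biphasic spike + 3 Hz
    half-wave after-discharge."""
    n_spike = max(4, int(round(0.070 * fs)))
    t = np.linspace(0, np.pi, n_spike)
    spike = np.sin(t) * np.sign(np.sin(2 * t) + 1e-12)  # sharp biphasic lobe
    n_wave = max(4, int(round(fs / 3.0 / 2.0)))  # half period of 3 Hz
    wave = -0.6 * np.sin(np.linspace(0, np.pi, n_wave))
    return np.concatenate([spike, wave])


def generate_segment(profile: ClassProfile, n: int = 4097,
                     fs: float = BONN_FS, seed: int = 0) -> EEGSegment:
    """One synthetic segment from a class profile; deterministic per seed."""
    profile.validate()
    if n < 512:
        raise ValueError(f"need n >= 512 samples, got {n}")
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    for frac, (low, high) in zip(profile.band_power, BAND_EDGES_HZ):
        if frac > 0:
            x += np.sqrt(frac) * _band_noise(rng, n, fs, low, high)
    background_std = x.std()
    if profile.spike_rate > 0:
        template = _spike_wave(fs) * 3.0 * background_std
        duration = n / fs
        n_spikes = rng.poisson(profile.spike_rate * duration)
        for _ in range(n_spikes):
            pos = rng.integers(0, max(1, n - len(template)))
            amp = rng.uniform(0.7, 1.3)
            x[pos:pos + len(template)] += amp * template[: n - pos]
    sd = x.std()
    if sd > 0:
        x *= profile.target_std / sd
    return EEGSegment(samples=x, fs=fs,
                      id=f"synthetic_c{profile.class_code}_s{seed}",
                      source_subset="synthetic")


def generate_dataset(n_per_class: dict[int, int] | None = None,
                     n_samples: int = 4097, fs: float = BONN_FS,
                     seed: int = 0,
                     profiles: dict[int, ClassProfile] | None = None
                     ) -> LabeledDataset:
    """Labelled synthetic dataset; defaults mirror the archive's
    200 healthy / 200 interictal / 100 ictal layout.

    Per-segment child seeds are spawned from the master seed, so the
    whole dataset is reproducible while segments stay independent.
    """
    n_per_class = n_per_class or {-1: 200, 0: 200, 1: 100}
    profiles = profiles or default_profiles()
    if any(c < 1 for c in n_per_class.values()):
        raise ValueError("counts must be >= 1")
    seed_seq = np.random.SeedSequence(seed)
    segments, labels = [], []
    for code in sorted(n_per_class):
        if code not in profiles:
            raise ValueError(f"no profile for class {code}")
        count = n_per_class[code]
        children = seed_seq.spawn(1)[0].generate_state(count) >> 1  # < 2^31
        for i in range(count):
            segments.append(generate_segment(profiles[code], n=n_samples,
                                             fs=fs, seed=int(children[i])))
            labels.append(code)
    return LabeledDataset(segments=segments, labels=labels)
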