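"""End-to-end glue: segments -> preprocessing -> wavelet features -> labels.

Thin composition layer used by the CLI, the tuning module and the
evaluation scripts; every step delegates to the module that owns it.
"""

from __future__ import annotations

import numpy as np

from .bonn_io import LabeledDataset
from .features import subband_stats
from .preprocess import PreprocessConfig, preprocess
from .sym_wavelet import WaveletFilterBank, sym4_filter_bank, wavedec4


def extract_features(dataset: LabeledDataset,
                     pre_cfg: PreprocessConfig | None = None,
                     fb: WaveletFilterBank | None = None,
                     abs_mode: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(X, y): the (n, 10) sub-band statistics matrix and class codes.

    Each segment is band-passed (and, by default, z-scored), decomposed
    four levels with the Symlet-4 bank, and summarised by the per-band
    mean/std features.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    fb = fb or sym4_filter_bank()
    rows = []
    for seg in dataset.segments:
        clean = preprocess(seg, pre_cfg)
        dec = wavedec4(clean, fb)
        rows.append(subband_stats(dec, abs_mode=abs_mode).values)
    return np.vstack(rows), dataset.y
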