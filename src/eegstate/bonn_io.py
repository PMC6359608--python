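"""Reading and writing EEG segments in the Bonn single-column ASCII dialect.

The Bonn epilepsy archive distributes each ~23.6 s single-channel segment as
a plain text file with one amplitude sample per line, recorded at 173.61 Hz
with 12-bit resolution.  The archive's five subsets are grouped into three
clinical states: ictal {S} (code 1), interictal {F,N} (code 0) and healthy
{O,Z} (code -1).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sampling rate of the Bonn recordings, Hz.
BONN_FS = 173.61

#: Class codes in ascending order: healthy {OZ}, interictal {FN}, ictal {S}.
CLASS_CODES = (-1, 0, 1)

_VALID_SOURCES = frozenset({"F", "N", "O", "Z", "S", "synthetic"})


class BonnFormatError(ValueError):
    """A segment file does not conform to the single-column dialect."""


@dataclass
class EEGSegment:
    """One channel's sampled signal with sampling-rate metadata.

    Parameters
    ----------
    samples
        Amplitudes in microvolts, in recording order.
    fs
        Sampling rate in Hz.  Defaults to the Bonn archive's 173.61 Hz.
    id
        Free-text identifier, typically derived from the file name.
    source_subset
        One of ``F, N, O, Z, S`` for archive data, or ``"synthetic"``.
    """

    samples: np.ndarray
    fs: float = BONN_FS
    id: str = ""
    source_subset: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError(
                f"segment {self.id!r}: need a 1-D signal of length >= 2, "
                f"got shape {self.samples.shape}"
            )
        if not np.isfinite(self.samples).all():
            raise ValueError(f"segment {self.id!r}: non-finite samples")
        if not self.fs > 0:
            raise ValueError(f"segment {self.id!r}: fs must be positive, got {self.fs}")
        if self.source_subset not in _VALID_SOURCES:
            raise ValueError(
                f"segment {self.id!r}: source_subset {self.source_subset!r} "
                f"not in {sorted(_VALID_SOURCES)}"
            )

    def __len__(self) -> int:
        return self.samples.size

    def with_samples(self, samples: np.ndarray) -> "EEGSegment":
        """Copy of this segment with new sample values (metadata preserved)."""
        return EEGSegment(samples=samples, fs=self.fs, id=self.id,
                          source_subset=self.source_subset)


@dataclass
class LabeledDataset:
    """Parallel lists of segments and three-state class codes.

    Codes follow the classifier's labelling convention: 1 = ictal {S},
    0 = interictal {FN}, -1 = healthy {OZ}.
    """

    segments: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.labels):
            raise ValueError(
                f"{len(self.segments)} segments but {len(self.labels)} labels"
            )
        bad = sorted({l for l in self.labels} - set(CLASS_CODES))
        if bad:
            raise ValueError(f"unknown class codes {bad}; expected subset of "
                             f"{list(CLASS_CODES)}")

    def __len__(self) -> int:
        return len(self.segments)

    def class_counts(self) -> dict:
        """Number of segments per class code, for every code present."""
        counts: dict = {}
        for l in self.labels:
            counts[l] = counts.get(l, 0) + 1
        return counts

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)


def read_segment(path, fs: float = BONN_FS, expect_length: int | None = None,
                 source_subset: str = "synthetic") -> EEGSegment:
    """Read one Bonn-dialect ASCII file: one decimal number per line.

    Blank lines (including trailing ones) are ignored.  ``expect_length``
    only logs a warning on mismatch — canonical Bonn files hold 4097
    samples, though 4096 is also seen in the literature — and never
    truncates.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise BonnFormatError(
                    f"{path}: line {lineno}: cannot parse {stripped!r} as a number"
                ) from None
    if not values:
        raise BonnFormatError(f"{path}: empty file")
    if expect_length is not None and len(values) != expect_length:
        logger.warning("%s: expected %d samples, found %d",
                       path, expect_length, len(values))
        warnings.warn(
            f"{path}: expected {expect_length} samples, found {len(values)}",
            stacklevel=2,
        )
    return EEGSegment(samples=np.array(values), fs=fs, id=path.stem,
                      source_subset=source_subset)


def write_segment(segment: EEGSegment, path) -> None:
    """Write a segment as one full-precision sample per line (LF endings)."""
    path = Path(path)
    try:
        with open(path, "w", newline="\n") as fh:
            for v in segment.samples:
                fh.write(f"{float(v)!r}\n")
    except OSError as exc:
        raise OSError(f"cannot write segment to {path}: {exc}") from exc


def assemble_dataset(groups: Mapping[int, Sequence[EEGSegment]]) -> LabeledDataset:
    """Combine per-class segment lists into one labelled dataset.

    ``groups`` maps class codes (1 = {S}, 0 = {FN}, -1 = {OZ}) to segment
    lists; input order is preserved within each class, classes appear in
    ascending code order.
    """
    if not groups:
        raise ValueError("empty group map: need at least one class")
    bad = sorted(set(groups) - set(CLASS_CODES))
    if bad:
        raise ValueError(f"unknown class codes {bad}; expected subset of "
                         f"{list(CLASS_CODES)}")
    segments: list[EEGSegment] = []
    labels: list[int] = []
    for code in sorted(groups):
        segs = list(groups[code])
        if not segs:
            raise ValueError(f"class {code}: empty segment list")
        segments.extend(segs)
        labels.extend([code] * len(segs))
    return LabeledDataset(segments=segments, labels=labels)


def write_manifest(rows: Sequence[tuple[str, int]], path) -> None:
    """Write a ``path,class_code`` manifest (CSV with header)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class_code"])
        for p, code in rows:
            writer.writerow([p, code])


def read_manifest_dataset(manifest_path, fs: float = BONN_FS,
                          expect_length: int | None = None) -> LabeledDataset:
    """Load a dataset from a ``path,class_code`` manifest.

    Relative paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    groups: dict[int, list[EEGSegment]] = {}
    order: list[tuple[EEGSegment, int]] = []
    with open(manifest_path, "r", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "path" not in reader.fieldnames \
                or "class_code" not in reader.fieldnames:
            raise BonnFormatError(
                f"{manifest_path}: manifest needs 'path' and 'class_code' columns"
            )
        for row in reader:
            code = int(row["class_code"])
            if code not in CLASS_CODES:
                raise ValueError(f"{manifest_path}: unknown class code {code}")
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            order.append((read_segment(p, fs=fs, expect_length=expect_length), code))
    if not order:
        raise BonnFormatError(f"{manifest_path}: empty manifest")
    return LabeledDataset(segments=[s for s, _ in order],
                          labels=[c for _, c in order])
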