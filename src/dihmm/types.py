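"""Core value types shared across the package.

The observation unit is a fixed-width genomic bin (200 bp by default, roughly
one nucleosome). A chromosome is represented as a bins x marks matrix: raw
read counts (:class:`BinCounts`) before binarization, presence/absence calls
(:class:`BinarizedTracks`) after. Decoding produces a :class:`StatePath`
holding the per-bin nucleosome-level state and the block-constant domain-level
state; stitching turns paths into :class:`GenomicSegment` intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class DihmmError(Exception):
    """Base class for all package errors."""


class ValidationError(DihmmError):
    """Invalid parameters, shapes or probability constraints."""


class FormatError(DihmmError):
    """Malformed input file."""


def _check_marks(mark_names: Sequence[str]) -> tuple[str, ...]:
    marks = tuple(str(m) for m in mark_names)
    if len(marks) == 0:
        raise ValidationError("at least one mark is required")
    if len(set(marks)) != len(marks):
        raise ValidationError(f"mark names must be unique, got {marks}")
    return marks


@dataclass(frozen=True)
class BinCounts:
    """Per-bin read counts for one (cell type, chromosome).

    ``counts`` has shape (num_bins, num_marks); entries are non-negative
    integers. Bins are 0-indexed, half-open, ``bin_size`` bp wide.
    """

    cell_type: str
    chromosome: str
    bin_size: int
    counts: np.ndarray
    mark_names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "mark_names", _check_marks(self.mark_names))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D (bins x marks) matrix")
        if counts.shape[1] != len(self.mark_names):
            raise ValidationError(
                f"counts has {counts.shape[1]} columns but {len(self.mark_names)} mark names"
            )
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        object.__setattr__(self, "counts", counts.astype(np.int64, copy=False))

    @property
    def num_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def num_marks(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class BinarizedTracks:
    """0/1 presence calls per mark per bin for one (cell type, chromosome)."""

    cell_type: str
    chromosome: str
    bin_size: int
    data: np.ndarray
    mark_names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "mark_names", _check_marks(self.mark_names))
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValidationError("data must be a 2-D (bins x marks) matrix")
        if data.shape[0] < 1:
            raise ValidationError("at least one bin is required")
        if data.shape[1] != len(self.mark_names):
            raise ValidationError(
                f"data has {data.shape[1]} columns but {len(self.mark_names)} mark names"
            )
        if not np.isin(data, (0, 1)).all():
            raise ValidationError("binarized entries must be 0 or 1")
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        object.__setattr__(self, "data", data.astype(np.uint8, copy=False))

    @property
    def num_bins(self) -> int:
        return self.data.shape[0]

    @property
    def num_marks(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class StatePath:
    """Joint per-bin state assignment.

    ``nuc_states[i]`` is the nucleosome-level state of bin i, ``dom_states[i]``
    the domain-level state. Domain states are constant within each block of
    ``block_size`` bins ([b*D_S, (b+1)*D_S)); the final block may be partial.
    """

    nuc_states: np.ndarray
    dom_states: np.ndarray
    block_size: int

    def __post_init__(self):
        nuc = np.asarray(self.nuc_states, dtype=np.int64)
        dom = np.asarray(self.dom_states, dtype=np.int64)
        if nuc.ndim != 1 or dom.ndim != 1 or nuc.shape != dom.shape:
            raise ValidationError("nuc_states and dom_states must be equal-length vectors")
        if nuc.size < 1:
            raise ValidationError("empty state path")
        if self.block_size < 1:
            raise ValidationError("block_size must be >= 1")
        for b in range(0, dom.size, self.block_size):
            block = dom[b : b + self.block_size]
            if (block != block[0]).any():
                raise ValidationError(
                    f"domain state changes inside block starting at bin {b}"
                )
        object.__setattr__(self, "nuc_states", nuc)
        object.__setattr__(self, "dom_states", dom)

    def __len__(self) -> int:
        return self.nuc_states.size


@dataclass(frozen=True)
class GenomicSegment:
    """A stitched run of one state at one annotation level (0-based, half-open)."""

    chromosome: str
    start: int
    end: int
    level: str  # "nucleosome" | "domain"
    state: int
    cell_type: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"segment end ({self.end}) must exceed start ({self.start})"
            )
        if self.level not in ("nucleosome", "domain"):
            raise ValidationError(f"unknown level {self.level!r}")

    @property
    def length(self) -> int:
        return self.end - self.start
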