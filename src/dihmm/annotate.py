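"""Genome-wide application of a trained model: decoding, stitching, BED output.

Each (cell type, chromosome) sequence is decoded independently. Runs of
identical states are stitched into maximal segments; nucleosome-level
segments are multiples of the bin size, domain-level segments multiples of
bin_size * D_S (4 kb at defaults) except for a possibly shorter
chromosome-terminal segment when the sequence length is not a whole number
of blocks.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import inference
from .model import DiHMMModel
from .types import BinarizedTracks, GenomicSegment, StatePath, ValidationError


def segment_genome(
    model: DiHMMModel,
    tracks_list: Sequence[BinarizedTracks],
    decoder: str = "viterbi",
) -> list[StatePath]:
    """Decode every sequence with the configured decoder."""
    if decoder not in ("viterbi", "posterior"):
        raise ValidationError(f"unknown decoder {decoder!r}")
    paths = []
    for tr in tracks_list:
        if decoder == "viterbi":
            paths.append(inference.viterbi(model, tr))
        else:
            post = inference.posteriors(model, tr)
            paths.append(inference.posterior_decode(post, model.block_size))
    return paths


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(start_idx, end_idx, state) for maximal constant runs."""
    change = np.nonzero(np.diff(states))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    return [(int(s), int(e), int(states[s])) for s, e in zip(starts, ends)]


def stitch(
    path: StatePath,
    level: str,
    bin_size: int = 200,
    chromosome: str = "chrS",
    cell_type: str = "",
    chrom_size: int | None = None,
) -> list[GenomicSegment]:
    """Merge consecutive identical states into maximal genomic segments.

    ``chrom_size`` optionally truncates the final segment to the true
    chromosome end (a trailing partial bin).
    """
    if level == "nucleosome":
        states = path.nuc_states
    elif level == "domain":
        states = path.dom_states
    else:
        raise ValidationError(f"unknown level {level!r}")
    segments = []
    for s, e, state in _runs(states):
        start, end = s * bin_size, e * bin_size
        if chrom_size is not None:
            end = min(end, chrom_size)
        segments.append(
            GenomicSegment(
                chromosome=chromosome,
                start=start,
                end=end,
                level=level,
                state=state,
                cell_type=cell_type,
            )
        )
    return segments


def unstitch(segments: Sequence[GenomicSegment], bin_size: int = 200) -> np.ndarray:
    """Per-bin state vector from tiling segments (inverse of :func:`stitch`)."""
    total_bins = -(-max(s.end for s in segments) // bin_size)
    states = np.full(total_bins, -1, dtype=np.int64)
    for seg in segments:
        states[seg.start // bin_size : -(-seg.end // bin_size)] = seg.state
    return states


_DEFAULT_COLORS = [
    "228,26,28", "55,126,184", "77,175,74", "152,78,163", "255,127,0",
    "255,255,51", "166,86,40", "247,129,191", "153,153,153", "102,194,165",
]


def write_bed(
    segments: Sequence[GenomicSegment],
    destination,
    label_map: dict[int, str] | None = None,
    color_map: dict[int, str] | None = None,
) -> None:
    """Write segments as BED9, sorted by (chromosome, start)."""
    rows = []
    for seg in sorted(segments, key=lambda s: (s.chromosome, s.start)):
        if label_map is not None and seg.state not in label_map:
            raise ValidationError(f"state {seg.state} missing from label_map")
        prefix = "N" if seg.level == "nucleosome" else "D"
        name = label_map[seg.state] if label_map else f"{prefix}{seg.state + 1}"
        color = (
            color_map[seg.state]
            if color_map
            else _DEFAULT_COLORS[seg.state % len(_DEFAULT_COLORS)]
        )
        rows.append(
            (seg.chromosome, seg.start, seg.end, name, 0, ".", seg.start, seg.end, color)
        )
    df = pd.DataFrame(rows)
    if hasattr(destination, "write"):
        df.to_csv(destination, sep="\t", header=False, index=False)
    else:
        df.to_csv(destination, sep="\t", header=False, index=False)


def read_bed_segments(
    source, level: str, cell_type: str = ""
) -> list[GenomicSegment]:
    """Read BED(9 or 4+) back into segments; state parsed from N#/D# names."""
    df = pd.read_csv(source, sep="\t", header=None)
    segments = []
    for _, row in df.iterrows():
        name = str(row[3])
        state = int(name.lstrip("ND")) - 1 if name[0] in "ND" else int(name)
        segments.append(
            GenomicSegment(
                chromosome=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                level=level,
                state=state,
                cell_type=cell_type,
            )
        )
    return segments


def domain_boundaries(domain_segments: Sequence[GenomicSegment]) -> list[int]:
    """Positions (bp) where adjacent domain segments carry different states."""
    for a, b in zip(domain_segments, domain_segments[1:]):
        if b.start < a.start:
            raise ValidationError("domain segments must be sorted by start")
    return [
        b.start
        for a, b in zip(domain_segments, domain_segments[1:])
        if a.state != b.state
    ]


def coverage_table(
    segments: Sequence[GenomicSegment], n_states: int
) -> pd.DataFrame:
    """Per-state genomic coverage fraction per cell type (one row per state)."""
    df = pd.DataFrame(
        [(s.cell_type, s.state, s.length) for s in segments],
        columns=["cell_type", "state", "length"],
    )
    table = df.pivot_table(
        index="state", columns="cell_type", values="length", aggfunc="sum", fill_value=0
    ).reindex(range(n_states), fill_value=0)
    return table / table.sum(axis=0)
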