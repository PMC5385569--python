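"""Poisson-background binarization of ChIP-seq signal into 0/1 calls per bin.

Reads are reduced to (optionally shifted) 5' positions and counted in fixed
200 bp bins. Each mark's background is a single Poisson rate — the mean count
per bin over the chromosome — and a bin is called present when its count's
upper-tail probability under that background falls at or below the P-value
threshold (1e-4 by default). Binarized matrices are written in a
ChromHMM-compatible plain-text format so they interoperate with existing
chromatin-state tooling.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import BinarizedTracks, BinCounts, FormatError, ValidationError

DEFAULT_BIN_SIZE = 200
DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_SHIFT = 100


def read_bed_reads(path) -> pd.DataFrame:
    """Read aligned-read intervals from BED (0-based, half-open, col 6 strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        i = int(np.nonzero(bad.values)[0][0])
        raise FormatError(f"{path}: line {i + 1}: strand must be '+' or '-'")
    return df


def count_reads(
    reads: pd.DataFrame,
    chrom_size: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    shift: int = DEFAULT_SHIFT,
    cell_type: str = "",
    chromosome: str = "",
    mark_names: Sequence[str] | None = None,
) -> BinCounts:
    """Bin shifted 5' read positions into per-mark counts.

    ``reads`` columns: start, end, strand, and (if multiple marks) mark. The
    5' end is ``start`` for + reads and ``end - 1`` for - reads; it is shifted
    ``shift`` bp toward the fragment centre (downstream for +, upstream for -)
    and clipped to the chromosome. Bins are [b*bin_size, (b+1)*bin_size); the
    trailing partial bin is kept.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    if chrom_size <= 0:
        raise ValidationError("chrom_size must be positive")
    if (reads["start"] < 0).any() or (reads["end"] > chrom_size).any():
        bad = reads[(reads["start"] < 0) | (reads["end"] > chrom_size)].iloc[0]
        raise ValidationError(
            f"read [{bad['start']}, {bad['end']}) outside chromosome of size {chrom_size}"
        )
    if "mark" in reads.columns:
        marks_col = reads["mark"].astype(str)
        if mark_names is None:
            mark_names = tuple(sorted(marks_col.unique()))
        unknown = set(marks_col.unique()) - set(mark_names)
        if unknown:
            raise ValidationError(f"unknown mark labels: {sorted(unknown)}")
    else:
        if mark_names is None or len(mark_names) != 1:
            raise ValidationError(
                "single-mark reads require exactly one name in mark_names"
            )
        marks_col = pd.Series([mark_names[0]] * len(reads))
    num_bins = -(-chrom_size // bin_size)
    counts = np.zeros((num_bins, len(mark_names)), dtype=np.int64)
    plus = reads["strand"].values == "+"
    five = np.where(plus, reads["start"].values, reads["end"].values - 1)
    pos = np.clip(five + np.where(plus, shift, -shift), 0, chrom_size - 1)
    bins = pos // bin_size
    mark_idx = pd.Categorical(marks_col, categories=list(mark_names)).codes
    np.add.at(counts, (bins, mark_idx), 1)
    return BinCounts(
        cell_type=cell_type,
        chromosome=chromosome,
        bin_size=bin_size,
        counts=counts,
        mark_names=tuple(mark_names),
    )


def poisson_binarize(
    counts: BinCounts, p_threshold: float = DEFAULT_P_THRESHOLD
) -> BinarizedTracks:
    """Call a bin present when P(X >= count | Poisson(lambda_m)) <= p_threshold.

    lambda_m is the mark's mean count per bin over the chromosome. A count of
    zero is never called present (the upper-tail test at 0 is vacuous).
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValidationError("p_threshold must be in (0, 1)")
    if counts.num_bins == 0:
        raise ValidationError("empty counts matrix")
    lam = counts.counts.mean(axis=0)  # per-mark background rate
    # P(X >= c) = sf(c - 1); upper tail including the observed count
    tail = sps.poisson.sf(counts.counts - 1, lam[None, :])
    data = ((tail <= p_threshold) & (counts.counts >= 1)).astype(np.uint8)
    return BinarizedTracks(
        cell_type=counts.cell_type,
        chromosome=counts.chromosome,
        bin_size=counts.bin_size,
        data=data,
        mark_names=counts.mark_names,
    )


def write_binarized(tracks: BinarizedTracks, destination) -> None:
    """ChromHMM-compatible text: header (cell TAB chrom), mark names, 0/1 rows."""
    lines = [
        f"{tracks.cell_type}\t{tracks.chromosome}",
        "\t".join(tracks.mark_names),
    ]
    lines.extend("\t".join(map(str, row)) for row in tracks.data)
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def read_binarized(source, bin_size: int = DEFAULT_BIN_SIZE) -> BinarizedTracks:
    """Parse the text format written by :func:`write_binarized`."""
    if hasattr(source, "read"):
        raw = source.read()
    else:
        raw = Path(source).read_text()
    lines = raw.splitlines()
    if len(lines) < 3:
        raise FormatError("binarized file needs a 2-line header and at least one bin")
    header = lines[0].split("\t")
    if len(header) != 2:
        raise FormatError("line 1: expected 'cell_type<TAB>chromosome'")
    cell_type, chromosome = header
    marks = lines[1].split("\t")
    rows = []
    for ln, line in enumerate(lines[2:], start=3):
        tokens = line.split("\t")
        if len(tokens) != len(marks):
            raise FormatError(
                f"line {ln}: {len(tokens)} fields, expected {len(marks)}"
            )
        for tok in tokens:
            if tok not in ("0", "1"):
                raise FormatError(f"line {ln}: token {tok!r} is not 0 or 1")
        rows.append([int(tok) for tok in tokens])
    return BinarizedTracks(
        cell_type=cell_type,
        chromosome=chromosome,
        bin_size=bin_size,
        data=np.array(rows, dtype=np.uint8),
        mark_names=tuple(marks),
    )


def binarized_filename(cell_type: str, chromosome: str) -> str:
    return f"{cell_type}_{chromosome}_binary.txt"
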