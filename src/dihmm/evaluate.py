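"""Downstream evaluation statistics for chromatin-state annotations.

Implements the standard battery used to characterize a segmentation:

- fold enrichment of a state against an interval annotation, computed as
  (m/n)/(M/N) on bin counts with a two-sided Fisher exact test;
- enrichment of domain-state transitions at externally supplied boundary
  intervals (for example TAD boundaries from Hi-C);
- strand-aware TSS-centred state-frequency profiles, min-max normalized
  per state;
- mean expression z-score per (state, cell line) for genes whose TSS falls
  within +/- 2 kb of a state segment;
- per-window state-frequency vectors and a composite similarity score
  between two segmentations combining best-match Pearson correlation with a
  conditional Gini specificity term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import GenomicSegment, ValidationError

TSS_WINDOW_BP = 2000


# ---------------------------------------------------------------------------
# bin-level helpers
# ---------------------------------------------------------------------------


def _segments_to_bins(
    segments: Sequence[GenomicSegment], bin_size: int
) -> tuple[np.ndarray, int]:
    """Per-bin state vector (-1 where unannotated) over the segment extent."""
    if not segments:
        raise ValidationError("no segments supplied")
    n_bins = -(-max(s.end for s in segments) // bin_size)
    states = np.full(n_bins, -1, dtype=np.int64)
    for seg in segments:
        states[seg.start // bin_size : -(-seg.end // bin_size)] = seg.state
    return states, n_bins


def _intervals_to_mask(intervals, n_bins: int, bin_size: int) -> np.ndarray:
    mask = np.zeros(n_bins, dtype=bool)
    for start, end in intervals:
        lo = max(int(start) // bin_size, 0)
        hi = min(-(-int(end) // bin_size), n_bins)
        mask[lo:hi] = True
    return mask


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def fold_enrichment(
    segments: Sequence[GenomicSegment],
    annotation: Sequence[tuple[int, int]],
    bin_size: int = 200,
) -> pd.DataFrame:
    """(m/n)/(M/N) per state, with the 2x2 counts and a Fisher exact p-value.

    m = state bins overlapping the annotation, n = annotated bins,
    M = state bins, N = total bins. Undefined ratios (n = 0 or M = 0) are
    reported with enrichment NaN and flagged in the ``defined`` column rather
    than silently dropped.
    """
    states, n_bins = _segments_to_bins(segments, bin_size)
    mask = _intervals_to_mask(annotation, n_bins, bin_size)
    n = int(mask.sum())
    N = n_bins
    rows = []
    for k in sorted(set(states[states >= 0])):
        in_state = states == k
        M = int(in_state.sum())
        m = int((in_state & mask).sum())
        defined = n > 0 and M > 0
        enr = (m / n) / (M / N) if defined else np.nan
        table = [[m, M - m], [n - m, N - M - (n - m)]]
        p = sps.fisher_exact(table, alternative="two-sided")[1] if defined else np.nan
        rows.append((k, m, n, M, N, enr, p, defined))
    return pd.DataFrame(
        rows, columns=["state", "m", "n", "M", "N", "enrichment", "fisher_p", "defined"]
    )


def boundary_enrichment(
    domain_segments: Sequence[GenomicSegment],
    intervals: Sequence[tuple[int, int]],
    bin_size: int = 200,
    block_size: int = 20,
) -> dict:
    """Enrichment of domain-state transitions at external boundary intervals.

    Every junction between consecutive blocks is a potential transition
    position; the fold change compares the transition rate at junctions that
    fall inside the intervals with the genome-wide rate. Fisher exact test on
    the 2x2 (inside/outside x transition/no-transition) counts.
    """
    segs = sorted(domain_segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        if b.start != a.end:
            raise ValidationError("domain segments must tile the chromosome")
    step = bin_size * block_size
    extent = segs[-1].end
    junctions = np.arange(step, extent, step)
    bounds = {
        b.start for a, b in zip(segs, segs[1:]) if a.state != b.state
    }
    is_trans = np.array([j in bounds for j in junctions])
    inside = np.zeros(junctions.size, dtype=bool)
    for start, end in intervals:
        inside |= (junctions >= start) & (junctions < end)
    n_in = int(inside.sum())
    if n_in == 0:
        return {"fold_change": np.nan, "fisher_p": np.nan, "defined": False,
                "n_inside": 0, "n_total": int(junctions.size)}
    rate_in = is_trans[inside].mean()
    rate_all = is_trans.mean()
    fold = rate_in / rate_all if rate_all > 0 else np.nan
    table = [
        [int(is_trans[inside].sum()), int(n_in - is_trans[inside].sum())],
        [int(is_trans[~inside].sum()), int((~inside).sum() - is_trans[~inside].sum())],
    ]
    p = sps.fisher_exact(table, alternative="two-sided")[1]
    return {
        "fold_change": float(fold),
        "fisher_p": float(p),
        "defined": bool(rate_all > 0),
        "n_inside": n_in,
        "n_total": int(junctions.size),
        "rate_inside": float(rate_in),
        "rate_genome": float(rate_all),
    }


# ---------------------------------------------------------------------------
# TSS profiles
# ---------------------------------------------------------------------------


def tss_enrichment_profile(
    segments: Sequence[GenomicSegment],
    tss: pd.DataFrame,
    window_bp: int = 10000,
    step_bp: int = 200,
    bin_size: int = 200,
) -> tuple[pd.DataFrame, list[int]]:
    """State frequency around TSS, strand-aware, min-max normalized per state.

    ``tss`` columns: ``tss`` (bp) and ``strand`` ('+'/'-'); minus-strand genes
    are flipped so downstream-of-gene always appears at positive offsets.
    Returns (profiles indexed by offset bp, flat_states) where flat states
    (constant raw profile) are left unnormalized at 0 and listed separately.
    """
    if window_bp % step_bp != 0:
        raise ValidationError("window_bp must be a multiple of step_bp")
    if len(tss) == 0:
        raise ValidationError("no TSS supplied")
    states, n_bins = _segments_to_bins(segments, bin_size)
    offsets = np.arange(-window_bp, window_bp + step_bp, step_bp)
    ks = sorted(set(states[states >= 0]))
    counts = np.zeros((len(ks), offsets.size))
    totals = np.zeros(offsets.size)
    k_index = {k: i for i, k in enumerate(ks)}
    for _, row in tss.iterrows():
        sign = 1 if row["strand"] == "+" else -1
        pos = int(row["tss"]) + sign * offsets
        ok = (pos >= 0) & (pos < n_bins * bin_size)
        st = states[pos[ok] // bin_size]
        idx = np.nonzero(ok)[0]
        totals[idx] += 1
        for o, s in zip(idx, st):
            if s >= 0:
                counts[k_index[s], o] += 1
    with np.errstate(invalid="ignore"):
        raw = counts / totals[None, :]
    raw = np.nan_to_num(raw)
    flat = []
    norm = np.zeros_like(raw)
    for i, k in enumerate(ks):
        lo, hi = raw[i].min(), raw[i].max()
        if hi - lo < 1e-12:
            flat.append(k)
        else:
            norm[i] = (raw[i] - lo) / (hi - lo)
    out = pd.DataFrame(norm.T, index=offsets, columns=ks)
    out.index.name = "offset_bp"
    return out, flat


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def expression_by_state(
    segments: Sequence[GenomicSegment],
    genes: pd.DataFrame,
    cell_lines: Sequence[str],
    bin_size: int = 200,
    tss_window: int = TSS_WINDOW_BP,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean expression z-score per (state, cell line).

    ``genes`` columns: ``tss``, ``strand``, and one expression column per
    cell line. Expression is z-scored per gene across cell lines (population
    standard deviation); genes with zero variance are excluded and counted.
    A state maps to a gene when any of its segments overlaps
    [TSS - tss_window, TSS + tss_window] (inclusive endpoints).
    """
    if len(cell_lines) < 2:
        raise ValidationError("z-scores require at least 2 cell lines")
    expr = genes[list(cell_lines)].to_numpy(dtype=float)
    mu = expr.mean(axis=1, keepdims=True)
    sd = expr.std(axis=1, keepdims=True)  # population sd
    ok = sd[:, 0] > 0
    z = np.full_like(expr, np.nan)
    z[ok] = (expr[ok] - mu[ok]) / sd[ok]
    ks = sorted({s.state for s in segments})
    sums = {k: np.zeros(len(cell_lines)) for k in ks}
    counts = {k: 0 for k in ks}
    tss_vals = genes["tss"].to_numpy(dtype=np.int64)
    for k in ks:
        segs = [s for s in segments if s.state == k]
        for gi in np.nonzero(ok)[0]:
            lo, hi = tss_vals[gi] - tss_window, tss_vals[gi] + tss_window
            if any(s.start <= hi and s.end - 1 >= lo for s in segs):
                sums[k] += z[gi]
                counts[k] += 1
    rows = {
        k: (sums[k] / counts[k] if counts[k] else np.full(len(cell_lines), np.nan))
        for k in ks
    }
    table = pd.DataFrame(rows, index=list(cell_lines)).T
    table.index.name = "state"
    gene_counts = pd.Series({k: counts[k] for k in ks}, name="n_genes")
    gene_counts.attrs["n_excluded_constant"] = int((~ok).sum())
    return table, gene_counts


# ---------------------------------------------------------------------------
# frequency vectors, Gini, similarity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyVectors:
    """Per-state coverage fraction in fixed windows tiling the genome from 0."""

    window_size: int
    states: tuple[int, ...]
    vectors: np.ndarray  # (num_states, num_windows)

    @property
    def dominant(self) -> np.ndarray:
        """Index (into ``states``) of the dominant state per window."""
        return np.argmax(self.vectors, axis=0)


def state_frequency_vectors(
    segments: Sequence[GenomicSegment], window_size: int = 4000
) -> FrequencyVectors:
    """Fraction of each window covered by each state (bp-fraction convention)."""
    if not segments:
        raise ValidationError("no segments supplied")
    extent = max(s.end for s in segments)
    n_win = -(-extent // window_size)
    ks = sorted({s.state for s in segments})
    k_index = {k: i for i, k in enumerate(ks)}
    vec = np.zeros((len(ks), n_win))
    for seg in segments:
        w0 = seg.start // window_size
        w1 = (seg.end - 1) // window_size
        for w in range(w0, w1 + 1):
            lo = max(seg.start, w * window_size)
            hi = min(seg.end, (w + 1) * window_size)
            vec[k_index[seg.state], w] += (hi - lo) / window_size
    return FrequencyVectors(window_size=window_size, states=tuple(ks), vectors=vec)


def gini_index(conditional: np.ndarray) -> float:
    """Concentration of a probability vector: 0 = uniform, (K-1)/K = point mass.

    Relative mean absolute difference: sum_{a,b} |p_a - p_b| / (2 K^2 pbar).
    """
    p = np.asarray(conditional, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("conditional must be a non-empty vector")
    if (p < 0).any():
        raise ValidationError("probabilities must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValidationError("zero probability vector")
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"probability vector sums to {total:.12g}, expected 1")
    K = p.size
    mad = np.abs(p[:, None] - p[None, :]).sum()
    return float(mad / (2.0 * K * K * (1.0 / K)))


def _pcc_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of X and every row of Y.

    Rows with zero variance (degenerate, constant frequency) get correlation
    0 against everything, by convention.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    yn = np.linalg.norm(Yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (Xc @ Yc.T) / np.outer(xn, yn)
    return np.nan_to_num(c)


def _directional_score(X: FrequencyVectors, Y: FrequencyVectors) -> float:
    pcc = _pcc_matrix(X.vectors, Y.vectors)
    domX, domY = X.dominant, Y.dominant
    Ky = len(Y.states)
    gini_norm = (Ky - 1) / Ky if Ky > 1 else 1.0
    terms = []
    for i in range(len(X.states)):
        win = domX == i
        if not win.any():
            continue  # state never dominant; no conditional distribution
        cond = np.bincount(domY[win], minlength=Ky).astype(float)
        cond /= cond.sum()
        g = gini_index(cond) / gini_norm if Ky > 1 else 1.0
        terms.append(max(pcc[i].max(), 0.0) * g)
    if not terms:
        raise ValidationError("no state is dominant in any window")
    return float(np.mean(terms))


def similarity_score(X: FrequencyVectors, Y: FrequencyVectors) -> float:
    """Composite agreement between two segmentations on the same window grid.

    For each state k of X: the best-match Pearson correlation
    max_j PCC(X_k, Y_j) is weighted by the normalized Gini of Y's
    dominant-state distribution over windows where X's dominant state is k
    (the specificity of the state mapping). The mean over states is
    symmetrized across both directions. Identical segmentations (up to state
    relabelling) score 1; independent ones score near 0.
    """
    if X.window_size != Y.window_size or X.vectors.shape[1] != Y.vectors.shape[1]:
        raise ValidationError("frequency vectors must share the same window grid")
    return 0.5 * (_directional_score(X, Y) + _directional_score(Y, X))
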