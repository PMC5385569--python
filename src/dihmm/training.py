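"""Hierarchical Baum-Welch training.

Each EM iteration runs the scaled forward-backward recursions on every
sequence (one sequence per cell type x chromosome, all sharing a single
parameter set), accumulates expected sufficient statistics, and re-estimates
the four parameter families in closed form:

- domain transitions from the expected pair counts at block boundaries,
- nucleosome transitions from the expected pair counts at every step,
  credited to the destination domain and marginalized over the source domain,
- initial probabilities from the first-bin posteriors averaged over
  sequences,
- emissions from the expected (state, mark on) counts divided by expected
  state occupancy, the domain marginalized out since emissions depend only
  on the nucleosome-level state.

A small pseudocount keeps every probability strictly positive, at the cost
of an O(pseudocount) violation of exact EM monotonicity; the convergence
check tolerates this.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernels, inference
from .binarize import read_binarized
from .model import DiHMMModel, init_kcentre, validate
from .types import BinarizedTracks, DihmmError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SufficientStats:
    """Expected counts from one E-step, additive over sequences."""

    xi_boundary: np.ndarray  # (K_d, K_d)
    xi_nuc: np.ndarray  # (K_d, K_n, K_n)
    gamma_first: np.ndarray  # (K_n, K_d), summed over sequences
    emit_on: np.ndarray  # (K_n, M)
    occupancy: np.ndarray  # (K_n,)
    n_sequences: int
    log_likelihood: float = 0.0

    def __iadd__(self, other: "SufficientStats") -> "SufficientStats":
        self.xi_boundary += other.xi_boundary
        self.xi_nuc += other.xi_nuc
        self.gamma_first += other.gamma_first
        self.emit_on += other.emit_on
        self.occupancy += other.occupancy
        self.n_sequences += other.n_sequences
        self.log_likelihood += other.log_likelihood
        return self

    def __add__(self, other: "SufficientStats") -> "SufficientStats":
        out = SufficientStats(
            xi_boundary=self.xi_boundary.copy(),
            xi_nuc=self.xi_nuc.copy(),
            gamma_first=self.gamma_first.copy(),
            emit_on=self.emit_on.copy(),
            occupancy=self.occupancy.copy(),
            n_sequences=self.n_sequences,
            log_likelihood=self.log_likelihood,
        )
        out += other
        return out


def accumulate_stats(model: DiHMMModel, tracks: BinarizedTracks) -> SufficientStats:
    """E-step sufficient statistics for one sequence under the current model."""
    fwd = inference.forward(model, tracks)
    beta = inference.backward(model, tracks, fwd.scales)
    B = inference.emission_matrix(model, tracks)
    xi_boundary, xi_nuc, gamma_first, emit_on, occupancy = _kernels.stats_kernel(
        tracks.data,
        B,
        model.nuc_trans,
        model.dom_trans,
        fwd.alpha_hat,
        beta,
        fwd.scales,
        model.block_size,
    )
    return SufficientStats(
        xi_boundary=xi_boundary,
        xi_nuc=xi_nuc,
        gamma_first=gamma_first,
        emit_on=emit_on,
        occupancy=occupancy,
        n_sequences=1,
        log_likelihood=fwd.log_likelihood,
    )


def update_parameters(
    stats: SufficientStats,
    block_size: int,
    mark_names: Sequence[str],
    pseudocount: float = 1e-6,
) -> DiHMMModel:
    """M-step: closed-form re-estimation from expected counts."""
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    kd, kn, _ = stats.xi_nuc.shape
    m = stats.emit_on.shape[1]
    Tn = stats.xi_boundary + pseudocount
    T = Tn / Tn.sum(axis=1, keepdims=True)
    tn = stats.xi_nuc + pseudocount
    t = tn / tn.sum(axis=2, keepdims=True)
    p0 = stats.gamma_first + pseudocount
    P0 = p0 / p0.sum()
    # Bernoulli MLE with matched smoothing of on/off outcomes
    E = (stats.emit_on + pseudocount) / (stats.occupancy + 2.0 * pseudocount)[:, None]
    model = DiHMMModel(
        emissions=E,
        nuc_trans=t,
        dom_trans=T,
        initial=P0,
        block_size=block_size,
        mark_names=tuple(mark_names),
    )
    problems = validate(model)
    if problems:
        raise ValidationError("re-estimated model invalid: " + "; ".join(problems))
    return model


def baum_welch(
    model0: DiHMMModel,
    tracks_list: Sequence[BinarizedTracks],
    max_iter: int = 500,
    tol: float = 1e-4,
    pseudocount: float = 1e-6,
) -> tuple[DiHMMModel, list[float]]:
    """Full-batch EM over multiple independent sequences sharing one model.

    Returns the final model and the log-likelihood trace (one entry per
    iteration, each evaluated at the model *entering* that iteration). The
    trace is non-decreasing up to a relative tolerance of ~1e-8 that absorbs
    pseudocount smoothing and floating-point rounding. Iteration stops when
    the absolute log-likelihood improvement falls below ``tol`` (total over
    all sequences, not per bin) or after ``max_iter`` iterations.
    """
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    if not tracks_list:
        raise ValidationError("at least one sequence is required")
    model = model0
    trace: list[float] = []
    for it in range(max_iter):
        stats = accumulate_stats(model, tracks_list[0])
        for tr in tracks_list[1:]:
            stats += accumulate_stats(model, tr)
        ll = stats.log_likelihood
        if not np.isfinite(ll):
            raise DihmmError(f"non-finite log-likelihood at iteration {it}")
        trace.append(ll)
        logger.info("EM iteration %d: log-likelihood %.6f", it, ll)
        model = update_parameters(
            stats, model.block_size, model.mark_names, pseudocount
        )
        if it > 0 and abs(ll - trace[-2]) < tol:
            break
    return model, trace


@dataclass
class TrainingReport:
    """Settings and diagnostics from one training run."""

    log_likelihood_trace: list[float]
    n_iterations: int
    converged: bool
    elapsed_seconds: float
    settings: dict = field(default_factory=dict)


def train(
    binarized_dir,
    n_nuc: int = 30,
    n_dom: int = 30,
    block_size: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    pseudocount: float = 1e-6,
    tracks_list: Sequence[BinarizedTracks] | None = None,
) -> tuple[DiHMMModel, TrainingReport]:
    """k-centre initialization followed by Baum-Welch over all sequences.

    Sequences (cell type x chromosome) are loaded from every ``*_binary.txt``
    file in ``binarized_dir`` unless ``tracks_list`` is given directly. All
    sequences must share the same marks and contribute to a single model.
    """
    if tracks_list is None:
        paths = sorted(Path(binarized_dir).glob("*_binary.txt"))
        if not paths:
            raise ValidationError(f"no *_binary.txt files found in {binarized_dir}")
        tracks_list = [read_binarized(p) for p in paths]
    marks = tracks_list[0].mark_names
    bad = [
        f"{tr.cell_type}/{tr.chromosome}"
        for tr in tracks_list
        if tr.mark_names != marks
    ]
    if bad:
        raise ValidationError(
            "inconsistent mark sets across sequences: " + ", ".join(bad)
        )
    t0 = time.perf_counter()
    model0 = init_kcentre(tracks_list, n_nuc, n_dom, block_size, seed=seed)
    model, trace = baum_welch(
        model0, tracks_list, max_iter=max_iter, tol=tol, pseudocount=pseudocount
    )
    elapsed = time.perf_counter() - t0
    converged = len(trace) < max_iter or (
        len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol
    )
    report = TrainingReport(
        log_likelihood_trace=trace,
        n_iterations=len(trace),
        converged=converged,
        elapsed_seconds=elapsed,
        settings={
            "n_nuc": n_nuc,
            "n_dom": n_dom,
            "block_size": block_size,
            "seed": seed,
            "max_iter": max_iter,
            "tol": tol,
            "pseudocount": pseudocount,
            "n_sequences": len(tracks_list),
        },
    )
    return model, report
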