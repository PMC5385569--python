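"""Generative sampling from the two-level model.

The sampler is the exact adjoint of the inference recursions: the initial
(nucleosome, domain) pair is drawn from the joint initial distribution, the
domain state is redrawn from the domain transition matrix only on steps
entering a new block, and every nucleosome step uses the transition matrix of
the *destination* domain. Observations are independent Bernoulli draws per
mark conditioned on the nucleosome state. All randomness derives from one
integer seed through numpy's SeedSequence spawning, so each operation has a
reproducible sub-stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .model import DiHMMModel, validate
from .types import BinarizedTracks, BinCounts, StatePath, ValidationError


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def sample_path(model: DiHMMModel, length_bins: int, seed: int = 0) -> StatePath:
    """Draw a joint state path of ``length_bins`` bins."""
    if length_bins < 1:
        raise ValidationError("length_bins must be >= 1")
    problems = validate(model)
    if problems:
        raise ValidationError("invalid model: " + "; ".join(problems))
    u = _rng(seed, 0).random((length_bins, 2))
    nuc, dom = _kernels.sample_path_kernel(
        model.nuc_trans, model.dom_trans, model.initial, model.block_size,
        length_bins, u,
    )
    return StatePath(nuc_states=nuc, dom_states=dom, block_size=model.block_size)


def sample_observations(
    model: DiHMMModel,
    path: StatePath,
    seed: int = 0,
    cell_type: str = "sim",
    chromosome: str = "chrS",
    bin_size: int = 200,
) -> BinarizedTracks:
    """Draw Bernoulli mark calls conditioned on the path's nucleosome states."""
    if path.nuc_states.max() >= model.n_nuc or path.dom_states.max() >= model.n_dom:
        raise ValidationError("path states out of range for this model")
    p = model.emissions[path.nuc_states]  # (L, M)
    data = (_rng(seed, 1).random(p.shape) < p).astype(np.uint8)
    return BinarizedTracks(
        cell_type=cell_type,
        chromosome=chromosome,
        bin_size=bin_size,
        data=data,
        mark_names=model.mark_names,
    )


def sample_counts(
    path: StatePath,
    lambda_bg: float,
    lambda_fg: float,
    enrichment_states: Sequence[int],
    seed: int = 0,
    mark_name: str = "mark",
    cell_type: str = "sim",
    chromosome: str = "chrS",
    bin_size: int = 200,
) -> BinCounts:
    """Poisson read counts: rate lambda_fg in enriched nucleosome states, else lambda_bg."""
    if lambda_bg <= 0 or lambda_fg <= 0:
        raise ValidationError("Poisson rates must be positive")
    enriched = np.isin(path.nuc_states, np.asarray(list(enrichment_states)))
    lam = np.where(enriched, lambda_fg, lambda_bg)
    counts = _rng(seed, 2).poisson(lam)[:, None]
    return BinCounts(
        cell_type=cell_type,
        chromosome=chromosome,
        bin_size=bin_size,
        counts=counts,
        mark_names=(mark_name,),
    )


def make_fixture_model(
    n_nuc: int = 4,
    n_dom: int = 2,
    n_marks: int = 5,
    block_size: int = 10,
    separation: float = 0.35,
    seed: int = 0,
    diag: float = 0.9,
) -> DiHMMModel:
    """Well-separated synthetic truth model for recovery experiments.

    Emissions are 0.5 +/- separation following the binary expansion of the
    state index, with each bit repeated over a band of marks (a repetition
    code), so emission rows are mutually distant in Hamming terms (requires
    2**n_marks >= n_nuc). Each domain "owns" a contiguous band of nucleosome
    states; its nucleosome transition matrix favours staying put and moving
    into the band, which makes domains identifiable from the nucleosome-state
    grammar. The domain transition matrix is diagonal-dominant (``diag``).
    Deterministic given the arguments; ``seed`` perturbs nothing by default
    and is kept for interface stability.
    """
    del seed  # construction is deterministic
    if not (0.0 < separation < 0.5):
        raise ValidationError("separation must be in (0, 0.5)")
    if 2**n_marks < n_nuc:
        raise ValidationError(
            f"{n_marks} marks cannot distinguish {n_nuc} states (need 2^M >= K_n)"
        )
    n_bits = max(1, int(np.ceil(np.log2(max(n_nuc, 2)))))
    # mark m encodes bit m % n_bits: bits are spread round-robin over marks
    E = np.empty((n_nuc, n_marks))
    for k in range(n_nuc):
        bits = [(k >> (m % n_bits)) & 1 for m in range(n_marks)]
        E[k] = [0.5 + separation if b else 0.5 - separation for b in bits]
    # contiguous bands of nucleosome states per domain
    bounds = np.linspace(0, n_nuc, n_dom + 1).astype(int)
    t = np.empty((n_dom, n_nuc, n_nuc))
    for nu in range(n_dom):
        band = np.zeros(n_nuc)
        band[bounds[nu] : max(bounds[nu + 1], bounds[nu] + 1)] = 1.0
        for j in range(n_nuc):
            w = 1.0 + 8.0 * band
            w[j] += 8.0
            t[nu, j] = w / w.sum()
    T = np.full((n_dom, n_dom), (1.0 - diag) / max(n_dom - 1, 1))
    np.fill_diagonal(T, diag if n_dom > 1 else 1.0)
    P0 = np.full((n_nuc, n_dom), 1.0 / (n_nuc * n_dom))
    model = DiHMMModel(
        emissions=E,
        nuc_trans=t,
        dom_trans=T,
        initial=P0,
        block_size=block_size,
        mark_names=tuple(f"mark{m + 1}" for m in range(n_marks)),
    )
    problems = validate(model)
    if problems:
        raise ValidationError("fixture construction failed: " + "; ".join(problems))
    return model


@dataclass
class SimulationBundle:
    """Ground truth plus sampled data for one reproducible experiment."""

    truth_model: DiHMMModel
    paths: list[StatePath]
    tracks: list[BinarizedTracks]
    seed: int
    metadata: dict = field(default_factory=dict)


def simulate_bundle(
    model: DiHMMModel,
    lengths: Sequence[int],
    seed: int = 0,
    cell_types: Sequence[str] | None = None,
    chromosome: str = "chrS",
) -> SimulationBundle:
    """Sample one path + track per requested length, with per-sequence sub-seeds."""
    if cell_types is None:
        cell_types = [f"cell{i + 1}" for i in range(len(lengths))]
    paths, tracks = [], []
    for i, (L, cell) in enumerate(zip(lengths, cell_types)):
        sub = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0] % (2**31))
        p = sample_path(model, L, seed=sub)
        paths.append(p)
        tracks.append(
            sample_observations(model, p, seed=sub, cell_type=cell, chromosome=chromosome)
        )
    return SimulationBundle(
        truth_model=model,
        paths=paths,
        tracks=tracks,
        seed=seed,
        metadata={"lengths": list(lengths), "cell_types": list(cell_types)},
    )
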