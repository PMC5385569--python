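"""Model/Results front end over the library modules.

``DiHMM`` holds the data (one or more binarized sequences) and the structural
configuration (state counts, block size); ``fit()`` runs k-centre
initialization followed by hierarchical Baum-Welch and returns a
``DiHMMResults`` carrying the estimated parameters, the log-likelihood trace,
convergence diagnostics and a ``summary()`` table. Decoding, posterior
computation and simulation hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import annotate, inference, simulate, training
from .binarize import read_binarized
from .model import DiHMMModel, init_kcentre, save_model
from .types import BinarizedTracks, StatePath, ValidationError


class DiHMM:
    """Two-level chromatin-state hidden Markov model bound to training data.

    Parameters
    ----------
    tracks : sequence of BinarizedTracks
        One entry per (cell type, chromosome); all must share the same marks
        and contribute to a single shared parameter set.
    n_nuc, n_dom : int
        Number of nucleosome-level and domain-level states (30/30 default).
    block_size : int
        Bins per domain block D_S (20 default; with 200 bp bins the minimum
        domain segment is block_size * 200 = 4000 bp).
    """

    def __init__(
        self,
        tracks: Sequence[BinarizedTracks],
        n_nuc: int = 30,
        n_dom: int = 30,
        block_size: int = 20,
    ):
        if not tracks:
            raise ValidationError("at least one sequence of tracks is required")
        marks = tracks[0].mark_names
        for tr in tracks:
            if tr.mark_names != marks:
                raise ValidationError("all tracks must share the same mark names")
        self.tracks = list(tracks)
        self.n_nuc = n_nuc
        self.n_dom = n_dom
        self.block_size = block_size
        self.mark_names = marks

    @classmethod
    def from_binarized_dir(cls, directory, **kwargs) -> "DiHMM":
        """Build from a directory of ChromHMM-style ``*_binary.txt`` files."""
        paths = sorted(Path(directory).glob("*_binary.txt"))
        if not paths:
            raise ValidationError(f"no *_binary.txt files in {directory}")
        return cls([read_binarized(p) for p in paths], **kwargs)

    def start_params(self, seed: int = 0) -> DiHMMModel:
        """Two-scale k-centre initial parameter estimate."""
        return init_kcentre(
            self.tracks, self.n_nuc, self.n_dom, self.block_size, seed=seed
        )

    def fit(
        self,
        max_iter: int = 500,
        tol: float = 1e-4,
        pseudocount: float = 1e-6,
        seed: int = 0,
        start_params: DiHMMModel | None = None,
    ) -> "DiHMMResults":
        """Maximum-likelihood fit by hierarchical Baum-Welch."""
        model0 = start_params if start_params is not None else self.start_params(seed)
        params, trace = training.baum_welch(
            model0,
            self.tracks,
            max_iter=max_iter,
            tol=tol,
            pseudocount=pseudocount,
        )
        converged = len(trace) < max_iter or (
            len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol
        )
        return DiHMMResults(model=self, params=params, loglik_trace=list(trace),
                            converged=converged)


@dataclass
class DiHMMResults:
    """Fitted parameters plus diagnostics, decoding and simulation."""

    model: DiHMM
    params: DiHMMModel
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def llf(self) -> float:
        """Final training log-likelihood."""
        return self.loglik_trace[-1] if self.loglik_trace else np.nan

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)

    def decode(
        self,
        tracks: Sequence[BinarizedTracks] | None = None,
        method: str = "viterbi",
    ) -> list[StatePath]:
        """Decode sequences (training data by default) at both levels."""
        if tracks is None:
            tracks = self.model.tracks
        return annotate.segment_genome(self.params, tracks, decoder=method)

    def posteriors(self, tracks: BinarizedTracks) -> inference.PosteriorSet:
        return inference.posteriors(self.params, tracks)

    def log_likelihood(self, tracks: BinarizedTracks) -> float:
        return inference.forward(self.params, tracks).log_likelihood

    def simulate(self, length_bins: int, seed: int = 0):
        """Sample a (path, tracks) pair from the fitted parameters."""
        path = simulate.sample_path(self.params, length_bins, seed=seed)
        obs = simulate.sample_observations(self.params, path, seed=seed)
        return path, obs

    def save(self, destination) -> None:
        save_model(self.params, destination)

    def summary(self) -> str:
        """Plain-text summary in the style of statistical model results."""
        p = self.params
        n_bins = sum(tr.num_bins for tr in self.model.tracks)
        n_params = (
            p.n_nuc * p.n_marks
            + p.n_dom * p.n_nuc * (p.n_nuc - 1)
            + p.n_dom * (p.n_dom - 1)
            + (p.n_nuc * p.n_dom - 1)
        )
        lines = [
            "          Hierarchical chromatin-state HMM results",
            "=" * 64,
            f"Nucleosome-level states:  {p.n_nuc:>6}    Sequences: {len(self.model.tracks):>10}",
            f"Domain-level states:      {p.n_dom:>6}    Total bins: {n_bins:>9}",
            f"Block size (bins):        {p.block_size:>6}    Marks: {p.n_marks:>14}",
            f"Free parameters:          {n_params:>6}    Converged: {str(self.converged):>10}",
            f"EM iterations:            {self.n_iter:>6}    Log-likelihood: {self.llf:>.4f}",
            "-" * 64,
            "Emission probabilities P(mark on | nucleosome state):",
        ]
        header = "state " + " ".join(f"{m:>9.9}" for m in p.mark_names)
        lines.append(header)
        for k in range(p.n_nuc):
            lines.append(
                f"  N{k + 1:<3} " + " ".join(f"{v:>9.4f}" for v in p.emissions[k])
            )
        lines.append("-" * 64)
        lines.append("Domain-level transition matrix:")
        for mu in range(p.n_dom):
            lines.append(
                f"  D{mu + 1:<3} " + " ".join(f"{v:>9.4f}" for v in p.dom_trans[mu])
            )
        lines.append("=" * 64)
        return "\n".join(lines)
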