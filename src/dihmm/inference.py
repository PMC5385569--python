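"""Exact inference: scaled forward/backward, posteriors, pair marginals, decoding.

All recursions respect the block structure: the domain-level state is frozen
inside blocks of ``block_size`` bins and may change only on the step entering
bin i with i % block_size == 0 (i > 0). Scaling follows the standard
normalized-forward-variable scheme: alpha_hat rows sum to one, the scaling
factors multiply to the sequence likelihood, and the backward variables are
rescaled with the forward factors so that sum(alpha_hat * beta_hat) == 1 at
every position — which makes the product directly the joint posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import DiHMMModel
from .types import BinarizedTracks, StatePath, ValidationError

_MIN_SCALE = _kernels.EMISSION_FLOOR


@dataclass(frozen=True)
class ForwardResult:
    """Rescaled forward variables (L, K_n, K_d), scaling factors and log-likelihood."""

    alpha_hat: np.ndarray
    scales: np.ndarray
    log_likelihood: float


@dataclass(frozen=True)
class PosteriorSet:
    """Joint per-bin posteriors gamma (L, K_n, K_d) with scales and log-likelihood."""

    gamma: np.ndarray
    scales: np.ndarray
    log_likelihood: float

    @property
    def nuc_marginal(self) -> np.ndarray:
        return self.gamma.sum(axis=2)

    @property
    def dom_marginal(self) -> np.ndarray:
        return self.gamma.sum(axis=1)


def _check_compat(model: DiHMMModel, tracks: BinarizedTracks) -> None:
    if tuple(tracks.mark_names) != tuple(model.mark_names):
        raise ValidationError(
            f"track marks {tracks.mark_names} do not match model marks {model.mark_names}"
        )


def emission_prob(model: DiHMMModel, observation: np.ndarray, nuc_state: int) -> float:
    """P(observed mark vector | nucleosome state) under independent Bernoulli marks."""
    x = np.asarray(observation)
    if x.shape != (model.n_marks,):
        raise ValidationError(
            f"observation has shape {x.shape}, expected ({model.n_marks},)"
        )
    if not (0 <= nuc_state < model.n_nuc):
        raise ValidationError(f"nucleosome state {nuc_state} out of range")
    e = model.emissions[nuc_state]
    return float(np.prod(np.where(x == 1, e, 1.0 - e)))


def emission_matrix(model: DiHMMModel, tracks: BinarizedTracks) -> np.ndarray:
    """Per-bin emission probabilities B (L, K_n), computed in log space."""
    return np.exp(_log_emission_matrix(model, tracks))


def _log_emission_matrix(model: DiHMMModel, tracks: BinarizedTracks) -> np.ndarray:
    X = tracks.data.astype(np.float64)
    with np.errstate(divide="ignore"):
        logE = np.log(model.emissions)
        log1mE = np.log1p(-model.emissions)
    logB = X @ np.where(np.isfinite(logE), logE, -1e30).T + (1.0 - X) @ np.where(
        np.isfinite(log1mE), log1mE, -1e30
    ).T
    return logB


def forward(model: DiHMMModel, tracks: BinarizedTracks) -> ForwardResult:
    """Scaled forward recursion; the product of the scales is P(x | theta)."""
    _check_compat(model, tracks)
    B = emission_matrix(model, tracks)
    alpha, scales = _kernels.forward_kernel(
        B, model.nuc_trans, model.dom_trans, model.initial, model.block_size
    )
    bad = np.nonzero(scales <= _MIN_SCALE)[0]
    if bad.size:
        raise ValidationError(
            f"probability mass vanished at bin {bad[0]}: the model assigns "
            "zero probability to the observations (check for structural zeros)"
        )
    return ForwardResult(
        alpha_hat=alpha, scales=scales, log_likelihood=float(np.log(scales).sum())
    )


def backward(model: DiHMMModel, tracks: BinarizedTracks, scales: np.ndarray) -> np.ndarray:
    """Rescaled backward variables (L, K_n, K_d) using the forward scales."""
    _check_compat(model, tracks)
    B = emission_matrix(model, tracks)
    return _kernels.backward_kernel(
        B, model.nuc_trans, model.dom_trans, np.asarray(scales, dtype=np.float64),
        model.block_size,
    )


def posteriors(model: DiHMMModel, tracks: BinarizedTracks) -> PosteriorSet:
    """Joint posterior P(pi_i = (j, mu) | x, theta) at every bin."""
    fwd = forward(model, tracks)
    beta = backward(model, tracks, fwd.scales)
    gamma = fwd.alpha_hat * beta
    # guard against rounding: renormalize rows (already 1 within ~1e-12)
    gamma /= gamma.sum(axis=(1, 2), keepdims=True)
    return PosteriorSet(
        gamma=gamma, scales=fwd.scales, log_likelihood=fwd.log_likelihood
    )


def pair_marginals(model: DiHMMModel, tracks: BinarizedTracks) -> np.ndarray:
    """Joint posterior of consecutive state pairs.

    Returns xi of shape (L-1, K_n, K_d, K_n, K_d) with
    xi[i, j, mu, k, nu] = P(pi_i = (j, mu), pi_{i+1} = (k, nu) | x, theta).
    Entries with mu != nu are exactly zero off block boundaries. Intended for
    small instances (tests, diagnostics); training accumulates the same mass
    in compressed form without materializing this array.
    """
    _check_compat(model, tracks)
    L = tracks.num_bins
    if L == 1:
        return np.zeros((0, model.n_nuc, model.n_dom, model.n_nuc, model.n_dom))
    fwd = forward(model, tracks)
    beta = backward(model, tracks, fwd.scales)
    B = emission_matrix(model, tracks)
    t, T = model.nuc_trans, model.dom_trans
    Kn, Kd = model.n_nuc, model.n_dom
    xi = np.zeros((L - 1, Kn, Kd, Kn, Kd))
    for i in range(L - 1):
        # w[nu, k] = B[i+1, k] * beta_hat[i+1, k, nu]
        w = (B[i + 1][:, None] * beta[i + 1]).T  # (Kd, Kn)
        if (i + 1) % model.block_size == 0:
            for mu in range(Kd):
                for nu in range(Kd):
                    xi[i, :, mu, :, nu] = (
                        fwd.alpha_hat[i][:, mu : mu + 1]
                        * T[mu, nu]
                        * t[nu]
                        * w[nu][None, :]
                    )
        else:
            for nu in range(Kd):
                xi[i, :, nu, :, nu] = (
                    fwd.alpha_hat[i][:, nu : nu + 1] * t[nu] * w[nu][None, :]
                )
        xi[i] /= fwd.scales[i + 1]
    return xi


def viterbi(model: DiHMMModel, tracks: BinarizedTracks) -> StatePath:
    """Most probable joint state path (log-space, lexicographic tie-break)."""
    _check_compat(model, tracks)
    logB = _log_emission_matrix(model, tracks)
    with np.errstate(divide="ignore"):
        logt = np.log(model.nuc_trans)
        logT = np.log(model.dom_trans)
        logP0 = np.log(model.initial)
    neg = -1e30
    logt = np.where(np.isfinite(logt), logt, neg)
    logT = np.where(np.isfinite(logT), logT, neg)
    logP0 = np.where(np.isfinite(logP0), logP0, neg)
    nuc, dom, best = _kernels.viterbi_kernel(
        logB, logt, logT, logP0, model.block_size
    )
    if best <= -1e29:
        raise ValidationError("no structurally allowed path has positive probability")
    return StatePath(nuc_states=nuc, dom_states=dom, block_size=model.block_size)


def viterbi_log_probability(model: DiHMMModel, tracks: BinarizedTracks) -> float:
    """Joint log P(best path, x); always <= the total log-likelihood."""
    _check_compat(model, tracks)
    logB = _log_emission_matrix(model, tracks)
    with np.errstate(divide="ignore"):
        logt = np.where(model.nuc_trans > 0, np.log(model.nuc_trans), -1e30)
        logT = np.where(model.dom_trans > 0, np.log(model.dom_trans), -1e30)
        logP0 = np.where(model.initial > 0, np.log(model.initial), -1e30)
    _, _, best = _kernels.viterbi_kernel(logB, logt, logT, logP0, model.block_size)
    return float(best)


def posterior_decode(post: PosteriorSet, block_size: int) -> StatePath:
    """Two-stage maximum-posterior decoding.

    Each block's domain state is the argmax of its (block-constant) domain
    marginal; each bin's nucleosome state is then the argmax of the joint
    posterior conditional on the chosen domain. Ties break to the lowest
    index (numpy argmax convention). Block constancy holds by construction.
    """
    gamma = post.gamma
    L = gamma.shape[0]
    dom_marg = gamma.sum(axis=1)  # (L, K_d)
    dom = np.empty(L, dtype=np.int64)
    nuc = np.empty(L, dtype=np.int64)
    for b in range(0, L, block_size):
        sl = slice(b, min(b + block_size, L))
        d = int(np.argmax(dom_marg[sl].sum(axis=0)))
        dom[sl] = d
        nuc[sl] = np.argmax(gamma[sl, :, d], axis=1)
    return StatePath(nuc_states=nuc, dom_states=dom, block_size=block_size)
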