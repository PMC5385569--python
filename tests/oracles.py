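"""Independent reference implementations used only to check the package.

Everything here is deliberately naive: exhaustive path enumeration over the
joint state space, a dense textbook scaled flat HMM, and direct Poisson tail
summation. None of it shares code with the package's recursions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _emis(E, x, k):
    return float(np.prod(np.where(x == 1, E[k], 1.0 - E[k])))


def enumerate_paths(model, X):
    """All structurally allowed joint paths with their joint probabilities.

    Yields ((nuc_tuple, dom_tuple), P(path, x)). A domain change is allowed
    only on the step entering bin i with i % block_size == 0.
    """
    L = X.shape[0]
    Kn, Kd, D = model.n_nuc, model.n_dom, model.block_size
    E, t, T, P0 = model.emissions, model.nuc_trans, model.dom_trans, model.initial
    for nuc in itertools.product(range(Kn), repeat=L):
        for dom in itertools.product(range(Kd), repeat=L):
            ok = all(
                dom[i] == dom[i - 1] for i in range(1, L) if i % D != 0
            )
            if not ok:
                continue
            p = P0[nuc[0], dom[0]] * _emis(E, X[0], nuc[0])
            for i in range(1, L):
                if i % D == 0:
                    p *= T[dom[i - 1], dom[i]]
                p *= t[dom[i], nuc[i - 1], nuc[i]] * _emis(E, X[i], nuc[i])
            yield (nuc, dom), p


def brute_likelihood(model, X):
    return sum(p for _, p in enumerate_paths(model, X))


def brute_posteriors(model, X):
    """gamma (L, K_n, K_d) by summing weighted paths."""
    L = X.shape[0]
    gamma = np.zeros((L, model.n_nuc, model.n_dom))
    total = 0.0
    for (nuc, dom), p in enumerate_paths(model, X):
        total += p
        for i in range(L):
            gamma[i, nuc[i], dom[i]] += p
    return gamma / total


def brute_pair_marginals(model, X):
    """xi (L-1, K_n, K_d, K_n, K_d) by summing weighted paths."""
    L = X.shape[0]
    Kn, Kd = model.n_nuc, model.n_dom
    xi = np.zeros((L - 1, Kn, Kd, Kn, Kd))
    total = 0.0
    for (nuc, dom), p in enumerate_paths(model, X):
        total += p
        for i in range(L - 1):
            xi[i, nuc[i], dom[i], nuc[i + 1], dom[i + 1]] += p
    return xi / total


def brute_viterbi(model, X):
    """Best path by enumeration; ties toward the lexicographically lowest
    (nucleosome sequence, domain sequence) pair, matching interleaved
    per-position (j, mu) order."""
    best, best_key = None, None
    for (nuc, dom), p in enumerate_paths(model, X):
        # interleave so per-position (nuc, dom) lexicographic order applies
        key = tuple(v for pair in zip(nuc, dom) for v in pair)
        if best is None or p > best[1] + 1e-18 or (
            abs(p - best[1]) <= 1e-18 and key < best_key
        ):
            best, best_key = ((nuc, dom), p), key
    return best


# ---------------------------------------------------------------------------
# textbook scaled flat HMM (Rabiner conventions)
# ---------------------------------------------------------------------------


class FlatBernoulliHMM:
    """Dense scaled forward-backward + Baum-Welch for a single-level HMM
    with independent Bernoulli emissions per mark."""

    def __init__(self, pi, A, E):
        self.pi = np.asarray(pi, float)
        self.A = np.asarray(A, float)
        self.E = np.asarray(E, float)

    def _B(self, X):
        X = np.asarray(X, float)
        return np.exp(
            X @ np.log(np.clip(self.E, 1e-300, 1)).T
            + (1 - X) @ np.log(np.clip(1 - self.E, 1e-300, 1)).T
        )

    def forward(self, X):
        B = self._B(X)
        L, K = B.shape
        alpha = np.zeros((L, K))
        c = np.zeros(L)
        alpha[0] = self.pi * B[0]
        c[0] = alpha[0].sum()
        alpha[0] /= c[0]
        for i in range(1, L):
            alpha[i] = (alpha[i - 1] @ self.A) * B[i]
            c[i] = alpha[i].sum()
            alpha[i] /= c[i]
        return alpha, c

    def backward(self, X, c):
        B = self._B(X)
        L, K = B.shape
        beta = np.zeros((L, K))
        beta[-1] = 1.0
        for i in range(L - 2, -1, -1):
            beta[i] = (self.A @ (B[i + 1] * beta[i + 1])) / c[i + 1]
        return beta

    def loglik(self, X):
        _, c = self.forward(X)
        return float(np.log(c).sum())

    def em_step(self, X):
        """One Baum-Welch update (plain MLE, no smoothing). Returns the
        log-likelihood of the model *before* the update."""
        B = self._B(X)
        alpha, c = self.forward(X)
        beta = self.backward(X, c)
        gamma = alpha * beta
        xi_sum = np.zeros_like(self.A)
        L = X.shape[0]
        for i in range(L - 1):
            xi_sum += (
                alpha[i][:, None] * self.A * (B[i + 1] * beta[i + 1])[None, :]
            ) / c[i + 1]
        ll = float(np.log(c).sum())
        self.pi = gamma[0] / gamma[0].sum()
        self.A = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        Xf = np.asarray(X, float)
        self.E = (gamma.T @ Xf) / gamma.sum(axis=0)[:, None]
        return ll


# ---------------------------------------------------------------------------
# Poisson upper tail by direct pmf summation
# ---------------------------------------------------------------------------


def poisson_upper_tail(c: int, lam: float) -> float:
    """P(X >= c) for X ~ Poisson(lam), by summing the pmf of the complement."""
    if c <= 0:
        return 1.0
    acc = 0.0
    for x in range(c):
        acc += math.exp(-lam) * lam**x / math.factorial(x)
    return 1.0 - acc
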