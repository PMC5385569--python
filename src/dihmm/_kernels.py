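"""Numba inner loops for the two-level HMM recursions.

All kernels operate on dense float64 arrays and exploit the block structure
directly: away from block boundaries the domain index is carried through
unchanged (cost O(K_d * K_n^2) per bin), and only at the 1-in-D_S boundary
steps is the domain transition matrix applied. The dense joint transition
matrix over (nucleosome, domain) pairs is never materialized.

Index convention (0-based): the step entering bin i allows a domain change
iff i % D_S == 0 and i > 0, so domain states are constant on blocks
[b*D_S, (b+1)*D_S).
"""

import numpy as np
from numba import njit

EMISSION_FLOOR = 1e-300


@njit(cache=True)
def forward_kernel(B, t, T, P0, block_size):
    """Scaled forward pass.

    B: (L, K_n) per-bin emission probabilities; t: (K_d, K_n, K_n);
    T: (K_d, K_d); P0: (K_n, K_d). Returns (alpha_hat (L, K_n, K_d),
    scales (L,)); scales[i] is the mass removed at position i, so the
    log-likelihood is sum(log(scales)). A scale at or below the floor
    signals vanished probability mass; the caller raises.
    """
    L, Kn = B.shape
    Kd = T.shape[0]
    alpha = np.zeros((L, Kn, Kd))
    scales = np.zeros(L)
    for j in range(Kn):
        for mu in range(Kd):
            alpha[0, j, mu] = P0[j, mu] * B[0, j]
    s = alpha[0].sum()
    scales[0] = s
    if s > EMISSION_FLOOR:
        alpha[0] /= s
    for i in range(1, L):
        if i % block_size == 0:
            # domain change permitted: collapse over source domain first
            a_jnu = np.zeros((Kn, Kd))
            for j in range(Kn):
                for nu in range(Kd):
                    acc = 0.0
                    for mu in range(Kd):
                        acc += alpha[i - 1, j, mu] * T[mu, nu]
                    a_jnu[j, nu] = acc
            for nu in range(Kd):
                for k in range(Kn):
                    acc = 0.0
                    for j in range(Kn):
                        acc += a_jnu[j, nu] * t[nu, j, k]
                    alpha[i, k, nu] = acc * B[i, k]
        else:
            for nu in range(Kd):
                for k in range(Kn):
                    acc = 0.0
                    for j in range(Kn):
                        acc += alpha[i - 1, j, nu] * t[nu, j, k]
                    alpha[i, k, nu] = acc * B[i, k]
        s = alpha[i].sum()
        scales[i] = s
        if s > EMISSION_FLOOR:
            alpha[i] /= s
    return alpha, scales


@njit(cache=True)
def backward_kernel(B, t, T, scales, block_size):
    """Scaled backward pass using the forward scaling factors.

    Convention: beta_hat[L-1] = 1 and each recursion step divides by
    scales[i+1], so sum_{k,nu} alpha_hat[i] * beta_hat[i] == 1 at every i.
    """
    L, Kn = B.shape
    Kd = T.shape[0]
    beta = np.zeros((L, Kn, Kd))
    beta[L - 1] = 1.0
    for i in range(L - 2, -1, -1):
        s = scales[i + 1]
        if (i + 1) % block_size == 0:
            for j in range(Kn):
                for mu in range(Kd):
                    acc = 0.0
                    for nu in range(Kd):
                        inner = 0.0
                        for k in range(Kn):
                            inner += t[nu, j, k] * B[i + 1, k] * beta[i + 1, k, nu]
                        acc += T[mu, nu] * inner
                    beta[i, j, mu] = acc / s
        else:
            for mu in range(Kd):
                for j in range(Kn):
                    acc = 0.0
                    for k in range(Kn):
                        acc += t[mu, j, k] * B[i + 1, k] * beta[i + 1, k, mu]
                    beta[i, j, mu] = acc / s
    return beta


@njit(cache=True)
def stats_kernel(X, B, t, T, alpha, beta, scales, block_size):
    """Expected sufficient statistics for one sequence.

    Accumulates, without materializing the per-step joint pair marginals:
    xi_boundary (K_d, K_d) over boundary steps; xi_nuc (K_d, K_n, K_n) over
    all steps with the mass credited to the destination domain; gamma at the
    first bin; expected mark-on counts and occupancy per nucleosome state.
    """
    L, Kn = B.shape
    Kd = T.shape[0]
    M = X.shape[1]
    xi_boundary = np.zeros((Kd, Kd))
    xi_nuc = np.zeros((Kd, Kn, Kn))
    gamma_first = np.zeros((Kn, Kd))
    emit_on = np.zeros((Kn, M))
    occupancy = np.zeros(Kn)
    gamma_first[:, :] = alpha[0] * beta[0]
    for i in range(L):
        for k in range(Kn):
            g = 0.0
            for nu in range(Kd):
                g += alpha[i, k, nu] * beta[i, k, nu]
            occupancy[k] += g
            for m in range(M):
                if X[i, m]:
                    emit_on[k, m] += g
    for i in range(L - 1):
        s = scales[i + 1]
        if (i + 1) % block_size == 0:
            for mu in range(Kd):
                for nu in range(Kd):
                    acc = 0.0
                    for j in range(Kn):
                        a = alpha[i, j, mu] * T[mu, nu]
                        for k in range(Kn):
                            w = a * t[nu, j, k] * B[i + 1, k] * beta[i + 1, k, nu] / s
                            acc += w
                            xi_nuc[nu, j, k] += w
                    xi_boundary[mu, nu] += acc
        else:
            for nu in range(Kd):
                for j in range(Kn):
                    a = alpha[i, j, nu]
                    for k in range(Kn):
                        xi_nuc[nu, j, k] += (
                            a * t[nu, j, k] * B[i + 1, k] * beta[i + 1, k, nu] / s
                        )
    return xi_boundary, xi_nuc, gamma_first, emit_on, occupancy


@njit(cache=True)
def viterbi_kernel(logB, logt, logT, logP0, block_size):
    """Max-probability joint path in log space.

    Ties break toward the lowest (nucleosome, domain) pair in lexicographic
    order, enforced by strict improvement while scanning indices upward.
    Returns (nuc_path, dom_path, best joint log-probability).
    """
    L, Kn = logB.shape
    Kd = logT.shape[0]
    NEG = -1e30
    delta = np.full((L, Kn, Kd), NEG)
    arg_j = np.zeros((L, Kn, Kd), dtype=np.int64)
    arg_mu = np.zeros((L, Kn, Kd), dtype=np.int64)
    for j in range(Kn):
        for mu in range(Kd):
            delta[0, j, mu] = logP0[j, mu] + logB[0, j]
    for i in range(1, L):
        boundary = i % block_size == 0
        for k in range(Kn):
            for nu in range(Kd):
                best = NEG
                bj = 0
                bmu = 0
                for j in range(Kn):
                    if boundary:
                        for mu in range(Kd):
                            v = delta[i - 1, j, mu] + logT[mu, nu] + logt[nu, j, k]
                            if v > best:
                                best = v
                                bj = j
                                bmu = mu
                    else:
                        v = delta[i - 1, j, nu] + logt[nu, j, k]
                        if v > best:
                            best = v
                            bj = j
                            bmu = nu
                delta[i, k, nu] = best + logB[i, k]
                arg_j[i, k, nu] = bj
                arg_mu[i, k, nu] = bmu
    # terminal argmax, lexicographic tie-break
    best = NEG
    bk = 0
    bnu = 0
    for k in range(Kn):
        for nu in range(Kd):
            if delta[L - 1, k, nu] > best:
                best = delta[L - 1, k, nu]
                bk = k
                bnu = nu
    nuc = np.zeros(L, dtype=np.int64)
    dom = np.zeros(L, dtype=np.int64)
    nuc[L - 1] = bk
    dom[L - 1] = bnu
    for i in range(L - 1, 0, -1):
        k = nuc[i]
        nu = dom[i]
        nuc[i - 1] = arg_j[i, k, nu]
        dom[i - 1] = arg_mu[i, k, nu]
    return nuc, dom, best


@njit(cache=True)
def sample_path_kernel(t, T, P0, block_size, length, u):
    """Draw a joint state path from pre-drawn uniforms u of shape (length, 2).

    Inverse-CDF sampling; at block boundaries the domain is drawn first
    (u[i, 0]) and the nucleosome step then uses the new domain's transition
    matrix (u[i, 1]). Off-boundary steps consume only u[i, 1].
    """
    Kn = P0.shape[0]
    Kd = P0.shape[1]
    nuc = np.zeros(length, dtype=np.int64)
    dom = np.zeros(length, dtype=np.int64)
    # initial joint draw from P0 using u[0, 0]
    r = u[0, 0]
    acc = 0.0
    done = False
    for j in range(Kn):
        for mu in range(Kd):
            acc += P0[j, mu]
            if r < acc and not done:
                nuc[0] = j
                dom[0] = mu
                done = True
    if not done:
        nuc[0] = Kn - 1
        dom[0] = Kd - 1
    for i in range(1, length):
        mu = dom[i - 1]
        if i % block_size == 0:
            r = u[i, 0]
            acc = 0.0
            nu = Kd - 1
            for cand in range(Kd):
                acc += T[mu, cand]
                if r < acc:
                    nu = cand
                    break
        else:
            nu = mu
        dom[i] = nu
        j = nuc[i - 1]
        r = u[i, 1]
        acc = 0.0
        k = Kn - 1
        for cand in range(Kn):
            acc += t[nu, j, cand]
            if r < acc:
                k = cand
                break
        nuc[i] = k
    return nuc, dom
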