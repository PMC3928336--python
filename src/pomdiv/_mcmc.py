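"""Jitted Gibbs-sampler core for the admixture model.

Everything here is numba-compiled and uses a self-contained counter-based
splitmix64 uniform stream (plus Marsaglia polar normals and
Marsaglia–Tsang gamma draws built on it), so a chain is a pure function of
its integer seed on any platform.

The categorical origin draws for the two allele copies of a genotype are
collapsed into a single uniform per genotype cell: for homozygotes the
pair of i.i.d. origins is sampled from the K(K+1)/2 unordered-count
outcomes, for heterozygotes from the K x K grid of (B-copy, A-copy)
origins.  Both are exact samples of the same joint conditional as two
sequential per-copy draws.  Uniforms for a sweep are pre-filled into a
buffer from independent counter values, and outcome selection is a
branch-free cumulative scan, which together keep the per-cell cost near
the arithmetic floor.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D4A2135D2E52D5)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(inline="always", cache=True)
def _mix64(x):
    z = x * _GOLDEN
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


@njit(inline="always", cache=True)
def _u01(state):
    """Advance splitmix64; return (uniform in (0,1], new state)."""
    state = state + np.uint64(1)
    z = _mix64(state)
    return ((z >> np.uint64(11)) + np.uint64(1)) * _INV53, state


@njit(inline="always", cache=True)
def _normal(state):
    """Standard normal by the Marsaglia polar method (one value kept)."""
    while True:
        u, state = _u01(state)
        v, state = _u01(state)
        x = 2.0 * u - 1.0
        y = 2.0 * v - 1.0
        s = x * x + y * y
        if 0.0 < s < 1.0:
            return x * np.sqrt(-2.0 * np.log(s) / s), state


@njit(inline="always", cache=True)
def _gamma(shape, state):
    """Gamma(shape, 1) by Marsaglia–Tsang; shape < 1 via the boost identity."""
    boost = 1.0
    if shape < 1.0:
        u, state = _u01(state)
        boost = u ** (1.0 / shape)
        shape = shape + 1.0
    d = shape - 1.0 / 3.0
    c = 1.0 / np.sqrt(9.0 * d)
    while True:
        x, state = _normal(state)
        v = 1.0 + c * x
        if v <= 0.0:
            continue
        v = v * v * v
        u, state = _u01(state)
        x2 = x * x
        if u < 1.0 - 0.0331 * x2 * x2:
            return boost * d * v, state
        if np.log(u) < 0.5 * x2 + d * (1.0 - v + np.log(v)):
            return boost * d * v, state


@njit(cache=True, fastmath=True)
def _fill_uniforms(buf, ctr):
    """Fill `buf` with uniforms from independent counter values."""
    n = buf.shape[0]
    for j in range(n):
        z = _mix64(ctr + np.uint64(j))
        buf[j] = ((z >> np.uint64(11)) + np.uint64(1)) * _INV53
    return ctr + np.uint64(n)


@njit(cache=True, fastmath=True)
def gibbs_chain(G, K, alpha, burnin, reps, thin, seed):
    """One Gibbs chain over the admixture model.

    G : (N, L) int8, -1 = no call, else count of B alleles.
    Returns (thinned post-burn-in lnL trace, posterior-mean Q (N, K),
    posterior-mean P (L, K)).
    """
    N, L = G.shape
    P = np.full((L, K), 0.5)
    q = np.full((N, K), 1.0 / K)
    n_rec = reps // thin
    trace = np.empty(n_rec)
    q_sum = np.zeros((N, K))
    p_sum = np.zeros((L, K))
    nB = np.zeros((L, K), dtype=np.int32)
    nA = np.zeros((L, K), dtype=np.int32)
    m = np.zeros((N, K), dtype=np.int32)
    # outcome tables: joint-draw index -> pair of origins, for the
    # homozygote triangle (T outcomes) and the heterozygote grid (K^2)
    T = K * (K + 1) // 2
    tri1 = np.empty(T, dtype=np.int64)
    tri2 = np.empty(T, dtype=np.int64)
    t_idx = 0
    for k in range(K):
        tri1[t_idx] = k
        tri2[t_idx] = k
        t_idx += 1
        for j in range(k + 1, K):
            tri1[t_idx] = k
            tri2[t_idx] = j
            t_idx += 1
    grid1 = np.empty(K * K, dtype=np.int64)
    grid2 = np.empty(K * K, dtype=np.int64)
    for k in range(K):
        for j in range(K):
            grid1[k * K + j] = k
            grid2[k * K + j] = j
    W = np.empty((L, K))  # B-copy weights q[i,k] * P[l,k] for the current sample
    V = np.empty((L, K))  # A-copy weights q[i,k] * (1 - P[l,k])
    SB = np.empty(L)
    SA = np.empty(L)
    n_cells = int((G >= 0).sum())
    ubuf = np.empty(n_cells)
    # two decorrelated streams: a counter for the cell uniforms and a
    # splitmix state for the gamma/normal draws
    ctr = _mix64(np.uint64(seed) ^ np.uint64(0xD6E8FEB86659FD93))
    state = _mix64(np.uint64(seed) + np.uint64(0x71EE2A46F1D8F0C2))
    rec = 0
    n_kept = 0

    if K == 1:
        # origins are deterministic: accumulate allele-copy counts once
        for l in range(L):
            b = 0
            a = 0
            for i in range(N):
                g = G[i, l]
                if g >= 0:
                    b += g
                    a += 2 - g
            nB[l, 0] = b
            nA[l, 0] = a

    for sweep in range(burnin + reps):
        if K > 1:
            nB[:] = 0
            nA[:] = 0
            m[:] = 0
            ctr = _fill_uniforms(ubuf, ctr)
            cell = 0
            for i in range(N):
                # hoisted per-sample weight matrices; the inner row sums SB
                # are also the B-allele probabilities r(i, l) = sum_k q P
                for l in range(L):
                    sB = 0.0
                    sA = 0.0
                    for k in range(K):
                        wb = q[i, k] * P[l, k]
                        W[l, k] = wb
                        sB += wb
                        wa = q[i, k] - wb
                        V[l, k] = wa
                        sA += wa
                    SB[l] = sB
                    SA[l] = sA
                for l in range(L):
                    g = G[i, l]
                    if g < 0:
                        continue
                    u = ubuf[cell]
                    cell += 1
                    # outcome selection is a branch-free inverse-CDF count:
                    # idx = #{cumulative outcome weights below u * total}
                    if g == 1:
                        # one B copy, one A copy: joint draw on the K x K grid
                        t = u * SB[l] * SA[l]
                        acc = 0.0
                        idx = 0
                        for kk in range(K):
                            row = W[l, kk]
                            for jj in range(K):
                                acc += row * V[l, jj]
                                idx += acc < t
                        if idx >= K * K:
                            idx = K * K - 1
                        kb = grid1[idx]
                        ka = grid2[idx]
                        nB[l, kb] += 1
                        nA[l, ka] += 1
                        m[i, kb] += 1
                        m[i, ka] += 1
                    else:
                        # homozygote: two i.i.d. origins, sampled jointly from
                        # the unordered-outcome triangle with one uniform
                        if g == 2:
                            R = W[l]
                            t = u * SB[l] * SB[l]
                        else:
                            R = V[l]
                            t = u * SA[l] * SA[l]
                        acc = 0.0
                        idx = 0
                        for kk in range(K):
                            row = R[kk]
                            acc += row * row
                            idx += acc < t
                            for jj in range(kk + 1, K):
                                acc += 2.0 * row * R[jj]
                                idx += acc < t
                        if idx >= T:
                            idx = T - 1
                        k1 = tri1[idx]
                        k2 = tri2[idx]
                        if g == 2:
                            nB[l, k1] += 1
                            nB[l, k2] += 1
                        else:
                            nA[l, k1] += 1
                            nA[l, k2] += 1
                        m[i, k1] += 1
                        m[i, k2] += 1

        # P | counts ~ Beta(1 + nB, 1 + nA)
        for l in range(L):
            for k in range(K):
                gb, state = _gamma(1.0 + nB[l, k], state)
                ga, state = _gamma(1.0 + nA[l, k], state)
                P[l, k] = gb / (gb + ga)

        # Q_i | counts ~ Dirichlet(alpha + m_i)
        if K > 1:
            for i in range(N):
                s = 0.0
                for k in range(K):
                    gk, state = _gamma(alpha + m[i, k], state)
                    q[i, k] = gk
                    s += gk
                for k in range(K):
                    q[i, k] /= s

        if sweep >= burnin and (sweep - burnin) % thin == thin - 1 and rec < n_rec:
            ll = 0.0
            for i in range(N):
                for l in range(L):
                    r = 0.0
                    for k in range(K):
                        r += q[i, k] * P[l, k]
                    SB[l] = r
                for l in range(L):
                    g = G[i, l]
                    if g < 0:
                        continue
                    r = SB[l]
                    if g == 0:
                        pr = (1.0 - r) * (1.0 - r)
                    elif g == 1:
                        pr = 2.0 * r * (1.0 - r)
                    else:
                        pr = r * r
                    ll += np.log(pr)
            trace[rec] = ll
            rec += 1
            q_sum += q
            p_sum += P
            n_kept += 1

    return trace[:rec], q_sum / n_kept, p_sum / n_kept
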