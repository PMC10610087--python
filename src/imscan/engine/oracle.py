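"""Independent Monte-Carlo oracle for the folded bSFS distribution.

Simulates the structured coalescent directly for one 2+2 haplotype sample
per block (two haplotypes from the A individual, two from the B
individual), accumulates branch length by mutation type, drops Poisson
mutations on each type, and folds at kmax. The implementation shares no
code with the matrix-exponential engine (and does not use msprime), so it
serves as a genuinely independent cross-check of both.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from imscan.demography import DemographyParams, KmaxSpec


@njit(cache=True)
def _branch_type(i: int, j: int) -> int:
    # axis order (het_b, het_a, het_ab, fixed_diff); root branch invisible
    if (i == 0 and j == 1) or (i == 2 and j == 1):
        return 0
    if (i == 1 and j == 0) or (i == 1 and j == 2):
        return 1
    if i == 1 and j == 1:
        return 2
    if (i == 2 and j == 0) or (i == 0 and j == 2):
        return 3
    return -1


@njit(cache=True)
def _simulate_tally(n_blocks, N_A, N_B, N_anc, T, m, theta, src_deme, has_split,
                    kb, ka, kab, kfd, seed):
    """Counts of folded bSFS configurations over `n_blocks` blocks.

    theta = mu * block_length (per lineage per generation); src_deme is the
    backward migration source (0 = A, 1 = B, -1 = none).
    """
    np.random.seed(seed)
    d1, d2, d3 = ka + 2, kab + 2, kfd + 2
    counts = np.zeros((kb + 2) * d1 * d2 * d3, dtype=np.int64)
    ii = np.empty(4, dtype=np.int64)
    jj = np.empty(4, dtype=np.int64)
    dd = np.empty(4, dtype=np.int64)
    L = np.empty(4, dtype=np.float64)
    for _ in range(n_blocks):
        ii[0] = 1; ii[1] = 1; ii[2] = 0; ii[3] = 0
        jj[0] = 0; jj[1] = 0; jj[2] = 1; jj[3] = 1
        dd[0] = 0; dd[1] = 0; dd[2] = 1; dd[3] = 1
        n = 4
        L[:] = 0.0
        t = 0.0
        two_demes = True
        while n > 1:
            if two_demes:
                nA = 0
                nS = 0
                for x in range(n):
                    if dd[x] == 0:
                        nA += 1
                    if dd[x] == src_deme:
                        nS += 1
                nB = n - nA
                cA = nA * (nA - 1) / 2.0 / (2.0 * N_A)
                cB = nB * (nB - 1) / 2.0 / (2.0 * N_B)
                mg = m * nS if src_deme >= 0 else 0.0
                R = cA + cB + mg
                if R <= 0.0:
                    # no event possible before the split (e.g. DIV with one
                    # lineage left per deme): jump to T
                    dt = T - t
                    for x in range(n):
                        b = _branch_type(ii[x], jj[x])
                        if b >= 0:
                            L[b] += dt
                    t = T
                    two_demes = False
                    continue
                dt = np.random.exponential(1.0 / R)
                if has_split and t + dt >= T:
                    dt = T - t
                    for x in range(n):
                        b = _branch_type(ii[x], jj[x])
                        if b >= 0:
                            L[b] += dt
                    t = T
                    two_demes = False
                    continue
                for x in range(n):
                    b = _branch_type(ii[x], jj[x])
                    if b >= 0:
                        L[b] += dt
                t += dt
                u = np.random.random() * R
                if u < cA or u < cA + cB:
                    deme = 0 if u < cA else 1
                    nd = nA if deme == 0 else nB
                    # choose an unordered pair among lineages in `deme`
                    r = int(np.random.random() * nd * (nd - 1))
                    p1 = r // (nd - 1)
                    p2 = r % (nd - 1)
                    if p2 >= p1:
                        p2 += 1
                    # map within-deme ranks to lineage slots
                    a1 = -1; a2 = -1; rank = 0
                    for x in range(n):
                        if dd[x] == deme:
                            if rank == p1:
                                a1 = x
                            if rank == p2:
                                a2 = x
                            rank += 1
                    if a2 < a1:
                        a1, a2 = a2, a1
                    ii[a1] += ii[a2]
                    jj[a1] += jj[a2]
                    ii[a2] = ii[n - 1]
                    jj[a2] = jj[n - 1]
                    dd[a2] = dd[n - 1]
                    n -= 1
                else:
                    # migration: move a uniform lineage out of the source deme
                    pick = int(np.random.random() * nS)
                    rank = 0
                    for x in range(n):
                        if dd[x] == src_deme:
                            if rank == pick:
                                dd[x] = 1 - src_deme
                                break
                            rank += 1
            else:
                c = n * (n - 1) / 2.0 / (2.0 * N_anc)
                dt = np.random.exponential(1.0 / c)
                for x in range(n):
                    b = _branch_type(ii[x], jj[x])
                    if b >= 0:
                        L[b] += dt
                t += dt
                r = int(np.random.random() * n * (n - 1))
                a1 = r // (n - 1)
                a2 = r % (n - 1)
                if a2 >= a1:
                    a2 += 1
                if a2 < a1:
                    a1, a2 = a2, a1
                ii[a1] += ii[a2]
                jj[a1] += jj[a2]
                ii[a2] = ii[n - 1]
                jj[a2] = jj[n - 1]
                n -= 1
        c0 = np.random.poisson(theta * L[0])
        c1 = np.random.poisson(theta * L[1])
        c2 = np.random.poisson(theta * L[2])
        c3 = np.random.poisson(theta * L[3])
        if c0 > kb + 1:
            c0 = kb + 1
        if c1 > ka + 1:
            c1 = ka + 1
        if c2 > kab + 1:
            c2 = kab + 1
        if c3 > kfd + 1:
            c3 = kfd + 1
        counts[((c0 * d1 + c1) * d2 + c2) * d3 + c3] += 1
    return counts


def sample_block_tally(params: DemographyParams, kmax: KmaxSpec | None = None,
                       n_blocks: int = 1, seed: int = 1) -> np.ndarray:
    """Folded bSFS count array from direct coalescent simulation.

    Reproducible by seed; the same seed always yields the identical tally.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    kmax = kmax or KmaxSpec()
    model = params.model
    src = {"A": 0, "B": 1, None: -1}[model.backward_source_deme]
    has_split = model.has_split
    T = float(params.T) if has_split else np.inf
    if not has_split and params.effective_m <= 0:
        raise ValueError("MIG model with m_e = 0 never coalesces across demes")
    n_anc = float(params.N_anc) if params.N_anc is not None else 1.0
    counts = _simulate_tally(
        int(n_blocks), float(params.N_A), float(params.N_B), n_anc, T,
        params.effective_m, float(params.theta_per_lineage), src, has_split,
        kmax.k_b, kmax.k_a, kmax.k_ab, kmax.k_fd, int(seed) % (2 ** 31),
    )
    return counts.reshape(kmax.shape)


def mc_oracle_pmf(params: DemographyParams, kmax: KmaxSpec | None = None,
                  n_blocks: int = 100_000, seed: int = 1):
    """Estimated folded bSFS pmf from `n_blocks` independent blocks."""
    from imscan.engine.pmf import BsfsPmf

    kmax = kmax or KmaxSpec()
    counts = sample_block_tally(params, kmax, n_blocks, seed)
    return BsfsPmf(probs=counts / float(n_blocks), params=params, kmax=kmax)
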