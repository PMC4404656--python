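"""Independent oracles used by the test suite.

The phasing oracle enumerates all parental phase-labeling sequences
explicitly (one bit per heterozygous marker per parent) and, for each,
computes every child's minimum transmission-switch count with a trivial
4-state dynamic program, vectorized over labeling combinations.  It shares
no code with the joint-state DP under test.
"""

import numpy as np

INF = 10**6


def brute_force_min_switches(d0, d1, dch):
    """Exhaustive minimum-recombinant switch count for a nuclear family.

    d0, d1: (M,) parent dosages in {0,1,2}; dch: (k, M) child dosages.
    Assumes genotypes are jointly consistent (no Mendelian errors).
    """
    d0 = np.asarray(d0)
    d1 = np.asarray(d1)
    dch = np.asarray(dch)
    k, M = dch.shape
    het0 = np.flatnonzero(d0 == 1)
    het1 = np.flatnonzero(d1 == 1)
    n0, n1 = het0.size, het1.size
    C = 1 << (n0 + n1)
    combos = np.arange(C)
    lam0 = np.zeros((C, M), dtype=np.int8)
    lam1 = np.zeros((C, M), dtype=np.int8)
    for i, m in enumerate(het0):
        lam0[:, m] = (combos >> i) & 1
    for i, m in enumerate(het1):
        lam1[:, m] = (combos >> (n0 + i)) & 1
    half0 = np.where(d0 == 1, 0, d0 // 2)
    half1 = np.where(d1 == 1, 0, d1 // 2)
    total = np.zeros(C, dtype=np.int64)
    # transition cost between 2-bit states
    ham = np.array([[bin(a ^ b).count("1") for b in range(4)] for a in range(4)])
    for ci in range(k):
        cost = np.zeros((C, 4), dtype=np.int64)
        started = False
        for m in range(M):
            ok = np.empty((C, 4), dtype=bool)
            for s in range(4):
                t0, t1 = s & 1, (s >> 1) & 1
                a0 = np.where(d0[m] == 1, lam0[:, m] ^ t0, half0[m])
                a1 = np.where(d1[m] == 1, lam1[:, m] ^ t1, half1[m])
                ok[:, s] = (a0 + a1) == dch[ci, m]
            step = np.where(ok, 0, INF)
            if not started:
                cost = step
                started = True
            else:
                # min-plus over the 4x4 Hamming transition matrix
                cost = (cost[:, :, None] + ham[None, :, :]).min(axis=1) + step
        total += cost.min(axis=1)
    return int(total.min())


def brute_force_binom_two_sided(k, n, p=0.5):
    """Two-sided exact binomial p by direct summation of all n+1 outcomes
    whose probability does not exceed the observed outcome's."""
    from math import comb

    probs = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    obs = probs[k]
    return sum(q for q in probs if q <= obs * (1 + 1e-12))


def random_family_instance(rng, max_markers=8, max_children=4, max_het=12,
                           p_missing=0.0):
    """Random consistent nuclear-family genotypes via explicit haplotypes."""
    while True:
        M = int(rng.integers(2, max_markers + 1))
        k = int(rng.integers(1, max_children + 1))
        h0 = rng.integers(0, 2, (2, M)).astype(np.int8)
        h1 = rng.integers(0, 2, (2, M)).astype(np.int8)
        d0 = h0.sum(axis=0)
        d1 = h1.sum(axis=0)
        if (d0 == 1).sum() + (d1 == 1).sum() > max_het:
            continue
        dch = np.empty((k, M), dtype=np.int8)
        for ci in range(k):
            # random transmissions with a few random switch points
            t0 = _random_bits(rng, M)
            t1 = _random_bits(rng, M)
            dch[ci] = h0[t0, np.arange(M)] + h1[t1, np.arange(M)]
        if p_missing > 0:
            for d in (d0, d1):
                d[rng.random(M) < p_missing] = -1
            hit = rng.random(dch.shape) < p_missing
            dch[hit] = -1
        return d0.astype(np.int8), d1.astype(np.int8), dch


def _random_bits(rng, M):
    bits = np.zeros(M, dtype=np.int64)
    b = int(rng.integers(2))
    for m in range(M):
        if rng.random() < 0.2:
            b ^= 1
        bits[m] = b
    return bits
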