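"""Jitted primitives for the discrete genetic algorithm.

These are the single authoritative implementations of the GA operators;
the public functions in :mod:`hsqcmatch.dga` are thin wrappers around
them. All kernels take a ``numpy.random.Generator`` so that a seeded run
is bit-reproducible. Index vectors are int64 arrays of pairwise-distinct
0-based slot indices; mutation kernels operate in place on a caller-owned
copy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# mutation codes used inside the evolve kernel
EXC, L3O, L4O, EXON = 0, 1, 2, 3
# crossover-mask codes
RX, BURSTRAND, SINGLEBURST = 0, 1, 2

# the 9 derangements of 4 elements, as index permutations
_L4O_DERANGEMENTS = np.array(
    [
        [1, 0, 3, 2],
        [1, 2, 3, 0],
        [1, 3, 0, 2],
        [2, 0, 3, 1],
        [2, 3, 0, 1],
        [2, 3, 1, 0],
        [3, 0, 1, 2],
        [3, 2, 0, 1],
        [3, 2, 1, 0],
    ],
    dtype=np.int64,
)


@njit(cache=True)
def match_cost_kernel(d, j):
    """Sum of matched pair distances: entries j[n] < M contribute d[n, j[n]]."""
    m = d.shape[1]
    s = 0.0
    for n in range(j.size):
        if j[n] < m:
            s += d[n, j[n]]
    return s


@njit(cache=True)
def random_injection(n, universe, rng):
    """Uniformly random injective vector of n distinct slots in [0, universe)."""
    perm = np.arange(universe)
    for i in range(n):  # partial Fisher-Yates: first n entries uniform
        k = rng.integers(i, universe)
        tmp = perm[i]
        perm[i] = perm[k]
        perm[k] = tmp
    return perm[:n].copy()


@njit(cache=True)
def _distinct_positions(n, k, rng):
    pos = np.arange(n)
    for i in range(k):
        t = rng.integers(i, n)
        tmp = pos[i]
        pos[i] = pos[t]
        pos[t] = tmp
    return pos[:k]


@njit(cache=True)
def mutate_exc(j, rng):
    """Exchange the values at two distinct random positions (2-opt swap)."""
    n = j.size
    i1 = rng.integers(0, n)
    i2 = rng.integers(0, n - 1)
    if i2 >= i1:
        i2 += 1
    tmp = j[i1]
    j[i1] = j[i2]
    j[i2] = tmp


@njit(cache=True)
def mutate_l3o(j, rng):
    """Derange the values at three random positions (2 derangements of 3)."""
    pos = _distinct_positions(j.size, 3, rng)
    a = j[pos[0]]
    b = j[pos[1]]
    c = j[pos[2]]
    if rng.integers(0, 2) == 0:
        j[pos[0]] = b
        j[pos[1]] = c
        j[pos[2]] = a
    else:
        j[pos[0]] = c
        j[pos[1]] = a
        j[pos[2]] = b


@njit(cache=True)
def mutate_l4o(j, rng):
    """Derange the values at four random positions (9 derangements of 4)."""
    pos = _distinct_positions(j.size, 4, rng)
    vals = j[pos].copy()
    der = _L4O_DERANGEMENTS[rng.integers(0, 9)]
    for t in range(4):
        j[pos[t]] = vals[der[t]]


@njit(cache=True)
def mutate_exon(j, m_target, rng):
    """Replace the value at a random position with an unused slot in [0, M).

    Only meaningful when N < M (an unused target slot exists).
    """
    n = j.size
    used = np.zeros(m_target, np.bool_)
    for i in range(n):
        used[j[i]] = True
    r = rng.integers(0, m_target - n)  # rank of the unused value to take
    val = -1
    for v in range(m_target):
        if not used[v]:
            if r == 0:
                val = v
                break
            r -= 1
    j[rng.integers(0, n)] = val


@njit(cache=True)
def mask_rx(n, rng):
    """Independent fair bits."""
    r = np.empty(n, np.uint8)
    for i in range(n):
        r[i] = 1 if rng.random() < 0.5 else 0
    return r


@njit(cache=True)
def mask_burstrand(n, rng):
    """Bursty bits: P(bit flips its predecessor) = 2/n (Gilbert-Elliott)."""
    r = np.empty(n, np.uint8)
    r[0] = 1 if rng.random() < 0.5 else 0
    pflip = 2.0 / n
    for i in range(1, n):
        if rng.random() < pflip:
            r[i] = 1 - r[i - 1]
        else:
            r[i] = r[i - 1]
    return r


@njit(cache=True)
def mask_singleburst(n, rng):
    """A single wrapping block of ones, length uniform in [3, n]."""
    length = rng.integers(3, n + 1)
    start = rng.integers(0, n)
    r = np.zeros(n, np.uint8)
    for t in range(length):
        r[(start + t) % n] = 1
    return r


@njit(cache=True)
def combine(a, b, mask, universe):
    """Order-based crossover fill.

    The child copies a's value where the mask is 1; remaining positions
    are filled left-to-right from b's value sequence, skipping values
    already present, falling back to unused slots in ascending order if b
    is exhausted. The child is always a valid injective vector.
    """
    n = a.size
    child = np.empty(n, np.int64)
    used = np.zeros(universe, np.bool_)
    for i in range(n):
        if mask[i] == 1:
            child[i] = a[i]
            used[a[i]] = True
    ptr = 0
    nxt = 0
    for i in range(n):
        if mask[i] == 1:
            continue
        while ptr < n and used[b[ptr]]:
            ptr += 1
        if ptr < n:
            child[i] = b[ptr]
            used[b[ptr]] = True
            ptr += 1
        else:
            while used[nxt]:
                nxt += 1
            child[i] = nxt
            used[nxt] = True
    return child


@njit(cache=True)
def evolve_kernel(d, k_pop, gmax, sweeps, rng):
    """Full evolution loop over the distance matrix d (N×M).

    Per generation: `sweeps` mutation sweeps (each member spawns one
    mutant via a uniformly chosen applicable mutation, greedily accepted
    iff strictly cheaper), then one crossover step (k_pop children from
    random distinct parent pairs with a uniformly chosen mask kind, each
    replacing the current worst member iff strictly cheaper). The best
    member can never be lost. Early exit when the best cost reaches 0.

    Returns (population, costs, best index, nfe, generations run).
    """
    n, m = d.shape
    universe = max(n, m)
    pop = np.empty((k_pop, n), np.int64)
    costs = np.empty(k_pop, np.float64)
    for k in range(k_pop):
        pop[k] = random_injection(n, universe, rng)
        costs[k] = match_cost_kernel(d, pop[k])
    nfe = k_pop

    kinds = np.empty(4, np.int64)
    nk = 0
    if n >= 2:
        kinds[nk] = EXC
        nk += 1
    if n >= 3:
        kinds[nk] = L3O
        nk += 1
    if n >= 4:
        kinds[nk] = L4O
        nk += 1
    if n < m:
        kinds[nk] = EXON
        nk += 1
    n_mask_kinds = 3 if n >= 3 else 2

    gens = 0
    for _ in range(gmax):
        if costs.min() == 0.0:
            break
        for _ in range(sweeps):
            for k in range(k_pop):
                mut = pop[k].copy()
                if nk > 0:
                    kind = kinds[rng.integers(0, nk)]
                    if kind == EXC:
                        mutate_exc(mut, rng)
                    elif kind == L3O:
                        mutate_l3o(mut, rng)
                    elif kind == L4O:
                        mutate_l4o(mut, rng)
                    else:
                        mutate_exon(mut, m, rng)
                c = match_cost_kernel(d, mut)
                nfe += 1
                if c < costs[k]:
                    pop[k] = mut
                    costs[k] = c
        for _ in range(k_pop):
            i1 = rng.integers(0, k_pop)
            i2 = rng.integers(0, k_pop - 1)
            if i2 >= i1:
                i2 += 1
            mk = rng.integers(0, n_mask_kinds)
            if mk == RX:
                mask = mask_rx(n, rng)
            elif mk == BURSTRAND:
                mask = mask_burstrand(n, rng)
            else:
                mask = mask_singleburst(n, rng)
            child = combine(pop[i1], pop[i2], mask, universe)
            c = match_cost_kernel(d, child)
            nfe += 1
            worst = np.argmax(costs)
            if c < costs[worst]:
                pop[worst] = child
                costs[worst] = c
        gens += 1

    best = int(np.argmin(costs))
    return pop, costs, best, nfe, gens
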