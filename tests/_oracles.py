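"""Brute-force references, independent of the library's own code paths.

Everything here enumerates inheritance vectors with plain Python loops
and first-principles chain probabilities, so it can serve as an oracle
for the closed forms, the sampling routines, and the dynamic program.
"""

from itertools import product

import numpy as np


def chain_prob(j, r, alpha0):
    p = alpha0 if j[0] == 0 else 1.0 - alpha0
    for i in range(1, len(j)):
        p *= (1.0 - r[i - 1]) if j[i] == j[i - 1] else r[i - 1]
    return p


def all_vectors(n):
    return list(product((0, 1), repeat=n))


def marginals_by_enumeration(r, alpha0, n):
    out = np.zeros(n)
    for j in all_vectors(n):
        p = chain_prob(j, r, alpha0)
        for i, bit in enumerate(j):
            if bit == 0:
                out[i] += p
    return out


def gamete_of(L, j):
    return [L[i][j[i]] for i in range(len(j))]


def g3_distribution(L1, L2, r, alpha0):
    """Yield (probability, g3) over all 2^(3N) joint inheritance vectors."""
    n = len(L1)
    for j1 in all_vectors(n):
        p1 = chain_prob(j1, r, alpha0)
        g1 = gamete_of(L1, j1)
        for j2 in all_vectors(n):
            p2 = chain_prob(j2, r, alpha0)
            g2 = gamete_of(L2, j2)
            child = list(zip(g1, g2))
            for j3 in all_vectors(n):
                yield p1 * p2 * chain_prob(j3, r, alpha0), gamete_of(child, j3)


def ecv_by_enumeration(L1, L2, r, alpha0):
    return sum(p * sum(g3) for p, g3 in g3_distribution(L1, L2, r, alpha0))


def pcv_by_enumeration(L1, L2, r, alpha0):
    n = len(L1)
    return sum(p for p, g3 in g3_distribution(L1, L2, r, alpha0) if sum(g3) == n)
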