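"""The inheritance distribution and gamete-level machinery.

Meiosis is modelled as a first-order Markov chain on the binary vector
``J``: locus by locus, ``J_i`` says which of the two parental gamete
columns contributes the allele.  The chain starts at 0 with probability
``alpha0`` and switches between consecutive loci with the adjacent-locus
recombination frequency ``r_{i-1}``.  Under Mendel's second law
``alpha0 = 0.5`` and every marginal is exactly 0.5.

Built on top of this law:

* ``gam`` maps a 2-column genotype matrix and an inheritance vector to a
  gamete;
* ``recombinant_gamete`` simulates the grandchild gamete ``g3`` obtained
  by crossing two parents and letting the child undergo meiosis (three
  independent inheritance vectors);
* ``pcv`` is the probability that ``g3`` carries only desirable alleles,
  computed exactly by a forward dynamic program over the 8 joint states
  ``(J1_i, J2_i, J3_i)`` (the three chains are independent, so the joint
  chain is Markov with constant 8-state transition work per locus);
* exhaustive enumeration helpers provide exact small-``N`` references.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "InheritanceParams",
    "phi",
    "marginal_prob_zero",
    "sample_inheritance",
    "gam",
    "recombinant_gamete",
    "loss_count",
    "pcv",
    "inheritance_vector_probability",
    "enumerate_marginals",
    "g3_locus_marginals",
]


@dataclass(frozen=True)
class InheritanceParams:
    """Parameters (r, alpha0) of the inheritance distribution over N loci.

    ``r`` has length ``N - 1`` with entries in ``[0, 0.5]``; ``alpha0`` is
    the probability that the first locus comes from the first gamete column.
    """

    r: np.ndarray
    alpha0: float = 0.5

    def __post_init__(self) -> None:
        r = np.atleast_1d(np.asarray(self.r, dtype=float))
        if r.size and (r.min() < 0.0 or r.max() > 0.5):
            raise ValueError("recombination frequencies must lie in [0, 0.5]")
        if not 0.0 <= self.alpha0 <= 1.0:
            raise ValueError("alpha0 must lie in [0, 1]")
        object.__setattr__(self, "r", r)

    @property
    def n_loci(self) -> int:
        return self.r.size + 1

    @classmethod
    def mendelian(cls, r: np.ndarray) -> "InheritanceParams":
        return cls(r=np.asarray(r, dtype=float), alpha0=0.5)


def phi(params: InheritanceParams) -> np.ndarray:
    """Recursion phi_1 = 0, phi_2 = r_1, phi_i = r_{i-1} + (1 - 2 r_{i-1}) phi_{i-1}.

    phi_i is the probability that J_i differs from J_1; all values lie in
    [0, 0.5].
    """
    r = params.r
    out = np.zeros(r.size + 1)
    for i in range(1, out.size):
        out[i] = r[i - 1] + (1.0 - 2.0 * r[i - 1]) * out[i - 1]
    return out


def marginal_prob_zero(params: InheritanceParams) -> np.ndarray:
    """Pr(J_i = 0) = alpha0 + (1 - 2 alpha0) phi_i(r) for every locus i."""
    return params.alpha0 + (1.0 - 2.0 * params.alpha0) * phi(params)


def sample_inheritance(
    params: InheritanceParams, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw inheritance vectors from the chain law.

    With ``size=None`` returns one length-``N`` 0/1 vector; otherwise a
    ``(size, N)`` matrix of independent draws.  The chain is simulated as a
    cumulative XOR of independent switch indicators, which vectorizes over
    draws.
    """
    m = 1 if size is None else int(size)
    n = params.n_loci
    first = rng.random(m) >= params.alpha0  # J_1 = 1 with prob 1 - alpha0
    switches = rng.random((m, n - 1)) < params.r[None, :] if n > 1 else np.empty((m, 0), bool)
    bits = np.empty((m, n), dtype=np.int64)
    bits[:, 0] = first
    if n > 1:
        bits[:, 1:] = switches
    j = (np.cumsum(bits, axis=1) % 2).astype(np.int8)
    return j[0] if size is None else j


def gam(L: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Gamete function: g_i = L[i, 0] if J_i = 0 else L[i, 1]."""
    L = _as_matrix(L)
    J = np.asarray(J)
    if J.shape != (L.shape[0],):
        raise ValueError(f"inheritance vector length {J.shape} does not match {L.shape[0]} loci")
    return L[np.arange(L.shape[0]), J.astype(np.intp)]


def recombinant_gamete(
    L1: np.ndarray, L2: np.ndarray, params: InheritanceParams, rng: np.random.Generator
) -> np.ndarray:
    """One draw of the grandchild gamete g3 = gam([gam(L1,J1), gam(L2,J2)], J3)."""
    L1, L2 = _as_matrix(L1), _as_matrix(L2)
    if L1.shape != L2.shape:
        raise ValueError("parent genotype matrices must have equal shapes")
    j1 = sample_inheritance(params, rng)
    j2 = sample_inheritance(params, rng)
    j3 = sample_inheritance(params, rng)
    g1 = gam(L1, j1)
    g2 = gam(L2, j2)
    return gam(np.column_stack([g1, g2]), j3)


def loss_count(g3: np.ndarray) -> int:
    """Number of undesirable alleles in a gamete: N - sum(g3)."""
    g3 = np.asarray(g3)
    return int(g3.size - g3.sum())


# ---------------------------------------------------------------------------
# Exact probabilities
# ---------------------------------------------------------------------------

_STATES = np.array(list(product((0, 1), repeat=3)), dtype=np.int8)  # (j1, j2, j3)


def _g3_of_state(L1: np.ndarray, L2: np.ndarray, i: int) -> np.ndarray:
    """g3 value at locus i for each of the 8 joint states."""
    g1 = L1[i, _STATES[:, 0]]
    g2 = L2[i, _STATES[:, 1]]
    return np.where(_STATES[:, 2] == 0, g1, g2)


def pcv(L1: np.ndarray, L2: np.ndarray, params: InheritanceParams) -> float:
    """Probability that g3 consists exclusively of desirable alleles.

    Exact forward DP over the joint state (J1_i, J2_i, J3_i), keeping only
    the mass on states whose g3_i equals 1; linear in N.
    """
    L1, L2 = _as_matrix(L1), _as_matrix(L2)
    if L1.shape != L2.shape:
        raise ValueError("parent genotype matrices must have equal shapes")
    n = L1.shape[0]
    if n != params.n_loci:
        raise ValueError("params length inconsistent with locus count")
    a0 = params.alpha0
    start = np.array([a0, 1.0 - a0])
    w = start[_STATES[:, 0]] * start[_STATES[:, 1]] * start[_STATES[:, 2]]
    w = w * (_g3_of_state(L1, L2, 0) == 1)
    for i in range(1, n):
        r = params.r[i - 1]
        stay = np.array([1.0 - r, r])  # prob of (same, switch) per chain
        trans = (
            stay[np.abs(_STATES[:, 0][:, None] - _STATES[:, 0][None, :])]
            * stay[np.abs(_STATES[:, 1][:, None] - _STATES[:, 1][None, :])]
            * stay[np.abs(_STATES[:, 2][:, None] - _STATES[:, 2][None, :])]
        )
        w = w @ trans
        w = w * (_g3_of_state(L1, L2, i) == 1)
    return float(w.sum())


def inheritance_vector_probability(j: np.ndarray, params: InheritanceParams) -> float:
    """Exact chain probability of one inheritance vector."""
    j = np.asarray(j)
    p = params.alpha0 if j[0] == 0 else 1.0 - params.alpha0
    for i in range(1, j.size):
        ri = params.r[i - 1]
        p *= ri if j[i] != j[i - 1] else 1.0 - ri
    return float(p)


def enumerate_marginals(params: InheritanceParams) -> np.ndarray:
    """Pr(J_i = 0) per locus by exhaustive enumeration of all 2^N vectors.

    Exact small-N reference for :func:`marginal_prob_zero`; intended for
    N <= ~16.
    """
    n = params.n_loci
    out = np.zeros(n)
    for bits in product((0, 1), repeat=n):
        j = np.array(bits, dtype=np.int8)
        p = inheritance_vector_probability(j, params)
        out += p * (j == 0)
    return out


def g3_locus_marginals(L1: np.ndarray, L2: np.ndarray, params: InheritanceParams) -> np.ndarray:
    """Pr(g3_i = 1) per locus, in closed form from the chain marginals.

    With beta_i = Pr(J_i = 1), locus i of g3 is desirable with probability
    (1 - beta_i) * [(1 - beta_i) L1[i,0] + beta_i L1[i,1]]
    + beta_i * [(1 - beta_i) L2[i,0] + beta_i L2[i,1]],
    since J3 picks the child column and J1 (resp. J2) picks within each
    parent.  Used for the Frechet upper bound on the PCV.
    """
    L1, L2 = _as_matrix(L1), _as_matrix(L2)
    beta = 1.0 - marginal_prob_zero(params)  # Pr(J_i = 1)
    p1 = (1.0 - beta) * L1[:, 0] + beta * L1[:, 1]
    p2 = (1.0 - beta) * L2[:, 0] + beta * L2[:, 1]
    return (1.0 - beta) * p1 + beta * p2


def _as_matrix(L: np.ndarray) -> np.ndarray:
    entries = getattr(L, "entries", L)
    entries = np.asarray(entries)
    if entries.ndim != 2 or entries.shape[1] != 2:
        raise ValueError("genotype matrix must be N x 2")
    return entries
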