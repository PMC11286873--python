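"""Closed-form expected cross value (ECV) of a parental pair.

The ECV of a pair is the expected number of desirable alleles in the
gamete ``g3`` that a child of the pair transmits to the next generation.
Under Mendelian segregation (``alpha0 = 0.5``) the expectation collapses
to a quarter of the total desirable-allele count of the four parental
gamete columns and does not depend on the recombination map; the general
non-Mendelian closed form is also provided, together with a Monte-Carlo
estimator used purely as a verification oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .inheritance import InheritanceParams, loss_count, phi, recombinant_gamete
from .population import HaplotypePopulation, TraitArchitecture, trait_view

__all__ = ["EcvValue", "ecv_mendel", "ecv_general", "ecv_all_traits", "ecv_monte_carlo"]


@dataclass(frozen=True)
class EcvValue:
    """An ECV together with its trait label; value lies in [0, N_l]."""

    value: float
    trait_id: str = ""

    @property
    def as_fraction(self) -> Fraction:
        """Exact quarter-integer form of a Mendelian ECV."""
        return Fraction(round(self.value * 4), 4)

    def __float__(self) -> float:
        return self.value


def ecv_mendel(view1, view2, trait_id: str = "") -> EcvValue:
    """Mendelian closed form: 0.25 * sum of all four parental gamete entries.

    Exact (a multiple of 0.25) and independent of the recombination map.
    """
    e1, e2 = _entries(view1), _entries(view2)
    if e1.shape != e2.shape:
        raise ValueError("parent views must have equal shapes")
    total = int(e1.sum()) + int(e2.sum())
    return EcvValue(value=0.25 * total, trait_id=trait_id or _trait_of(view1, view2))


def ecv_general(view1, view2, params: InheritanceParams, trait_id: str = "") -> EcvValue:
    """General closed form without Mendel's second law.

    With beta_i = 1 - alpha0 + (2 alpha0 - 1) phi_i(r) = Pr(J_i = 1), the
    per-locus contribution is
    L1[i,0] + beta_i (L1[i,1] - 2 L1[i,0] + L2[i,0])
            + beta_i^2 (L2[i,1] + L1[i,0] - L1[i,1] - L2[i,0]).
    Reduces to :func:`ecv_mendel` at alpha0 = 0.5.
    """
    e1, e2 = _entries(view1), _entries(view2)
    if e1.shape != e2.shape:
        raise ValueError("parent views must have equal shapes")
    if e1.shape[0] != params.n_loci:
        raise ValueError("params length inconsistent with locus count")
    beta = 1.0 - params.alpha0 + (2.0 * params.alpha0 - 1.0) * phi(params)
    a, b = e1[:, 0].astype(float), e1[:, 1].astype(float)
    c, d = e2[:, 0].astype(float), e2[:, 1].astype(float)
    per_locus = a + beta * (b - 2.0 * a + c) + beta**2 * (d + a - b - c)
    return EcvValue(value=float(per_locus.sum()), trait_id=trait_id or _trait_of(view1, view2))


def ecv_all_traits(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    k1: int | str,
    k2: int | str,
    allow_self_cross: bool = False,
) -> list[EcvValue]:
    """Per-trait Mendelian ECVs of a candidate pair, in trait order."""
    i1 = pop.index_of(k1) if isinstance(k1, str) else int(k1)
    i2 = pop.index_of(k2) if isinstance(k2, str) else int(k2)
    if i1 == i2 and not allow_self_cross:
        raise ValueError(f"self-cross of individual {k1!r} requested but not enabled")
    return [
        ecv_mendel(trait_view(pop, arch, i1, t), trait_view(pop, arch, i2, t), trait_id=t)
        for t in arch.trait_ids
    ]


def ecv_monte_carlo(
    view1,
    view2,
    params: InheritanceParams,
    rng: np.random.Generator,
    n_draws: int = 100_000,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the ECV with its standard error.

    Averages N - loss over simulated g3 gametes; a slow verification oracle
    for the closed forms, never used by the selectors.
    """
    e1, e2 = _entries(view1), _entries(view2)
    n = e1.shape[0]
    vals = np.empty(n_draws)
    for t in range(n_draws):
        vals[t] = n - loss_count(recombinant_gamete(e1, e2, params, rng))
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_draws))


def _entries(view) -> np.ndarray:
    entries = np.asarray(getattr(view, "entries", view))
    if entries.ndim != 2 or entries.shape[1] != 2:
        raise ValueError("trait view must be an N x 2 matrix")
    return entries


def _trait_of(view1, view2) -> str:
    return getattr(view1, "trait_id", "") or getattr(view2, "trait_id", "")
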