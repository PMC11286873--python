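"""Mate-selection optimizers built on the ECV criterion.

The single-trait problem is: over unordered candidate pairs (k, k'),
maximize the Mendelian ECV subject to a cap ``G(k, k') <= epsilon`` on
the VanRaden genomic relationship of the mates, excluding an explicit
set of forbidden ("conflict") pairs.  A crossing block of ``n_c`` pairs
is built by re-solving with a conflict constraint added for each pair
already chosen, so objectives are non-increasing across slots.  Multiple
traits are handled lexicographically: stage ``l`` maximizes the trait-l
ECV subject to every earlier stage retaining at least a ``(1 - tau_i)``
fraction of its optimum.

Three exact, mutually agreeing routes solve each single-pair problem:

* ``ilp`` — a binary program solved by HiGHS through scipy, with one
  indicator per admissible pair linked to per-individual indicators and
  an integer-scaled objective whose index penalty makes the optimum the
  lexicographically smallest maximizing pair;
* ``exhaustive`` — a vectorized scan of all admissible pairs (the
  semantic oracle, guarded to small populations);
* ``fast`` — a best-first search over pairs sorted by per-individual
  allele counts, exploiting the additivity of the Mendelian ECV; this is
  the route the breeding simulator uses at population sizes where a
  pair-indexed model is out of reach (candidate pools of 10^4 imply
  ~5x10^7 pairs).

Ties are always broken toward the lexicographically smallest (k, k')
index pair, making every route deterministic and solver-independent.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .population import HaplotypePopulation, TraitArchitecture, trait_counts

__all__ = [
    "SelectionConfig",
    "CrossingPlan",
    "PlanEntry",
    "InfeasibleSelectionError",
    "PartialPlanError",
    "select_best_pair_ilp",
    "select_best_pair_exhaustive",
    "select_best_pair",
    "select_pairs_iterative",
    "select_pairs_lexicographic",
    "select_pairs_by_score",
]

_ENUM_GUARD = 2000  # largest K for which pair-indexed (exhaustive / ILP) models are built
_TOL = 1e-9


class InfeasibleSelectionError(RuntimeError):
    """No admissible pair satisfies the constraints; names the binding one."""


class PartialPlanError(RuntimeError):
    """Selection became infeasible before n_c pairs were found."""

    def __init__(self, message: str, plan: "CrossingPlan"):
        super().__init__(message)
        self.plan = plan


@dataclass
class SelectionConfig:
    """Knobs of the mate-selection problem.

    ``epsilon`` is the maximum admissible VanRaden relationship between
    mates (``None`` disables the constraint); ``tolerances`` are the
    lexicographic degradation tolerances, one per trait in priority order,
    with the last entry required to be 0.
    """

    epsilon: float | None = 0.20
    n_pairs: int = 1
    tolerances: tuple[float, ...] = (0.0,)
    trait_priority: tuple[str, ...] = ()
    allow_self_cross: bool = False
    allow_repeated_parent: bool = True

    def __post_init__(self) -> None:
        if self.epsilon is not None and not np.isfinite(self.epsilon):
            self.epsilon = None
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be positive")
        taus = tuple(float(t) for t in self.tolerances)
        if any(not 0.0 <= t <= 1.0 for t in taus):
            raise ValueError("tolerances must lie in [0, 1]")
        if taus and taus[-1] != 0.0:
            raise ValueError("the last tolerance must be 0 (final stage is fully optimized)")
        self.tolerances = taus
        if self.trait_priority and len(self.trait_priority) != len(taus):
            raise ValueError("one tolerance per prioritized trait is required")
        if len(set(self.trait_priority)) != len(self.trait_priority):
            raise ValueError("trait_priority must list each trait once")


@dataclass(frozen=True)
class PlanEntry:
    parent1: int
    parent2: int
    parent1_id: str
    parent2_id: str
    ecv: tuple[float, ...]  # per trait, in priority order of the solve
    g_value: float
    stage_optima: tuple[float, ...] = ()

    @property
    def pair(self) -> tuple[int, int]:
        return (self.parent1, self.parent2)


@dataclass
class CrossingPlan:
    """Ordered crossing block for one generation."""

    entries: list[PlanEntry] = field(default_factory=list)
    trait_ids: tuple[str, ...] = ()
    method: str = "ecv"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [e.pair for e in self.entries]

    def mean_g(self) -> float:
        return float(np.mean([e.g_value for e in self.entries]))


# ---------------------------------------------------------------------------
# Problem assembly helpers
# ---------------------------------------------------------------------------


def _pair_g_fn(G) -> Callable[[int, int], float] | None:
    """Normalize any relationship representation to a pair lookup."""
    if G is None:
        return None
    if hasattr(G, "pair"):
        return G.pair
    mat = getattr(G, "G", G)
    mat = np.asarray(mat)
    return lambda a, b: float(mat[a, b])


def _norm_pair(k1: int, k2: int) -> tuple[int, int]:
    return (k1, k2) if k1 <= k2 else (k2, k1)


def _feasibility(
    G, config: SelectionConfig, forbidden: set[tuple[int, int]]
) -> Callable[[int, int], bool]:
    g_fn = _pair_g_fn(G)
    eps = config.epsilon

    def feasible(k1: int, k2: int) -> bool:
        if (k1, k2) in forbidden:
            return False
        if g_fn is not None and eps is not None and g_fn(k1, k2) > eps:
            return False
        return True

    return feasible


def _priority_counts(
    pop: HaplotypePopulation, arch: TraitArchitecture, trait_ids: Sequence[str]
) -> np.ndarray:
    counts = trait_counts(pop, arch)
    cols = [arch.trait_ids.index(t) if t in arch.trait_ids else -1 for t in trait_ids]
    for t, c in zip(trait_ids, cols):
        if c < 0:
            raise KeyError(f"unknown trait id {t!r}")
    return counts[:, cols]


def _threshold(opt_sum: int, tau: float) -> float:
    """Integer-count threshold equivalent to ECV >= (1 - tau) * opt."""
    return (1.0 - tau) * opt_sum - _TOL


# ---------------------------------------------------------------------------
# Exhaustive route (semantic oracle)
# ---------------------------------------------------------------------------


def _enumerate_all_pairs(K: int, allow_self: bool) -> tuple[np.ndarray, np.ndarray]:
    if K > _ENUM_GUARD:
        raise ValueError(f"pair enumeration guarded at K <= {_ENUM_GUARD} (got K={K})")
    k1, k2 = np.triu_indices(K, k=0 if allow_self else 1)
    return k1.astype(np.int64), k2.astype(np.int64)


def _scan_best(
    k1: np.ndarray,
    k2: np.ndarray,
    sums: np.ndarray,
    feasible: Callable[[int, int], bool],
) -> tuple[int, int, int] | None:
    """Best feasible pair under (-sum, k1, k2) order, or None.

    Walks equal-sum plateaus from the top instead of fully sorting: the
    maximum is located in O(n), its plateau is lex-ordered (it is tiny in
    practice), and only if a whole plateau is infeasible does the walk
    descend to the next value.
    """
    if k1.size == 0:
        return None
    active = np.ones(k1.size, dtype=bool)
    masked = sums.astype(np.int64, copy=True)
    lo = masked.min() - 1
    while active.any():
        vmax = int(masked.max())
        if vmax <= lo:
            break
        idx = np.flatnonzero(masked == vmax)
        order = np.lexsort((k2[idx], k1[idx]))
        for i in idx[order]:
            if feasible(int(k1[i]), int(k2[i])):
                return int(k1[i]), int(k2[i]), vmax
        active[idx] = False
        masked[idx] = lo
    return None


def _lex_solve_explicit(
    k1: np.ndarray,
    k2: np.ndarray,
    counts: np.ndarray,
    taus: Sequence[float],
    feasible: Callable[[int, int], bool],
) -> tuple[tuple[int, int], list[int]]:
    """Lexicographic solve over an explicit admissible-pair list."""
    m = counts.shape[1]
    opts: list[int] = []
    best: tuple[int, int] | None = None
    for stage in range(m):
        sums = counts[k1, stage] + counts[k2, stage]
        hit = _scan_best(k1, k2, sums, feasible)
        if hit is None:
            binding = "relatedness threshold epsilon / conflict constraints"
            raise InfeasibleSelectionError(
                f"no admissible pair at lexicographic stage {stage + 1}; binding: {binding}"
            )
        a, b, opt = hit
        opts.append(opt)
        best = (a, b)
        if stage < m - 1:
            keep = sums >= _threshold(opt, taus[stage])
            k1, k2 = k1[keep], k2[keep]
    assert best is not None
    return best, opts


# ---------------------------------------------------------------------------
# Fast route: best-first search on count-sorted pairs
# ---------------------------------------------------------------------------


def _heap_best_sum(
    c: np.ndarray, feasible: Callable[[int, int], bool]
) -> tuple[int, int, int] | None:
    """Max feasible c[k1]+c[k2] over k1<k2 via best-first search.

    Returns the lexicographically smallest feasible pair achieving the
    maximum feasible sum.  Pops are non-increasing in sum, so the first
    feasible pop fixes the optimum; the lex tie is then resolved by a
    direct scan of the equal-sum plateau.
    """
    K = c.size
    if K < 2:
        return None
    order = np.lexsort((np.arange(K), -c))
    sc = c[order]
    heap: list[tuple[int, int, int]] = [(-int(sc[0] + sc[1]), 0, 1)]
    seen = {(0, 1)}
    best_sum: int | None = None
    while heap:
        neg, a, b = heapq.heappop(heap)
        if feasible(*_norm_pair(int(order[a]), int(order[b]))):
            best_sum = -neg
            break
        if b + 1 < K and (a, b + 1) not in seen:
            seen.add((a, b + 1))
            heapq.heappush(heap, (-int(sc[a] + sc[b + 1]), a, b + 1))
        if a + 1 < b and (a + 1, b) not in seen:
            seen.add((a + 1, b))
            heapq.heappush(heap, (-int(sc[a + 1] + sc[b]), a + 1, b))
    if best_sum is None:
        return None
    # lexicographic winner on the plateau c[k1] + c[k2] == best_sum
    buckets: dict[int, np.ndarray] = {}
    for v in np.unique(c):
        buckets[int(v)] = np.flatnonzero(c == v)
    for a_idx in range(K):
        need = best_sum - int(c[a_idx])
        partners = buckets.get(need)
        if partners is None:
            continue
        for b_idx in partners[partners > a_idx]:
            if feasible(a_idx, int(b_idx)):
                return a_idx, int(b_idx), best_sum
    return None  # pragma: no cover - plateau always contains the heap hit


def _threshold_pairs(c: np.ndarray, thr: float) -> tuple[np.ndarray, np.ndarray]:
    """All k1<k2 with c[k1]+c[k2] >= thr, via a sorted two-pointer sweep."""
    K = c.size
    order = np.lexsort((np.arange(K), -c))
    sc = c[order].astype(np.float64)
    # partner positions b > a with sc[a] + sc[b] >= thr form a prefix (a, cut_a]
    cuts = np.searchsorted(-sc, -(thr - sc), side="right")  # first pos where sc < thr - sc[a]
    a_pos = np.arange(K)
    lens = np.maximum(cuts - (a_pos + 1), 0)
    if lens.sum() == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    a_rep = np.repeat(a_pos, lens)
    b_flat = np.concatenate([np.arange(a + 1, a + 1 + n) for a, n in zip(a_pos, lens) if n])
    k1 = order[a_rep]
    k2 = order[b_flat]
    swap = k1 > k2
    k1[swap], k2[swap] = k2[swap], k1[swap]
    return k1.astype(np.int64), k2.astype(np.int64)


def _lex_solve_fast(
    counts: np.ndarray,
    taus: Sequence[float],
    feasible: Callable[[int, int], bool],
    allow_self: bool,
    enum_guard: int = _ENUM_GUARD,
    cache: dict | None = None,
) -> tuple[tuple[int, int], list[int]]:
    K = counts.shape[0]
    if K <= enum_guard or allow_self:
        if K > _ENUM_GUARD:
            raise ValueError("self-cross selection guarded to enumerable population sizes")
        if cache is not None and "all_pairs" in cache:
            k1, k2 = cache["all_pairs"]
        else:
            k1, k2 = _enumerate_all_pairs(K, allow_self)
            if cache is not None:
                cache["all_pairs"] = (k1, k2)
        return _lex_solve_explicit(k1, k2, counts, taus, feasible)
    hit = _heap_best_sum(counts[:, 0], feasible)
    if hit is None:
        raise InfeasibleSelectionError(
            "no admissible pair at lexicographic stage 1; "
            "binding: relatedness threshold epsilon / conflict constraints"
        )
    a, b, opt1 = hit
    if counts.shape[1] == 1:
        return (a, b), [opt1]
    thr = _threshold(opt1, taus[0])
    key = ("thr_pairs", round(thr, 9))
    if cache is not None and key in cache:
        k1, k2 = cache[key]
    else:
        k1, k2 = _threshold_pairs(counts[:, 0], thr)
        if cache is not None:
            cache[key] = (k1, k2)
    best, opts = _lex_solve_explicit_unguarded(k1, k2, counts[:, 1:], taus[1:], feasible)
    return best, [opt1, *opts]


def _lex_solve_explicit_unguarded(k1, k2, counts_rest, taus_rest, feasible):
    # same walk as _lex_solve_explicit but on a pre-built (possibly large) pair list
    m = counts_rest.shape[1]
    opts: list[int] = []
    best = None
    for stage in range(m):
        sums = counts_rest[k1, stage] + counts_rest[k2, stage]
        hit = _scan_best(k1, k2, sums, feasible)
        if hit is None:
            raise InfeasibleSelectionError(
                f"no admissible pair at lexicographic stage {stage + 2}; "
                "binding: relatedness threshold epsilon / conflict constraints"
            )
        a, b, opt = hit
        opts.append(opt)
        best = (a, b)
        if stage < m - 1:
            keep = sums >= _threshold(opt, taus_rest[stage])
            k1, k2 = k1[keep], k2[keep]
    return best, opts


# ---------------------------------------------------------------------------
# ILP route (HiGHS through scipy.optimize.milp)
# ---------------------------------------------------------------------------


def _lex_solve_ilp(
    counts: np.ndarray,
    taus: Sequence[float],
    G,
    config: SelectionConfig,
    forbidden: set[tuple[int, int]],
) -> tuple[tuple[int, int], list[int]]:
    """Lexicographic stages as a sequence of binary programs.

    One binary ``x_p`` per admissible pair, linked to per-individual
    binaries ``y_k = sum_{p : k in p} x_p``; exactly one pair is chosen.
    Pairs violating the relationship cap or listed as conflicts are removed
    from the model rather than constrained to zero.  The stage objective is
    the integer-scaled trait sum times ``K^2 + K + 1`` minus the pair's
    lexicographic rank, which makes the optimum unique and equal to the
    lexicographically smallest maximizing pair.
    """
    K = counts.shape[0]
    k1, k2 = _enumerate_all_pairs(K, config.allow_self_cross)
    keep = np.ones(k1.size, dtype=bool)
    if G is not None and config.epsilon is not None:
        mat = G.full_matrix() if hasattr(G, "full_matrix") else np.asarray(getattr(G, "G", G))
        keep &= mat[k1, k2] <= config.epsilon
    if forbidden:
        forb_ranks = np.array([a * (K + 1) + b for a, b in forbidden], dtype=np.int64)
        keep &= ~np.isin(k1 * (K + 1) + k2, forb_ranks)
    k1, k2 = k1[keep], k2[keep]
    n_pairs = k1.size
    if n_pairs == 0:
        raise InfeasibleSelectionError(
            "no admissible pair: every pair violates the relatedness threshold epsilon "
            "or is excluded by conflict constraints"
        )
    n_var = n_pairs + K  # pair indicators then individual indicators
    big = K * K + K + 1
    rank = k1 * (K + 1) + k2

    # sum_p x_p = 1 ; y_k - sum_{p: k in p} x_p = 0 for every individual
    one_row = sparse.csr_matrix(
        (np.ones(n_pairs), (np.zeros(n_pairs, int), np.arange(n_pairs))), shape=(1, n_var)
    )
    self_mask = k1 == k2
    rows_link = np.concatenate([k1, k2[~self_mask]])
    cols_link = np.concatenate([np.arange(n_pairs), np.arange(n_pairs)[~self_mask]])
    link = sparse.csr_matrix(
        (np.ones(rows_link.size), (rows_link, cols_link)), shape=(K, n_var)
    ) + sparse.csr_matrix(
        (-np.ones(K), (np.arange(K), n_pairs + np.arange(K))), shape=(K, n_var)
    )

    stage_sums = [counts[k1, j] + counts[k2, j] for j in range(counts.shape[1])]
    opts: list[int] = []
    best: tuple[int, int] | None = None
    extra_rows: list[sparse.csr_matrix] = []
    extra_lb: list[float] = []
    for stage in range(counts.shape[1]):
        sums = stage_sums[stage]
        c = np.zeros(n_var)
        c[:n_pairs] = -(sums.astype(np.int64) * big - rank)  # maximize
        A = sparse.vstack([one_row, link, *extra_rows], format="csr")
        lb = np.concatenate([[1.0], np.zeros(K), extra_lb])
        ub = np.concatenate([[1.0], np.zeros(K), np.full(len(extra_lb), np.inf)])
        res = milp(
            c=c,
            constraints=LinearConstraint(A, lb, ub),
            integrality=np.ones(n_var),
            bounds=Bounds(0, 1),
        )
        if res.status != 0 or res.x is None:
            raise InfeasibleSelectionError(
                f"MILP infeasible at lexicographic stage {stage + 1}; "
                "binding: relatedness threshold epsilon / conflict constraints"
            )
        chosen = int(np.argmax(res.x[:n_pairs]))
        best = (int(k1[chosen]), int(k2[chosen]))
        opt = int(sums[chosen])
        opts.append(opt)
        if stage < counts.shape[1] - 1:
            row = sparse.csr_matrix(
                (sums.astype(float), (np.zeros(n_pairs, int), np.arange(n_pairs))),
                shape=(1, n_var),
            )
            extra_rows.append(row)
            extra_lb.append(_threshold(opt, taus[stage]))
    assert best is not None
    return best, opts


# ---------------------------------------------------------------------------
# Public single-pair and multi-pair operations
# ---------------------------------------------------------------------------

_SOLVERS = ("exhaustive", "ilp", "fast")


def _solve_single(
    counts: np.ndarray,
    taus: Sequence[float],
    G,
    config: SelectionConfig,
    forbidden: set[tuple[int, int]],
    solver: str,
    cache: dict | None = None,
) -> tuple[tuple[int, int], list[int]]:
    if solver == "auto":
        solver = "fast"
    if solver not in _SOLVERS:
        raise ValueError(f"unknown solver {solver!r}; choose from {_SOLVERS}")
    if solver == "ilp":
        return _lex_solve_ilp(counts, taus, G, config, forbidden)
    feasible = _feasibility(G, config, forbidden)
    if solver == "exhaustive":
        k1, k2 = _enumerate_all_pairs(counts.shape[0], config.allow_self_cross)
        return _lex_solve_explicit(k1, k2, counts, taus, feasible)
    return _lex_solve_fast(counts, taus, feasible, config.allow_self_cross, cache=cache)


def _single_trait_setup(pop, arch, trait_id):
    counts = _priority_counts(pop, arch, [trait_id])
    return counts


def select_best_pair_ilp(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    trait_id: str,
    G,
    config: SelectionConfig,
    forbidden: Sequence[tuple[int, int]] = (),
) -> tuple[tuple[int, int], float]:
    """Single-trait optimal pair via the binary program (HiGHS)."""
    counts = _single_trait_setup(pop, arch, trait_id)
    pair, opts = _lex_solve_ilp(counts, [0.0], G, config, {_norm_pair(*p) for p in forbidden})
    return pair, 0.25 * opts[0]


def select_best_pair_exhaustive(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    trait_id: str,
    G,
    config: SelectionConfig,
    forbidden: Sequence[tuple[int, int]] = (),
) -> tuple[tuple[int, int], float]:
    """Single-trait optimal pair by scanning every admissible pair."""
    counts = _single_trait_setup(pop, arch, trait_id)
    forb = {_norm_pair(*p) for p in forbidden}
    pair, opts = _solve_single(counts, [0.0], G, config, forb, "exhaustive")
    return pair, 0.25 * opts[0]


def select_best_pair(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    trait_id: str,
    G,
    config: SelectionConfig,
    forbidden: Sequence[tuple[int, int]] = (),
    solver: str = "auto",
) -> tuple[tuple[int, int], float]:
    """Single-trait optimal pair via the configured solver route."""
    counts = _single_trait_setup(pop, arch, trait_id)
    forb = {_norm_pair(*p) for p in forbidden}
    pair, opts = _solve_single(counts, [0.0], G, config, forb, solver)
    return pair, 0.25 * opts[0]


def _build_plan(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    counts: np.ndarray,
    taus: Sequence[float],
    trait_ids: Sequence[str],
    G,
    config: SelectionConfig,
    solver: str,
    method: str,
) -> CrossingPlan:
    plan = CrossingPlan(trait_ids=tuple(trait_ids), method=method)
    forbidden: set[tuple[int, int]] = set()
    g_fn = _pair_g_fn(G)
    cache: dict = {}  # pair enumerations reused across crossing-block slots
    for _ in range(config.n_pairs):
        try:
            (a, b), opts = _solve_single(counts, taus, G, config, forbidden, solver, cache)
        except InfeasibleSelectionError as exc:
            raise PartialPlanError(
                f"selection infeasible after {len(plan)} of {config.n_pairs} pairs: {exc}",
                plan,
            ) from exc
        ecvs = tuple(0.25 * (int(counts[a, j]) + int(counts[b, j])) for j in range(counts.shape[1]))
        plan.entries.append(
            PlanEntry(
                parent1=a,
                parent2=b,
                parent1_id=pop.individual_id[a],
                parent2_id=pop.individual_id[b],
                ecv=ecvs,
                g_value=float("nan") if g_fn is None else g_fn(a, b),
                stage_optima=tuple(0.25 * o for o in opts),
            )
        )
        forbidden.add(_norm_pair(a, b))
    return plan


def select_pairs_iterative(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    trait_id: str,
    G,
    config: SelectionConfig,
    solver: str = "auto",
) -> CrossingPlan:
    """n_c single-trait pairs via repeated solves with conflict constraints."""
    counts = _priority_counts(pop, arch, [trait_id])
    return _build_plan(pop, arch, counts, [0.0], [trait_id], G, config, solver, "ecv")


def select_pairs_lexicographic(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    G,
    config: SelectionConfig,
    solver: str = "auto",
) -> CrossingPlan:
    """n_c pairs by lexicographic multi-trait ECV with degradation tolerances."""
    priority = config.trait_priority or arch.trait_ids
    taus = config.tolerances if len(config.tolerances) == len(priority) else (0.0,) * len(priority)
    counts = _priority_counts(pop, arch, priority)
    return _build_plan(pop, arch, counts, taus, priority, G, config, solver, "ecv")


def select_pairs_by_score(
    scores: np.ndarray,
    config: SelectionConfig,
    individual_ids: Sequence[str] | None = None,
    G=None,
    method: str = "score",
) -> CrossingPlan:
    """Baseline pairing: top n_c pairs by summed per-individual scores.

    ``scores`` is K x M (or length K); the pair score is the sum of both
    mates' scores over all traits.  No relationship constraint is applied,
    and self-crossing is never allowed; ties fall to the smallest index
    pair.  Only the top ``n_c + 1`` individuals under the strict
    (-score, index) order can appear in the top ``n_c`` pairs, so the
    enumeration is restricted to them.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    total = s.sum(axis=1)
    K = total.size
    n_c = config.n_pairs
    if K * (K - 1) // 2 < n_c:
        raise InfeasibleSelectionError(f"fewer than {n_c} distinct pairs exist (K={K})")
    order = np.lexsort((np.arange(K), -total))
    top = order[: min(K, n_c + 1)]
    a, b = np.triu_indices(top.size, k=1)
    k1, k2 = top[a], top[b]
    swap = k1 > k2
    k1[swap], k2[swap] = k2[swap], k1[swap]
    sums = total[k1] + total[k2]
    pick = np.lexsort((k2, k1, -sums))[:n_c]
    g_fn = _pair_g_fn(G)
    plan = CrossingPlan(trait_ids=(), method=method)
    for idx in pick:
        aa, bb = int(k1[idx]), int(k2[idx])
        plan.entries.append(
            PlanEntry(
                parent1=aa,
                parent2=bb,
                parent1_id=individual_ids[aa] if individual_ids else str(aa),
                parent2_id=individual_ids[bb] if individual_ids else str(bb),
                ecv=(),
                g_value=float("nan") if g_fn is None else g_fn(aa, bb),
            )
        )
    return plan
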