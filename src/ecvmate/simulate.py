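"""Synthetic breeding populations and multi-generation selection runs.

The generator emulates the study conditions of the benchmark: an initial
panel of 10,000 individuals genotyped at 200 biallelic QTL plus 100
neutral markers, every allele an independent fair coin (allele frequency
0.5 at all loci).  Three traits are wired into the QTL: Trait 1 on 40
loci, Trait 2 on 10, Trait 3 on 70, with 20 loci shared between Traits
1 and 3 carrying antagonistic orientation (the allele that raises
Trait 1 lowers Trait 3), which induces a negative genetic correlation.

Unprinted physical details are fixed here as package defaults: ten
chromosomes of 30 interleaved positions (qtl, qtl, marker), adjacent
recombination 0.1 within and 0.5 across chromosomes, |effect| = 1 per
desirable-allele copy, heritability 0.5 per trait, and a VanRaden
relatedness cap of 0.20 for ECV selection.

Generations advance by simulating meiosis for every selected cross: an
offspring's two gametes are independent draws from its two parents under
the first-order Markov inheritance law with alpha0 = 0.5 over the full
map, vectorized across progeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomic import VanRadenG, fit_rrblup, predict_gebv
from .inheritance import InheritanceParams, sample_inheritance
from .population import (
    MARKER,
    QTL,
    GeneticMap,
    HaplotypePopulation,
    TraitArchitecture,
    trait_counts,
)
from .selection import (
    CrossingPlan,
    SelectionConfig,
    select_pairs_by_score,
    select_pairs_lexicographic,
)

__all__ = [
    "SimConfig",
    "TraitEffects",
    "ScenarioResult",
    "scenario_config",
    "build_genetic_map",
    "generate_initial_population",
    "derive_effects",
    "simulate_phenotypes",
    "genetic_values",
    "advance_generation",
    "run_scenario",
    "SCENARIO_PAIRS",
]

# crossing-block sizes per generation for the three selection-intensity scenarios
SCENARIO_PAIRS = {"A": (50, 10, 3, 3), "B": (50, 10, 5, 5), "C": (50, 25, 5, 5)}

# printed degradation-tolerance schedule: tau_{1,c} = .17,.05,.05,.05 and
# tau_{2,c} = 0,0,0,.05; the last-priority trait always carries tau = 0
DEFAULT_TAU_SCHEDULE = (
    (0.17, 0.00, 0.0),
    (0.05, 0.00, 0.0),
    (0.05, 0.00, 0.0),
    (0.05, 0.05, 0.0),
)


@dataclass
class SimConfig:
    """Study conditions for one simulated breeding program."""

    k0: int = 10_000
    n_qtl: int = 200
    n_markers: int = 100
    trait_sizes: tuple[int, ...] = (40, 10, 70)
    n_antagonistic: int = 20
    progeny_per_cross: int = 100
    generations: int = 4
    pairs_per_generation: tuple[int, ...] = SCENARIO_PAIRS["B"]
    heritability: float | tuple[float, ...] = 0.5
    n_chromosomes: int = 10
    r_within: float = 0.1
    epsilon: float = 0.20
    # lexicographic importance order: Trait 1 first, Trait 3 second (protected
    # by a zero tolerance in early generations, favouring it against the
    # antagonistic pull of Trait 1), Trait 2 optimized last
    trait_priority: tuple[str, ...] = ("trait1", "trait3", "trait2")
    tau_schedule: tuple[tuple[float, ...], ...] = DEFAULT_TAU_SCHEDULE
    replications: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pairs_per_generation) != self.generations:
            raise ValueError("one crossing-block size per generation is required")
        if len(self.tau_schedule) < self.generations:
            raise ValueError("tau_schedule must cover every generation")
        if sum(self.trait_sizes[:2]) + self.trait_sizes[2] - self.n_antagonistic > self.n_qtl:
            raise ValueError("trait loci exceed the available QTL")
        if (self.n_qtl + self.n_markers) % self.n_chromosomes != 0:
            raise ValueError("loci must divide evenly across chromosomes")

    def heritability_of(self, trait_index: int) -> float:
        h2 = self.heritability
        return float(h2[trait_index]) if isinstance(h2, (tuple, list)) else float(h2)


@dataclass
class TraitEffects:
    """Environmental noise scale per trait, derived from heritability.

    Additive effects themselves live in the trait architecture; here we
    keep the per-trait environmental standard deviation calibrated so that
    genetic variance / total variance equals the configured heritability
    in the initial population.
    """

    sigma_env: dict[str, float]


@dataclass
class ScenarioResult:
    """Per-replication, per-generation records of one scenario run."""

    method: str
    metrics: pd.DataFrame  # replication, generation, method, trait, allele_freq, phenotype_mean
    relatedness: pd.DataFrame  # replication, generation, method, mean_g
    plans: list[list[CrossingPlan]] = field(default_factory=list)

    def final_allele_freq(self, trait_id: str) -> float:
        m = self.metrics
        last = m["generation"].max()
        sel = m[(m["generation"] == last) & (m["trait"] == trait_id)]
        return float(sel["allele_freq"].mean())

    def final_mean_relatedness(self) -> float:
        r = self.relatedness
        last = r["generation"].max()
        return float(r[r["generation"] == last]["mean_g"].mean())

    def summary(self) -> pd.DataFrame:
        """Per-generation, per-trait mean and sd over replications."""
        return (
            self.metrics.groupby(["method", "generation", "trait"])
            .agg(
                allele_freq_mean=("allele_freq", "mean"),
                allele_freq_sd=("allele_freq", "std"),
                phenotype_mean=("phenotype_mean", "mean"),
                phenotype_sd=("phenotype_mean", "std"),
            )
            .reset_index()
        )


def scenario_config(scenario: str, **overrides) -> SimConfig:
    """SimConfig preset for selection-intensity scenario A, B, or C."""
    try:
        pairs = SCENARIO_PAIRS[scenario.upper()]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario!r}; choose A, B, or C") from None
    return replace(SimConfig(pairs_per_generation=pairs), **overrides)


# ---------------------------------------------------------------------------
# Genome and population construction
# ---------------------------------------------------------------------------


def build_genetic_map(config: SimConfig) -> GeneticMap:
    """Interleaved QTL/marker map: blocks of (qtl, qtl, marker) per chromosome.

    QTL and markers are spread evenly over the chromosomes so that markers
    sit in linkage with trait loci; adjacent positions recombine at
    ``r_within`` and chromosome boundaries at exactly 0.5.
    """
    n_total = config.n_qtl + config.n_markers
    per_chrom = n_total // config.n_chromosomes
    if config.n_qtl == 2 * config.n_markers:
        block = (QTL, QTL, MARKER)
        classes = [block[i % 3] for i in range(n_total)]
    else:
        # generic layout: markers spread evenly among the QTL
        marker_at = set(
            np.floor((np.arange(config.n_markers) + 0.5) * n_total / config.n_markers)
            .astype(int)
            .tolist()
        )
        classes = [MARKER if i in marker_at else QTL for i in range(n_total)]
        if classes.count(MARKER) != config.n_markers:  # collision fallback
            classes = [QTL] * config.n_qtl + [MARKER] * config.n_markers
    chromosome = np.repeat(np.arange(config.n_chromosomes), per_chrom)
    r = np.full(n_total - 1, config.r_within)
    r[np.flatnonzero(np.diff(chromosome) != 0)] = 0.5
    qtl_counter = iter(range(1, config.n_qtl + 1))
    mk_counter = iter(range(1, config.n_markers + 1))
    locus_id = tuple(
        f"q{next(qtl_counter):03d}" if c == QTL else f"m{next(mk_counter):03d}" for c in classes
    )
    return GeneticMap(
        locus_id=locus_id, chromosome=chromosome, locus_class=tuple(classes), r_adjacent=r
    )


def build_architecture(config: SimConfig, rng: np.random.Generator, gmap: GeneticMap) -> TraitArchitecture:
    """Wire the three traits into the map's QTL.

    Trait 1 takes the first 40 QTL in map order and Trait 2 the next 10;
    Trait 3 combines ``n_antagonistic`` loci drawn from Trait 1's set
    (orientation flipped: desirable allele 0) with private loci from the
    remaining QTL (deterministic given the generator's seed).
    """
    qtl = gmap.qtl_indices
    n1, n2, n3 = config.trait_sizes
    t1 = qtl[:n1]
    t2 = qtl[n1 : n1 + n2]
    shared = np.sort(rng.choice(t1, size=config.n_antagonistic, replace=False))
    remainder = qtl[n1 + n2 :]
    n_private = n3 - config.n_antagonistic
    private = np.sort(rng.choice(remainder, size=n_private, replace=False))
    t3 = np.concatenate([shared, private])
    des3 = np.concatenate(
        [np.zeros(shared.size, dtype=np.int8), np.ones(private.size, dtype=np.int8)]
    )
    return TraitArchitecture(
        trait_ids=("trait1", "trait2", "trait3"),
        qtl_indices={"trait1": t1, "trait2": t2, "trait3": t3},
        desirable_allele={
            "trait1": np.ones(t1.size, dtype=np.int8),
            "trait2": np.ones(t2.size, dtype=np.int8),
            "trait3": des3,
        },
        effect_size={
            "trait1": np.ones(t1.size),
            "trait2": np.ones(t2.size),
            "trait3": np.ones(t3.size),
        },
    )


def generate_initial_population(
    config: SimConfig, rng: np.random.Generator
) -> tuple[HaplotypePopulation, TraitArchitecture]:
    """Initial panel: every allele copy an independent fair coin."""
    gmap = build_genetic_map(config)
    arch = build_architecture(config, rng, gmap)
    alleles = rng.integers(0, 2, size=(config.k0, gmap.n_loci, 2), dtype=np.int8)
    ids = tuple(f"g0_{i}" for i in range(config.k0))
    return HaplotypePopulation(alleles=alleles, individual_id=ids, map=gmap), arch


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def genetic_values(pop: HaplotypePopulation, arch: TraitArchitecture) -> np.ndarray:
    """Additive genetic value per individual and trait (K x M)."""
    out = np.empty((pop.n_individuals, arch.n_traits))
    for j, t in enumerate(arch.trait_ids):
        idx = arch.qtl_indices[t]
        des = arch.desirable_allele[t]
        dosage = (pop.alleles[:, idx, :] == des[None, :, None]).sum(axis=2)
        out[:, j] = dosage @ arch.effect_size[t]
    return out


def derive_effects(
    pop: HaplotypePopulation, arch: TraitArchitecture, config: SimConfig
) -> TraitEffects:
    """Calibrate environmental noise against the initial population.

    sigma_e is set per trait so that genetic variance over total variance
    equals the configured heritability in the population handed in (the
    generation-0 panel); it is then held fixed across generations
    (consistent growing environment).
    """
    gv = genetic_values(pop, arch)
    sigma: dict[str, float] = {}
    for j, t in enumerate(arch.trait_ids):
        h2 = config.heritability_of(j)
        var_g = float(np.var(gv[:, j]))
        sigma[t] = float(np.sqrt(var_g * (1.0 - h2) / h2)) if h2 < 1.0 else 0.0
    return TraitEffects(sigma_env=sigma)


def simulate_phenotypes(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    effects: TraitEffects,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotype = additive genetic value + Normal(0, sigma_e) noise (K x M)."""
    gv = genetic_values(pop, arch)
    for j, t in enumerate(arch.trait_ids):
        s = effects.sigma_env[t]
        if s > 0:
            gv[:, j] += rng.normal(0.0, s, size=gv.shape[0])
    return gv


# ---------------------------------------------------------------------------
# Meiosis and generation advance
# ---------------------------------------------------------------------------


def _gametes_from_parent(
    parent: np.ndarray, params: InheritanceParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n independent meiotic gametes from one phased parent (n x N)."""
    J = sample_inheritance(params, rng, size=n)
    cols = np.arange(parent.shape[0])
    return parent[cols[None, :], J]


def advance_generation(
    pop: HaplotypePopulation,
    plan: CrossingPlan,
    config: SimConfig,
    rng: np.random.Generator,
    generation: int = 1,
) -> HaplotypePopulation:
    """Cross every planned pair; each cross yields ``progeny_per_cross`` offspring.

    Each offspring receives one independent recombinant gamete from each
    parent under the Mendelian inheritance law over the full map.
    """
    if len(plan) == 0:
        raise ValueError("empty crossing plan")
    params = InheritanceParams.mendelian(pop.map.r_adjacent)
    n_prog = config.progeny_per_cross
    n_total = len(plan) * n_prog
    alleles = np.empty((n_total, pop.n_loci, 2), dtype=np.int8)
    for c, entry in enumerate(plan):
        sl = slice(c * n_prog, (c + 1) * n_prog)
        alleles[sl, :, 0] = _gametes_from_parent(pop.alleles[entry.parent1], params, n_prog, rng)
        alleles[sl, :, 1] = _gametes_from_parent(pop.alleles[entry.parent2], params, n_prog, rng)
    ids = tuple(f"g{generation}_{i}" for i in range(n_total))
    return HaplotypePopulation(alleles=alleles, individual_id=ids, map=pop.map)


# ---------------------------------------------------------------------------
# Scenario driver
# ---------------------------------------------------------------------------


def _allele_freqs(pop: HaplotypePopulation, arch: TraitArchitecture) -> np.ndarray:
    counts = trait_counts(pop, arch)
    n_loci = np.array([arch.n_loci(t) for t in arch.trait_ids])
    return counts.mean(axis=0) / (2.0 * n_loci)


def _standardize(columns: np.ndarray) -> np.ndarray:
    mu = columns.mean(axis=0)
    sd = columns.std(axis=0)
    sd[sd == 0.0] = 1.0
    return (columns - mu) / sd


def _select_plan(
    method: str,
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    phenotypes: np.ndarray,
    config: SimConfig,
    generation: int,
    base_freqs: np.ndarray | None = None,
) -> CrossingPlan:
    n_pairs = config.pairs_per_generation[generation]
    # relatedness stays on the founder scale: centre on generation-0 frequencies
    G = VanRadenG.from_population(pop, freqs=base_freqs)
    if method == "ecv":
        priority = config.trait_priority
        taus = tuple(config.tau_schedule[generation][: len(priority)])
        if len(priority) == 1:
            taus = (0.0,)
        sel = SelectionConfig(
            epsilon=config.epsilon,
            n_pairs=n_pairs,
            tolerances=taus,
            trait_priority=priority,
        )
        return select_pairs_lexicographic(pop, arch, G, sel, solver="fast")
    sel = SelectionConfig(epsilon=None, n_pairs=n_pairs, tolerances=(0.0,))
    trait_cols = [arch.trait_ids.index(t) for t in config.trait_priority]
    if method == "phenotypic":
        scores = _standardize(phenotypes[:, trait_cols])
        if len(trait_cols) == 1:
            scores = phenotypes[:, trait_cols]
        return select_pairs_by_score(
            scores, sel, individual_ids=pop.individual_id, G=G, method="phenotypic"
        )
    if method == "gebv":
        markers = pop.dosage(pop.map.marker_indices).astype(float)
        gebv = np.empty((pop.n_individuals, len(trait_cols)))
        for out_col, col in enumerate(trait_cols):
            h2 = config.heritability_of(col)
            model = fit_rrblup(markers, phenotypes[:, col], heritability_fallback=h2)
            gebv[:, out_col] = predict_gebv(model, markers)
        scores = _standardize(gebv) if len(trait_cols) > 1 else gebv
        return select_pairs_by_score(
            scores, sel, individual_ids=pop.individual_id, G=G, method="gebv"
        )
    raise ValueError(f"unknown selection method {method!r}")


def _rng_for(config: SimConfig, replication: int) -> np.random.Generator:
    seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(replication,))
    return np.random.Generator(np.random.PCG64(seq))


def run_scenario(
    method: str,
    config: SimConfig,
    replications: int | None = None,
    keep_plans: bool = False,
) -> ScenarioResult:
    """Run the full generational benchmark for one selection method.

    Loops ``replications`` independent runs (seeds derived from
    ``config.seed`` by replication index): generate the initial panel,
    then per generation simulate phenotypes, select a crossing block by
    ``method``, record desirable-allele frequencies, phenotype means and
    the mean relatedness of the selected mates, and advance.
    """
    reps = config.replications if replications is None else replications
    metric_rows = []
    g_rows = []
    all_plans: list[list[CrossingPlan]] = []
    for rep in range(reps):
        rng = _rng_for(config, rep)
        pop, arch = generate_initial_population(config, rng)
        effects = derive_effects(pop, arch, config)
        base_freqs = pop.dosage(pop.map.marker_indices).mean(axis=0) / 2.0
        plans: list[CrossingPlan] = []
        for gen in range(config.generations + 1):
            phen = simulate_phenotypes(pop, arch, effects, rng)
            freqs = _allele_freqs(pop, arch)
            for j, t in enumerate(arch.trait_ids):
                metric_rows.append(
                    {
                        "replication": rep,
                        "generation": gen,
                        "method": method,
                        "trait": t,
                        "allele_freq": freqs[j],
                        "phenotype_mean": float(phen[:, j].mean()),
                    }
                )
            if gen == config.generations:
                break
            plan = _select_plan(method, pop, arch, phen, config, gen, base_freqs=base_freqs)
            g_rows.append(
                {
                    "replication": rep,
                    "generation": gen,
                    "method": method,
                    "mean_g": plan.mean_g(),
                }
            )
            plans.append(plan)
            pop = advance_generation(pop, plan, config, rng, generation=gen + 1)
        if keep_plans:
            all_plans.append(plans)
    return ScenarioResult(
        method=method,
        metrics=pd.DataFrame(metric_rows),
        relatedness=pd.DataFrame(g_rows),
        plans=all_plans,
    )
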