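"""Genotypes, genetic maps, and trait architectures.

A breeding candidate is stored as a phased diploid genotype: an ``N x 2``
binary matrix whose columns are the two parental gametes, in *physical*
0/1 allele coding.  Which physical allele counts as *desirable* is a
per-trait orientation layer (:class:`TraitArchitecture`), so a single
physical allele can be desirable for one trait and undesirable for
another (antagonistic pleiotropy) without duplicating the genotypes.

Locus order is owned by the genetic map: adjacent-locus recombination
frequencies are only meaningful for a fixed total order, and a
chromosome boundary is encoded as a recombination frequency of exactly
0.5 (independent assortment) between the flanking loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "HaplotypePopulation",
    "TraitArchitecture",
    "TraitGenotypeView",
    "trait_view",
    "allele_count",
    "read_population",
    "write_population",
    "read_trait_architecture",
    "write_trait_architecture",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the TSV schemas."""


QTL = "qtl"
MARKER = "marker"


@dataclass(frozen=True)
class GeneticMap:
    """Ordered loci with chromosome assignment and adjacent recombination rates.

    Parameters
    ----------
    locus_id
        Unique identifiers, one per locus, in map order.
    chromosome
        Integer chromosome label per locus; loci of one chromosome must be
        contiguous in map order.
    locus_class
        ``"qtl"`` or ``"marker"`` per locus.
    r_adjacent
        Recombination frequency between consecutive loci, length ``N - 1``,
        each in ``[0, 0.5]``.  Entries spanning a chromosome boundary must be
        exactly 0.5.
    """

    locus_id: tuple[str, ...]
    chromosome: np.ndarray
    locus_class: tuple[str, ...]
    r_adjacent: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=np.int64))
        object.__setattr__(self, "r_adjacent", np.asarray(self.r_adjacent, dtype=float))
        n = len(self.locus_id)
        if self.chromosome.shape != (n,):
            raise FormatError("chromosome vector length does not match locus count")
        if len(self.locus_class) != n:
            raise FormatError("locus_class length does not match locus count")
        if self.r_adjacent.shape != (max(n - 1, 0),):
            raise FormatError("r_adjacent must have length N - 1")
        if n and (np.any(self.r_adjacent < 0.0) or np.any(self.r_adjacent > 0.5)):
            raise FormatError("recombination frequencies must lie in [0, 0.5]")
        if len(set(self.locus_id)) != n:
            raise FormatError("duplicate locus ids")
        for cls in self.locus_class:
            if cls not in (QTL, MARKER):
                raise FormatError(f"unknown locus class {cls!r}")
        boundary = self.chromosome[1:] != self.chromosome[:-1]
        if np.any(self.r_adjacent[boundary] != 0.5):
            raise FormatError("chromosome boundaries must carry r = 0.5")

    @property
    def n_loci(self) -> int:
        return len(self.locus_id)

    @property
    def locus_index(self) -> dict[str, int]:
        return {lid: i for i, lid in enumerate(self.locus_id)}

    def class_mask(self, cls: str) -> np.ndarray:
        return np.fromiter((c == cls for c in self.locus_class), dtype=bool, count=self.n_loci)

    @property
    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(self.class_mask(MARKER))

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.class_mask(QTL))


@dataclass
class HaplotypePopulation:
    """K phased diploid individuals over the loci of a genetic map.

    ``alleles`` has shape ``(K, N, 2)``; the two trailing columns are the two
    parental gametes, stored in physical 0/1 coding.
    """

    alleles: np.ndarray
    individual_id: tuple[str, ...]
    map: GeneticMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise FormatError("alleles must have shape (K, N, 2)")
        if self.alleles.shape[0] != len(self.individual_id):
            raise FormatError("individual_id length does not match allele tensor")
        if self.alleles.shape[1] != self.map.n_loci:
            raise FormatError("allele tensor does not match map locus count")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise FormatError("alleles must be 0/1")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def index_of(self, individual_id: str) -> int:
        try:
            return self.individual_id.index(individual_id)
        except ValueError:
            raise KeyError(f"unknown individual id {individual_id!r}") from None

    def dosage(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Physical allele-1 dosage matrix (K x N or K x len(loci)), entries 0/1/2."""
        d = self.alleles.sum(axis=2, dtype=np.int16)
        return d if loci is None else d[:, loci]


@dataclass
class TraitArchitecture:
    """Per-trait QTL membership, desirable-allele orientation, and effect sizes.

    For trait ``l`` and its ``i``-th QTL, ``desirable_allele[l][i]`` is the
    physical allele state (0 or 1) counted as desirable, and
    ``effect_size[l][i]`` is the phenotype change per desirable-allele copy.
    """

    trait_ids: tuple[str, ...]
    qtl_indices: dict[str, np.ndarray]
    desirable_allele: dict[str, np.ndarray]
    effect_size: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.trait_ids:
            idx = np.asarray(self.qtl_indices[t], dtype=np.int64)
            des = np.asarray(self.desirable_allele[t], dtype=np.int8)
            if idx.size == 0:
                raise FormatError(f"trait {t!r} has no loci")
            if des.shape != idx.shape:
                raise FormatError(f"trait {t!r}: orientation length mismatch")
            if not np.isin(des, (0, 1)).all():
                raise FormatError(f"trait {t!r}: desirable_allele must be 0/1")
            self.qtl_indices[t] = idx
            self.desirable_allele[t] = des
            if t in self.effect_size:
                eff = np.asarray(self.effect_size[t], dtype=float)
                if eff.shape != idx.shape:
                    raise FormatError(f"trait {t!r}: effect length mismatch")
                self.effect_size[t] = eff
            else:
                self.effect_size[t] = np.ones(idx.size)

    @property
    def n_traits(self) -> int:
        return len(self.trait_ids)

    def n_loci(self, trait_id: str) -> int:
        return int(self.qtl_indices[self._check(trait_id)].size)

    def _check(self, trait_id: str) -> str:
        if trait_id not in self.qtl_indices:
            raise KeyError(f"unknown trait id {trait_id!r}")
        return trait_id

    def validate_against_map(self, gmap: GeneticMap) -> None:
        qtl = set(gmap.qtl_indices.tolist())
        for t in self.trait_ids:
            bad = [i for i in self.qtl_indices[t].tolist() if i not in qtl]
            if bad:
                raise FormatError(f"trait {t!r} references non-QTL loci {bad}")


@dataclass(frozen=True)
class TraitGenotypeView:
    """The ``N_l x 2`` desirability matrix of one individual for one trait.

    ``entries[i, j] = 1`` iff the physical allele at the trait's ``i``-th
    locus on gamete ``j`` equals the desirable state for that trait.  Derived,
    never stored.
    """

    entries: np.ndarray
    trait_id: str = ""

    @property
    def n_loci(self) -> int:
        return self.entries.shape[0]


def trait_view(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    individual: int | str,
    trait_id: str,
) -> TraitGenotypeView:
    """Desirability matrix L^{k,l} for one individual and one trait.

    Pure function of the stored physical alleles and the trait orientation.
    """
    k = pop.index_of(individual) if isinstance(individual, str) else int(individual)
    if not 0 <= k < pop.n_individuals:
        raise KeyError(f"unknown individual index {individual!r}")
    arch._check(trait_id)
    idx = arch.qtl_indices[trait_id]
    des = arch.desirable_allele[trait_id]
    phys = pop.alleles[k, idx, :]
    entries = (phys == des[:, None]).astype(np.int8)
    return TraitGenotypeView(entries=entries, trait_id=trait_id)


def allele_count(view: TraitGenotypeView | np.ndarray) -> int:
    """Total desirable-allele count of a two-column view, in ``[0, 2 N_l]``."""
    entries = view.entries if isinstance(view, TraitGenotypeView) else np.asarray(view)
    return int(entries.sum())


def trait_counts(pop: HaplotypePopulation, arch: TraitArchitecture) -> np.ndarray:
    """Per-individual desirable-allele counts, shape (K, M), traits in order.

    Vectorized equivalent of ``allele_count(trait_view(pop, arch, k, t))``
    for all ``k`` and ``t``; the selection engines and metrics use this.
    """
    out = np.empty((pop.n_individuals, arch.n_traits), dtype=np.int64)
    for j, t in enumerate(arch.trait_ids):
        idx = arch.qtl_indices[t]
        des = arch.desirable_allele[t]
        hits = pop.alleles[:, idx, :] == des[None, :, None]
        out[:, j] = hits.sum(axis=(1, 2))
    return out


# ---------------------------------------------------------------------------
# TSV round-trip I/O
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | Path) -> GeneticMap:
    df = _read_tsv(path, ["locus_id", "chromosome", "locus_class", "r_to_next"])
    r = df["r_to_next"].to_numpy(dtype=float)
    if np.any(r < 0.0) or np.any(r > 0.5):
        bad = int(np.flatnonzero((r < 0.0) | (r > 0.5))[0]) + 2  # 1-based + header
        raise FormatError(f"{path}: line {bad}: r_to_next outside [0, 0.5]")
    return GeneticMap(
        locus_id=tuple(df["locus_id"].astype(str)),
        chromosome=df["chromosome"].to_numpy(dtype=np.int64),
        locus_class=tuple(df["locus_class"].astype(str)),
        r_adjacent=r[:-1] if len(df) else np.empty(0),
    )


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    r_to_next = np.append(gmap.r_adjacent, 0.5)  # genome-end sentinel, ignored on read
    pd.DataFrame(
        {
            "locus_id": gmap.locus_id,
            "chromosome": gmap.chromosome,
            "locus_class": gmap.locus_class,
            "r_to_next": r_to_next,
        }
    ).to_csv(path, sep="\t", index=False)


def read_population(haplotype_file: str | Path, map_file: str | Path) -> HaplotypePopulation:
    """Read a phased population; locus order is taken from the map file."""
    gmap = read_genetic_map(map_file)
    df = pd.read_csv(haplotype_file, sep="\t", dtype=str)
    expected = ["individual_id", "haplotype", *gmap.locus_id]
    if list(df.columns) != expected:
        raise FormatError(
            f"{haplotype_file}: columns must be individual_id, haplotype, then loci in map order"
        )
    cells = df[list(gmap.locus_id)].to_numpy()
    ok = np.isin(cells, ("0", "1"))
    if not ok.all():
        row = int(np.argwhere(~ok)[0, 0]) + 2
        raise FormatError(f"{haplotype_file}: line {row}: non-binary allele value")
    ids: list[str] = []
    rows_by_id: dict[str, dict[int, np.ndarray]] = {}
    for pos in range(len(df)):
        iid = str(df.iloc[pos]["individual_id"])
        hap = df.iloc[pos]["haplotype"]
        if hap not in ("1", "2"):
            raise FormatError(f"{haplotype_file}: line {pos + 2}: haplotype must be 1 or 2")
        if iid not in rows_by_id:
            rows_by_id[iid] = {}
            ids.append(iid)
        rows_by_id[iid][int(hap)] = cells[pos].astype(np.int8)
    alleles = np.empty((len(ids), gmap.n_loci, 2), dtype=np.int8)
    for k, iid in enumerate(ids):
        haps = rows_by_id[iid]
        if set(haps) != {1, 2}:
            raise FormatError(f"{haplotype_file}: individual {iid!r} must have haplotypes 1 and 2")
        alleles[k, :, 0] = haps[1]
        alleles[k, :, 1] = haps[2]
    return HaplotypePopulation(alleles=alleles, individual_id=tuple(ids), map=gmap)


def write_population(pop: HaplotypePopulation, haplotype_file: str | Path, map_file: str | Path) -> None:
    write_genetic_map(pop.map, map_file)
    records = []
    for k, iid in enumerate(pop.individual_id):
        for hap in (1, 2):
            records.append([iid, hap, *pop.alleles[k, :, hap - 1].tolist()])
    pd.DataFrame(records, columns=["individual_id", "haplotype", *pop.map.locus_id]).to_csv(
        haplotype_file, sep="\t", index=False
    )


def read_trait_architecture(path: str | Path, gmap: GeneticMap) -> TraitArchitecture:
    df = _read_tsv(path, ["trait_id", "locus_id", "desirable_allele", "effect_size"])
    lookup = gmap.locus_index
    trait_ids: list[str] = []
    qtl: dict[str, list[int]] = {}
    des: dict[str, list[int]] = {}
    eff: dict[str, list[float]] = {}
    for pos in range(len(df)):
        t = str(df.iloc[pos]["trait_id"])
        lid = str(df.iloc[pos]["locus_id"])
        if lid not in lookup:
            raise FormatError(f"{path}: line {pos + 2}: unknown locus id {lid!r}")
        if t not in qtl:
            trait_ids.append(t)
            qtl[t], des[t], eff[t] = [], [], []
        qtl[t].append(lookup[lid])
        des[t].append(int(df.iloc[pos]["desirable_allele"]))
        eff[t].append(float(df.iloc[pos]["effect_size"]))
    arch = TraitArchitecture(
        trait_ids=tuple(trait_ids),
        qtl_indices={t: np.array(v) for t, v in qtl.items()},
        desirable_allele={t: np.array(v) for t, v in des.items()},
        effect_size={t: np.array(v) for t, v in eff.items()},
    )
    arch.validate_against_map(gmap)
    return arch


def write_trait_architecture(arch: TraitArchitecture, gmap: GeneticMap, path: str | Path) -> None:
    rows = []
    for t in arch.trait_ids:
        for i, locus in enumerate(arch.qtl_indices[t]):
            rows.append(
                [t, gmap.locus_id[locus], int(arch.desirable_allele[t][i]), float(arch.effect_size[t][i])]
            )
    pd.DataFrame(rows, columns=["trait_id", "locus_id", "desirable_allele", "effect_size"]).to_csv(
        path, sep="\t", index=False
    )


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    if list(df.columns) != list(columns):
        raise FormatError(f"{path}: expected columns {list(columns)}, found {list(df.columns)}")
    return df
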