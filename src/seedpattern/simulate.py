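"""Forward simulation of F2, RIL, and 8-founder MAGIC populations.

Gametes are drawn under the Haldane map function (no interference):
adjacent markers d cM apart recombine with probability
``r = (1 - exp(-2 d / 100)) / 2`` and chromosomes assort independently.
Haplotypes store founder-origin labels, so founder blocks are contiguous
by construction and genotypes are looked up through the founder allele
matrix.  All randomness flows through an explicit ``numpy`` generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from seedpattern.model import MultiLocusGenotype, PhenotypeModel, phenotype_of

MAP_COLUMNS = ("marker", "chrom", "cM", "bp")


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a distance in cM under Haldane's map."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


class GeneticMap:
    """Ordered markers with genetic (cM) and physical (bp) positions.

    Rows are sorted by chromosome (order of first appearance) and cM.
    Within a chromosome both cM and bp must be nondecreasing and marker
    ids unique.
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(MAP_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"map table missing columns {sorted(missing)}")
        if len(table) == 0:
            raise ValueError("empty genetic map")
        chrom_order = {c: i for i, c in enumerate(dict.fromkeys(table["chrom"]))}
        table = (
            table.assign(_ord=table["chrom"].map(chrom_order))
            .sort_values(["_ord", "cM", "bp"], kind="stable")
            .drop(columns="_ord")
            .reset_index(drop=True)
        )
        if table["marker"].duplicated().any():
            dupes = table.loc[table["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker ids: {dupes[:5]}")
        for chrom, sub in table.groupby("chrom", sort=False):
            if (np.diff(sub["bp"].to_numpy()) < 0).any():
                raise ValueError(f"bp positions decrease within {chrom}")
        self.table = table
        self._index = {m: i for i, m in enumerate(table["marker"])}
        self._slices: dict[str, slice] = {}
        start = 0
        for chrom, sub in table.groupby("chrom", sort=False):
            self._slices[chrom] = slice(start, start + len(sub))
            start += len(sub)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._slices)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[chrom]

    def marker_index(self, marker: str) -> int:
        return self._index[marker]

    def recomb_fractions(self, chrom: str) -> np.ndarray:
        """Per-interval recombination fractions for one chromosome."""
        cm = self.table["cM"].to_numpy()[self._slices[chrom]]
        return np.asarray(haldane_r(np.diff(cm)))

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int,
        markers_per_chrom: int,
        cm_length: float = 100.0,
        bp_per_cm: int = 400_000,
        prefix: str = "Vu",
    ) -> "GeneticMap":
        """Evenly spaced synthetic map with ``Vu01``-style chromosome names."""
        rows = []
        for c in range(1, n_chromosomes + 1):
            chrom = f"{prefix}{c:02d}"
            cm = np.linspace(0.0, cm_length, markers_per_chrom)
            for j, pos in enumerate(cm):
                rows.append((f"m{c:02d}_{j:04d}", chrom, float(pos), int(round(pos * bp_per_cm)) + 1))
        return cls(pd.DataFrame(rows, columns=MAP_COLUMNS))

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class FounderSet:
    """Inbred founders: marker alleles plus symbolic pattern-locus alleles.

    ``alleles`` holds one integer allele code per founder per map marker.
    ``pattern_loci`` places each phenotype locus at a marker id;
    ``pattern_alleles`` gives the allele symbol each founder carries
    there (founders are fully homozygous).
    """

    names: list[str]
    genmap: GeneticMap
    alleles: np.ndarray  # (n_founders, n_markers) int8
    pattern_loci: dict[str, str] = field(default_factory=dict)
    pattern_alleles: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.names), self.genmap.n_markers):
            raise ValueError("allele matrix shape does not match founders x markers")
        for locus, marker in self.pattern_loci.items():
            self.genmap.marker_index(marker)  # raises KeyError if absent
        for locus, symbols in self.pattern_alleles.items():
            if len(symbols) != len(self.names):
                raise ValueError(f"pattern_alleles[{locus!r}] must give one allele per founder")
            # a locus segregating among founders must live on the map;
            # monomorphic loci may stay unplaced (constant background)
            if locus not in self.pattern_loci and len(set(symbols)) > 1:
                raise ValueError(f"polymorphic pattern locus {locus!r} must be placed on the map")

    @property
    def n_founders(self) -> int:
        return len(self.names)

    def genotype(self, founder: int) -> MultiLocusGenotype:
        """Pattern-locus genotype of one (homozygous) founder."""
        return MultiLocusGenotype(
            {locus: (sym[founder], sym[founder]) for locus, sym in self.pattern_alleles.items()}
        )


@dataclass
class Individual:
    """Two haplotypes per chromosome, stored as founder-origin labels."""

    haplotypes: dict[str, np.ndarray]  # chrom -> (2, m) int

    def __post_init__(self) -> None:
        for chrom, h in self.haplotypes.items():
            if h.ndim != 2 or h.shape[0] != 2:
                raise ValueError(f"haplotypes[{chrom!r}] must have shape (2, m)")


@dataclass(frozen=True)
class FunnelPedigree:
    """Founder order for one 8-way funnel: ((a,b),(c,d),(e,f),(g,h))."""

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(8)):
            raise ValueError("funnel must use each of the 8 founders exactly once")


def meiosis(
    parent: Individual, genmap: GeneticMap, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One recombinant gamete from an individual (Haldane, no interference)."""
    if genmap.n_markers == 0:
        raise ValueError("empty genetic map")
    gamete = {}
    for chrom in genmap.chromosomes:
        h = parent.haplotypes[chrom]
        r = genmap.recomb_fractions(chrom)
        m = h.shape[1]
        row = np.empty(m, dtype=np.int64)
        row[0] = rng.integers(2)
        if m > 1:
            switches = rng.random(m - 1) < r
            row[1:] = (row[0] + np.cumsum(switches)) % 2
        gamete[chrom] = h[row, np.arange(m)]
    return gamete


class Population:
    """A simulated population over a founder set.

    Per-chromosome origins have shape ``(n, 2, m)``: line, haplotype,
    marker.  Genotypes are derived by indexing the founder allele matrix.
    """

    def __init__(self, founders: FounderSet, origins: dict[str, np.ndarray]):
        self.founders = founders
        self.genmap = founders.genmap
        self.origins = origins
        sizes = {o.shape[0] for o in origins.values()}
        if len(sizes) != 1:
            raise ValueError("inconsistent population size across chromosomes")
        self.n = sizes.pop()

    def individual(self, i: int) -> Individual:
        return Individual({c: self.origins[c][i] for c in self.genmap.chromosomes})

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[Individual]:
        return (self.individual(i) for i in range(self.n))

    def origin_matrix(self) -> np.ndarray:
        """Founder origins as one ``(n, 2, n_markers)`` array in map order."""
        return np.concatenate([self.origins[c] for c in self.genmap.chromosomes], axis=2)

    def allele_matrix(self) -> np.ndarray:
        """Allele codes per line/haplotype/marker, ``(n, 2, n_markers)``."""
        return self.founders.alleles[self.origin_matrix(), np.arange(self.genmap.n_markers)]

    def dosage(self) -> np.ndarray:
        """Summed allele codes, ``(n, n_markers)``; 0/1/2 for biallelic markers."""
        alleles = self.allele_matrix()
        return alleles[:, 0, :].astype(np.int16) + alleles[:, 1, :]

    def heterozygosity(self) -> float:
        """Mean per-marker, per-line heterozygosity (by allele code)."""
        alleles = self.allele_matrix()
        return float(np.mean(alleles[:, 0, :] != alleles[:, 1, :]))

    def pattern_genotype(self, i: int) -> MultiLocusGenotype:
        pairs = {}
        for locus, symbols in self.founders.pattern_alleles.items():
            marker = self.founders.pattern_loci.get(locus)
            if marker is None:  # monomorphic background locus, unplaced
                pairs[locus] = (symbols[0], symbols[0])
                continue
            j = self.genmap.marker_index(marker)
            chrom = self.genmap.table.at[j, "chrom"]
            jj = j - self.genmap.chrom_slice(chrom).start
            o1, o2 = self.origins[chrom][i, :, jj]
            pairs[locus] = (symbols[o1], symbols[o2])
        return MultiLocusGenotype(pairs)


def _gametes_batch(
    haps: np.ndarray, r: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized meiosis: one gamete per line from ``(n, 2, m)`` haplotypes."""
    n, _, m = haps.shape
    rows = np.empty((n, m), dtype=np.int8)
    rows[:, 0] = rng.integers(2, size=n)
    if m > 1:
        switches = rng.random((n, m - 1)) < r
        rows[:, 1:] = (rows[:, [0]] + np.cumsum(switches, axis=1)) % 2
    return haps[np.arange(n)[:, None], rows, np.arange(m)[None, :]]


def _cross(pop_a: dict[str, np.ndarray], pop_b: dict[str, np.ndarray],
           genmap: GeneticMap, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Pairwise cross of two equally sized origin dicts (line i x line i)."""
    out = {}
    for chrom in genmap.chromosomes:
        r = genmap.recomb_fractions(chrom)
        g1 = _gametes_batch(pop_a[chrom], r, rng)
        g2 = _gametes_batch(pop_b[chrom], r, rng)
        out[chrom] = np.stack([g1, g2], axis=1)
    return out


def _self(pop: dict[str, np.ndarray], genmap: GeneticMap,
          rng: np.random.Generator) -> dict[str, np.ndarray]:
    return _cross(pop, pop, genmap, rng)


def _constant_origins(founders: FounderSet, idx_a: np.ndarray, idx_b: np.ndarray) -> dict[str, np.ndarray]:
    """Origin dict for n lines that are simple (idx_a, idx_b) hybrids."""
    out = {}
    for chrom in founders.genmap.chromosomes:
        m = founders.genmap.chrom_slice(chrom).stop - founders.genmap.chrom_slice(chrom).start
        h1 = np.repeat(idx_a[:, None], m, axis=1).astype(np.int8)
        h2 = np.repeat(idx_b[:, None], m, axis=1).astype(np.int8)
        out[chrom] = np.stack([h1, h2], axis=1)
    return out


def _check_parents(founders: FounderSet, parents: Sequence[int]) -> None:
    for p in parents:
        if not 0 <= p < founders.n_founders:
            raise ValueError(f"parent index {p} out of range")


def make_f2(
    founders: FounderSet,
    n: int,
    rng: np.random.Generator,
    parents: Sequence[int] = (0, 1),
) -> Population:
    """F2 population: self-progeny of the (parents[0] x parents[1]) F1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_parents(founders, parents)
    a = np.full(n, parents[0], dtype=np.int8)
    b = np.full(n, parents[1], dtype=np.int8)
    f1 = _constant_origins(founders, a, b)
    return Population(founders, _self(f1, founders.genmap, rng))


def make_ril(
    founders: FounderSet,
    n: int,
    k_selfing: int,
    rng: np.random.Generator,
    parents: Sequence[int] = (0, 1),
) -> Population:
    """RILs by single-seed descent: F1 then ``k_selfing`` selfing rounds.

    ``k_selfing`` generations of selfing from the F1 gives F(k+1) lines
    (k=7 -> F8), each advanced as one offspring per line per generation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k_selfing < 1:
        raise ValueError("k_selfing must be >= 1")
    _check_parents(founders, parents)
    a = np.full(n, parents[0], dtype=np.int8)
    b = np.full(n, parents[1], dtype=np.int8)
    pop = _constant_origins(founders, a, b)
    for _ in range(k_selfing):
        pop = _self(pop, founders.genmap, rng)
    return Population(founders, pop)


def make_magic(
    founders: FounderSet,
    n: int,
    rng: np.random.Generator,
    k_selfing: int = 7,
    pedigree: FunnelPedigree | None = None,
) -> Population:
    """8-founder MAGIC: 2-way, 4-way, 8-way funnel crosses, then selfing.

    Each line gets its own random funnel order unless a fixed
    :class:`FunnelPedigree` is supplied.
    """
    if founders.n_founders != 8:
        raise ValueError(f"MAGIC requires exactly 8 founders, got {founders.n_founders}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if pedigree is None:
        order = np.stack([rng.permutation(8) for _ in range(n)]).astype(np.int8)
    else:
        order = np.tile(np.asarray(pedigree.order, dtype=np.int8), (n, 1))
    genmap = founders.genmap
    # four 2-way crosses per line
    two_way = [
        _constant_origins(founders, order[:, 2 * i], order[:, 2 * i + 1]) for i in range(4)
    ]
    # two 4-way crosses
    four_way = [
        _cross(two_way[0], two_way[1], genmap, rng),
        _cross(two_way[2], two_way[3], genmap, rng),
    ]
    # one 8-way cross, then selfing by single-seed descent
    pop = _cross(four_way[0], four_way[1], genmap, rng)
    for _ in range(k_selfing):
        pop = _self(pop, genmap, rng)
    return Population(founders, pop)


def assign_phenotypes(population: Population, model: PhenotypeModel) -> list[str]:
    """Pattern class for every line, via the epistasis model.

    Propagates unresolved-dominance errors from heterozygous lines at
    unresolved allele pairs.
    """
    loci = population.founders.pattern_alleles
    if not loci:
        raise ValueError("founder set declares no pattern loci")
    missing = set(model.series) - set(loci)
    if missing:
        raise ValueError(f"pattern loci {sorted(missing)} not placed on the map")
    cache: dict[MultiLocusGenotype, str] = {}
    out = []
    for i in range(population.n):
        g = population.pattern_genotype(i)
        if g not in cache:
            cache[g] = phenotype_of(g, model)
        out.append(cache[g])
    return out


def population_to_tsv(population: Population, path, phenotypes: Sequence[str] | None = None) -> None:
    """Write one row per line with {AA,AB,BB} calls per marker.

    Call letters refer to the two lowest/highest allele codes present at
    each marker across the founders.
    """
    alleles = population.allele_matrix()
    markers = population.genmap.table["marker"].tolist()
    lo = population.founders.alleles.min(axis=0)
    hi = population.founders.alleles.max(axis=0)
    a1 = alleles[:, 0, :]
    a2 = alleles[:, 1, :]
    calls = np.where(
        a1 == a2, np.where(a1 == lo, "AA", "BB"), "AB"
    )
    df = pd.DataFrame(calls, columns=markers)
    df.insert(0, "line", [f"line{i:05d}" for i in range(population.n)])
    if phenotypes is not None:
        df.insert(1, "phenotype", list(phenotypes))
    df.to_csv(path, sep="\t", index=False)
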