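"""Seeded synthetic fixtures: founders, maps, populations, bulks, noise.

Everything every other module needs can be generated from a
:class:`FixtureSpec` plus a seed — no external data.  The default scale
(11 chromosomes, ~50 markers each, named ``Vu01``–``Vu11``) is a desk
stand-in for a dense SNP array; pattern loci default to the middles of
``Vu07`` (C), ``Vu09`` (W) and ``Vu10`` (H).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from seedpattern.bsa import CALLS, MarkerTable, bulk_call
from seedpattern.model import MultiLocusGenotype, PhenotypeModel, default_model
from seedpattern.simulate import FounderSet, GeneticMap, Population, assign_phenotypes

#: the eight MAGIC founders with their proposed C/W/H genotypes
TABLE1_FOUNDERS: dict[str, str] = {
    "CB27": "C=C2/C2 W=W0/W0 H=H0/H0",
    "IT00K-1263": "C=C2/C2 W=W1/W1 H=H1/H1",
    "IT82E-18": "C=C2/C2 W=W1/W1 H=H1/H1",
    "IT84S-2049": "C=C1/C1 W=W1/W1 H=H1/H1",
    "IT84S-2246": "C=C2/C2 W=W1/W1 H=H1/H1",
    "IT89KD-288": "C=C1/C1 W=W1/W1 H=H1/H1",
    "IT93K-503-1": "C=C1/C1 W=W1/W1 H=H1/H1",
    "SuVita 2": "C=C2/C2 W=W1/W1 H=H1/H1",
}

_PRESETS: dict[str, dict[str, str]] = {"table1_founders": TABLE1_FOUNDERS}


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic fixture set."""

    n_chromosomes: int = 11
    markers_per_chrom: int = 50
    cm_length: float = 100.0
    #: pattern locus -> chromosome label it sits on (middle marker);
    #: None = C/W/H on Vu07/Vu09/Vu10, or spread over the last
    #: chromosomes when the map is smaller
    pattern_placement: Mapping[str, str] | None = None
    polymorphic_fraction: float = 0.8
    genotyping_error_rate: float = 0.005
    confusion_rate: float = 0.02
    bulk_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.polymorphic_fraction, self.genotyping_error_rate, self.confusion_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be within [0, 1]")
        if self.markers_per_chrom < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one marker on at least one chromosome")
        chroms = [f"Vu{c:02d}" for c in range(1, self.n_chromosomes + 1)]
        if self.pattern_placement is None:
            if self.n_chromosomes >= 10:
                placement = {"C": "Vu07", "W": "Vu09", "H": "Vu10"}
            else:
                if self.n_chromosomes < 3:
                    raise ValueError(
                        "default placement needs at least 3 chromosomes; "
                        "pass pattern_placement explicitly"
                    )
                placement = dict(zip(("C", "W", "H"), chroms[-3:]))
            object.__setattr__(self, "pattern_placement", placement)
        bad = set(self.pattern_placement.values()) - set(chroms)
        if bad:
            raise ValueError(f"pattern loci placed on unknown chromosomes: {sorted(bad)}")


@dataclass
class ObservedPopulation:
    """What a genotyping run sees: a call table plus scored phenotypes."""

    table: MarkerTable
    phenotypes: pd.Series  # index = line sample names


def make_founders(
    spec: FixtureSpec,
    pattern_genotypes: Mapping[str, str | MultiLocusGenotype] | None = None,
    preset: str | None = None,
    model: PhenotypeModel | None = None,
) -> FounderSet:
    """Fully homozygous founders over a fresh uniform map.

    ``pattern_genotypes`` maps founder name to its pattern-locus genotype
    (string form like ``"C=C2/C2 W=W0/W0 H=H0/H0"``); the
    ``"table1_founders"`` preset supplies the eight MAGIC founders.
    SNP markers are polymorphic at ``spec.polymorphic_fraction``; all
    output is reproducible from (spec, seed).
    """
    if preset is not None:
        pattern_genotypes = {k: v for k, v in _PRESETS[preset].items()}
    if not pattern_genotypes:
        raise ValueError("supply pattern_genotypes or a preset name")
    model = model if model is not None else default_model()
    genotypes = {
        name: g if isinstance(g, MultiLocusGenotype) else MultiLocusGenotype.from_string(g)
        for name, g in pattern_genotypes.items()
    }
    for name, g in genotypes.items():
        g.validate(model.loci)
        if not g.is_homozygous():
            raise ValueError(f"founder {name!r} is not fully homozygous")

    rng = np.random.default_rng(spec.seed)
    genmap = GeneticMap.uniform(spec.n_chromosomes, spec.markers_per_chrom, spec.cm_length)
    names = list(genotypes)
    n_f, n_m = len(names), genmap.n_markers

    polymorphic = rng.random(n_m) < spec.polymorphic_fraction
    alleles = np.zeros((n_f, n_m), dtype=np.int8)
    if n_f == 2:
        alleles[1, polymorphic] = 1
    else:
        draw = rng.integers(0, 2, size=(n_f, n_m)).astype(np.int8)
        # force both alleles present where the marker is polymorphic
        draw[0, :] = 0
        draw[1, :] = 1
        alleles[:, polymorphic] = draw[:, polymorphic]

    model_loci = set(next(iter(genotypes.values())).pairs)
    pattern_loci: dict[str, str] = {}
    pattern_alleles: dict[str, list[str]] = {
        locus: [genotypes[name][locus][0] for name in names] for locus in model_loci
    }
    for locus, chrom in spec.pattern_placement.items():
        if locus not in model.series:
            raise ValueError(f"placement for unknown locus {locus!r}")
        if locus not in pattern_alleles:
            continue
        sl = genmap.chrom_slice(chrom)
        j = sl.start + (sl.stop - sl.start) // 2
        marker = genmap.table.at[j, "marker"]
        pattern_loci[locus] = marker
        symbols = pattern_alleles[locus]
        distinct = sorted(set(symbols))
        if len(distinct) == 2:
            # keep call orientation consistent with neighboring SNPs:
            # whatever allele founder 0 carries gets code 0
            code = {symbols[0]: 0, next(s for s in distinct if s != symbols[0]): 1}
            alleles[:, j] = [code[s] for s in symbols]
        else:
            order = list(model.loci[locus].alleles)
            alleles[:, j] = [order.index(s) for s in symbols]
    return FounderSet(
        names=names,
        genmap=genmap,
        alleles=alleles,
        pattern_loci=pattern_loci,
        pattern_alleles=pattern_alleles,
    )


def population_to_observed(
    population: Population,
    model: PhenotypeModel | None = None,
    include_founders: Sequence[int] = (),
) -> ObservedPopulation:
    """Call table ({hom_ref, het, hom_alt}) plus model phenotypes.

    Founder columns (role ``parent``) may be included for polymorphism
    filtering.  Markers where founders carry more than two distinct
    allele codes are dropped — the call alphabet is biallelic.
    """
    model = model if model is not None else default_model()
    founders = population.founders
    lo = founders.alleles.min(axis=0)
    hi = founders.alleles.max(axis=0)
    n_codes = np.array([len(set(founders.alleles[:, j])) for j in range(founders.alleles.shape[1])])
    keep = n_codes <= 2

    alleles = population.allele_matrix()
    a1, a2 = alleles[:, 0, :], alleles[:, 1, :]
    calls = np.where(a1 == a2, np.where(a1 == lo, "hom_ref", "hom_alt"), "het")

    line_names = [f"line{i:05d}" for i in range(population.n)]
    data = {}
    roles = {}
    for idx in include_founders:
        name = founders.names[idx]
        f_call = np.where(founders.alleles[idx] == lo, "hom_ref", "hom_alt")
        data[name] = f_call
        roles[name] = "parent"
    for i, name in enumerate(line_names):
        data[name] = calls[i]
        roles[name] = "line"
    meta = population.genmap.table[["marker", "chrom", "bp"]].copy()
    table = MarkerTable(meta.loc[keep].reset_index(drop=True),
                        pd.DataFrame(data).loc[keep].reset_index(drop=True), roles)
    phen = pd.Series(assign_phenotypes(population, model), index=line_names, name="phenotype")
    return ObservedPopulation(table=table, phenotypes=phen)


def corrupt(
    observed: ObservedPopulation,
    error_rate: float,
    confusion_rate: float,
    rng: np.random.Generator,
    confusable: tuple[str, str] = ("Eye1", "Watson"),
) -> ObservedPopulation:
    """Add genotyping error and phenotype-scoring confusion.

    Each line genotype call is flipped to one of the two other non-missing
    calls with ``error_rate``; each phenotype in ``confusable`` (the
    hard-to-distinguish pair) is swapped with ``confusion_rate``.  Parent
    columns are left clean.  Rates of 0 return an identical copy.
    """
    for rate in (error_rate, confusion_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must be within [0, 1]")
    calls = observed.table.calls.copy()
    line_cols = [s for s in calls.columns if observed.table.roles.get(s, "line") == "line"]
    sub = calls[line_cols].to_numpy(dtype=object)
    orig = sub.copy()
    flip = rng.random(sub.shape) < error_rate
    non_missing = [c for c in CALLS if c != "missing"]
    for cur in non_missing:
        sel = flip & (orig == cur)
        if not sel.any():
            continue
        others = [c for c in non_missing if c != cur]
        sub[sel] = rng.choice(others, size=int(sel.sum()))
    calls[line_cols] = sub

    phen = observed.phenotypes.copy()
    a, b = confusable
    swap_mask = phen.isin(confusable).to_numpy() & (rng.random(len(phen)) < confusion_rate)
    phen[swap_mask] = phen[swap_mask].map({a: b, b: a})

    table = MarkerTable(observed.table.meta.copy(), calls, observed.table.roles)
    return ObservedPopulation(table=table, phenotypes=phen)


def make_bulks(
    observed: ObservedPopulation,
    recessive_class: str,
    dominant_class: str,
    bulk_size: int,
    rng: np.random.Generator,
) -> MarkerTable:
    """Pool lines by phenotype class into two bulk samples.

    ``bulk_size`` lines are sampled per class (without replacement) and
    pooled with :func:`seedpattern.bsa.bulk_call` marker by marker.
    Parent columns from the observed table are carried through so the
    result can go straight into polymorphism filtering and the scan.
    """
    table = observed.table
    cols = {}
    roles = {}
    for s in table.samples:
        if table.roles.get(s) == "parent":
            cols[s] = table.calls[s].to_numpy()
            roles[s] = "parent"
    for cls_name, role in ((recessive_class, "recessive_bulk"), (dominant_class, "dominant_bulk")):
        members = observed.phenotypes.index[observed.phenotypes == cls_name].tolist()
        if len(members) < bulk_size:
            raise ValueError(
                f"only {len(members)} lines with phenotype {cls_name!r}; need {bulk_size}"
            )
        chosen = list(rng.choice(members, size=bulk_size, replace=False))
        member_calls = table.calls[chosen].to_numpy()
        # vectorized equivalent of bulk_call applied row-wise
        has_ref = (member_calls == "hom_ref").any(axis=1)
        has_alt = (member_calls == "hom_alt").any(axis=1)
        has_het = (member_calls == "het").any(axis=1)
        pooled = np.full(len(member_calls), "missing", dtype=object)
        pooled[has_ref & ~has_alt & ~has_het] = "hom_ref"
        pooled[has_alt & ~has_ref & ~has_het] = "hom_alt"
        pooled[has_het | (has_ref & has_alt)] = "het"
        name = f"bulk_{cls_name}"
        cols[name] = pooled
        roles[name] = role
    return MarkerTable(table.meta.copy(), pd.DataFrame(cols), roles)
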