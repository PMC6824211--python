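"""Analytic segregation-ratio prediction and chi-square goodness of fit.

Per-locus genotype distributions are derived for F2, RIL (k selfing
generations from the F1), and 8-founder MAGIC designs, multiplied across
unlinked loci, and collapsed through the phenotype model to an exact
rational class ratio.  Everything stays in :class:`fractions.Fraction`
until the chi-square step so small-integer ratios like 192:5:35:35:245
are exact, not floating-point approximations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Mapping, Sequence

import yaml
from scipy import stats

from seedpattern.model import (
    Locus,
    MultiLocusGenotype,
    PhenotypeModel,
    UnresolvedDominanceError,
    phenotype_of,
)

Pair = tuple[str, str]


@dataclass
class PopulationDesign:
    """Declarative description of a cross.

    kind
        ``"F2"``, ``"RIL"`` or ``"MAGIC"``.
    parents
        Fully homozygous founder genotypes: 2 for F2/RIL, 8 for MAGIC.
    selfing_generations
        RIL only: number of selfing generations after the F1 (default 7,
        i.e. F8 lines with residual heterozygosity (1/2)^7 per locus).
        ``None`` means the complete-homozygosity idealization used for
        printed integer ratios.
    founder_weights
        MAGIC only: per-founder transmission probability (default 1/8
        each, the idealized funnel).
    """

    kind: str
    parents: Sequence[MultiLocusGenotype]
    selfing_generations: int | None = 7
    founder_weights: Sequence[Fraction] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("F2", "RIL", "MAGIC"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        expected = 8 if self.kind == "MAGIC" else 2
        if len(self.parents) != expected:
            raise ValueError(f"{self.kind} design needs {expected} parents, got {len(self.parents)}")
        for i, p in enumerate(self.parents):
            if not p.is_homozygous():
                raise ValueError(f"parent {i} is heterozygous; designs require inbred parents")
        if self.founder_weights is None:
            n = len(self.parents)
            self.founder_weights = [Fraction(1, n)] * n
        else:
            self.founder_weights = [Fraction(w) for w in self.founder_weights]
            if sum(self.founder_weights) != 1:
                raise ValueError("founder_weights must sum to 1")
            if len(self.founder_weights) != len(self.parents):
                raise ValueError("one founder weight per parent required")


@dataclass(frozen=True)
class RatioPrediction:
    """Expected phenotype-class proportions with an exact integer form."""

    classes: tuple[str, ...]
    proportions: tuple[Fraction, ...]
    integer_ratio: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be nonnegative")
        if abs(float(sum(self.proportions)) - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")

    @classmethod
    def from_proportions(
        cls, classes: Sequence[str], proportions: Sequence[Fraction]
    ) -> "RatioPrediction":
        return cls(tuple(classes), tuple(proportions), _smallest_integer_ratio(proportions))

    @classmethod
    def from_ratio(cls, classes: Sequence[str], ratio: Sequence[int]) -> "RatioPrediction":
        """Build a prediction directly from an integer ratio like ``3:1``."""
        total = sum(ratio)
        props = [Fraction(r, total) for r in ratio]
        return cls.from_proportions(classes, props)

    def as_dict(self) -> dict[str, Fraction]:
        return dict(zip(self.classes, self.proportions))


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-square goodness-of-fit result."""

    statistic: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]


def _smallest_integer_ratio(proportions: Sequence[Fraction]) -> tuple[int, ...]:
    denom = math.lcm(*(p.denominator for p in proportions))
    ints = [int(p * denom) for p in proportions]
    g = math.gcd(*ints)
    return tuple(i // g for i in ints) if g else tuple(ints)


def per_locus_genotype_probs(design: PopulationDesign, locus: Locus | str) -> dict[Pair, Fraction]:
    """Distribution over unordered genotype pairs at one locus.

    F2 segregates 1/4 : 1/2 : 1/4; a RIL after k selfing generations
    keeps heterozygote mass (1/2)^k with the remainder split equally
    between the parental homozygotes; MAGIC assigns each founder's
    homozygote its transmission weight, aggregated over founders sharing
    an allele.
    """
    name = locus.name if isinstance(locus, Locus) else locus
    parental = []
    for p in design.parents:
        a, b = p[name]
        if a != b:
            raise ValueError(f"parent heterozygous at locus {name!r}")
        parental.append(a)

    if design.kind == "MAGIC":
        dist: dict[Pair, Fraction] = {}
        for allele, w in zip(parental, design.founder_weights):
            pair = (allele, allele)
            dist[pair] = dist.get(pair, Fraction(0)) + w
        return dist

    a, b = parental
    if a == b:
        return {(a, a): Fraction(1)}
    het = tuple(sorted((a, b)))
    if design.kind == "F2":
        return {(a, a): Fraction(1, 4), het: Fraction(1, 2), (b, b): Fraction(1, 4)}
    # RIL: selfing from the F1 halves heterozygosity each generation
    k = design.selfing_generations
    h = Fraction(0) if k is None else Fraction(1, 2) ** k
    hom = (1 - h) / 2
    dist = {(a, a): hom, (b, b): hom}
    if h:
        dist[het] = h
    return dist


def joint_genotype_probs(
    design: PopulationDesign, loci: Mapping[str, Locus]
) -> dict[MultiLocusGenotype, Fraction]:
    """Product distribution over multi-locus genotypes for unlinked loci.

    Raises if two loci share a chromosome — linkage has no closed form
    here; use the forward simulator for linked designs.
    """
    seen: dict[str, str] = {}
    for name, locus in loci.items():
        if locus.chromosome in seen.values():
            other = next(k for k, v in seen.items() if v == locus.chromosome)
            raise ValueError(
                f"loci {other!r} and {name!r} are both on {locus.chromosome}; "
                "analytic ratios assume unlinked loci — use the cross simulator"
            )
        seen[name] = locus.chromosome

    names = list(loci)
    per_locus = [per_locus_genotype_probs(design, loci[n]) for n in names]
    joint: dict[MultiLocusGenotype, Fraction] = {}
    for combo in product(*(d.items() for d in per_locus)):
        genotype = MultiLocusGenotype({n: pair for n, (pair, _) in zip(names, combo)})
        prob = math.prod((p for _, p in combo), start=Fraction(1))
        joint[genotype] = joint.get(genotype, Fraction(0)) + prob
    return joint


def expected_phenotype_ratio(design: PopulationDesign, model: PhenotypeModel) -> RatioPrediction:
    """Expected class proportions for a design under a phenotype model.

    Classes with zero probability are dropped; the remaining classes keep
    the model's declared order.  Any reachable genotype that hits an
    unresolved dominance pair is an error (never a silent guess).
    """
    joint = joint_genotype_probs(design, model.loci)
    totals: dict[str, Fraction] = {c: Fraction(0) for c in model.classes}
    for genotype, prob in joint.items():
        if prob == 0:
            continue
        try:
            cls = phenotype_of(genotype, model)
        except UnresolvedDominanceError as err:
            raise UnresolvedDominanceError(
                f"{err} (genotype {genotype!r} reachable with probability {prob})"
            ) from err
        totals[cls] += prob
    classes = [c for c in model.classes if totals[c] > 0]
    return RatioPrediction.from_proportions(classes, [totals[c] for c in classes])


def chi_square_gof(
    observed: Mapping[str, float] | Sequence[float], prediction: RatioPrediction
) -> GofResult:
    """Pearson chi-square of observed class counts against a prediction.

    Expected counts are the prediction's proportions scaled to the
    *observed* total (lines scored in other classes are simply absent
    from the test).  No continuity correction.  df = number of classes
    with nonzero expectation minus 1.
    """
    if isinstance(observed, Mapping):
        extra = {k for k, v in observed.items() if k not in prediction.classes and v > 0}
        if extra:
            raise ValueError(f"nonzero observed counts for classes with zero expectation: {sorted(extra)}")
        counts = [float(observed.get(c, 0.0)) for c in prediction.classes]
    else:
        if len(observed) != len(prediction.classes):
            raise ValueError("observed counts do not align with prediction classes")
        counts = [float(v) for v in observed]
    if any(c < 0 for c in counts):
        raise ValueError("observed counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("no observations")
    expected = [float(p) * total for p in prediction.proportions]
    statistic = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    df = sum(1 for e in expected if e > 0) - 1
    p_value = float(stats.chi2.sf(statistic, df))
    return GofResult(
        statistic=statistic,
        df=df,
        p_value=p_value,
        observed=dict(zip(prediction.classes, counts)),
        expected=dict(zip(prediction.classes, expected)),
    )


# -- design (de)serialization ------------------------------------------


def design_from_dict(data: Mapping) -> PopulationDesign:
    parents = [MultiLocusGenotype.from_string(p) for p in data["parents"]]
    return PopulationDesign(
        kind=data["kind"],
        parents=parents,
        selfing_generations=data.get("selfing_generations", 7),
        founder_weights=data.get("founder_weights"),
    )


def design_from_yaml(path) -> PopulationDesign:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))
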