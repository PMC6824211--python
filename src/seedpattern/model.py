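"""Loci, allelic series, and the epistatic genotype->phenotype map.

The default model covers three unlinked loci:

* ``C`` — a "constriction" factor with a three-allele series
  (``C2 > C0``, ``C2 > C1``; ``C1`` vs ``C0`` unresolved),
* ``W`` and ``H`` — two "expansion" factors, each biallelic with the
  ``1`` allele dominant.

An individual expressing ``C0`` shows no pigment pattern and one
expressing ``C1`` shows the Eye 1 pattern, in both cases regardless of
the ``W``/``H`` genotype; only with ``C2`` expressed do the expansion
loci become visible, yielding Eye 2, Holstein, Watson, or Full Coat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

#: Canonical pattern classes, always present in a model (extensible).
PATTERN_CLASSES: tuple[str, ...] = (
    "NoColor",
    "Eye1",
    "Eye2",
    "Holstein",
    "Watson",
    "FullCoat",
)

#: Sentinel for a trait score that must be treated as missing data.
MISSING = math.nan


class UnresolvedDominanceError(ValueError):
    """Raised for a heterozygote whose allele pair has no dominance order."""


@dataclass(frozen=True)
class Locus:
    """A named locus with an ordered allele list.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"C"``.
    chromosome
        Chromosome label, e.g. ``"Vu07"``.
    alleles
        Ordered allele symbols; at least two, unique.
    """

    name: str
    chromosome: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) < 2:
            raise ValueError(f"locus {self.name!r} needs at least 2 alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"duplicate allele symbols in locus {self.name!r}")


@dataclass(frozen=True)
class AllelicSeries:
    """Partial dominance order over the alleles of one locus.

    ``dominance`` lists (dominant, recessive) pairs; the relation used for
    expression is its transitive closure.  ``unresolved_pairs`` are
    heterozygote combinations whose order is genuinely unknown — asking for
    their expressed allele raises :class:`UnresolvedDominanceError` rather
    than silently picking one.
    """

    locus: Locus
    dominance: tuple[tuple[str, str], ...] = ()
    unresolved_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        mentioned = {a for pair in self.dominance for a in pair}
        mentioned |= {a for pair in self.unresolved_pairs for a in pair}
        unknown = mentioned - set(self.locus.alleles)
        if unknown:
            raise ValueError(f"alleles {sorted(unknown)} not in locus {self.locus.name!r}")
        missing = set(self.locus.alleles) - mentioned
        if missing:
            raise ValueError(
                f"alleles {sorted(missing)} of locus {self.locus.name!r} "
                "appear in neither dominance nor unresolved_pairs"
            )
        closure = self._closure()
        for a in self.locus.alleles:
            if (a, a) in closure:
                raise ValueError(f"dominance relation of locus {self.locus.name!r} is cyclic")

    def _closure(self) -> frozenset[tuple[str, str]]:
        rel = set(self.dominance)
        changed = True
        while changed:
            changed = False
            for a, b in list(rel):
                for c, d in list(rel):
                    if b == c and (a, d) not in rel:
                        rel.add((a, d))
                        changed = True
        return frozenset(rel)

    def dominates(self, a: str, b: str) -> bool:
        return (a, b) in self._closure()


def expressed_allele(pair: Sequence[str], series: AllelicSeries) -> str:
    """Return the allele a genotype pair expresses under a dominance series.

    Homozygotes express their allele; heterozygotes express the dominant
    one.  A heterozygote with no resolved order raises
    :class:`UnresolvedDominanceError`.
    """
    a, b = pair
    alleles = set(series.locus.alleles)
    if a not in alleles or b not in alleles:
        raise ValueError(f"pair {pair!r} not in locus {series.locus.name!r} alleles")
    if a == b:
        return a
    if series.dominates(a, b):
        return a
    if series.dominates(b, a):
        return b
    raise UnresolvedDominanceError(
        f"unresolved dominance between {a!r} and {b!r} at locus {series.locus.name!r}"
    )


class MultiLocusGenotype:
    """Unordered allele pair per locus, keyed by locus name.

    Pairs are stored sorted so reciprocal genotypes compare equal (no
    parent-of-origin effect).
    """

    __slots__ = ("pairs",)

    def __init__(self, pairs: Mapping[str, Sequence[str]]):
        self.pairs: dict[str, tuple[str, str]] = {
            name: tuple(sorted(pair)) for name, pair in pairs.items()  # type: ignore[misc]
        }
        for name, pair in self.pairs.items():
            if len(pair) != 2:
                raise ValueError(f"locus {name!r}: genotype pair must have 2 alleles")

    @classmethod
    def from_string(cls, text: str) -> "MultiLocusGenotype":
        """Parse ``"C=C2/C2 W=W0/W0 H=H0/H0"`` into a genotype."""
        pairs = {}
        for token in text.split():
            name, _, alleles = token.partition("=")
            pairs[name] = tuple(alleles.split("/"))
        return cls(pairs)

    def validate(self, loci: Mapping[str, Locus]) -> None:
        for name, pair in self.pairs.items():
            locus = loci.get(name)
            if locus is None:
                raise ValueError(f"unknown locus {name!r}")
            for allele in pair:
                if allele not in locus.alleles:
                    raise ValueError(f"allele {allele!r} not in locus {name!r}")

    def is_homozygous(self) -> bool:
        return all(a == b for a, b in self.pairs.values())

    def __getitem__(self, locus_name: str) -> tuple[str, str]:
        return self.pairs[locus_name]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MultiLocusGenotype) and self.pairs == other.pairs

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.pairs.items())))

    def __repr__(self) -> str:
        body = " ".join(f"{k}={a}/{b}" for k, (a, b) in sorted(self.pairs.items()))
        return f"MultiLocusGenotype({body})"


@dataclass(frozen=True)
class Rule:
    """One epistasis rule: expressed-allele conditions -> pattern class.

    ``when`` maps locus name to the set of expressed alleles that satisfy
    the rule; loci absent from ``when`` match anything.
    """

    when: Mapping[str, frozenset[str]]
    pattern: str

    def matches(self, expressed: Mapping[str, str]) -> bool:
        return all(expressed[locus] in allowed for locus, allowed in self.when.items())


@dataclass
class PhenotypeModel:
    """Allelic series per locus plus ordered first-match epistasis rules."""

    series: dict[str, AllelicSeries]
    rules: list[Rule]
    classes: tuple[str, ...] = PATTERN_CLASSES
    #: classes that epistatically mask the others (scored missing in strict mode)
    masking_classes: tuple[str, ...] = ("Eye1",)

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("pattern class names must be unique")
        absent = set(PATTERN_CLASSES) - set(self.classes)
        if absent:
            raise ValueError(f"canonical classes missing from model: {sorted(absent)}")
        for rule in self.rules:
            if rule.pattern not in self.classes:
                raise ValueError(f"rule targets unknown class {rule.pattern!r}")

    @property
    def loci(self) -> dict[str, Locus]:
        return {name: s.locus for name, s in self.series.items()}

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "masking_classes": list(self.masking_classes),
            "loci": {
                name: {
                    "chromosome": s.locus.chromosome,
                    "alleles": list(s.locus.alleles),
                    "dominance": [list(p) for p in s.dominance],
                    "unresolved_pairs": [list(p) for p in s.unresolved_pairs],
                }
                for name, s in self.series.items()
            },
            "rules": [
                {
                    "when": {k: sorted(v) for k, v in rule.when.items()},
                    "pattern": rule.pattern,
                }
                for rule in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PhenotypeModel":
        series = {}
        for name, spec in data["loci"].items():
            locus = Locus(name, spec["chromosome"], tuple(spec["alleles"]))
            series[name] = AllelicSeries(
                locus,
                tuple(tuple(p) for p in spec.get("dominance", ())),
                tuple(tuple(p) for p in spec.get("unresolved_pairs", ())),
            )
        rules = [
            Rule({k: frozenset(v) for k, v in r["when"].items()}, r["pattern"])
            for r in data["rules"]
        ]
        return cls(
            series=series,
            rules=rules,
            classes=tuple(data.get("classes", PATTERN_CLASSES)),
            masking_classes=tuple(data.get("masking_classes", ("Eye1",))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhenotypeModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_model() -> PhenotypeModel:
    """Load the bundled three-locus C/W/H model (``cwh_default.yaml``)."""
    ref = resources.files("seedpattern") / "data" / "cwh_default.yaml"
    with ref.open() as fh:
        return PhenotypeModel.from_dict(yaml.safe_load(fh))


def phenotype_of(genotype: MultiLocusGenotype, model: PhenotypeModel) -> str:
    """Map a multi-locus genotype to its pattern class.

    Expressed alleles are computed per locus under the model's allelic
    series, then the first matching epistasis rule wins.  Heterozygotes at
    an unresolved allele pair propagate :class:`UnresolvedDominanceError`.
    """
    missing = set(model.series) - set(genotype.pairs)
    if missing:
        raise ValueError(f"genotype does not cover loci {sorted(missing)}")
    genotype.validate(model.loci)
    expressed = {
        name: expressed_allele(genotype[name], series)
        for name, series in model.series.items()
    }
    for rule in model.rules:
        if rule.matches(expressed):
            return rule.pattern
    raise ValueError(f"no rule matches expressed alleles {expressed}")


def encode_traits(
    pattern: str,
    trait_list: Iterable[str],
    mode: str = "strict",
    model: PhenotypeModel | None = None,
) -> list[float]:
    """Encode one line's pattern class as a presence/absence trait vector.

    Each trait in ``trait_list`` scores 1.0 when expressed and 0.0
    otherwise, except for lines whose class epistatically masks the other
    patterns (Eye 1 by default): in ``strict`` mode those lines score
    missing (NaN) for every other trait, to keep masked lines out of the
    other traits' mapping; in ``magic`` mode they score 0.0 instead, for
    pipelines that cannot tolerate that much missing data.
    """
    if mode not in ("strict", "magic"):
        raise ValueError(f"unknown mode {mode!r}")
    model = model if model is not None else default_model()
    if pattern not in model.classes:
        raise ValueError(f"unknown pattern class {pattern!r}")
    traits = list(trait_list)
    out = []
    for trait in traits:
        if trait == pattern:
            out.append(1.0)
        elif pattern in model.masking_classes and mode == "strict":
            out.append(MISSING)
        else:
            out.append(0.0)
    return out
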