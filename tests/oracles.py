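"""Independent brute-force oracles used to cross-check the analytic code.

These deliberately avoid the package's own probability machinery: the
selfing oracle iterates a 3-state Markov chain, and the ratio oracle
enumerates every founder/gamete assignment combination and tabulates
phenotypes by counting.
"""

from fractions import Fraction
from itertools import product

import numpy as np

from seedpattern.model import MultiLocusGenotype, phenotype_of


def selfing_genotype_probs(k: int) -> dict[str, Fraction]:
    """Genotype distribution after k selfing generations from an F1 (Aa).

    Transition-matrix oracle over states (AA, Aa, aa): selfing sends
    Aa -> 1/4 AA + 1/2 Aa + 1/4 aa and fixes homozygotes.
    """
    state = {"AA": Fraction(0), "Aa": Fraction(1), "aa": Fraction(0)}
    for _ in range(k):
        het = state["Aa"]
        state = {
            "AA": state["AA"] + het / 4,
            "Aa": het / 2,
            "aa": state["aa"] + het / 4,
        }
    return state


def enumerate_ratio(design, model) -> dict[str, Fraction]:
    """Expected class proportions by exhaustive enumeration.

    MAGIC: every assignment of one founder per locus (8^L combos).
    F2: every gamete pair per locus (4^L combos).
    RIL: per-locus outcomes from the selfing Markov oracle, enumerated
    across loci (ideal RIL when selfing_generations is None).
    """
    loci = list(model.series)
    per_locus: list[list[tuple[tuple[str, str], Fraction]]] = []
    for locus in loci:
        alleles = [p[locus][0] for p in design.parents]
        outcomes: dict[tuple[str, str], Fraction] = {}
        if design.kind == "MAGIC":
            for allele, w in zip(alleles, design.founder_weights):
                pair = (allele, allele)
                outcomes[pair] = outcomes.get(pair, Fraction(0)) + w
        elif design.kind == "F2":
            a, b = alleles
            for g1, g2 in product((a, b), repeat=2):
                pair = tuple(sorted((g1, g2)))
                outcomes[pair] = outcomes.get(pair, Fraction(0)) + Fraction(1, 4)
        else:  # RIL
            a, b = alleles
            if a == b:
                outcomes[(a, a)] = Fraction(1)
            else:
                k = design.selfing_generations
                if k is None:
                    outcomes[(a, a)] = Fraction(1, 2)
                    outcomes[(b, b)] = Fraction(1, 2)
                else:
                    probs = selfing_genotype_probs(k)
                    outcomes[(a, a)] = probs["AA"]
                    outcomes[tuple(sorted((a, b)))] = probs["Aa"]
                    outcomes[(b, b)] = probs["aa"]
        per_locus.append(list(outcomes.items()))

    totals: dict[str, Fraction] = {}
    for combo in product(*per_locus):
        genotype = MultiLocusGenotype({n: pair for n, (pair, _) in zip(loci, combo)})
        prob = Fraction(1)
        for _, p in combo:
            prob *= p
        cls = phenotype_of(genotype, model)
        totals[cls] = totals.get(cls, Fraction(0)) + prob
    return totals


def pearson_bruteforce(x, y) -> float:
    """Textbook covariance formula, no library correlation call."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
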