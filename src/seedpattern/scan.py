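"""Simplified single-marker association scan with permutation thresholds.

This is deliberately NOT a reimplementation of multiparent mixed-model or
hidden-Markov interval mapping: each marker is tested by ordinary
regression of the (binary) trait on genotype dosage {0, 1, 2}, and the
genome-wide significance threshold is the alpha-quantile of the minimum
p-value over seeded permutations of the trait labels (permuted jointly
across markers, preserving LD).  Sufficient for validating synthetic
populations with a known causal locus; labeled simplified on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from seedpattern.bsa import MarkerTable

_DOSAGE = {"hom_ref": 0.0, "het": 1.0, "hom_alt": 2.0, "missing": np.nan}


@dataclass
class ScanResult:
    """Per-marker statistics plus the permutation threshold."""

    table: pd.DataFrame  # marker, chrom, bp, slope, r, p, neg_log10_p, monomorphic
    threshold: float
    alpha: float
    n_permutations: int

    @property
    def significant(self) -> list[str]:
        hit = self.table["p"] <= self.threshold
        return self.table.loc[hit, "marker"].tolist()

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# permutation_threshold\t{self.threshold:.6g}\t"
                     f"alpha\t{self.alpha}\tn_permutations\t{self.n_permutations}\n")
            self.table.to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class CodedVectors:
    """±1 phenotype codes with +1/0/−1 genotype codes, listwise complete."""

    phenotype: tuple[int, ...]
    genotype: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.phenotype) != len(self.genotype):
            raise ValueError("phenotype and genotype code vectors differ in length")
        if not set(self.phenotype) <= {1, -1}:
            raise ValueError("phenotype codes must be +1/-1")
        if not set(self.genotype) <= {1, 0, -1}:
            raise ValueError("genotype codes must be +1/0/-1")


def dosage_matrix(table: MarkerTable, samples: list[str]) -> np.ndarray:
    """(n_samples, n_markers) dosage of the alt allele; NaN for missing."""
    calls = table.calls[samples].to_numpy()
    out = np.empty(calls.shape, dtype=float)
    for call, dose in _DOSAGE.items():
        out[calls == call] = dose
    return out.T


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from correlation r with df = n - 2 (t distribution)."""
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p[~np.isfinite(t)] = np.where(np.abs(r[~np.isfinite(t)]) >= 1.0, 0.0, 1.0)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _masked_corr(X: np.ndarray, Y: np.ndarray):
    """Pairwise-complete correlation of each column of X with each column of Y.

    X may contain NaN (missing genotypes); Y must be complete.  Returns
    (r, slope, n_obs) with shapes (m, P), (m, P), (m,).
    """
    mask = ~np.isnan(X)
    Xz = np.where(mask, X, 0.0)
    n = mask.sum(axis=0).astype(float)  # (m,)
    n_ = n[:, None]
    sx = Xz.sum(axis=0)[:, None]  # (m, 1)
    sxx = (Xz**2).sum(axis=0)[:, None]
    sy = mask.T @ Y  # (m, P)
    syy = mask.T @ (Y**2)
    sxy = Xz.T @ Y
    cov = n_ * sxy - sx * sy
    varx = n_ * sxx - sx**2
    vary = n_ * syy - sy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(varx * vary)
        slope = cov / varx
    r[~np.isfinite(r)] = 0.0
    slope[~np.isfinite(slope)] = 0.0
    monomorphic = varx[:, 0] <= 0
    return r, slope, n, monomorphic


def single_marker_scan(
    trait: pd.Series,
    genotypes: MarkerTable,
    rng: np.random.Generator,
    n_permutations: int = 1000,
    alpha: float = 0.05,
) -> ScanResult:
    """Scan one trait against every marker, with a permutation threshold.

    ``trait`` is a presence/absence (or any numeric) vector indexed by
    sample name; NaN entries (masked lines) are dropped listwise.  Only
    samples present both in the trait and in the genotype table are used.
    Monomorphic markers get p = 1 and a ``monomorphic`` flag.
    """
    shared = [s for s in genotypes.samples if s in trait.index]
    if not shared:
        raise ValueError("no samples shared between trait and genotype table")
    y = trait.loc[shared].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    used = [s for s, k in zip(shared, keep) if k]
    if len(y) < 3:
        raise ValueError("fewer than 3 lines with non-missing trait values")
    if np.ptp(y) == 0:
        raise ValueError("trait has zero variance after listwise deletion")

    X = dosage_matrix(genotypes, used)  # (n, m)
    r, slope, n_obs, monomorphic = _masked_corr(X, y[:, None])
    p = _pearson_p(r[:, 0], n_obs)
    p[monomorphic] = 1.0

    # permutations: one shared label permutation per replicate
    perms = np.stack([rng.permutation(y) for _ in range(n_permutations)], axis=1)
    r_perm, _, n_perm, mono = _masked_corr(X, perms)
    p_perm = _pearson_p(r_perm, n_perm[:, None])
    p_perm[mono, :] = 1.0
    min_p = p_perm.min(axis=0)
    threshold = float(np.quantile(min_p, alpha))

    table = pd.DataFrame(
        {
            "marker": genotypes.meta["marker"],
            "chrom": genotypes.meta["chrom"],
            "bp": genotypes.meta["bp"],
            "slope": slope[:, 0],
            "r": r[:, 0],
            "p": p,
            "neg_log10_p": -np.log10(p),
            "monomorphic": monomorphic,
        }
    )
    return ScanResult(table=table, threshold=threshold, alpha=alpha,
                      n_permutations=n_permutations)


def coded_correlation(v: CodedVectors) -> tuple[float, float]:
    """Pearson correlation of ±1 phenotype vs +1/0/−1 genotype codes.

    Returns (r, two-sided p) with the p-value from the t distribution on
    n − 2 degrees of freedom.
    """
    x = np.asarray(v.phenotype, dtype=float)
    g = np.asarray(v.genotype, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(g) == 0:
        raise ValueError("zero variance in coded vector")
    res = stats.pearsonr(x, g)
    return float(res.statistic), float(res.pvalue)
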