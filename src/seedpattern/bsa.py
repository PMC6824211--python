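"""Bulked-segregant region scan and minimal haplotype-block intersection.

The scan is a categorical zygosity contrast, not an allele-frequency
statistic: a causal region shows the recessive bulk homozygous (for one
parent's allele, constant along the run) while the dominant bulk is
heterozygous.  Runs of qualifying markers are reported as regions, with a
small tolerance for isolated discordant (mis-genotyped) markers.

Coordinates are 1-based inclusive throughout; region length is
``end - start + 1`` bp.  BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: call alphabet, also used for presence/absence variants (presence ->
#: hom_ref/hom_alt dialect chosen by the caller)
CALLS = ("hom_ref", "het", "hom_alt", "missing")

META_COLUMNS = ("marker", "chrom", "bp")


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive genomic interval supported by scan markers."""

    chromosome: str
    start: int
    end: int
    flank_left: str
    flank_right: str
    n_markers: int
    markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, bp: int) -> bool:
        return chrom == self.chromosome and self.start <= bp <= self.end

    def to_bed_interval(self) -> tuple[str, int, int]:
        """(chrom, start, end) as 0-based half-open BED coordinates."""
        return (self.chromosome, self.start - 1, self.end)

    @classmethod
    def from_bed_interval(
        cls, chrom: str, start0: int, end_excl: int, **kwargs
    ) -> "Region":
        defaults = dict(flank_left="", flank_right="", n_markers=0)
        defaults.update(kwargs)
        return cls(chrom, start0 + 1, end_excl, **defaults)


class MarkerTable:
    """Genotype calls for markers (rows) by samples (columns).

    Backed by a metadata frame (``marker``, ``chrom``, ``bp``) plus a
    call frame with values from :data:`CALLS`.  Rows are sorted by
    (chromosome, bp); positions must be strictly increasing within a
    chromosome and sample names unique.
    """

    def __init__(self, meta: pd.DataFrame, calls: pd.DataFrame,
                 roles: Mapping[str, str] | None = None):
        missing_cols = set(META_COLUMNS) - set(meta.columns)
        if missing_cols:
            raise ValueError(f"meta missing columns {sorted(missing_cols)}")
        if len(meta) != len(calls):
            raise ValueError("meta and calls row counts differ")
        if calls.columns.duplicated().any():
            raise ValueError("duplicate sample names")
        bad = set(pd.unique(calls.to_numpy().ravel())) - set(CALLS)
        if bad:
            raise ValueError(f"unknown call values: {sorted(bad)}")
        order = np.lexsort((meta["bp"].to_numpy(), meta["chrom"].to_numpy()))
        self.meta = meta.iloc[order].reset_index(drop=True)
        self.calls = calls.iloc[order].reset_index(drop=True)
        for chrom, sub in self.meta.groupby("chrom", sort=False):
            if (np.diff(sub["bp"].to_numpy()) <= 0).any():
                raise ValueError(f"bp positions not strictly increasing within {chrom}")
        self.roles = dict(roles or {})

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_markers(self) -> int:
        return len(self.meta)

    def subset(self, keep: np.ndarray) -> "MarkerTable":
        return MarkerTable(
            self.meta.loc[keep].reset_index(drop=True),
            self.calls.loc[keep].reset_index(drop=True),
            self.roles,
        )

    # -- IO ------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Wide TSV with a 2-line header: sample names, then sample roles."""
        wide = pd.concat([self.meta.reset_index(drop=True), self.calls], axis=1)
        with open(path, "w") as fh:
            fh.write("\t".join(wide.columns) + "\n")
            roles = ["", "", ""] + [self.roles.get(s, "line") for s in self.samples]
            fh.write("\t".join(roles) + "\n")
            wide.to_csv(fh, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            role_row = fh.readline().rstrip("\n").split("\t")
            body = pd.read_csv(fh, sep="\t", names=header)
        samples = header[3:]
        roles = {s: r for s, r in zip(samples, role_row[3:]) if r}
        meta = body[list(META_COLUMNS)]
        calls = body[samples]
        return cls(meta, calls, roles)

    @classmethod
    def from_vcf(cls, path, roles: Mapping[str, str] | None = None) -> "MarkerTable":
        """Import biallelic sites from a VCF; GT fields map to the call alphabet."""
        from pysam import VariantFile

        rows, call_rows, samples = [], [], None
        with VariantFile(path) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf.fetch() if vcf.index is not None else vcf:
                if rec.alts is None or len(rec.alts) != 1:
                    continue
                rows.append((rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos))
                calls = []
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        calls.append("missing")
                    elif set(gt) == {0}:
                        calls.append("hom_ref")
                    elif 0 in gt:
                        calls.append("het")
                    else:
                        calls.append("hom_alt")
                call_rows.append(calls)
        meta = pd.DataFrame(rows, columns=META_COLUMNS)
        calls = pd.DataFrame(call_rows, columns=samples)
        return cls(meta, calls, roles)


def bulk_call(individual_calls: Iterable[str]) -> str:
    """Genotype call of a pooled-DNA sample from its members' calls.

    A pool containing both parental alleles — any heterozygote, or a
    mixture of opposite homozygotes — reads as het; a uniform pool reads
    as its homozygote.  All-missing pools are missing.
    """
    present = [c for c in individual_calls if c != "missing"]
    for c in present:
        if c not in CALLS:
            raise ValueError(f"unknown call {c!r}")
    if not present:
        return "missing"
    uniq = set(present)
    if uniq == {"hom_ref"} or uniq == {"hom_alt"}:
        return uniq.pop()
    return "het"


def filter_polymorphic(table: MarkerTable, parent_a: str, parent_b: str) -> MarkerTable:
    """Keep markers where the parents carry opposite homozygous calls.

    Markers missing in either parent are dropped (no imputation).
    """
    for p in (parent_a, parent_b):
        if p not in table.calls.columns:
            raise KeyError(f"parent sample {p!r} not in table")
    a = table.calls[parent_a].to_numpy()
    b = table.calls[parent_b].to_numpy()
    keep = ((a == "hom_ref") & (b == "hom_alt")) | ((a == "hom_alt") & (b == "hom_ref"))
    return table.subset(keep)


def _marker_states(
    rec: np.ndarray,
    dom: np.ndarray,
    parent_a: np.ndarray | None = None,
    parent_b: np.ndarray | None = None,
) -> np.ndarray:
    """Qualifying state per marker: 'R'/'A' (recessive hom) or '' (none).

    With parent columns supplied, states are oriented by which parent's
    homozygous call the recessive bulk matches, so arbitrary per-marker
    ref/alt polarity cannot break a run.
    """
    states = np.full(len(rec), "", dtype=object)
    qual = dom == "het"
    if parent_a is not None and parent_b is not None:
        states[qual & (rec == parent_a) & (parent_a != "het") & (parent_a != "missing")] = "R"
        states[qual & (rec == parent_b) & (parent_b != "het") & (parent_b != "missing")] = "A"
    else:
        states[qual & (rec == "hom_ref")] = "R"
        states[qual & (rec == "hom_alt")] = "A"
    return states


def bsa_scan(
    table: MarkerTable,
    recessive_bulk: str,
    dominant_bulk: str,
    min_run: int = 5,
    max_gap: int = 1,
    parent_a: str | None = None,
    parent_b: str | None = None,
) -> list[Region]:
    """Scan for runs where the recessive bulk is homozygous and the
    dominant bulk heterozygous.

    The homozygous allele must be constant within a run.  Runs separated
    by at most ``max_gap`` consecutive non-qualifying markers are merged
    (genotyping-error tolerance); only runs supported by at least
    ``min_run`` qualifying markers are reported.  Output is independent
    of input row order (rows are position-sorted internally).
    """
    for s in (recessive_bulk, dominant_bulk):
        if s not in table.calls.columns:
            raise KeyError(f"bulk sample {s!r} not in table")
    regions: list[Region] = []
    for chrom, idx in table.meta.groupby("chrom", sort=False).groups.items():
        sub_meta = table.meta.loc[idx]
        rec = table.calls.loc[idx, recessive_bulk].to_numpy()
        dom = table.calls.loc[idx, dominant_bulk].to_numpy()
        pa = table.calls.loc[idx, parent_a].to_numpy() if parent_a else None
        pb = table.calls.loc[idx, parent_b].to_numpy() if parent_b else None
        states = _marker_states(rec, dom, pa, pb)
        markers = sub_meta["marker"].to_numpy()
        bps = sub_meta["bp"].to_numpy()

        # one pass per homozygous state: markers of the other state count
        # as discordant, exactly like genotyping errors
        runs: list[list[int]] = []
        for target in ("R", "A"):
            support: list[int] = []
            gap = 0
            for i, s in enumerate(states):
                if s == target:
                    support.append(i)
                    gap = 0
                elif support:
                    gap += 1
                    if gap > max_gap:
                        runs.append(support)
                        support, gap = [], 0
            if support:
                runs.append(support)

        for support in runs:
            if len(support) < min_run:
                continue
            first, last = support[0], support[-1]
            regions.append(
                Region(
                    chromosome=str(chrom),
                    start=int(bps[first]),
                    end=int(bps[last]),
                    flank_left=str(markers[first]),
                    flank_right=str(markers[last]),
                    n_markers=len(support),
                    markers=tuple(str(markers[i]) for i in support),
                )
            )
    return regions


def intersect_blocks(regions: Sequence[Region]) -> Region:
    """Minimal interval shared by one region per population.

    Returns ``[max(starts), min(ends)]``; disjoint inputs raise a
    "no shared block" error.  Associative and commutative in the
    population order.
    """
    if not regions:
        raise ValueError("no regions to intersect")
    chroms = {r.chromosome for r in regions}
    if len(chroms) > 1:
        raise ValueError(f"regions span multiple chromosomes: {sorted(chroms)}")
    start = max(r.start for r in regions)
    end = min(r.end for r in regions)
    if start > end:
        raise ValueError("no shared block: region intersection is empty")
    by_start = max(regions, key=lambda r: r.start)
    by_end = min(regions, key=lambda r: r.end)
    return Region(
        chromosome=chroms.pop(),
        start=start,
        end=end,
        flank_left=by_start.flank_left,
        flank_right=by_end.flank_right,
        n_markers=0,
        markers=(),
    )


def regions_to_bed(regions: Sequence[Region], path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            chrom, start, end = r.to_bed_interval()
            fh.write(f"{chrom}\t{start}\t{end}\tregion{i}\t{r.n_markers}\t.\n")


def regions_from_bed(path) -> list[Region]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            out.append(Region.from_bed_interval(fields[0], int(fields[1]), int(fields[2])))
    return out


def regions_to_tsv(regions: Sequence[Region], path) -> None:
    rows = [
        {
            "chrom": r.chromosome,
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "flank_left": r.flank_left,
            "flank_right": r.flank_right,
            "n_markers": r.n_markers,
        }
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def verify_region(
    table: MarkerTable,
    region: Region,
    recessive_bulk: str,
    dominant_bulk: str,
    parent_a: str | None = None,
    parent_b: str | None = None,
) -> bool:
    """Check that every supporting marker still shows the zygosity contrast."""
    meta = table.meta.set_index("marker")
    states = []
    for m in region.markers:
        if not region.contains(meta.at[m, "chrom"], int(meta.at[m, "bp"])):
            return False
        i = table.meta.index[table.meta["marker"] == m][0]
        rec = table.calls.at[i, recessive_bulk]
        dom = table.calls.at[i, dominant_bulk]
        if dom != "het" or rec not in ("hom_ref", "hom_alt"):
            return False
        if parent_a is not None and parent_b is not None:
            if rec == table.calls.at[i, parent_a]:
                states.append("R")
            elif rec == table.calls.at[i, parent_b]:
                states.append("A")
            else:
                return False
        else:
            states.append(rec)
    return len(set(states)) <= 1
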