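# seedpattern

A toolkit for three-locus epistatic seed-coat pattern genetics in cowpea-style
populations. It models a "constriction" locus `C` (three-allele series) and
two "expansion" loci `W` and `H`, and provides:

- **`seedpattern.model`** — loci, allelic series (partial dominance orders with
  explicit *unresolved* pairs), the epistatic genotype→pattern map
  (`NoColor`, `Eye1`, `Eye2`, `Holstein`, `Watson`, `FullCoat`), and
  mapping-ready trait encoding (with strict/MAGIC handling of the
  epistatically masking Eye 1 class). The default model ships as
  `src/seedpattern/data/cwh_default.yaml`.
- **`seedpattern.segregation`** — exact (rational-arithmetic) expected
  phenotype ratios for F2, RIL (k selfing generations), and idealized
  8-founder MAGIC designs, plus Pearson chi-square goodness of fit against
  observed class counts. The classic MAGIC prediction 192:5:35:35:245 comes
  out exactly.
- **`seedpattern.simulate`** — forward simulator (Haldane map function, no
  interference) for F2, single-seed-descent RIL, and funnel-crossed MAGIC
  populations over a genetic map, with founder-origin tracking and phenotype
  assignment; used to validate the analytic predictions.
- **`seedpattern.bsa`** — bulked-segregant scan on pooled-DNA genotype calls
  (recessive bulk homozygous / dominant bulk heterozygous runs, with
  gap tolerance for genotyping errors) and minimal haplotype-block
  intersection across populations. Coordinates are 1-based inclusive;
  BED export is 0-based half-open.
- **`seedpattern.scan`** — a deliberately *simplified* single-marker
  regression scan with seeded permutation thresholds (not an interval-mapping
  or multiparent HMM reimplementation), plus the ±1/0 coded Pearson
  correlation test.
- **`seedpattern.synth`** — seeded synthetic fixtures: founder sets (including
  the eight-founder `table1_founders` preset), uniform genetic maps,
  genotyping-error and phenotype-confusion noise, and bulk construction.

## CLI

All commands live under one entry point:

```sh
seedpattern predict-ratio --design design.yaml            # expected class ratio
seedpattern gof --observed "Eye1=121,Eye2=0,Holstein=21,Watson=13,FullCoat=141" \
                --design design.yaml                      # chi-square GoF
seedpattern gof --observed "Watson=27,FullCoat=93" --ratio 1:3
seedpattern simulate --design magic --n 305 --seed 42 --out pop.tsv
seedpattern make-fixtures --out fixtures/ --n 200 --seed 8
seedpattern bsa-scan --table fixtures/bulks.tsv \
    --recessive bulk_Watson --dominant bulk_FullCoat \
    --parent-a parentA --parent-b parentB --bed regions.bed
seedpattern intersect-blocks --region Vu07:1000-5000 --region Vu07:2500-4500
seedpattern marker-scan --traits traits.tsv --genotypes pop.tsv \
    --perms 1000 --alpha 0.05 --seed 7
```

A design file is YAML:

```yaml
kind: RIL            # F2 | RIL | MAGIC
parents:
  - "C=C2/C2 W=W0/W0 H=H0/H0"
  - "C=C2/C2 W=W1/W1 H=H1/H1"
selfing_generations: 7   # RIL only; null = idealized fully homozygous lines
```

## Notes

- Analytic ratios require unlinked loci (distinct chromosomes); linked
  designs are served by the simulator.
- Heterozygotes at an allele pair with unknown dominance order (`C1`/`C0`)
  raise an explicit error instead of guessing.
- All stochastic code takes an explicit `numpy.random.Generator`; fixed seeds
  give bit-identical populations.
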