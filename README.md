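# ssrscape

Genome-wide cataloguing of perfect simple sequence repeats (SSRs) and
read-based estimation of SSR heterozygosity, for population and genome
biologists working with shotgun-sequenced heterozygous diploids (the
motivating system is the *Daphnia pulex* genome, sequenced from a
single heterozygous genotype at ~8.7× with ~774 nt reads).

An SSR locus is a maximal perfect tandem array of a primitive motif
(period-free unit; GA, not GAGA) of size 1–100 nt repeated ≥ 3 times.
From an assembly plus read alignments, the package measures, per motif
size *m*, motif class and repeat number *n*:

* **repeat-length heterozygosity** — the two haplotypes differ by whole
  units (slippage; Δ = ±1 under the stepwise mutation model);
* **multistep variation** — allelic difference |Δ| ≥ 2 units, whose
  share of heterozygotes grows with *n* and *m*;
* **NRUPs** (non-repeat-unit polymorphisms) — substitutions or
  non-unit-length indels interrupting the array, tested against the
  uniform-placement expectation E[end] = total · 2/*n* (an interruption
  is "end" when it falls in a terminal complete unit);
* **motif biases** — starting-nucleotide preference within
  rotation/complement classes (CA = AC = GT = TG, …) by chi-square with
  df = class size − 1, and A/T vs G/C homopolymer abundance against the
  genomic base composition;
* **density vs recombination** — per genetic-map interval, loci/Mb
  against cM/Mb by least squares with 95% confidence/prediction bands.

Genotyping is deliberately conservative: every locus position must have
read depth in [4, 16] (the cap removes collapsed paralogs), each allele
or NRUP needs ≥ 2 supporting reads, anchored reads must match a 5 nt
flank exactly on both sides, and loci with more than two supported
alleles (or a third state at one site) are discarded as paralogous.
Repeat-length alleles are called by re-counting motif units in the read
segment between the anchors, not by trusting indel placement in the
alignment, which is ambiguous inside a tandem repeat.

A synthetic-data module generates diploid genomes with planted,
isolation-verified SSR loci, a slippage/multistep/NRUP heterozygosity
model, shotgun reads and their truth alignments (SAM), plus genetic
maps with either SSR-independent or SSR-coupled recombination rates —
so the whole pipeline is testable without any downloads. See
`docs/methods.md` for the model and every default.

## Worked example

```python
from ssrscape import find_ssrs
find_ssrs("GAGAGAGAGATTTTTTCACACACA")
```

```
SsrLocus(seq_id='seq', start=0,  end=10, motif='GA', motif_size=2, repeat_number=5)
SsrLocus(seq_id='seq', start=10, end=16, motif='T',  motif_size=1, repeat_number=6)
SsrLocus(seq_id='seq', start=16, end=24, motif='CA', motif_size=2, repeat_number=4)
```

The scanner is greedy: at each position the candidate spanning the most
complete-unit nucleotides wins (so `GAGAGAGA` is 4 × GA, never 2 × GAGA),
and scanning resumes after each locus.

End to end on synthetic data — plant four locus bins in a 250 kb
diploid, sequence it at 8.7×, and genotype every planted locus:

```python
from ssrscape import (SimConfig, PlantedSpec, generate_reference, diploidize,
                      simulate_reads, genotype_catalog, summarize_heterozygosity)

cfg = SimConfig(seed=42, genome_length=250_000,
                planted=[PlantedSpec("A", 10, 80), PlantedSpec("C", 10, 80),
                         PlantedSpec("AC", 10, 80), PlantedSpec("AG", 12, 60)])
refs, truth = generate_reference(cfg)
alts, truth = diploidize(refs, truth, cfg)
simulate_reads(refs, alts, truth, cfg, "reads.fastq", "alignments.sam")
gts = genotype_catalog("alignments.sam", [l.as_locus() for l in truth.loci], refs)
het = summarize_heterozygosity(gts)
print(het.by_class[["motif_class", "repeat_number", "n_assayed",
                    "n_het", "pct_het", "pct_multistep"]].to_string(index=False))
```

```
motif_class  repeat_number  n_assayed  n_het   pct_het  pct_multistep
          A             10         76      1  1.315789       0.000000
         AC             10         77     10 12.987013      30.000000
         AG             12         55     10 18.181818      20.000000
          C             10         76     11 14.473684      18.181818
```

284 of 300 planted loci pass the depth window; heterozygosity is
motif-specific (AC/AG dimers and G/C homopolymers well above A/T
homopolymers, as the generator's slippage model dictates), and about a
fifth of heterozygotes at these repeat numbers are multistep. The
`pct_*` columns are percentages of assayed and of heterozygous loci
respectively.

The same stages run from the shell:

```bash
ssrscape simulate --seed 42 --out sim/
ssrscape catalog  --fasta sim/reference.fasta --min-repeats 3 --max-motif 100 --out cat/
ssrscape genotype --catalog cat/catalog.tsv --sam sim/alignments.sam \
                  --fasta sim/reference.fasta --out gt/
ssrscape stats    --catalog cat/catalog.tsv --map sim/genetic_map.tsv --out st/
ssrscape run      --config run.yaml    # all of the above from one YAML
```

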