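# Methods

## Scope and model

`ssrscape` analyses perfect simple sequence repeats (SSRs) in an
assembly and their heterozygosity in the shotgun reads the assembly was
built from. The underlying picture is a single highly heterozygous
diploid genotype: at any repeat locus the two haplotypes may differ by
whole repeat units (replication slippage, the stepwise mutation model),
by two or more units at once (multistep change), or by interruptions
that are not whole-unit indels — base substitutions and non-unit-length
indels, here called non-repeat-unit polymorphisms (NRUPs). The package
asks how the rates of these events depend on motif size, motif
sequence, repeat number and position in the array, and how repeat
density relates to recombination rate.

## Repeat detection

A locus is a maximal perfect tandem array of a primitive motif (no
shorter tiling period) with at least `min_repeats` complete copies
(default 3) and motif size 1–100 nt. The scanner walks each sequence
left to right; at a position the maximal run for every motif size is
computed (vectorised as lagged self-comparison plus run-length
encoding) and the candidate covering the most complete-unit
nucleotides wins. Ties go to the smaller motif size, which also
guarantees primitivity: a non-primitive winner would tie its own
period and lose to it. Scanning resumes after each recorded locus, so
reported loci never overlap. `GAGAGAGA` is one locus of 4 × GA, and
`AAAGAGAAAGAG` (at `min_repeats=2`) one locus of 2 × AAAGAG rather than
two homopolymer runs.

Conventions where a choice had to be made:

* coordinates are 0-based half-open on the forward strand; motifs are
  orientation-resolved (GA ≠ AG) as they occur at the locus start;
* repeat_number counts complete units only; a trailing partial copy is
  outside the recorded span;
* `N` (and any non-ACGT character after uppercasing) breaks every run;
  soft-masked lowercase is folded to uppercase;
* the first (leftmost) qualifying locus wins; the scan resumes at its
  end.

A consequence of greedy non-overlapping selection worth knowing:
overlap resolution at *chained* repeats (one array abutting another
whose period continues across the junction) depends on scan direction.
Genome-wide class counts under reverse complementation therefore agree
only up to ±1 per chained junction; for isolated arrays the mapping is
exact, and the test suite checks exactly that. Likewise, a reported
locus is always right-maximal, but left extension may be "possible"
when the extension bases were already consumed by the previous locus.

The brute-force reference scanner (`brute_force_ssrs`) enumerates every
(start, motif size) pair by direct character comparison in O(n³) and
applies the same selection rule; the two implementations are compared
on thousands of random strings in the tests.

## Abundance statistics

Homopolymer A/T vs G/C counts are compared with the genomic A+T base
fraction by a two-sided 1-df chi-square goodness of fit; the exact
binomial tail is substituted below 1000 loci or when an expected cell
drops under 5 (at genome scale the statistic is astronomically large
and the p-value underflows to 0, which is how it is reported).

Motif classes pool all rotations of a motif with all rotations of its
reverse complement (CA = AC = GT = TG; AT = TA; trimer classes have up
to six members). Under no starting-base preference each member of a
class carries an equal share of the class total; the departure is
tested by chi-square with df = class size − 1. Expected values are
displayed rounded half-up but tested unrounded.

Interruption position: an NRUP is classed "end" when its offset lies in
the first or last complete repeat unit. Under uniform placement the
end expectation for a locus of n units is total × 2/n. This
two-terminal-units definition reproduces the published expectation
columns for homopolymers and dimers alike, and the 1-df chi-square on
the unrounded expectations reproduces the printed p-value magnitudes
(e.g. ~5e-277 for the homopolymer n=5 row).

Per-scaffold abundance flags use a two-sided exact binomial test of
each scaffold's locus count against a length-proportional expectation,
Bonferroni-corrected across scaffolds × motif-size groups (α = 0.05);
"+" marks excess, "−" dearth.

Heterozygosity-vs-repeat-number curves are fit by ordinary least
squares, either linear or exponential (OLS on log y, positive
responses only); a selection helper returns the better-r² family.
Density/recombination regression pairs each genetic-map interval's
SSR density (loci/Mb, motif-size filtered) with its cM/Mb and reports
the linear fit with 95% confidence and prediction bands from the
closed-form t-based formulas.

## Genotyping from reads

The caller consumes standard SAM alignments of reads to the assembly;
it does not re-implement an assembler. Per locus:

1. **Anchoring.** A read contributes only if it spans the locus plus a
   `flank` (default 5 nt) on both sides, the flank columns are aligned
   gap-free and match the assembly exactly, alignment identity is at
   least 0.90 (mismatches and indel bases over alignment columns), and
   the record is primary and unclipped through the locus.
2. **Allele extraction.** The read bases between the anchors are
   re-examined directly. A pure motif tiling gives the repeat-length
   delta immediately; otherwise the segment is globally aligned to the
   reference array at unit cost (edlib), indels are left-shifted, and
   each event is classified: indel length a multiple of the motif size
   → whole-unit change absorbed into the delta; anything else
   (substitutions, non-unit indels) → an NRUP with an end/middle class.
   Re-counting units instead of trusting gap columns makes the call
   independent of the aligner's ambiguous indel placement inside a
   repeat.
3. **Filters, in order.** Depth at every locus position must lie in
   [4, 16] (the cap suppresses collapsed paralogs, the floor guarantees
   a detectable second allele), else unassayable. Alleles and NRUPs
   need ≥ 2 supporting reads; singleton variants go to a read-error
   tally. More than two supported repeat-length alleles, or a third
   state at a single site, discard the locus as putatively paralogous.
   Two supported alleles differing by ≥ 2 units (both retaining ≥ 2
   perfect units) are multistep; by one unit, a unit heterozygote.

These filters are deliberately conservative: lowering the support
minimum can only add het calls, raising it only remove them (tested as
a monotonicity property). Allele polarity (which haplotype is
ancestral) is not inferred — a single diploid genotype cannot polarize.

Summaries bin loci by motif size × repeat number and by motif class,
reporting assayed counts, % het, the multistep share of het loci
(undefined — NaN — in bins with no het locus), NRUP events per assayed
nucleotide, and the multiallelic discard frequency.

## Synthetic data generator

The generator emulates the study conditions, not real-genome
complexity. Defaults: A+T fraction 0.59; 8.7× single-end coverage;
read lengths N(774, 150) truncated at 100 nt; substitution-only read
errors at 10⁻³/base (indel-free errors keep the singleton filter
interpretable). Planted loci (default ~1,780 across 15 bins: A/C
homopolymers at 8–12 repeats, AC/AG/AT/GC dimers, a trimer, a tetramer
and a pentamer bin) are spaced evenly with wide non-repetitive spacers;
guard bases adjacent to each array are chosen to differ from the
motif's first and last base, and — because a background repeat can
still chain across a boundary — each planted locus is verified by a
local re-scan and its guards redrawn until the scanner reports the
planted coordinates exactly. Planted truth therefore matches the
catalogue byte-for-byte, while the random background contributes a
realistic sea of incidental (mostly short) repeats.

Haplotype B is derived per locus: a unit-slippage heterozygote occurs
with probability ceiling(class) / (1 + e^(−0.45 (n − 10))) — ceilings
0.10 (A/T homopolymer), 0.25 (G/C), 0.32/0.28/0.22/0.15 for AC/AG/AT/GC
dimers, 0.20 otherwise, mirroring the reported ordering AC/AG > AT > GC
and the ~3-fold G/C excess over A/T with saturation beyond ~12
repeats. Multistep share of heterozygotes is 0.05 + 0.02·(n−4) +
0.05·(m−1) capped at 0.85, step size 1 + Geometric(0.6), contraction
never reducing an array below two units. Length-identical loci receive
an NRUP with probability 0.004/nt × array length, placed in a terminal
unit with probability 0.8 (the end bias). A locus gets either a length
event or an NRUP, never both, so every planted rate is exactly
recoverable; this is a simplification relative to real loci, where the
two co-occur. All knobs are config fields.

Reads carry their true alignments to the reference haplotype in SAM
(haplotype-B reads get cigars from the recorded per-scaffold op map,
with left-aligned unit indels; leading/trailing insertions soft-clip).
An optional paralogy mode adds a few reads from a divergent third
allele at selected heterozygous loci, emulating a collapsed paralog;
this measurably raises the multiallelic discard frequency (a
directional, not calibrated, effect). The genetic-map generator tiles
the genome into intervals and assigns cM either independently of SSR
content (gamma-distributed rates; the null) or as rate = 1 +
0.05·density + N(0, 0.3) cM/Mb (planted positive correlation).

## What the synthetic tests do and do not show

Parameter recovery on a 1 Mb diploid at 8.7× shows the caller is
unbiased to within the support/depth filters' detection efficiency
(at depth 4 a true heterozygote has a ~31% chance of fewer than 2
variant reads; averaged over the depth window the shortfall is a few
percent relative) and that planted per-bin rates, the multistep share
and the NRUP end bias sit inside joint 95% confidence intervals
(Bonferroni-adjusted Clopper–Pearson across bins — ~15 independent
95% intervals would otherwise fail half of all runs by construction).
The generator does not model real features that matter at genome
scale: imperfect/compound repeats, transposable elements, base-quality
variation, alignment errors from a real aligner, chimeric reads, or
true paralogy with its own divergence spectrum. Passing these tests
therefore validates the machinery under the stated model, not the
biological conclusions on any particular genome.

## Problem sizes and numerics

Default test problem sizes: 1 Mb genome (≈52,000 catalogued loci,
≈11,200 reads) for end-to-end recovery, 400 kb × 100 map replicates
for null calibration, ≥1,000 random ≤300-nt strings for oracle
equivalence. The whole suite runs in a few minutes on one CPU.
Chi-square p-values below ~1e-308 underflow to exactly 0 and are
reported as such, matching how the reference tables print them.
Expected values are rounded half-up for display only. Degenerate
inputs (zero totals, all-equal predictors, non-positive responses for
the exponential model, repeat_number < 2 in the end/middle model) are
rejected with `ValueError` rather than guessed at.
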