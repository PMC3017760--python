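"""Perfect simple-sequence-repeat (SSR) detection and genome cataloguing.

The scanner walks each sequence left to right.  At every position it
considers, for each motif size up to ``max_motif``, the maximal perfect
tandem run starting there; the candidate spanning the most nucleotides
of complete units wins (ties go to the smaller motif size, which also
guarantees the reported motif is primitive: a non-primitive winner would
be beaten by its own period).  Scanning resumes immediately after each
recorded locus, so reported loci never overlap.  Runs are perfect — a
single mismatch or an N terminates them — and only whole motif copies
count toward the repeat number.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Iterator, TextIO, Union

import numpy as np
from Bio import SeqIO
from scipy import stats as _st

from .motifs import primitive_motif  # noqa: F401  (re-exported convenience)

@dataclass(frozen=True)
class SsrLocus:
    """One perfect repeat array on the forward strand.

    Coordinates are 0-based, half-open; ``motif`` is the unit as it
    occurs at ``start`` (orientation-resolved: GA and AG are distinct).
    """

    seq_id: str
    start: int
    end: int
    motif: str
    motif_size: int
    repeat_number: int

    @property
    def array_length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end - self.start != self.motif_size * self.repeat_number:
            raise ValueError("array_length must equal motif_size * repeat_number")
        if len(self.motif) != self.motif_size:
            raise ValueError("motif length disagrees with motif_size")


@dataclass
class CatalogSummary:
    """Abundance summary of a catalogued sequence set."""

    counts_by_motif_size: dict[int, int] = field(default_factory=dict)
    counts_by_motif: dict[str, int] = field(default_factory=dict)
    total_loci: int = 0
    bases_covered: int = 0
    genome_size: int = 0

    @property
    def fraction_covered(self) -> float:
        return self.bases_covered / self.genome_size if self.genome_size else 0.0


def find_ssrs(seq: str, seq_id: str = "seq",
              min_repeats: int = 3, max_motif: int = 100) -> list[SsrLocus]:
    """Scan one sequence for perfect SSRs.

    Parameters
    ----------
    seq
        Nucleotide string over A/C/G/T/N (case-insensitive; soft-masked
        lowercase is uppercased, N breaks every run).
    min_repeats
        Minimum number of complete perfect copies (default 3).
    max_motif
        Largest motif size considered, in nt (default 100).

    Returns
    -------
    Non-overlapping loci in left-to-right order.  Every reported motif
    is primitive; every array is right-maximal and, relative to the
    unconsumed sequence, left-maximal (one more whole unit would break
    perfection or overlap an earlier locus).
    """
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    if max_motif < 1:
        raise ValueError("max_motif must be >= 1")
    s = seq.upper()
    n = len(s)
    if n == 0:
        return []
    b = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    valid = (b == ord("A")) | (b == ord("C")) | (b == ord("G")) | (b == ord("T"))
    if not bool((valid | (b == ord("N"))).all()):
        raise ValueError("sequence contains characters outside A/C/G/T/N")

    best_len = np.zeros(n, dtype=np.int64)
    best_m = np.zeros(n, dtype=np.int64)
    positions = np.arange(n, dtype=np.int64)
    top_m = min(max_motif, n // min_repeats)
    for m in range(1, top_m + 1):
        match = np.zeros(n, dtype=bool)
        match[m:] = (b[m:] == b[:-m]) & valid[m:] & valid[:-m]
        # cnt[i] = length of the True run starting at i
        false_pos = np.flatnonzero(~match)
        nxt = np.concatenate([false_pos, [n]])
        cnt = nxt[np.searchsorted(false_pos, positions, side="left")] - positions
        run = np.zeros(n, dtype=np.int64)
        run[: n - m] = m + cnt[m:]
        cand = (run // m) * m
        cand[run // m < min_repeats] = 0
        upd = cand > best_len
        best_len[upd] = cand[upd]
        best_m[upd] = m

    loci: list[SsrLocus] = []
    hits = np.flatnonzero(best_len)
    cursor = 0
    for pos in hits:
        if pos < cursor:
            continue
        pos = int(pos)
        length = int(best_len[pos])
        m = int(best_m[pos])
        loci.append(SsrLocus(seq_id, pos, pos + length, s[pos:pos + m], m, length // m))
        cursor = pos + length
    return loci


FastaSource = Union[str, PathLike, TextIO, Iterable]


def _iter_sequences(source: FastaSource) -> Iterator[tuple[str, str]]:
    if isinstance(source, (str, PathLike)) or isinstance(source, io.TextIOBase):
        for rec in SeqIO.parse(source, "fasta"):
            yield rec.id, str(rec.seq)
        return
    for item in source:
        if hasattr(item, "seq"):  # SeqRecord
            yield item.id, str(item.seq)
        else:
            sid, s = item
            yield sid, s


def catalog_genome(source: FastaSource, min_repeats: int = 3,
                   max_motif: int = 100) -> tuple[list[SsrLocus], CatalogSummary]:
    """Catalogue every record of a FASTA file (or (id, seq) iterable).

    Records are scanned independently; the summary pools them.  Motif
    counts are orientation-resolved — a motif is recorded as it first
    occurs, so GA and AG accumulate separately.
    """
    loci: list[SsrLocus] = []
    summary = CatalogSummary()
    for seq_id, seq in _iter_sequences(source):
        summary.genome_size += len(seq)
        for loc in find_ssrs(seq, seq_id=seq_id, min_repeats=min_repeats,
                             max_motif=max_motif):
            loci.append(loc)
            summary.total_loci += 1
            summary.bases_covered += loc.array_length
            summary.counts_by_motif_size[loc.motif_size] = (
                summary.counts_by_motif_size.get(loc.motif_size, 0) + 1)
            summary.counts_by_motif[loc.motif] = (
                summary.counts_by_motif.get(loc.motif, 0) + 1)
    return loci, summary


@dataclass(frozen=True)
class CompositionTest:
    """Observed vs. base-composition expectation for homopolymer counts."""

    expected_a_t: float
    expected_g_c: float
    statistic: float
    p_value: float
    method: str  # 'chi-square' or 'exact-binomial'


# Below this many loci the exact binomial tail replaces the chi-square
# approximation (also whenever an expected cell drops under 5).
_EXACT_TOTAL = 1000


def composition_expectation_test(observed_a_t: int, observed_g_c: int,
                                 base_comp_a_t: float) -> CompositionTest:
    """Test the A/T vs G/C homopolymer split against base composition.

    Compares the observed share of A/T homopolymer loci to the genomic
    A+T base fraction (two-sided).  Uses a 1-df chi-square goodness of
    fit for large counts and the exact binomial tail for small ones.
    """
    if observed_a_t < 0 or observed_g_c < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 < base_comp_a_t < 1.0:
        raise ValueError("base_comp_a_t must be in (0, 1)")
    total = observed_a_t + observed_g_c
    if total == 0:
        raise ValueError("no homopolymer loci: test undefined")
    exp_at = total * base_comp_a_t
    exp_gc = total - exp_at
    stat = (observed_a_t - exp_at) ** 2 / exp_at + (observed_g_c - exp_gc) ** 2 / exp_gc
    if total < _EXACT_TOTAL or min(exp_at, exp_gc) < 5:
        p = _st.binomtest(observed_a_t, total, base_comp_a_t,
                          alternative="two-sided").pvalue
        method = "exact-binomial"
    else:
        p = float(_st.chi2.sf(stat, df=1))
        method = "chi-square"
    return CompositionTest(exp_at, exp_gc, float(stat), float(p), method)


def brute_force_ssrs(seq: str, seq_id: str = "seq", min_repeats: int = 3,
                     max_motif: int = 100) -> list[SsrLocus]:
    """Exhaustive O(n^3) reference scanner for small inputs.

    Independently enumerates, for every (start, motif size) pair, the
    maximal perfect run by direct character comparison, then applies the
    same greedy left-to-right selection (longest array, ties to the
    smaller motif) used by :func:`find_ssrs`.  Intended for testing.
    """
    if min_repeats < 2 or max_motif < 1:
        raise ValueError("invalid parameters")
    s = seq.upper()
    n = len(s)
    ok = set("ACGT")
    best: dict[int, tuple[int, int]] = {}
    for i in range(n):
        for m in range(1, min(max_motif, (n - i) // min_repeats) + 1):
            if any(c not in ok for c in s[i:i + m]):
                continue
            j = i + m
            while j < n and s[j] in ok and s[j] == s[j - m]:
                j += 1
            rep = (j - i) // m
            if rep >= min_repeats:
                length = rep * m
                cur = best.get(i)
                if cur is None or length > cur[0]:
                    best[i] = (length, m)
    loci = []
    i = 0
    while i < n:
        if i in best:
            length, m = best[i]
            loci.append(SsrLocus(seq_id, i, i + length, s[i:i + m], m, length // m))
            i += length
        else:
            i += 1
    return loci


def homopolymer_split(summary: CatalogSummary) -> tuple[int, int]:
    """(A/T, G/C) homopolymer locus counts from a catalogue summary."""
    at = summary.counts_by_motif.get("A", 0) + summary.counts_by_motif.get("T", 0)
    gc = summary.counts_by_motif.get("G", 0) + summary.counts_by_motif.get("C", 0)
    return at, gc
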