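"""Per-locus SSR genotyping from read-to-assembly alignments.

Each catalogued locus is genotyped from the reads that span it.  A read
contributes an observation only when it covers the locus plus a short
flank on both sides with the flanks matching the assembly exactly; the
repeat-length allele of the read is obtained by re-examining the read
bases between the anchors rather than by trusting gap placement in the
alignment, because indel placement inside a tandem repeat is ambiguous.

Filters mirror a conservative shotgun-heterozygosity protocol:

* every position of the locus must lie within a coverage window
  (default 4-16 inclusive; the cap suppresses collapsed paralogs),
* an allele or a point variant needs at least 2 supporting reads
  (singleton variant reads go to a read-error tally),
* loci presenting more than two supported repeat-length alleles, or
  more than two states at a single site, are discarded as putative
  paralogs,
* allelic differences of two or more whole repeat units are classed as
  multistep.

Interruptions of the repeat array that are not whole-unit indels
(NRUPs: base substitutions, or indels whose length is not a multiple of
the motif size) are recorded with an end/middle position class: "end"
means the first or last full repeat unit of the array.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
import pysam

from .catalog import SsrLocus
from .motifs import motif_class_label

UNASSAYABLE = "unassayable"
HOMOZYGOUS = "homozygous"
HET_UNIT = "het_unit"
HET_MULTISTEP = "het_multistep"
DISCARDED = "discarded_multiallelic"

HET_STATUSES = (HET_UNIT, HET_MULTISTEP)


def classify_nrup_position(offset: int, locus: SsrLocus) -> str:
    """'end' if ``offset`` falls in the first or last full repeat unit."""
    if not 0 <= offset < locus.array_length:
        raise ValueError(f"offset {offset} outside locus of length {locus.array_length}")
    if offset < locus.motif_size or offset >= locus.array_length - locus.motif_size:
        return "end"
    return "middle"


@dataclass(frozen=True)
class Nrup:
    """A non-repeat-unit polymorphism inside a locus.

    ``offset`` is 0-based within the locus (reference coordinates);
    ``detail`` identifies the event (alternate base, or indel sequence)
    so that identical events on different reads can be pooled.
    """

    kind: str            # 'substitution' | 'insertion' | 'deletion'
    offset: int
    position_class: str  # 'end' | 'middle'
    detail: str = ""


@dataclass
class AlleleObservation:
    """One anchored read's view of a locus."""

    read_id: str
    delta_units: int
    nrups: tuple[Nrup, ...] = ()
    anchored: bool = True


@dataclass
class LocusGenotype:
    locus: SsrLocus
    status: str
    alleles: list[tuple[int, int]] = field(default_factory=list)   # (delta, support)
    nrup_calls: list[tuple[Nrup, int]] = field(default_factory=list)
    depth_range: tuple[int, int] = (0, 0)
    n_observations: int = 0
    n_singleton_repeat: int = 0   # reads in unsupported repeat-length alleles
    n_singleton_snp: int = 0      # unsupported point-variant observations

    @property
    def is_het(self) -> bool:
        return self.status in HET_STATUSES

    @property
    def is_assayed(self) -> bool:
        return self.status != UNASSAYABLE


class ParsedRead:
    """Alignment of one read, pre-digested for fast locus queries."""

    __slots__ = ("name", "ref_name", "ref_start", "ref_end", "query",
                 "_block_ref_starts", "_block_ref_ends", "_block_q_starts",
                 "identity")

    def __init__(self, name: str, ref_name: str, ref_start: int, query: str,
                 cigartuples: Sequence[tuple[int, int]], ref_bytes: np.ndarray):
        self.name = name
        self.ref_name = ref_name
        self.ref_start = ref_start
        self.query = query
        rs, re_, qs = [], [], []
        r, q = ref_start, 0
        mismatches = 0
        columns = 0
        qarr = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        for op, length in cigartuples:
            if op in (0, 7, 8):          # M / = / X
                rs.append(r)
                re_.append(r + length)
                qs.append(q)
                mismatches += int((qarr[q:q + length] !=
                                   ref_bytes[r:r + length]).sum())
                columns += length
                r += length
                q += length
            elif op == 1:                # I
                columns += length
                mismatches += length
                q += length
            elif op == 2:                # D
                columns += length
                mismatches += length
                r += length
            elif op == 3:                # N (skip)
                r += length
            elif op in (4,):             # S
                q += length
            # H (5) / P (6): consume nothing
        self.ref_end = r
        self._block_ref_starts = rs
        self._block_ref_ends = re_
        self._block_q_starts = qs
        self.identity = 1.0 - mismatches / columns if columns else 0.0

    def query_pos(self, ref_pos: int, contiguous_to: int | None = None) -> int | None:
        """Query index aligned to ``ref_pos``.

        When ``contiguous_to`` is given, the whole reference range
        [ref_pos, contiguous_to) must sit inside one aligned block
        (gap-free columns), otherwise None.
        """
        i = bisect.bisect_right(self._block_ref_starts, ref_pos) - 1
        if i < 0 or ref_pos >= self._block_ref_ends[i]:
            return None
        if contiguous_to is not None and contiguous_to > self._block_ref_ends[i]:
            return None
        return self._block_q_starts[i] + (ref_pos - self._block_ref_starts[i])


def _left_shift_deletion(ref: str, pos: int, length: int) -> int:
    while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return pos

def _left_shift_insertion(ref: str, pos: int, ins: str) -> tuple[int, str]:
    while pos > 0 and ref[pos - 1] == ins[-1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def _parse_ext_cigar(cigar: str) -> Iterable[tuple[int, str]]:
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def compare_interior(interior: str, locus: SsrLocus) -> tuple[int, tuple[Nrup, ...]]:
    """Repeat-length delta and NRUPs of a read segment vs. the assembly.

    ``interior`` is the read's bases between the flank anchors.  If it
    is a pure tiling of the motif, the delta is read off directly;
    otherwise a global unit-cost alignment against the reference array
    is walked, indels are left-aligned, and each event is classed as a
    whole-unit change (length a multiple of the motif size, absorbed
    into ``delta_units``) or as an NRUP.
    """
    m = locus.motif_size
    ref = locus.motif * locus.repeat_number
    if interior == ref:
        return 0, ()
    k, rem = divmod(len(interior), m)
    if rem == 0 and interior == locus.motif * k:
        return k - locus.repeat_number, ()
    res = edlib.align(interior, ref, mode="NW", task="path")
    delta = 0
    nrups: list[Nrup] = []
    p = q = 0
    L = locus.array_length
    for length, op in _parse_ext_cigar(res["cigar"]):
        if op == "=":
            p += length
            q += length
        elif op == "X":
            for j in range(length):
                off = p + j
                nrups.append(Nrup("substitution", off,
                                  classify_nrup_position(off, locus),
                                  interior[q + j]))
            p += length
            q += length
        elif op == "I":
            ins = interior[q:q + length]
            pos, ins = _left_shift_insertion(ref, p, ins)
            if length % m == 0:
                delta += length // m
            else:
                off = min(pos, L - 1)
                nrups.append(Nrup("insertion", off,
                                  classify_nrup_position(off, locus), ins))
            q += length
        elif op == "D":
            pos = _left_shift_deletion(ref, p, length)
            if length % m == 0:
                delta -= length // m
            else:
                nrups.append(Nrup("deletion", pos,
                                  classify_nrup_position(pos, locus),
                                  ref[pos:pos + length]))
            p += length
        else:  # pragma: no cover
            raise ValueError(f"unexpected cigar op {op!r}")
    return delta, tuple(nrups)


def extract_locus_observations(alignments: Iterable,
                               locus: SsrLocus,
                               reference: str,
                               flank: int = 5,
                               min_identity: float = 0.90) -> list[AlleleObservation]:
    """Observations from every read that fully anchors across a locus.

    ``alignments`` may hold :class:`ParsedRead` objects or pysam
    ``AlignedSegment``s (unmapped/secondary/supplementary records are
    skipped).  A read qualifies when it spans
    ``[start - flank, end + flank)``, aligns with identity at least
    ``min_identity``, and both flanks match the assembly exactly and
    gap-free; reads clipped through the locus never qualify.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    a = locus.start - flank
    b = locus.end + flank
    if a < 0 or b > len(reference):
        return []
    left_ref = reference[a:locus.start]
    right_ref = reference[locus.end:b]
    ref_bytes = None  # built lazily: only raw pysam records need it
    out: list[AlleleObservation] = []
    for aln in alignments:
        pr = aln
        if isinstance(aln, pysam.AlignedSegment):
            if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
                    or aln.query_sequence is None):
                continue
            if ref_bytes is None:
                ref_bytes = np.frombuffer(reference.encode("ascii"),
                                          dtype=np.uint8)
            pr = ParsedRead(aln.query_name, aln.reference_name,
                            aln.reference_start, aln.query_sequence,
                            aln.cigartuples or [], ref_bytes)
        if pr.ref_start > a or pr.ref_end < b:
            continue
        if pr.identity < min_identity:
            continue
        qla = pr.query_pos(a, contiguous_to=locus.start)
        qra = pr.query_pos(locus.end, contiguous_to=b)
        if qla is None or qra is None:
            continue
        if pr.query[qla:qla + flank] != left_ref:
            continue
        if pr.query[qra:qra + flank] != right_ref:
            continue
        interior = pr.query[qla + flank:qra]
        delta, nrups = compare_interior(interior, locus)
        out.append(AlleleObservation(pr.name, delta, nrups, anchored=True))
    return out


def genotype_locus(observations: Sequence[AlleleObservation],
                   locus: SsrLocus,
                   depth_by_position: Sequence[int] | np.ndarray,
                   min_depth: int = 4,
                   max_depth: int = 16,
                   min_support: int = 2) -> LocusGenotype:
    """Apply the genotyping filters, in order, to one locus.

    Coverage window first (any position outside [min_depth, max_depth]
    makes the locus unassayable), then allele grouping with the
    ``min_support`` read minimum, then the two-allele cap — applied
    separately to repeat-length alleles and to per-site substitution
    states — and finally the unit/multistep classification.
    """
    depth = np.asarray(depth_by_position)
    if depth.size == 0:
        raise ValueError("depth_by_position must cover the locus")
    d_rng = (int(depth.min()), int(depth.max()))
    obs = [o for o in observations if o.anchored]
    gt = LocusGenotype(locus, UNASSAYABLE, depth_range=d_rng,
                       n_observations=len(obs))
    if d_rng[0] < min_depth or d_rng[1] > max_depth or not obs:
        return gt

    counts = Counter(o.delta_units for o in obs)
    supported = sorted((d, c) for d, c in counts.items() if c >= min_support)
    gt.alleles = supported
    gt.n_singleton_repeat = sum(c for d, c in counts.items()
                                if c < min_support)

    nrup_counts = Counter(n for o in obs for n in o.nrups)
    gt.nrup_calls = sorted(((n, c) for n, c in nrup_counts.items()
                            if c >= min_support),
                           key=lambda t: (t[0].offset, t[0].kind, t[0].detail))
    gt.n_singleton_snp = sum(c for n, c in nrup_counts.items()
                             if c < min_support)

    if not supported:
        return gt  # no allele reaches the read minimum

    # >2 substitution states at one site (reference + 2 alternates)
    subs_by_site = Counter(
        n.offset for n, _ in gt.nrup_calls if n.kind == "substitution")
    snp_multi = any(v >= 2 for v in subs_by_site.values())
    if len(supported) > 2 or snp_multi:
        gt.status = DISCARDED
        return gt
    if len(supported) == 1:
        gt.status = HOMOZYGOUS
        return gt
    (d1, _), (d2, _) = supported
    span = abs(d1 - d2)
    units_ok = all(locus.repeat_number + d >= 2 for d in (d1, d2))
    gt.status = HET_MULTISTEP if span >= 2 and units_ok else HET_UNIT
    return gt


def load_alignments(sam_path, references: Mapping[str, str],
                    ) -> tuple[dict[str, list[ParsedRead]], dict[str, np.ndarray]]:
    """Read a SAM/BAM once: per-scaffold sorted reads and depth arrays."""
    ref_bytes = {sid: np.frombuffer(s.encode("ascii"), dtype=np.uint8)
                 for sid, s in references.items()}
    reads: dict[str, list[ParsedRead]] = {sid: [] for sid in references}
    cover = {sid: np.zeros(len(s) + 1, dtype=np.int32)
             for sid, s in references.items()}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for aln in sam:
            if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
                    or aln.query_sequence is None):
                continue
            sid = aln.reference_name
            if sid not in references:
                continue
            pr = ParsedRead(aln.query_name, sid, aln.reference_start,
                            aln.query_sequence, aln.cigartuples or [],
                            ref_bytes[sid])
            reads[sid].append(pr)
            cover[sid][pr.ref_start] += 1
            cover[sid][pr.ref_end] -= 1
    depth = {sid: np.cumsum(arr[:-1]).astype(np.int32)
             for sid, arr in cover.items()}
    for sid in reads:
        reads[sid].sort(key=lambda r: r.ref_start)
    return reads, depth


def genotype_catalog(sam_path,
                     loci: Sequence[SsrLocus],
                     references: Mapping[str, str],
                     flank: int = 5,
                     min_identity: float = 0.90,
                     min_depth: int = 4,
                     max_depth: int = 16,
                     min_support: int = 2) -> list[LocusGenotype]:
    """Genotype every catalogued locus against one alignment file."""
    reads, depth = load_alignments(sam_path, references)
    starts = {sid: np.array([r.ref_start for r in lst], dtype=np.int64)
              for sid, lst in reads.items()}
    maxlen = {sid: max((r.ref_end - r.ref_start for r in lst), default=0)
              for sid, lst in reads.items()}
    out = []
    for locus in loci:
        sid = locus.seq_id
        if sid not in references:
            continue
        a = locus.start - flank
        b = locus.end + flank
        st = starts.get(sid)
        if st is None or st.size == 0 or a < 0 or b > len(references[sid]):
            out.append(LocusGenotype(locus, UNASSAYABLE))
            continue
        lo = int(np.searchsorted(st, a - maxlen[sid] - 1))
        hi = int(np.searchsorted(st, a, side="right"))
        window = [r for r in reads[sid][lo:hi] if r.ref_end >= b]
        obs = extract_locus_observations(window, locus, references[sid],
                                         flank=flank, min_identity=min_identity)
        out.append(genotype_locus(obs, locus, depth[sid][locus.start:locus.end],
                                  min_depth=min_depth, max_depth=max_depth,
                                  min_support=min_support))
    return out


@dataclass
class HetSummary:
    """Binned heterozygosity / multistep / NRUP rates plus run totals."""

    by_bin: pd.DataFrame          # motif_size x repeat_number bins
    by_class: pd.DataFrame        # motif class x repeat_number bins
    overall: dict


def _bin_frame(records: list[dict], keys: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(records)
    if df.empty:
        return pd.DataFrame(columns=keys + ["n_assayed", "n_het", "pct_het",
                                            "n_multistep", "pct_multistep",
                                            "n_nrup", "nrup_per_nt",
                                            "n_discarded"])
    g = df.groupby(keys, as_index=False).agg(
        n_assayed=("assayed", "sum"), n_het=("het", "sum"),
        n_multistep=("multistep", "sum"), n_nrup=("nrup", "sum"),
        nt=("nt", "sum"), n_discarded=("discarded", "sum"))
    g["pct_het"] = np.where(g.n_assayed > 0, 100.0 * g.n_het / g.n_assayed, np.nan)
    g["pct_multistep"] = np.where(g.n_het > 0, 100.0 * g.n_multistep / g.n_het, np.nan)
    g["nrup_per_nt"] = np.where(g.nt > 0, g.n_nrup / g.nt, np.nan)
    return g.drop(columns=["nt"])


def summarize_heterozygosity(genotypes: Sequence[LocusGenotype]) -> HetSummary:
    """Aggregate genotypes into per-bin rates.

    Bins are motif_size x repeat_number (``by_bin``) and motif class x
    repeat_number (``by_class``).  Assayed = not unassayable (discarded
    putative paralogs count toward the assayed denominator, not the het
    numerator).  ``pct_multistep`` is the share of het loci whose
    alleles differ by two or more units; it is NaN where a bin has no
    het locus.  ``nrup_per_nt`` is supported NRUP events per assayed
    nucleotide.
    """
    records = []
    n_singleton_rep = n_singleton_snp = 0
    for gt in genotypes:
        loc = gt.locus
        assayed = gt.is_assayed
        records.append({
            "motif_size": loc.motif_size,
            "motif_class": motif_class_label(loc.motif),
            "repeat_number": loc.repeat_number,
            "assayed": int(assayed),
            "het": int(gt.is_het),
            "multistep": int(gt.status == HET_MULTISTEP),
            "discarded": int(gt.status == DISCARDED),
            "nrup": len(gt.nrup_calls) if assayed else 0,
            "nt": loc.array_length if assayed else 0,
        })
        n_singleton_rep += gt.n_singleton_repeat
        n_singleton_snp += gt.n_singleton_snp
    by_bin = _bin_frame(records, ["motif_size", "repeat_number"])
    by_class = _bin_frame(records, ["motif_class", "motif_size", "repeat_number"])
    n_total = len(genotypes)
    n_assayed = sum(r["assayed"] for r in records)
    n_het = sum(r["het"] for r in records)
    n_multi = sum(r["multistep"] for r in records)
    n_disc = sum(r["discarded"] for r in records)
    overall = {
        "n_total": n_total,
        "n_assayed": n_assayed,
        "n_het": n_het,
        "n_multistep": n_multi,
        "n_discarded": n_disc,
        "discard_frequency": n_disc / n_assayed if n_assayed else float("nan"),
        "pct_het": 100.0 * n_het / n_assayed if n_assayed else float("nan"),
        "pct_multistep": 100.0 * n_multi / n_het if n_het else float("nan"),
        "n_singleton_repeat": n_singleton_rep,
        "n_singleton_snp": n_singleton_snp,
    }
    return HetSummary(by_bin, by_class, overall)
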