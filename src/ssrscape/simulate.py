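"""Synthetic diploid genomes with planted SSR loci, reads, and truth.

The generator emulates the data situation of a shotgun-sequenced,
highly heterozygous diploid: a reference haplotype carrying planted
perfect repeat arrays in a background of the organism's base
composition, a second haplotype derived from it by repeat-slippage
events, and single-end shotgun reads sampled from both haplotypes and
emitted together with their true alignments to the reference (so the
genotyping stage can be exercised without an assembler or aligner).

Defaults follow the sequenced *Daphnia pulex* genotype: A+T fraction
0.59, 8.7x coverage, mean read length 774 nt.  The heterozygosity model
is a logistic increase of the per-locus unit-slippage probability with
repeat number, with motif-class ceilings ordered AC/AG > AT > GC for
dimers and G/C above A/T for homopolymers; the multistep share of
heterozygous loci rises with both repeat number and motif size, and
point interruptions (NRUPs) are placed with a configurable bias toward
the terminal repeat units.  Every probability is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .calling import Nrup, classify_nrup_position
from .catalog import SsrLocus
from .motifs import is_primitive, motif_class_label

_BASES = np.frombuffer(b"ATGC", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSpec:
    """Request for ``count`` loci of ``motif`` x ``repeat_number``."""

    motif: str
    repeat_number: int
    count: int
    scaffold: int | None = None   # pin to one scaffold, or spread round-robin


def default_planted() -> list[PlantedSpec]:
    """Planted bins spanning the motif sizes and repeat numbers assayed."""
    bins = [
        ("A", 8, 150), ("A", 10, 150), ("A", 12, 150),
        ("C", 8, 150), ("C", 10, 150), ("C", 12, 150),
        ("AC", 8, 120), ("AC", 10, 120), ("AC", 12, 120),
        ("AG", 10, 120), ("AT", 8, 120), ("GC", 8, 80),
        ("AAC", 6, 80), ("AAAT", 5, 60), ("AACTG", 4, 60),
    ]
    return [PlantedSpec(m, n, c) for m, n, c in bins]


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with field-realistic defaults."""

    seed: int = 0
    genome_length: int = 1_000_000
    scaffold_lengths: tuple[int, ...] | None = None   # default: one scaffold
    base_comp_a_t: float = 0.59
    planted: list[PlantedSpec] = field(default_factory=default_planted)

    # unit-slippage heterozygosity: ceiling[class] / (1 + e^{-slope (n - mid)})
    het_ceiling: dict[str, float] = field(default_factory=lambda: {
        "A": 0.10, "C": 0.25,                 # homopolymer classes A/T, G/C
        "AC": 0.32, "AG": 0.28, "AT": 0.22, "CG": 0.15,
    })
    het_ceiling_default: float = 0.20
    het_midpoint: float = 10.0
    het_slope: float = 0.45

    # multistep share of heterozygous loci
    multistep_base: float = 0.05
    multistep_per_repeat: float = 0.02       # per repeat unit above 4
    multistep_per_motif: float = 0.05        # per nt of motif size above 1
    multistep_max: float = 0.85
    multistep_geom_p: float = 0.6            # extra step size ~ 1 + Geom(p)

    # point interruptions
    nrup_rate_per_nt: float = 0.004
    nrup_end_bias: float = 0.8               # probability of a terminal unit

    # read model
    coverage: float = 8.7
    read_length_mean: float = 774.0
    read_length_sd: float = 150.0
    read_length_min: int = 100
    error_rate: float = 0.001                # substitutions only

    # collapsed-paralog emulation: extra reads from a third allele
    paralog_fraction: float = 0.0
    paralog_reads: int = 3
    paralog_delta: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.base_comp_a_t < 1:
            raise ValueError("base_comp_a_t must be in (0, 1)")
        for name in ("nrup_end_bias", "error_rate", "paralog_fraction",
                     "multistep_geom_p"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for spec in self.planted:
            if not is_primitive(spec.motif):
                raise ValueError(f"planted motif {spec.motif!r} is not primitive")
            if spec.repeat_number < 3 or spec.count < 0:
                raise ValueError("planted repeat_number must be >= 3, count >= 0")

    @property
    def scaffolds(self) -> tuple[int, ...]:
        return self.scaffold_lengths or (self.genome_length,)


def unit_het_prob(motif: str, repeat_number: int, config: SimConfig) -> float:
    """Per-locus probability of a unit-slippage heterozygote."""
    ceiling = config.het_ceiling.get(motif_class_label(motif),
                                     config.het_ceiling_default)
    return ceiling / (1.0 + math.exp(-config.het_slope *
                                     (repeat_number - config.het_midpoint)))


def multistep_prob(motif_size: int, repeat_number: int, config: SimConfig) -> float:
    """Probability that a heterozygote differs by two or more units."""
    p = (config.multistep_base
         + config.multistep_per_repeat * max(0, repeat_number - 4)
         + config.multistep_per_motif * (motif_size - 1))
    return min(config.multistep_max, max(0.0, p))


@dataclass
class PlantedLocus:
    """Truth record for one planted array (reference coordinates)."""

    seq_id: str
    start: int
    end: int
    motif: str
    repeat_number: int
    delta_units: int = 0                      # haplotype B minus reference
    nrups: tuple[Nrup, ...] = ()
    paralog: bool = False

    @property
    def motif_size(self) -> int:
        return len(self.motif)

    @property
    def array_length(self) -> int:
        return self.end - self.start

    def as_locus(self) -> SsrLocus:
        return SsrLocus(self.seq_id, self.start, self.end, self.motif,
                        self.motif_size, self.repeat_number)


@dataclass
class SimTruth:
    """Everything the downstream checks need to score a run."""

    loci: list[PlantedLocus] = field(default_factory=list)
    # per-scaffold op list describing haplotype B vs the reference:
    # (op, ref_len, alt_len) with op in {'M','I','D'}
    hap_ops: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    read_origins: pd.DataFrame | None = None


def _scaffold_name(i: int) -> str:
    return f"scaffold_{i + 1}"


def _verify_planted(arr: np.ndarray, pos: int, end: int, motif: str) -> bool:
    """True when a local re-scan reports exactly the planted array.

    The window extends well past the maximal possible boundary
    chaining, so any background run bleeding into the array is seen.
    """
    from .catalog import find_ssrs
    w0 = max(0, pos - 48)
    w1 = min(len(arr), end + 48)
    window = arr[w0:w1].tobytes().decode("ascii")
    hit = False
    for loc in find_ssrs(window, min_repeats=3,
                         max_motif=max(10, 2 * len(motif))):
        a, b = loc.start + w0, loc.end + w0
        if a < end and b > pos:              # overlaps the planted span
            if (a, b, loc.motif) == (pos, end, motif):
                hit = True
            else:
                return False
    return hit


def generate_reference(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Background sequence at the configured base composition with
    planted loci at evenly spaced, recorded coordinates.

    The bases immediately flanking each planted array are constrained so
    the array can neither merge with the background nor shift its start:
    they differ from both the first and the last motif base.  Because a
    background repeat can still chain across the boundary (e.g. a TA run
    abutting an AC array), every planted locus is verified by a local
    re-scan and its guard bases are redrawn until the scan reports the
    planted coordinates exactly.
    """
    rng = np.random.default_rng(config.seed)
    at = config.base_comp_a_t
    probs = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]   # A T G C
    per_scaffold: list[list[tuple[str, int]]] = [[] for _ in config.scaffolds]
    spread_i = 0
    for spec in config.planted:
        for _ in range(spec.count):
            tgt = spec.scaffold if spec.scaffold is not None else spread_i
            per_scaffold[tgt % len(per_scaffold)].append(
                (spec.motif, spec.repeat_number))
            spread_i += 1
    refs: dict[str, str] = {}
    truth = SimTruth()
    max_m = max([len(s.motif) for s in config.planted], default=1)
    for si, length in enumerate(config.scaffolds):
        sid = _scaffold_name(si)
        arr = _BASES[rng.choice(4, size=length, p=probs)]
        plan = per_scaffold[si]
        if plan:
            widest = max(len(m) * n for m, n in plan)
            slot = length // (len(plan) + 1)
            if slot < widest + 4 * max_m + 2:
                raise ValueError("planted loci exceed genome_length: "
                                 "increase the genome or plant fewer loci")
            for j, (motif, rep) in enumerate(plan):
                pos = (j + 1) * slot
                unit = np.frombuffer(motif.encode(), dtype=np.uint8)
                arr[pos:pos + len(motif) * rep] = np.tile(unit, rep)
                end = pos + len(motif) * rep
                allowed = [b for b in "ACGT" if b not in {motif[0], motif[-1]}]
                arr[pos - 1] = ord(allowed[int(rng.integers(len(allowed)))])
                arr[end] = ord(allowed[int(rng.integers(len(allowed)))])
                for attempt in range(200):
                    if _verify_planted(arr, pos, end, motif):
                        break
                    # redraw the guard bases next to both boundaries
                    for g in range(2, 5):
                        if pos - g >= 0:
                            arr[pos - g] = _BASES[int(rng.integers(4))]
                        if end + g - 1 < length:
                            arr[end + g - 1] = _BASES[int(rng.integers(4))]
                    arr[pos - 1] = ord(allowed[int(rng.integers(len(allowed)))])
                    arr[end] = ord(allowed[int(rng.integers(len(allowed)))])
                else:
                    raise RuntimeError("could not isolate a planted locus")
                truth.loci.append(PlantedLocus(sid, pos, end, motif, rep))
        refs[sid] = arr.tobytes().decode("ascii")
    truth.loci.sort(key=lambda l: (l.seq_id, l.start))
    return refs, truth


def _draw_nrup(rng: np.random.Generator, locus: PlantedLocus,
               config: SimConfig) -> Nrup:
    m, L = locus.motif_size, locus.array_length
    has_middle = L > 2 * m
    if not has_middle or rng.random() < config.nrup_end_bias:
        side_first = rng.random() < 0.5
        offset = int(rng.integers(0, m)) if side_first \
            else int(rng.integers(L - m, L))
    else:
        offset = int(rng.integers(m, L - m))
    ref_base = locus.motif[offset % m]
    alt = [b for b in "ACGT" if b != ref_base][int(rng.integers(3))]
    return Nrup("substitution", offset,
                classify_nrup_position(offset, locus.as_locus()), alt)


def diploidize(references: Mapping[str, str], truth: SimTruth,
               config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Derive haplotype B by mutating the planted loci.

    Per locus, a unit-slippage heterozygote occurs with the model
    probability (multistep with its own probability, step size
    1 + geometric, contraction never reducing the array below two
    units); loci left length-identical may instead receive a point
    interruption (end-biased substitution).  All events and the
    haplotype-B op structure are recorded in the truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    alts: dict[str, str] = {}
    for sid, ref in references.items():
        loci = [l for l in truth.loci if l.seq_id == sid]
        parts: list[str] = []
        ops: list[tuple[str, int, int]] = []

        def emit_match(n: int) -> None:
            if n <= 0:
                return
            if ops and ops[-1][0] == "M":
                ops[-1] = ("M", ops[-1][1] + n, ops[-1][2] + n)
            else:
                ops.append(("M", n, n))

        cursor = 0
        for li, locus in enumerate(loci):
            emit_match(locus.start - cursor)
            parts.append(ref[cursor:locus.start])
            rep, m = locus.repeat_number, locus.motif_size
            delta = 0
            nrups: tuple[Nrup, ...] = ()
            if rng.random() < unit_het_prob(locus.motif, rep, config):
                step = 1
                if rng.random() < multistep_prob(m, rep, config):
                    step = 2 + int(rng.geometric(config.multistep_geom_p)) - 1
                sign = 1 if rng.random() < 0.5 else -1
                if sign < 0 and rep - step < 2:
                    sign = 1
                delta = sign * step
            elif rng.random() < min(1.0, config.nrup_rate_per_nt *
                                    locus.array_length):
                nrups = (_draw_nrup(rng, locus, config),)
            alt_seq = locus.motif * (rep + delta)
            if nrups:
                chars = list(alt_seq)
                for nv in nrups:
                    chars[nv.offset] = nv.detail
                alt_seq = "".join(chars)
            a, b = locus.array_length, len(alt_seq)
            if b > a:
                ops.append(("I", 0, b - a))
                emit_match(a)
            elif b < a:
                ops.append(("D", a - b, 0))
                emit_match(b)
            else:
                emit_match(a)
            parts.append(alt_seq)
            truth.loci[truth.loci.index(locus)] = replace(
                locus, delta_units=delta, nrups=nrups)
            cursor = locus.end
        emit_match(len(ref) - cursor)
        parts.append(ref[cursor:])
        alts[sid] = "".join(parts)
        truth.hap_ops[sid] = ops
    return alts, truth


def _alt_cigar(ops: list[tuple[str, int, int]], s: int, e: int
               ) -> tuple[int, list[tuple[int, int]]]:
    """SAM position and cigar for haplotype-B interval [s, e)."""
    cig: list[tuple[int, int]] = []
    ref_pos = None
    ref_cursor = alt_cursor = 0
    for op, rl, al in ops:
        if alt_cursor >= e:
            break
        if op == "D":
            if cig:                      # interior deletion
                cig.append((2, rl))
            ref_cursor += rl
            continue
        lo = max(s, alt_cursor)
        hi = min(e, alt_cursor + al)
        if hi > lo:
            off = lo - alt_cursor
            take = hi - lo
            if op == "M":
                if ref_pos is None:
                    ref_pos = ref_cursor + off
                cig.append((0, take))
            else:                        # I
                cig.append((1 if ref_pos is not None else 4, take))
        ref_cursor += rl
        alt_cursor += al
    # drop a dangling interior deletion, soft-clip a trailing insertion
    while cig and cig[-1][0] == 2:
        cig.pop()
    if cig and cig[-1][0] == 1:
        cig[-1] = (4, cig[-1][1])
    if ref_pos is None:
        raise ValueError("read lies entirely within an insertion")
    # merge adjacent identical ops
    merged: list[tuple[int, int]] = []
    for op_i, ln in cig:
        if merged and merged[-1][0] == op_i:
            merged[-1] = (op_i, merged[-1][1] + ln)
        else:
            merged.append((op_i, ln))
    return ref_pos, merged


def _apply_errors(rng: np.random.Generator, seq: str, rate: float
                  ) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    n_err = int(rng.binomial(len(seq), rate))
    if n_err == 0:
        return seq, 0
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        p = int(p)
        chars[p] = [b for b in "ACGT" if b != chars[p]][int(rng.integers(3))]
    return "".join(chars), n_err


def simulate_reads(references: Mapping[str, str],
                   haplotype_b: Mapping[str, str],
                   truth: SimTruth,
                   config: SimConfig,
                   fastq_path,
                   sam_path) -> pd.DataFrame:
    """Sample single-end shotgun reads from both haplotypes.

    Reads are uniform over the genome at the configured coverage, with
    N(mean, sd) lengths and substitution errors; each read is written to
    FASTQ and, with its true alignment to the reference haplotype, to a
    plain SAM.  Returns the read-origin table (also stored on the
    truth object).
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sids = list(references)
    ref_lens = np.array([len(references[s]) for s in sids], dtype=float)
    total = ref_lens.sum()
    n_reads = int(round(config.coverage * total / config.read_length_mean))
    sc_probs = ref_lens / total
    header = pysam.AlignmentHeader.from_references(
        sids, [len(references[s]) for s in sids])
    origins = []
    with open(fastq_path, "w") as fq, \
            pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
        for i in range(n_reads):
            si = int(rng.choice(len(sids), p=sc_probs))
            sid = sids[si]
            hap = int(rng.integers(2))
            src = references[sid] if hap == 0 else haplotype_b[sid]
            length = int(np.clip(rng.normal(config.read_length_mean,
                                            config.read_length_sd),
                                 config.read_length_min, len(src)))
            start = int(rng.integers(0, len(src) - length + 1))
            seq, n_err = _apply_errors(rng, src[start:start + length],
                                       config.error_rate)
            name = f"read{i:07d}"
            if hap == 0:
                pos, cig = start, [(0, length)]
            else:
                pos, cig = _alt_cigar(truth.hap_ops[sid], start, start + length)
            _write_read(fq, sam, header, name, sid, seq, pos, cig)
            origins.append({"read_id": name, "seq_id": sid, "hap": hap,
                            "src_start": start, "length": length,
                            "n_errors": n_err})
        origins += _paralog_reads(rng, references, truth, config, fq, sam, header)
    truth.read_origins = pd.DataFrame(origins)
    return truth.read_origins


def _write_read(fq, sam, header, name, sid, seq, pos, cig) -> None:
    fq.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = 0
    a.reference_id = header.get_tid(sid)
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigartuples = cig
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    sam.write(a)


def _paralog_reads(rng, references, truth: SimTruth, config: SimConfig,
                   fq, sam, header) -> list[dict]:
    """Extra reads from a divergent third allele at selected loci,
    emulating a collapsed paralogous copy mapping onto the locus."""
    if config.paralog_fraction <= 0:
        return []
    het = [l for l in truth.loci if l.delta_units != 0]
    pool = het if het else truth.loci
    n_sel = max(1, int(round(config.paralog_fraction * len(truth.loci))))
    sel = pool[:n_sel]
    origins = []
    counter = 0
    for locus in sel:
        d = config.paralog_delta
        while d in (0, locus.delta_units):
            d += 1
        ref = references[locus.seq_id]
        idx = truth.loci.index(locus)
        truth.loci[idx] = replace(locus, paralog=True)
        alt = locus.motif * (locus.repeat_number + d)
        pad = 20
        for _ in range(config.paralog_reads):
            length = int(np.clip(rng.normal(config.read_length_mean,
                                            config.read_length_sd),
                                 config.read_length_min, len(ref)))
            lo = max(0, locus.end + pad - (length - d * locus.motif_size))
            hi = max(lo + 1, min(locus.start - pad, len(ref) - length))
            s = int(rng.integers(lo, hi))
            left = ref[s:locus.start]
            right_len = length - len(left) - len(alt)
            if right_len < pad:
                right_len = pad
            right = ref[locus.end:locus.end + right_len]
            seq = left + alt + right
            seq, n_err = _apply_errors(rng, seq, config.error_rate)
            cig = [(0, len(left))]
            if d > 0:
                cig += [(1, d * locus.motif_size), (0, locus.array_length + len(right))]
            else:
                cig += [(0, len(alt)), (2, -d * locus.motif_size), (0, len(right))]
            name = f"paralog{counter:05d}"
            counter += 1
            _write_read(fq, sam, header, name, locus.seq_id, seq, s, cig)
            origins.append({"read_id": name, "seq_id": locus.seq_id, "hap": 2,
                            "src_start": s, "length": len(seq),
                            "n_errors": n_err})
    return origins


def generate_map(truth: SimTruth, config: SimConfig,
                 scaffold_lengths: Mapping[str, int],
                 mode: str = "independent",
                 n_intervals: int = 40,
                 seed: int | None = None,
                 base_rate: float = 1.0,
                 coupling: float = 0.05,
                 noise_sd: float = 0.3,
                 min_motif_size: int = 2) -> pd.DataFrame:
    """Genetic-map intervals tiling the genome.

    ``mode='independent'`` draws each interval's map distance without
    reference to SSR content (null for the density/recombination
    regression); ``mode='coupled'`` sets the rate to
    ``base_rate + coupling * density`` plus noise, giving a planted
    positive correlation.  Rates are in cM/Mb; ``cm = rate * span``.
    """
    if mode not in ("independent", "coupled"):
        raise ValueError(f"unknown map mode {mode!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 3]))
    total = sum(scaffold_lengths.values())
    rows = []
    for sid, length in scaffold_lengths.items():
        k = max(1, int(round(n_intervals * length / total)))
        bounds = np.linspace(0, length, k + 1).astype(int)
        starts = [l.start for l in truth.loci
                  if l.seq_id == sid and l.motif_size >= min_motif_size]
        starts = np.sort(np.array(starts, dtype=int))
        for a, b in zip(bounds[:-1], bounds[1:]):
            span_mb = (b - a) / 1e6
            dens = (np.searchsorted(starts, b) - np.searchsorted(starts, a)) / span_mb
            if mode == "independent":
                rate = rng.gamma(2.0, base_rate / 2.0)
            else:
                rate = base_rate + coupling * dens + rng.normal(0, noise_sd)
            rate = max(rate, 0.01)
            rows.append({"seq_id": sid, "phys_start": int(a),
                         "phys_end": int(b), "cm": rate * span_mb})
    return pd.DataFrame(rows)
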