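"""Readers and writers for the pipeline's plain-text interchange formats.

Catalogue: BED-style TSV (seq_id, start, end, motif, motif_size,
repeat_number).  Genotypes: one locus per line with status, alleles and
NRUP calls.  Genetic map: TSV of (seq_id, phys_start, phys_end, cm).
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import LocusGenotype, Nrup
from .catalog import CatalogSummary, SsrLocus
from .stats import MapInterval

CATALOG_COLUMNS = ["seq_id", "start", "end", "motif", "motif_size", "repeat_number"]


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_catalog(loci: Iterable[SsrLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for l in loci:
            fh.write(f"{l.seq_id}\t{l.start}\t{l.end}\t{l.motif}"
                     f"\t{l.motif_size}\t{l.repeat_number}\n")


def read_catalog(path) -> list[SsrLocus]:
    df = pd.read_csv(path, sep="\t")
    return [SsrLocus(r.seq_id, int(r.start), int(r.end), r.motif,
                     int(r.motif_size), int(r.repeat_number))
            for r in df.itertuples()]


def write_summary(summary: CatalogSummary, path_json, path_tsv=None) -> None:
    payload = {
        "total_loci": summary.total_loci,
        "bases_covered": summary.bases_covered,
        "genome_size": summary.genome_size,
        "fraction_covered": summary.fraction_covered,
        "counts_by_motif_size": {str(k): v for k, v in
                                 sorted(summary.counts_by_motif_size.items())},
    }
    with open(path_json, "w") as fh:
        json.dump(payload, fh, indent=2)
    if path_tsv is not None:
        rows = [{"motif": m, "count": c}
                for m, c in sorted(summary.counts_by_motif.items())]
        pd.DataFrame(rows).to_csv(path_tsv, sep="\t", index=False)


def _fmt_nrup(n: Nrup, support: int) -> str:
    return f"{n.kind}:{n.offset}:{n.position_class}:{n.detail}:{support}"


def write_genotypes(genotypes: Sequence[LocusGenotype], path) -> None:
    cols = CATALOG_COLUMNS + ["status", "alleles", "nrups",
                              "depth_min", "depth_max", "n_observations",
                              "n_singleton_repeat", "n_singleton_snp"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for g in genotypes:
            l = g.locus
            alleles = ",".join(f"{d:+d}x{c}" for d, c in g.alleles) or "."
            nrups = ",".join(_fmt_nrup(n, c) for n, c in g.nrup_calls) or "."
            fh.write(f"{l.seq_id}\t{l.start}\t{l.end}\t{l.motif}"
                     f"\t{l.motif_size}\t{l.repeat_number}\t{g.status}"
                     f"\t{alleles}\t{nrups}\t{g.depth_range[0]}"
                     f"\t{g.depth_range[1]}\t{g.n_observations}"
                     f"\t{g.n_singleton_repeat}\t{g.n_singleton_snp}\n")


def write_map(map_df: pd.DataFrame, path) -> None:
    map_df.to_csv(path, sep="\t", index=False)


def read_map(path) -> list[MapInterval]:
    df = pd.read_csv(path, sep="\t")
    return [MapInterval(r.seq_id, int(r.phys_start), int(r.phys_end), float(r.cm))
            for r in df.itertuples()]
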