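"""End-to-end orchestration: simulate -> catalog -> genotype -> stats.

The pipeline writes every stage's artefacts to one output directory as
plain text: FASTA/FASTQ/SAM for the synthetic data, a BED-style
catalogue, per-locus genotypes, binned heterozygosity tables, the
starting-preference and end/middle bias tables, per-scaffold abundance
flags, heterozygosity-vs-repeat-number curve fits, and the
density/recombination regression.  Runs are deterministic given the
seed in the configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from .calling import genotype_catalog, summarize_heterozygosity
from .catalog import (catalog_genome, composition_expectation_test,
                      homopolymer_split)
from .motifs import motif_class_members
from .simulate import (PlantedSpec, SimConfig, diploidize, generate_map,
                       generate_reference, simulate_reads)
from .stats import (density_recombination_correlation, end_middle_expected,
                    end_middle_test, scaffold_abundance_flags,
                    select_het_model, starting_preference_test)

log = logging.getLogger("ssrscape")


@dataclass
class RunConfig:
    """Validated configuration of a full synthetic run."""

    out_dir: Path
    sim: SimConfig = field(default_factory=SimConfig)
    min_repeats: int = 3
    max_motif: int = 100
    flank: int = 5
    min_identity: float = 0.90
    min_depth: int = 4
    max_depth: int = 16
    min_support: int = 2
    map_mode: str = "coupled"
    map_intervals: int = 40

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = dict(raw.get("simulate", {}))
        if "planted" in sim_raw:
            sim_raw["planted"] = [PlantedSpec(str(m), int(n), int(c))
                                  for m, n, c in sim_raw["planted"]]
        if "scaffold_lengths" in sim_raw and sim_raw["scaffold_lengths"]:
            sim_raw["scaffold_lengths"] = tuple(sim_raw["scaffold_lengths"])
        if "seed" in raw:
            sim_raw["seed"] = int(raw["seed"])
        sim = SimConfig(**sim_raw)
        cat = raw.get("catalog", {})
        gt = raw.get("genotype", {})
        mp = raw.get("map", {})
        return cls(
            out_dir=Path(raw.get("out_dir", "ssrscape_out")),
            sim=sim,
            min_repeats=int(cat.get("min_repeats", 3)),
            max_motif=int(cat.get("max_motif", 100)),
            flank=int(gt.get("flank", 5)),
            min_identity=float(gt.get("min_identity", 0.90)),
            min_depth=int(gt.get("min_depth", 4)),
            max_depth=int(gt.get("max_depth", 16)),
            min_support=int(gt.get("min_support", 2)),
            map_mode=str(mp.get("mode", "coupled")),
            map_intervals=int(mp.get("n_intervals", 40)),
        )


def _setup_logging(out: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.FileHandler(out / "run.log", mode="w"),
              logging.StreamHandler()):
        h.setFormatter(fmt)
        log.addHandler(h)


def _class_tables(counts_by_motif: dict[str, int]) -> pd.DataFrame:
    """Starting-preference table over dimer and trimer classes."""
    rows = []
    seen: set[str] = set()
    for motif, _ in sorted(counts_by_motif.items()):
        if len(motif) not in (2, 3) or motif in seen:
            continue
        cls = motif_class_members(motif)
        seen |= cls.members
        member_counts = {m: counts_by_motif.get(m, 0)
                         for m in sorted(cls.members)}
        if sum(member_counts.values()) == 0:
            continue
        res = starting_preference_test(member_counts)
        for m in sorted(cls.members):
            rows.append({"class": cls.label, "motif_size": len(motif),
                         "motif": m, "observed": member_counts[m],
                         "expected": res.expected[m],
                         "chi2": res.statistic, "p_value": res.p_value})
    return pd.DataFrame(rows)


def _end_middle_table(genotypes) -> pd.DataFrame:
    """End/middle NRUP counts vs. random placement, by motif size
    (homopolymers and dimers) and repeat number."""
    tallies: dict[tuple[int, int], list[int]] = {}
    for g in genotypes:
        if not g.is_assayed:
            continue
        key0 = (g.locus.motif_size, g.locus.repeat_number)
        for nrup, _support in g.nrup_calls:
            t = tallies.setdefault(key0, [0, 0])
            t[0 if nrup.position_class == "end" else 1] += 1
    rows = []
    for (msize, rep), (end_o, mid_o) in sorted(tallies.items()):
        if msize > 2:
            continue
        end_e, mid_e = end_middle_expected(rep, end_o + mid_o)
        stat, p = end_middle_test(end_o, mid_o, rep)
        rows.append({"motif_size": msize, "repeat_number": rep,
                     "end_obs": end_o, "middle_obs": mid_o,
                     "end_exp": end_e, "middle_exp": mid_e,
                     "chi2": stat, "p_value": p})
    return pd.DataFrame(rows)


def _curve_fit_table(by_bin: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for msize, grp in by_bin.groupby("motif_size"):
        pts = [(r.repeat_number, r.pct_het) for r in grp.itertuples()
               if r.n_assayed >= 10 and pd.notna(r.pct_het) and r.pct_het > 0]
        if len(pts) < 3:
            continue
        fit = select_het_model(pts)
        rows.append({"motif_size": msize, "model": fit.model,
                     "slope": fit.slope, "intercept": fit.intercept,
                     "r2": fit.r2, "p_value": fit.p_value, "n": fit.n})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a bundle of result objects/paths.

    Raises on the first stage failure; partial outputs are overwritten
    on rerun, never reused.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    t0 = time.time()
    bundle: dict = {"out_dir": out}

    log.info("stage simulate: genome=%d nt, coverage=%.1fx",
             sum(config.sim.scaffolds), config.sim.coverage)
    refs, truth = generate_reference(config.sim)
    alts, truth = diploidize(refs, truth, config.sim)
    _io.write_fasta(refs, out / "reference.fasta")
    _io.write_fasta(alts, out / "haplotype_b.fasta")
    origins = simulate_reads(refs, alts, truth, config.sim,
                             out / "reads.fastq", out / "alignments.sam")
    origins.to_csv(out / "read_origins.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame([{
        "seq_id": l.seq_id, "start": l.start, "end": l.end,
        "motif": l.motif, "repeat_number": l.repeat_number,
        "delta_units": l.delta_units,
        "nrups": ";".join(f"{n.kind}:{n.offset}:{n.position_class}:{n.detail}"
                          for n in l.nrups) or ".",
        "paralog": int(l.paralog)} for l in truth.loci])
    truth_df.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
    scaffold_lengths = {sid: len(s) for sid, s in refs.items()}
    map_df = generate_map(truth, config.sim, scaffold_lengths,
                          mode=config.map_mode,
                          n_intervals=config.map_intervals)
    _io.write_map(map_df, out / "genetic_map.tsv")
    bundle["truth"] = truth

    log.info("stage catalog: min_repeats=%d max_motif=%d",
             config.min_repeats, config.max_motif)
    loci, summary = catalog_genome(refs.items(), min_repeats=config.min_repeats,
                                   max_motif=config.max_motif)
    _io.write_catalog(loci, out / "catalog.tsv")
    _io.write_summary(summary, out / "catalog_summary.json",
                      out / "catalog_motifs.tsv")
    at, gc = homopolymer_split(summary)
    if at + gc:
        comp = composition_expectation_test(at, gc, config.sim.base_comp_a_t)
        with open(out / "composition_test.json", "w") as fh:
            json.dump({"observed_a_t": at, "observed_g_c": gc,
                       "expected_a_t": comp.expected_a_t,
                       "statistic": comp.statistic, "p_value": comp.p_value,
                       "method": comp.method}, fh, indent=2)
    bundle["catalog"] = loci
    bundle["summary"] = summary
    log.info("catalogued %d loci covering %.1f%% of %d nt",
             summary.total_loci, 100 * summary.fraction_covered,
             summary.genome_size)

    log.info("stage genotype: depth window [%d,%d], min support %d",
             config.min_depth, config.max_depth, config.min_support)
    genotypes = genotype_catalog(out / "alignments.sam", loci, refs,
                                 flank=config.flank,
                                 min_identity=config.min_identity,
                                 min_depth=config.min_depth,
                                 max_depth=config.max_depth,
                                 min_support=config.min_support)
    _io.write_genotypes(genotypes, out / "genotypes.tsv")
    het = summarize_heterozygosity(genotypes)
    het.by_bin.to_csv(out / "het_by_bin.tsv", sep="\t", index=False)
    het.by_class.to_csv(out / "het_by_class.tsv", sep="\t", index=False)
    with open(out / "het_overall.json", "w") as fh:
        json.dump(het.overall, fh, indent=2)
    bundle["genotypes"] = genotypes
    bundle["het"] = het
    log.info("assayed %d/%d loci; %.2f%% het; %d discarded as multiallelic",
             het.overall["n_assayed"], het.overall["n_total"],
             het.overall["pct_het"] or 0.0, het.overall["n_discarded"])

    log.info("stage stats")
    table1 = _class_tables(summary.counts_by_motif)
    table1.to_csv(out / "starting_preference.tsv", sep="\t", index=False)
    table2 = _end_middle_table(genotypes)
    table2.to_csv(out / "end_middle_bias.tsv", sep="\t", index=False)
    fits = _curve_fit_table(het.by_bin)
    fits.to_csv(out / "het_curve_fits.tsv", sep="\t", index=False)
    flag_rows = []
    if len(scaffold_lengths) >= 2:
        groups = {str(ms): [ms, ms] for ms in range(1, 7)}
        groups["2-6"] = [2, 6]
        n_tests = len(scaffold_lengths) * len(groups)
        for gname, (lo_m, hi_m) in groups.items():
            counts = {sid: 0 for sid in scaffold_lengths}
            for l in loci:
                if lo_m <= l.motif_size <= hi_m:
                    counts[l.seq_id] += 1
            for f in scaffold_abundance_flags(counts, scaffold_lengths,
                                              n_tests=n_tests):
                flag_rows.append({"scaffold": f.seq_id, "motif_sizes": gname,
                                  "observed": f.observed,
                                  "expected": f.expected,
                                  "p_adjusted": f.p_value, "flag": f.flag})
    pd.DataFrame(flag_rows).to_csv(out / "scaffold_flags.tsv",
                                   sep="\t", index=False)
    intervals = _io.read_map(out / "genetic_map.tsv")
    fit, per_interval = density_recombination_correlation(loci, intervals,
                                                          min_motif_size=2)
    per_interval.to_csv(out / "recombination_intervals.tsv",
                        sep="\t", index=False)
    with open(out / "recombination_regression.json", "w") as fh:
        json.dump({"model": fit.model, "slope": fit.slope,
                   "intercept": fit.intercept, "r2": fit.r2,
                   "p_value": fit.p_value, "n": fit.n}, fh, indent=2)
    bundle["recombination_fit"] = fit
    log.info("density/recombination: slope=%.3f r2=%.3f p=%.3g",
             fit.slope, fit.r2, fit.p_value)
    log.info("pipeline complete in %.1f s", time.time() - t0)
    return bundle
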