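"""Shared fixtures: synthetic runs at two scales.

Everything is generated programmatically; nothing is read from disk
except files the fixtures themselves write to tmp directories.
"""

from __future__ import annotations

import pytest

from ssrscape.calling import genotype_catalog
from ssrscape.catalog import catalog_genome
from ssrscape.simulate import (SimConfig, PlantedSpec, diploidize,
                               generate_reference, simulate_reads)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """250 kb diploid with three planted bins, reads and genotypes."""
    tmp = tmp_path_factory.mktemp("small_run")
    cfg = SimConfig(seed=7, genome_length=250_000,
                    planted=[PlantedSpec("A", 10, 80),
                             PlantedSpec("AC", 10, 80),
                             PlantedSpec("AG", 12, 60)])
    refs, truth = generate_reference(cfg)
    alts, truth = diploidize(refs, truth, cfg)
    fq, sam = tmp / "reads.fastq", tmp / "alignments.sam"
    simulate_reads(refs, alts, truth, cfg, fq, sam)
    genotypes = genotype_catalog(sam, [l.as_locus() for l in truth.loci], refs)
    return {"cfg": cfg, "refs": refs, "alts": alts, "truth": truth,
            "sam": sam, "fastq": fq, "genotypes": genotypes}


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """Default study conditions: 1 Mb diploid at 8.7x, fully genotyped.

    The whole reference is catalogued and every catalogued locus is
    genotyped, so planted bins can be evaluated inside a realistic
    background of incidental repeats.
    """
    tmp = tmp_path_factory.mktemp("full_run")
    cfg = SimConfig(seed=1)
    refs, truth = generate_reference(cfg)
    alts, truth = diploidize(refs, truth, cfg)
    fq, sam = tmp / "reads.fastq", tmp / "alignments.sam"
    simulate_reads(refs, alts, truth, cfg, fq, sam)
    loci, summary = catalog_genome(refs.items())
    genotypes = genotype_catalog(sam, loci, refs)
    return {"cfg": cfg, "refs": refs, "alts": alts, "truth": truth,
            "sam": sam, "loci": loci, "summary": summary,
            "genotypes": genotypes}
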