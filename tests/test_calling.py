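import numpy as np
import pytest

from ssrscape.calling import (DISCARDED, HET_MULTISTEP, HET_UNIT, HOMOZYGOUS,
                              UNASSAYABLE, AlleleObservation, Nrup, ParsedRead,
                              classify_nrup_position, compare_interior,
                              extract_locus_observations, genotype_catalog,
                              genotype_locus, summarize_heterozygosity)
from ssrscape.catalog import SsrLocus
from ssrscape.simulate import (SimConfig, PlantedSpec, diploidize,
                               generate_reference, simulate_reads)


def obs(n, delta, nrups=()):
    return [AlleleObservation(f"r{delta}_{i}", delta, tuple(nrups))
            for i in range(n)]


def hp(rep=7, seq_id="s"):
    return SsrLocus(seq_id, 100, 100 + rep, "A", 1, rep)


def dimer(rep=10, motif="GA", seq_id="s"):
    return SsrLocus(seq_id, 100, 100 + 2 * rep, motif, 2, rep)


DEPTH_OK = [8] * 64  # sliced to locus length where needed


class TestClassifyNrupPosition:
    @pytest.mark.parametrize("offset,locus,expected", [
        (0, hp(7), "end"),
        (6, hp(7), "end"),
        (3, hp(7), "middle"),
        (14, dimer(8), "end"),     # within the last unit of (GA)x8
        (1, dimer(8), "end"),
        (2, dimer(8), "middle"),
    ])
    def test_examples(self, offset, locus, expected):
        assert classify_nrup_position(offset, locus) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_nrup_position(7, hp(7))
        with pytest.raises(ValueError):
            classify_nrup_position(-1, hp(7))


class TestCompareInterior:
    def test_perfect_match(self):
        assert compare_interior("GA" * 10, dimer(10)) == (0, ())

    def test_unit_expansion_and_contraction(self):
        assert compare_interior("GA" * 11, dimer(10))[0] == 1
        assert compare_interior("GA" * 7, dimer(10))[0] == -3
        assert compare_interior("A" * 9, hp(7))[0] == 2

    def test_substitution_is_an_nrup_not_a_length_change(self):
        seq = list("A" * 10)
        seq[4] = "T"
        delta, nrups = compare_interior("".join(seq), hp(10))
        assert delta == 0
        assert nrups == (Nrup("substitution", 4, "middle", "T"),)

    def test_end_substitution(self):
        delta, nrups = compare_interior("T" + "A" * 9, hp(10))
        assert delta == 0
        assert nrups[0].position_class == "end"
        assert nrups[0].offset == 0

    def test_non_unit_indel_is_an_nrup(self):
        # one base inserted into a dimer array: length not a multiple of 2
        delta, nrups = compare_interior("GAGAG" + "T" + "AGAGA" + "GAGAGA",
                                        dimer(8))
        assert delta == 0
        assert len(nrups) == 1
        assert nrups[0].kind == "insertion"

    def test_indels_left_aligned(self):
        # deleting any single A from a homopolymer reports offset 0
        delta, nrups = compare_interior("A" * 6 + "CC" + "A" * 6,
                                        SsrLocus("s", 0, 14, "A", 1, 14))
        # interior shorter by 2 with CC substituting: alignment detail
        # aside, deletions inside the run must be pushed left
        for n in nrups:
            if n.kind == "deletion":
                assert n.offset == 0


class TestGenotypeLocus:
    def test_het_unit_from_supported_alleles(self):
        gt = genotype_locus(obs(6, 0) + obs(4, +1), hp(), [8] * 7)
        assert gt.status == HET_UNIT
        assert gt.alleles == [(0, 6), (1, 4)]

    def test_singleton_variant_not_an_allele(self):
        gt = genotype_locus(obs(7, 0) + obs(1, +2), hp(), [8] * 7)
        assert gt.status == HOMOZYGOUS
        assert gt.n_singleton_repeat == 1

    def test_three_supported_alleles_discarded(self):
        gt = genotype_locus(obs(4, 0) + obs(3, +1) + obs(3, -1), hp(), [10] * 7)
        assert gt.status == DISCARDED

    def test_multistep_by_two_or_more_units(self):
        gt = genotype_locus(obs(5, 0) + obs(4, +3), hp(), [9] * 7)
        assert gt.status == HET_MULTISTEP
        gt = genotype_locus(obs(5, -1) + obs(4, +1), hp(), [9] * 7)
        assert gt.status == HET_MULTISTEP

    def test_coverage_window_is_strict(self):
        assert genotype_locus(obs(3, 0), hp(), [3] * 7).status == UNASSAYABLE
        assert genotype_locus(obs(8, 0), hp(),
                              [8, 8, 8, 17, 8, 8, 8]).status == UNASSAYABLE
        assert genotype_locus(obs(4, 0), hp(), [4] * 7).status == HOMOZYGOUS
        assert genotype_locus(obs(8, 0), hp(), [16] * 7).status == HOMOZYGOUS

    def test_empty_observations_unassayable(self):
        assert genotype_locus([], hp(), [8] * 7).status == UNASSAYABLE

    def test_snp_states_capped_separately(self):
        # two supported alternate bases at one site -> 3 states -> discard
        n1 = Nrup("substitution", 3, "middle", "T")
        n2 = Nrup("substitution", 3, "middle", "G")
        gt = genotype_locus(obs(4, 0, [n1]) + obs(4, 0, [n2]) + obs(4, 0),
                            hp(), [12] * 7)
        assert gt.status == DISCARDED

    def test_supported_nrup_called(self):
        n1 = Nrup("substitution", 3, "middle", "T")
        gt = genotype_locus(obs(5, 0, [n1]) + obs(5, 0), hp(), [10] * 7)
        assert gt.status == HOMOZYGOUS
        assert gt.nrup_calls == [(n1, 5)]

    def test_observation_conservation(self):
        """supported + singleton reads = anchored observations."""
        gt = genotype_locus(obs(5, 0) + obs(2, 1) + obs(1, 2) + obs(1, -1),
                            hp(), [9] * 7)
        assert sum(c for _, c in gt.alleles) + gt.n_singleton_repeat \
            == gt.n_observations == 9

    def test_support_threshold_monotone(self):
        """Raising the read minimum never increases het calls."""
        rng = np.random.default_rng(0)
        n_het = {}
        for ms in (1, 2, 3):
            calls = 0
            for _ in range(300):
                reads = obs(int(rng.integers(2, 7)), 0) + \
                    obs(int(rng.integers(0, 4)), +1)
                g = genotype_locus(reads, hp(), [len(reads)] * 7
                                   if 4 <= len(reads) <= 16 else [3] * 7,
                                   min_support=ms)
                calls += g.is_het
            n_het[ms] = calls
        assert n_het[1] >= n_het[2] >= n_het[3]


class TestExtractObservations:
    def _read(self, ref, start, seq, cigar):
        ref_b = np.frombuffer(ref.encode(), dtype=np.uint8)
        return ParsedRead("r", "s", start, seq, cigar, ref_b)

    def test_expansion_read(self):
        left = "CGTTG"
        right = "TTGCC"
        ref = "C" * 95 + left + "GA" * 10 + right + "C" * 95
        locus = SsrLocus("s", 100, 120, "GA", 2, 10)
        read_seq = left + "GA" * 11 + right
        read = self._read(ref, 95, read_seq,
                          [(0, 5), (1, 2), (0, 25)])
        [ob] = extract_locus_observations([read], locus, ref)
        assert ob.delta_units == 1 and ob.nrups == ()

    def test_reference_identical_read(self):
        ref = "C" * 95 + "AGTCG" + "GA" * 10 + "CTGAT" + "C" * 95
        locus = SsrLocus("s", 100, 120, "GA", 2, 10)
        read = self._read(ref, 90, ref[90:140], [(0, 50)])
        [ob] = extract_locus_observations([read], locus, ref)
        assert ob.delta_units == 0

    def test_partial_span_or_mismatched_flank_skipped(self):
        ref = "C" * 95 + "AGTCG" + "GA" * 10 + "CTGAT" + "C" * 95
        locus = SsrLocus("s", 100, 120, "GA", 2, 10)
        short = self._read(ref, 98, ref[98:118], [(0, 20)])
        assert extract_locus_observations([short], locus, ref) == []
        bad_flank = ref[90:96] + "T" + ref[97:140]
        read = self._read(ref, 90, bad_flank, [(0, 50)])
        assert extract_locus_observations([read], locus, ref) == []

    def test_low_identity_skipped(self):
        ref = "C" * 95 + "AGTCG" + "GA" * 10 + "CTGAT" + "C" * 95
        locus = SsrLocus("s", 100, 120, "GA", 2, 10)
        seg = list(ref[90:140])
        for i in range(20, 31, 2):   # pepper mismatches outside the flanks
            seg[i] = "T" if seg[i] != "T" else "C"
        read = self._read(ref, 90, "".join(seg), [(0, 50)])
        assert extract_locus_observations([read], locus, ref,
                                          min_identity=0.95) == []


class TestAgainstSimulatedTruth:
    def test_error_free_diploid_recovers_planted_deltas(self, small_run):
        truth, gts = small_run["truth"], small_run["genotypes"]
        by_coord = {(g.locus.seq_id, g.locus.start): g for g in gts}
        checked = 0
        for tl in truth.loci:
            g = by_coord[(tl.seq_id, tl.start)]
            if not g.is_assayed or g.status == DISCARDED:
                continue
            called = sorted(d for d, _ in g.alleles)
            # at least 2 reads per haplotype are needed for both alleles
            support = sum(c for _, c in g.alleles) + g.n_singleton_repeat
            if tl.delta_units != 0 and g.status in (HET_UNIT, HET_MULTISTEP):
                assert called == sorted({0, tl.delta_units})
                checked += 1
            elif tl.delta_units == 0 and not tl.nrups:
                assert called == [0] or g.status == UNASSAYABLE
        assert checked > 5

    def test_homozygous_error_free_genome_has_no_calls(self, tmp_path):
        """Zero het and zero NRUP calls when the haplotypes are identical
        and reads are error-free."""
        cfg = SimConfig(seed=21, genome_length=120_000, error_rate=0.0,
                        het_ceiling={}, het_ceiling_default=0.0,
                        nrup_rate_per_nt=0.0,
                        planted=[PlantedSpec("A", 10, 40),
                                 PlantedSpec("AC", 10, 40)])
        refs, truth = generate_reference(cfg)
        alts, truth = diploidize(refs, truth, cfg)
        assert alts == refs
        sam = tmp_path / "a.sam"
        simulate_reads(refs, alts, truth, cfg, tmp_path / "r.fq", sam)
        gts = genotype_catalog(sam, [l.as_locus() for l in truth.loci], refs)
        assert all(not g.is_het for g in gts)
        assert all(not g.nrup_calls for g in gts)


class TestSummarize:
    def test_multistep_share_matches_hand_ratio(self):
        """17,544 het loci of which 2,129 multistep -> 12.14%."""
        gts = []
        locus = hp(12)
        for i in range(2129):
            gts.append(_gt(locus, HET_MULTISTEP))
        for i in range(17544 - 2129):
            gts.append(_gt(locus, HET_UNIT))
        s = summarize_heterozygosity(gts)
        assert round(s.overall["pct_multistep"], 2) == 12.14

    def test_empty_input(self):
        s = summarize_heterozygosity([])
        assert s.overall["n_total"] == 0
        assert s.by_bin.empty

    def test_bin_without_hets_has_no_multistep_fraction(self):
        s = summarize_heterozygosity([_gt(hp(5), HOMOZYGOUS)])
        row = s.by_bin.iloc[0]
        assert row.pct_het == 0.0
        assert np.isnan(row.pct_multistep)


def _gt(locus, status):
    from ssrscape.calling import LocusGenotype
    return LocusGenotype(locus, status, depth_range=(8, 8))
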