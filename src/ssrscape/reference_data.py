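"""Published *Daphnia pulex* SSR survey counts used for validation.

These are the printed observed counts from the genome-wide SSR survey
of the *D. pulex* assembly (motif sizes 1-100, minimum 3 perfect
repeats, ~8.7x shotgun coverage): per-motif locus counts for the dimer
and trimer starting-nucleotide tables, observed end/middle interruption
counts by repeat number, and the headline catalogue/heterozygosity
totals.  They serve as fixed inputs for re-deriving every quantity that
is a function of printed counts (class expectations, chi-square
p-values, multistep shares, the paralogy frequency); the genome-scale
counts themselves can only be regenerated from the real assembly and
trace reads.
"""

from __future__ import annotations

# ---- starting-nucleotide preference: observed per-motif locus counts ----

DIMER_COUNTS: dict[str, dict[str, int]] = {
    # class label -> member motif -> observed loci
    "AT": {"TA": 48814, "AT": 35558},
    "CG": {"GC": 8444, "CG": 6802},
    "AG": {"GA": 33951, "AG": 30185, "TC": 40029, "CT": 23511},
    "AC": {"AC": 33773, "CA": 26535, "TG": 35249, "GT": 24437},
}

TRIMER_COUNTS: dict[str, dict[str, int]] = {
    "AAC": {"AAC": 2728, "ACA": 2431, "CAA": 3380,
            "GTT": 2339, "TGT": 2657, "TTG": 3390},
    "ACT": {"ACT": 598, "CTA": 734, "TAC": 791,
            "AGT": 665, "TAG": 564, "GTA": 815},
    "AAG": {"AAG": 5734, "AGA": 3657, "GAA": 4278,
            "CTT": 3393, "TCT": 3692, "TTC": 6161},
    "AGC": {"AGC": 1839, "GCA": 2363, "CAG": 4131,
            "GCT": 3115, "TGC": 2725, "CTG": 2767},
    "AAT": {"AAT": 4099, "ATA": 2260, "TAA": 2406,
            "ATT": 3533, "TAT": 2233, "TTA": 3093},
    "AGG": {"AGG": 971, "GGA": 1222, "GAG": 988,
            "CCT": 905, "TCC": 1207, "CTC": 940},
    "ACC": {"ACC": 855, "CAC": 1057, "CCA": 1383,
            "GGT": 1034, "GTG": 921, "TGG": 1285},
    "ATC": {"ATC": 1153, "TCA": 1703, "CAT": 1342,
            "GAT": 1452, "TGA": 1661, "ATG": 1111},
    "ACG": {"ACG": 1229, "CGA": 1406, "GAC": 1561,
            "CGT": 1325, "TCG": 1267, "GTC": 1452},
    "CCG": {"CCG": 703, "CGC": 519, "GGC": 916,
            "CGG": 731, "GCG": 585, "GCC": 995},
}

# published (rounded) class expectations, for cross-checking
DIMER_EXPECTED = {"AT": 42186, "CG": 7623, "AG": 31919, "AC": 29999}
TRIMER_EXPECTED = {"AAC": 2821, "ACT": 695, "AAG": 4486, "AGC": 2823,
                   "AAT": 2937, "AGG": 1039, "ACC": 1089, "ATC": 1404,
                   "ACG": 1373, "CCG": 742}

# ---- interruption (NRUP) position by repeat number: observed counts ----
# repeat_number -> (end_obs, middle_obs); published expectations appended
# as (end_exp, middle_exp) for cross-checking.

HP_END_MIDDLE: dict[int, tuple[int, int]] = {
    3: (15005, 50), 4: (5793, 1392), 5: (2549, 1168), 6: (1309, 735),
    7: (810, 492), 8: (447, 294), 9: (459, 253), 10: (350, 285),
    11: (178, 191), 12: (119, 167), 13: (65, 121), 14: (45, 107),
    15: (34, 77), 16: (18, 43), 17: (12, 40), 18: (6, 28),
    19: (3, 23), 20: (6, 15),
}
HP_END_MIDDLE_EXPECTED: dict[int, tuple[int, int]] = {
    3: (10037, 5018), 4: (3593, 3593), 5: (1487, 2230), 6: (681, 1363),
    7: (372, 930), 8: (185, 556), 9: (158, 554), 10: (127, 508),
    11: (67, 302), 12: (48, 238), 13: (29, 157), 14: (22, 130),
    15: (15, 96), 16: (8, 53), 17: (6, 46), 18: (4, 30),
    19: (3, 23), 20: (2, 19),
}

DIMER_END_MIDDLE: dict[int, tuple[int, int]] = {
    3: (1588, 641), 4: (332, 208), 5: (121, 83), 6: (65, 61),
    7: (58, 53), 8: (47, 29), 9: (39, 30), 10: (17, 10),
    11: (11, 7), 12: (9, 7), 13: (7, 4),
}
DIMER_END_MIDDLE_EXPECTED: dict[int, tuple[int, int]] = {
    3: (1486, 743), 4: (270, 270), 5: (82, 122), 6: (42, 84),
    7: (32, 79), 8: (19, 57), 9: (15, 54), 10: (5, 22),
    11: (3, 15), 12: (3, 13), 13: (2, 9),
}

# ---- headline catalogue and heterozygosity totals ----

TOTAL_SSRS = 7_229_342
HOMOPOLYMER_LOCI = 6_726_771
DIMER_LOCI = 347_288
TRIMER_LOCI = 133_428
AT_HOMOPOLYMERS = 5_276_283
GC_HOMOPOLYMERS = 1_450_489
BASE_COMP_A_T = 0.59
ASSAYABLE_LOCI = 6_062_268
HET_LOCI = 23_360

# multistep shares: (multistep het loci, all het loci) per motif group
MULTISTEP_AT_HP = (2_129, 17_544)
MULTISTEP_GC_HP = (972, 3_547)
MULTISTEP_DIMER = (288, 1_353)
MULTISTEP_AC_AG_GT13 = (12, 23)      # AC/AG dimers with > 13 repeats

MULTIALLELIC_LOCI = 1_497            # 1220 SNP-state + 277 repeat-allele
MULTIALLELIC_SNP = 1_220
MULTIALLELIC_REPEAT = 277

SINGLETON_REPEAT = (966_758, 9_468_378)     # variant-singleton sites, reads
SINGLETON_SNP = (1_675_976, 15_642_919)
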