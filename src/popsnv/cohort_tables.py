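"""Worked-example summary counts from a 35-individual Korean whole-genome cohort.

These are the printed summary tables of a dual-pipeline SNV study of 35
Korean genomes compared against 1KGP and HapMap reference panels:
consensus and per-pipeline totals, the panel-partition counts, the
occurrence extremes of the population-only set, per-term consequence
category counts for five SNV groups, gene-involvement totals, and the
drug-association rows of the smallest stratum. They are bundled as
*inputs* for the package's reporting arithmetic (percentages, Ts/Tv,
non-synonymous fractions, BH adjustment), which the worked examples and
the acceptance script recompute from these counts at run time.

Column order of the category table: SNV-1 (population-only, occurrence
≥1), SNV-35 (population-only, fixed in all 35), shared with both panels,
shared with panel 1 (1KGP), shared with panel 1 or panel 2 (HapMap).
"""

from __future__ import annotations

from typing import Dict

# --- pipeline and partition totals -----------------------------------------

PIPELINE_TOTALS = {
    "pipeline_a": 9_119_633,   # BWA + SAMtools merged cohort sites
    "pipeline_b": 9_964_511,   # SOAP2 + SOAPsnp merged cohort sites
}
CONSENSUS_TOTAL = 8_555_726

PARTITION_COUNTS = {
    "shared_both": 2_677_812,
    "shared_panel1_only": 4_653_510,   # 1KGP only
    "shared_panel2_only": 10_791,      # HapMap only
    "population_only": 1_213_613,      # SNV-1
}

# --- occurrence stratification of the population-only set -------------------

POPULATION_ONLY_TOTAL = 1_213_613
SINGLETON_COUNT = 735_271      # occurrence = 1
FIXED_COUNT = 12_640           # occurrence = 35 (SNV-35)
COHORT_SIZE = 35

# --- gene involvement --------------------------------------------------------

GENES_TOTAL_SNV1 = 53_771
GENES_NONSYN_SNV1 = 5_754
GENES_TOTAL_SNV35 = 1_640
GENES_NONSYN_SNV35 = 37
NONSYN_VARIANTS_SNV1 = 8_361   # distinct-variant count
NONSYN_VARIANTS_SNV35 = 58

# --- consequence category counts (five SNV groups) ---------------------------

CATEGORY_SET_NAMES = (
    "snv1",
    "snv35",
    "shared_both",
    "shared_panel1",
    "shared_either",
)

_CATEGORY_ROWS = {
    "synonymous_variant":                (3_587,    29,     13_978,    25_988,    26_030),
    "missense_variant":                  (6_620,    40,     14_147,    26_835,    26_909),
    "stop_gained":                       (173,      1,      129,       343,       348),
    "stop_lost":                         (20,       0,      70,        105,       106),
    "stop_retained_variant":             (5,        0,      22,        45,        45),
    "initiator_codon_variant":           (18,       0,      62,        104,       104),
    "incomplete_terminal_codon_variant": (4,        0,      8,         16,        16),
    "coding_sequence_variant":           (5,        0,      15,        29,        29),
    "splice_donor_variant":              (162,      0,      226,       557,       562),
    "splice_acceptor_variant":           (95,       0,      165,       357,       359),
    "splice_region_variant":             (1_496,    18,     3_983,     8_298,     8_312),
    "5_prime_UTR_variant":               (3_358,    22,     8_462,     19_526,    19_568),
    "3_prime_UTR_variant":               (13_638,   99,     37_145,    76_397,    76_547),
    "regulatory_region_variant":         (117_783,  1_186,  267_822,   649_464,   650_799),
    "TF_binding_site_variant":           (1_645,    11,     2_511,     6_913,     6_927),
    "upstream_gene_variant":             (185_499,  2_010,  343_491,   989_954,   991_984),
    "downstream_gene_variant":           (192_188,  1_999,  370_173,   1_028_139, 1_030_243),
    "NMD_transcript_variant":            (127_138,  634,    287_027,   779_516,   780_572),
    "mature_miRNA_variant":              (48,       1,      20,        146,       146),
    "non_coding_exon_variant":           (28_539,   292,    62_513,    143_214,   143_617),
    "nc_transcript_variant":             (376_646,  4_590,  815_372,   2_191_354, 2_195_528),
    "intron_variant":                    (602_464,  5_272,  1_379_647, 3_703_303, 3_708_842),
    "intergenic_variant":                (462_916,  5_264,  1_030_973, 2_876_064, 2_879_598),
}

CATEGORY_SET_TOTALS = {
    "snv1": 1_213_613,
    "snv35": 12_640,
    "shared_both": 2_677_812,
    "shared_panel1": 7_331_322,
    "shared_either": 7_342_113,
}


def category_counts(set_name: str) -> Dict[str, int]:
    """Per-term category counts for one of the five SNV groups."""
    col = CATEGORY_SET_NAMES.index(set_name)
    return {term: row[col] for term, row in _CATEGORY_ROWS.items()}


# --- association-table rows (smallest stratum, drug terms) -------------------

# (term, gene count k, percent of category, raw p)
DRUG_TERM_ROWS_SNV35 = (
    ("mannitol", 2, 10.0, 8.23e-05),
    ("niflumic acid", 2, 10.0, 8.23e-05),
    ("adenosine monophosphate", 2, 1.961, 2.2e-03),
)
DRUG_TERM_ADJUSTED_PRINTED_SNV35 = (0.0001, 0.0001, 0.0022)

# disease-association row of the smallest stratum: k=3 of a 673-gene term
DISEASE_TERM_SNV35 = ("Nelson syndrome", 3, 673, 1.02e-02)

# genome-wide transition/transversion ratio of the consensus set
CONSENSUS_TSTV = 2.1
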