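import itertools
import math

import numpy as np
import pytest

from popsnv.model import COMPLEMENT, AnnotationRecord, GenomicPosition
from popsnv.spectrum import (
    NONSYN_TERMS,
    TRANSITION_CLASSES,
    UNCERTAIN,
    classify_consequence,
    classify_substitution,
    nonsyn_fraction,
    nonsyn_variants,
    snv_count_per_gene,
    spectrum_summary,
    tabulate_categories,
)


class TestClassifySubstitution:
    def test_c_to_t_is_cg_ta_transition(self):
        c = classify_substitution("C", ("T",))
        assert c.label == "C:G->T:A" and c.is_transition

    def test_strand_collapse_g_to_a(self):
        assert classify_substitution("G", ("A",)).label == "C:G->T:A"

    def test_multi_alt_is_uncertain(self):
        c = classify_substitution("A", ("C", "T"))
        assert c.label == UNCERTAIN and c.is_transition is None

    def test_ref_equals_alt_is_error(self):
        with pytest.raises(ValueError):
            classify_substitution("A", ("A",))

    @pytest.mark.parametrize(
        "ref,alt", [(r, a) for r, a in itertools.product("ACGT", "ACGT") if r != a]
    )
    def test_complement_symmetry_all_12_pairs(self, ref, alt):
        direct = classify_substitution(ref, (alt,))
        comp = classify_substitution(COMPLEMENT[ref], (COMPLEMENT[alt],))
        assert direct == comp

    def test_exactly_two_transition_classes(self):
        labels = {
            classify_substitution(r, (a,)).label
            for r, a in itertools.product("ACGT", "ACGT")
            if r != a
        }
        assert len(labels) == 6
        assert {l for l in labels if classify_substitution(
            l[0], (l[5],)).is_transition} == TRANSITION_CLASSES


class TestSpectrumSummary:
    def test_ratio_definition(self):
        sites = [("C", ("T",))] * 21 + [("C", ("A",))] * 10
        summ = spectrum_summary(sites)
        assert summ.ts_tv_ratio == pytest.approx(2.1)
        assert summ.counts["C:G->T:A"] == 21

    def test_all_one_class(self):
        summ = spectrum_summary([("C", ("T",))] * 5)
        assert summ.fractions["C:G->T:A"] == 1.0

    def test_counts_sum_to_total_with_uncertain(self):
        sites = [("C", ("T",)), ("A", ("C", "T")), ("G", ("C",))]
        summ = spectrum_summary(sites)
        assert sum(summ.counts.values()) == summ.total == 3
        assert summ.counts[UNCERTAIN] == 1
        # uncertain sites are excluded from Ts/Tv
        assert summ.n_transitions + summ.n_transversions == 2

    def test_zero_transversions_is_infinity(self):
        assert math.isinf(spectrum_summary([("C", ("T",))]).ts_tv_ratio)

    def test_binomial_recovery(self):
        rng = np.random.default_rng(0)
        ts_fraction, n = 0.7, 100_000
        is_ts = rng.random(n) < ts_fraction
        sites = [("C", ("T",)) if t else ("C", ("A",)) for t in is_ts]
        summ = spectrum_summary(sites)
        p_hat = summ.n_transitions / n
        se = math.sqrt(ts_fraction * (1 - ts_fraction) / n)
        assert abs(p_hat - ts_fraction) < 3 * se
        assert abs(summ.ts_tv_ratio - 7 / 3) < 3 * se / (1 - ts_fraction) ** 2


class TestClassifyConsequence:
    @pytest.mark.parametrize("term", NONSYN_TERMS)
    def test_each_nonsyn_label(self, term):
        assert classify_consequence((term,)) == "non_synonymous"

    def test_precedence_and_other(self):
        assert classify_consequence(("missense_variant", "synonymous_variant")) == "non_synonymous"
        assert classify_consequence(("synonymous_variant",)) == "synonymous"
        assert classify_consequence(("intron_variant",)) == "other"


def ann(pos, terms, gene=None, alt="G"):
    return AnnotationRecord(GenomicPosition("1", pos), alt, tuple(terms), gene)


class TestCategoryTable:
    def test_multi_term_variant_counts_in_each_category(self):
        positions = {GenomicPosition("1", 10)}
        table = tabulate_categories(
            positions, [ann(10, ("intron_variant", "regulatory_region_variant"))]
        )
        assert table.count("intron_variant") == 1
        assert table.count("regulatory_region_variant") == 1
        # column sums may exceed the set total
        assert sum(table.counts.values()) == 2 > table.set_total == 1

    def test_variant_level_dedup_vs_category_level(self):
        positions = {GenomicPosition("1", 10)}
        annotations = [ann(10, ("missense_variant", "splice_region_variant"))]
        table = tabulate_categories(positions, annotations)
        # category level: both terms counted
        assert table.count("missense_variant") == 1
        assert table.count("splice_region_variant") == 1
        # variant level: one non-synonymous variant, no double count
        assert len(nonsyn_variants(positions, annotations)) == 1

    def test_empty_set_all_zero(self):
        table = tabulate_categories(set(), [])
        assert table.set_total == 0 and all(v == 0 for v in table.counts.values())

    def test_unannotated_row(self):
        positions = {GenomicPosition("1", 10), GenomicPosition("1", 20)}
        table = tabulate_categories(positions, [ann(10, ("intron_variant",))])
        assert table.n_unannotated == 1

    def test_percentages_use_set_total(self):
        positions = {GenomicPosition("1", p) for p in (10, 20, 30, 40)}
        table = tabulate_categories(positions, [ann(10, ("intron_variant",))])
        row = table.table.set_index("term").loc["intron_variant"]
        assert row["percent"] == pytest.approx(25.0)


class TestNonsynFraction:
    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(5)
        counts = {t: int(rng.integers(0, 100)) for t in NONSYN_TERMS}
        counts["synonymous_variant"] = 37
        expected = (
            100.0 * sum(counts[t] for t in NONSYN_TERMS)
            / (sum(counts[t] for t in NONSYN_TERMS) + 37)
        )
        assert nonsyn_fraction(counts) == pytest.approx(expected)

    def test_all_synonymous_is_zero(self):
        assert nonsyn_fraction({"synonymous_variant": 10}) == 0.0

    def test_empty_denominator_is_nan(self):
        assert math.isnan(nonsyn_fraction({"intron_variant": 5}))


class TestGeneCounts:
    def test_ranking_and_ties(self):
        positions = {GenomicPosition("1", p) for p in (10, 20, 30, 40)}
        annotations = [
            ann(10, ("missense_variant",), "geneA"),
            ann(20, ("missense_variant",), "geneA"),
            ann(30, ("missense_variant",), "geneA"),
            ann(40, ("missense_variant",), "geneB"),
        ]
        table = snv_count_per_gene(positions, annotations)
        assert list(zip(table["gene"], table["count"])) == [("geneA", 3), ("geneB", 1)]

    def test_variant_in_two_genes_counts_once_each(self):
        positions = {GenomicPosition("1", 10)}
        annotations = [
            ann(10, ("missense_variant",), "geneA"),
            ann(10, ("intron_variant",), "geneB", alt="T"),
        ]
        table = snv_count_per_gene(positions, annotations)
        assert dict(zip(table["gene"], table["count"])) == {"geneA": 1, "geneB": 1}
        # brute-force recount: total gene-hits equals sum over genes
        assert table["count"].sum() == 2
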