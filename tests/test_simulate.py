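import math

import numpy as np
import pandas as pd
import pytest

from popsnv.filtering import intersect_pipelines, merge_cohort
from popsnv.harmonize import (
    liftover_sites,
    remove_invalid_sites,
    rescue_failed_by_rsid,
)
from popsnv.model import GenomicPosition
from popsnv.simulate import (
    SimConfig,
    simulate_annotations_terms,
    simulate_cohort_calls,
    simulate_panels,
    simulate_truth,
)

SMALL = SimConfig(seed=7, n_samples=6, n_true_sites=2000)


@pytest.fixture(scope="module")
def sim():
    return simulate_truth(SMALL)


def test_same_seed_identical_tables(sim):
    again = simulate_truth(SMALL)
    pd.testing.assert_frame_equal(sim.truth, again.truth)
    assert sim.genome_new == again.genome_new


def test_ts_fraction_one_all_transitions():
    cfg = SimConfig(seed=1, n_samples=3, n_true_sites=500, ts_fraction=1.0)
    truth = simulate_truth(cfg).truth
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    assert all((r, a) in transitions for r, a in zip(truth["ref"], truth["alt"]))


def test_refs_match_genome(sim):
    for row in sim.truth.head(200).itertuples(index=False):
        assert sim.genome_new[row.chrom][row.pos - 1] == row.ref


def test_overlap_fractions_within_sampling_error():
    cfg = SimConfig(seed=3, n_samples=5, n_true_sites=50_000,
                    panel_overlap=(0.3, 0.5, 0.01, 0.19))
    truth = simulate_truth(cfg).truth
    n = len(truth)
    for label, p in zip(("both", "panel1_only", "panel2_only", "none"),
                        (0.3, 0.5, 0.01, 0.19)):
        observed = (truth["panel_label"] == label).mean()
        se = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * se


class TestCohortCalls:
    def test_error_free_pipelines_identical(self):
        cfg = SimConfig(seed=5, n_samples=4, n_true_sites=800,
                        fp_rate=(0.0, 0.0), fn_rate=(0.0, 0.0))
        sim = simulate_truth(cfg)
        cohort = simulate_cohort_calls(sim)
        for ca, cb in zip(cohort.callsets["a"], cohort.callsets["b"]):
            assert ca.positions() == cb.positions()
        # consensus equals the union of carried sites
        a = merge_cohort(cohort.callsets["a"])
        b = merge_cohort(cohort.callsets["b"])
        cons = intersect_pipelines(a, b, genotype_source="b")
        carried = {
            GenomicPosition(c, int(p))
            for (c, p), any_carrier in zip(
                zip(sim.truth["chrom"], sim.truth["pos"]),
                (cohort.carrier_codes > 0).any(axis=1),
            )
            if any_carrier
        }
        assert cons.positions() == carried

    def test_occurrence_recovers_carrier_counts(self):
        cfg = SimConfig(seed=5, n_samples=4, n_true_sites=800,
                        fp_rate=(0.0, 0.0), fn_rate=(0.0, 0.0))
        sim = simulate_truth(cfg)
        cohort = simulate_cohort_calls(sim)
        b = merge_cohort(cohort.callsets["b"])
        cons = intersect_pipelines(merge_cohort(cohort.callsets["a"]), b, "b")
        truth_pos = {
            GenomicPosition(c, int(p)): i
            for i, (c, p) in enumerate(zip(sim.truth["chrom"], sim.truth["pos"]))
        }
        drawn = (cohort.carrier_codes > 0).sum(axis=1)
        for pos, idx in list(truth_pos.items())[:300]:
            if pos in cons.position_index:
                assert cons.occurrences[cons.position_index[pos]] == drawn[idx]

    def test_private_false_positives_excluded_from_consensus(self, sim):
        cohort = simulate_cohort_calls(sim)
        truth_positions = {
            GenomicPosition(c, int(p))
            for c, p in zip(sim.truth["chrom"], sim.truth["pos"])
        }
        a = merge_cohort(cohort.callsets["a"])
        b = merge_cohort(cohort.callsets["b"])
        cons = intersect_pipelines(a, b, genotype_source="b")
        # false-positive positions are pipeline-private, so every consensus
        # site is a true site (precision exactly 1 by construction)
        assert cons.positions() <= truth_positions
        assert len(a.positions() - truth_positions) > 0  # FPs do exist upstream


@pytest.fixture(scope="module")
def panels(sim):
    return simulate_panels(sim)


class TestPanels:
    def test_old_genome_carries_same_base_at_mapped_positions(self, sim, panels):
        for i, (old, new) in enumerate(panels.coordinate_map.items()):
            if i >= 200:
                break
            assert (
                panels.genome_old[old.chrom][old.pos - 1]
                == sim.genome_new[new.chrom][new.pos - 1]
            )

    def test_planted_invalid_sites_all_flagged(self, sim, panels):
        cleaned, removed = remove_invalid_sites(panels.panel2_old)
        assert len(removed) == panels.n_planted_invalid
        assert len(cleaned) + len(removed) == len(panels.panel2_old)

    def test_harmonization_conservation(self, sim, panels):
        cleaned, _ = remove_invalid_sites(panels.panel2_old)
        converted, failed = liftover_sites(cleaned, panels.coordinate_map)
        rescued, lost = rescue_failed_by_rsid(failed, panels.panel1)
        assert len(converted) + len(rescued) + len(lost) == len(cleaned)
        assert len(failed) == len(rescued) + len(lost)

    def test_zero_failure_fraction_lossless(self):
        cfg = SimConfig(seed=9, n_samples=3, n_true_sites=1000,
                        liftover_failure_fraction=0.0, nonunique_rsid_pairs=0,
                        indel_sites=0)
        sim = simulate_truth(cfg)
        panels = simulate_panels(sim)
        cleaned, removed = remove_invalid_sites(panels.panel2_old)
        assert removed == []
        converted, failed = liftover_sites(cleaned, panels.coordinate_map)
        assert failed == [] and len(converted) == len(panels.panel2_old)


class TestAnnotationsTerms:
    def test_annotations_consistent_with_truth(self, sim):
        ann = simulate_annotations_terms(sim)
        assert len(ann.annotations) == len(sim.truth)
        by_pos = {a.position: a for a in ann.annotations}
        for row in sim.truth.head(100).itertuples(index=False):
            a = by_pos[GenomicPosition(row.chrom, int(row.pos))]
            assert a.consequence_terms == tuple(row.terms)
            assert a.gene_symbol == row.gene

    def test_catalog_structure(self, sim):
        ann = simulate_annotations_terms(sim)
        assert len(ann.catalog) == SMALL.n_terms + 1
        assert ann.planted_term_id in ann.catalog.terms
        assert len(ann.catalog.universe) == SMALL.n_genes

    def test_all_intronic_truth_gives_empty_nonsyn_query(self):
        from popsnv.enrichment import enrich
        cfg = SimConfig(
            seed=2, n_samples=3, n_true_sites=300,
            consequence_probs=(("intron_variant", 1.0),),
        )
        sim = simulate_truth(cfg)
        ann = simulate_annotations_terms(sim)
        from popsnv.spectrum import nonsyn_variants
        positions = {
            GenomicPosition(c, int(p))
            for c, p in zip(sim.truth["chrom"], sim.truth["pos"])
        }
        assert nonsyn_variants(positions, ann.annotations) == set()
        with pytest.raises(ValueError):
            enrich(set(), ann.catalog)
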