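"""Shared study conditions for the analysis drivers.

One seeded synthetic cohort is used across all numbered steps: 20
individuals, 50,000 true variant sites on two synthetic contigs, two
error-prone calling pipelines, and two reference panels overlapping the
cohort at the study fractions. Every step rebuilds its inputs from the
generators (they are pure functions of the seed), so the scripts can be
run independently and in any order.
"""

from pathlib import Path

from popsnv.filtering import FilterThresholds, filter_calls, intersect_pipelines, merge_cohort
from popsnv.harmonize import (
    liftover_sites,
    merge_panels,
    remove_invalid_sites,
    rescue_failed_by_rsid,
)
from popsnv.simulate import (
    SimConfig,
    simulate_annotations_terms,
    simulate_cohort_calls,
    simulate_panels,
    simulate_truth,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY = SimConfig(
    seed=1,
    n_samples=20,
    n_true_sites=50_000,
    contig_lengths=(("1", 1_500_000), ("2", 1_000_000)),
)

THRESHOLDS = {
    "a": FilterThresholds(min_quality=0, min_neighbor_distance=0, min_depth=5),
    "b": FilterThresholds(min_quality=20, min_neighbor_distance=5, min_depth=3),
}


def build_truth():
    return simulate_truth(STUDY)


def build_consensus(sim):
    cohort = simulate_cohort_calls(sim)
    filtered = {
        p: [filter_calls(cs, THRESHOLDS[p])[0] for cs in cohort.callsets[p]]
        for p in ("a", "b")
    }
    a = merge_cohort(filtered["a"])
    b = merge_cohort(filtered["b"])
    return cohort, a, b, intersect_pipelines(a, b, genotype_source="b")


def build_panels(sim):
    panels = simulate_panels(sim)
    cleaned, removed = remove_invalid_sites(panels.panel2_old)
    converted, failed = liftover_sites(cleaned, panels.coordinate_map)
    rescued, lost = rescue_failed_by_rsid(failed, panels.panel1)
    panel2 = merge_panels("panel2", converted, rescued)
    stats = {
        "raw": len(panels.panel2_old),
        "removed": len(removed),
        "converted": len(converted),
        "rescued": len(rescued),
        "lost": len(lost),
    }
    return panels.panel1, panel2, stats


def build_annotations(sim):
    return simulate_annotations_terms(sim)
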