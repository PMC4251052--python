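import numpy as np
import pytest

from popsnv.filtering import (
    FilterThresholds,
    filter_calls,
    intersect_pipelines,
    merge_cohort,
)
from popsnv.model import GenomicPosition

from conftest import make_callset, make_record

TH = FilterThresholds(min_quality=20, min_neighbor_distance=5, min_depth=3)


def brute_force_neighbor_violations(records, min_dist):
    """Oracle: pairwise distance scan; both members of a close pair fail."""
    bad = set()
    for i, a in enumerate(records):
        for j, b in enumerate(records):
            if i != j and a.position.chrom == b.position.chrom:
                if abs(a.position.pos - b.position.pos) < min_dist:
                    bad.add(i)
                    bad.add(j)
    return bad


class TestFilterCalls:
    def test_boundaries_inclusive(self):
        # q=20, d=3, nearest neighbour exactly 5 bp away: all at threshold, kept
        cs = make_callset(
            [make_record(pos=100, quality=20.0, depth=3), make_record(pos=105)]
        )
        filtered, stats = filter_calls(cs, TH)
        assert len(filtered) == 2 and stats.n_retained == 2

    def test_quality_boundary_removes(self):
        cs = make_callset([make_record(pos=100, quality=19.9, depth=10)])
        filtered, stats = filter_calls(cs, TH)
        assert len(filtered) == 0 and stats.n_removed_quality == 1

    def test_depth_boundary_removes(self):
        cs = make_callset([make_record(pos=100, depth=2)])
        _, stats = filter_calls(cs, TH)
        assert stats.n_removed_depth == 1

    def test_neighbor_filter_removes_both_members(self):
        cs = make_callset(
            [make_record(pos=100), make_record(pos=103, ref="C", alt="T")]
        )
        filtered, stats = filter_calls(cs, TH)
        assert len(filtered) == 0 and stats.n_removed_neighbor == 2

    def test_neighbor_filter_respects_chromosomes(self):
        cs = make_callset(
            [make_record(chrom="1", pos=100), make_record(chrom="2", pos=102)]
        )
        filtered, _ = filter_calls(cs, TH)
        assert len(filtered) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_neighbor_filter_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = sorted(rng.choice(5000, size=60, replace=False) + 1)
        records = [make_record(pos=int(p)) for p in positions]
        cs = make_callset(records)
        filtered, _ = filter_calls(cs, FilterThresholds(0, 7, 0))
        bad = brute_force_neighbor_violations(cs.records, 7)
        expected = [r for i, r in enumerate(cs.records) if i not in bad]
        assert filtered.records == expected

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        records = [
            make_record(pos=int(p), quality=float(q), depth=int(d))
            for p, q, d in zip(
                sorted(rng.choice(2000, size=80, replace=False) + 1),
                rng.uniform(0, 60, 80),
                rng.integers(0, 12, 80),
            )
        ]
        once, _ = filter_calls(make_callset(records), TH)
        twice, stats = filter_calls(once, TH)
        assert twice.records == once.records
        assert stats.n_input == stats.n_retained


class TestMergeCohort:
    def test_backfills_homozygous_reference(self):
        s1 = make_callset([make_record(pos=100, genotype=("A", "G"))], sample_id="S1")
        s2 = make_callset([], sample_id="S2")
        matrix = merge_cohort([s1, s2])
        assert len(matrix) == 1
        pos = GenomicPosition("1", 100)
        assert matrix.genotype_code(pos, "S1") == 1
        assert matrix.genotype_code(pos, "S2") == 0  # backfilled hom-ref

    def test_empty_roster_is_error(self):
        with pytest.raises(ValueError):
            merge_cohort([])

    def test_disjoint_sites_union(self):
        sets = [
            make_callset([make_record(pos=100 * (j + 1))], sample_id=f"S{j}")
            for j in range(3)
        ]
        matrix = merge_cohort(sets)
        assert len(matrix) == 3
        # each site: one carrier, two backfilled
        assert (matrix.genotypes > 0).sum() == 3

    def test_ref_conflict_is_fatal(self):
        s1 = make_callset([make_record(pos=100, ref="A", alt="G")], sample_id="S1")
        s2 = make_callset([make_record(pos=100, ref="C", alt="T")], sample_id="S2")
        with pytest.raises(ValueError, match="1:100"):
            merge_cohort([s1, s2])

    def test_carrier_conservation(self):
        """Non-reference genotypes in the matrix equal the call sets exactly."""
        rng = np.random.default_rng(11)
        sets = []
        for j in range(5):
            positions = sorted(rng.choice(10_000, size=40, replace=False) + 1)
            recs = [
                make_record(pos=int(p),
                            genotype=("A", "G") if rng.random() < 0.6 else ("G", "G"))
                for p in positions
            ]
            sets.append(make_callset(recs, sample_id=f"S{j}"))
        matrix = merge_cohort(sets)
        for j, cs in enumerate(sets):
            carriers = {
                GenomicPosition(matrix.sites["chrom"].iat[i], matrix.sites["pos"].iat[i])
                for i in np.flatnonzero(matrix.genotypes[:, j] > 0)
            }
            assert carriers == {r.position for r in cs if r.is_carrier}


class TestIntersect:
    def _matrix(self, positions, pipeline, genotype=("A", "G")):
        sets = [
            make_callset(
                [make_record(chrom=c, pos=p, genotype=genotype) for c, p in positions],
                sample_id="S1", pipeline_id=pipeline,
            )
        ]
        return merge_cohort(sets)

    def test_position_intersection(self):
        a = self._matrix([("1", 100), ("1", 200)], "a")
        b = self._matrix([("1", 200), ("2", 50)], "b")
        cons = intersect_pipelines(a, b, genotype_source="b")
        assert cons.positions() == {GenomicPosition("1", 200)}
        assert cons.coverage_a == 0.5 and cons.coverage_b == 0.5

    def test_genotypes_come_from_source(self):
        a = self._matrix([("1", 200)], "a", genotype=("A", "G"))  # het
        b = self._matrix([("1", 200)], "b", genotype=("G", "G"))  # hom-alt
        cons = intersect_pipelines(a, b, genotype_source="b")
        assert cons.genotypes[0, 0] == 2
        cons2 = intersect_pipelines(a, b, genotype_source="a")
        assert cons2.genotypes[0, 0] == 1

    def test_roster_mismatch_is_error(self):
        a = self._matrix([("1", 100)], "a")
        b = merge_cohort([make_callset([make_record(pos=100)], sample_id="SX",
                                       pipeline_id="b")])
        with pytest.raises(ValueError):
            intersect_pipelines(a, b, genotype_source="b")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos_a = rng.choice(3000, size=150, replace=False) + 1
        pos_b = rng.choice(3000, size=150, replace=False) + 1
        a = self._matrix([("1", int(p)) for p in sorted(pos_a)], "a")
        b = self._matrix([("1", int(p)) for p in sorted(pos_b)], "b")
        cons = intersect_pipelines(a, b, genotype_source="b")
        expected = {
            GenomicPosition("1", int(p))
            for p in pos_a
            for q in pos_b
            if p == q
        }
        assert cons.positions() == expected
        assert cons.positions() <= a.positions() and cons.positions() <= b.positions()
        assert 0.0 <= cons.coverage_a <= 1.0 and 0.0 <= cons.coverage_b <= 1.0

    def test_symmetric_site_content(self):
        a = self._matrix([("1", 100), ("1", 300)], "a")
        b = self._matrix([("1", 300), ("1", 500)], "b")
        ab = intersect_pipelines(a, b, genotype_source="a")
        ba = intersect_pipelines(b, a, genotype_source="a")
        assert ab.positions() == ba.positions()
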