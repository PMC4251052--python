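"""Per-sample call filtering, cohort merging, and cross-pipeline consensus.

The consensus procedure mirrors dual-pipeline SNV calling practice: each
sample is called by two independent aligner+caller pipelines, per-sample
calls are filtered (quality, read depth, distance to the nearest
neighbouring candidate), merged across the cohort with homozygous-
reference backfill for samples lacking a call at a merged site, and the
two cohort matrices are intersected by genomic position. Sites seen by
both pipelines are retained as the consensus set; genotypes are taken
from one designated pipeline.

The neighbour-distance filter operates on the candidate calls of one
sample and chromosome before the quality/depth filters, and removes
*both* members of any pair closer than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GenomicPosition, SampleCallSet, SnvRecord

GT_HOM_REF, GT_HET, GT_HOM_ALT = 0, 1, 2


@dataclass(frozen=True)
class FilterThresholds:
    """Post-call filter thresholds; all comparisons are inclusive (≥)."""

    min_quality: float = 20.0
    min_neighbor_distance: int = 5
    min_depth: int = 3

    def __post_init__(self):
        if self.min_quality < 0 or self.min_neighbor_distance < 0 or self.min_depth < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class FilterStats:
    n_input: int = 0
    n_removed_quality: int = 0
    n_removed_depth: int = 0
    n_removed_neighbor: int = 0
    n_retained: int = 0


def filter_calls(
    callset: SampleCallSet, thresholds: FilterThresholds = FilterThresholds()
) -> tuple:
    """Apply quality/neighbour-distance/depth filters to one call set.

    Returns ``(filtered_callset, FilterStats)``. A record removed by the
    neighbour filter is counted there even if it would also fail quality
    or depth.
    """
    recs = callset.records  # sorted by position
    n = len(recs)
    too_close = [False] * n
    for i in range(n - 1):
        a, b = recs[i], recs[i + 1]
        if (
            a.position.chrom == b.position.chrom
            and b.position.pos - a.position.pos < thresholds.min_neighbor_distance
        ):
            too_close[i] = too_close[i + 1] = True
    stats = FilterStats(n_input=n)
    kept = []
    for i, r in enumerate(recs):
        if too_close[i]:
            stats.n_removed_neighbor += 1
        elif r.quality < thresholds.min_quality:
            stats.n_removed_quality += 1
        elif r.depth < thresholds.min_depth:
            stats.n_removed_depth += 1
        else:
            kept.append(r)
    stats.n_retained = len(kept)
    filtered = SampleCallSet(
        sample_id=callset.sample_id, pipeline_id=callset.pipeline_id, records=kept
    )
    return filtered, stats


class CohortMatrix:
    """Cohort-level genotype matrix for one calling pipeline.

    Site list is the union of per-sample call positions; samples without
    a call at a site are backfilled homozygous-reference. Genotypes are
    coded 0 (hom-ref), 1 (het), 2 (hom-alt, i.e. two non-reference
    alleles).
    """

    def __init__(self, pipeline_id, sites: pd.DataFrame, samples, genotypes):
        self.pipeline_id = pipeline_id
        self.sites = sites.reset_index(drop=True)
        self.samples = list(samples)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        self.position_index = {
            GenomicPosition(c, p): i
            for i, (c, p) in enumerate(zip(self.sites["chrom"], self.sites["pos"]))
        }

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self) -> set:
        return set(self.position_index)

    def genotype_code(self, position: GenomicPosition, sample_id: str) -> int:
        return int(
            self.genotypes[self.position_index[position], self.samples.index(sample_id)]
        )


def _genotype_code(record: SnvRecord) -> int:
    n = record.n_alt_alleles
    return (GT_HOM_REF, GT_HET, GT_HOM_ALT)[n]


def merge_cohort(callsets: Sequence[SampleCallSet]) -> CohortMatrix:
    """Merge per-sample call sets of one pipeline into a cohort matrix.

    Errors on an empty roster, duplicate sample ids, mixed pipelines, or
    conflicting reference alleles at one position.
    """
    if not callsets:
        raise ValueError("cannot merge an empty list of call sets")
    pipeline_ids = {cs.pipeline_id for cs in callsets}
    if len(pipeline_ids) != 1:
        raise ValueError(f"call sets span multiple pipelines: {sorted(pipeline_ids)}")
    samples = [cs.sample_id for cs in callsets]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in cohort")

    site_ref: dict = {}
    site_alts: dict = {}
    site_genos: dict = {}
    for j, cs in enumerate(callsets):
        for r in cs:
            pos = r.position
            prev = site_ref.get(pos)
            if prev is None:
                site_ref[pos] = r.ref
                site_alts[pos] = set(r.alts)
                site_genos[pos] = {}
            elif prev != r.ref:
                raise ValueError(
                    f"conflicting reference alleles at {pos.chrom}:{pos.pos}: "
                    f"{prev} vs {r.ref} (sample {cs.sample_id})"
                )
            else:
                site_alts[pos].update(r.alts)
            site_genos[pos][j] = _genotype_code(r)

    order = sorted(site_ref, key=lambda p: p.sort_key())
    geno = np.zeros((len(order), len(samples)), dtype=np.int8)
    for i, pos in enumerate(order):
        for j, code in site_genos[pos].items():
            geno[i, j] = code
    sites = pd.DataFrame(
        {
            "chrom": [p.chrom for p in order],
            "pos": [p.pos for p in order],
            "ref": [site_ref[p] for p in order],
            "alts": [",".join(sorted(site_alts[p])) for p in order],
        }
    )
    return CohortMatrix(pipeline_ids.pop(), sites, samples, geno)


@dataclass
class ConsensusSet:
    """Consensus variant sites: positions called by both pipelines.

    Genotypes (and site alleles) come from the designated genotype-source
    pipeline. ``occurrences[i]`` is the number of cohort samples carrying
    at least one non-reference allele at site ``i``.
    """

    sites: pd.DataFrame
    samples: list
    genotypes: np.ndarray
    pipeline_a: str
    pipeline_b: str
    genotype_source: str
    coverage_a: float = float("nan")
    coverage_b: float = float("nan")
    position_index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.position_index:
            self.position_index = {
                GenomicPosition(c, p): i
                for i, (c, p) in enumerate(zip(self.sites["chrom"], self.sites["pos"]))
            }
        self.occurrences = (self.genotypes > 0).sum(axis=1).astype(int)

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self) -> set:
        return set(self.position_index)

    def n_samples(self) -> int:
        return len(self.samples)


def intersect_pipelines(
    a: CohortMatrix, b: CohortMatrix, genotype_source: str, strict_alleles: bool = False
) -> ConsensusSet:
    """Intersect two cohort matrices by genomic position.

    ``genotype_source`` names the pipeline whose genotypes (and alleles)
    the consensus carries. With ``strict_alleles`` the intersection
    additionally requires the alt-allele sets to agree.
    """
    if a.samples != b.samples:
        raise ValueError("cohort matrices have different sample rosters")
    if genotype_source not in (a.pipeline_id, b.pipeline_id):
        raise ValueError(f"genotype source {genotype_source!r} is neither pipeline")
    src = a if genotype_source == a.pipeline_id else b
    other = b if src is a else a

    common = a.positions() & b.positions()
    if strict_alleles:
        common = {
            p
            for p in common
            if src.sites["alts"].iat[src.position_index[p]]
            == other.sites["alts"].iat[other.position_index[p]]
        }
    idx = sorted((src.position_index[p] for p in common))
    sites = src.sites.iloc[idx].reset_index(drop=True)
    geno = src.genotypes[idx, :].copy()
    n = len(idx)
    return ConsensusSet(
        sites=sites,
        samples=list(src.samples),
        genotypes=geno,
        pipeline_a=a.pipeline_id,
        pipeline_b=b.pipeline_id,
        genotype_source=genotype_source,
        coverage_a=n / len(a) if len(a) else float("nan"),
        coverage_b=n / len(b) if len(b) else float("nan"),
    )
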