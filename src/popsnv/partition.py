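"""Panel partitioning, occurrence stratification and reproducibility.

A consensus site is *shared* when its position occurs in a reference
panel and *population-only* when it occurs in none. The occurrence of a
site is the number of cohort samples carrying at least one non-reference
allele there; SNV-i denotes the population-only sites with occurrence
≥ i, so SNV-1 is every population-only site and SNV-N (N = cohort size)
the sites fixed in the cohort. Membership is by position only, matching
the partition rule used to define the sets (an allele-aware strict mode
is available upstream at the consensus step).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .filtering import ConsensusSet
from .model import GenomicPosition, PanelDataset

LABELS = ("shared_both", "shared_panel1_only", "shared_panel2_only", "population_only")


@dataclass
class PartitionResult:
    """Exhaustive, mutually exclusive assignment of consensus sites."""

    labels: pd.Series  # site index → label
    counts: Dict[str, int]
    fractions: Dict[str, float]
    total: int

    def positions(self, consensus: ConsensusSet, label: str) -> set:
        idx = np.flatnonzero((self.labels == label).to_numpy())
        return {
            GenomicPosition(consensus.sites["chrom"].iat[i], consensus.sites["pos"].iat[i])
            for i in idx
        }


def class_percentages(counts: Dict[str, int], total: int) -> Dict[str, float]:
    """Per-class percentages of a partition/occurrence count table."""
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: 100.0 * v / total for k, v in counts.items()}


def occurrence(consensus: ConsensusSet, site: GenomicPosition) -> int:
    """Number of samples carrying ≥1 non-reference allele at ``site``."""
    try:
        i = consensus.position_index[site]
    except KeyError:
        raise KeyError(f"site {site.chrom}:{site.pos} not in consensus set") from None
    return int(consensus.occurrences[i])


def partition_snvs(
    consensus: ConsensusSet,
    panel1: Optional[PanelDataset],
    panel2: Optional[PanelDataset] = None,
) -> PartitionResult:
    """Label each consensus site by positional membership in the panels.

    With a single panel the result degrades to
    {shared_panel1_only, population_only}.
    """
    for p in (panel1, panel2):
        if p is not None and p.assembly != "new":
            raise ValueError(
                f"panel {p.name} is on assembly {p.assembly!r}; harmonize first"
            )
    p1 = panel1.positions() if panel1 is not None else set()
    p2 = panel2.positions() if panel2 is not None else set()
    labels = []
    for c, p in zip(consensus.sites["chrom"], consensus.sites["pos"]):
        pos = GenomicPosition(c, p)
        in1, in2 = pos in p1, pos in p2
        if in1 and in2:
            labels.append("shared_both")
        elif in1:
            labels.append("shared_panel1_only")
        elif in2:
            labels.append("shared_panel2_only")
        else:
            labels.append("population_only")
    labels = pd.Series(labels, name="label")
    total = len(labels)
    counts = {lab: int((labels == lab).sum()) for lab in LABELS}
    if total:
        fractions = {k: v / 100.0 for k, v in class_percentages(counts, total).items()}
    else:
        fractions = {lab: 0.0 for lab in LABELS}
    return PartitionResult(labels=labels, counts=counts, fractions=fractions, total=total)


@dataclass
class OccurrenceSet:
    """Population-only sites with occurrence ≥ threshold."""

    threshold: int
    members: set
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.members)


def snv_i(occurrences_by_site: Dict[GenomicPosition, int], i: int, roster_size: int,
          source_id: str = "population_only") -> OccurrenceSet:
    """Build the SNV-i stratum: sites with occurrence ≥ i."""
    if not 1 <= i <= roster_size:
        raise ValueError(f"occurrence threshold {i} outside [1, {roster_size}]")
    members = {pos for pos, occ in occurrences_by_site.items() if occ >= i}
    return OccurrenceSet(threshold=i, members=members, source_id=source_id)


def occurrence_distribution(
    occurrences: Sequence[int], roster_size: int
) -> pd.DataFrame:
    """Histogram of occurrences 1..roster with percentages summing to 100."""
    occ = np.asarray(list(occurrences), dtype=int)
    if occ.size and (occ.min() < 1 or occ.max() > roster_size):
        raise ValueError("occurrences outside [1, roster size]")
    counts = np.bincount(occ, minlength=roster_size + 1)[1:]
    total = counts.sum()
    pct = 100.0 * counts / total if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame(
        {"occurrence": np.arange(1, roster_size + 1), "count": counts, "percent": pct}
    )


def carrier_frequency_spectrum(
    occurrences: Sequence[int], population_size: int, bins: int = 20
) -> pd.DataFrame:
    """Carrier-frequency distribution (occurrence / population size), binned.

    The frequency here is the fraction of individuals carrying the
    variant, matching the occurrence definition; it is not the allele
    frequency (allele count / 2N).
    """
    if population_size <= 0:
        raise ValueError("population size must be positive")
    freqs = np.asarray(list(occurrences), dtype=float) / population_size
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(freqs, bins=edges)
    # a fully fixed site (frequency exactly 1.0) falls in the last bin
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
            "percent": 100.0 * counts / total if total else np.zeros(bins),
        }
    )


def reproducibility(stratum: OccurrenceSet, independent: set) -> float:
    """Fraction of stratum members found in an independent call set."""
    if not stratum.members:
        raise ValueError("reproducibility undefined for an empty occurrence set")
    found = sum(1 for pos in stratum.members if pos in independent)
    return found / len(stratum.members)


def occurrences_by_site(
    consensus: ConsensusSet, positions: Optional[Iterable[GenomicPosition]] = None
) -> Dict[GenomicPosition, int]:
    """Map position → occurrence, optionally restricted to ``positions``."""
    if positions is None:
        return {
            GenomicPosition(c, p): int(consensus.occurrences[i])
            for i, (c, p) in enumerate(
                zip(consensus.sites["chrom"], consensus.sites["pos"])
            )
        }
    return {pos: occurrence(consensus, pos) for pos in positions}
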