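"""Core domain types for cohort SNV analysis.

Coordinates are 1-based and inclusive throughout (VCF convention).
Chromosome labels are normalized to a canonical no-prefix form (``chr1``
and ``1`` are the same chromosome) and ordered naturally: autosomes by
number, then X, Y, MT, then any other contig lexically.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

BASES = ("A", "C", "G", "T")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

_SPECIAL_CHROM_ORDER = {"X": 23, "Y": 24, "MT": 25, "M": 25}


def normalize_chrom(chrom: str) -> str:
    """Canonical chromosome label: ``chr`` prefix stripped, upper-case X/Y/MT."""
    c = chrom.strip()
    if not c:
        raise ValueError("empty chromosome label")
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("X", "Y", "MT", "M"):
        c = "MT" if c.upper() == "M" else c.upper()
    return c


def chrom_sort_key(chrom: str) -> tuple:
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    if c in _SPECIAL_CHROM_ORDER:
        return (0, _SPECIAL_CHROM_ORDER[c], "")
    return (1, 0, c)


@functools.total_ordering
class GenomicPosition(NamedTuple):
    """A 1-based point location on a chromosome."""

    chrom: str
    pos: int

    @classmethod
    def make(cls, chrom: str, pos: int) -> "GenomicPosition":
        pos = int(pos)
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        return cls(normalize_chrom(chrom), pos)

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos)

    def __lt__(self, other) -> bool:  # natural chromosome order, then position
        return self.sort_key() < other.sort_key()


@dataclass(frozen=True)
class SnvRecord:
    """One called single-nucleotide variant in one sample.

    ``genotype`` is an unordered pair of alleles, each drawn from
    {ref} ∪ alts; ``alts`` holds one to three distinct single-base
    alternatives, none equal to the reference.
    """

    position: GenomicPosition
    ref: str
    alts: tuple
    genotype: tuple
    quality: float
    depth: int
    rsid: Optional[str] = None

    def __post_init__(self):
        if self.ref not in BASES:
            raise ValueError(f"invalid reference base {self.ref!r} at {self.position}")
        if not self.alts or len(self.alts) > 3:
            raise ValueError(f"need 1-3 alt alleles at {self.position}")
        if len(set(self.alts)) != len(self.alts):
            raise ValueError(f"duplicate alt alleles at {self.position}")
        for a in self.alts:
            if a not in BASES:
                raise ValueError(f"invalid alt base {a!r} at {self.position}")
            if a == self.ref:
                raise ValueError(f"alt equals ref ({a}) at {self.position}")
        allowed = {self.ref, *self.alts}
        if len(self.genotype) != 2 or not set(self.genotype) <= allowed:
            raise ValueError(
                f"genotype {self.genotype} not drawn from ref/alt alleles at {self.position}"
            )
        if self.quality < 0:
            raise ValueError("negative quality")
        if self.depth < 0:
            raise ValueError("negative depth")

    @property
    def n_alt_alleles(self) -> int:
        return sum(1 for a in self.genotype if a != self.ref)

    @property
    def is_carrier(self) -> bool:
        return self.n_alt_alleles > 0


@dataclass
class SampleCallSet:
    """All SNV calls of one sample from one calling pipeline.

    Records are kept sorted by genomic position and unique per position.
    """

    sample_id: str
    pipeline_id: str
    records: list = field(default_factory=list)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: r.position.sort_key())
        seen = set()
        for r in self.records:
            if r.position in seen:
                raise ValueError(
                    f"duplicate call at {r.position.chrom}:{r.position.pos} "
                    f"in sample {self.sample_id}"
                )
            seen.add(r.position)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def positions(self) -> set:
        return {r.position for r in self.records}


@dataclass(frozen=True)
class PanelSite:
    """One site of a reference panel (e.g. a 1KGP- or HapMap-style catalog)."""

    position: GenomicPosition
    rsid: Optional[str] = None
    ref: Optional[str] = None
    alts: tuple = ()
    assembly: str = "new"
    is_snv: bool = True

    def __post_init__(self):
        if self.is_snv:
            if self.ref is not None and len(self.ref) != 1:
                raise ValueError(f"SNV site {self.position} has non-single ref {self.ref!r}")
            for a in self.alts:
                if len(a) != 1:
                    raise ValueError(f"SNV site {self.position} has non-single alt {a!r}")


class PanelDataset:
    """Reference-panel sites keyed by position, with an rsID index.

    At most one site per position; an rsID may (transiently, before
    harmonization) index several positions.
    """

    def __init__(self, name: str, assembly: str, sites: Iterable[PanelSite] = ()):
        self.name = name
        self.assembly = assembly
        self.sites: dict = {}
        self.rsid_index: dict = {}
        for s in sites:
            self.add_site(s)

    def add_site(self, site: PanelSite) -> None:
        if site.position in self.sites:
            raise ValueError(
                f"panel {self.name}: duplicate site at "
                f"{site.position.chrom}:{site.position.pos}"
            )
        self.sites[site.position] = site
        if site.rsid is not None:
            self.rsid_index.setdefault(site.rsid, set()).add(site.position)

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, position: GenomicPosition) -> bool:
        return position in self.sites

    def positions(self) -> set:
        return set(self.sites)

    def rsid_positions(self, rsid: str) -> set:
        return set(self.rsid_index.get(rsid, ()))


@dataclass(frozen=True)
class AnnotationRecord:
    """Consequence annotation of one (site, alt allele) pair."""

    position: GenomicPosition
    alt: str
    consequence_terms: tuple
    gene_symbol: Optional[str] = None

    def __post_init__(self):
        if not self.consequence_terms:
            raise ValueError(f"annotation at {self.position} has no consequence terms")


class CoordinateMap:
    """Old-assembly → new-assembly position map (liftover surrogate).

    Injective per chromosome on the mapped positions; positions absent
    from the map are liftover failures.
    """

    def __init__(self, pairs: Iterable = ()):
        self._fwd: dict = {}
        self._images: set = set()
        for old, new in pairs:
            self.add(old, new)

    def add(self, old: GenomicPosition, new: GenomicPosition) -> None:
        if old in self._fwd:
            raise ValueError(f"duplicate map source {old.chrom}:{old.pos}")
        if new in self._images:
            raise ValueError(
                f"map is not injective: two old positions map to {new.chrom}:{new.pos}"
            )
        self._fwd[old] = new
        self._images.add(new)

    def get(self, old: GenomicPosition):
        return self._fwd.get(old)

    def __contains__(self, old: GenomicPosition) -> bool:
        return old in self._fwd

    def __len__(self) -> int:
        return len(self._fwd)

    def items(self):
        return self._fwd.items()


def sort_positions(positions: Sequence[GenomicPosition]) -> list:
    return sorted(positions, key=lambda p: p.sort_key())
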