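"""Substitution spectrum, consequence classification and category tables.

Substitutions are strand-collapsed into six classes named by the
reference base pair and the resulting pair (e.g. a C→T on either strand
is the C:G→T:A transition). Sites with more than one alternative allele
are classed *uncertain* and excluded from the Ts/Tv ratio.

Consequence handling follows VEP-style controlled vocabulary. A variant
is non-synonymous when any of its consequence terms belongs to a fixed
ten-term label set spanning protein-altering and splice-disrupting
effects; category tables count a variant once under each distinct term
it carries (so column sums can exceed the set total), with percentages
over the set total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .model import COMPLEMENT, AnnotationRecord, GenomicPosition

# Ten consequence labels defining a non-synonymous variant.
NONSYN_TERMS = (
    "missense_variant",
    "stop_gained",
    "stop_lost",
    "stop_retained_variant",
    "coding_sequence_variant",
    "initiator_codon_variant",
    "incomplete_terminal_codon_variant",
    "splice_donor_variant",
    "splice_acceptor_variant",
    "splice_region_variant",
)

SYNONYMOUS_TERM = "synonymous_variant"

# Category vocabulary grouped as in standard whole-genome annotation reports.
CATEGORY_GROUPS: Dict[str, Tuple[str, ...]] = {
    "cds_and_splicing": (SYNONYMOUS_TERM,) + NONSYN_TERMS,
    "regulatory_adjacent": (
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "regulatory_region_variant",
        "TF_binding_site_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
    ),
    "non_coding": (
        "NMD_transcript_variant",
        "mature_miRNA_variant",
        "non_coding_exon_variant",
        "nc_transcript_variant",
    ),
    "intron": ("intron_variant",),
    "intergenic": ("intergenic_variant",),
}

KNOWN_TERMS = frozenset(t for terms in CATEGORY_GROUPS.values() for t in terms)

_TERM_ORDER = [t for terms in CATEGORY_GROUPS.values() for t in terms]
_TERM_GROUP = {t: g for g, terms in CATEGORY_GROUPS.items() for t in terms}

_CLASS_LABELS = (
    "A:T->C:G",
    "A:T->G:C",
    "A:T->T:A",
    "C:G->A:T",
    "C:G->G:C",
    "C:G->T:A",
)
UNCERTAIN = "uncertain"
TRANSITION_CLASSES = frozenset({"A:T->G:C", "C:G->T:A"})


@dataclass(frozen=True)
class SubstitutionClass:
    label: str
    is_transition: Optional[bool]  # None for uncertain


def _pair_label(base: str) -> str:
    return f"{base}:{COMPLEMENT[base]}"


def classify_substitution(ref: str, alts: Sequence[str]) -> SubstitutionClass:
    """Strand-collapsed substitution class of a site.

    Multi-allelic sites are *uncertain*; ``classify(x→y)`` equals
    ``classify(complement(x)→complement(y))`` by construction.
    """
    if ref not in "ACGT":
        raise ValueError(f"invalid reference base {ref!r}")
    for a in alts:
        if a not in "ACGT":
            raise ValueError(f"invalid alt base {a!r}")
        if a == ref:
            raise ValueError("alt equals ref")
    if len(alts) != 1:
        return SubstitutionClass(UNCERTAIN, None)
    alt = alts[0]
    # collapse onto the A/C representative strand
    if ref in "GT":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    label = f"{_pair_label(ref)}->{_pair_label(alt)}"
    return SubstitutionClass(label, label in TRANSITION_CLASSES)


@dataclass
class SpectrumSummary:
    counts: Dict[str, int]
    fractions: Dict[str, float]
    n_transitions: int
    n_transversions: int
    ts_tv_ratio: float  # math.inf when no transversions
    total: int

    def to_frame(self) -> pd.DataFrame:
        order = list(_CLASS_LABELS) + [UNCERTAIN]
        return pd.DataFrame(
            {
                "class": order,
                "count": [self.counts[c] for c in order],
                "percent": [100.0 * self.fractions[c] for c in order],
            }
        )


def spectrum_summary(sites: Iterable[Tuple[str, Sequence[str]]]) -> SpectrumSummary:
    """Classify ``(ref, alts)`` pairs and summarize the spectrum.

    Ts/Tv is computed over single-alt sites only.
    """
    counts = {c: 0 for c in _CLASS_LABELS}
    counts[UNCERTAIN] = 0
    n_ts = n_tv = 0
    total = 0
    for ref, alts in sites:
        c = classify_substitution(ref, alts)
        counts[c.label] += 1
        total += 1
        if c.is_transition is True:
            n_ts += 1
        elif c.is_transition is False:
            n_tv += 1
    if total == 0:
        raise ValueError("empty site list")
    fractions = {c: counts[c] / total for c in counts}
    ratio = n_ts / n_tv if n_tv else math.inf
    return SpectrumSummary(
        counts=counts,
        fractions=fractions,
        n_transitions=n_ts,
        n_transversions=n_tv,
        ts_tv_ratio=ratio,
        total=total,
    )


def classify_consequence(terms: Sequence[str]) -> str:
    """Variant-level class: non_synonymous > synonymous > other."""
    nonsyn = set(NONSYN_TERMS)
    tset = set(terms)
    if tset & nonsyn:
        return "non_synonymous"
    if SYNONYMOUS_TERM in tset:
        return "synonymous"
    return "other"


@dataclass
class CategoryTable:
    """Per-term counts for one named SNV set (one report column)."""

    name: str
    table: pd.DataFrame  # columns: group, term, count, percent
    set_total: int
    n_unannotated: int
    counts: Dict[str, int]

    def count(self, term: str) -> int:
        return self.counts.get(term, 0)


def tabulate_categories(
    positions: set,
    annotations: Sequence[AnnotationRecord],
    name: str = "snv_set",
) -> CategoryTable:
    """Count, per consequence term, the set's variants carrying it.

    A variant contributes once to each *distinct* term it carries;
    percentages use the set size as denominator. Variants of the set
    with no annotation are reported in an explicit ``unannotated`` row.
    Terms outside the known vocabulary are counted under ``other_term``
    with a warning semantics handled by the caller's logging.
    """
    terms_by_pos: Dict[GenomicPosition, set] = {}
    for a in annotations:
        if a.position in positions:
            terms_by_pos.setdefault(a.position, set()).update(a.consequence_terms)
    counts = {t: 0 for t in _TERM_ORDER}
    n_unknown = 0
    for pos_terms in terms_by_pos.values():
        for t in pos_terms:
            if t in counts:
                counts[t] += 1
            else:
                n_unknown += 1
    total = len(positions)
    n_unannotated = total - len(terms_by_pos)
    rows = [
        {
            "group": _TERM_GROUP[t],
            "term": t,
            "count": counts[t],
            "percent": 100.0 * counts[t] / total if total else 0.0,
        }
        for t in _TERM_ORDER
    ]
    rows.append(
        {
            "group": "unannotated",
            "term": "unannotated",
            "count": n_unannotated,
            "percent": 100.0 * n_unannotated / total if total else 0.0,
        }
    )
    if n_unknown:
        rows.append(
            {
                "group": "other",
                "term": "other_term",
                "count": n_unknown,
                "percent": 100.0 * n_unknown / total if total else 0.0,
            }
        )
    return CategoryTable(
        name=name,
        table=pd.DataFrame(rows),
        set_total=total,
        n_unannotated=n_unannotated,
        counts=counts,
    )


def nonsyn_fraction(category_counts: Dict[str, int]) -> float:
    """Percent non-synonymous among coding/splicing category counts.

    ``100 × Σ(non-synonymous term counts) / (Σ + synonymous count)``,
    computed on category-level counts (a multi-term variant contributes
    to every term it carries).
    """
    nonsyn = sum(category_counts.get(t, 0) for t in NONSYN_TERMS)
    syn = category_counts.get(SYNONYMOUS_TERM, 0)
    denom = nonsyn + syn
    if denom == 0:
        return math.nan
    return 100.0 * nonsyn / denom


def nonsyn_variants(
    positions: set, annotations: Sequence[AnnotationRecord]
) -> set:
    """Distinct variants of the set carrying ≥1 non-synonymous term."""
    nonsyn = set(NONSYN_TERMS)
    return {
        a.position
        for a in annotations
        if a.position in positions and set(a.consequence_terms) & nonsyn
    }


def snv_count_per_gene(
    positions: set, annotations: Sequence[AnnotationRecord]
) -> pd.DataFrame:
    """Distinct-SNV count per gene, ranked descending (ties lexical).

    A variant annotated to several genes counts once in each.
    """
    genes_by_pos: Dict[GenomicPosition, set] = {}
    for a in annotations:
        if a.position in positions and a.gene_symbol:
            genes_by_pos.setdefault(a.position, set()).add(a.gene_symbol)
    counts: Dict[str, int] = {}
    for genes in genes_by_pos.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "gene": [g for g, _ in items],
            "count": [c for _, c in items],
            "rank": range(1, len(items) + 1),
        }
    )
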