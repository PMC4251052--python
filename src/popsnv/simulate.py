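"""Seeded generators for every input the analysis consumes.

The simulator emulates the study design end to end at desk scale: a
cohort of N individuals whose variant sites have carrier frequencies
drawn from a Beta law; two error-prone calling pipelines, each with
pipeline-private (and sample-private) false-positive positions and
independent per-call false negatives; two partially overlapping
reference panels, one of which lives on an older assembly and must be
harmonized through a coordinate map with planted conversion failures,
rescue-eligible rsIDs, duplicate rsIDs and non-SNV sites; VEP-style
consequence annotations tied to a synthetic gene model; and a term
catalog with one term whose gene membership is enriched (at configurable
odds) for the genes of non-synonymous population-only variants.

All generators are pure functions of (config, seed): the same config
yields byte-identical outputs. False positives are position-private per
pipeline, so the positional intersection removes them exactly; this
makes consensus behaviour analytically checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .model import (
    BASES,
    COMPLEMENT,
    AnnotationRecord,
    CoordinateMap,
    GenomicPosition,
    PanelDataset,
    PanelSite,
    SampleCallSet,
    SnvRecord,
)
from .enrichment import TermCatalog
from .spectrum import NONSYN_TERMS

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

# consequence law: probabilities of the primary consequence term of a site,
# shaped like a whole-genome annotation profile (intron/intergenic dominate)
DEFAULT_CONSEQUENCE_PROBS = {
    "intron_variant": 0.459,
    "intergenic_variant": 0.380,
    "upstream_gene_variant": 0.060,
    "downstream_gene_variant": 0.060,
    "nc_transcript_variant": 0.020,
    "regulatory_region_variant": 0.010,
    "missense_variant": 0.0055,
    "synonymous_variant": 0.0040,
    "splice_region_variant": 0.0012,
    "stop_gained": 0.0002,
    "splice_donor_variant": 0.0001,
}

_GENELESS_TERMS = {"intergenic_variant", "regulatory_region_variant"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated study: a 35-individual cohort, panel
    overlap fractions matching the reported partition (31.3% in both
    panels, 54.4% panel-1 only, 0.1% panel-2 only, 14.2% in neither),
    and a transition fraction giving the genome-wide Ts/Tv of 2.1.
    """

    seed: int = 0
    n_samples: int = 35
    n_true_sites: int = 20_000
    contig_lengths: Tuple[Tuple[str, int], ...] = (
        ("1", 400_000), ("2", 300_000), ("X", 200_000), ("Y", 100_000),
    )
    ts_fraction: float = 0.677  # => E[Ts/Tv] = 0.677/0.323 ≈ 2.1
    af_beta: Tuple[float, float] = (0.2, 2.0)  # carrier-frequency law
    het_fraction: float = 0.6
    fp_rate: Tuple[float, float] = (0.02, 0.02)    # per pipeline (a, b)
    fn_rate: Tuple[float, float] = (0.05, 0.05)
    quality_mean: float = 60.0
    quality_sd: float = 20.0
    depth_mean: float = 30.0
    panel_overlap: Tuple[float, float, float, float] = (0.313, 0.544, 0.001, 0.142)
    liftover_failure_fraction: float = 0.05
    multi_rsid_fraction: float = 0.005
    nonunique_rsid_pairs: int = 3
    indel_sites: int = 5
    n_genes: int = 200
    gene_intensity_shape: float = 1.0  # gamma shape of per-gene site intensity
    consequence_probs: Tuple[Tuple[str, float], ...] = tuple(
        DEFAULT_CONSEQUENCE_PROBS.items()
    )
    secondary_term_fraction: float = 0.10  # missense sites also splice_region
    n_terms: int = 50
    term_size: int = 25
    planted_odds: float = 10.0

    def __post_init__(self):
        for p in (
            self.ts_fraction, self.het_fraction, *self.fp_rate, *self.fn_rate,
            self.liftover_failure_fraction, self.multi_rsid_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.panel_overlap) - 1.0) > 1e-9:
            raise ValueError("panel overlap fractions must sum to 1")
        if self.n_true_sites > self.genome_length // 4:
            raise ValueError("too many sites for the genome length")

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.contig_lengths)


@dataclass
class SimTruth:
    config: SimConfig
    genome_new: Dict[str, str]
    truth: pd.DataFrame  # chrom,pos,ref,alt,freq,gene,terms,panel_label,rsid,extra_rsid


@dataclass
class SimCohort:
    callsets: Dict[str, List[SampleCallSet]]  # pipeline id -> one per sample
    carrier_codes: np.ndarray  # (n_sites, n_samples) genotype codes 0/1/2
    samples: List[str]


@dataclass
class SimPanels:
    panel1: PanelDataset          # target assembly, VCF-style
    panel2_old: PanelDataset      # old assembly, HapMap-style
    coordinate_map: CoordinateMap
    genome_old: Dict[str, str]
    n_planted_invalid: int


@dataclass
class SimAnnotations:
    annotations: List[AnnotationRecord]
    catalog: TermCatalog
    planted_term_id: str


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _offsets_to_positions(config: SimConfig, offsets: np.ndarray):
    chroms = np.empty(offsets.shape, dtype=object)
    pos = np.empty(offsets.shape, dtype=np.int64)
    start = 0
    for name, length in config.contig_lengths:
        mask = (offsets >= start) & (offsets < start + length)
        chroms[mask] = name
        pos[mask] = offsets[mask] - start + 1
        start += length
    return chroms, pos


def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw the true variant sites and the target-assembly genome."""
    rng = _rng(config, 1)
    genome_new = {
        name: _random_sequence(rng, length)
        for name, length in config.contig_lengths
    }
    offsets = rng.choice(config.genome_length, size=config.n_true_sites, replace=False)
    offsets.sort()
    chroms, positions = _offsets_to_positions(config, offsets)
    refs = np.array(
        [genome_new[c][p - 1] for c, p in zip(chroms, positions)], dtype=object
    )
    is_ts = rng.random(config.n_true_sites) < config.ts_fraction
    tv_pick = rng.integers(2, size=config.n_true_sites)
    alts = np.array(
        [
            TRANSITION[r] if ts else TRANSVERSIONS[r][tv]
            for r, ts, tv in zip(refs, is_ts, tv_pick)
        ],
        dtype=object,
    )
    a, b = config.af_beta
    freqs = rng.beta(a, b, size=config.n_true_sites)
    freqs = np.clip(freqs, 1.0 / (10 * config.n_samples), 1.0)

    labels = rng.choice(
        ["both", "panel1_only", "panel2_only", "none"],
        size=config.n_true_sites,
        p=list(config.panel_overlap),
    )

    probs = dict(config.consequence_probs)
    terms = list(probs)
    pvec = np.array([probs[t] for t in terms], dtype=float)
    pvec = pvec / pvec.sum()
    primary = rng.choice(terms, size=config.n_true_sites, p=pvec)
    secondary = (primary == "missense_variant") & (
        rng.random(config.n_true_sites) < config.secondary_term_fraction
    )
    term_tuples = [
        (t, "splice_region_variant") if sec else (t,)
        for t, sec in zip(primary, secondary)
    ]

    gene_weights = rng.gamma(config.gene_intensity_shape, size=config.n_genes)
    gene_weights /= gene_weights.sum()
    gene_idx = rng.choice(config.n_genes, size=config.n_true_sites, p=gene_weights)
    genes = [
        None if t[0] in _GENELESS_TERMS else f"GENE{gi:04d}"
        for t, gi in zip(term_tuples, gene_idx)
    ]

    rsids = [f"rs{i + 1}" for i in range(config.n_true_sites)]
    extra = rng.random(config.n_true_sites) < config.multi_rsid_fraction
    extra_rsids = [
        f"rs{900_000 + i}" if e else None for i, e in enumerate(extra)
    ]

    truth = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "freq": freqs,
            "gene": genes,
            "terms": term_tuples,
            "panel_label": labels,
            "rsid": rsids,
            "extra_rsid": extra_rsids,
        }
    )
    return SimTruth(config=config, genome_new=genome_new, truth=truth)


def simulate_cohort_calls(sim: SimTruth) -> SimCohort:
    """Draw carrier genotypes and the two pipelines' per-sample call sets."""
    config = sim.config
    rng = _rng(config, 2)
    n_sites, n_samples = len(sim.truth), config.n_samples
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]

    freqs = sim.truth["freq"].to_numpy()
    carrier = rng.random((n_sites, n_samples)) < freqs[:, None]
    hom = rng.random((n_sites, n_samples)) >= config.het_fraction
    codes = np.where(carrier, np.where(hom, 2, 1), 0).astype(np.int8)

    # pipeline-private false-positive position pool, disjoint from truth
    truth_offsets = np.array(_truth_offsets(config, sim.truth), dtype=np.int64)
    free = np.setdiff1d(np.arange(config.genome_length), truth_offsets)
    callsets: Dict[str, List[SampleCallSet]] = {}
    pipelines = ("a", "b")
    n_fp_expected = [
        int(round(rate * n_sites)) for rate in config.fp_rate
    ]
    fp_needed = sum(n * n_samples for n in n_fp_expected)
    fp_pool = rng.choice(free, size=min(fp_needed, len(free)), replace=False)
    pool_cursor = 0

    chroms = sim.truth["chrom"].to_numpy()
    positions = sim.truth["pos"].to_numpy()
    refs = sim.truth["ref"].to_numpy()
    alts = sim.truth["alt"].to_numpy()

    for pi, pipeline in enumerate(pipelines):
        fn = config.fn_rate[pi]
        per_sample = []
        detected = (codes > 0) & (rng.random((n_sites, n_samples)) >= fn)
        for j in range(n_samples):
            idx = np.flatnonzero(detected[:, j])
            n_fp = n_fp_expected[pi]
            fp_offsets = fp_pool[pool_cursor : pool_cursor + n_fp]
            pool_cursor += n_fp
            records = []
            qual = np.clip(
                rng.normal(config.quality_mean, config.quality_sd, size=len(idx) + n_fp),
                0.0, None,
            )
            depth = rng.poisson(config.depth_mean, size=len(idx) + n_fp)
            for t, i in enumerate(idx):
                ref, alt = refs[i], alts[i]
                gt = (alt, alt) if codes[i, j] == 2 else (ref, alt)
                records.append(
                    SnvRecord(
                        position=GenomicPosition(chroms[i], int(positions[i])),
                        ref=ref,
                        alts=(alt,),
                        genotype=gt,
                        quality=float(qual[t]),
                        depth=int(depth[t]),
                    )
                )
            fp_chroms, fp_pos = _offsets_to_positions(config, np.sort(fp_offsets))
            for t, (c, p) in enumerate(zip(fp_chroms, fp_pos)):
                ref = sim.genome_new[c][p - 1]
                alt = TRANSITION[ref] if rng.random() < config.ts_fraction else (
                    TRANSVERSIONS[ref][rng.integers(2)]
                )
                records.append(
                    SnvRecord(
                        position=GenomicPosition(c, int(p)),
                        ref=ref,
                        alts=(alt,),
                        genotype=(ref, alt),
                        quality=float(qual[len(idx) + t]),
                        depth=int(depth[len(idx) + t]),
                    )
                )
            per_sample.append(
                SampleCallSet(sample_id=samples[j], pipeline_id=pipeline, records=records)
            )
        callsets[pipeline] = per_sample
    return SimCohort(callsets=callsets, carrier_codes=codes, samples=samples)


def _truth_offsets(config: SimConfig, truth: pd.DataFrame):
    starts = {}
    start = 0
    for name, length in config.contig_lengths:
        starts[name] = start
        start += length
    return [starts[c] + p - 1 for c, p in zip(truth["chrom"], truth["pos"])]


def simulate_panels(sim: SimTruth, block_size: int = 50_000) -> SimPanels:
    """Build both reference panels, the coordinate map and the old genome.

    The old assembly inserts a random non-negative pad in front of every
    ``block_size`` block, so old positions are new positions plus a
    piecewise-constant cumulative offset; the map is injective and the
    old genome carries the same base at each mapped position.
    """
    config = sim.config
    rng = _rng(config, 3)
    truth = sim.truth

    # a multi-rsID site carries its alias in panel 1 and its primary rsID in
    # panel 2, so after harmonization the position holds two identifiers and
    # exercises the one-rsID-per-site resolution
    panel1 = PanelDataset(name="panel1", assembly="new")
    for row in truth.itertuples(index=False):
        if row.panel_label in ("both", "panel1_only"):
            panel1.add_site(
                PanelSite(
                    position=GenomicPosition(row.chrom, int(row.pos)),
                    rsid=row.extra_rsid if row.extra_rsid else row.rsid,
                    ref=row.ref,
                    alts=(row.alt,),
                    assembly="new",
                    is_snv=True,
                )
            )

    # piecewise offsets and the old-assembly genome
    genome_old: Dict[str, str] = {}
    offset_fn: Dict[str, np.ndarray] = {}
    for name, length in config.contig_lengths:
        n_blocks = (length + block_size - 1) // block_size
        pads = rng.integers(0, 200, size=n_blocks)
        cum = np.cumsum(pads)
        offset_fn[name] = cum
        pieces = []
        seq = sim.genome_new[name]
        for b in range(n_blocks):
            pad = pads[b]
            pieces.append(_random_sequence(rng, int(pad)))
            pieces.append(seq[b * block_size : (b + 1) * block_size])
        genome_old[name] = "".join(pieces)

    def to_old(chrom: str, pos: int) -> int:
        return pos + int(offset_fn[chrom][(pos - 1) // block_size])

    panel2 = PanelDataset(name="panel2", assembly="old")
    cmap = CoordinateMap()
    in_panel2 = truth["panel_label"].isin(["both", "panel2_only"]).to_numpy()
    fail = rng.random(len(truth)) < config.liftover_failure_fraction
    for i, row in enumerate(truth.itertuples(index=False)):
        if not in_panel2[i]:
            continue
        old_pos = GenomicPosition(row.chrom, to_old(row.chrom, int(row.pos)))
        panel2.add_site(
            PanelSite(
                position=old_pos,
                rsid=row.rsid,
                ref=row.ref,
                alts=(row.alt,),
                assembly="old",
                is_snv=True,
            )
        )
        if not fail[i]:
            cmap.add(old_pos, GenomicPosition(row.chrom, int(row.pos)))

    # planted invalid sites: indel-like entries and pairs sharing one rsID,
    # at otherwise unused old-assembly positions
    n_planted = 0
    free_old = _free_old_positions(config, genome_old, panel2, rng)
    for _ in range(config.indel_sites):
        pos = next(free_old)
        panel2.add_site(
            PanelSite(
                position=pos, rsid=f"rsindel{n_planted}", ref="AT", alts=("A",),
                assembly="old", is_snv=False,
            )
        )
        n_planted += 1
    for d in range(config.nonunique_rsid_pairs):
        shared = f"rsdup{d}"
        for _ in range(2):
            pos = next(free_old)
            ref = genome_old[pos.chrom][pos.pos - 1]
            panel2.add_site(
                PanelSite(
                    position=pos, rsid=shared, ref=ref,
                    alts=(TRANSITION[ref],), assembly="old", is_snv=True,
                )
            )
            n_planted += 1

    return SimPanels(
        panel1=panel1,
        panel2_old=panel2,
        coordinate_map=cmap,
        genome_old=genome_old,
        n_planted_invalid=n_planted,
    )


def _free_old_positions(config, genome_old, panel2, rng):
    taken = {(s.position.chrom, s.position.pos) for s in panel2.sites.values()}
    while True:
        name, _ = config.contig_lengths[int(rng.integers(len(config.contig_lengths)))]
        p = int(rng.integers(1, len(genome_old[name]) + 1))
        if (name, p) not in taken:
            taken.add((name, p))
            yield GenomicPosition(name, p)


def simulate_annotations_terms(sim: SimTruth) -> SimAnnotations:
    """Emit VEP-style annotations and a term catalog with one planted term.

    The planted term's member genes are drawn with sampling weight
    ``planted_odds`` for genes carrying non-synonymous population-only
    variants and 1 for all others; odds 1 reduces to a null term.
    """
    config = sim.config
    rng = _rng(config, 4)
    annotations = [
        AnnotationRecord(
            position=GenomicPosition(row.chrom, int(row.pos)),
            alt=row.alt,
            consequence_terms=tuple(row.terms),
            gene_symbol=row.gene,
        )
        for row in sim.truth.itertuples(index=False)
    ]

    universe = {f"GENE{i:04d}" for i in range(config.n_genes)}
    nonsyn = set(NONSYN_TERMS)
    target_genes = {
        row.gene
        for row in sim.truth.itertuples(index=False)
        if row.gene and row.panel_label == "none" and set(row.terms) & nonsyn
    }

    genes_sorted = sorted(universe)
    terms: Dict[str, set] = {}
    names: Dict[str, str] = {}
    for t in range(config.n_terms):
        tid = f"T{t:03d}"
        members = rng.choice(genes_sorted, size=config.term_size, replace=False)
        terms[tid] = set(members)
        names[tid] = f"null term {t}"
    weights = np.array(
        [config.planted_odds if g in target_genes else 1.0 for g in genes_sorted]
    )
    weights = weights / weights.sum()
    planted = rng.choice(genes_sorted, size=config.term_size, replace=False, p=weights)
    terms["T_PLANTED"] = set(planted)
    names["T_PLANTED"] = "planted term"
    catalog = TermCatalog(terms=terms, term_names=names, universe=universe)
    return SimAnnotations(
        annotations=annotations, catalog=catalog, planted_term_id="T_PLANTED"
    )


# ---------------------------------------------------------------------------
# writing a simulated dataset to disk in every accepted format
# ---------------------------------------------------------------------------

def write_simulation(outdir, sim: SimTruth, cohort: SimCohort, panels: SimPanels,
                     ann: SimAnnotations) -> Dict[str, object]:
    """Write all simulated inputs under ``outdir``; returns a path manifest."""
    outdir = Path(outdir)
    (outdir / "calls_a").mkdir(parents=True, exist_ok=True)
    (outdir / "calls_b").mkdir(exist_ok=True)

    paths: Dict[str, object] = {}
    for cs in cohort.callsets["a"]:
        p = outdir / "calls_a" / f"{cs.sample_id}.vcf"
        pio.write_sample_calls(cs, p, dialect="vcf")
    for cs in cohort.callsets["b"]:
        p = outdir / "calls_b" / f"{cs.sample_id}.tsv"
        pio.write_sample_calls(cs, p, dialect="tsv-caller")
    paths["calls_a"] = sorted((outdir / "calls_a").glob("*.vcf"))
    paths["calls_b"] = sorted((outdir / "calls_b").glob("*.tsv"))

    paths["panel1_vcf"] = outdir / "panel1.vcf"
    _write_panel_vcf(panels.panel1, paths["panel1_vcf"])

    # HapMap-style: two overlapping population tables whose union is panel 2
    rng = _rng(sim.config, 5)
    sites = sorted(panels.panel2_old.sites.values(), key=lambda s: s.position.sort_key())
    in1 = rng.random(len(sites)) < 0.7
    in2 = rng.random(len(sites)) < 0.7
    neither = ~(in1 | in2)
    in1 |= neither
    for pop, mask in (("pop1", in1), ("pop2", in2)):
        p = outdir / f"hapmap_{pop}.tsv"
        with open(p, "w") as fh:
            fh.write("rsid\tchrom\tpos\tref\talt\n")
            for s, m in zip(sites, mask):
                if m:
                    fh.write(
                        f"{s.rsid or '.'}\t{s.position.chrom}\t{s.position.pos}\t"
                        f"{s.ref}\t{','.join(s.alts)}\n"
                    )
        paths[f"hapmap_{pop}"] = p

    paths["coordinate_map"] = outdir / "liftover_map.tsv"
    pio.write_coordinate_map(panels.coordinate_map, paths["coordinate_map"])
    paths["genome_new"] = outdir / "genome_new.fa"
    pio.write_fasta(sim.genome_new, paths["genome_new"])
    paths["genome_old"] = outdir / "genome_old.fa"
    pio.write_fasta(panels.genome_old, paths["genome_old"])
    paths["vep"] = outdir / "annotations.tsv"
    pio.write_vep_table(ann.annotations, paths["vep"])

    rows = []
    for tid in sorted(ann.catalog.terms):
        for g in sorted(ann.catalog.terms[tid]):
            rows.append({"term_id": tid, "term_name": ann.catalog.term_names[tid],
                         "gene_symbol": g})
    paths["terms"] = outdir / "terms.tsv"
    pio.write_gene_term_table(pd.DataFrame(rows), paths["terms"])

    paths["truth"] = outdir / "truth.tsv"
    truth_out = sim.truth.copy()
    truth_out["terms"] = [",".join(t) for t in truth_out["terms"]]
    truth_out.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def _write_panel_vcf(panel: PanelDataset, path) -> None:
    from .model import chrom_sort_key

    sites = sorted(panel.sites.values(), key=lambda s: s.position.sort_key())
    chroms = sorted({s.position.chrom for s in sites}, key=chrom_sort_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            vt = "SNP" if s.is_snv else "INDEL"
            fh.write(
                f"{s.position.chrom}\t{s.position.pos}\t{s.rsid or '.'}\t{s.ref}\t"
                f"{','.join(s.alts)}\t.\tPASS\tVT={vt}\n"
            )
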