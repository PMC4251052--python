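"""Readers and writers for every external format the pipeline touches.

Formats
-------
* per-sample call sets: VCF 4.x (via cyvcf2/htslib) or the documented
  tab-separated caller dialect (header ``chrom pos ref alt genotype
  quality depth``, genotype written ``A/G``, alts comma-separated);
* reference panels: sites VCF with an ``INFO`` column (``VT=SNP``
  filtering), or HapMap-style per-population genotype site tables;
* genome sequence: FASTA, indexed through pyfaidx;
* coordinate map: four-column TSV (chrom_old, pos_old, chrom_new, pos_new);
* consequence annotation: VEP-style TSV (Uploaded_variation, Location,
  Allele, Gene, Consequence);
* gene→term associations: TSV (term_id, term_name, gene_symbol);
* report tables: deterministic TSV (stable column order, percentages to
  3 decimals, p-values in 2-significant-digit scientific notation).

Tolerant parsing: malformed lines in the tab-separated dialects are
skipped and counted; if more than 10% of data lines fail, the file is
rejected as malformed.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import pandas as pd
from cyvcf2 import VCF

from .model import (
    AnnotationRecord,
    CoordinateMap,
    GenomicPosition,
    PanelDataset,
    PanelSite,
    SampleCallSet,
    SnvRecord,
    chrom_sort_key,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

MAX_MALFORMED_FRACTION = 0.10

TSV_CALLER_COLUMNS = ["chrom", "pos", "ref", "alt", "genotype", "quality", "depth"]


class MalformedFileError(ValueError):
    """Raised when a file fails wholesale parsing (bad header, >10% bad lines)."""


class ReferenceBase(NamedTuple):
    """A genome base lookup result; ``known`` is False for masked (N) bases."""

    base: str
    known: bool


# ---------------------------------------------------------------------------
# per-sample call sets
# ---------------------------------------------------------------------------

def _record_from_vcf_variant(v) -> Optional[SnvRecord]:
    if v.REF is None or len(v.REF) != 1 or not v.ALT:
        return None
    alts = tuple(a for a in v.ALT if len(a) == 1 and a in "ACGT")
    if len(alts) != len(v.ALT) or v.REF not in "ACGT":
        return None
    alleles = [v.REF, *alts]
    gt = v.genotypes[0] if len(v.genotypes) else [0, 0, False]
    idx = [i if i >= 0 else 0 for i in gt[:2]]
    genotype = tuple(alleles[i] for i in idx)
    depth = v.format("DP")
    if depth is not None:
        depth = int(depth[0][0])
    else:
        depth = int(v.INFO.get("DP", 0))
    return SnvRecord(
        position=GenomicPosition.make(v.CHROM, v.POS),
        ref=v.REF,
        alts=alts,
        genotype=genotype,
        quality=float(v.QUAL) if v.QUAL is not None else 0.0,
        depth=depth,
        rsid=v.ID if v.ID not in (None, ".") else None,
    )


def _read_calls_vcf(path: Path, sample_id: str, pipeline_id: str) -> SampleCallSet:
    records = []
    skipped = 0
    vcf = VCF(str(path))
    try:
        if len(vcf.samples) > 1:
            raise MalformedFileError(f"{path}: expected a single-sample VCF")
        for v in vcf:
            rec = _record_from_vcf_variant(v)
            if rec is None:
                skipped += 1
                continue
            records.append(rec)
    finally:
        vcf.close()
    if skipped:
        logger.warning("%s: skipped %d non-SNV/malformed variant lines", path, skipped)
    return SampleCallSet(sample_id=sample_id, pipeline_id=pipeline_id, records=records)


def _parse_tsv_caller_line(fields: list) -> SnvRecord:
    chrom, pos, ref, alt, genotype, quality, depth = fields
    alts = tuple(alt.split(","))
    gt = tuple(genotype.split("/"))
    return SnvRecord(
        position=GenomicPosition.make(chrom, int(pos)),
        ref=ref,
        alts=alts,
        genotype=gt,
        quality=float(quality),
        depth=int(depth),
    )


def _read_calls_tsv(path: Path, sample_id: str, pipeline_id: str) -> SampleCallSet:
    records = []
    n_bad = n_total = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_CALLER_COLUMNS:
            raise MalformedFileError(
                f"{path}: bad caller-dialect header {header!r}; "
                f"expected {TSV_CALLER_COLUMNS}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            n_total += 1
            fields = line.split("\t")
            try:
                if len(fields) != 7:
                    raise ValueError("wrong field count")
                records.append(_parse_tsv_caller_line(fields))
            except ValueError as exc:
                n_bad += 1
                logger.warning("%s: skipping malformed line (%s): %r", path, exc, line)
    if n_total and n_bad / n_total > MAX_MALFORMED_FRACTION:
        raise MalformedFileError(
            f"{path}: {n_bad}/{n_total} lines malformed (>{MAX_MALFORMED_FRACTION:.0%})"
        )
    return SampleCallSet(sample_id=sample_id, pipeline_id=pipeline_id, records=records)


def read_sample_calls(
    path, dialect: str = "vcf", sample_id: Optional[str] = None,
    pipeline_id: str = "unknown",
) -> SampleCallSet:
    """Read one sample's SNV calls from ``path``.

    ``dialect`` is ``"vcf"`` or ``"tsv-caller"``. Duplicate positions
    within the sample raise a validation error naming the position.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if dialect == "vcf":
        return _read_calls_vcf(path, sample_id, pipeline_id)
    if dialect == "tsv-caller":
        return _read_calls_tsv(path, sample_id, pipeline_id)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_sample_calls(callset: SampleCallSet, path, dialect: str = "tsv-caller") -> None:
    """Write a call set; round-trips exactly through :func:`read_sample_calls`."""
    path = Path(path)
    if dialect == "tsv-caller":
        with open(path, "w") as fh:
            fh.write("\t".join(TSV_CALLER_COLUMNS) + "\n")
            for r in callset:
                fh.write(
                    "\t".join(
                        [
                            r.position.chrom,
                            str(r.position.pos),
                            r.ref,
                            ",".join(r.alts),
                            "/".join(r.genotype),
                            format_number(r.quality),
                            str(r.depth),
                        ]
                    )
                    + "\n"
                )
        return
    if dialect == "vcf":
        chroms = sorted({r.position.chrom for r in callset}, key=chrom_sort_key)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + callset.sample_id
                + "\n"
            )
            for r in callset:
                alleles = [r.ref, *r.alts]
                gt = "/".join(str(alleles.index(a)) for a in r.genotype)
                fh.write(
                    "\t".join(
                        [
                            r.position.chrom,
                            str(r.position.pos),
                            r.rsid or ".",
                            r.ref,
                            ",".join(r.alts),
                            format_number(r.quality),
                            "PASS",
                            ".",
                            "GT:DP",
                            f"{gt}:{r.depth}",
                        ]
                    )
                    + "\n"
                )
        return
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# reference panels
# ---------------------------------------------------------------------------

def read_panel_vcf(
    path, name: str = "panel", assembly: str = "new",
    vt_exempt_chroms: Iterable[str] = ("Y",),
) -> PanelDataset:
    """Read a sites VCF into a :class:`PanelDataset`.

    Autosome and X sites are kept only when the INFO field carries
    ``VT=SNP``; chromosomes in ``vt_exempt_chroms`` (by default Y) are
    kept unconditionally.
    """
    exempt = {normalize_chrom(c) for c in vt_exempt_chroms}
    panel = PanelDataset(name=name, assembly=assembly)
    vcf = VCF(str(path))
    try:
        for v in vcf:
            chrom = normalize_chrom(v.CHROM)
            if chrom not in exempt and v.INFO.get("VT") != "SNP":
                continue
            alts = tuple(v.ALT or ())
            is_snv = (
                v.REF is not None and len(v.REF) == 1
                and alts != () and all(len(a) == 1 for a in alts)
            )
            panel.add_site(
                PanelSite(
                    position=GenomicPosition.make(chrom, v.POS),
                    rsid=v.ID if v.ID not in (None, ".") else None,
                    ref=v.REF,
                    alts=alts,
                    assembly=assembly,
                    is_snv=is_snv,
                )
            )
    finally:
        vcf.close()
    return panel


HAPMAP_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt"]


def read_hapmap_genotypes(
    paths_by_population: dict, name: str = "hapmap", assembly: str = "old",
) -> PanelDataset:
    """Merge HapMap-style per-population site tables into one panel.

    The merged panel is the union of sites over populations. The same
    rsID appearing at two distinct positions is retained as two sites
    (flagged for removal downstream by the harmonization step); the same
    position with conflicting reference alleles is a validation error.
    """
    if not paths_by_population:
        raise ValueError("need at least one population file")
    panel = PanelDataset(name=name, assembly=assembly)
    presence: dict = {}
    for pop, path in sorted(paths_by_population.items()):
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns) != HAPMAP_COLUMNS:
            raise MalformedFileError(
                f"{path}: expected columns {HAPMAP_COLUMNS}, got {list(df.columns)}"
            )
        for row in df.itertuples(index=False):
            position = GenomicPosition.make(row.chrom, int(row.pos))
            site = panel.sites.get(position)
            if site is not None:
                if site.ref != row.ref:
                    raise ValueError(
                        f"conflicting reference alleles for {row.rsid} at "
                        f"{position.chrom}:{position.pos}: {site.ref} vs {row.ref}"
                    )
            else:
                alts = tuple(row.alt.split(","))
                is_snv = len(row.ref) == 1 and all(len(a) == 1 for a in alts)
                panel.add_site(
                    PanelSite(
                        position=position,
                        rsid=row.rsid if row.rsid != "." else None,
                        ref=row.ref,
                        alts=alts,
                        assembly=assembly,
                        is_snv=is_snv,
                    )
                )
            presence.setdefault(position, set()).add(pop)
    panel.population_presence = presence
    return panel


def write_panel_tsv(panel: PanelDataset, path) -> None:
    """Harmonized panel as a sorted site TSV."""
    rows = sorted(panel.sites.values(), key=lambda s: s.position.sort_key())
    with open(path, "w") as fh:
        fh.write("chrom\tpos\trsid\tref\talts\tsource_panel\n")
        for s in rows:
            fh.write(
                f"{s.position.chrom}\t{s.position.pos}\t{s.rsid or '.'}\t"
                f"{s.ref or '.'}\t{','.join(s.alts) or '.'}\t{panel.name}\n"
            )


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------

def lookup_reference_allele(genome, position: GenomicPosition) -> ReferenceBase:
    """Look up the genome base at a 1-based position.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of chromosome →
    sequence supporting slicing). Masked bases (N) are returned with
    ``known=False`` rather than raising.
    """
    keys = set(genome.keys())
    chrom = position.chrom if position.chrom in keys else "chr" + position.chrom
    if chrom not in keys:
        raise KeyError(f"chromosome {position.chrom} not in genome")
    contig = genome[chrom]
    if position.pos > len(contig):
        raise IndexError(
            f"position {position.pos} beyond end of {position.chrom} ({len(contig)} bp)"
        )
    base = str(contig[position.pos - 1 : position.pos]).upper()
    return ReferenceBase(base=base, known=base in "ACGT")


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# coordinate map
# ---------------------------------------------------------------------------

def read_coordinate_map(path) -> CoordinateMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom_old": str, "chrom_new": str})
    expected = ["chrom_old", "pos_old", "chrom_new", "pos_new"]
    if list(df.columns) != expected:
        raise MalformedFileError(f"{path}: expected columns {expected}")
    cmap = CoordinateMap()
    for row in df.itertuples(index=False):
        cmap.add(
            GenomicPosition.make(row.chrom_old, int(row.pos_old)),
            GenomicPosition.make(row.chrom_new, int(row.pos_new)),
        )
    return cmap


def write_coordinate_map(cmap: CoordinateMap, path) -> None:
    items = sorted(cmap.items(), key=lambda kv: kv[0].sort_key())
    with open(path, "w") as fh:
        fh.write("chrom_old\tpos_old\tchrom_new\tpos_new\n")
        for old, new in items:
            fh.write(f"{old.chrom}\t{old.pos}\t{new.chrom}\t{new.pos}\n")


# ---------------------------------------------------------------------------
# consequence annotation (VEP-style table)
# ---------------------------------------------------------------------------

VEP_COLUMNS = ["Uploaded_variation", "Location", "Allele", "Gene", "Consequence"]


def read_vep_table(path) -> list:
    """Parse a VEP-style tab-separated annotation table into records.

    ``Location`` is ``chrom:pos``; ``Consequence`` is a comma-separated
    list of controlled-vocabulary terms.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != VEP_COLUMNS:
        raise MalformedFileError(f"{path}: expected columns {VEP_COLUMNS}")
    out = []
    for row in df.itertuples(index=False):
        chrom, pos = row.Location.split(":")
        out.append(
            AnnotationRecord(
                position=GenomicPosition.make(chrom, int(pos)),
                alt=row.Allele,
                consequence_terms=tuple(row.Consequence.split(",")),
                gene_symbol=None if row.Gene in ("-", ".", "") or pd.isna(row.Gene)
                else row.Gene,
            )
        )
    return out


def write_vep_table(annotations: Iterable[AnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VEP_COLUMNS) + "\n")
        for a in annotations:
            loc = f"{a.position.chrom}:{a.position.pos}"
            fh.write(
                f"{a.position.chrom}_{a.position.pos}_{a.alt}\t{loc}\t{a.alt}\t"
                f"{a.gene_symbol or '-'}\t{','.join(a.consequence_terms)}\n"
            )


# ---------------------------------------------------------------------------
# gene→term association tables
# ---------------------------------------------------------------------------

TERM_COLUMNS = ["term_id", "term_name", "gene_symbol"]


def read_gene_term_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != TERM_COLUMNS:
        raise MalformedFileError(f"{path}: expected columns {TERM_COLUMNS}")
    return df


def write_gene_term_table(df: pd.DataFrame, path) -> None:
    df.loc[:, TERM_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def format_percent(x: float) -> str:
    return f"{x:.3f}"


def format_pvalue(p: float) -> str:
    if p == 0:
        return "0.0E+00"
    return f"{p:.1E}"


def format_number(x) -> str:
    if isinstance(x, float):
        if math.isinf(x):
            return "inf"
        if x == int(x):
            return str(int(x))
        return f"{x:.6g}"
    return str(x)


def write_report_table(table: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write a report table with deterministic byte output.

    Column order follows the DataFrame; percentage columns (named
    ``*percent*``) print 3 decimals, p-value columns (``p_raw`` /
    ``p_adjusted`` / ``*pvalue*``) print 2-significant-digit scientific
    notation, all other floats a compact general format.
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported format {fmt!r}")
    cols = list(table.columns)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in table.itertuples(index=False):
            out = []
            for col, val in zip(cols, row):
                lc = col.lower()
                if isinstance(val, float) and ("percent" in lc or lc.endswith("_pct")):
                    out.append(format_percent(val))
                elif isinstance(val, float) and ("pvalue" in lc or lc in ("p_raw", "p_adjusted")):
                    out.append(format_pvalue(val))
                else:
                    out.append(format_number(val))
            fh.write("\t".join(out) + "\n")
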