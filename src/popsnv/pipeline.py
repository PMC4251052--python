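"""End-to-end orchestration: one config file in, a report bundle out.

Stages: per-sample filtering → cohort merge per pipeline → positional
consensus → panel harmonization → partition against panels → occurrence
stratification → substitution spectrum → consequence category tables →
per-gene counts → term enrichment → report tables plus a run manifest
(seeds, thresholds, input checksums, stage counts). Outputs are a pure
function of (inputs, config); re-running a config reproduces identical
bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .enrichment import TermCatalog, enrich, results_frame
from .filtering import (
    CohortMatrix,
    ConsensusSet,
    FilterThresholds,
    filter_calls,
    intersect_pipelines,
    merge_cohort,
)
from .harmonize import (
    dedup_rsids,
    liftover_sites,
    merge_panels,
    remove_invalid_sites,
    rescue_failed_by_rsid,
)
from .model import GenomicPosition
from .partition import (
    PartitionResult,
    occurrence_distribution,
    occurrences_by_site,
    partition_snvs,
    snv_i,
)
from .spectrum import (
    nonsyn_fraction,
    nonsyn_variants,
    snv_count_per_gene,
    spectrum_summary,
    tabulate_categories,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    # pipeline a: depth-only post-filter (mpileup-style calling)
    "a": {"min_quality": 0.0, "min_neighbor_distance": 0, "min_depth": 5},
    # pipeline b: quality / neighbour-distance / depth post-filters
    "b": {"min_quality": 20.0, "min_neighbor_distance": 5, "min_depth": 3},
}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunResult:
    consensus: ConsensusSet
    partition: PartitionResult
    groups: Dict[str, set]
    snv_i_sizes: pd.DataFrame
    occurrence_hist_consensus: pd.DataFrame
    occurrence_hist_population_only: pd.DataFrame
    spectra: Dict[str, object]
    category_tables: Dict[str, object]
    nonsyn_fractions: Dict[str, float]
    gene_counts: Dict[str, pd.DataFrame]
    enrichment: pd.DataFrame
    manifest: Dict[str, object]
    output_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def report_set_groups(consensus: ConsensusSet, partition: PartitionResult) -> Dict[str, set]:
    """The five report groups of consensus sites.

    ``population_only_min`` is the whole population-only set (occurrence
    ≥ 1) and ``population_only_max`` its subset fixed in every sample;
    ``shared_panel1`` = in panel 1 (alone or with panel 2),
    ``shared_both`` = in both panels, ``shared_either`` = in at least
    one panel, so shared_both ⊆ shared_panel1 ⊆ shared_either.
    """
    pop = partition.positions(consensus, "population_only")
    both = partition.positions(consensus, "shared_both")
    p1only = partition.positions(consensus, "shared_panel1_only")
    p2only = partition.positions(consensus, "shared_panel2_only")
    occ = occurrences_by_site(consensus, pop)
    n = consensus.n_samples()
    fixed = {p for p, o in occ.items() if o >= n}
    return {
        "population_only_min": pop,
        "population_only_max": fixed,
        "shared_panel1": both | p1only,
        "shared_both": both,
        "shared_either": both | p1only | p2only,
    }


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


@_stage("read_and_filter")
def _read_and_filter(cfg) -> Dict[str, List]:
    out = {}
    for pipeline in ("a", "b"):
        paths = cfg["inputs"][f"calls_{pipeline}"]
        dialect = cfg["inputs"].get(f"calls_{pipeline}_dialect", "vcf")
        th = FilterThresholds(**cfg.get("thresholds", DEFAULT_THRESHOLDS)[pipeline])
        callsets = []
        for p in paths:
            cs = pio.read_sample_calls(p, dialect=dialect, pipeline_id=pipeline)
            filtered, stats = filter_calls(cs, th)
            logger.info(
                "filter %s/%s: %d in, %d kept (q:%d nd:%d d:%d removed)",
                pipeline, cs.sample_id, stats.n_input, stats.n_retained,
                stats.n_removed_quality, stats.n_removed_neighbor,
                stats.n_removed_depth,
            )
            callsets.append(filtered)
        out[pipeline] = callsets
    return out


@_stage("consensus")
def _consensus(cfg, callsets) -> ConsensusSet:
    a = merge_cohort(callsets["a"])
    b = merge_cohort(callsets["b"])
    cons = intersect_pipelines(a, b, genotype_source=cfg.get("genotype_source", "b"))
    logger.info(
        "consensus: %d sites (%.2f%% of a, %.2f%% of b)",
        len(cons), 100 * cons.coverage_a, 100 * cons.coverage_b,
    )
    return cons


@_stage("harmonize")
def _harmonize(cfg, consensus):
    inputs = cfg["inputs"]
    panel1 = pio.read_panel_vcf(inputs["panel1_vcf"], name="panel1", assembly="new")
    panel2 = None
    if inputs.get("hapmap"):
        raw = pio.read_hapmap_genotypes(
            {pop: p for pop, p in inputs["hapmap"].items()}, name="panel2",
            assembly="old",
        )
        cleaned, removed = remove_invalid_sites(raw)
        cmap = pio.read_coordinate_map(inputs["coordinate_map"])
        converted, failed = liftover_sites(cleaned, cmap)
        rescued, lost = rescue_failed_by_rsid(failed, panel1)
        assert len(converted) + len(rescued) + len(lost) == len(cleaned)
        panel2 = merge_panels("panel2", converted, rescued)
        logger.info(
            "harmonize panel2: %d raw, %d removed, %d converted, %d rescued, %d lost",
            len(raw), len(removed), len(converted), len(rescued), len(lost),
        )
    else:
        logger.warning("no second panel configured; partition runs in one-panel mode")
    seed = int(cfg.get("seed", 0))
    datasets = {"panel1": panel1}
    if panel2 is not None:
        datasets["panel2"] = panel2
    datasets = dedup_rsids(datasets, seed=seed)
    return datasets["panel1"], datasets.get("panel2")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = Path(path).parent
    inputs = cfg.get("inputs", {})

    def resolve(v):
        p = base / v
        return str(p) if p.exists() else v

    for key, val in list(inputs.items()):
        if isinstance(val, str):
            inputs[key] = resolve(val)
        elif isinstance(val, list):
            inputs[key] = [resolve(x) for x in val]
        elif isinstance(val, dict):
            inputs[key] = {k: resolve(x) for k, x in val.items()}
    return cfg


def run_pipeline(config, output_dir: Optional[str] = None) -> RunResult:
    """Execute the full analysis from a config mapping or YAML path."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = config
    outdir = Path(output_dir or cfg.get("output_dir", "results/run"))
    outdir.mkdir(parents=True, exist_ok=True)

    callsets = _read_and_filter(cfg)
    consensus = _consensus(cfg, callsets)
    panel1, panel2 = _harmonize(cfg, consensus)
    partition = partition_snvs(consensus, panel1, panel2)

    # occurrence stratification
    n = consensus.n_samples()
    all_occ = occurrences_by_site(consensus)
    pop_positions = partition.positions(consensus, "population_only")
    pop_occ = {p: all_occ[p] for p in pop_positions}
    strata = [snv_i(pop_occ, i, n) for i in range(1, n + 1)]
    snv_i_sizes = pd.DataFrame(
        {"i": range(1, n + 1), "size": [len(s) for s in strata]}
    )
    hist_all = occurrence_distribution(list(all_occ.values()), n)
    hist_pop = occurrence_distribution(list(pop_occ.values()), n)

    groups = report_set_groups(consensus, partition)

    # substitution spectrum per report set
    ref_alt = {
        GenomicPosition(c, p): (r, tuple(a.split(",")))
        for c, p, r, a in zip(
            consensus.sites["chrom"], consensus.sites["pos"],
            consensus.sites["ref"], consensus.sites["alts"],
        )
    }
    spectra = {"consensus": spectrum_summary(ref_alt.values())}
    for gname in ("population_only_min", "population_only_max"):
        members = groups[gname]
        if members:
            spectra[gname] = spectrum_summary([ref_alt[p] for p in members])

    # consequence categories and per-gene counts
    annotations = pio.read_vep_table(cfg["inputs"]["vep"])
    category_tables = {}
    fractions = {}
    gene_counts = {}
    for gname, members in groups.items():
        tab = tabulate_categories(members, annotations, name=gname)
        category_tables[gname] = tab
        fractions[gname] = nonsyn_fraction(tab.counts)
    for gname in ("population_only_min", "population_only_max"):
        gene_counts[gname] = snv_count_per_gene(groups[gname], annotations)
        ns = nonsyn_variants(groups[gname], annotations)
        gene_counts[gname + "_ns"] = snv_count_per_gene(ns, annotations)

    # enrichment on the genes of non-synonymous population-only variants
    catalog = TermCatalog.from_table(pio.read_gene_term_table(cfg["inputs"]["terms"]))
    ns_genes = set(gene_counts["population_only_min_ns"]["gene"])
    min_genes = int(cfg.get("min_genes", 2))
    try:
        results = enrich(ns_genes, catalog, min_genes=min_genes)
        enrichment_table = results_frame(results)
    except ValueError:
        enrichment_table = results_frame([])

    # report bundle
    _write_consensus_vcf(consensus, outdir / "consensus.vcf")
    prov = pd.DataFrame(
        {
            "key": ["pipeline_a", "pipeline_b", "genotype_source",
                    "coverage_a", "coverage_b", "n_sites"],
            "value": [consensus.pipeline_a, consensus.pipeline_b,
                      consensus.genotype_source, f"{consensus.coverage_a:.6f}",
                      f"{consensus.coverage_b:.6f}", str(len(consensus))],
        }
    )
    pio.write_report_table(prov, outdir / "consensus_provenance.tsv")
    part_tab = pd.DataFrame(
        {
            "label": list(partition.counts),
            "count": list(partition.counts.values()),
            "percent": [100.0 * partition.fractions[k] for k in partition.counts],
        }
    )
    pio.write_report_table(part_tab, outdir / "partition.tsv")
    _write_partition_bed(consensus, partition, all_occ, outdir / "partition_sites.tsv")
    pio.write_report_table(snv_i_sizes, outdir / "snv_i_sizes.tsv")
    pio.write_report_table(hist_all, outdir / "occurrence_hist_consensus.tsv")
    pio.write_report_table(hist_pop, outdir / "occurrence_hist_population_only.tsv")
    for gname, summ in spectra.items():
        pio.write_report_table(summ.to_frame(), outdir / f"spectrum_{gname}.tsv")
    for gname, tab in category_tables.items():
        pio.write_report_table(tab.table, outdir / f"categories_{gname}.tsv")
    for gname, gc in gene_counts.items():
        pio.write_report_table(gc, outdir / f"genes_{gname}.tsv")
    pio.write_report_table(enrichment_table, outdir / "enrichment.tsv")

    manifest = {
        "version": __version__,
        "seed": int(cfg.get("seed", 0)),
        "genotype_source": cfg.get("genotype_source", "b"),
        "thresholds": cfg.get("thresholds", DEFAULT_THRESHOLDS),
        "min_genes": min_genes,
        "inputs": _input_checksums(cfg["inputs"]),
        "counts": {
            "consensus_sites": len(consensus),
            "partition": partition.counts,
            "snv_1": int(snv_i_sizes["size"].iloc[0]),
            f"snv_{n}": int(snv_i_sizes["size"].iloc[-1]),
            "n_samples": n,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunResult(
        consensus=consensus,
        partition=partition,
        groups=groups,
        snv_i_sizes=snv_i_sizes,
        occurrence_hist_consensus=hist_all,
        occurrence_hist_population_only=hist_pop,
        spectra=spectra,
        category_tables=category_tables,
        nonsyn_fractions=fractions,
        gene_counts=gene_counts,
        enrichment=enrichment_table,
        manifest=manifest,
        output_dir=outdir,
    )


def _input_checksums(inputs: dict) -> dict:
    out = {}
    for key, val in sorted(inputs.items()):
        if isinstance(val, (str, Path)) and Path(val).exists():
            out[key] = _sha256(Path(val))
        elif isinstance(val, list):
            out[key] = [_sha256(Path(p)) for p in val]
        elif isinstance(val, dict):
            out[key] = {k: _sha256(Path(p)) for k, p in sorted(val.items())}
    return out


def _write_consensus_vcf(consensus: ConsensusSet, path) -> None:
    from .model import chrom_sort_key

    chroms = sorted(set(consensus.sites["chrom"]), key=chrom_sort_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(consensus.samples) + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i in range(len(consensus)):
            row = consensus.sites.iloc[i]
            gts = "\t".join(gt_strings[int(g)] for g in consensus.genotypes[i])
            rsid = row["rsid"] if "rsid" in consensus.sites.columns else "."
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{rsid or '.'}\t{row['ref']}\t"
                f"{row['alts']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _write_partition_bed(consensus, partition, occurrences, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart0\tend\tlabel\toccurrence\trsid\n")
        for i in range(len(consensus)):
            c = consensus.sites["chrom"].iat[i]
            p = int(consensus.sites["pos"].iat[i])
            pos = GenomicPosition(c, p)
            fh.write(
                f"{c}\t{p - 1}\t{p}\t{partition.labels.iat[i]}\t"
                f"{occurrences[pos]}\t.\n"
            )
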