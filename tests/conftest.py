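import pytest

from popsnv.model import GenomicPosition, SampleCallSet, SnvRecord
from popsnv.simulate import (
    SimConfig,
    simulate_annotations_terms,
    simulate_cohort_calls,
    simulate_panels,
    simulate_truth,
    write_simulation,
)


def simulate_bundle(outdir, config: SimConfig, include_hapmap: bool = True):
    """Write a full synthetic input bundle; returns a pipeline config dict."""
    sim = simulate_truth(config)
    cohort = simulate_cohort_calls(sim)
    panels = simulate_panels(sim)
    ann = simulate_annotations_terms(sim)
    paths = write_simulation(outdir, sim, cohort, panels, ann)
    cfg = {
        "seed": config.seed,
        "genotype_source": "b",
        "min_genes": 2,
        "output_dir": str(outdir / "report"),
        "inputs": {
            "calls_a": [str(p) for p in paths["calls_a"]],
            "calls_a_dialect": "vcf",
            "calls_b": [str(p) for p in paths["calls_b"]],
            "calls_b_dialect": "tsv-caller",
            "panel1_vcf": str(paths["panel1_vcf"]),
            "coordinate_map": str(paths["coordinate_map"]),
            "vep": str(paths["vep"]),
            "terms": str(paths["terms"]),
        },
    }
    if include_hapmap:
        cfg["inputs"]["hapmap"] = {
            "pop1": str(paths["hapmap_pop1"]),
            "pop2": str(paths["hapmap_pop2"]),
        }
    return cfg


def make_record(chrom="1", pos=100, ref="A", alt="G", genotype=None, quality=50.0,
                depth=10, rsid=None):
    alts = (alt,) if isinstance(alt, str) else tuple(alt)
    if genotype is None:
        genotype = (ref, alts[0])
    return SnvRecord(
        position=GenomicPosition.make(chrom, pos),
        ref=ref,
        alts=alts,
        genotype=genotype,
        quality=quality,
        depth=depth,
        rsid=rsid,
    )


def make_callset(records, sample_id="S1", pipeline_id="b"):
    return SampleCallSet(sample_id=sample_id, pipeline_id=pipeline_id, records=records)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def callset_factory():
    return make_callset
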