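"""Substitution spectrum, consequence categories and per-gene counts.

Summarizes the strand-collapsed substitution classes and Ts/Tv ratio of
the consensus and population-only sets, tabulates consequence categories
for the report groups, and ranks genes by distinct-SNV count.

Writes results/04_spectrum_*.tsv, 04_categories_*.tsv, 04_nonsyn.tsv
and 04_genes_top.tsv.
"""

import pandas as pd

from _common import RESULTS, build_annotations, build_consensus, build_panels, build_truth
from popsnv.io import write_report_table
from popsnv.model import GenomicPosition
from popsnv.partition import partition_snvs
from popsnv.pipeline import report_set_groups
from popsnv.spectrum import (
    nonsyn_fraction,
    nonsyn_variants,
    snv_count_per_gene,
    spectrum_summary,
    tabulate_categories,
)


def main():
    sim = build_truth()
    _, _, _, cons = build_consensus(sim)
    panel1, panel2, _ = build_panels(sim)
    ann = build_annotations(sim)
    RESULTS.mkdir(exist_ok=True)

    part = partition_snvs(cons, panel1, panel2)
    groups = report_set_groups(cons, part)

    ref_alt = {
        GenomicPosition(c, p): (r, tuple(a.split(",")))
        for c, p, r, a in zip(
            cons.sites["chrom"], cons.sites["pos"],
            cons.sites["ref"], cons.sites["alts"],
        )
    }
    summ = spectrum_summary(ref_alt.values())
    write_report_table(summ.to_frame(), RESULTS / "04_spectrum_consensus.tsv")
    print(f"consensus Ts/Tv = {summ.ts_tv_ratio:.3f} over {summ.total} sites")

    rows = []
    for gname in ("population_only_min", "shared_panel1", "shared_both", "shared_either"):
        tab = tabulate_categories(groups[gname], ann.annotations, name=gname)
        write_report_table(tab.table, RESULTS / f"04_categories_{gname}.tsv")
        frac = nonsyn_fraction(tab.counts)
        n_var = len(nonsyn_variants(groups[gname], ann.annotations))
        rows.append({"group": gname, "set_total": tab.set_total,
                     "nonsyn_percent": frac, "nonsyn_variants": float(n_var)})
        print(f"{gname}: {tab.set_total} sites, {frac:.2f}% non-synonymous "
              f"(category counts), {n_var} distinct non-synonymous variants")
    write_report_table(pd.DataFrame(rows), RESULTS / "04_nonsyn.tsv")

    genes = snv_count_per_gene(groups["population_only_min"], ann.annotations)
    write_report_table(genes.head(25), RESULTS / "04_genes_top.tsv")
    if len(genes):
        print(f"top gene by population-only SNV count: "
              f"{genes['gene'].iloc[0]} ({genes['count'].iloc[0]} SNVs) "
              f"of {len(genes)} genes involved")


if __name__ == "__main__":
    main()
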