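"""Harmonize the old-assembly panel, partition the consensus, stratify.

The HapMap-style panel is cleaned (indels, non-unique rsIDs), converted
through the coordinate map, and conversion failures are rescued by rsID
against the target-assembly panel. Consensus sites are then labeled
shared/population-only by position, and the population-only set is
stratified into SNV-i occurrence strata.

Writes results/03_partition.tsv, 03_harmonization.tsv, 03_snv_i_sizes.tsv
and 03_occurrence_hist.tsv.
"""

import pandas as pd

from _common import RESULTS, STUDY, build_consensus, build_panels, build_truth
from popsnv.io import write_report_table
from popsnv.partition import (
    occurrence_distribution,
    occurrences_by_site,
    partition_snvs,
    snv_i,
)


def main():
    sim = build_truth()
    _, _, _, cons = build_consensus(sim)
    panel1, panel2, stats = build_panels(sim)
    RESULTS.mkdir(exist_ok=True)

    write_report_table(
        pd.DataFrame([{"stage": k, "count": v} for k, v in stats.items()]),
        RESULTS / "03_harmonization.tsv",
    )
    assert stats["converted"] + stats["rescued"] + stats["lost"] == (
        stats["raw"] - stats["removed"]
    )

    part = partition_snvs(cons, panel1, panel2)
    write_report_table(
        pd.DataFrame(
            {
                "label": list(part.counts),
                "count": list(part.counts.values()),
                "percent": [100 * part.fractions[k] for k in part.counts],
            }
        ),
        RESULTS / "03_partition.tsv",
    )

    n = cons.n_samples()
    pop = part.positions(cons, "population_only")
    occ = occurrences_by_site(cons, pop)
    sizes = [(i, len(snv_i(occ, i, n))) for i in range(1, n + 1)]
    write_report_table(
        pd.DataFrame(sizes, columns=["i", "size"]), RESULTS / "03_snv_i_sizes.tsv"
    )
    hist = occurrence_distribution(list(occ.values()), n)
    write_report_table(hist, RESULTS / "03_occurrence_hist.tsv")

    print(f"harmonization: {stats}")
    print(f"partition: { {k: v for k, v in part.counts.items()} }")
    print(
        f"population-only: {part.counts['population_only']} sites "
        f"({100 * part.fractions['population_only']:.2f}%, "
        f"configured {100 * STUDY.panel_overlap[3]:.1f}%)"
    )
    print(f"SNV-1 size {sizes[0][1]}, SNV-{n} size {sizes[-1][1]}; "
          f"singletons {hist['percent'].iloc[0]:.2f}% of population-only")


if __name__ == "__main__":
    main()
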