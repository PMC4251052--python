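"""Recompute the bundled 35-individual cohort report percentages.

Runs the package's reporting arithmetic over the bundled summary counts
(`popsnv.cohort_tables`): non-synonymous fractions per SNV group,
partition and occurrence percentages, pipeline coverage, gene
involvement, and the BH-adjusted association p-values.

Writes results/06_reference_arithmetic.tsv.
"""

import numpy as np
import pandas as pd

from _common import RESULTS
from popsnv import cohort_tables as ct
from popsnv.enrichment import bh_adjust, category_percent
from popsnv.io import write_report_table
from popsnv.partition import class_percentages, occurrence_distribution
from popsnv.spectrum import nonsyn_fraction


def main():
    RESULTS.mkdir(exist_ok=True)
    rows = []

    for set_name in ct.CATEGORY_SET_NAMES:
        frac = nonsyn_fraction(ct.category_counts(set_name))
        rows.append({"quantity": f"nonsyn_percent_{set_name}", "percent": frac})
        print(f"non-synonymous fraction, {set_name}: {frac:.2f}%")

    pct = class_percentages(ct.PARTITION_COUNTS, ct.CONSENSUS_TOTAL)
    for label, v in pct.items():
        rows.append({"quantity": f"partition_percent_{label}", "percent": v})
    print(f"partition: shared both {pct['shared_both']:.2f}%, "
          f"panel1 only {pct['shared_panel1_only']:.2f}%, "
          f"population only {pct['population_only']:.2f}%")

    n_other = ct.POPULATION_ONLY_TOTAL - ct.SINGLETON_COUNT - ct.FIXED_COUNT
    occurrences = np.concatenate(
        [np.ones(ct.SINGLETON_COUNT, dtype=int), np.full(n_other, 2, dtype=int),
         np.full(ct.FIXED_COUNT, ct.COHORT_SIZE, dtype=int)]
    )
    hist = occurrence_distribution(occurrences, ct.COHORT_SIZE)
    rows.append({"quantity": "singleton_percent", "percent": float(hist["percent"].iloc[0])})
    rows.append({"quantity": "fixed_percent", "percent": float(hist["percent"].iloc[-1])})
    print(f"population-only singletons {hist['percent'].iloc[0]:.2f}%, "
          f"fixed in all {ct.COHORT_SIZE}: {hist['percent'].iloc[-1]:.2f}%")

    for pl, key in (("pipeline_a", "coverage_percent_a"), ("pipeline_b", "coverage_percent_b")):
        cov = class_percentages({"c": ct.CONSENSUS_TOTAL}, ct.PIPELINE_TOTALS[pl])["c"]
        rows.append({"quantity": key, "percent": cov})
        print(f"consensus covers {cov:.2f}% of {pl}")

    gene_pct = category_percent(ct.GENES_NONSYN_SNV1, ct.GENES_TOTAL_SNV1)
    rows.append({"quantity": "genes_nonsyn_percent", "percent": gene_pct})
    print(f"genes with non-synonymous population-only SNVs: {gene_pct:.2f}% "
          f"({ct.GENES_NONSYN_SNV1} of {ct.GENES_TOTAL_SNV1})")

    raw = [p for *_, p in ct.DRUG_TERM_ROWS_SNV35]
    for (term, *_), q in zip(ct.DRUG_TERM_ROWS_SNV35, bh_adjust(raw)):
        rows.append({"quantity": f"bh_adjusted_{term.replace(' ', '_')}", "percent": float(q)})
        print(f"BH-adjusted p, {term}: {q:.4f}")

    write_report_table(pd.DataFrame(rows), RESULTS / "06_reference_arithmetic.tsv")


if __name__ == "__main__":
    main()
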