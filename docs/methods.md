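# Methods

## The analysis model

The pipeline identifies variants private to a sequenced population by
combining three ideas:

1. **Dual-pipeline consensus.** Single-caller SNV sets carry
   caller-specific artifacts; sites called by two independent
   aligner+caller pipelines at the same genomic position are kept as the
   consensus set. The intersection is positional, not allele-aware,
   matching the design it implements (an optional strict mode requiring
   alt-allele agreement exists but is off by default). Genotypes for
   consensus sites are copied from one designated pipeline, because the
   two pipelines may genotype a shared site differently.
2. **Reference-panel partition.** A consensus site found (by position)
   in neither reference panel is *population-only*. Panels first have to
   live on one assembly with one rsID per site, which is what the
   harmonization step guarantees.
3. **Occurrence stratification.** The occurrence of a site is the
   number of cohort samples carrying at least one non-reference allele.
   SNV-i denotes population-only sites with occurrence ≥ i; higher
   strata are enriched for reliable, population-typical variation, the
   lowest stratum for singletons and artifacts.

Downstream summaries — strand-collapsed substitution spectrum,
consequence categories, per-gene counts, hypergeometric term enrichment
with Benjamini–Hochberg adjustment — operate on these sets.

## Filters and their semantics

Per-sample post-call filters are inclusive at the threshold: quality
≥ 20, depth ≥ 3, and distance to the nearest other candidate call of
the same sample and chromosome ≥ 5 bp. Two semantics were genuinely
open and are resolved as follows:

- The neighbour-distance filter runs on the *candidate* call list,
  before the quality/depth filters, and removes **both** members of a
  violating pair — the conservative reading, since either member may be
  the artifact. Records removed this way are counted under the
  neighbour criterion even when they would also fail quality or depth.
- Filters are configured per pipeline: the mpileup-style pipeline uses a
  depth ≥ 5 rule alone; the other pipeline the quality/neighbour/depth
  triple. Defaults sit in `pipeline.DEFAULT_THRESHOLDS`.

Cohort merging backfills absent (site, sample) pairs as
homozygous-reference; a site reported with conflicting reference alleles
by two samples is a fatal validation error, because silently picking
one would corrupt occurrence counts.

## Harmonization choices

- Sites that are not single-base SNVs, and sites whose rsID occurs at
  more than one position, are removed before coordinate conversion.
- Conversion goes through a precomputed old→new position map (two-column
  TSV). Chain-file parsing and strand-aware allele flipping are out of
  scope; the map is the interface.
- A conversion failure is rescued only when its rsID occurs at exactly
  one position of the target-assembly panel; ambiguous or absent rsIDs
  are dropped, not guessed. Bookkeeping is conserved:
  |converted| + |rescued| + |lost| equals the post-removal panel size,
  asserted at run time.
- Positions carrying several rsIDs across datasets keep exactly one,
  chosen uniformly by a seeded generator recorded in the run manifest,
  and applied consistently in every dataset (global resolution, not
  per-dataset).

## Statistics

- **Spectrum.** Substitutions collapse onto six reference-pair classes
  (e.g. C→T and G→A are both C:G→T:A); multi-allelic sites are
  *uncertain* and excluded from Ts/Tv. A spectrum with zero
  transversions reports an infinite ratio rather than failing.
- **Non-synonymous fraction.** Category tables count a variant once per
  distinct consequence term, so column sums may exceed the set total;
  the non-synonymous fraction is computed on these category counts:
  100·Σns/(Σns + synonymous) over the fixed ten-term label set. A
  distinct-variant count (each variant once, regardless of how many
  non-synonymous terms it carries) is exposed separately
  (`nonsyn_variants`); the two are deliberately both reported because
  they answer different questions and differ on multi-term variants.
- **Carrier frequency.** "Frequency" is occurrence divided by cohort
  size, matching the occurrence definition by samples, not alleles;
  X/Y sites use the same definition (no ploidy adjustment) as a
  documented simplification.
- **Enrichment.** Upper-tail hypergeometric probability P[X ≥ k]
  (enrichment only, no depletion test), computed via the stable survival
  function. The BH family is exactly the set of terms with k ≥
  `min_genes` — the filter precedes testing. The gene universe defaults
  to all genes in the catalog and is overridable, since the universe
  behind literature-mining catalogs is generally unpublished; printed
  raw p-values from such catalogs are therefore not reproducible, only
  the adjustment and percentage arithmetic are.

## Synthetic data: what it emulates and what it does not

`SimConfig` defaults are the study conditions of the emulated design: a
35-sample cohort; panel-overlap fractions (0.313, 0.544, 0.001, 0.142)
matching the reported partition of consensus sites into
both/panel1-only/panel2-only/neither; transition fraction 0.677, giving
the genome-wide expected Ts/Tv of about 2.1; carrier frequencies from
Beta(0.2, 2), a rare-skewed law yielding a singleton-heavy occurrence
distribution; per-pipeline false-positive mass of 2% of true sites per
sample and a 5% per-call false-negative rate; call quality
Normal(60, 20) truncated at 0 and depth Poisson(30), so the threshold
filters remove a small, known fraction of real calls; a 5% liftover
failure fraction with rsID-rescuable failures; 0.5% multi-rsID sites,
plus a handful of planted indel-like and duplicate-rsID panel entries.
The genome is a set of short synthetic contigs (~1 Mb total by default)
so FASTA lookups and neighbour-distance filtering run at desk scale;
analyses that need more sites scale the contigs up with the site count.

Two deliberate idealizations make the generator a sharp oracle rather
than a realistic error model:

- False positives are **position-private per pipeline** (and per
  sample), so the positional intersection removes them exactly and
  consensus precision is analytically 1. Shared-artifact error modes
  are not modelled; consequently the synthetic consensus coverage of
  each pipeline (~50% at 20 samples) is far below the ~86–94% of real
  cohorts, where the two callers' errors overlap heavily.
- There is no linkage disequilibrium, no sequencing-error model at read
  level, and consequence terms are drawn independently of position.

Passing tests on synthetic data therefore demonstrate the correctness
of the set operations, bookkeeping and statistics under known truth —
not the behaviour of the pipeline under correlated caller errors.

## Problem sizes used in tests and acceptance runs

Parameter-recovery checks run at 50,000 sites × 20 samples (recovering
the population-only fraction and Ts/Tv within three standard errors);
enrichment calibration uses 100 seeds at planted odds 10 (power: the
planted term must rank first in ≥ 95) and 200 seeds under the null,
compared against the exact level of the discrete test; oracle
equivalence runs 100 seeds of ≤ 1,000-site fixtures against brute-force
nested-loop and exhaustive-enumeration implementations. These sizes are
the package's chosen desk-scale study conditions; the cohort-scale
counts of the motivating study (millions of sites from terabytes of
reads) are represented by the bundled summary tables instead.

## Numerical and formatting conventions

Report tables print percentages to 3 decimals and p-values in
2-significant-digit scientific notation; byte-determinism of every
report file for a fixed input is contractual and tested. The BH
implementation delegates to `statsmodels.multipletests(method="fdr_bh")`
behind the package's own validated surface; the hypergeometric tail is
`scipy.stats.hypergeom.sf(k-1, N, K, n)`. One printed worked-example
value (the 59/88 = 67.045% non-synonymous fraction of the smallest
stratum) was evidently truncated rather than rounded in its source
table; comparisons there use printed precision.

## Known limitations

- Position-only panel membership can mislabel a site as shared when the
  panels carry a different allele at the same position; the strict
  allele-aware mode mitigates this at the cost of fidelity to the
  emulated design.
- The multi-rsID resolution picks a survivor uniformly; no preference
  for the canonical (lowest-numbered) identifier is implemented.
- One-panel mode degrades the partition to shared/population-only; the
  shared-both and panel2-only classes are then structurally zero.
- The HapMap-style reader records population presence but the
  per-population frequency comparison uses the cohort generator's
  frequencies, not panel genotypes (panel genotype matrices are not
  modelled).
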