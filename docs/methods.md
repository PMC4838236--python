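# Methods

GRIP (gamma-retrovirus integration profiling) analyses a set of mapped
proviral insertion sites to find the genes and regulatory elements the virus
preferentially targets, and to ask whether the observed clustering reflects
integration preference or post-integration clonal selection. This note
records the statistical models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic-data generator does and does
not emulate.

## Data model and coordinates

All coordinates are 0-based, half-open (BED native). An insertion is a
strand-oriented point; its position is the BED start field, its strand is
the proviral orientation, and its `copies` attribute is the number of
junction fragments supporting it (the clonal copy count). Records sharing
(chrom, pos, strand) are merged on ingest by summing copies. A gene's TSS is
`txStart` on the forward strand and `txEnd − 1` on the reverse strand.

## Common insertion site (CIS) enrichment

Each insertion is assigned to at most one gene: the gene whose flanked
window (gene span ± `flank`, default 25 kb, capturing local regulatory
elements) contains it and whose gene-body distance is minimal; ties break by
smaller TSS distance, then gene id. The window truncates at chromosome
position 0 only — gene tables do not carry chromosome lengths, so no right
truncation is applied.

Per-gene enrichment models insertions as draws of base positions without
replacement from the *mappable genome*, defined as the union of all gene
windows (length `N` bp). With `k` of the `n` in-union insertions falling in
a gene's window of `K` bp, the p-value is the upper hypergeometric tail
P(X ≥ k), X ~ HG(N, K, n). This one-sided tail is identical to the
one-sided Fisher exact test on the corresponding 2×2 table, so the output
can be read as either. Two deliberate asymmetries are inherent to the
construction and are stated in output headers: assignment is exclusive, but
each gene's test uses its full window length even where windows overlap; and
insertions outside every window are excluded from `n` (they are outside the
null's population). Benjamini–Hochberg FDR corrects across genes. Top
targets are chosen by significance first (`p < alpha`, default 0.05;
raise `alpha` for much larger datasets to obtain comparable list sizes),
then ranked by insertion count `k` descending, with an option to expand the
list across a tied `k` at the boundary. Extreme hypergeometric tails that
underflow double precision are clamped to the smallest positive float so
that p stays in (0, 1] for downstream corrections.

## Clonal-selection tests

**Orientation bias ("heads–tails").** Enhancer insertion activates genes in
an orientation-dependent way, so clonal outgrowth produces strand bias at
the selected locus. For each nearest-gene cluster (same 25 kb windows as the
CIS analysis) the forward/reverse split is compared with the remainder of
the dataset by Fisher's exact test — two-sided by point-probability
summation by default, with one-sided tails available — and corrected by both
Bonferroni and Benjamini–Hochberg over the number of genes examined (which
may exceed the number of p-values reported, e.g. findings corrected within a
100-gene screen).

**Copy number.** Mean copies per insertion at the top target genes is
compared with the dataset as a whole by a two-tailed Welch t-test
(unequal variance, Welch–Satterthwaite df). Reports round copies/insertion
half-away-from-zero to one decimal.

## TSS profiling

Distances to the nearest TSS are signed in the gene's reading direction
(negative = upstream), so reverse-strand genes contribute symmetrically.
The histogram uses half-open bins (default 500 bp over ±10 kb, chosen to
render the characteristic double peak at ±1.5 kb with a trough at the TSS;
both are flags). Position classes use the six-term vocabulary of
peak-annotation tools (inside, upstream, downstream, overlapStart,
overlapEnd, includeFeature); only the first three are reachable for point
insertions — the boundary classes require interval input.

## Chromatin-mark association

**Global overlap.** An insertion intersects a mark iff its point lies inside
any peak of that mark's set (exact half-open containment, no slop window).
Counts are reported over the power set of marks. An optional pairwise
hypergeometric p treats base pairs of a stated population (e.g. the window
union) as the sampling frame; the population choice is the caller's and is
echoed with the result.

**Top-list overlap.** The top-N genes by insertion targeting are intersected
with the top-N genes of a peak-score ranking (N = 500 by default; score
ties at the boundary expand the effective size, and the expanded size is
what the null simulation uses). Significance is estimated by Monte-Carlo
simulation: each draw samples `effective_size` genes uniformly without
replacement from the full gene universe and records its overlap with the
fixed top list. Because that overlap count is exactly
hypergeometric-distributed, each draw is generated directly from the
without-replacement distribution — distributionally identical to
materialising the subset, and fast enough for 10⁶–6×10⁷ draws on one CPU.
Default `n_sim` is 10⁶; larger runs are reserved for explicit requests.
When no draw reaches the observed overlap the empirical p is reported as
the bound 1/n_sim with an explicit `is_bound` flag (the true p is lower);
the (exceed+1)/(n_sim+1) estimator is available behind a flag but is not
the default, to keep the bound convention explicit. p-values are also
reported as −log10(p) ("transformed p").

## Gene-set enrichment

Enrichment of an annotated set (e.g. cancer drivers at a genome-wide
background fraction of 2.2%) among the top targets is a chi-square goodness
of fit with 1 df and **no continuity correction**; with Yates' correction
the statistic is conservative for these cell counts and was deliberately
not used. Symbol matching is case-insensitive and matched symbols are
returned, never silently aggregated. Two-list contrasts (e.g. integration
targeting of predicted upstream regulators, 10/8 vs 2/16) use Fisher's
exact test with selectable sidedness. The expression-rank profile sweeps
sample sizes (50, 100, … genes), intersects the top integration targets
with the most highly expressed genes at each size, and estimates chance
levels with the same Monte-Carlo machinery.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
the sequence-level biology: no reads, no alignment artefacts, no mappability
gaps, and a gene density far above the human genome's (so absolute p-values
on synthetic data are not comparable to real screens — only the recovery of
planted structure is).

Defaults (chosen once as a desk-scale caricature of a real screen):
4 chromosomes × 2 Mb; 200 non-overlapping genes of 5–20 kb (uniform), strand
Bernoulli(0.5); a 2 kb peak centred at a Bernoulli(`peak_fraction` = 0.3)
subset of TSSs (designated hot genes always carry one so their weight can
act); 5,000 insertions of which a fraction `pi` = 0.6 is chromatin-biased.
A biased insertion picks a peak-bearing gene with probability proportional
to its weight (`hot_genes`, default weight 1) and lands at
TSS ± offset in reading direction, |offset| ~ Normal(1500, 600) rejected
below 300 bp — a symmetric double peak at ±1.5 kb with a trough at the TSS,
reproducing the shape without claiming a mechanism. Background insertions
are uniform over the genome. Strand is forward with probability
`beta` (per-gene overrides model orientation bias; default 0.5 = none).
Copies are Geometric(`copies_geometric_p` = 0.39) on {1, 2, …}, mean ≈ 2.56
— matching the fragment-to-insertion ratio of a real screen (20,634/8,052).
All randomness flows from one seed through named substreams
(`default_rng([seed, stage])`), so the genome, peaks and insertions can be
regenerated independently.

What passing recovery tests shows: the pipeline finds planted hot genes,
controls orientation-bias false positives at β = 0.5 and detects β = 0.95
with ≥ 30 insertions per gene. What it does not show: behaviour under real
mappability structure, assembly errors, or biological confounders between
marks.

## Problem sizes and numerical conventions

Recovery statistics use 10–20 independent seeds of 4,000–5,000 insertions
and Monte-Carlo runs of 10⁵–10⁶ draws; exhaustive oracle sweeps cover all
hypergeometric instances with N ≤ 20 and all 2×2 tables with N ≤ 40. These
sizes give stable pass/fail behaviour at desk scale. Degenerate inputs are
errors, not silent results: empty insertion sets for copy statistics,
zero-margin 2×2 tables, zero-variance Welch samples, out-of-range p-values.
Gene windows clamp at position 0; BH correction may be run with more tests
than supplied p-values (extras count as p = 1).

## Known limitations

* The CIS null ignores window overlap between neighbouring genes (each test
  uses the full window length); dense gene clusters therefore share
  insertions' evidence across members.
* The generator places biased insertions only at peak-bearing TSSs; real
  integration also tracks gene bodies and enhancers away from TSSs.
* Chromosome right-ends are unknown to gene tables, so windows may extend
  past the true end of a real chromosome.
* The pairwise insertion/peak hypergeometric p depends strongly on the
  population definition, which is left to the caller.
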