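# Methods

## Model and procedure

`toxfocus` implements a filtering pipeline over three inputs: per-condition
gene-level statistics (log2 fold change and p-value per gene), a pathway
collection (GMT), and gene→GO annotations with evidence codes (GAF 2.x or
3-column TSV). Gene identifiers are opaque case-sensitive strings; the user
must supply a consistent namespace across the three inputs, and no
symbol↔Ensembl mapping is attempted.

**DEG selection.** A gene is differentially expressed when
|log2FC| > log2(1.2) and p < 0.05, both strict, so a gene exactly at a
threshold does not pass. The working threshold is the unrounded
log2(1.2) ≈ 0.26303; 0.26 is its two-decimal display value. Because scripts
elsewhere sometimes filter on the printed 0.26, `criteria_from_fold_change`
takes `use_rounded=True` for literal replication; the two modes differ only
for |log2FC| in (0.26, 0.26303]. Genes with p = 0 (numerical underflow)
pass the p criterion; no flooring is applied. The four-way volcano
categorization (both / p-only / FC-only / none) partitions every table and
is exported with the DEG list.

**Overrepresentation.** For each pathway the exact hypergeometric upper
tail `P(X ≥ k)` is computed with `scipy.stats.hypergeom.sf` (no normal
approximation); the surrounding machinery — universe construction, size
filtering, BH adjustment via `statsmodels`, selection — is the package's
own. The universe defaults to *intersection* (collection genes ∩ measured
genes): genes neither annotated to any pathway nor measured on the platform
carry no information for the test. `collection` and `measured` modes are
available, and the mode is recorded in the effective config because N — and
therefore every p-value — depends on it. Set-size bounds (default 10–300,
inclusive) are applied to *in-universe* set sizes, matching the behaviour of
common ORA tools that filter after universe restriction; `size_filter_on="raw"`
switches to GMT sizes. Selection uses raw p < 0.05 by default — mirroring
the practice of setting the tool-side p/q cutoffs to 1 and screening
afterwards — while BH q-values over exactly the tested sets are always
reported; `select_on="bh_q"` switches the screen. Results are sorted by
(p-value, set id) so ties break deterministically.

**Toxicity classification.** The statistic is the overlap fraction
|P ∩ G_t|/|P|, with the *full* parsed pathway gene list as denominator (the
fraction describes the pathway as curated, not as measured). The cutoff
comparison `fraction ≥ c` runs in `fractions.Fraction` arithmetic; float
cutoffs are snapped to small-denominator rationals (0.6 → 3/5), so boundary
cases are exact at every swept cutoff (1/2, 3/5, 7/10, 4/5). Labels are
multi-label: a pathway can satisfy the cutoff for several focus terms, which
is why per-term counts may sum to more than the number of unique
toxicity-related pathways. GO gene sets use direct annotations only — no
DAG propagation — filtered to the experimental/curated evidence whitelist
(IBA, IC, IDA, IEP, IGI, IMP, IPI, TAS; matching is token-exact,
case-normalised). The ORA-based alternative classifier tests pathway genes
against each GO gene list over the union of all involved genes (unless a
universe is given), with raw p < 0.05, no size filters and no correction:
it is intentionally the permissive comparator, and the degenerate case
G_t = universe yields p = 1 and never labels.

**Pipeline and networks.** Labels depend only on (collection, GO sets,
cutoff) and are computed once, then intersected with each condition's
significant pathways; a significant pathway with no label contributes only
to the "Significant" column. The summary table has a collection-level
header row (total pathways, labeled pathways, per-term labeled counts)
followed by one row per condition. Networks connect each altered
toxicity-related pathway to its genes; the default gene scope is the
enrichment *hit* genes, because the networks depict what changed in that
condition — `all_pathway_genes` is available since full membership is an
equally defensible reading. Exports (edge/node TSV, GraphML via networkx,
SIF with token `contains`) sort nodes and edges, so identical inputs give
byte-identical files.

## Synthetic data

The generator produces datasets with the structure the analysis assumes,
not a simulation of any real platform: no probe-level intensities,
normalisation artefacts, correlated expression, or annotation bias. GO-term
gene sets are disjoint blocks; planted pathway–term overlap fractions are
constructed *exactly* by composing member genes from inside/outside the
term block in the planted integer ratio (a config whose fractions are
unrealisable at any pathway size in range is rejected up front), so
classification tests are deterministic while expression-level tests are
stochastic. Null genes draw log2FC ~ N(0, 0.1) and p ~ U(0,1); planted
genes get log2FC = ±1 and p ~ U(0,1)·1e-4, over a 1% background rate of
incidental differential expression — a strong, clean effect chosen so that
recovery failures indicate pipeline defects rather than marginal power.
Each generator draws from its own stream seeded by (seed, stream id,
index), so outputs are reproducible and mutually independent.

Passing tests on these data show the machinery is correct (exact tests,
exact boundaries, calibrated nulls, recovery of strong planted signal);
they do not show robustness to the noise structure of real microarray or
RNA-seq data, nor to annotation incompleteness.

The default "toy-tox" dataset (2,000 genes; 60 pathways of 10–40 genes;
4 focus terms of 200 genes; 3 cell models × 2 doses with dose-escalating
planted pathways; 12 pathways with planted fractions spanning 2/5–4/5,
including one multi-label pathway and two below-cutoff distractors) is the
fixture for the golden-output regression: the shipped golden files were
produced by one run of the workflow and must be reproduced byte-for-byte.

## Numerical choices

- Hypergeometric p-values come from scipy's exact survival function; the
  test suite checks them against an independent integer-arithmetic closed
  form and, at small sizes, exhaustive subset enumeration (tolerance 1e-12).
- BH adjustment wraps `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`), verified against the direct step-up definition.
- Cutoff and fraction comparisons never touch floats; sweep tables key
  columns by the fraction's canonical string ("1/2", "3/5", ...).
- Degenerate inputs: empty DEG sets short-circuit to empty results with a
  warning; empty GO sets score zero overlap; an empty universe or a query
  disjoint from it is an error carrying diagnostic counts and the condition
  id.
- Simulation problem sizes in tests and in the acceptance script (≤ 2,000
  genes, ≤ 60 pathways, 50 replicate seeds, 200 null tests) were chosen as
  the smallest sizes at which the stochastic checks are statistically
  informative.

## Known limitations

- Direct GO annotations only; if the annotation source propagates
  annotations to ancestor terms, set sizes — and classifications — change.
- The background universe is a modelling choice the user must own; printed
  pathway counts are not comparable across universe modes.
- The overlap denominator ignores the measurement platform: a pathway whose
  genes are largely unmeasured is still classified by its curated content.
- No rank-based (GSEA-style) enrichment and no pathway-topology scoring.
- The generator's planted effects are binary (null vs. strongly DE); it
  does not emulate graded dose–response curves within a condition.
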