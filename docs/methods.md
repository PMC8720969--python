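# Methods

## Scope and model of the analysis

herbnet implements the desk half of a network-pharmacology study as a
deterministic chain of eight stages.  Nothing in the package queries an
external service: component tables, target maps, expression matrices, PPI
edge lists, gene-set collections and docking tables are all plain-text
inputs, and a synthetic module can generate each of them with known ground
truth.  The statistical content of each stage, the tunable parameters and
the reasoning behind the open design choices are recorded here.

## Component screening

Components carry TCMSP-style properties: oral bioavailability OB (percent),
drug-likeness DL (unitless), AlogP and half-life HL.  The screen keeps rows
with OB ≥ 30 and DL ≥ 0.18.  Both comparisons are **inclusive**: the
criterion is stated with ≥ and a compound printed at exactly DL 0.18 is
understood to have passed it.  Drug-likeness ranking uses descending DL
with ties broken by descending OB and then ascending molecule id; the tie
rule is our own convention, fixed so the ranking is a total order and
byte-reproducible.  Molecules listed under several herbs are one record
with a herb set, deduplicated by molecule id.

## Differential expression

The expression model is microarray-like: log₂-scale intensities with
Gaussian noise, a case group and a control group (the packaged default
design is 30 cases vs 9 controls, a typical small-control cohort).  Per
gene, `log2FC` is the difference of group means and the p-value is a
two-sided Welch *t* (unequal variances); multiplicity is controlled by
Benjamini–Hochberg.  A DEG requires |log2FC| > 1.0 **and** q < 0.05, both
strict — a gene at exactly 1.0 is not called.

Two deliberate choices:

* **Welch rather than moderated-t.**  Cohort reanalyses of this kind are
  usually run through limma-style moderated statistics, but the moderation
  constants are tool- and version-specific.  A plain Welch test is exactly
  reproducible from first principles and is the right default for a
  library whose tests must pin every number; `gene_test` is the single
  entry point of the statistic, so a moderated backend can be swapped in
  without touching the calling convention.
* **Degenerate rows.**  A gene constant in both groups gets p = 1 when the
  means agree and p = 0 (with a warning) when they differ — a noiseless
  shift is unambiguous.  A guard warns when the value range (max > 30)
  suggests unlogged intensities.

## Enrichment

ORA uses the upper-tail hypergeometric probability P(X ≥ k | N, K, n).
The universe defaults to the union of the collection's members; this is
**the single biggest driver of differences** between enrichment tools, so
callers comparing against other software should pass the universe
explicitly.  BH adjustment runs within each category (BP, CC, MF, KEGG,
custom) because top-term reporting is per-category; a set competes only
with its own kind.  Retention requires adjusted p < 0.05.

Preranked GSEA accumulates the weighted running sum over a
descending-score ranking: hits add |score|^weight normalized by the hit
total, misses subtract 1/(N − N_h); ES is the running sum at its
maximum-magnitude point.  The null permutes gene labels (hit positions),
not phenotypes — the interface is a preranked list, so phenotype
permutation is not available by construction.  NES divides ES by the mean
|ES| of the sign-matched null half, and nominal p uses the add-one
estimator (b+1)/(n_perm+1), so p is never zero.  If every hit score is
zero at weight > 0 the hit increments fall back to equal steps rather than
dividing by zero.

## PPI topological screening

The two-stage screen reduces a large interaction network to a core:

1. **Median-degree stage.**  Threshold = 2 × median degree (the multiplier
   is configurable, and an absolute cutoff can be supplied instead — both
   readings of a "double median degree" rule are supported because
   published values are sometimes quoted as constants).  Nodes strictly
   above the threshold induce the subnetwork.
2. **Centrality stage.**  Degree (DC) and betweenness (BC) are
   **recomputed on the subnetwork** before thresholding (DC > 60,
   BC > 645 by default, strict).  Stage-wise recomputation is the
   convention of interactive network tools and the only reading under
   which a fixed BC cutoff in the hundreds is meaningful on a network of
   a few hundred nodes.

BC convention: unnormalized Brandes accumulation, each unordered pair
counted once, endpoints excluded, equal-length shortest paths split
evenly.  Closeness (CC) is computed within each connected component and
reported in the centrality table but does **not** participate in the
default screen: the screen is defined by the DC and BC thresholds, and CC
is provided for inspection.  Betweenness pairs are within-component by
construction on disconnected graphs.

The paper-scale defaults (60/645) are meaningless on the ~630-node
synthetic regime; there the package's tests use DC > 15 and BC > 0 on the
subnetwork.  Those values follow from the generator's construction: a
30-node planted core at edge probability 0.8 has expected within-core
degree ≈ 23, while a preferential-attachment background with m = 2
contributes induced degrees below ~10 for all but its top hub, so any DC
cutoff in the teens separates the two populations.

## Hubs and coexpression

Hub targets are the double intersection core ∩ component-targets ∩
pathway-genes, with per-symbol provenance recording which layers support
it.  Coexpression is Pearson *r* (the linear-fit convention of the usual
scatter presentations; configurable in principle) with the two-sided
t-transform p-value at n − 2 df.  The default flag rule is positive-only
(r > 0.3, p < 0.05), matching how such panels are usually reported; an
absolute-value mode flags strong negative correlations as well.
Zero-variance genes yield an undefined r; the pair is reported unflagged
with the reason, never silently dropped.

## Docking tables

Docking computation is out of scope; only result tables are consumed.
When multiple binding modes exist for a pair, mode 1 is the best mode if
present (engines emit modes ranked by affinity), otherwise the
minimum-energy record — the fallback is logged.  The binder rule keeps
energy ≤ −5.0 kcal/mol (inclusive: −5.0 itself passes, reading the
threshold as attained) and ≥ 2 hydrogen bonds **only when an explicit
hydrogen-bond column exists**; "total interactions" mixes hydrogen bonds
with π-stacking and alkyl contacts and is treated as an opaque count.
Rankings (energy ascending or interactions descending, ties broken by the
other criterion then lexicographically) are total orders.

## Synthetic data: what it emulates and what it does not

Each generator draws from one master integer seed through a fixed named
stream, so adding a generator never perturbs the others and identical
(seed, parameters) give byte-identical artifacts.

* **Components** — uniform OB/DL draws placed strictly above both
  thresholds for the passing fraction and strictly below at least one
  otherwise, covering the published pivotal ranges (DL 0.21–0.29,
  OB 30.68–69.67); exactly round(frac × n) rows pass.
* **Expression** — Gaussian log₂ noise around uniform(4, 12) baselines;
  n_de planted genes shift the case mean by ±lfc, half up and half down
  (odd counts give the extra gene to up, since real volcano plots show
  both directions).  Defaults: 30 vs 9, lfc 2, σ 0.5.  This is a
  microarray-era model: no count overdispersion, no probe effects, no
  normalization artifacts — passing tests show the caller recovers clean
  planted shifts, not that it handles platform pathology.
* **PPI** — Barabási–Albert background (m = 2) plus a planted core with
  within-core edge probability 0.8; each core node also gets m background
  edges so the core is not a separate component.  Core nodes can be given
  real gene symbols for end-to-end runs.
* **Gene sets** — enriched sets draw ≥ 60 % of members from the planted
  list, the rest uniformly.
* **Coexpression pairs** — independent bivariate normals at the requested
  correlations (|ρ| < 1 strictly).
* **Docking** — a ligand × receptor grid with a known passing subset under
  the energy/H-bond rule (added so the end-to-end bundle exercises all
  eight stages).

The end-to-end bundle wires these together coherently: component targets
are drawn from a pool enriched in the planted DEGs, the planted PPI core
is labelled with targeted DE symbols, and the planted gene sets are built
from targeted DEGs — so the hub stage has genes supported by all three
layers and recovery can be scored against the truth ledger.

## Problem sizes, determinism, numerical details

Test and acceptance runs use deliberately desk-scale problems — 2 000
genes × 39 samples, a 630-node PPI, 30–40 gene sets, 20-seed null
batteries — which exercise every code path while keeping the whole suite
in seconds.  The pipeline's determinism contract is byte-identity of every
artifact for a fixed seed; the run report's wall-clock timings are the one
field exempt from it.  BH adjusted values are capped at 1; hypergeometric
tails are clipped to [0, 1]; permutation p-values are add-one; all sort
operations use stable sorts with explicit tie keys.

## Known limitations

* No probe-to-gene mapping, normalization or batch correction: inputs are
  assumed clean, log₂-scale, symbol-keyed.
* No gene-symbol alias resolution (symbols are only case/whitespace
  normalized), no ontology topology, no external database access.
* The Welch default will not numerically reproduce moderated-t pipelines
  run on real cohorts, and ORA p-values depend strongly on the universe
  choice; both caveats are deliberate and documented above.
* GSEA supports one gene set per call with gene-permutation nulls; no
  multi-set FDR field is computed.
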