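# herbnet

Network-pharmacology inference for multi-component herbal formulas.

Traditional-medicine formulas act through many compounds hitting many
targets at once, so the standard desk analysis is a chain of filters and
network operations rather than a single model: screen the formula's
constituents for drug-like, orally available compounds; call disease genes
from a case/control expression cohort; intersect the compounds' predicted
targets with those genes; ask which pathways the shared targets crowd into;
compress a large protein–protein interaction (PPI) network down to its
topological core; and keep as *hub targets* the genes supported by all three
evidence layers (network core, compound target, enriched pathway).  herbnet
implements that whole chain as a tested, reusable library with a thin CLI,
using the worked example of Shen Qi Sha Bai Decoction (SQSBD, a 12-herb
formula used in acute myeloid leukemia) for its packaged reference tables.

## The statistics at the core

* **ADME screen** — keep components with oral bioavailability OB ≥ 30 % and
  drug-likeness DL ≥ 0.18 (both inclusive), the standard TCMSP activity
  criterion.
* **Differential expression** — per-gene log₂ fold change
  `log2FC = mean(case) − mean(control)` on log₂-scale values, two-sided
  Welch *t* p-values, Benjamini–Hochberg *q*; a DEG has |log2FC| > 1.0 and
  *q* < 0.05 (strict).
* **Over-representation** — upper-tail hypergeometric
  P(X ≥ k | N, K, n) per gene set, BH-adjusted within each category
  (BP/CC/MF/KEGG), retained at adjusted *p* < 0.05.
* **Preranked GSEA** — weighted Kolmogorov–Smirnov running sum
  (hits +|s|ʷ/Σ|s|ʷ, misses −1/(N−N_h)); ES is the maximum-magnitude
  deviation, with gene-permutation NES and add-one p-values.
* **Topological screen** — stage 1 keeps nodes with degree strictly above
  2 × median degree (or an absolute cutoff); stage 2 recomputes degree (DC)
  and unnormalized Brandes betweenness (BC) on the induced subnetwork and
  keeps DC > 60 and BC > 645 by default.
* **Coexpression** — Pearson *r* with the *t*-transform p-value (n − 2 df);
  a pair is flagged when r > 0.3 and p < 0.05.
* **Docking tables** — best mode per ligand–receptor pair (mode 1, else
  minimum energy), good binders at energy ≤ −5.0 kcal/mol with ≥ 2 hydrogen
  bonds, ranked by energy or interaction count.

A synthetic-data module generates every input with a known ground-truth
ledger (passing components, planted DEGs, a planted dense PPI core, planted
enriched sets, planted correlations), so the whole chain is testable
offline.

## Worked example

```python
>>> from herbnet.components import load_pivotal_components, filter_components, rank_by_dl
>>> table = load_pivotal_components()          # 9 pivotal SQSBD components
>>> len(filter_components(table, ob_min=30, dl_min=0.18))
9
>>> rank_by_dl(table, 2)[["name", "DL", "OB"]]
             name    DL     OB
0  Licochalcone A  0.29  40.79
1       Quercetin  0.28  46.43
```

All nine packaged pivotal components survive the OB/DL screen, and
licochalcone A and quercetin top the drug-likeness ranking — the two
compounds the docking table then singles out:

```python
>>> from herbnet.docking import load_reference_docking, rank_pairs
>>> rank_pairs(load_reference_docking(), by="energy").iloc[0][["ligand", "receptor", "energy"]]
ligand      Quercetin
receptor         CDK1
energy           -9.1
```

Quercetin–CDK1 is the strongest binder (−9.1 kcal/mol); ranking by
interactions instead puts licochalcone A–MAPK1 first (14 contacts).

A full synthetic run:

```sh
herbnet simulate --out-dir demo --seed 1
herbnet run --config demo/config.yaml
```

writes eight stage artifacts under `demo/results/` (filtered components,
DEG table, common targets, ORA results, core network, hub table,
coexpression flags, ranked docking pairs) plus a JSON run report; the
planted PPI core is recovered as the core-active target set.

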