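# ksnet

Probabilistic kinase–substrate network inference at phosphosite resolution.

Most phosphosites detected in phosphoproteomics experiments have no
annotated upstream kinase, and a large fraction of the kinome has no known
substrate. `ksnet` addresses this gap for computational biologists working
on cell signaling: it learns a scored kinase→phosphosite network from
heterogeneous evidence — kinase specificity models (PSSMs), co-expression
and proteome co-regulation across contexts, and site-level functional
scores — and then uses that network to interpret condition-specific
phosphoproteomics data.

## The method

For every specificity-respecting pair (kinase *k*, phosphosite *s*) a
feature vector *x(k, s)* is assembled (PSSM log-score
Σᵢ log₂ Wₖ(i, aaᵢ) over the ±5 flank, its per-kinase percentile,
pairwise-complete correlations of expression/proteome profiles, and the
site's functional score). Because no negative training pairs exist,
an ensemble of random forests is trained on the known positive pairs plus
fresh uniform samples of unannotated pairs (10× the positives for feature
selection, 50× for final training), with per-run grid-searched
hyper-parameters and stratified k-fold validation; the edge probability is
the mean over ensemble members,

    p(k → s) = (1/R) Σᵣ pᵣ(k → s).

Feature selection is recursive feature elimination with cross-validation on
resampled training sets, retaining features selected in >50% of runs.

On top of the network:

- **Condition fitting** — the network (plus a kinase–kinase backbone),
  filtered at p > 0.5 with edge cost 1 − p, is fitted to per-condition
  log₂ fold changes by a prize-collecting Steiner forest
  (prize w·|log₂FC| per measured site, hub penalty μ·degree, at most *b*
  trees); the grid point maximising F1 against known edges defines the
  condition-specific subnetwork.
- **Kinase activities** — substrate sets gated at the 95th percentile of
  edge probabilities are tested by preranked permutation enrichment in each
  condition's log₂FC ranking; significant (BH ≤ 0.05) normalised enrichment
  scores quantify activation or inhibition, with dual-specificity kinases
  scored separately on Ser/Thr and Tyr targets.
- **Kinase similarity** — Jaccard overlap of predicted substrate sets,
  UPGMA dendrograms on 1 − J, high-overlap clusters (J > 0.5), and
  Fisher's-exact gene-set enrichment of substrate proteins.

A fully seeded synthetic-data module generates a benchmark world (kinome,
PSSMs, flanking sequences, expression matrices, planted truth network,
activation conditions) so the entire pipeline is testable without any
download. See `docs/methods.md` for model details and assumptions.

## Worked example

```sh
ksnet simulate --seed 9 --out demo/world --n-kinases 6 --n-sites 120 --n-true-pairs 50
ksnet features --world demo/world --out demo/features.tsv
ksnet train --world demo/world --features demo/features.tsv \
      --positives demo/world/truth.tsv --out demo/network.tsv \
      --seed 9 --n-runs 2 --k-folds 3 --neg-ratio 5 --reduced-grid
ksnet predict --network demo/network.tsv --out demo/summary.tsv
```

The `train` step logs its cross-validated performance:

```
INFO ksnet: mean CV AUC: 0.9846
```

meaning each ensemble member separates planted pairs from sampled negatives
with AUC ≈ 0.98 under 3-fold cross-validation. `demo/summary.tsv` then
counts confident predictions per kinase (probability > 0.5), split by
residue class:

```
kinase_id  n_ST  n_Y  n_total
KIN001     0     9    9
KIN002     9     0    9
KIN003     8     0    8
...
```

(KIN001 is a tyrosine kinase in this world, hence its targets are all Tyr
sites.)

`ksnet activity --network demo/network.tsv --world demo/world --out
demo/activity.tsv --seed 9` scores each condition in the world's condition
table; the output matrix holds the NES of each significant kinase (positive
= activated), and the planted active kinase of each synthetic condition
appears with a positive NES.

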