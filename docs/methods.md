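# Methods

## The model

`ksnet` builds a probabilistic kinase–substrate network at phosphosite
resolution. Every specificity-respecting (kinase, phosphosite) pair is
described by a feature vector and scored by an ensemble of random forests;
the edge probability is the arithmetic mean of the member probabilities.
Downstream machinery consumes this network: condition-specific subnetwork
extraction by a prize-collecting Steiner forest (PCSF), kinase-activity
inference by preranked enrichment of gated substrate sets, and kinase
similarity analysis through the Jaccard index of predicted substrate sets.

### Features

The default registry mirrors the categories of evidence the approach
integrates, one representative column per category:

| feature            | source                    | meaning |
|--------------------|---------------------------|---------|
| `pssm_log_score`   | PSSM × flank              | Σ log2 of the kinase's positional amino-acid preferences over the ±5 flank; pads contribute 0 |
| `pssm_percentile`  | per-kinase transform      | midrank percentile of the raw score among the kinase's candidate sites; comparable across kinases |
| `coexpr_tissue`    | expression matrix         | pairwise-complete Pearson correlation of kinase and substrate-protein profiles across contexts |
| `coreg_proteome`   | proteomics matrix         | same, on the (noisier) proteome-level matrix |
| `functional_score` | site table                | [0, 1] functional-relevance score of the phosphosite |

The registry is data: callers can add or replace columns (`source="extra"`),
and the training engine consumes whatever the registry declares. Missing
values stay `NaN` in the assembled table; imputation (per-feature median) is
fit inside each training run/fold only, so the feature table remains a
faithful image of its sources.

### Training protocol

Negatives do not exist as curated data, so they are sampled uniformly
without replacement from the specificity-respecting pair space minus the
positives — 10× the positive count for feature selection, 50× for final
training (both configurable; the two stages are deliberately independent
knobs). Feature selection runs recursive feature elimination on each of
`n_runs` resampled training sets, scoring each elimination step by
stratified cross-validated AUC-ROC, and keeps the features that appear in
strictly more than half of the selected subsets. Final training fits one
forest per run on positives plus a fresh negative sample, choosing
hyper-parameters by grid search (default grid: `max_depth`
[10, 20, 50, 70, 80, 100] × `min_samples_split` [8, 10, 12] ×
`n_estimators` [150, 500, 1000, 1500] = 72 points) with mean CV AUC-ROC as
the objective; ties break towards smaller `n_estimators`, then smaller
`max_depth`, for determinism.

**Subset choice within RFE.** With strong planted signal the CV AUC path
saturates near 1.0, and an argmax over it picks among statistically
indistinguishable subsets at random — which retains noise features. We
therefore apply the standard one-standard-error parsimony rule: the smallest
subset whose mean CV AUC lies within one standard error of the path maximum.
This is the usual operationalisation of "best subset" under noise (cf. the
1-SE rule in regularised model selection) and is what makes planted-noise
rejection reproducible.

### PCSF formulation

The reference graph merges a kinase→kinase backbone with the kinase→site
predictions, both filtered at probability strictly greater than 0.5, with
edge cost 1 − probability. A condition assigns prize `w·|log2FC|` to each
measured site present in the graph; `mu` implements hub penalisation as a
degree-proportional prize deduction, `prize'(v) = max(0, prize(v) −
mu·degree(v))`; `b` caps the number of trees. The objective minimised is

    Σ_{v ∉ forest} prize'(v) + Σ_{e ∈ forest} cost(e) + c·(number of trees)

with root charge `c` (default 1.0 — one maximally uncertain edge; it sets
the prize scale a node must clear to justify a new tree).

The solver exploits a decomposition: *for a fixed node set S the optimal
forest is computable exactly* — a Kruskal sweep on the induced subgraph
gives the minimum-cost spanning forest for every feasible tree count `t`
(graphic-matroid greedy), and the best `t ≤ b` is selected in closed form.
The search over node sets combines (i) a constructive start: minimum
spanning tree over the graph plus a virtual root (root edges cost `c`)
followed by strong pruning of subtrees whose cost exceeds their collected
prize; (ii) local search with single-node toggles; (iii) branch-drop moves
that cut one forest edge and discard a side, which escape local optima
created by the tree cap; and (iv), on instances of ≤ 16 nodes, seeded random
restarts. Small instances use best-improvement with pair moves; large ones
use first-improvement sweeps with a profitability pre-filter on candidate
nodes. `exact_small` enumerates all node sets (≤ 15 edges) and serves as the
oracle: on 1,200 random small instances the heuristic matched the
exhaustive optimum in every case.

PCSF runs on the undirected skeleton (antiparallel edges collapse to the
cheaper cost) and directions are restored on output. The fitted subnetwork
for a condition is the grid point (b × w × mu, default 10 × 6 × 5 = 300
combinations) maximising F1 of retained edges against known relationships,
with precision = |forest ∩ known| / |forest| and recall measured against the
known edges present in the input graph.

### Kinase activity

High-confidence substrate sets take every edge strictly above the 95th
percentile of the probability distribution — by default one global
threshold over all edges (`scope="global"`); a per-kinase quantile is
available as a switch since either reading of "95th percentile" is
defensible. Dual-specificity kinases are split into separate Ser/Thr and
Tyr sets and scored independently. The enrichment statistic is the
classical weighted Kolmogorov–Smirnov running sum over the descending
log2FC ranking (hit increments ∝ |stat|^w, default w = 1; miss decrements
1/(N−n)); the p-value comes from a permutation null of random same-size
sets, one-sided by ES sign, so its resolution is bounded by 1/(n_perm + 1);
NES = ES / mean |null ES of the matching sign|. Per condition, p-values are
Benjamini–Hochberg adjusted across sets and entries with adjusted p ≤ 0.05
are reported. A multilevel split Monte-Carlo estimator would give finer
p-values for extreme sets; the classical estimator is sufficient for the
α = 0.05 decisions made here and is documented as such. Ranking ties break
by site id for determinism.

### Kinase similarity

Substrate sets at probability > 0.5 feed the Jaccard index; 1 − J is the
distance for UPGMA. Our UPGMA reports ultrametric node heights (merge height
= half the merged distance, so cophenetic distance equals the average-link
distance) and breaks distance ties towards the lexicographically smallest
cluster-id pair. High-overlap clusters are connected components of the
J > 0.5 graph, singletons omitted. Gene-set enrichment of a kinase's
substrate *proteins* (any site above cutoff includes its protein) uses
one-sided Fisher's exact tests with BH control; the background universe is a
required input because no default is defensible.

## The synthetic world

The generator emulates the full input stack with planted ground truth:

- **PSSMs**: per-position Dirichlet(0.2) rows over the 20 amino acids —
  peaky, kinase-specific preferences.
- **Flanks**: planted sites draw each flank position from their kinase's
  PSSM with probability `signal_strength` (uniform otherwise), i.i.d. per
  position; background sites are uniform. One kinase per site defines the
  flank (planting prefers unused sites), so the sequence signal is
  attributable.
- **Expression/proteomics**: one latent factor per kinase, shared by the
  kinase and its true substrates' proteins plus independent Gaussian noise
  (sd 0.5 expression, 1.0 proteomics); background proteins are independent.
  This makes co-regulation informative by construction.
- **Functional scores**: Beta(4, 2) for planted sites, Beta(2, 4) for
  background — a mildly informative site-level covariate.
- **Conditions**: an activation condition shifts the true substrates of the
  active kinases by `effect_size` plus Gaussian noise; everything else is
  pure noise.

All randomness flows from one integer seed through `SeedSequence` spawning,
so sub-generators are independently reproducible and a fixed seed gives a
bit-identical world. What the generator does *not* model: mass-spectrometry
missingness, positional dependence within motifs, shared substrates between
paralogous kinases' PSSMs, or batch structure in expression data. Passing
tests therefore demonstrate correct recovery of signal of the assumed form,
not performance on real phosphoproteomes.

## Benchmark problem sizes

The standard procedures in `ksnet.benchmarks` use sizes chosen to give
stable statistics on a single CPU: the ranking benchmark uses 25 kinases ×
3,000 sites with 1,500 planted pairs (signal strength 0.9) and a 10-member
ensemble on a single-point grid (the full grid is exercised at toy scale in
unit tests); its kinase-class mix (12% Tyr, 8% dual) keeps the
specificity-respecting pair space large enough for 50× negative sampling.
Condition fitting uses 12 kinases × 1,200 sites, 50 activation conditions
and a compact 8-point b/w/mu grid; activity recovery uses 40 seeded
replicates at effect size 3 and noise sd 1.

## Numerical choices and degenerate inputs

- Probability cutoffs are strict (> 0.5) wherever a 0.5 threshold appears.
- The substrate-gate quantile uses lower interpolation, so the threshold is
  an observed probability and "strictly above" is well defined on grids.
- Correlations use pairwise-complete observations with `min_overlap` 5;
  zero-variance overlaps are missing, not 0.
- An all-zero log2FC condition yields a degenerate permutation null; results
  carry a `degenerate_ranking` flag and nothing reaches significance.
- Empty forests report precision 0 with an explicit undefined flag rather
  than NaN.
- Writers are atomic and stamp version + seed + config hash; headers carry
  no timestamps, so equal runs produce byte-identical files.

## Known limitations

- The heuristic PCSF solver is exact on enumerable instances but carries no
  approximation guarantee at scale; the sweep's F1 selection partially
  compensates, since parameter choice is validated against known edges.
- Permutation p-values are bounded below by 1/(n_perm + 1); very small
  activity p-values are reported at that resolution.
- The feature registry is a category-level reconstruction, not a fixed
  48-column list; users supply their own columns for richer feature spaces.
- Negative sampling treats all unannotated pairs as negative, as the
  training protocol requires; label noise from true-but-unannotated pairs
  is inherent to that choice.
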