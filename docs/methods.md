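# Methods

## Stage 1 — inventory classification

The detection matrix is a genes × experiments 0/1 table: 1 if a gene
product was identified in that proteomic dataset.  Because purified
mitochondria are contaminated and genuine residents are intermittently
missed, individual datasets disagree; the classifier treats the 23 (by
default) experiments as binary features and learns which detection
patterns indicate genuine residency.

* **Model.** AdaBoost.M1 over depth-1 decision stumps
  (scikit-learn's `AdaBoostClassifier` with a `max_depth=1` tree base
  learner).  With binary features each stump is a single-dataset vote;
  boosting weights the votes.  Stump ties are resolved by the tree's
  deterministic split search, so results are reproducible given the
  seed and input order.  `rounds` (default 50) is the number of weak
  learners; training error is non-increasing in rounds on a fixed set.
* **Evaluation.** Stratified (not plain random) 10-fold CV, so both
  classes appear in every fold even at small n.  Confusion counts are
  summed across folds; sensitivity = TP/(TP+FN), FDR = FP/(FP+TP).
  Zero denominators raise an explicit undefined-metric error rather
  than silently returning 0.
* **Tiers.** High = classifier positives ∪ curated gold positives (a
  curated positive predicted negative is restored, never demoted).
  Middle = reference-compendium members or genes detected in strictly
  more than `vote_threshold` (default 5) experiments — "more than
  five" is read literally as ≥ 6.  Everything else is low.  The three
  tiers partition the gene universe exactly.

## Stage 2 — likelihood-ratio integration

Gold standard: positives are unordered pairs sharing ≥ 1 pathway or
complex annotation; negatives are pairs where both members are
annotated but share nothing.  Pairs with an unannotated member are
outside the gold standard.  Pairs are keyed in lexicographically
sorted order everywhere.

* **Coverage filter.** Evidences scoring < 20% of gold pairs (default,
  configurable) are excluded from the integrated model but still
  fitted and reported individually.
* **Independence screen.** Pearson correlation of each evidence pair
  on jointly covered gold pairs; entries with < 3 common observations
  are flagged not-assessable (NaN).
* **Binning.** Equal-frequency (quantile) bins over the gold-pair
  scores, default 5 bins.  Quantile rather than equal-width binning was
  chosen for robustness to skewed score distributions; the bin count is
  configurable per evidence.  Scores outside the fitted range clamp to
  the end bins.  Non-numeric (string) scores are treated as categorical
  and their categories used as bins directly.
* **Smoothing.** Laplace pseudocount (default 1) added per bin to both
  class counts, with totals inflated by B·pseudocount; all bin LRs are
  then finite and positive even for empty bins.
* **Composite LR.** Product of bin LRs over covering evidences,
  accumulated as a sum of logs; a pair with no covering evidence has
  LR exactly 1 (missing data is tolerated, never imputed).  Posterior
  odds = prior odds × composite LR, with prior odds defaulting to 1 so
  cutoffs act on the LR scale directly.
* **Cutoff.** The TP/FP ratio is computed on the gold standard as a
  function of the LR cutoff; the selected cutoff is the smallest
  evaluated value whose ratio reaches the target (default 1, i.e. 50%
  precision among gold calls).  Network edges are the pairs at or above
  the cutoff, weighted by composite LR; isolated genes are dropped from
  the node set.
* **Cross-validation.** 5-fold stratified CV over gold pairs: LR models
  are refitted on training folds and held-out pairs scored; pooled
  held-out scores give one ROC (trapezoidal AUC) per single evidence,
  for the full integration, and optionally per evidence scale group
  (genome-scale vs mitochondria-specific).

Pair counting supports two conventions: combinatorial n(n−1)/2, and a
"paper" convention ⌊n²/2⌋ that reproduces the originally reported
candidate-linkage total for the 1124-protein inventory; the
combinatorial count is used everywhere internally.

## Stage 3 — propagation ranking

The transition model is W = D⁻¹A on the undirected weighted graph
(aᵢⱼ = wᵢⱼ); rows of W sum to 1 for positive-degree nodes.  The
published propagation equations are orientation-ambiguous; here scores
propagate by Wᵀ so probability mass flows from the seeds outward, and
each ranker is verified against a dense linear-algebra oracle in the
tests (direct solve for PRP, explicit matrix powers for KSM, matrix
exponential for HKDR, subset enumeration for AAR).

* **AAR.** Each of `iterations` (default 100) rounds samples m seeds
  without replacement; every gene outside the sample accrues its total
  edge weight to the sampled seeds (raw weights, not transition
  probabilities).  The final score divides by nᵢ, the number of rounds
  gene i was outside the sample — the normalization chosen among the
  readings of the resampled-average definition; m = |seeds| is the
  deterministic limit.
* **PRP.** π = βp + (1−β)Wᵀπ with p uniform on seeds, solved by power
  iteration to L1 tolerance 1e−10 (non-convergence raises with the
  residual); scores sum to 1.  β is the restart ("back") probability.
* **KSM.** Σₖ₌₁..K (Wᵀ)ᵏ p — cumulative occupancy over exactly K
  steps; total mass equals K when all reached nodes have positive
  degree.
* **HKDR.** p = (I − (α/N)Lᵀ)ᴺ p₀, the N-iteration discretization of
  exp(−αLᵀ)p₀.  The swept integer parameter is N (2…7) with the
  diffusion rate α fixed at 1 by default, N being the only integer in
  the update; α is independently configurable.
* **Ranking.** Seeds are excluded; ties break by ascending gene
  identifier, making every ranking deterministic.  Optional
  three-level confidence bands by score quantile.  Zero-degree nodes
  score 0 and are flagged.

## Evaluation

LOOCV: for each disease with ≥ 2 seed genes in the network (others
skipped with a logged reason), each member is held out and re-ranked
from the rest.  Trials are pooled across diseases into one ROC per
algorithm: within a trial the held-out gene is the positive and the
other candidates the negatives, scored by normalized rank so pools of
different sizes are comparable; the negative pool is all network genes
not annotated to the disease.  Per-disease curves remain available by
filtering the trial records.  Parameter grids follow the standard
sweep (HKDR N = 2…7; PRP β = 0.01…0.95; KSM K = 2…9), with AUC ties
broken toward the smaller parameter value.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline
assumes: Bernoulli detection with class-specific probabilities
(defaults 0.6 mitochondrial / 0.1 contaminant across 23 experiments),
overlapping pathway memberships drawn only from mitochondrial proteins
(defaults 12 pathways of 6–14 members over 120 + 60 proteins),
class-conditional evidence scores (Normal and Beta families; default
Normal(1, 1) vs Normal(0, 1)) with class-independent uniform
missingness, and disease modules planted into the network by boosting
internal edge weights 10× (absent internal edges are first created at
the network's median weight so the boost stays interpretable).  All
generators are pure functions of an explicit integer seed.

It does **not** emulate tissue-specific expression, correlated
missingness, evidence-specific score shapes, dependence between
evidences, or any sequence-level biology.  Passing tests therefore
demonstrate correctness of the estimators and rankers under the
model's own assumptions — calibrated LR recovery, naive Bayes
identities, oracle-exact propagation — not performance on real
proteomic or clinical data, where violated independence and
informative missingness would lower the reported AUCs.

## Numerical choices and limitations

Log-domain LR accumulation avoids under/overflow for many evidences;
the product and log forms agree to 12 significant digits.  Equal
quantile edges that collide (heavily tied scores) are merged, reducing
the effective bin count.  ROC points use scikit-learn's threshold
sweep with trapezoidal areas.  Benchmark problem sizes in the tests
and analysis scripts (worlds of tens to hundreds of proteins, 1e5-pair
calibration checks, 20-replicate recovery experiments) were chosen as
the smallest scales at which the statistical claims are stable.  With
a strong 10× module boost the planted-module benchmark saturates
(LOOCV AUC ≈ 1); it checks recoverability, not algorithm separation —
distinguishing the four rankers requires weaker boosts or denser
background graphs.
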