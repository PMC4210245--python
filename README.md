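# mitofln

Mitochondrial dysfunction underlies a broad range of human diseases, yet
both the organelle's protein inventory and the functional relationships
among those proteins are incompletely known.  `mitofln` implements a
three-stage systems-biology pipeline for this problem as a tested,
reusable Python library with a synthetic-data module that supplies every
input with known ground truth:

1. **Inventory** (`mitofln.inventory`) — proteins are classified as
   mitochondrial from their binary detection profile across many
   proteomic experiments using AdaBoost.M1 over one-feature decision
   stumps, evaluated by stratified 10-fold cross-validation
   (sensitivity = TP/(TP+FN), FDR = FP/(FP+TP)) against curated
   gold-standard positive/negative gene sets.  Remaining proteins are
   tiered by a voting policy: *middle* confidence if reference-listed or
   detected in more than five experiments, *low* otherwise.
2. **Evidence integration** (`mitofln.integration`) — heterogeneous
   pairwise evidence datasets are calibrated against gold-standard
   protein pairs (pairs sharing a pathway/complex vs. annotated pairs
   sharing none).  Each evidence's scores are cut into equal-frequency
   bins and a smoothed likelihood ratio estimated per bin,
   LR_b = P(bin | linked) / P(bin | unlinked).  Under naive Bayes
   conditional independence the composite score of a pair is
   LR(E₁,…,Eₙ) = ∏ᵢ LR(Eᵢ), with posterior odds = prior odds × LR.
   A cutoff where the TP/FP ratio reaches 1 (50% precision) defines the
   edges of the weighted **functional linkage network** (FLN).
3. **Prioritization** (`mitofln.prioritization`, `mitofln.evaluation`)
   — candidate disease genes are ranked by propagating signal from seed
   genes over the FLN with four algorithms: average adjacency ranking
   (AAR), PageRank with priors (PRP, restart probability β), K-step
   Markov (KSM), and heat kernel diffusion ranking
   (HKDR, p = (I − (α/N)Lᵀ)ᴺ p₀ with L = I − D⁻¹A), benchmarked by
   leave-one-out cross-validation with pooled ROC/AUC and parameter
   sweeps.

It is aimed at computational biologists who want the statistical
machinery of organelle-scale evidence integration and network-based
gene prioritization without the (non-redistributable) curated inputs.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on
synthetic data (a world of 120 mitochondrial + 60 contaminant proteins,
12 pathways, 23 simulated proteomic experiments, 5 evidence datasets)
and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_build_inventory.py
python analysis/03_build_fln.py
python analysis/04_prioritize.py
python analysis/05_evaluate.py
```

Stage 1 prints

```
10-fold CV on 136 labeled proteins: sensitivity 0.961, FDR 0.027
tier counts: {'high': 120, 'low': 56, 'middle': 4}
```

— the boosted classifier recovers the mitochondrial proteins from noisy
detections almost perfectly under these simulation settings.  Stage 2
shows the coverage filter (one evidence excluded below 20% gold
coverage), the independence screen (max |PCC| 0.122), and that
integration beats every single evidence:

```
5-fold CV AUC coexpression: 0.757 ... uninformative: 0.503
5-fold CV AUC integrated: 0.809
selected composite-LR cutoff 2.91 (TP/FP first >= 1)
FLN: 120 proteins, 716 linkages, average neighbors 11.933, density 0.100
```

Stage 3 plants four 6-gene disease modules (internal edges boosted
10×), then re-finds a held-out module member:

```
DIS01: seeding with 5 genes, held-out member G006
  HKDR : held-out member ranked 1/115
HKDR : LOOCV AUC 1.000 (mean held-out rank 1.0 of 115; best params {'n_iter': 2})
```

A rank of 1/115 means the held-out disease gene is the top candidate
among all non-seed network genes.  `docs/methods.md` describes the
models, parameters and limitations; each module also has a CLI
(`mitofln build-inventory | build-fln | prioritize | evaluate`).

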