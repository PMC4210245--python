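"""Stage 2: naive Bayes likelihood-ratio integration into a weighted FLN.

Each heterogeneous evidence dataset (co-expression, interaction,
similarity scores, ...) is calibrated against the gold standard by
binning its scores and estimating a per-bin likelihood ratio

    LR_b = P(score in bin b | linked) / P(score in bin b | not linked),

with Laplace smoothing for sparse bins.  Under the conditional
independence assumption, the composite likelihood ratio of a gene pair
is the product of the bin LRs of every evidence covering it (missing
evidence contributes a factor of 1), accumulated in the log domain;
posterior odds = prior odds x composite LR.  A cutoff on the composite
LR is chosen where the true-positive to false-positive ratio on the
gold standard reaches a target (default 1, i.e. 50% precision), and
pairs at or above it become the weighted edges of the functional
linkage network.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from .inventory import UndefinedMetricError
from .netcore import EvidenceTable, GoldStandardPairs, Pair, canonical_pair, make_fln


class NotFittableError(ValueError):
    """Evidence has no usable overlap with the gold standard."""


class CutoffNotAttainableError(ValueError):
    """No evaluated cutoff reaches the requested TP/FP target."""


def compute_coverage(ev: EvidenceTable, gold: GoldStandardPairs) -> float:
    """Fraction of gold-standard pairs (GSP plus GSN) scored by ``ev``."""
    gold_pairs = gold.all_pairs
    if not gold_pairs:
        raise UndefinedMetricError("coverage undefined: empty gold standard")
    return sum(1 for p in gold_pairs if p in ev.scores) / len(gold_pairs)


def pairwise_independence(evs: Sequence[EvidenceTable],
                          gold: GoldStandardPairs,
                          min_common: int = 3) -> pd.DataFrame:
    """Pearson correlation between evidences on jointly covered gold pairs.

    Entries backed by fewer than ``min_common`` common observations are
    NaN (not assessable).  Used to screen the conditional-independence
    assumption before integration.
    """
    if len(evs) < 2:
        raise ValueError("need at least 2 evidences")
    names = [e.name for e in evs]
    gold_pairs = sorted(gold.all_pairs)
    mat = pd.DataFrame(np.eye(len(evs)), index=names, columns=names)
    for (i, a), (j, b) in itertools.combinations(enumerate(evs), 2):
        common = [p for p in gold_pairs if p in a.scores and p in b.scores]
        if len(common) < min_common:
            r = np.nan
        else:
            xa = np.array([a.scores[p] for p in common])
            xb = np.array([b.scores[p] for p in common])
            with np.errstate(invalid="ignore"):
                r = float(np.corrcoef(xa, xb)[0, 1])
        mat.iloc[i, j] = mat.iloc[j, i] = r
    return mat


@dataclass
class BinnedLikelihood:
    """Per-evidence bin boundaries with smoothed likelihood ratios.

    For continuous scores, ``edges`` holds B+1 ordered boundaries of
    equal-frequency bins over the gold-pair scores; out-of-range scores
    fall into the first or last bin.  For categorical evidence,
    ``categories`` holds the observed category labels and ``edges`` is
    None.
    """

    name: str
    pos_counts: np.ndarray
    neg_counts: np.ndarray
    pseudocount: float
    edges: np.ndarray | None = None
    categories: List | None = None

    @property
    def n_bins(self) -> int:
        return len(self.pos_counts)

    @property
    def bin_lrs(self) -> np.ndarray:
        """Smoothed LR per bin; finite and positive for pseudocount > 0."""
        B, pc = self.n_bins, self.pseudocount
        pos_rate = (self.pos_counts + pc) / (self.pos_counts.sum() + B * pc)
        neg_rate = (self.neg_counts + pc) / (self.neg_counts.sum() + B * pc)
        return pos_rate / neg_rate

    def bin_of(self, score) -> int:
        if self.categories is not None:
            try:
                return self.categories.index(score)
            except ValueError:
                raise KeyError(f"unseen category {score!r} for {self.name}")
        # interior edges only: values below/above the range clamp to end bins
        return int(np.searchsorted(self.edges[1:-1], score, side="right"))

    def lr_for_score(self, score) -> float:
        return float(self.bin_lrs[self.bin_of(score)])

    def report(self) -> pd.DataFrame:
        rows = []
        lrs = self.bin_lrs
        for b in range(self.n_bins):
            bounds = (
                str(self.categories[b]) if self.categories is not None
                else f"[{self.edges[b]:.6g}, {self.edges[b + 1]:.6g}]"
            )
            rows.append({"evidence": self.name, "bin": b, "bounds": bounds,
                         "pos_count": int(self.pos_counts[b]),
                         "neg_count": int(self.neg_counts[b]),
                         "LR": float(lrs[b])})
        return pd.DataFrame(rows)


def fit_binned_likelihood(ev: EvidenceTable, gold: GoldStandardPairs,
                          n_bins: int = 5, pseudocount: float = 1.0,
                          categorical: bool = False) -> BinnedLikelihood:
    """Estimate per-bin likelihood ratios of one evidence on the gold standard.

    Continuous scores get equal-frequency (quantile) bins computed over
    all gold-pair scores; categorical scores (requested explicitly, or
    detected from non-numeric values) use their observed categories as
    bins directly.
    """
    pos_scores = [ev.scores[p] for p in gold.positives if p in ev.scores]
    neg_scores = [ev.scores[p] for p in gold.negatives if p in ev.scores]
    if not pos_scores or not neg_scores:
        raise NotFittableError(
            f"evidence {ev.name!r} covers no gold "
            f"{'positives' if not pos_scores else 'negatives'}"
        )
    if not categorical:
        categorical = any(isinstance(s, str) for s in (pos_scores[0], neg_scores[0]))
    if categorical:
        cats = sorted(set(pos_scores) | set(neg_scores))
        pos_counts = np.array([pos_scores.count(c) for c in cats], dtype=float)
        neg_counts = np.array([neg_scores.count(c) for c in cats], dtype=float)
        return BinnedLikelihood(ev.name, pos_counts, neg_counts,
                                pseudocount, categories=list(cats))
    allscores = np.asarray(pos_scores + neg_scores, dtype=float)
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(allscores, qs))
    if len(edges) < 2:  # all scores identical -> single bin
        edges = np.array([edges[0], edges[0]])
    interior = edges[1:-1]
    pos_counts = np.bincount(
        np.searchsorted(interior, pos_scores, side="right"), minlength=len(edges) - 1
    ).astype(float)
    neg_counts = np.bincount(
        np.searchsorted(interior, neg_scores, side="right"), minlength=len(edges) - 1
    ).astype(float)
    return BinnedLikelihood(ev.name, pos_counts, neg_counts, pseudocount, edges=edges)


def composite_lr(pair: Pair, models: Sequence[BinnedLikelihood],
                 evs: Sequence[EvidenceTable]) -> float:
    """Composite LR of one pair: product of bin LRs over covering evidences.

    Accumulated as a sum of logs for numerical safety; a pair covered by
    no evidence has composite LR exactly 1.
    """
    log_lr = 0.0
    for model, ev in zip(models, evs):
        if pair in ev.scores:
            log_lr += math.log(model.lr_for_score(ev.scores[pair]))
    return math.exp(log_lr)


def posterior_odds(prior_odds: float, lr: float) -> float:
    """Posterior odds of functional linkage = prior odds x composite LR."""
    return prior_odds * lr


@dataclass
class CompositeLR:
    """Composite likelihood ratios over a pair universe, with provenance."""

    scores: Dict[Pair, float]
    contributing: Dict[Pair, List[str]] = field(default_factory=dict)
    prior_odds: float = 1.0

    def posterior(self, pair: Pair) -> float:
        return posterior_odds(self.prior_odds, self.scores[pair])


def score_pairs(pairs: Iterable[Pair], models: Sequence[BinnedLikelihood],
                evs: Sequence[EvidenceTable], prior_odds: float = 1.0) -> CompositeLR:
    """Composite LR for every pair in the universe (vectorised per evidence)."""
    pairs = list(pairs)
    log_lr = np.zeros(len(pairs))
    contributing: Dict[Pair, List[str]] = {p: [] for p in pairs}
    for model, ev in zip(models, evs):
        log_bin_lrs = np.log(model.bin_lrs)
        for i, p in enumerate(pairs):
            if p in ev.scores:
                log_lr[i] += log_bin_lrs[model.bin_of(ev.scores[p])]
                contributing[p].append(ev.name)
    return CompositeLR(
        scores={p: float(math.exp(v)) for p, v in zip(pairs, log_lr)},
        contributing=contributing,
        prior_odds=prior_odds,
    )


def tp_fp_curve(scores: Mapping[Pair, float] | CompositeLR,
                gold: GoldStandardPairs,
                cutoffs: Sequence[float]) -> pd.DataFrame:
    """TP, FP, TP/FP and sensitivity on the gold standard per LR cutoff.

    TP counts gold positives scoring at or above the cutoff, FP the
    corresponding gold negatives; sensitivity = TP/(TP+FN).
    """
    if isinstance(scores, CompositeLR):
        scores = scores.scores
    pos = np.array([scores[p] for p in sorted(gold.positives)])
    neg = np.array([scores[p] for p in sorted(gold.negatives)])
    rows = []
    for c in sorted(cutoffs):
        tp = int((pos >= c).sum())
        fp = int((neg >= c).sum())
        rows.append({
            "cutoff": c, "TP": tp, "FP": fp,
            "tp_fp_ratio": tp / fp if fp else math.inf,
            "sensitivity": tp / len(pos) if len(pos) else math.nan,
        })
    return pd.DataFrame(rows)


def select_cutoff(curve: pd.DataFrame, target_ratio: float = 1.0) -> float:
    """Smallest evaluated cutoff whose TP/FP ratio reaches ``target_ratio``."""
    if curve.empty:
        raise ValueError("empty TP/FP curve")
    ok = curve[curve["tp_fp_ratio"] >= target_ratio]
    if ok.empty:
        raise CutoffNotAttainableError(
            f"no cutoff reaches TP/FP >= {target_ratio} "
            f"(max {curve['tp_fp_ratio'].max():.3g})"
        )
    return float(ok["cutoff"].min())


def build_fln(genes: Iterable[str], scores: Mapping[Pair, float] | CompositeLR,
              cutoff: float | None) -> nx.Graph:
    """Assemble the weighted FLN from composite-LR-scored pairs.

    Every scored pair among ``genes`` with LR >= cutoff becomes an edge
    weighted by its composite LR (all scored pairs when cutoff is
    None).  Genes with no retained linkage are dropped from the node
    set.
    """
    if isinstance(scores, CompositeLR):
        scores = scores.scores
    genes = set(genes)
    edges = [
        (a, b, lr) for (a, b), lr in scores.items()
        if a in genes and b in genes and (cutoff is None or lr >= cutoff)
    ]
    return make_fln(edges)


def _roc_from_scores(y: np.ndarray, s: np.ndarray) -> Tuple[pd.DataFrame, float]:
    fpr, tpr, _ = _roc_curve(y, s)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), float(_trapezoid_auc(fpr, tpr))


def crossvalidate_integration_5fold(evs: Sequence[EvidenceTable],
                                    gold: GoldStandardPairs,
                                    n_bins: int = 5, pseudocount: float = 1.0,
                                    seed: int = 0, n_folds: int = 5,
                                    group_by_scale: bool = False,
                                    ) -> Dict[str, Dict]:
    """Cross-validated ROC/AUC of single-evidence and integrated models.

    Gold pairs are stratified into ``n_folds`` folds; LR models are
    fitted on the training folds and held-out pairs scored by log
    composite LR.  Returns per-model ROC points and trapezoidal AUC for
    every single evidence, the fully integrated model, and (optionally)
    per ``scale_tag`` subsets of the evidences.
    """
    pairs = sorted(gold.all_pairs)
    y = np.array([gold.label(p) for p in pairs])
    if min((y == 1).sum(), (y == 0).sum()) < n_folds:
        raise ValueError(f"need >= {n_folds} gold pairs per class")
    model_sets: Dict[str, List[int]] = {ev.name: [i] for i, ev in enumerate(evs)}
    model_sets["integrated"] = list(range(len(evs)))
    if group_by_scale:
        for tag in sorted({ev.scale_tag for ev in evs}):
            model_sets[f"integrated:{tag}"] = [
                i for i, ev in enumerate(evs) if ev.scale_tag == tag
            ]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    held_scores: Dict[str, np.ndarray] = {m: np.zeros(len(pairs)) for m in model_sets}
    for train_idx, test_idx in skf.split(np.zeros(len(pairs)), y):
        train_gold = GoldStandardPairs(
            frozenset(pairs[i] for i in train_idx if y[i] == 1),
            frozenset(pairs[i] for i in train_idx if y[i] == 0),
        )
        fitted = [
            fit_binned_likelihood(ev, train_gold, n_bins, pseudocount) for ev in evs
        ]
        for mname, idxs in model_sets.items():
            sub_models = [fitted[i] for i in idxs]
            sub_evs = [evs[i] for i in idxs]
            for i in test_idx:
                held_scores[mname][i] = math.log(
                    composite_lr(pairs[i], sub_models, sub_evs)
                )
    out = {}
    for mname in model_sets:
        roc, auc = _roc_from_scores(y, held_scores[mname])
        out[mname] = {"roc": roc, "auc": auc, "scores": held_scores[mname]}
    return out
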