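import itertools
import math

import numpy as np
import pytest

from mitofln import (
    EvidenceSpec,
    build_fln,
    composite_lr,
    compute_coverage,
    crossvalidate_integration_5fold,
    fit_binned_likelihood,
    make_gold_standard,
    make_world,
    pairwise_independence,
    posterior_odds,
    score_pairs,
    select_cutoff,
    simulate_evidence,
    tp_fp_curve,
)
from mitofln.integration import CutoffNotAttainableError, NotFittableError
from mitofln.inventory import UndefinedMetricError
from mitofln.netcore import EvidenceTable, GoldStandardPairs
from .conftest import all_pairs


def pair(i, j):
    a, b = f"g{i:03d}", f"g{j:03d}"
    return (a, b) if a < b else (b, a)


def big_gold(n_pos=200, n_neg=200):
    """Disjoint synthetic positive/negative pairs over a gene grid."""
    pos = frozenset(pair(2 * i, 2 * i + 1) for i in range(n_pos))
    neg = frozenset(pair(2 * (n_pos + i), 2 * (n_pos + i) + 1) for i in range(n_neg))
    return GoldStandardPairs(pos, neg)


class TestCoverage:
    def test_full_and_empty(self, small_gold):
        full = EvidenceTable("f", {p: 1.0 for p in small_gold.all_pairs})
        assert compute_coverage(full, small_gold) == 1.0
        assert compute_coverage(EvidenceTable("e"), small_gold) == 0.0

    def test_boundary_fraction(self):
        gs = big_gold(75, 75)
        covered = sorted(gs.all_pairs)[:30]
        ev = EvidenceTable("e", {p: 0.5 for p in covered})
        assert compute_coverage(ev, gs) == pytest.approx(0.2)

    def test_empty_gold_standard_raises(self):
        with pytest.raises(UndefinedMetricError):
            compute_coverage(EvidenceTable("e"), GoldStandardPairs(frozenset(),
                                                                   frozenset()))


class TestPairwiseIndependence:
    def test_self_and_negation(self):
        gs = big_gold(50, 50)
        rng = np.random.default_rng(0)
        scores = {p: float(rng.normal()) for p in gs.all_pairs}
        a = EvidenceTable("a", scores)
        b = EvidenceTable("b", {p: -s for p, s in scores.items()})
        mat = pairwise_independence([a, b], gs)
        assert mat.loc["a", "a"] == 1.0
        assert mat.loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_evidences_uncorrelated(self):
        gs = big_gold(5000, 5000)
        rng = np.random.default_rng(1)
        a = EvidenceTable("a", {p: float(rng.normal()) for p in gs.all_pairs})
        b = EvidenceTable("b", {p: float(rng.normal()) for p in gs.all_pairs})
        mat = pairwise_independence([a, b], gs)
        assert abs(mat.loc["a", "b"]) < 0.1

    def test_insufficient_overlap_flagged_nan(self):
        gs = big_gold(10, 10)
        pairs = sorted(gs.all_pairs)
        a = EvidenceTable("a", {pairs[0]: 1.0, pairs[1]: 2.0})
        b = EvidenceTable("b", {pairs[0]: 1.0, pairs[2]: 2.0})
        mat = pairwise_independence([a, b], gs)
        assert np.isnan(mat.loc["a", "b"])


class TestBinnedLikelihood:
    def test_direct_count_ratio_with_zero_pseudocount(self):
        # one category holds 10/100 positives vs 5/100 negatives -> LR 2
        gs = big_gold(100, 100)
        pos = sorted(gs.positives)
        neg = sorted(gs.negatives)
        scores = {}
        scores.update({p: "hit" for p in pos[:10]})
        scores.update({p: "miss" for p in pos[10:]})
        scores.update({p: "hit" for p in neg[:5]})
        scores.update({p: "miss" for p in neg[5:]})
        ev = EvidenceTable("cat", scores)
        model = fit_binned_likelihood(ev, gs, pseudocount=0.0, categorical=True)
        assert model.lr_for_score("hit") == pytest.approx(2.0)

    def test_uninformative_evidence_all_bins_near_one(self):
        gs = big_gold(50_000, 50_000)
        rng = np.random.default_rng(2)
        ev = EvidenceTable("u", {p: float(s) for p, s in
                                 zip(sorted(gs.all_pairs), rng.normal(size=100_000))})
        model = fit_binned_likelihood(ev, gs, n_bins=5)
        assert np.allclose(model.bin_lrs, 1.0, atol=0.1)

    def test_separated_classes_have_informative_bin(self, small_world, small_gold):
        spec = EvidenceSpec("e", ("normal", 2.0, 1.0), ("normal", 0.0, 1.0))
        ev = simulate_evidence(small_gold, sorted(small_gold.all_pairs), spec, seed=3)
        model = fit_binned_likelihood(ev, small_gold, n_bins=5)
        assert (model.bin_lrs > 1).any()

    def test_no_gold_overlap_raises(self, small_gold):
        with pytest.raises(NotFittableError):
            fit_binned_likelihood(EvidenceTable("e"), small_gold)

    def test_pseudocount_keeps_lrs_finite_and_positive(self):
        gs = big_gold(20, 20)
        # all positives in the top bin, all negatives in the bottom one
        scores = {p: 10.0 for p in gs.positives}
        scores.update({p: -10.0 for p in gs.negatives})
        model = fit_binned_likelihood(EvidenceTable("e", scores), gs,
                                      n_bins=2, pseudocount=1.0)
        assert np.isfinite(model.bin_lrs).all()
        assert (model.bin_lrs > 0).all()


class TestCompositeLR:
    def make_setup(self):
        gs = big_gold(60, 60)
        rng = np.random.default_rng(4)
        evs, models = [], []
        for name in ("e1", "e2", "e3"):
            scores = {p: float(rng.normal(1.0, 1.0)) for p in gs.positives}
            scores.update({p: float(rng.normal(0.0, 1.0)) for p in gs.negatives})
            ev = EvidenceTable(name, scores)
            evs.append(ev)
            models.append(fit_binned_likelihood(ev, gs, n_bins=4))
        return gs, evs, models

    def test_product_of_known_factors(self):
        # two-category models whose "x" bins carry LRs 2, 3 and 0.5:
        # with equal class totals, LR("x") = pos_x / neg_x
        evs, models = [], []
        for name, (pos_x, neg_x) in (("e1", (4, 2)), ("e2", (6, 2)),
                                     ("e3", (2, 4))):
            sub = big_gold(10, 10)
            scores = {}
            for i, p in enumerate(sorted(sub.positives)):
                scores[p] = "x" if i < pos_x else "y"
            for i, p in enumerate(sorted(sub.negatives)):
                scores[p] = "x" if i < neg_x else "y"
            ev = EvidenceTable(name, scores)
            model = fit_binned_likelihood(ev, sub, pseudocount=0.0, categorical=True)
            assert model.lr_for_score("x") == pytest.approx(pos_x / neg_x)
            ev.scores[("a", "b")] = "x"
            evs.append(ev)
            models.append(model)
        assert composite_lr(("a", "b"), models, evs) == pytest.approx(3.0)

    def test_uncovered_pair_is_unit(self):
        gs, evs, models = self.make_setup()
        assert composite_lr(("zz1", "zz2"), models, evs) == 1.0

    def test_order_invariance(self):
        gs, evs, models = self.make_setup()
        p = sorted(gs.positives)[0]
        fwd = composite_lr(p, models, evs)
        rev = composite_lr(p, models[::-1], evs[::-1])
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_posterior_odds_identity(self):
        gs, evs, models = self.make_setup()
        scored = score_pairs(sorted(gs.all_pairs), models, evs, prior_odds=0.035)
        for p in itertools.islice(sorted(gs.all_pairs), 10):
            assert scored.posterior(p) == pytest.approx(0.035 * scored.scores[p],
                                                        rel=1e-15)

    def test_unit_lr_evidence_is_noop(self):
        gs, evs, models = self.make_setup()
        flat = EvidenceTable("flat", {p: 0.0 for p in gs.all_pairs})
        sub = big_gold(30, 30)
        flat_model = fit_binned_likelihood(
            EvidenceTable("flat", {p: 0.0 for p in sub.all_pairs}), sub,
            n_bins=3, pseudocount=1.0)
        assert np.allclose(flat_model.bin_lrs, 1.0)
        p = sorted(gs.positives)[0]
        assert composite_lr(p, models + [flat_model], evs + [flat]) == \
            pytest.approx(composite_lr(p, models, evs), rel=1e-12)


class TestCutoffAndFln:
    def make_curve(self):
        gs = big_gold(100, 100)
        rng = np.random.default_rng(5)
        scores = {p: float(np.exp(rng.normal(1.0, 1.0))) for p in gs.positives}
        scores.update({p: float(np.exp(rng.normal(-1.0, 1.0))) for p in gs.negatives})
        cutoffs = np.linspace(0.0, 10.0, 101)
        return gs, scores, tp_fp_curve(scores, gs, cutoffs)

    def test_low_cutoff_full_sensitivity(self):
        gs, scores, curve = self.make_curve()
        assert curve["sensitivity"].iloc[0] == 1.0

    def test_sensitivity_and_counts_non_increasing(self):
        gs, scores, curve = self.make_curve()
        assert (np.diff(curve["sensitivity"]) <= 0).all()
        assert (np.diff(curve["TP"]) <= 0).all()
        assert (np.diff(curve["FP"]) <= 0).all()

    def test_precision_is_half_where_ratio_is_one(self):
        gs, scores, curve = self.make_curve()
        exact = curve[curve["tp_fp_ratio"] == 1.0]
        for row in exact.itertuples():
            assert row.TP / (row.TP + row.FP) == 0.5

    def test_select_cutoff_ge_rule(self):
        import pandas as pd
        curve = pd.DataFrame({"cutoff": [1, 2, 3, 4],
                              "tp_fp_ratio": [0.5, 0.9, 1.2, 2.0]})
        assert select_cutoff(curve, target_ratio=1.0) == 3
        assert select_cutoff(curve, target_ratio=0.0) == 1
        with pytest.raises(CutoffNotAttainableError):
            select_cutoff(curve, target_ratio=5.0)

    def test_build_fln_cutoffs(self):
        gs, scores, curve = self.make_curve()
        genes = {g for p in scores for g in p}
        empty = build_fln(genes, scores, cutoff=1e9)
        assert empty.number_of_edges() == 0
        full = build_fln(genes, scores, cutoff=None)
        assert full.number_of_edges() == len(scores)
        assert full.number_of_nodes() <= len(genes)


class TestIntegrationCV:
    def synthetic_evidences(self, seed, mus=(1.2, 1.0, 0.8), coverage=0.8):
        w = make_world(50, 0, 10, (4, 10), seed=seed)
        gs = make_gold_standard(w)
        evs = []
        for i, mu in enumerate(mus):
            spec = EvidenceSpec(f"e{i}", ("normal", mu, 1.0), ("normal", 0.0, 1.0),
                                coverage=coverage)
            evs.append(simulate_evidence(gs, sorted(gs.all_pairs), spec,
                                         seed=seed * 101 + i))
        return gs, evs

    def test_uninformative_evidence_auc_near_chance(self):
        gs, _ = self.synthetic_evidences(seed=1)
        spec = EvidenceSpec("flat", ("normal", 0, 1), ("normal", 0, 1))
        ev = simulate_evidence(gs, sorted(gs.all_pairs), spec, seed=2)
        out = crossvalidate_integration_5fold([ev], gs, seed=3)
        assert out["flat"]["auc"] == pytest.approx(0.5, abs=0.08)

    def test_perfect_evidence_auc_one(self):
        # disjoint supports: positives and negatives never share a category
        gs, _ = self.synthetic_evidences(seed=4)
        scores = {p: "present" for p in gs.positives}
        scores.update({p: "absent" for p in gs.negatives})
        ev = EvidenceTable("perfect", scores)
        out = crossvalidate_integration_5fold([ev], gs, n_bins=2, seed=5)
        assert out["perfect"]["auc"] == 1.0

    def test_integration_beats_singles(self):
        gs, evs = self.synthetic_evidences(seed=6)
        out = crossvalidate_integration_5fold(evs, gs, seed=7)
        singles = [out[e.name]["auc"] for e in evs]
        assert out["integrated"]["auc"] >= max(singles) - 0.02

    def test_scale_groups_reported(self):
        gs, evs = self.synthetic_evidences(seed=8)
        evs[0].scale_tag = "mitochondria-specific"
        out = crossvalidate_integration_5fold(evs, gs, seed=9, group_by_scale=True)
        assert "integrated:mitochondria-specific" in out
        assert "integrated:genome-scale" in out
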