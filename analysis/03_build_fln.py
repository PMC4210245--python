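"""Stage 2: integrate the evidence tables into the weighted FLN.

Applies the 20% gold-standard coverage filter, screens pairwise Pearson
correlation between the retained evidences (the conditional
independence assumption), fits equal-frequency-binned likelihood ratios
per evidence, reports 5-fold cross-validated ROC AUC of each single
evidence versus the integrated model, selects the composite-LR cutoff
where the TP/FP ratio first reaches 1, and writes the resulting network
as a TSV edge list plus GraphML, with summary statistics.
"""

import sys
from pathlib import Path

import pandas as pd

import mitofln.netcore as netcore
from mitofln import (
    build_fln,
    canonical_pair,
    compute_coverage,
    crossvalidate_integration_5fold,
    fit_binned_likelihood,
    pairwise_independence,
    score_pairs,
    select_cutoff,
    tp_fp_curve,
)
from mitofln.netcore import GoldStandardPairs
from mitofln.synthetic import read_evidence_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240917
DATA = Path("results/data")
OUT = Path("results")
COVERAGE_MIN = 0.20
N_BINS = 5
PSEUDOCOUNT = 1.0


def main():
    gold_df = pd.read_csv(DATA / "gold_pairs.tsv", sep="\t")
    gold = GoldStandardPairs(
        frozenset(canonical_pair(r.gene_a, r.gene_b)
                  for r in gold_df.itertuples() if r.label == "pos"),
        frozenset(canonical_pair(r.gene_a, r.gene_b)
                  for r in gold_df.itertuples() if r.label == "neg"),
    )
    evs = [read_evidence_table(p)
           for p in sorted(DATA.glob("evidence_*.tsv"))]

    kept = []
    for ev in evs:
        cov = compute_coverage(ev, gold)
        verdict = "kept" if cov >= COVERAGE_MIN else "excluded (low coverage)"
        print(f"  {ev.name}: gold coverage {cov:.2f} -> {verdict}")
        if cov >= COVERAGE_MIN:
            kept.append(ev)

    pcc = pairwise_independence(kept, gold)
    pcc.to_csv(OUT / "evidence_pcc.tsv", sep="\t")
    off_diag = pcc.mask(pd.DataFrame(
        [[a == b for b in pcc.columns] for a in pcc.index],
        index=pcc.index, columns=pcc.columns))
    print(f"max |PCC| between retained evidences: "
          f"{off_diag.abs().max().max():.3f}")

    cv = crossvalidate_integration_5fold(kept, gold, n_bins=N_BINS,
                                         pseudocount=PSEUDOCOUNT, seed=SEED)
    auc_rows = [{"model": name, "auc": res["auc"]} for name, res in cv.items()]
    pd.DataFrame(auc_rows).to_csv(OUT / "integration_auc.tsv", sep="\t",
                                  index=False)
    for row in auc_rows:
        print(f"  5-fold CV AUC {row['model']}: {row['auc']:.3f}")

    models = [fit_binned_likelihood(ev, gold, N_BINS, PSEUDOCOUNT) for ev in kept]
    pd.concat([m.report() for m in models]).to_csv(
        OUT / "binned_lr_models.tsv", sep="\t", index=False)

    universe = sorted({p for ev in kept for p in ev.scores} | gold.all_pairs)
    scored = score_pairs(universe, models, kept)
    cutoffs = sorted({round(s, 6) for p in gold.all_pairs
                      for s in [scored.scores[p]]})
    curve = tp_fp_curve(scored, gold, cutoffs)
    curve.to_csv(OUT / "tp_fp_curve.tsv", sep="\t", index=False)
    cutoff = select_cutoff(curve, target_ratio=1.0)
    print(f"selected composite-LR cutoff {cutoff:.3g} (TP/FP first >= 1)")

    genes = {g for p in universe for g in p}
    fln = build_fln(genes, scored, cutoff)
    netcore.write_edgelist(fln, OUT / "fln.tsv")
    netcore.export_graphml(fln, OUT / "fln.graphml")
    stats = netcore.graph_stats(fln)
    pd.DataFrame([stats]).to_csv(OUT / "fln_stats.tsv", sep="\t", index=False)
    print(f"FLN: {stats['nodes']} proteins, {stats['edges']} linkages, "
          f"average neighbors {stats['average_neighbors']:.3f}, "
          f"density {stats['density']:.3f}")


if __name__ == "__main__":
    main()
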