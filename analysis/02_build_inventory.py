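"""Stage 1: classify proteins as mitochondrial and tier the inventory.

Trains AdaBoost.M1 over decision stumps on the detection matrix using
the pathway-annotated mitochondrial proteins as gold positives and the
contaminants as gold negatives, reports stratified 10-fold CV
sensitivity and FDR, then assembles the confidence tiers (high =
classifier positives plus restored gold positives; middle = detected in
more than 5 experiments; low = the rest).
"""

import sys
from pathlib import Path

import pandas as pd

from mitofln import (
    assemble_inventory,
    crossvalidate_10fold,
    fdr,
    predict_membership,
    sensitivity,
    train_boosted_classifier,
)
from mitofln.inventory import inventory_report

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240917
DATA = Path("results/data")
OUT = Path("results")


def main():
    detections = pd.read_csv(DATA / "detections.tsv", sep="\t", index_col=0)
    genes = pd.read_csv(DATA / "genes.tsv", sep="\t").fillna({"pathways": ""})
    annotated = genes["pathways"] != ""
    gsp = set(genes.loc[annotated & (genes["true_mito"] == 1), "gene"])
    gsn = set(genes.loc[genes["true_mito"] == 0, "gene"])
    labels = pd.Series({**{g: 1 for g in gsp}, **{g: 0 for g in gsn}})

    counts, per_fold = crossvalidate_10fold(detections, labels, rounds=50,
                                            seed=SEED)
    model = train_boosted_classifier(detections, labels, rounds=50, seed=SEED)
    predictions = predict_membership(model, detections)
    tiers = assemble_inventory(predictions, gsp, reference_members=set(),
                               matrix=detections, vote_threshold=5)

    inventory_report(tiers, detections, gsp, set()).to_csv(
        OUT / "inventory_tiers.tsv", sep="\t", index=False)
    metrics = pd.DataFrame([{
        "sensitivity": sensitivity(counts), "fdr": fdr(counts),
        "TP": counts.TP, "FP": counts.FP, "FN": counts.FN, "TN": counts.TN,
    }])
    metrics.to_csv(OUT / "inventory_metrics.tsv", sep="\t", index=False)

    true_mito = set(genes.loc[genes["true_mito"] == 1, "gene"])
    high = set(tiers[tiers == "high"].index)
    print(f"10-fold CV on {len(labels)} labeled proteins: "
          f"sensitivity {sensitivity(counts):.3f}, FDR {fdr(counts):.3f}")
    print("tier counts:", tiers.value_counts().to_dict())
    print(f"high tier recovers {len(high & true_mito)}/{len(true_mito)} "
          f"true mitochondrial proteins "
          f"({len(high - true_mito)} contaminants slipped in)")


if __name__ == "__main__":
    main()
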