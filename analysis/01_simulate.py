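"""Generate the synthetic study inputs with known ground truth.

Builds a world of 120 mitochondrial and 60 contaminant proteins with 12
overlapping pathways (6-14 members), simulates 23 binary proteomic
detection experiments (detection probability 0.6 for mitochondrial
proteins, 0.1 for contaminants), derives the gold-standard pair sets
from shared pathway membership, and draws five heterogeneous pairwise
evidence datasets of varying informativeness and coverage — including
one below the 20% coverage bar and one uninformative control.

Writes everything as TSV under results/data/.
"""

import itertools
import sys
from pathlib import Path

import pandas as pd

from mitofln import (
    EvidenceSpec,
    canonical_pair,
    make_gold_standard,
    make_world,
    simulate_detections,
    simulate_evidence,
)
from mitofln.synthetic import write_evidence_table, write_gene_table

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240917
OUT = Path("results/data")

EVIDENCE_SPECS = [
    # name, pos mean, coverage, scale
    EvidenceSpec("coexpression", ("normal", 1.2, 1.0), ("normal", 0.0, 1.0),
                 coverage=0.8, scale_tag="genome-scale"),
    EvidenceSpec("interaction", ("normal", 1.0, 1.0), ("normal", 0.0, 1.0),
                 coverage=0.5, scale_tag="genome-scale"),
    EvidenceSpec("func_similarity", ("normal", 0.8, 1.0), ("normal", 0.0, 1.0),
                 coverage=0.3, scale_tag="mitochondria-specific"),
    EvidenceSpec("sparse_profile", ("normal", 1.5, 1.0), ("normal", 0.0, 1.0),
                 coverage=0.15, scale_tag="mitochondria-specific"),
    EvidenceSpec("uninformative", ("normal", 0.0, 1.0), ("normal", 0.0, 1.0),
                 coverage=0.6, scale_tag="genome-scale"),
]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    world = make_world(n_mito=120, n_nonmito=60, n_pathways=12,
                       pathway_size_range=(6, 14), seed=SEED)
    write_gene_table(world, OUT / "genes.tsv")

    detections = simulate_detections(world, n_datasets=23, p_detect_mito=0.6,
                                     p_detect_contaminant=0.1, seed=SEED + 1)
    detections.to_csv(OUT / "detections.tsv", sep="\t")

    gold = make_gold_standard(world)
    rows = [{"gene_a": a, "gene_b": b, "label": "pos"}
            for a, b in sorted(gold.positives)]
    rows += [{"gene_a": a, "gene_b": b, "label": "neg"}
             for a, b in sorted(gold.negatives)]
    pd.DataFrame(rows).to_csv(OUT / "gold_pairs.tsv", sep="\t", index=False)

    pairs = [canonical_pair(a, b)
             for a, b in itertools.combinations(world.mito_proteins, 2)]
    for i, spec in enumerate(EVIDENCE_SPECS):
        ev = simulate_evidence(gold, pairs, spec, seed=SEED + 10 + i)
        write_evidence_table(ev, OUT / f"evidence_{spec.name}.tsv")

    print(f"world: {len(world.proteins)} proteins "
          f"({len(world.mito_proteins)} mitochondrial), "
          f"{len(world.pathways)} pathways")
    print(f"gold standard: {len(gold.positives)} positive / "
          f"{len(gold.negatives)} negative pairs")
    print(f"wrote detections ({detections.shape[0]}x{detections.shape[1]}) and "
          f"{len(EVIDENCE_SPECS)} evidence tables to {OUT}/")


if __name__ == "__main__":
    main()
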