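"""Synthetic inputs with known ground truth for the three-stage pipeline.

Real runs of this procedure consume curated resources that are not
redistributable: organelle proteomic surveys, pathway/complex
memberships, heterogeneous pairwise evidence datasets and disease gene
annotations.  This module generates statistical stand-ins for all of
them — a world of mitochondrial and contaminant proteins with pathway
structure, Bernoulli detection matrices, class-conditional pairwise
evidence scores, and disease modules planted into a weighted network —
so that every downstream estimate can be checked against a known truth.

All generators are pure functions of an explicit integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .netcore import EvidenceTable, GoldStandardPairs, Pair, canonical_pair


@dataclass
class SyntheticWorld:
    """A universe of proteins with known compartment and pathway truth.

    ``true_mito`` flags genuinely mitochondrial proteins; the rest model
    co-purifying contaminants.  Pathways (standing in for curated
    pathway/complex memberships) are drawn only from mitochondrial
    proteins and may overlap.  Disease modules are filled in later by
    :func:`plant_disease_modules`.
    """

    proteins: List[str]
    true_mito: Dict[str, bool]
    pathways: Dict[str, FrozenSet[str]]
    disease_modules: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("protein identifiers must be unique")
        universe = set(self.proteins)
        for pid, members in self.pathways.items():
            if not members <= universe:
                raise ValueError(f"pathway {pid} has members outside the world")
            if any(not self.true_mito[m] for m in members):
                raise ValueError(f"pathway {pid} contains non-mitochondrial proteins")
        for did, members in self.disease_modules.items():
            if not members <= universe:
                raise ValueError(f"disease module {did} has members outside the world")

    @property
    def mito_proteins(self) -> List[str]:
        return [p for p in self.proteins if self.true_mito[p]]


@dataclass(frozen=True)
class EvidenceSpec:
    """Parametric description of one synthetic pairwise evidence dataset.

    ``positive_distribution`` / ``negative_distribution`` are
    ``(family, *params)`` tuples; supported families are ``"normal"``
    (loc, scale) and ``"beta"`` (a, b).  ``coverage`` is the fraction of
    the pair universe that receives a score at all; missingness is
    uninformative (independent of class).
    """

    name: str
    positive_distribution: Tuple = ("normal", 1.0, 1.0)
    negative_distribution: Tuple = ("normal", 0.0, 1.0)
    coverage: float = 1.0
    scale_tag: str = "genome-scale"

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        fam_p, fam_n = self.positive_distribution[0], self.negative_distribution[0]
        if fam_p not in _FAMILIES or fam_n not in _FAMILIES:
            raise ValueError(f"unsupported distribution family: {fam_p!r}/{fam_n!r}")
        if fam_p != fam_n:
            raise ValueError("positive and negative distributions must share a support")


def _draw(dist: Tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    family, *params = dist
    return _FAMILIES[family](rng, params, size)


_FAMILIES = {
    "normal": lambda rng, p, size: rng.normal(p[0], p[1], size=size),
    "beta": lambda rng, p, size: rng.beta(p[0], p[1], size=size),
}


def make_world(n_mito: int, n_nonmito: int, n_pathways: int,
               pathway_size_range: Tuple[int, int] = (5, 15),
               seed: int = 0) -> SyntheticWorld:
    """Generate proteins, compartment truth and overlapping pathways.

    Pathway sizes are drawn uniformly from ``pathway_size_range``
    (inclusive) and members sampled without replacement from the
    mitochondrial proteins; a protein may sit in several pathways.
    """
    if n_mito <= 0 or n_nonmito < 0 or n_pathways < 0:
        raise ValueError("counts must be positive (n_nonmito, n_pathways may be 0)")
    lo, hi = pathway_size_range
    if lo < 2 or hi < lo:
        raise ValueError("pathway sizes must be >= 2 and the range non-empty")
    if hi > n_mito:
        raise ValueError(f"pathway size {hi} exceeds n_mito={n_mito}")
    rng = np.random.default_rng(seed)
    width = len(str(n_mito + n_nonmito))
    proteins = [f"G{i:0{width}d}" for i in range(1, n_mito + n_nonmito + 1)]
    true_mito = {p: i < n_mito for i, p in enumerate(proteins)}
    mito = proteins[:n_mito]
    pathways = {}
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(mito, size=size, replace=False)
        pathways[f"PW{k + 1:03d}"] = frozenset(members.tolist())
    return SyntheticWorld(proteins, true_mito, pathways, rng_seed=seed)


def make_gold_standard(world: SyntheticWorld) -> GoldStandardPairs:
    """Derive gold standard pairs from shared pathway membership.

    Positives are unordered pairs co-annotated to at least one pathway;
    negatives are pairs where both members carry some pathway annotation
    but share none.  Pairs with an unannotated member are not part of
    the gold standard.
    """
    if not world.pathways:
        raise ValueError("world has no pathways; gold standard undefined")
    membership: Dict[str, Set[str]] = {}
    for pid, members in world.pathways.items():
        for m in members:
            membership.setdefault(m, set()).add(pid)
    annotated = sorted(membership)
    positives, negatives = set(), set()
    for a, b in itertools.combinations(annotated, 2):
        pair = canonical_pair(a, b)
        if membership[a] & membership[b]:
            positives.add(pair)
        else:
            negatives.add(pair)
    return GoldStandardPairs(frozenset(positives), frozenset(negatives))


def simulate_evidence(gold: GoldStandardPairs, all_pairs: Sequence[Pair],
                      spec: EvidenceSpec, seed: int = 0,
                      planted_positives: FrozenSet[Pair] = frozenset()) -> EvidenceTable:
    """Draw one evidence dataset from class-conditional score distributions.

    Exactly ``floor(coverage * len(all_pairs))`` pairs, chosen uniformly
    at random, receive a score: from the positive distribution if the
    pair is a gold positive (or listed in ``planted_positives``), else
    from the negative distribution.
    """
    rng = np.random.default_rng(seed)
    all_pairs = sorted(set(all_pairs))
    n_cov = int(np.floor(spec.coverage * len(all_pairs)))
    idx = rng.choice(len(all_pairs), size=n_cov, replace=False) if n_cov else []
    covered = [all_pairs[i] for i in sorted(idx)]
    is_pos = np.array(
        [p in gold.positives or p in planted_positives for p in covered], dtype=bool
    )
    scores = np.empty(len(covered))
    scores[is_pos] = _draw(spec.positive_distribution, int(is_pos.sum()), rng)
    scores[~is_pos] = _draw(spec.negative_distribution, int((~is_pos).sum()), rng)
    return EvidenceTable(
        name=spec.name,
        scores={p: float(s) for p, s in zip(covered, scores)},
        scale_tag=spec.scale_tag,
    )


def simulate_detections(world: SyntheticWorld, n_datasets: int,
                        p_detect_mito: float, p_detect_contaminant: float,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate a binary protein-by-experiment detection matrix.

    Each protein is detected in each simulated proteomic experiment
    independently, with probability ``p_detect_mito`` for genuinely
    mitochondrial proteins and ``p_detect_contaminant`` for
    contaminants.  Returns genes x datasets 0/1 DataFrame.
    """
    for p in (p_detect_mito, p_detect_contaminant):
        if not 0.0 <= p <= 1.0:
            raise ValueError("detection probabilities must lie in [0, 1]")
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [p_detect_mito if world.true_mito[g] else p_detect_contaminant
         for g in world.proteins]
    )
    values = (rng.random((len(world.proteins), n_datasets)) < probs[:, None]).astype(int)
    cols = [f"DS{j + 1:02d}" for j in range(n_datasets)]
    return pd.DataFrame(values, index=world.proteins, columns=cols)


def plant_disease_modules(fln: nx.Graph, n_diseases: int, module_size: int,
                          boost: float = 10.0, seed: int = 0,
                          ) -> Tuple[Dict[str, FrozenSet[str]], nx.Graph]:
    """Plant disjoint disease gene modules into a weighted network.

    For each disease, ``module_size`` nodes are sampled (disjointly
    across diseases) and every internal edge weight is multiplied by
    ``boost``; internal edges absent from the network are created at the
    network's median edge weight first, so the boost is interpretable on
    the same scale everywhere.  Returns the module map and a modified
    copy of the graph.
    """
    if boost < 1:
        raise ValueError("boost must be >= 1")
    nodes = sorted(fln.nodes)
    if n_diseases * module_size > len(nodes):
        raise ValueError(
            f"{n_diseases} disjoint modules of size {module_size} exceed "
            f"{len(nodes)} network nodes"
        )
    if fln.number_of_edges() == 0:
        raise ValueError("network has no edges; baseline weight undefined")
    rng = np.random.default_rng(seed)
    baseline = float(np.median([d["weight"] for _, _, d in fln.edges(data=True)]))
    g = fln.copy()
    chosen = rng.choice(nodes, size=n_diseases * module_size, replace=False)
    modules: Dict[str, FrozenSet[str]] = {}
    for k in range(n_diseases):
        members = sorted(chosen[k * module_size:(k + 1) * module_size].tolist())
        modules[f"DIS{k + 1:02d}"] = frozenset(members)
        for a, b in itertools.combinations(members, 2):
            if not g.has_edge(a, b):
                g.add_edge(a, b, weight=baseline)
            g[a][b]["weight"] *= boost
    return modules, g


def write_gene_table(world: SyntheticWorld, path) -> None:
    """Write the gene table TSV: id, true_mito flag, semicolon-joined pathways."""
    membership: Dict[str, List[str]] = {g: [] for g in world.proteins}
    for pid in sorted(world.pathways):
        for m in world.pathways[pid]:
            membership[m].append(pid)
    rows = [
        {"gene": g, "true_mito": int(world.true_mito[g]),
         "pathways": ";".join(sorted(membership[g]))}
        for g in world.proteins
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_evidence_table(ev: EvidenceTable, path) -> None:
    """Write evidence TSV: gene_a, gene_b, evidence_name, score."""
    rows = [
        {"gene_a": a, "gene_b": b, "evidence_name": ev.name, "score": s}
        for (a, b), s in sorted(ev.scores.items())
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "evidence_name", "score"]
                 ).to_csv(path, sep="\t", index=False)


def read_evidence_table(path) -> EvidenceTable:
    df = pd.read_csv(path, sep="\t")
    name = str(df["evidence_name"].iloc[0]) if len(df) else "evidence"
    scores = {
        canonical_pair(str(r.gene_a), str(r.gene_b)): float(r.score)
        for r in df.itertuples()
    }
    return EvidenceTable(name=name, scores=scores)
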