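"""Drug-drug similarity measures and repurposing-pair selection.

Three complementary views of drug relatedness:

* **functional** -- each drug is described by its vector of Pearson
  correlations between predicted drug activity and multi-omics pathway
  activity across cell lines; the functional similarity of two drugs is
  the Pearson correlation of those vectors.  Range [-1, 1].
* **structural** -- Tanimoto coefficient |A & B| / |A | B| of binary
  structural fingerprints computed from SMILES.  Range [0, 1].
* **target distance** -- S = A * exp(-b * D) where D is the minimal
  shortest-path length in the PPI network between the two drugs' target
  sets (D = 0 for a shared target).  A = 0.9, b = 1 following Perlman et
  al.; self-similarity is 1 and unreachable pairs score 0.

Candidate repurposing pairs are the unordered drug pairs whose functional
similarity exceeds a threshold (default 0.95).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    DrugResponseMatrix,
    PathwayActivityMatrix,
    SimilarityMatrix,
    TargetMap,
)

__all__ = [
    "DrugPathwayCorrelation",
    "drug_pathway_correlation",
    "functional_similarity",
    "tanimoto",
    "tanimoto_similarity",
    "target_distance_similarity",
    "PairSelection",
    "select_repurposing_pairs",
]

DEFAULT_THRESHOLD = 0.95
PERLMAN_A = 0.9
PERLMAN_B = 1.0


@dataclass
class DrugPathwayCorrelation:
    """Drugs x pathways matrix of Pearson correlations across cell lines."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("DrugPathwayCorrelation: non-finite entry")
        if np.abs(vals).max() > 1 + 1e-12:
            raise ValueError("DrugPathwayCorrelation: |r| > 1")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.data.columns)


def _rowwise_correlation(a: np.ndarray, b: np.ndarray, what: str) -> np.ndarray:
    """Pearson correlation of every row of ``a`` with every row of ``b``.

    Zero-variance rows yield 0 entries with a warning instead of NaN, so
    downstream matrices stay finite.
    """
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac * ac).sum(axis=1))
    sb = np.sqrt((bc * bc).sum(axis=1))
    if (sa == 0).any() or (sb == 0).any():
        warnings.warn(
            f"{what}: zero-variance vector(s); the affected correlations are set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    denom = np.outer(sa, sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac @ bc.T) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def drug_pathway_correlation(
    predicted: DrugResponseMatrix, profiles: PathwayActivityMatrix
) -> DrugPathwayCorrelation:
    """Correlate each drug's (predicted) activity with each pathway's
    activity over the cell lines both matrices share (>= 3 required)."""
    shared = [c for c in predicted.cellline_ids if c in set(profiles.sample_ids)]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared cell lines, found {len(shared)}"
        )
    d = predicted.data[shared].to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("predicted response must be dense over the shared cell lines")
    p = profiles.data[shared].to_numpy(dtype=float)
    r = _rowwise_correlation(d, p, "drug-pathway correlation")
    return DrugPathwayCorrelation(
        data=pd.DataFrame(r, index=predicted.drug_ids, columns=profiles.pathway_ids)
    )


def functional_similarity(corr: DrugPathwayCorrelation) -> SimilarityMatrix:
    """Pairwise Pearson correlation of the drugs' pathway-correlation rows."""
    if corr.data.shape[1] < 3:
        raise ValueError("need >= 3 pathways for a stable functional similarity")
    vals = corr.data.to_numpy(dtype=float)
    sim = _rowwise_correlation(vals, vals, "functional similarity")
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(
        kind="functional",
        data=pd.DataFrame(sim, index=corr.drug_ids, columns=corr.drug_ids),
    )


def tanimoto(features_a, features_b) -> float:
    """Tanimoto coefficient of two feature sets: |A & B| / |A | B|."""
    a, b = set(features_a), set(features_b)
    union = a | b
    if not union:
        raise ValueError("both feature sets are empty")
    return len(a & b) / len(union)


def _fingerprint(mol, fingerprint: str, n_bits: int, radius: int):
    from rdkit.Chem import rdFingerprintGenerator

    if fingerprint == "rdkit":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    elif fingerprint == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    else:
        raise ValueError(f"unknown fingerprint type {fingerprint!r}")
    return gen.GetFingerprint(mol)


def tanimoto_similarity(
    smiles_by_drug: dict[str, str],
    fingerprint: str = "rdkit",
    n_bits: int = 2048,
    radius: int = 2,
) -> SimilarityMatrix:
    """Structural similarity matrix from SMILES via binary fingerprints.

    Drugs whose SMILES cannot be parsed are excluded with a warning (they
    appear in no row/column), mirroring missing structures in the source
    annotation rather than crashing the run.  Default is the path-based
    RDKit fingerprint; ``fingerprint='morgan'`` selects circular
    fingerprints of the given radius.
    """
    from rdkit import Chem, DataStructs

    fps: dict[str, object] = {}
    for drug, smiles in smiles_by_drug.items():
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            warnings.warn(
                f"drug {drug!r}: unparseable SMILES {smiles!r}; excluded from "
                "structural similarity",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        fps[drug] = _fingerprint(mol, fingerprint, n_bits, radius)
    if not fps:
        raise ValueError("no drug has a parseable SMILES")
    drugs = list(fps)
    n = len(drugs)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = DataStructs.TanimotoSimilarity(fps[drugs[i]], fps[drugs[j]])
            sim[i, j] = sim[j, i] = s
    return SimilarityMatrix(
        kind="structural", data=pd.DataFrame(sim, index=drugs, columns=drugs)
    )


def _min_target_distance(
    graph: nx.Graph, targets_a: set[str], targets_b: set[str]
) -> float:
    """Minimal unweighted shortest-path length between two target sets.

    A shared target gene means distance 0 even if the gene is absent from
    the PPI network; otherwise only genes present in the network can be
    connected, and disjoint components give an infinite distance.
    """
    if targets_a & targets_b:
        return 0.0
    sources = [t for t in targets_a if t in graph]
    sinks = {t for t in targets_b if t in graph}
    if not sources or not sinks:
        return math.inf
    best = math.inf
    dist = nx.multi_source_dijkstra_path_length(graph, sources, weight=None)
    for t in sinks:
        if t in dist and dist[t] < best:
            best = dist[t]
    return best


def target_distance_similarity(
    targets: TargetMap, a: float = PERLMAN_A, b: float = PERLMAN_B
) -> SimilarityMatrix:
    """PPI target-distance similarity S = a * exp(-b * D).

    D is the minimum over all cross pairs of target genes of the unweighted
    shortest-path length in the PPI network; a shared target gives D = 0 and
    hence S = a.  Self-similarity is fixed to 1; pairs with no connecting
    path score 0 (the D -> inf limit).
    """
    drugs = targets.drug_ids
    if not drugs:
        raise ValueError("no drug has mapped targets")
    n = len(drugs)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = _min_target_distance(
                targets.graph, targets.targets[drugs[i]], targets.targets[drugs[j]]
            )
            s = 0.0 if math.isinf(d) else a * math.exp(-b * d)
            sim[i, j] = sim[j, i] = s
    return SimilarityMatrix(
        kind="target_distance", data=pd.DataFrame(sim, index=drugs, columns=drugs)
    )


@dataclass
class PairSelection:
    """Thresholded candidate pairs plus the total number of unordered pairs."""

    pairs: list[tuple[str, str, float]]
    total_pairs: int
    threshold: float

    @property
    def n_selected(self) -> int:
        return len(self.pairs)


def select_repurposing_pairs(
    sim: SimilarityMatrix, threshold: float = DEFAULT_THRESHOLD
) -> PairSelection:
    """All unordered off-diagonal pairs with similarity strictly above the
    threshold, sorted by descending similarity (stable in drug-id order)."""
    if not -1.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (-1, 1)")
    drugs = sim.drug_ids
    n = len(drugs)
    if n < 2:
        warnings.warn("fewer than 2 drugs: no pairs to select", RuntimeWarning, stacklevel=2)
        return PairSelection(pairs=[], total_pairs=0, threshold=threshold)
    vals = sim.data.to_numpy(dtype=float)
    hits = [
        (drugs[i], drugs[j], float(vals[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if vals[i, j] > threshold
    ]
    hits.sort(key=lambda t: -t[2])
    return PairSelection(pairs=hits, total_pairs=n * (n - 1) // 2, threshold=threshold)
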