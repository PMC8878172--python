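"""Seeded desk-scale synthetic inputs for every pipeline stage.

The generators emit data with the statistical structure the pipeline
assumes -- three omics layers with a planted pathway-level signal, drug
responses drawn exactly from the factorization model (for recovery tests),
a small chemistry table of real SMILES, and a random PPI network with
drug-target assignments that include a shared-target pair and a
disconnected pair.  Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    CellLineFeatures,
    DrugResponseMatrix,
    GeneSetCollection,
    OmicsMatrix,
    RecommenderModel,
    TargetMap,
)
from .recommender import predict

__all__ = [
    "FixtureConfig",
    "make_gene_sets",
    "make_omics_layers",
    "make_response_from_model",
    "make_chem_and_targets",
    "write_fixture_dir",
]

# Real, parseable molecules; cycled (with a trivial methyl-extension twist)
# when more drugs are requested than the list holds.
_SMILES_POOL = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "c1ccc2ccccc2c1",                   # naphthalene
    "Cc1ccccc1",                        # toluene
    "Oc1ccccc1",                        # phenol
    "c1ccncc1",                         # pyridine
    "CCO",                              # ethanol
    "CC(=O)C",                          # acetone
    "NC(=O)c1ccccc1",                   # benzamide
    "OCC1OC(O)C(O)C(O)C1O",             # glucopyranose
]


@dataclass
class FixtureConfig:
    """Sizes and noise levels of the synthetic study.

    Defaults are chosen to be the smallest sizes at which correlations,
    enrichment scores and the factorization are all non-degenerate: 60
    genes, 20 cell lines, 10 drugs, 8 gene sets of 6 genes, a rank-2 latent
    structure, no noise and no missingness unless requested.
    """

    seed: int = 0
    n_genes: int = 60
    n_samples: int = 20
    n_drugs: int = 10
    n_sets: int = 8
    genes_per_set: int = 6
    f_true: int = 2
    noise_sd: float = 0.0
    missing_fraction: float = 0.0
    n_ppi_nodes: int = 30
    edge_probability: float = 0.15
    gene_ids: list[str] = field(init=False)
    sample_ids: list[str] = field(init=False)
    drug_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_drugs", "n_sets", "genes_per_set", "n_ppi_nodes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.f_true < 0:
            raise ValueError("f_true must be >= 0")
        if self.n_ppi_nodes > self.n_genes:
            raise ValueError("n_ppi_nodes cannot exceed n_genes")
        self.gene_ids = [f"g{i:03d}" for i in range(1, self.n_genes + 1)]
        self.sample_ids = [f"cl{i:02d}" for i in range(1, self.n_samples + 1)]
        self.drug_ids = [f"d{i:02d}" for i in range(1, self.n_drugs + 1)]


def make_gene_sets(config: FixtureConfig) -> GeneSetCollection:
    """Disjoint-leaning gene sets drawn without replacement per set."""
    rng = np.random.default_rng([config.seed, 11])
    sets = {}
    for k in range(config.n_sets):
        members = rng.choice(config.gene_ids, size=config.genes_per_set, replace=False)
        sets[f"set{k + 1:02d}"] = [str(g) for g in members]
    return GeneSetCollection(sets)


def make_omics_layers(
    config: FixtureConfig, sets: GeneSetCollection | None = None
) -> list[OmicsMatrix]:
    """Expression (lognormal), methylation (in (0,1)) and CNV (counts).

    The first gene set's members get an expression shift in the first half
    of the samples, planting a pathway-level covariance that ssGSEA should
    recover as a high-vs-low group separation.
    """
    if sets is None:
        sets = make_gene_sets(config)
    rng = np.random.default_rng([config.seed, 23])
    g, s = config.n_genes, config.n_samples

    log_expr = rng.normal(3.0, 1.0, size=(g, s))
    first_set = sets[sets.set_ids[0]]
    member_rows = [config.gene_ids.index(x) for x in first_set]
    half = s // 2
    log_expr[np.ix_(member_rows, range(half))] += 1.5
    expression = np.exp(log_expr)

    methylation = 1.0 / (1.0 + np.exp(-rng.normal(0.0, 1.5, size=(g, s))))
    cnv = rng.poisson(2.0, size=(g, s)).astype(float)

    def frame(arr):
        return pd.DataFrame(arr, index=config.gene_ids, columns=config.sample_ids)

    return [
        OmicsMatrix("expression", frame(expression)),
        OmicsMatrix("methylation", frame(methylation)),
        OmicsMatrix("cnv", frame(cnv)),
    ]


def make_response_from_model(
    config: FixtureConfig, features: CellLineFeatures
) -> tuple[DrugResponseMatrix, RecommenderModel]:
    """Drug responses generated exactly from a seeded ground-truth model.

    Returns the emitted matrix (plus Gaussian noise of sd ``noise_sd``,
    with ``missing_fraction`` of the entries masked at random) and the
    generating model, for parameter-recovery testing.
    """
    rng = np.random.default_rng([config.seed, 37])
    n_d = config.n_drugs
    d = features.d
    truth = RecommenderModel(
        mu=float(rng.normal(0.0, 0.5)),
        drug_bias=pd.Series(rng.normal(0.0, 0.5, size=n_d), index=config.drug_ids),
        cell_bias=pd.Series(
            rng.normal(0.0, 0.5, size=len(features.cellline_ids)),
            index=features.cellline_ids,
        ),
        drug_latent=pd.DataFrame(
            rng.normal(0.0, 0.5, size=(n_d, config.f_true)), index=config.drug_ids
        ),
        projection=rng.normal(0.0, 0.5, size=(d, config.f_true)),
        f=config.f_true,
        feature_ids=features.feature_ids,
        seed=config.seed,
    )
    clean = predict(truth, features).data
    noisy = clean + rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd else clean.copy()
    n_cells = len(features.cellline_ids)
    n_mask = round(config.missing_fraction * n_d * n_cells)
    if n_mask:
        flat = rng.choice(n_d * n_cells, size=n_mask, replace=False)
        arr = noisy.to_numpy()
        arr[np.unravel_index(flat, arr.shape)] = np.nan
        noisy = pd.DataFrame(arr, index=noisy.index, columns=noisy.columns)
    return DrugResponseMatrix(data=noisy), truth


def make_chem_and_targets(config: FixtureConfig) -> tuple[dict[str, str], TargetMap]:
    """SMILES per drug plus a random PPI network with target assignments.

    The first two drugs share a target (distance 0); the last drug targets
    an isolated gene so that at least one pair is disconnected.
    """
    rng = np.random.default_rng([config.seed, 53])
    smiles = {
        drug: _SMILES_POOL[i % len(_SMILES_POOL)]
        for i, drug in enumerate(config.drug_ids)
    }
    nodes = config.gene_ids[: config.n_ppi_nodes]
    er = nx.gnp_random_graph(
        config.n_ppi_nodes, config.edge_probability, seed=int(config.seed) % (2**31)
    )
    graph = nx.relabel_nodes(er, dict(enumerate(nodes)))
    isolated = "g_iso"
    graph.add_node(isolated)

    targets: dict[str, set[str]] = {}
    shared = nodes[0]
    for i, drug in enumerate(config.drug_ids):
        if i < 2:
            targets[drug] = {shared}
        elif i == config.n_drugs - 1 and config.n_drugs > 2:
            targets[drug] = {isolated}
        else:
            k = int(rng.integers(1, 4))
            picked = rng.choice(nodes, size=min(k, len(nodes)), replace=False)
            targets[drug] = {str(t) for t in picked}
    return smiles, TargetMap(targets=targets, graph=graph)


def write_fixture_dir(config: FixtureConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize a complete demo dataset in the on-disk input formats.

    Responses are written already on the -log10(IC50) scale.  Returns the
    mapping of logical name -> written path.
    """
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sets = make_gene_sets(config)
    layers = make_omics_layers(config, sets)
    from .enrichment import build_multiomics_profiles
    from .recommender import compute_cellline_features

    profiles = build_multiomics_profiles(layers, sets)
    features = compute_cellline_features(profiles)
    response, _ = make_response_from_model(config, features)
    smiles, target_map = make_chem_and_targets(config)

    paths = {}
    for layer in layers:
        paths[layer.layer_name] = outdir / f"{layer.layer_name}.csv"
        pio.write_matrix(layer.data, paths[layer.layer_name])
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    pio.write_gmt(sets, paths["gene_sets"])
    paths["response"] = outdir / "response.csv"
    pio.write_matrix(response.data, paths["response"])
    paths["smiles"] = outdir / "smiles.tsv"
    pio.write_smiles(smiles, paths["smiles"])
    paths["targets"] = outdir / "targets.tsv"
    pio.write_targets(target_map.targets, paths["targets"])
    paths["ppi"] = outdir / "ppi_edges.tsv"
    pio.write_ppi_edgelist(target_map.graph, paths["ppi"])
    return paths
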