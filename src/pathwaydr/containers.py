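"""Domain containers shared across the pipeline.

Each container wraps a :class:`pandas.DataFrame` (or plain mappings) and
validates the invariants the downstream stages rely on.  Containers are
deliberately thin: all numerics live in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "GeneSetCollection",
    "PathwayActivityMatrix",
    "DrugResponseMatrix",
    "CellLineFeatures",
    "RecommenderModel",
    "SimilarityMatrix",
    "TargetMap",
]

KNOWN_LAYERS = ("expression", "methylation", "cnv", "other")


def _check_frame(df: pd.DataFrame, what: str) -> None:
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{what}: matrix is empty")


@dataclass
class OmicsMatrix:
    """One omics layer: genes x samples of real values.

    ``data`` may carry duplicate gene ids before
    :func:`~pathwaydr.enrichment.aggregate_duplicate_genes` is applied;
    afterwards the index is unique.  Rows that are entirely missing are
    rejected (they can never contribute to a rank).
    """

    layer_name: str
    data: pd.DataFrame  # genes x samples

    def __post_init__(self) -> None:
        _check_frame(self.data, f"OmicsMatrix[{self.layer_name}]")
        if self.data.isna().all(axis=1).any():
            bad = self.data.index[self.data.isna().all(axis=1)][0]
            raise ValueError(
                f"OmicsMatrix[{self.layer_name}]: gene {bad!r} is missing in every sample"
            )
        if self.data.columns.duplicated().any():
            raise ValueError(f"OmicsMatrix[{self.layer_name}]: duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def has_unique_genes(self) -> bool:
        return not self.data.index.duplicated().any()


class GeneSetCollection:
    """Mapping of set id -> ordered, de-duplicated member gene ids."""

    def __init__(self, sets: Mapping[str, Iterable[str]]):
        self._sets: dict[str, list[str]] = {}
        for set_id, members in sets.items():
            unique = list(dict.fromkeys(members))
            if not unique:
                raise ValueError(f"gene set {set_id!r} is empty")
            if set_id in self._sets:
                raise ValueError(f"duplicate set id {set_id!r}")
            self._sets[set_id] = unique

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __getitem__(self, set_id: str) -> list[str]:
        return self._sets[set_id]

    def items(self):
        return self._sets.items()

    @property
    def set_ids(self) -> list[str]:
        return list(self._sets)


@dataclass
class PathwayActivityMatrix:
    """Pathways x samples of enrichment scores.

    Row ids are layer-qualified (``"<layer>:<set_id>"``) so the same
    pathway may appear once per omics layer after concatenation.
    """

    data: pd.DataFrame  # pathways x samples

    def __post_init__(self) -> None:
        _check_frame(self.data, "PathwayActivityMatrix")
        if self.data.index.duplicated().any():
            raise ValueError("PathwayActivityMatrix: duplicate pathway ids")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("PathwayActivityMatrix: non-finite score")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DrugResponseMatrix:
    """Drugs x cell lines of -log10(IC50); NaN marks unobserved entries."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_frame(self.data, "DrugResponseMatrix")
        if self.data.index.duplicated().any():
            raise ValueError("DrugResponseMatrix: duplicate drug ids")
        if self.data.columns.duplicated().any():
            raise ValueError("DrugResponseMatrix: duplicate cell line ids")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cellline_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_observed(self) -> int:
        return int(self.data.notna().to_numpy().sum())


@dataclass
class CellLineFeatures:
    """Cell-line feature vectors x_u: correlations with reference cell lines.

    Rows are cell lines, columns the ``d`` reference cell lines.  When a
    cell line is its own reference the diagonal entry is 1.
    """

    data: pd.DataFrame  # cell lines x reference cell lines

    def __post_init__(self) -> None:
        _check_frame(self.data, "CellLineFeatures")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmax(np.abs(vals)) > 1 + 1e-9:
            raise ValueError("CellLineFeatures: correlation outside [-1, 1]")

    @property
    def cellline_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def d(self) -> int:
        return self.data.shape[1]


@dataclass
class RecommenderModel:
    """Fitted (or ground-truth) recommender: mu, biases, latents, projection.

    Predictions follow
    ``s_hat(u, i) = mu + b_drug[i] + b_cell[u] + q_i . (x_u @ W)``
    with ``q_i`` the drug latent vector and ``W`` the d x f projection of
    cell-line features into the latent space.
    """

    mu: float
    drug_bias: pd.Series  # indexed by drug id
    cell_bias: pd.Series  # indexed by cell line id
    drug_latent: pd.DataFrame  # drugs x f
    projection: np.ndarray  # d x f
    f: int
    feature_ids: list[str] = field(default_factory=list)
    seed: int | None = None
    loss_trace: list[float] | None = None

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("latent dimension f must be >= 0")
        self.projection = np.asarray(self.projection, dtype=float)
        if self.drug_latent.shape != (len(self.drug_bias), self.f):
            raise ValueError("drug_latent shape inconsistent with drug count / f")
        if self.projection.shape[1] != self.f:
            raise ValueError("projection column count must equal f")
        if self.feature_ids and self.projection.shape[0] != len(self.feature_ids):
            raise ValueError("projection row count must equal feature dimension d")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.drug_bias.index)


SIMILARITY_KINDS = ("functional", "structural", "target_distance")


@dataclass
class SimilarityMatrix:
    """Symmetric drug x drug similarity with unit diagonal, tagged by kind."""

    kind: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        _check_frame(self.data, f"SimilarityMatrix[{self.kind}]")
        if list(self.data.index) != list(self.data.columns):
            raise ValueError("SimilarityMatrix: row/column ids differ")
        vals = self.data.to_numpy(dtype=float)
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("SimilarityMatrix: not symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-12):
            raise ValueError("SimilarityMatrix: diagonal must be 1")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class TargetMap:
    """Drug -> target gene set, plus the PPI network the targets live on."""

    targets: dict[str, set[str]]
    graph: nx.Graph

    def __post_init__(self) -> None:
        for drug, genes in self.targets.items():
            if not genes:
                raise ValueError(f"drug {drug!r} has an empty target set")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.targets)
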