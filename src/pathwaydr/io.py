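"""Readers and writers for the pipeline's on-disk dialects.

All formats are plain text:

* matrices -- CSV/TSV, first column the row id, header row of column ids;
* gene sets -- GMT (set id, description, members..., tab-separated);
* SMILES -- two columns ``drug_id<TAB>SMILES``;
* drug targets -- two columns ``drug_id<TAB>gene_id`` (one row per pair);
* PPI network -- edge list ``gene_a<TAB>gene_b[<TAB>combined_score]`` with
  an optional STRING-style confidence score filtered at ``min_score``;
* models -- a single JSON bundle with every prediction component plus the
  training seed.

Malformed rows are reported with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GeneSetCollection, RecommenderModel

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_smiles",
    "write_smiles",
    "read_targets",
    "write_targets",
    "read_ppi_edgelist",
    "write_ppi_edgelist",
    "model_to_json",
    "model_from_json",
]

DEFAULT_PPI_MIN_SCORE = 700.0


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read an id-indexed numeric matrix (CSV by default, TSV by suffix)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write with shortest round-trip float reprs, so write->read is the
    identity on values (not merely close)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), float_format=lambda x: repr(float(x)))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT: ``set_id<TAB>description<TAB>members...``."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT rows need id, description and >= 1 member"
                )
            set_id, members = parts[0], [g for g in parts[2:] if g]
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            sets[set_id] = members
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for set_id, members in sets.items():
            fh.write("\t".join([set_id, "na", *members]) + "\n")


def _read_two_column(path: str | Path, what: str) -> list[tuple[str, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed {what} row {line!r}")
            rows.append((parts[0], parts[1]))
    return rows


def read_smiles(path: str | Path) -> dict[str, str]:
    """Read ``drug_id<TAB>SMILES`` records (one per line)."""
    out: dict[str, str] = {}
    for drug, smi in _read_two_column(path, "SMILES"):
        if drug in out:
            raise ValueError(f"{path}: duplicate drug id {drug!r}")
        out[drug] = smi
    return out


def write_smiles(smiles: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for drug, smi in smiles.items():
            fh.write(f"{drug}\t{smi}\n")


def read_targets(path: str | Path) -> dict[str, set[str]]:
    """Read ``drug_id<TAB>gene_id`` target pairs into drug -> gene set."""
    out: dict[str, set[str]] = {}
    for drug, gene in _read_two_column(path, "drug-target"):
        out.setdefault(drug, set()).add(gene)
    return out


def write_targets(targets: dict[str, set[str]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for drug in targets:
            for gene in sorted(targets[drug]):
                fh.write(f"{drug}\t{gene}\n")


def read_ppi_edgelist(
    path: str | Path,
    min_score: float = DEFAULT_PPI_MIN_SCORE,
    extra_nodes=None,
) -> nx.Graph:
    """Read an undirected PPI edge list, dropping edges below ``min_score``.

    A third column, when present, is a STRING-style combined confidence
    score (0-1000); rows without one always pass.  ``extra_nodes`` (for
    example target genes that appear in no edge) are added as isolated
    nodes so distance queries can resolve them.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed edge row {line!r}")
            a, b = parts[0], parts[1]
            if len(parts) >= 3 and parts[2]:
                try:
                    score = float(parts[2])
                except ValueError as err:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric edge score {parts[2]!r}"
                    ) from err
                if score < min_score:
                    continue
            graph.add_edge(a, b)
    if extra_nodes:
        graph.add_nodes_from(extra_nodes)
    return graph


def write_ppi_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Write edges (sorted for reproducibility); isolated nodes are implied
    by whichever target table accompanies the network."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def model_to_json(model: RecommenderModel, path: str | Path) -> None:
    """Serialize every prediction component of the model to one JSON file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    bundle = {
        "mu": model.mu,
        "f": model.f,
        "seed": model.seed,
        "drug_ids": model.drug_ids,
        "cellline_ids": list(model.cell_bias.index),
        "feature_ids": model.feature_ids,
        "drug_bias": model.drug_bias.to_list(),
        "cell_bias": model.cell_bias.to_list(),
        "drug_latent": model.drug_latent.to_numpy().tolist(),
        "projection": np.asarray(model.projection).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=1)


def model_from_json(path: str | Path) -> RecommenderModel:
    with open(path) as fh:
        bundle = json.load(fh)
    f = int(bundle["f"])
    n_drugs = len(bundle["drug_ids"])
    d = len(bundle["feature_ids"])
    return RecommenderModel(
        mu=float(bundle["mu"]),
        drug_bias=pd.Series(bundle["drug_bias"], index=bundle["drug_ids"], dtype=float),
        cell_bias=pd.Series(bundle["cell_bias"], index=bundle["cellline_ids"], dtype=float),
        drug_latent=pd.DataFrame(
            np.asarray(bundle["drug_latent"], dtype=float).reshape(n_drugs, f),
            index=bundle["drug_ids"],
        ),
        projection=np.asarray(bundle["projection"], dtype=float).reshape(d, f),
        f=f,
        feature_ids=list(bundle["feature_ids"]),
        seed=bundle.get("seed"),
    )
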