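"""Single-sample GSEA pathway activity scoring.

Each omics layer (expression, methylation, copy number) is converted into a
pathways x samples activity matrix.  Within one sample the genes are
rank-normalized, then each gene set receives an enrichment score: the running
sum over the ranked gene list of the difference between a rank-weighted ECDF
of the set members and the uniform ECDF of the non-members,

    ES(G, S) = sum_i [ P_G^w(i) - P_NG(i) ]
    P_G^w(i) = sum_{j in G, j <= i} r_j^alpha / sum_{j in G} r_j^alpha
    P_NG(i)  = |{j not in G, j <= i}| / (N - N_G)

with genes ordered by decreasing rank and ``alpha`` (default 0.25) damping
the rank weights.  Scores from the three layers are concatenated with
layer-qualified pathway ids into one multi-omics activity profile.

Conventions (documented because the literature varies):

* Ranks are ordinal integers 1..N; the largest value gets rank N.  Ties are
  broken by input order (stable), so scores are reproducible bit-for-bit.
* Genes missing (NaN) in a sample are dropped from that sample's universe
  before ranking: N is per-sample.
* A set is eligible on a layer iff at least ``min_overlap`` of its members
  are measured there (default 5).
* Values are used as-is; pass ``absolute=True`` to rank by magnitude when a
  layer contains signed quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import GeneSetCollection, OmicsMatrix, PathwayActivityMatrix

__all__ = [
    "aggregate_duplicate_genes",
    "rank_normalize_sample",
    "ssgsea_score",
    "enrichment_score",
    "build_multiomics_profiles",
]

DEFAULT_ALPHA = 0.25
DEFAULT_MIN_OVERLAP = 5


def aggregate_duplicate_genes(matrix: OmicsMatrix, mode: str) -> OmicsMatrix:
    """Collapse rows sharing a gene id, elementwise by ``mode``.

    ``mode='mean'`` is used for expression and copy-number layers,
    ``mode='sum'`` for methylation.  Sample order and first-occurrence gene
    order are preserved; the operation is idempotent.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    if matrix.data.empty:
        raise ValueError("cannot aggregate an empty matrix")
    grouped = matrix.data.groupby(level=0, sort=False).agg(mode)
    # groupby(.. min_count) semantics: sum of all-NaN yields 0; restore NaN
    if mode == "sum":
        all_nan = matrix.data.isna().groupby(level=0, sort=False).all()
        grouped = grouped.mask(all_nan)
    return OmicsMatrix(layer_name=matrix.layer_name, data=grouped)


def rank_normalize_sample(values) -> np.ndarray:
    """Ordinal ranks of one sample's values: largest value -> rank N.

    Ties are broken by input position (stable), so a constant vector maps to
    ``[1, 2, ..., N]``.  All values must be finite; drop missing genes first.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector of per-gene values")
    if arr.size < 2 or not np.isfinite(arr).all():
        raise ValueError("need >= 2 finite values to rank a sample")
    return rankdata(arr, method="ordinal").astype(np.int64)


def ssgsea_score(sample_ranks, member_mask, alpha: float = DEFAULT_ALPHA) -> float:
    """Enrichment score of one gene set in one sample.

    Parameters
    ----------
    sample_ranks : array of rank-normalized values (1..N, no ties).
    member_mask : boolean array marking set members, aligned to
        ``sample_ranks``.
    alpha : rank-weight exponent.
    """
    r = np.asarray(sample_ranks, dtype=float)
    member = np.asarray(member_mask, dtype=bool)
    if r.shape != member.shape:
        raise ValueError("ranks and membership mask must align")
    n = r.size
    n_g = int(member.sum())
    if n_g == 0:
        raise ValueError("gene set has no overlap with the measured genes")
    if n_g == n:
        raise ValueError("gene set covers the whole universe: complement is empty")
    order = np.argsort(-r, kind="stable")
    member_sorted = member[order]
    weights = np.where(member_sorted, r[order] ** alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~member_sorted) / float(n - n_g)
    return float(np.sum(p_in - p_out))


def enrichment_score(
    sample_values: pd.Series,
    members,
    alpha: float = DEFAULT_ALPHA,
    absolute: bool = False,
) -> float:
    """Convenience wrapper: NaN handling + ranking + scoring for one sample."""
    finite = sample_values.dropna()
    vals = finite.abs() if absolute else finite
    ranks = rank_normalize_sample(vals.to_numpy())
    mask = finite.index.isin(set(members))
    return ssgsea_score(ranks, mask, alpha=alpha)


def build_multiomics_profiles(
    layers: list[OmicsMatrix],
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    absolute: bool = False,
) -> PathwayActivityMatrix:
    """Concatenated multi-omics pathway activity profiles.

    One row per eligible (layer, set) pair, labelled ``"<layer>:<set_id>"``;
    columns are the samples shared by every layer (in first-layer order).
    """
    if not layers:
        raise ValueError("need at least one omics layer")
    for layer in layers:
        if not layer.has_unique_genes():
            raise ValueError(
                f"layer {layer.layer_name!r} has duplicate gene ids; "
                "run aggregate_duplicate_genes first"
            )
    shared = [s for s in layers[0].sample_ids if all(s in set(l.sample_ids) for l in layers)]
    if not shared:
        raise ValueError("omics layers share no sample ids")

    rows: dict[str, list[float]] = {}
    for layer in layers:
        measured = set(layer.gene_ids)
        for set_id, members in sets.items():
            overlap = [g for g in members if g in measured]
            if len(overlap) < min_overlap:
                continue
            row_id = f"{layer.layer_name}:{set_id}"
            scores = [
                enrichment_score(layer.data[s], overlap, alpha=alpha, absolute=absolute)
                for s in shared
            ]
            rows[row_id] = scores
    if not rows:
        raise ValueError("no (layer, set) pair passes the overlap rule")
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=shared)
    return PathwayActivityMatrix(data=frame)
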