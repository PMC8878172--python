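"""Feature-projected matrix-factorization model of drug response.

The model predicts the sensitivity of cell line u to drug i as

    s_hat(u, i) = mu + b_i + b_u + q_i . p_u,      p_u = x_u @ W

where mu is the global mean response, b_i and b_u are drug and cell-line
biases, q_i is an f-dimensional drug latent vector and W projects the
cell-line feature vector x_u (its correlations with the d reference cell
lines, computed from the multi-omics pathway activity profiles) into the
latent space.  Training minimizes the squared-error loss over the observed
entries only,

    L = (1 / 2K) * sum_observed (s - s_hat)^2,

by full-batch gradient descent with a backtracking step size, so the loss
trace is monotone non-increasing.  Ranking quality is measured per cell line
with NDCG, where the gain of a drug with relevance s at rank k is
(2^s - 1) / log2(k + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CellLineFeatures,
    DrugResponseMatrix,
    PathwayActivityMatrix,
    RecommenderModel,
)

__all__ = [
    "convert_ic50",
    "compute_cellline_features",
    "predict",
    "train",
    "ndcg",
    "sse_loss",
    "leave_one_cellline_out",
    "RankingEvaluation",
    "evaluate_ranking",
]

LN10 = np.log(10.0)


def convert_ic50(values, input_scale: str):
    """Convert raw IC50 responses to -log10(IC50).

    ``input_scale`` is ``'ln'`` (natural-log IC50, the GDSC convention),
    ``'log10'`` or ``'linear'`` (raw molar concentration, must be > 0).
    Higher output means a more sensitive cell line.  Accepts scalars,
    arrays, Series or DataFrames; NaNs pass through.
    """
    if input_scale == "ln":
        return -values / LN10 if np.isscalar(values) else -(values / LN10)
    if input_scale == "log10":
        return -values
    if input_scale == "linear":
        arr = np.asarray(values, dtype=float) if np.isscalar(values) else values
        if np.nanmin(np.asarray(arr, dtype=float)) <= 0:
            raise ValueError("linear-scale IC50 values must be positive")
        return -np.log10(values) if np.isscalar(values) else -np.log10(arr)
    raise ValueError(f"input_scale must be 'ln', 'log10' or 'linear', got {input_scale!r}")


def compute_cellline_features(profiles: PathwayActivityMatrix) -> CellLineFeatures:
    """Cell-line features: Pearson correlation of every pair of cell lines
    over their multi-omics pathway activity vectors.

    Every cell line in ``profiles`` serves as a reference, so d equals the
    number of cell lines and the diagonal is 1.
    """
    if profiles.data.shape[0] < 2:
        raise ValueError("need >= 2 pathways to correlate cell lines")
    if profiles.data.shape[1] < 2:
        raise ValueError("need >= 2 cell lines")
    stds = profiles.data.std(axis=0, ddof=0)
    flat = stds[stds == 0.0]
    if len(flat):
        raise ValueError(
            f"cell line {flat.index[0]!r} has zero variance across pathways"
        )
    corr = profiles.data.corr(method="pearson")  # samples x samples
    return CellLineFeatures(data=corr.clip(-1.0, 1.0))


def _predict_array(
    mu: float,
    b_drug: np.ndarray,
    b_cell: np.ndarray,
    q: np.ndarray,
    w: np.ndarray,
    x: np.ndarray,
) -> np.ndarray:
    p = x @ w  # cells x f
    return mu + b_drug[:, None] + b_cell[None, :] + q @ p.T


def predict(model: RecommenderModel, features: CellLineFeatures) -> DrugResponseMatrix:
    """Dense predicted response for every drug x cell-line combination."""
    if model.feature_ids and model.feature_ids != features.feature_ids:
        raise ValueError("feature ids of model and features disagree")
    if model.projection.shape[0] != features.d:
        raise ValueError(
            f"feature dimension mismatch: model expects d={model.projection.shape[0]}, "
            f"features have d={features.d}"
        )
    missing = [c for c in features.cellline_ids if c not in model.cell_bias.index]
    if missing:
        raise ValueError(f"no cell-line bias for {missing[0]!r}")
    b_cell = model.cell_bias.reindex(features.cellline_ids).to_numpy(dtype=float)
    s = _predict_array(
        model.mu,
        model.drug_bias.to_numpy(dtype=float),
        b_cell,
        model.drug_latent.to_numpy(dtype=float),
        model.projection,
        features.data.to_numpy(dtype=float),
    )
    return DrugResponseMatrix(
        data=pd.DataFrame(s, index=model.drug_ids, columns=features.cellline_ids)
    )


def train(
    observed: DrugResponseMatrix,
    features: CellLineFeatures,
    f: int = 10,
    seed: int = 0,
    learning_rate: float = 0.01,
    max_epochs: int = 5000,
    tol: float = 1e-8,
    l2: float = 0.0,
    mu: float | None = None,
) -> RecommenderModel:
    """Fit the recommender to the observed response matrix.

    Missing entries are excluded from the loss.  ``mu`` defaults to the mean
    of the observed responses and is held fixed; biases start at 0 and the
    latent factors are drawn from a seeded normal(0, 0.1).  Gradient descent
    backtracks (halving the step) whenever a step would increase the loss and
    grows the step gently after accepted epochs, so the recorded loss trace
    never increases.  ``l2`` adds an optional ridge penalty on q and W
    (default 0: the plain squared-error loss).
    """
    drugs = observed.drug_ids
    cells = observed.cellline_ids
    if list(features.cellline_ids) != cells:
        raise ValueError("features must cover the observed cell lines in order")
    s_obs = observed.data.to_numpy(dtype=float)
    mask = np.isfinite(s_obs)
    k = int(mask.sum())
    if k == 0:
        raise ValueError("no observed response values to train on")
    if not mask.any(axis=1).all():
        raise ValueError("every drug needs at least one observed value")
    if not mask.any(axis=0).all():
        raise ValueError("every cell line needs at least one observed value")
    s_filled = np.where(mask, s_obs, 0.0)
    x = features.data.to_numpy(dtype=float)
    d = x.shape[1]

    mu_val = float(np.nanmean(s_obs)) if mu is None else float(mu)
    rng = np.random.default_rng(seed)
    b_drug = np.zeros(len(drugs))
    b_cell = np.zeros(len(cells))
    q = rng.normal(0.0, 0.1, size=(len(drugs), f))
    w = rng.normal(0.0, 0.1, size=(d, f))

    def loss(bd, bc, qq, ww):
        s_hat = _predict_array(mu_val, bd, bc, qq, ww, x)
        e = np.where(mask, s_filled - s_hat, 0.0)
        base = float((e * e).sum()) / (2.0 * k)
        if l2:
            base += 0.5 * l2 * (float((qq * qq).sum()) + float((ww * ww).sum()))
        return base, e

    lr = float(learning_rate)
    cur, e = loss(b_drug, b_cell, q, w)
    trace = [cur]
    converged = False
    for _ in range(max_epochs):
        g_bd = -e.sum(axis=1) / k
        g_bc = -e.sum(axis=0) / k
        p = x @ w
        g_q = -(e @ p) / k + l2 * q
        g_w = -(x.T @ (e.T @ q)) / k + l2 * w
        while True:
            nb_d = b_drug - lr * g_bd
            nb_c = b_cell - lr * g_bc
            nq = q - lr * g_q
            nw = w - lr * g_w
            new, new_e = loss(nb_d, nb_c, nq, nw)
            if new <= cur + 1e-15:
                break
            lr *= 0.5
            if lr < 1e-18:
                break
        if new > cur + 1e-15:
            break  # step size underflow: keep best-so-far
        b_drug, b_cell, q, w, e = nb_d, nb_c, nq, nw, new_e
        trace.append(new)
        if abs(cur - new) <= tol * max(abs(cur), 1e-12):
            cur = new
            converged = True
            break
        cur = new
        lr *= 1.1
    if not converged:
        warnings.warn(
            f"training did not converge within {max_epochs} epochs "
            f"(final loss {cur:.3e}); returning best-so-far model",
            RuntimeWarning,
            stacklevel=2,
        )
    return RecommenderModel(
        mu=mu_val,
        drug_bias=pd.Series(b_drug, index=drugs),
        cell_bias=pd.Series(b_cell, index=cells),
        drug_latent=pd.DataFrame(q, index=drugs),
        projection=w,
        f=f,
        feature_ids=features.feature_ids,
        seed=seed,
        loss_trace=trace,
    )


def _dcg(gains: np.ndarray, order: np.ndarray) -> float:
    ranks = np.arange(1, order.size + 1, dtype=float)
    return float(np.sum(gains[order] / np.log2(ranks + 1.0)))


def ndcg(predicted_scores, observed_scores, shift_relevance: bool = True) -> float:
    """Normalized discounted cumulative gain of one cell line's drug ranking.

    Relevance values are the observed responses; because -log10(IC50) can be
    negative (which would make the gain 2^s - 1 negative and break the [0, 1]
    range), relevances are shifted by their minimum to be >= 0 by default
    (``shift_relevance=False`` uses them raw).  Both orderings break ties by
    input position, so pass drug vectors in a fixed (id-sorted) order.  A
    constant relevance vector carries no ranking information and scores 1.
    """
    pred = np.asarray(predicted_scores, dtype=float)
    obs = np.asarray(observed_scores, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed score vectors must align")
    keep = np.isfinite(obs)
    pred, obs = pred[keep], obs[keep]
    if obs.size == 0:
        raise ValueError("need at least one observed score")
    s = obs - obs.min() if shift_relevance else obs
    gains = np.power(2.0, s) - 1.0
    ideal_order = np.argsort(-obs, kind="stable")
    ideal = _dcg(gains, ideal_order)
    if ideal == 0.0:
        return 1.0
    model_order = np.argsort(-pred, kind="stable")
    return _dcg(gains, model_order) / ideal


def sse_loss(
    observed: DrugResponseMatrix, predicted: DrugResponseMatrix
) -> tuple[float, pd.DataFrame]:
    """Squared-error loss L = sum(e^2) / 2K over the K observed entries.

    Returns the scalar loss and the residual matrix (NaN where unobserved)
    for diagnostics.
    """
    pred = predicted.data.reindex(
        index=observed.data.index, columns=observed.data.columns
    )
    resid = observed.data - pred
    k = int(resid.notna().to_numpy().sum())
    if k == 0:
        raise ValueError("no observed entries: K = 0")
    total = float(np.nansum(resid.to_numpy() ** 2))
    return total / (2.0 * k), resid


def leave_one_cellline_out(
    observed: DrugResponseMatrix,
    features: CellLineFeatures,
    f: int = 10,
    seed: int = 0,
    shift_relevance: bool = True,
    **train_kwargs,
) -> pd.Series:
    """Held-out NDCG per cell line.

    For each cell line u, the model is refit without u's column (the
    feature dimension d stays the full reference panel) and u's drugs are
    ranked from ``mu + b_i + q_i . (x_u W)`` — the held-out cell line has no
    fitted bias, and a per-cell-line constant cannot change its ranking
    anyway.  No default split is imposed beyond this leave-one-out scheme.
    """
    scores = {}
    for cell in observed.cellline_ids:
        rest = [c for c in observed.cellline_ids if c != cell]
        obs_col = observed.data[cell]
        if obs_col.notna().sum() == 0:
            continue
        sub = DrugResponseMatrix(data=observed.data[rest])
        feats = CellLineFeatures(data=features.data.loc[rest])
        model = train(sub, feats, f=f, seed=seed, **train_kwargs)
        x_u = features.data.loc[cell].to_numpy(dtype=float)
        pred = (
            model.mu
            + model.drug_bias.to_numpy(dtype=float)
            + model.drug_latent.to_numpy(dtype=float) @ (x_u @ model.projection)
        )
        scores[cell] = ndcg(pred, obs_col.to_numpy(), shift_relevance=shift_relevance)
    return pd.Series(scores, dtype=float)


@dataclass
class RankingEvaluation:
    """Per-cell-line NDCG, their mean, a pooled NDCG, and the SSE loss."""

    per_cellline: pd.Series
    mean_ndcg: float
    pooled_ndcg: float
    sse: float


def evaluate_ranking(
    observed: DrugResponseMatrix,
    predicted: DrugResponseMatrix,
    shift_relevance: bool = True,
) -> RankingEvaluation:
    """NDCG per cell line (drugs ranked within each cell line) plus SSE.

    The headline number is the mean of the per-cell-line NDCGs; a pooled
    variant (all observed pairs ranked jointly) is also reported.
    """
    pred = predicted.data.reindex(
        index=observed.data.index, columns=observed.data.columns
    )
    scores = {}
    for cell in observed.cellline_ids:
        obs_col = observed.data[cell]
        if obs_col.notna().sum() == 0:
            continue
        scores[cell] = ndcg(
            pred[cell].to_numpy(), obs_col.to_numpy(), shift_relevance=shift_relevance
        )
    per_cell = pd.Series(scores, dtype=float)
    obs_flat = observed.data.to_numpy().ravel()
    pred_flat = pred.to_numpy().ravel()
    keep = np.isfinite(obs_flat)
    pooled = ndcg(pred_flat[keep], obs_flat[keep], shift_relevance=shift_relevance)
    sse, _ = sse_loss(observed, predicted)
    return RankingEvaluation(
        per_cellline=per_cell,
        mean_ndcg=float(per_cell.mean()),
        pooled_ndcg=pooled,
        sse=sse,
    )
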