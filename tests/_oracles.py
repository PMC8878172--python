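"""Independent brute-force oracles used only by the tests.

These deliberately avoid the vectorized implementation paths: plain Python
loops that transcribe the defining formulas directly, so agreement with the
package is a genuine cross-check.
"""

from __future__ import annotations

import math


def ordinal_ranks(values) -> list[int]:
    """Largest value -> rank N; ties broken by input position."""
    n = len(values)
    # ascending sort, ties by input position: earlier position gets the
    # smaller rank, matching stable ordinal ranking
    order = sorted(range(n), key=lambda j: (values[j], j))
    ranks = [0] * n
    for r, j in enumerate(order, start=1):
        ranks[j] = r
    return ranks


def ssgsea_brute(ranks, member_mask, alpha: float) -> float:
    """Direct O(N^2) transcription of the weighted-ECDF difference walk."""
    n = len(ranks)
    members = [j for j in range(n) if member_mask[j]]
    n_g = len(members)
    assert 0 < n_g < n
    order = sorted(range(n), key=lambda j: (-ranks[j], j))
    denom_in = sum(ranks[j] ** alpha for j in members)
    es = 0.0
    for i in range(1, n + 1):
        prefix = order[:i]
        p_in = sum(ranks[j] ** alpha for j in prefix if member_mask[j]) / denom_in
        p_out = sum(1 for j in prefix if not member_mask[j]) / (n - n_g)
        es += p_in - p_out
    return es


def dcg_brute(relevances, order) -> float:
    """DCG of items presented in ``order`` (indices), gains 2^s - 1."""
    total = 0.0
    for rank, j in enumerate(order, start=1):
        total += (2.0 ** relevances[j] - 1.0) / math.log2(rank + 1)
    return total


def ndcg_brute(predicted, observed, shift: bool = True) -> float:
    """NDCG with stable tie-breaking by input position."""
    n = len(observed)
    s = [x - min(observed) for x in observed] if shift else list(observed)
    model_order = sorted(range(n), key=lambda j: (-predicted[j], j))
    ideal_order = sorted(range(n), key=lambda j: (-observed[j], j))
    ideal = dcg_brute(s, ideal_order)
    if ideal == 0.0:
        return 1.0
    return dcg_brute(s, model_order) / ideal


def pearson_brute(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[j] - mx) * (y[j] - my) for j in range(n))
    dx = math.sqrt(sum((x[j] - mx) ** 2 for j in range(n)))
    dy = math.sqrt(sum((y[j] - my) ** 2 for j in range(n)))
    if dx == 0.0 or dy == 0.0:
        return 0.0
    return num / (dx * dy)


def sse_brute(observed, predicted) -> float:
    """Loss over observed (non-None) cells: sum(e^2) / 2K."""
    total, k = 0.0, 0
    for row_o, row_p in zip(observed, predicted):
        for o, p in zip(row_o, row_p):
            if o is None or (isinstance(o, float) and math.isnan(o)):
                continue
            total += (o - p) ** 2
            k += 1
    return total / (2 * k)
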