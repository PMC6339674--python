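"""Non-parametric IRT checks: Loevinger scalability and monotonicity.

Polytomous Loevinger H coefficients compare observed inter-item covariances
with the maximum covariance attainable given the observed marginals (the
comonotonic sort-and-pair coupling).  Items scaling at H_i >= 0.30 and a
total scale H >= 0.50 indicate a strong Mokken scale.  Monotonicity of the
item-step response functions is checked against rest-score groups: the
probability of endorsing at least category k must not decrease (beyond a
small noise tolerance) as the rest score rises.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ResponseMatrix, ValidationError

VIOLATION_TOLERANCE = 0.03


@dataclass
class ScalabilityResult:
    h_pairs: np.ndarray          # (p, p), nan diagonal
    h_items: np.ndarray          # (p,)
    h_scale: float
    item_ids: list


@dataclass
class MonotonicityResult:
    violations: pd.DataFrame     # item_id, n_violations, max_violation
    restscore_curves: pd.DataFrame
    minsize: int
    tolerance: float


def _pairwise_covariances(x):
    n, p = x.shape
    cov = np.cov(x.T, ddof=1)
    if p == 2:
        cov = np.asarray(cov)
    covmax = np.zeros((p, p))
    sorted_cols = np.sort(x, axis=0)
    for i in range(p):
        for j in range(i + 1, p):
            c = np.cov(sorted_cols[:, i], sorted_cols[:, j], ddof=1)[0, 1]
            covmax[i, j] = covmax[j, i] = c
    return cov, covmax


def scalability(rm: ResponseMatrix) -> ScalabilityResult:
    """Loevinger H per item pair, per item, and for the total scale.

    H_ij = cov(X_i, X_j) / covmax(X_i, X_j) where covmax is the covariance
    of the comonotonic coupling of the two observed marginals; item and
    scale coefficients are ratio-of-sums aggregates.
    """
    rm.require_complete("scalability analysis")
    x = rm.responses.astype(float)
    if rm.n_items < 2:
        raise ValidationError("scalability needs at least 2 items")
    var = x.var(axis=0)
    if np.any(var == 0):
        bad = rm.item_ids[int(np.argmin(var))]
        raise ValidationError(f"item {bad} has zero variance")
    cov, covmax = _pairwise_covariances(x)
    p = rm.n_items
    off = ~np.eye(p, dtype=bool)
    h_pairs = np.full((p, p), np.nan)
    h_pairs[off] = cov[off] / covmax[off]
    h_items = np.array([cov[i, off[i]].sum() / covmax[i, off[i]].sum()
                        for i in range(p)])
    iu = np.triu_indices(p, k=1)
    h_scale = float(cov[iu].sum() / covmax[iu].sum())
    return ScalabilityResult(h_pairs, h_items, h_scale, list(rm.item_ids))


def _restscore_groups(rest, minsize):
    """Group persons by rest score: ascending distinct values accumulated
    until each group holds at least ``minsize`` persons (equal rest scores
    never straddle a boundary); a trailing short group merges backwards."""
    values, counts = np.unique(rest, return_counts=True)
    groups = []
    current = []
    size = 0
    for v, c in zip(values, counts):
        current.append(v)
        size += c
        if size >= minsize:
            groups.append(current)
            current, size = [], 0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    labels = np.empty(len(rest), dtype=int)
    for g, vals in enumerate(groups):
        labels[np.isin(rest, vals)] = g
    return labels, groups


def monotonicity_check(rm: ResponseMatrix, minsize: int | None = None,
                       tolerance: float = VIOLATION_TOLERANCE) -> MonotonicityResult:
    """Count item-step monotonicity violations across rest-score groups.

    A violation is a decrease larger than ``tolerance`` in P(X_i >= k)
    between adjacent rest-score groups.  Default group size is
    max(n // 10, 50), a common choice when none is prescribed.
    """
    rm.require_complete("monotonicity check")
    x = rm.responses
    n, p = x.shape
    if minsize is None:
        minsize = max(n // 10, 50)
    if n < 2 * minsize:
        raise ValidationError(
            f"too few persons ({n}) for rest-score groups of {minsize}; "
            "pass a smaller minsize")
    total = x.sum(axis=1)
    rows = []
    curve_rows = []
    for i in range(p):
        rest = total - x[:, i]
        labels, groups = _restscore_groups(rest, minsize)
        n_groups = labels.max() + 1
        cats = np.unique(x[:, i])
        steps = [k for k in range(2, int(cats.max()) + 1)]
        n_viol = 0
        max_viol = 0.0
        probs = np.zeros((n_groups, len(steps)))
        for g in range(n_groups):
            sel = labels == g
            for s, k in enumerate(steps):
                probs[g, s] = (x[sel, i] >= k).mean()
            curve_rows.append({"item_id": rm.item_ids[i], "group": g,
                               "rest_min": int(min(groups[g])),
                               "rest_max": int(max(groups[g])),
                               "n": int(sel.sum()),
                               **{f"p_ge_{k}": probs[g, s]
                                  for s, k in enumerate(steps)}})
        drops = probs[:-1] - probs[1:]           # positive = decrease
        viol = drops[drops > tolerance]
        n_viol = int(viol.size)
        max_viol = float(viol.max()) if viol.size else 0.0
        rows.append({"item_id": rm.item_ids[i], "n_violations": n_viol,
                     "max_violation": max_viol, "n_groups": int(n_groups)})
    return MonotonicityResult(pd.DataFrame(rows), pd.DataFrame(curve_rows),
                              minsize, tolerance)
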