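"""Orlando–Thissen S-X² item fit for graded (polytomous) items.

Observed response frequencies per category, tabulated within rest-score
groups (summed score over the other items), are compared with their
model-implied expectations under the fitted GRM.  The summed-score
distribution at each quadrature node comes from the generalized
Lord–Wingersky recursion.  Sparse tables are collapsed in two stages —
adjacent score groups merge toward the nearer distribution tail until each
group holds enough expected observations, then adjacent category cells
merge within a group until every expected cell reaches a minimum count —
and the Pearson statistic is referred to a chi-square distribution.  Items
with p < 0.001 are flagged as misfitting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data_io import ItemBank, ResponseMatrix, ValidationError
from .grm import EstimationResult, prob_categories, quadrature

MIN_EXPECTED_CELL = 1.0
FLAG_ALPHA = 0.001


@dataclass
class ItemFitResult:
    table: pd.DataFrame      # item_id, s_x2, df, p_value, n_collapsed_cells, flagged
    alpha: float = FLAG_ALPHA

    @property
    def flagged_items(self):
        return self.table.loc[self.table["flagged"], "item_id"].tolist()


def summed_score_distribution(bank: ItemBank, theta, items=None) -> np.ndarray:
    """P(S = s | theta) for the summed 0-based score over the given items.

    Generalized Lord–Wingersky recursion: successive convolution of the
    per-item category-score distributions at theta.  Returns shape
    (max_score + 1,) for scalar theta, (max_score + 1, T) otherwise.
    """
    scalar = np.isscalar(theta) or np.ndim(theta) == 0
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    idx = list(range(bank.n_items)) if items is None else list(items)
    if not idx:
        raise ValidationError("need at least one item")
    dist = np.ones((1, len(th)))
    for i in idx:
        p = prob_categories(bank.slopes[i], bank.thresholds[i], th)  # (m, T)
        m = p.shape[0]
        new = np.zeros((dist.shape[0] + m - 1, len(th)))
        for k in range(m):
            new[k:k + dist.shape[0]] += dist * p[k]
        dist = new
    return dist[:, 0] if scalar else dist


def _collapse_rows(obs, exp, row_min):
    """Merge adjacent score rows until every row's total expected count
    reaches ``row_min``; the offending row merges toward the nearer
    distribution tail (ties go to the lower-score side)."""
    obs = [row for row in obs]
    exp = [row for row in exp]
    merges = 0
    while len(obs) > 1:
        tot = np.array([row.sum() for row in exp])
        if tot.min() >= row_min:
            break
        r = int(np.argmin(tot))
        last = len(obs) - 1
        if r == 0:
            other = 1
        elif r == last:
            other = last - 1
        else:
            other = r - 1 if r <= last - r else r + 1
        lo, hi = min(r, other), max(r, other)
        obs[lo] = obs[lo] + obs[hi]
        exp[lo] = exp[lo] + exp[hi]
        del obs[hi], exp[hi]
        merges += 1
    return obs, exp, merges


def _collapse_cells(o, e, min_cell=MIN_EXPECTED_CELL):
    """Within one score row, merge adjacent category cells until every
    expected cell reaches ``min_cell`` (merging into the smaller
    neighbour).  Returns (obs_cells, exp_cells)."""
    o = list(o)
    e = list(e)
    while len(e) > 1 and min(e) < min_cell:
        r = int(np.argmin(e))
        if r == 0:
            other = 1
        elif r == len(e) - 1:
            other = r - 1
        else:
            other = r - 1 if e[r - 1] <= e[r + 1] else r + 1
        lo, hi = min(r, other), max(r, other)
        o[lo] += o[hi]
        e[lo] += e[hi]
        del o[hi], e[hi]
    return np.array(o), np.array(e)


def s_x2(rm: ResponseMatrix, fitted: EstimationResult | ItemBank,
         alpha: float = FLAG_ALPHA) -> ItemFitResult:
    """S-X² statistic, degrees of freedom and p-value for every item.

    Expected frequencies condition on the rest score: E_{s,k} is N_s times
    the posterior probability of category k among persons whose other items
    sum to s, integrated over the N(0,1) population density by quadrature.
    df = (cells after collapsing, minus one per score group for the fixed
    group totals) - (free item parameters); items whose df falls to zero or
    below are reported untestable, not flagged.
    """
    bank = fitted.bank if isinstance(fitted, EstimationResult) else fitted
    rm.require_complete("item fit")
    x = rm.responses
    n, p = x.shape
    if list(rm.item_ids) != list(bank.item_ids):
        raise ValidationError("response matrix and bank items differ")
    nodes, wq = quadrature()
    u = x - 1                                  # 0-based item scores
    rows = []
    for i in range(p):
        m = int(bank.n_categories[i])
        others = [j for j in range(p) if j != i]
        probs_i = prob_categories(bank.slopes[i], bank.thresholds[i], nodes)
        rest_dist = summed_score_distribution(bank, nodes, others)  # (S+1, q)
        rest = u.sum(axis=1) - u[:, i]
        smax = rest_dist.shape[0] - 1
        obs = np.zeros((smax + 1, m))
        np.add.at(obs, (rest, u[:, i]), 1.0)
        n_s = obs.sum(axis=1)
        denom = rest_dist @ wq                                   # P(S_-i = s)
        num = np.einsum("kq,sq,q->sk", probs_i, rest_dist, wq)   # joint
        keep = n_s > 0
        cond = num[keep] / np.where(denom[keep] > 1e-300,
                                    denom[keep], 1.0)[:, None]
        exp = n_s[keep][:, None] * cond
        obs_r, exp_r, merges = _collapse_rows(list(obs[keep]), list(exp),
                                              row_min=2 * m)
        stat = 0.0
        df = -m                                # m free parameters: a + m-1 b's
        n_cells = 0
        for o_row, e_row in zip(obs_r, exp_r):
            o_c, e_c = _collapse_cells(o_row, e_row)
            stat += float(((o_c - e_c) ** 2 / e_c).sum())
            df += len(e_c) - 1                 # row total fixed
            n_cells += len(e_c)
        if df <= 0:
            rows.append({"item_id": rm.item_ids[i], "s_x2": np.nan,
                         "df": int(df), "p_value": np.nan,
                         "n_collapsed_cells": int(n_cells),
                         "flagged": False, "testable": False})
            continue
        pval = float(chi2.sf(stat, df))
        rows.append({"item_id": rm.item_ids[i], "s_x2": stat, "df": int(df),
                     "p_value": pval, "n_collapsed_cells": int(n_cells),
                     "flagged": bool(pval < alpha), "testable": True})
    return ItemFitResult(pd.DataFrame(rows), alpha)
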