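"""Differential item functioning screening via ordinal logistic regression.

For each item, three nested proportional-odds (cumulative-logit) models are
fitted: M1 regresses the item response on the latent trait only, M2 adds
the group main effect, M3 adds the trait x group interaction.  DIF is
flagged when the total McFadden pseudo-R² change (M3 - M1) reaches 0.02;
the uniform (M2 - M1) and non-uniform (M3 - M2) components classify the
effect.  Optional purification rescores the trait from the unflagged items
and repeats until the flag set stabilises.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .data_io import ItemBank, ResponseMatrix, ValidationError
from . import grm

DIF_THRESHOLD = 0.02
MIN_GROUP_SIZE = 50


@dataclass
class OrdinalFit:
    loglik: float
    alpha: np.ndarray            # ordered intercepts
    beta: np.ndarray
    converged: bool
    ridge_stabilized: bool = False


def _negll_grad(params, y0, X, m, ridge):
    """Negative log-likelihood + gradient of the proportional-odds model.

    Intercepts are parameterised as alpha_1 plus positive log-gaps so they
    stay ordered.  y0 is the 0-based category index.
    """
    n, p = X.shape
    z = params[:m - 1]
    beta = params[m - 1:]
    alpha = np.empty(m - 1)
    alpha[0] = z[0]
    if m > 2:
        alpha[1:] = z[0] + np.cumsum(np.exp(z[1:]))
    xb = X @ beta
    eta = alpha[None, :] - xb[:, None]                 # (n, m-1)
    cum = expit(eta)
    full = np.hstack([np.zeros((n, 1)), cum, np.ones((n, 1))])
    pk = np.clip(full[:, 1:] - full[:, :-1], 1e-12, 1.0)   # P(y = k)
    prob = pk[np.arange(n), y0]
    ll = float(np.log(prob).sum()) - 0.5 * ridge * float(beta @ beta)

    # d log p / d alpha_k: psi_k (delta_{k,y} - delta_{k,y-1}) / p
    psi = cum * (1 - cum)                              # (n, m-1)
    galpha = np.zeros(m - 1)
    coef = np.zeros((n, m - 1))
    ky = y0                                            # alpha index = y0 (upper cut)
    sel_up = ky <= m - 2
    coef[np.arange(n)[sel_up], ky[sel_up]] += psi[np.arange(n)[sel_up], ky[sel_up]]
    kl = y0 - 1                                        # lower cut
    sel_lo = kl >= 0
    coef[np.arange(n)[sel_lo], kl[sel_lo]] -= psi[np.arange(n)[sel_lo], kl[sel_lo]]
    coef /= prob[:, None]
    galpha = coef.sum(axis=0)
    gbeta = -(coef.sum(axis=1) @ X) - ridge * beta

    gz = np.empty(m - 1)
    tails = np.cumsum(galpha[::-1])[::-1]
    gz[0] = tails[0]
    if m > 2:
        gz[1:] = np.exp(z[1:]) * tails[1:]
    grad = np.concatenate([gz, gbeta])
    return -ll, -grad


def null_loglik(y: np.ndarray) -> float:
    """Closed-form intercept-only log-likelihood: sum n_k log(n_k / n)."""
    _, counts = np.unique(y, return_counts=True)
    n = counts.sum()
    return float((counts * np.log(counts / n)).sum())


def cumulative_logit_fit(y, X, ridge: float = 0.0) -> OrdinalFit:
    """Fit a proportional-odds model P(y <= k) = logistic(alpha_k - x beta).

    y: ordinal responses (any integer coding; categories are ranked);
    X: (n, p) predictor matrix.  Quasi-Newton with analytic gradients;
    apparent separation (runaway coefficients) triggers a ridge-stabilised
    refit with a warning.
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValidationError("predictors must be finite")
    cats = np.unique(y)
    if len(cats) < 2:
        raise ValidationError("response needs at least 2 observed categories")
    y0 = np.searchsorted(cats, y)
    m = len(cats)
    n = len(y)

    cum = np.cumsum(np.bincount(y0, minlength=m))[:-1] / n
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    a0 = np.log(cum / (1 - cum))
    z0 = np.empty(m - 1)
    z0[0] = a0[0]
    if m > 2:
        z0[1:] = np.log(np.clip(np.diff(a0), 1e-6, None))
    x0 = np.concatenate([z0, np.zeros(X.shape[1])])

    res = minimize(_negll_grad, x0, args=(y0, X, m, ridge), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    beta = res.x[m - 1:]
    if ridge == 0.0 and np.any(np.abs(beta) > 15):
        warnings.warn("possible separation in ordinal fit; ridge applied")
        fit = cumulative_logit_fit(y, X, ridge=1e-3)
        fit.ridge_stabilized = True
        return fit
    z = res.x[:m - 1]
    alpha = np.empty(m - 1)
    alpha[0] = z[0]
    if m > 2:
        alpha[1:] = z[0] + np.cumsum(np.exp(z[1:]))
    return OrdinalFit(-float(res.fun), alpha, beta, bool(res.success))


def mcfadden_r2(fit: OrdinalFit, ll_null: float) -> float:
    return 1.0 - fit.loglik / ll_null


@dataclass
class DIFResult:
    table: pd.DataFrame
    grouping: str
    threshold: float = DIF_THRESHOLD
    purification_iterations: int = 0

    @property
    def flagged_items(self):
        return self.table.loc[self.table["flagged"], "item_id"].tolist()


def _encode_group(series: pd.Series):
    """Two-level or ordered groups become one ordinal column; unordered
    multi-level groups a reference-vs-each-level dummy block."""
    if isinstance(series.dtype, pd.CategoricalDtype) and series.cat.ordered:
        return series.cat.codes.to_numpy(float)[:, None]
    if pd.api.types.is_numeric_dtype(series):
        return series.to_numpy(float)[:, None]
    levels = sorted(series.astype(str).unique())
    if len(levels) == 2:
        return (series.astype(str) == levels[1]).to_numpy(float)[:, None]
    return np.column_stack([(series.astype(str) == l).astype(float)
                            for l in levels[1:]])


def _screen_once(x, thetas, G, item_ids, items, threshold):
    rows = []
    for i in items:
        y = x[:, i]
        ll0 = null_loglik(y)
        X1 = thetas[:, None]
        X2 = np.hstack([X1, G])
        X3 = np.hstack([X2, thetas[:, None] * G])
        r2 = []
        for X in (X1, X2, X3):
            fit = cumulative_logit_fit(y, X)
            r2.append(mcfadden_r2(fit, ll0))
        r2_m1, r2_m2, r2_m3 = r2
        d_tot = r2_m3 - r2_m1
        d_uni = r2_m2 - r2_m1
        d_non = r2_m3 - r2_m2
        flagged = d_tot >= threshold
        if not flagged:
            cls = "none"
        elif d_uni >= threshold and d_non >= threshold:
            cls = "mixed"
        elif d_non >= threshold:
            cls = "non-uniform"
        else:
            cls = "uniform"
        rows.append({"item_id": item_ids[i], "r2_m1": r2_m1, "r2_m2": r2_m2,
                     "r2_m3": r2_m3, "delta_total": d_tot,
                     "delta_uniform": d_uni, "delta_nonuniform": d_non,
                     "flagged": bool(flagged), "classification": cls})
    return pd.DataFrame(rows)


def dif_screen(rm: ResponseMatrix, thetas, group: str,
               purify: bool = False, bank: ItemBank | None = None,
               threshold: float = DIF_THRESHOLD,
               min_group: int = MIN_GROUP_SIZE, items=None) -> DIFResult:
    """Screen items for DIF with the nested-model pseudo-R² criterion.

    thetas: per-person trait scores (typically EAP from the full bank, which
    stays finite for all-extreme patterns); group: name of a covariate
    column with >= 2 levels of at least ``min_group`` persons each.  With
    purify=True (requires ``bank``), thetas are re-estimated from the
    currently unflagged items until the flag set stabilises (max 10 rounds).
    """
    rm.require_complete("DIF screening")
    if rm.covariates is None or group not in rm.covariates.columns:
        raise ValidationError(f"no covariate column {group!r}")
    series = rm.covariates[group]
    counts = series.astype(str).value_counts()
    if (counts > 0).sum() < 2:
        raise ValidationError(f"group {group!r} has fewer than 2 levels")
    low = counts[counts < min_group]
    if len(low):
        raise ValidationError(
            f"group levels below the size floor {min_group}: "
            f"{dict(low.astype(int))}")
    G = _encode_group(series)
    thetas = np.asarray(thetas, dtype=float)
    x = rm.responses
    item_idx = list(range(rm.n_items)) if items is None else \
        [rm.item_ids.index(it) if not isinstance(it, (int, np.integer)) else it
         for it in items]

    table = _screen_once(x, thetas, G, rm.item_ids, item_idx, threshold)
    iters = 0
    if purify:
        if bank is None:
            raise ValidationError("purification requires the item bank")
        prev = set(table.loc[table.flagged, "item_id"])
        for iters in range(1, 11):
            clean = [i for i in range(rm.n_items)
                     if rm.item_ids[i] not in prev]
            if not clean:
                break
            sub = bank.subset(clean)
            th = np.array([grm.score_theta(row, sub, "EAP").theta
                           for row in x[:, clean]])
            table = _screen_once(x, th, G, rm.item_ids, item_idx, threshold)
            cur = set(table.loc[table.flagged, "item_id"])
            if cur == prev:
                break
            prev = cur
    return DIFResult(table, group, threshold, iters)


def age_median_split(age) -> pd.Series:
    """Dichotomise age at the sample median: levels '<=median' / '>median'."""
    age = pd.Series(age)
    med = float(np.median(age))
    labels = np.where(age <= med, f"<={med:g}", f">{med:g}")
    return pd.Series(pd.Categorical(labels), name="age_split")
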