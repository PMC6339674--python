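"""Unidimensionality and local-independence checks on ordinal items.

Polychoric correlations are estimated in two steps: item thresholds from
inverse-normal cumulative marginals, then each pairwise correlation by
maximising the bivariate-normal likelihood of the contingency table.  A
one-factor model is fitted to the polychoric matrix by diagonally weighted
least squares (weights = reciprocal asymptotic variances of the polychoric
estimates; unweighted fallback), yielding chi-square-based fit indices
(CFI, TLI, RMSEA, SRMR).  Exploratory evidence comes from the eigenvalues
of the polychoric matrix (first-to-second ratio, share of variance), and
local dependence is flagged from large residual correlations.

The chi-square and derived indices are plain (unscaled) DWLS statistics;
no mean-and-variance adjustment is applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import norm

from .data_io import ResponseMatrix, ValidationError

_CLIP = 8.0          # effective +/- infinity for thresholds on the normal scale
_RHO_BOUND = 0.999
_GL_NODES = 32


@dataclass
class PolychoricResult:
    corr: np.ndarray                    # (p, p) symmetric, unit diagonal
    thresholds: list                    # per item, normal-metric cuts
    item_ids: list
    converged: np.ndarray               # (p, p) bool
    avar: np.ndarray                    # (p, p) n * Var(rho_hat), nan if unavailable

    @property
    def n_items(self):
        return self.corr.shape[0]


@dataclass
class FitIndices:
    chi_square: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    eigenvalues: list
    variance_ratio_first_to_second: float
    pct_variance_first: float
    baseline_chi_square: float = np.nan
    baseline_df: int = 0
    degenerate_baseline: bool = False
    heywood: bool = False


@dataclass
class LocalDependenceResult:
    residual_corr: np.ndarray
    flagged_pairs: list                 # [(item_i, item_j, residual)] by |residual| desc
    threshold: float = 0.20


# ---------------------------------------------------------------------------
# polychoric estimation
# ---------------------------------------------------------------------------

def _bvn_cell_probs(tau_x, tau_y, rho):
    """Rectangle probabilities of a standard bivariate normal.

    tau_x, tau_y: interior thresholds (finite); returns matrix of cell
    probabilities for the (len(tau_x)+1) x (len(tau_y)+1) grid.  Integrates
    phi(x) * [Phi((t_hi - rho x)/s) - Phi((t_lo - rho x)/s)] over each x
    interval with Gauss-Legendre quadrature.
    """
    tx = np.concatenate([[-_CLIP], np.clip(tau_x, -_CLIP, _CLIP), [_CLIP]])
    ty = np.concatenate([[-_CLIP], np.clip(tau_y, -_CLIP, _CLIP), [_CLIP]])
    s = np.sqrt(max(1.0 - rho * rho, 1e-12))
    gl_x, gl_w = np.polynomial.legendre.leggauss(_GL_NODES)
    mx, my = len(tx) - 1, len(ty) - 1
    out = np.empty((mx, my))
    for i in range(mx):
        a, b = tx[i], tx[i + 1]
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        x = mid + half * gl_x
        w = half * gl_w * norm.pdf(x)
        cond = norm.cdf((ty[None, :] - rho * x[:, None]) / s)   # (nodes, my+1)
        out[i] = w @ (cond[:, 1:] - cond[:, :-1])
    return np.clip(out, 0.0, 1.0)


def estimate_polychoric(counts: np.ndarray):
    """Two-step polychoric correlation from a contingency table of counts.

    Returns (rho, tau_x, tau_y, converged, avar_scaled) where avar_scaled
    is n * Var(rho_hat) from the observed pairwise information.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    px = counts.sum(axis=1) / n
    py = counts.sum(axis=0) / n
    tau_x = norm.ppf(np.clip(np.cumsum(px)[:-1], 1e-10, 1 - 1e-10))
    tau_y = norm.ppf(np.clip(np.cumsum(py)[:-1], 1e-10, 1 - 1e-10))

    def negll(rho):
        p = np.clip(_bvn_cell_probs(tau_x, tau_y, rho), 1e-12, None)
        return -float((counts * np.log(p)).sum())

    res = minimize_scalar(negll, bounds=(-_RHO_BOUND, _RHO_BOUND),
                          method="bounded", options={"xatol": 1e-5})
    rho = float(res.x)
    at_bound = abs(rho) >= _RHO_BOUND - 1e-4
    if at_bound:
        rho = np.sign(rho) * _RHO_BOUND
    h = 1e-4
    if abs(rho) < _RHO_BOUND - 2 * h:
        d2 = (negll(rho + h) - 2 * negll(rho) + negll(rho - h)) / h ** 2
        avar = n / d2 if d2 > 0 else np.nan
    else:
        avar = np.nan
    return rho, tau_x, tau_y, not at_bound, avar


def polychoric_matrix(rm: ResponseMatrix) -> PolychoricResult:
    """Polychoric correlation matrix of all item pairs (complete cases)."""
    rm.require_complete("polychoric estimation")
    x = rm.responses
    p = rm.n_items
    cats = [np.unique(x[:, i]) for i in range(p)]
    for i, c in enumerate(cats):
        if len(c) < 2:
            raise ValidationError(
                f"item {rm.item_ids[i]} has a single observed category")
    corr = np.eye(p)
    conv = np.ones((p, p), dtype=bool)
    avar = np.full((p, p), np.nan)
    thresholds = [None] * p
    for i in range(p):
        marg = np.array([(x[:, i] == c).mean() for c in cats[i]])
        thresholds[i] = norm.ppf(np.clip(np.cumsum(marg)[:-1], 1e-10, 1 - 1e-10))
    for i in range(p):
        for j in range(i + 1, p):
            tab = np.zeros((len(cats[i]), len(cats[j])))
            xi = np.searchsorted(cats[i], x[:, i])
            xj = np.searchsorted(cats[j], x[:, j])
            np.add.at(tab, (xi, xj), 1.0)
            rho, _, _, ok, av = estimate_polychoric(tab)
            corr[i, j] = corr[j, i] = rho
            conv[i, j] = conv[j, i] = ok
            avar[i, j] = avar[j, i] = av
    return PolychoricResult(corr, thresholds, list(rm.item_ids), conv, avar)


def smooth_psd(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue smoothing: raise negative eigenvalues to ``floor`` and
    rescale back to a unit-diagonal correlation matrix."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= 0:
        return corr
    vals = np.clip(vals, floor, None)
    s = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(s))
    return s / np.outer(d, d)


# ---------------------------------------------------------------------------
# one-factor DWLS fit
# ---------------------------------------------------------------------------

def efa_eigen_ratio(pc: PolychoricResult | np.ndarray):
    """Eigenvalues of the polychoric matrix (descending), the first-to-second
    ratio and the first eigenvalue's share of total variance."""
    corr = pc.corr if isinstance(pc, PolychoricResult) else np.asarray(pc)
    eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
    ratio = eig[0] / eig[1] if len(eig) > 1 else np.inf
    return eig, float(ratio), float(eig[0] / len(eig))


def one_factor_fit(pc: PolychoricResult, n: int):
    """Fit a single-factor model to a polychoric matrix by DWLS.

    Returns (FitIndices, loadings, residual_matrix).  chi^2 = (n-1) * F_min
    with F the weighted least-squares discrepancy over the p(p-1)/2 unique
    correlations; the independence model is the baseline for CFI/TLI.
    """
    corr = smooth_psd(pc.corr if isinstance(pc, PolychoricResult) else pc)
    p = corr.shape[0]
    iu = np.triu_indices(p, k=1)
    r = corr[iu]
    if isinstance(pc, PolychoricResult) and np.isfinite(pc.avar[iu]).all() \
            and np.all(pc.avar[iu] > 0):
        w = 1.0 / pc.avar[iu]
    else:
        w = np.ones_like(r)           # unweighted fallback
    sw = np.sqrt(w)

    eigvals, eigvecs = np.linalg.eigh(corr)
    lam0 = eigvecs[:, -1] * np.sqrt(max(eigvals[-1], 0.0))
    if lam0.sum() < 0:
        lam0 = -lam0
    lam0 = np.clip(lam0, -0.995, 0.995)

    def resid(lam):
        return sw * (r - (np.outer(lam, lam))[iu])

    sol = least_squares(resid, lam0, bounds=(-_RHO_BOUND, _RHO_BOUND),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    lam = sol.x
    heywood = bool(np.any(np.abs(lam) >= _RHO_BOUND - 1e-6))

    f_min = float(np.sum(resid(lam) ** 2))
    f_base = float(np.sum((sw * r) ** 2))
    df_m = p * (p - 1) // 2 - p
    df_b = p * (p - 1) // 2
    chi2_m = (n - 1) * f_min
    chi2_b = (n - 1) * f_base

    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, 0.0)
    degenerate = den <= 0
    cfi = 1.0 if degenerate else float(np.clip(1.0 - num / den, 0.0, 1.0))
    if degenerate or df_m <= 0 or chi2_b <= 0:
        tli = 1.0
    else:
        tli = ((chi2_b / df_b) - (chi2_m / df_m)) / ((chi2_b / df_b) - 1.0)
        tli = float(np.clip(tli, 0.0, 1.0))
    rmsea = (float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * (n - 1))))
             if df_m > 0 else 0.0)

    implied = np.outer(lam, lam)
    np.fill_diagonal(implied, 1.0)
    residual = corr - implied
    np.fill_diagonal(residual, 0.0)
    srmr = float(np.sqrt(np.mean(residual[iu] ** 2)))

    eig, ratio, pct = efa_eigen_ratio(corr)
    fit = FitIndices(chi_square=float(chi2_m), df=df_m, cfi=cfi, tli=tli,
                     rmsea=rmsea, srmr=srmr, eigenvalues=eig.tolist(),
                     variance_ratio_first_to_second=ratio,
                     pct_variance_first=pct,
                     baseline_chi_square=float(chi2_b), baseline_df=df_b,
                     degenerate_baseline=degenerate, heywood=heywood)
    return fit, lam, residual


def local_dependence(residual: np.ndarray, item_ids=None,
                     threshold: float = 0.20) -> LocalDependenceResult:
    """Flag item pairs whose absolute residual correlation exceeds the
    threshold, sorted by magnitude (largest first)."""
    residual = np.asarray(residual)
    p = residual.shape[0]
    ids = item_ids if item_ids is not None else list(range(p))
    pairs = []
    for i in range(p):
        for j in range(i + 1, p):
            if abs(residual[i, j]) > threshold:
                pairs.append((ids[i], ids[j], float(residual[i, j])))
    pairs.sort(key=lambda t: -abs(t[2]))
    return LocalDependenceResult(residual, pairs, threshold)
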