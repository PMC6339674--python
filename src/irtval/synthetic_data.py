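"""GRM-consistent synthetic respondents.

Emulates the statistical structure of a general-population sample answering
a polytomous item bank: theta ~ Normal(0, 1), five-category graded
responses with strong slopes, a ceiling of all-extreme response patterns,
and demographic labels drawn to realistic population proportions.  Optional
differential item functioning (uniform threshold shifts and/or slope
multipliers for a focal group) can be injected for power studies.

Defaults mirror the "ability to participate" bank regime: 35 five-category
items, slopes uniform in [2.4, 4.8], thresholds in [-2.5, 0.6].
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import norm

from .data_io import ItemBank, ResponseMatrix, ValidationError
from . import grm

MIN_THRESHOLD_GAP = 0.05

# demographic label proportions of a Dutch general-population internet panel
DEMOGRAPHIC_PROPORTIONS = {
    "gender": {"male": 0.476, "female": 0.524},
    "age_group": {"18-39": 0.315, "40-65": 0.456, ">65": 0.229},
    "education": {"low": 0.293, "middle": 0.426, "high": 0.280},
    "region": {"north": 0.102, "east": 0.199, "south": 0.201, "west": 0.497},
    "ethnicity": {"native": 0.772, "western_immigrant": 0.126,
                  "non_western_immigrant": 0.101},
}
_AGE_BANDS = {"18-39": (18, 39), "40-65": (40, 65), ">65": (66, 90)}


@dataclass
class BankSpec:
    n_items: int = 35
    n_categories: int = 5
    slope_range: tuple = (2.4, 4.8)
    threshold_range: tuple = (-2.5, 0.6)


@dataclass
class DIFEffect:
    """One injected DIF effect: the focal group's parameters for ``item``
    get all thresholds shifted by ``uniform_shift`` (theta units) and the
    slope multiplied by ``slope_multiplier``."""
    item: str
    group_var: str = "gender"
    focal_level: str = "female"
    uniform_shift: float = 0.0
    slope_multiplier: float = 1.0


@dataclass
class SimulationDesign:
    n_persons: int = 1000
    bank_spec: BankSpec = field(default_factory=BankSpec)
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    dif_spec: list = field(default_factory=list)
    extreme_target: float | None = None
    language_split: float = 0.0       # fraction labelled "english"
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValidationError("n_persons must be >= 1")
        if self.theta_sd <= 0:
            raise ValidationError("theta_sd must be positive")
        if self.extreme_target is not None and not 0 <= self.extreme_target < 1:
            raise ValidationError("extreme_target must be in [0, 1)")


def sample_bank(design: SimulationDesign) -> ItemBank:
    """Draw an item bank from the design's parameter ranges.

    Slopes are uniform in slope_range; each item's m-1 thresholds are sorted
    uniforms over threshold_range, redrawn until adjacent gaps are at least
    0.05 so no category is nearly degenerate.  Deterministic under seed.
    """
    spec = design.bank_spec
    lo_a, hi_a = spec.slope_range
    lo_b, hi_b = spec.threshold_range
    m = spec.n_categories
    if not (0 < lo_a <= hi_a):
        raise ValidationError("slope_range must be within (0, inf) and ordered")
    if lo_b > hi_b:
        raise ValidationError("threshold_range must be ordered")
    if m < 2:
        raise ValidationError("need at least 2 categories")
    if m > 2 and hi_b - lo_b < (m - 2) * MIN_THRESHOLD_GAP:
        raise ValidationError(
            f"threshold_range too narrow for {m - 1} thresholds with gap "
            f"{MIN_THRESHOLD_GAP}")
    rng = np.random.default_rng(design.seed)
    slopes = rng.uniform(lo_a, hi_a, spec.n_items)
    thresholds = []
    for _ in range(spec.n_items):
        for _attempt in range(1000):
            b = np.sort(rng.uniform(lo_b, hi_b, m - 1))
            if m == 2 or np.min(np.diff(b)) >= MIN_THRESHOLD_GAP:
                break
        else:  # extremely narrow range: fall back to an even grid
            b = np.linspace(lo_b, hi_b, m - 1)
        thresholds.append(b)
    ids = [f"item{i + 1:02d}" for i in range(spec.n_items)]
    return ItemBank(ids, slopes, thresholds)


def inject_dif(bank: ItemBank, dif_spec) -> ItemBank:
    """Return the focal group's bank with the DIF effects applied.

    The reference bank is left unchanged; uniform DIF shifts all thresholds
    of the item, non-uniform DIF multiplies the slope.
    """
    focal = bank.copy()
    for eff in dif_spec:
        i = focal.index_of(eff.item)
        focal.thresholds[i] = focal.thresholds[i] + eff.uniform_shift
        focal.slopes[i] = focal.slopes[i] * eff.slope_multiplier
        if focal.slopes[i] <= 0:
            raise ValidationError(f"slope_multiplier makes item {eff.item} "
                                  "slope non-positive")
    return focal


def expected_extreme_fraction(bank: ItemBank, mean: float, sd: float) -> float:
    """Model-implied fraction of all-lowest plus all-highest patterns."""
    nodes = np.linspace(mean - 8 * sd, mean + 8 * sd, 301)
    w = norm.pdf(nodes, mean, sd)
    w /= w.sum()
    log_low = np.zeros_like(nodes)
    log_high = np.zeros_like(nodes)
    for a, b in zip(bank.slopes, bank.thresholds):
        p = grm.prob_categories(a, b, nodes)
        log_low += np.log(np.clip(p[0], 1e-300, None))
        log_high += np.log(np.clip(p[-1], 1e-300, None))
    return float(w @ (np.exp(log_low) + np.exp(log_high)))


def _calibrated_mean(bank, design):
    """Shift the theta mean until the expected all-extreme fraction matches
    the target (within well under 0.005).

    The fraction is U-shaped in the mean (all-lowest patterns dominate far
    left, all-highest far right); the shift is resolved on the increasing
    right branch, emulating a ceiling effect."""
    target = design.extreme_target

    def f(mu):
        return expected_extreme_fraction(bank, mu, design.theta_sd) - target

    opt = minimize_scalar(f, bounds=(-4.0, 4.0), method="bounded")
    mu_min = float(opt.x)
    if f(mu_min) > 0:
        raise ValidationError(
            "extreme_target below the minimum all-extreme fraction "
            "attainable by a mean shift")
    if f(4.0) < 0:
        raise ValidationError("extreme_target unreachable by a mean shift "
                              "within [-4, 4]")
    return brentq(f, mu_min, 4.0, xtol=1e-6)


def _draw_covariates(n, rng, language_split=0.0):
    cov = {}
    for name, props in DEMOGRAPHIC_PROPORTIONS.items():
        levels = list(props)
        p = np.array([props[l] for l in levels], dtype=float)
        cov[name] = rng.choice(levels, size=n, p=p / p.sum())
    band_lo = np.array([_AGE_BANDS[g][0] for g in cov["age_group"]])
    band_hi = np.array([_AGE_BANDS[g][1] for g in cov["age_group"]])
    cov["age"] = rng.integers(band_lo, band_hi + 1)
    cov["language"] = np.where(rng.random(n) < language_split,
                               "english", "dutch")
    df = pd.DataFrame(cov)
    df["education"] = pd.Categorical(df["education"],
                                     categories=["low", "middle", "high"],
                                     ordered=True)
    return df


def simulate_responses(bank: ItemBank, design: SimulationDesign,
                       rng: np.random.Generator | None = None):
    """Simulate a respondent sample; returns (ResponseMatrix, true_thetas).

    Thetas are Normal(theta_mean, theta_sd^2); when ``extreme_target`` is
    set, the mean is shifted so the model-implied fraction of all-extreme
    patterns matches it (ceiling-effect emulation that leaves the bank
    parameters untouched).  Categories are drawn from the graded-model
    probabilities; with a dif_spec, members of the focal group respond under
    the DIF-shifted bank.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed + 1)
    n = design.n_persons
    mean = (design.theta_mean if design.extreme_target is None
            else _calibrated_mean(bank, design))
    theta = rng.normal(mean, design.theta_sd, n)
    cov = _draw_covariates(n, rng, design.language_split)

    focal_bank = inject_dif(bank, design.dif_spec) if design.dif_spec else bank
    # membership is per effect; responses for an item use the focal params
    # only for persons in that effect's focal level
    item_focal = {}
    for eff in design.dif_spec:
        i = bank.index_of(eff.item)
        mask = (cov[eff.group_var].astype(str) == eff.focal_level).to_numpy()
        item_focal[i] = mask

    resp = np.empty((n, bank.n_items), dtype=int)
    for i in range(bank.n_items):
        u = rng.random(n)
        pstar_ref = grm.cumulative_probs(bank.slopes[i], bank.thresholds[i],
                                         theta)          # (m-1, n)
        x = 1 + (u[None, :] < pstar_ref).sum(axis=0)
        if i in item_focal:
            mask = item_focal[i]
            pstar_f = grm.cumulative_probs(focal_bank.slopes[i],
                                           focal_bank.thresholds[i],
                                           theta[mask])
            x[mask] = 1 + (u[mask][None, :] < pstar_f).sum(axis=0)
        resp[:, i] = x

    pids = [f"p{j + 1:05d}" for j in range(n)]
    rm = ResponseMatrix(resp, pids, list(bank.item_ids), cov)
    return rm, theta


def simulate_dataset(design: SimulationDesign):
    """Convenience: sample a bank, then respondents from it.

    Returns (ResponseMatrix, ItemBank, true_thetas)."""
    bank = sample_bank(design)
    rm, theta = simulate_responses(bank, design)
    return rm, bank, theta


def all_extreme_mask(rm: ResponseMatrix, bank: ItemBank) -> np.ndarray:
    """Persons whose every response is the lowest or every response the
    highest category (the patterns ML scoring clamps to -4 / +4)."""
    m = bank.n_categories[None, :]
    return (np.all(rm.responses == 1, axis=1)
            | np.all(rm.responses == m, axis=1))
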