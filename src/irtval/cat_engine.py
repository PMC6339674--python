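"""Post-hoc computerized adaptive testing (CAT) simulation.

Each simulated CAT replays a person's recorded full-bank response vector:
items are administered one at a time, always the unadministered item with
maximum Fisher information at the current trait estimate (the first item
maximises information at the population average, theta = 0).  After each
response the trait is re-estimated (ML by default, clamped to [-4, 4] while
the interim pattern is all-extreme) and the standard error is recomputed
from the administered items' information.  The standard stopping rule halts
once the SE on the T-score metric drops to ``se_stop`` (default 3, i.e.
SE(theta) <= 0.3, reliability just above 0.90) or ``max_items`` (default
12) have been given; a fixed-length mode administers exactly
``fixed_length`` items instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ItemBank, ResponseMatrix, ValidationError, MISSING
from . import grm


@dataclass
class CATConfig:
    se_stop: float = 3.0          # T-score metric; theta-metric SE * 10
    max_items: int = 12
    min_items: int = 0
    fixed_length: int | None = None
    estimator: str = "ML"
    theta_bounds: tuple = grm.THETA_BOUNDS
    start_theta: float = 0.0

    def __post_init__(self):
        if not 0 <= self.min_items <= self.max_items:
            raise ValidationError("need 0 <= min_items <= max_items")
        if self.se_stop <= 0:
            raise ValidationError("se_stop must be positive")


@dataclass
class CATTrace:
    person_id: object
    administered: list
    interim_thetas: list
    interim_ses: list
    final: grm.ThetaEstimate
    stop_reason: str

    @property
    def n_items(self) -> int:
        return len(self.administered)


def select_start_item(bank: ItemBank, start_theta: float = 0.0) -> int:
    """Index of the item with maximum information at the starting trait
    level; ties break to the lowest index."""
    if bank.n_items == 0:
        raise ValidationError("empty bank")
    return int(np.argmax(grm.bank_information(bank, start_theta)))


def _interim_estimate(resp, bank, admin, config):
    lo, hi = config.theta_bounds
    sub = resp[admin]
    cats = bank.n_categories[admin]
    if np.all(sub == 1):
        info = grm.test_information(bank, lo, admin)
        se = 1.0 / np.sqrt(info) if info > 0 else np.inf
        return grm.ThetaEstimate(lo, se, config.estimator, clamped=True,
                                 n_items_used=len(admin))
    if np.all(sub == cats):
        info = grm.test_information(bank, hi, admin)
        se = 1.0 / np.sqrt(info) if info > 0 else np.inf
        return grm.ThetaEstimate(hi, se, config.estimator, clamped=True,
                                 n_items_used=len(admin))
    full = np.zeros(bank.n_items, dtype=int)
    full[admin] = sub
    return grm.score_theta(full, bank, config.estimator)


def run_cat(responses, bank: ItemBank, config: CATConfig | None = None,
            person_id=None) -> CATTrace:
    """Replay one person's responses through the adaptive algorithm.

    ``responses`` must contain the person's recorded answer to every bank
    item (post-hoc replay); a missing response to a selected item is an
    error.
    """
    config = config or CATConfig()
    resp = np.asarray(responses, dtype=int)
    if resp.shape != (bank.n_items,):
        raise ValidationError("responses must cover every bank item")
    admin: list[int] = []
    remaining = set(range(bank.n_items))
    thetas, ses = [], []
    theta = config.start_theta
    est = None
    stop_reason = None
    while True:
        if not admin:
            item = select_start_item(bank, config.start_theta)
        else:
            cand = sorted(remaining)
            info = grm.bank_information(bank, theta, cand)
            item = cand[int(np.argmax(info))]
        if resp[item] == MISSING or resp[item] < 1:
            raise ValidationError(
                f"person {person_id!r} has no recorded response to item "
                f"{bank.item_ids[item]}; replay requires completeness")
        admin.append(item)
        remaining.discard(item)
        est = _interim_estimate(resp, bank, admin, config)
        theta = est.theta
        thetas.append(est.theta)
        ses.append(est.se)
        n = len(admin)
        if config.fixed_length is not None:
            if n >= config.fixed_length:
                stop_reason = "fixed_length"
                break
        else:
            if est.se * 10.0 <= config.se_stop and n >= config.min_items:
                stop_reason = "se_met"
                break
            if n >= config.max_items:
                stop_reason = "max_items"
                break
        if not remaining:
            stop_reason = "bank_exhausted"
            break
    return CATTrace(person_id, admin, thetas, ses, est, stop_reason)


@dataclass
class CohortSummary:
    n_persons: int
    frac_reliable: float          # final reliability >= 0.90, all persons
    frac_reliable_unclamped: float
    n_clamped: int
    mean_items: float
    min_items: int
    max_items: int
    items_distribution: dict = field(default_factory=dict)
    stop_reasons: dict = field(default_factory=dict)

    def to_dict(self):
        return {k: getattr(self, k) for k in
                ("n_persons", "frac_reliable", "frac_reliable_unclamped",
                 "n_clamped", "mean_items", "min_items", "max_items",
                 "items_distribution", "stop_reasons")}


RELIABILITY_TARGET = 0.90


def simulate_cat_cohort(rm: ResponseMatrix, bank: ItemBank,
                        config: CATConfig | None = None):
    """Run the CAT replay for every person; returns (traces, CohortSummary).

    Persons whose final trait estimate is clamped at a boundary (all-extreme
    patterns) are counted separately, mirroring reporting practice that
    excludes them from precision plots.
    """
    config = config or CATConfig()
    rm.require_complete("CAT simulation")
    traces = [run_cat(row, bank, config, pid)
              for row, pid in zip(rm.responses, rm.person_ids)]
    rel = np.array([t.final.reliability for t in traces])
    clamped = np.array([t.final.clamped for t in traces])
    n_items = np.array([t.n_items for t in traces])
    reliable = rel >= RELIABILITY_TARGET
    dist = {int(k): int(v) for k, v in
            zip(*np.unique(n_items, return_counts=True))}
    reasons = {}
    for t in traces:
        reasons[t.stop_reason] = reasons.get(t.stop_reason, 0) + 1
    summary = CohortSummary(
        n_persons=len(traces),
        frac_reliable=float(reliable.mean()),
        frac_reliable_unclamped=float(reliable[~clamped].mean())
        if (~clamped).any() else float("nan"),
        n_clamped=int(clamped.sum()),
        mean_items=float(n_items.mean()),
        min_items=int(n_items.min()),
        max_items=int(n_items.max()),
        items_distribution=dist,
        stop_reasons=reasons,
    )
    return traces, summary


def score_fixed_form(rm: ResponseMatrix, bank: ItemBank, items,
                     estimator: str = "ML"):
    """Non-adaptive scoring of a fixed item subset (a short form).

    Returns (estimates, summary dict) with the same reliability criterion
    as the CAT summaries."""
    idx = [bank.index_of(it) if not isinstance(it, (int, np.integer)) else it
           for it in items]
    sub = bank.subset(idx)
    ests = [grm.score_theta(row, sub, estimator)
            for row in rm.responses[:, idx]]
    rel = np.array([e.reliability for e in ests])
    clamped = np.array([e.clamped for e in ests])
    summary = {"n_persons": len(ests), "n_items": len(idx),
               "frac_reliable": float((rel >= RELIABILITY_TARGET).mean()),
               "n_clamped": int(clamped.sum())}
    return ests, summary


def se_curve(bank: ItemBank, item_sets: dict, theta_grid=None) -> pd.DataFrame:
    """SE versus T-score for named item sets (full bank, short form, ...).

    The data behind a precision plot: for each theta on the grid, the SE
    implied by the test information of each item set."""
    if theta_grid is None:
        theta_grid = np.linspace(-4, 4, 81)
    rows = []
    for name, items in item_sets.items():
        idx = [bank.index_of(it) if not isinstance(it, (int, np.integer))
               else it for it in items]
        for t in theta_grid:
            info = grm.test_information(bank, t, idx)
            rows.append({"set": name, "theta": float(t),
                         "t_score": 10 * float(t) + 50,
                         "se_theta": 1 / np.sqrt(info) if info > 0 else np.inf})
    return pd.DataFrame(rows)
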