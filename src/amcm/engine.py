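"""Incentive-bidding strategies.

Two policies attach a dollar bid to each triggered mission:

* **fixed** -- always the same deduction (the study's control arm used
  $0.30), never consulting history;
* **adaptive** -- before every bid, refit the logistic behavior model on
  the most recent 7 days of bid/outcome observations, invert it at the
  target compliance probability ybar (default 0.5), and snap the estimate
  onto the feasible bid grid ($0.30 to $3.00 in $0.30 steps).

The adaptive policy degrades gracefully when the window cannot support an
invertible fit.  With too little history, with an all-success window, or
when the fitted incentive coefficient is non-positive (an
incentive-insensitive model that cannot be inverted), it bids the grid
minimum -- the cheapest, most conservative choice under loss framing.  An
all-failure window instead escalates: every bid seen recently has failed,
so the next bid goes one grid step above the largest of them.  This is the
mechanism's stated behavior under consecutive rejections and is what lets
the engine climb away from a floor that a hard-to-motivate user simply
ignores; a logistic fit on a single-class window could never do this (its
incentive coefficient is not identified, so inversion is unavailable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .behavior import (
    ObservationWindow,
    TargetProbability,
    estimate_incentive,
    fit_behavior_model,
)
from .tracker import MissionRecord

__all__ = [
    "BidGrid",
    "EngineConfig",
    "discretize_bid",
    "next_bid",
    "estimate_raw_bid",
    "run_bidding_loop",
    "load_config",
]


@dataclass(frozen=True)
class BidGrid:
    """The feasible bid magnitudes: an arithmetic grid of dollar values."""

    minimum: float = 0.30
    maximum: float = 3.00
    step: float = 0.30

    def __post_init__(self) -> None:
        if self.minimum <= 0:
            raise ValueError("grid minimum must be > 0")
        if self.step <= 0:
            raise ValueError("grid step must be > 0")
        n = (self.maximum - self.minimum) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(maximum - minimum) must be an integer multiple of step")

    @property
    def values(self) -> tuple[float, ...]:
        n = int(round((self.maximum - self.minimum) / self.step))
        return tuple(round(self.minimum + i * self.step, 10) for i in range(n + 1))

    def __contains__(self, value: float) -> bool:
        return any(abs(value - v) < 1e-9 for v in self.values)


def discretize_bid(raw: float, grid: BidGrid = BidGrid()) -> float:
    """Snap a raw dollar estimate onto the nearest grid value.

    Estimates below the minimum (including negative ones) clamp to the
    minimum, above the maximum to the maximum.  Exact midpoints round up,
    toward the stronger reinforcer.
    """
    if raw <= grid.minimum:
        return grid.minimum
    if raw >= grid.maximum:
        return grid.maximum
    # half-up in units of the grid step
    idx = math.floor((raw - grid.minimum) / grid.step + 0.5)
    return round(grid.minimum + idx * grid.step, 10)


@dataclass(frozen=True)
class EngineConfig:
    """Everything a bidding policy needs to know."""

    strategy: str = "adaptive"  # "fixed" | "adaptive"
    fixed_bid: float = 0.30
    grid: BidGrid = field(default_factory=BidGrid)
    ybar: TargetProbability = field(default_factory=TargetProbability)
    window_days: int = 7
    min_observations: int = 5
    ridge: float = 1e-3

    def __post_init__(self) -> None:
        if self.strategy not in ("fixed", "adaptive"):
            raise ValueError(f"unknown strategy: {self.strategy!r}")
        if self.fixed_bid not in self.grid:
            raise ValueError(f"fixed_bid {self.fixed_bid} is not on the grid")
        if self.min_observations < 1:
            raise ValueError("min_observations must be >= 1")


def load_config(path) -> EngineConfig:
    """Load an EngineConfig from a flat YAML key-value file."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    grid = BidGrid(
        minimum=float(doc.get("grid_minimum", 0.30)),
        maximum=float(doc.get("grid_maximum", 3.00)),
        step=float(doc.get("grid_step", 0.30)),
    )
    return EngineConfig(
        strategy=doc.get("strategy", "adaptive"),
        fixed_bid=float(doc.get("fixed_bid", 0.30)),
        grid=grid,
        ybar=TargetProbability(float(doc.get("ybar", 0.5))),
        window_days=int(doc.get("window_days", 7)),
        min_observations=int(doc.get("min_observations", 5)),
        ridge=float(doc.get("ridge", 1e-3)),
    )


def _recency_window(
    config: EngineConfig, history: Sequence[MissionRecord], now: datetime
) -> ObservationWindow:
    return ObservationWindow.from_history(
        history, as_of=now, horizon_days=config.window_days
    )


def _usable_window(
    config: EngineConfig, history: Sequence[MissionRecord], now: datetime
) -> Optional[ObservationWindow]:
    """The 7-day window ending at `now`, or None if it cannot support a fit."""
    window = _recency_window(config, history, now)
    if len(window) < config.min_observations:
        return None
    outcomes = {r.success for r in window.records}
    if outcomes != {True, False}:
        return None
    return window


def estimate_raw_bid(
    config: EngineConfig,
    history: Sequence[MissionRecord],
    context: str,
    now: datetime,
) -> Optional[float]:
    """The adaptive policy's pre-discretization estimate, or None on fallback.

    Exposed separately so the qualitative mechanism (failures raise the
    next estimate, successes lower it) can be examined without the grid
    masking small movements.
    """
    window = _usable_window(config, history, now)
    if window is None:
        return None
    model = fit_behavior_model(window, ridge=config.ridge)
    if model.beta0 <= 0:
        return None
    return estimate_incentive(model, context, config.ybar)


def next_bid(
    config: EngineConfig,
    history: Sequence[MissionRecord],
    context: str,
    now: datetime,
) -> float:
    """The dollar bid to attach to the mission about to trigger.

    Fixed strategy: always ``fixed_bid`` (history is never consulted).
    Adaptive strategy: refit on the recency window, invert at ybar,
    discretize onto the grid.  Fallbacks when the fit is unavailable: the
    grid minimum on cold start, on an all-success window, or on a
    non-positive fitted incentive coefficient; one grid step above the
    window's largest bid (clamped at the maximum) on an all-failure window
    of at least ``min_observations`` records -- consecutive rejections
    escalate the deduction.
    """
    if config.strategy == "fixed":
        return config.fixed_bid
    window = _recency_window(config, history, now)
    if len(window) >= config.min_observations:
        outcomes = {r.success for r in window.records}
        if outcomes == {False}:
            top = max(r.bid for r in window.records)
            return min(
                config.grid.maximum,
                discretize_bid(top + config.grid.step, config.grid),
            )
    raw = estimate_raw_bid(config, history, context, now)
    if raw is None:
        return config.grid.minimum
    return discretize_bid(raw, config.grid)


def run_bidding_loop(
    config: EngineConfig,
    responder,
    n_missions: int,
    seed: int | np.random.Generator,
    missions_per_day: int = 9,
    start: datetime = datetime(2020, 4, 20, 9, 50),
) -> list[MissionRecord]:
    """Closed-loop simulation of sequential bidding against one responder.

    Missions are paced hourly within 9-hour days (the cadence a fully
    sedentary participant would produce).  Before each mission the engine
    computes its bid from the accumulated history; the responder profile
    then draws the compliance outcome.  Fully reproducible given the seed.
    """
    from .simulator import decide_compliance  # deferred to avoid import cycle

    if n_missions < 1:
        raise ValueError("n_missions must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cells = responder.location_cells_geohashed()
    weights = np.asarray(responder.location_weights, dtype=float)
    weights = weights / weights.sum()

    records: list[MissionRecord] = []
    for i in range(n_missions):
        day, slot = divmod(i, missions_per_day)
        now = start + timedelta(days=day, minutes=60 * slot)
        context = cells[int(rng.choice(len(cells), p=weights))]
        bid = next_bid(config, records, context, now)
        success = decide_compliance(responder, bid, context, rng)
        records.append(
            MissionRecord(
                participant="sim",
                triggered_at=now,
                geohash=context,
                bid=bid,
                success=success,
            )
        )
    return records
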