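"""Client-side sedentary tracking, mission delivery, and the budget ledger.

This module reproduces the StandUp client logic at minute resolution:

* every minute is classified from its step count (<10 stationary, >45
  moving, 10-45 a transition that is deliberately left ambiguous);
* 50 uninterrupted stationary minutes trigger an active-break mission,
  provided the current time lies inside the participant's 9-hour mission
  window and fewer than 10 missions were delivered that day;
* a scheduled-but-untriggered prompt is canceled by ANY minute with >= 10
  steps -- the cancellation threshold is looser than the "moving" class on
  purpose, so even ambiguous movement resets the countdown;
* an active mission succeeds on the first minute with >45 steps within 10
  minutes; otherwise it fails, the bid is deducted from the daily budget,
  and the next prompt is rescheduled 50 minutes after expiry;
* the budget is loss-framed: the participant starts each day with the full
  budget ($1.50, shown as 100 points) and only ever loses from it.

Deductions clamp at the remaining balance; missions keep being delivered
after the budget is exhausted (the displayed bid simply cannot be
collected), because stopping prompts would let a broke participant sit
unchallenged for the rest of the day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Callable, Optional

from .geo import UNKNOWN_CONTEXT, encode_geohash

__all__ = [
    "STATIONARY",
    "MOVING",
    "TRANSITION",
    "MinuteSample",
    "MissionRecord",
    "BudgetLedger",
    "TrackerEvent",
    "Tracker",
    "StreamError",
    "classify_minute",
    "apply_deduction",
    "reset_daily",
    "DAILY_BUDGET_DOLLARS",
    "POINTS_PER_BUDGET",
    "MISSION_WINDOW_MINUTES",
    "PROMPT_DELAY_MINUTES",
    "MISSION_DURATION_MINUTES",
    "MAX_MISSIONS_PER_DAY",
]

STATIONARY = "stationary"
MOVING = "moving"
TRANSITION = "transition"

DAILY_BUDGET_DOLLARS = 1.50
POINTS_PER_BUDGET = 100  # $1.50 is displayed as 100 points
MISSION_WINDOW_MINUTES = 9 * 60
PROMPT_DELAY_MINUTES = 50
MISSION_DURATION_MINUTES = 10
CANCEL_STEP_THRESHOLD = 10  # >= 10 steps cancels an untriggered prompt
MAX_MISSIONS_PER_DAY = 10


class StreamError(ValueError):
    """Raised when minute samples are not contiguous."""


def classify_minute(steps: int) -> str:
    """Classify one minute of step counts into a mobility state.

    <10 steps is stationary, >45 is moving, and 10-45 inclusive is a
    transition between the two, left unclassified on purpose.
    """
    if steps < 0:
        raise ValueError(f"steps must be >= 0, got {steps}")
    if steps < 10:
        return STATIONARY
    if steps > 45:
        return MOVING
    return TRANSITION


@dataclass(frozen=True)
class MinuteSample:
    """One minute of sensed data: step count and (optionally) location."""

    timestamp: datetime
    steps: int
    location: Optional[tuple[float, float]] = None  # (lat, lon) degrees

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")


@dataclass(frozen=True)
class MissionRecord:
    """One completed active-break mission: the unit of the mission log."""

    participant: str
    triggered_at: datetime
    geohash: str
    bid: float
    success: bool


@dataclass
class BudgetLedger:
    """Daily loss-framed budget: a fixed morning allowance minus deductions."""

    daily_budget: float = DAILY_BUDGET_DOLLARS
    balance: float = None  # type: ignore[assignment]
    current_day: Optional[date] = None
    deductions: list[tuple[datetime, float]] = field(default_factory=list)
    archive: dict[date, list[tuple[datetime, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.balance is None:
            self.balance = self.daily_budget

    @property
    def points(self) -> float:
        """Balance expressed on the in-app point scale (full budget = 100)."""
        return self.balance / self.daily_budget * POINTS_PER_BUDGET

    @property
    def total_deducted(self) -> float:
        return sum(a for _, a in self.deductions)


def apply_deduction(
    ledger: BudgetLedger, amount: float, when: Optional[datetime] = None
) -> float:
    """Deduct ``amount`` from the ledger, clamped at the remaining balance.

    Returns the amount actually deducted.  The balance never goes negative:
    once the budget is exhausted there is nothing left to lose.
    """
    if amount < 0:
        raise ValueError(f"deduction must be >= 0, got {amount}")
    applied = min(amount, ledger.balance)
    ledger.balance -= applied
    ledger.deductions.append((when, applied))
    return applied


def reset_daily(ledger: BudgetLedger, day: date) -> BudgetLedger:
    """Start a new day: restore the full budget, archive yesterday's deductions."""
    if ledger.current_day is not None and day <= ledger.current_day:
        raise ValueError(
            f"reset day {day} is not after current day {ledger.current_day}"
        )
    if ledger.current_day is not None:
        ledger.archive[ledger.current_day] = list(ledger.deductions)
    ledger.deductions = []
    ledger.balance = ledger.daily_budget
    ledger.current_day = day
    return ledger


@dataclass(frozen=True)
class TrackerEvent:
    """Something the tracker did at a given minute."""

    kind: str  # prompt_scheduled | prompt_canceled | mission_triggered |
    #            mission_succeeded | mission_failed
    timestamp: datetime
    bid: Optional[float] = None
    geohash: Optional[str] = None
    deducted: Optional[float] = None


@dataclass
class _ActiveMission:
    started_at: datetime
    bid: float
    geohash: str
    forced_outcome: Optional[bool] = None  # simulator-decided outcome, if any


class Tracker:
    """Mobility state machine + prompt/mission bookkeeping for one participant.

    Feed minute samples in order through :meth:`advance`; the tracker emits
    events and appends completed missions to :attr:`records`.  Invariants
    maintained: an active mission and a scheduled prompt are never both
    present, and a scheduled prompt always sits exactly 50 minutes after
    the stationary onset that armed it.

    Parameters
    ----------
    participant
        Identifier stamped onto mission records.
    window_start
        Start of the 9-hour mission window for the current day (the study
        let each participant pick this between 9:00 and 11:59).
    ledger
        The participant's budget ledger; failures deduct from it.
    geohash_precision
        Cell size of the location context (7 characters ~ 150 m).
    """

    def __init__(
        self,
        participant: str,
        window_start: datetime,
        ledger: Optional[BudgetLedger] = None,
        window_minutes: int = MISSION_WINDOW_MINUTES,
        max_missions_per_day: int = MAX_MISSIONS_PER_DAY,
        geohash_precision: int = 7,
    ) -> None:
        self.participant = participant
        self.window_start = window_start
        self.window_minutes = window_minutes
        self.max_missions_per_day = max_missions_per_day
        self.geohash_precision = geohash_precision
        self.ledger = ledger if ledger is not None else BudgetLedger()
        if self.ledger.current_day is None:
            self.ledger.current_day = window_start.date()
        # mutable state
        self.mobility: Optional[str] = None
        self.stationary_since: Optional[datetime] = None
        self.stationary_geohash: Optional[str] = None
        self.scheduled_prompt_at: Optional[datetime] = None
        self.active_mission: Optional[_ActiveMission] = None
        self.last_location: Optional[tuple[float, float]] = None
        self.last_timestamp: Optional[datetime] = None
        self.missions_today = 0
        self.records: list[MissionRecord] = []

    # -- helpers ----------------------------------------------------------

    def in_window(self, t: datetime) -> bool:
        return (
            self.window_start
            <= t
            < self.window_start + timedelta(minutes=self.window_minutes)
        )

    def _context_code(self) -> str:
        if self.last_location is None:
            return UNKNOWN_CONTEXT
        lat, lon = self.last_location
        return encode_geohash(lat, lon, self.geohash_precision)

    def _close_mission(self, success: bool, when: datetime) -> TrackerEvent:
        m = self.active_mission
        assert m is not None
        self.active_mission = None
        self.records.append(
            MissionRecord(
                participant=self.participant,
                triggered_at=m.started_at,
                geohash=m.geohash,
                bid=m.bid,
                success=success,
            )
        )
        if success:
            # back to neutral: the next stationary minute restarts the countdown
            self.stationary_since = None
            self.stationary_geohash = None
            return TrackerEvent("mission_succeeded", when, bid=m.bid, geohash=m.geohash)
        applied = apply_deduction(self.ledger, m.bid, when)
        # reschedule: the 50-minute countdown restarts at mission expiry and
        # is subject to the usual >=10-step cancellation
        self.stationary_since = when
        self.stationary_geohash = m.geohash
        self.scheduled_prompt_at = when + timedelta(minutes=PROMPT_DELAY_MINUTES)
        return TrackerEvent(
            "mission_failed", when, bid=m.bid, geohash=m.geohash, deducted=applied
        )

    # -- main transition --------------------------------------------------

    def advance(
        self,
        sample: MinuteSample,
        bid_provider: Callable[[str], float],
        compliance_oracle: Optional[Callable[[str, float], bool]] = None,
    ) -> list[TrackerEvent]:
        """Consume one minute sample and return the events it produced.

        ``bid_provider`` maps the stationary-onset geohash to the dollar
        bid attached to a triggered mission.  ``compliance_oracle``, when
        given, decides each mission's outcome at trigger time (used by the
        trial simulator to model the user's bid-dependent response); when
        absent, adjudication is purely step-based.
        """
        t = sample.timestamp
        if self.last_timestamp is not None and t - self.last_timestamp != timedelta(
            minutes=1
        ):
            raise StreamError(
                f"non-contiguous stream: {self.last_timestamp} -> {t}"
            )
        self.last_timestamp = t
        if sample.location is not None:
            self.last_location = sample.location
        self.mobility = classify_minute(sample.steps)

        events: list[TrackerEvent] = []

        # 1) adjudicate an active mission
        if self.active_mission is not None:
            m = self.active_mission
            expired = t - m.started_at >= timedelta(minutes=MISSION_DURATION_MINUTES)
            if m.forced_outcome is True:
                if t > m.started_at:  # the user responds at the next minute
                    events.append(self._close_mission(True, t))
            elif m.forced_outcome is False:
                if expired:
                    events.append(self._close_mission(False, t))
            else:
                if sample.steps > 45:
                    events.append(self._close_mission(True, t))
                elif expired:
                    events.append(self._close_mission(False, t))

        # 2) prompt scheduling / cancellation / triggering
        if self.active_mission is None:
            if sample.steps >= CANCEL_STEP_THRESHOLD:
                if self.scheduled_prompt_at is not None:
                    self.scheduled_prompt_at = None
                    events.append(TrackerEvent("prompt_canceled", t))
                self.stationary_since = None
                self.stationary_geohash = None
            else:
                if self.stationary_since is None:
                    self.stationary_since = t
                    self.stationary_geohash = self._context_code()
                if self.scheduled_prompt_at is None:
                    self.scheduled_prompt_at = self.stationary_since + timedelta(
                        minutes=PROMPT_DELAY_MINUTES
                    )
                    events.append(
                        TrackerEvent(
                            "prompt_scheduled",
                            t,
                            geohash=self.stationary_geohash,
                        )
                    )
                if (
                    t >= self.scheduled_prompt_at
                    and self.in_window(t)
                    and self.missions_today < self.max_missions_per_day
                ):
                    context = self.stationary_geohash or UNKNOWN_CONTEXT
                    bid = float(bid_provider(context))
                    forced = (
                        compliance_oracle(context, bid)
                        if compliance_oracle is not None
                        else None
                    )
                    self.scheduled_prompt_at = None
                    self.active_mission = _ActiveMission(
                        started_at=t, bid=bid, geohash=context, forced_outcome=forced
                    )
                    self.missions_today += 1
                    events.append(
                        TrackerEvent("mission_triggered", t, bid=bid, geohash=context)
                    )

        return events
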