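"""The hypothesized user-behavior model and incentive estimation.

The central modeling assumption of adaptive microcontingency management is
that a user's probability of complying with a behavioral mission is
monotone non-decreasing in the offered incentive, all else equal.  The
working model is a logistic regression of mission success on the incentive
magnitude r (dollars) and a one-hot encoded location context c:

    P(comply | r, c) = logistic(beta0 * r + beta_c + eps)

where ``beta0`` is the per-dollar incentive coefficient, ``beta_c`` the
coefficient of the active context cell, and ``eps`` the intercept.  Under
the monotonicity assumption beta0 > 0, the model inverts in closed form to
give the incentive expected to elicit compliance with a chosen target
probability ybar:

    r(ybar, c) = (logit(ybar) - eps - beta_c) / beta0

The model is refit after every observed bid/outcome on a sliding recency
window (default: the most recent 7 days), so the next bid always reflects
the user's latest responses.

Fitting maximizes an L2-penalized likelihood.  The small ridge (default
1e-3) on the slope coefficients -- never on the intercept -- keeps the fit
finite under perfect separation, which is common on the tiny windows this
engine sees in deployment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "BehaviorModel",
    "TargetProbability",
    "ObservationWindow",
    "IncentiveInsensitiveError",
    "InsufficientDataError",
    "predict_probability",
    "estimate_incentive",
    "fit_behavior_model",
]


class IncentiveInsensitiveError(ValueError):
    """Raised when inversion is requested on a model with beta0 <= 0.

    Such a model says larger deductions do not make compliance more likely,
    contradicting the monotonicity assumption; callers must fall back to a
    default bid instead of inverting.
    """


class InsufficientDataError(ValueError):
    """Raised when a fit is requested on an empty observation window."""


@dataclass(frozen=True)
class BehaviorModel:
    """A fitted logistic description of compliance vs incentive and context.

    Attributes
    ----------
    beta0
        Coefficient of incentive magnitude, per dollar.
    context_coefs
        Map from context label (geohash string) to its coefficient.  A
        context absent from the map contributes 0: one-hot factoring over a
        finite window cannot produce coefficients for unvisited cells.
    intercept
        The intercept term.
    """

    beta0: float
    context_coefs: Mapping[str, float] = field(default_factory=dict)
    intercept: float = 0.0

    def linear_predictor(self, incentive: float, context: str | None = None) -> float:
        coef = self.context_coefs.get(context, 0.0) if context is not None else 0.0
        return self.beta0 * incentive + coef + self.intercept

    def to_dict(self) -> dict:
        """Flat JSON-style document for logging and inspection."""
        return {
            "beta0": float(self.beta0),
            "intercept": float(self.intercept),
            "context_coefs": {k: float(v) for k, v in self.context_coefs.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "BehaviorModel":
        return cls(
            beta0=float(doc["beta0"]),
            context_coefs=dict(doc.get("context_coefs", {})),
            intercept=float(doc.get("intercept", 0.0)),
        )


@dataclass(frozen=True)
class TargetProbability:
    """The compliance probability the engine aims for when picking a bid.

    ybar close to 0.5 keeps adherence deliberately uncertain, which both
    limits cost and lets the engine explore the smaller magnitudes that may
    already be sufficient.
    """

    ybar: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.ybar < 1.0:
            raise ValueError(f"ybar must lie in (0, 1), got {self.ybar}")


@dataclass(frozen=True)
class ObservationWindow:
    """Recency-windowed mission observations used to (re)fit the model.

    Records must be sorted by timestamp and all lie within
    ``[as_of - horizon_days, as_of]``.  Recency is a hard cutoff: no decay
    weighting is applied inside the window.
    """

    records: tuple
    as_of: datetime
    horizon_days: int = 7

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be a positive integer")
        lo = self.as_of - timedelta(days=self.horizon_days)
        prev = None
        for r in self.records:
            ts = r.triggered_at
            if not lo <= ts <= self.as_of:
                raise ValueError(
                    f"record at {ts} outside window [{lo}, {self.as_of}]"
                )
            if prev is not None and ts < prev:
                raise ValueError("records must be sorted by timestamp")
            prev = ts

    @classmethod
    def from_history(
        cls,
        history: Sequence,
        as_of: datetime,
        horizon_days: int = 7,
    ) -> "ObservationWindow":
        """Build a window by filtering a full mission history to the horizon."""
        lo = as_of - timedelta(days=horizon_days)
        kept = sorted(
            (r for r in history if lo <= r.triggered_at <= as_of),
            key=lambda r: r.triggered_at,
        )
        return cls(records=tuple(kept), as_of=as_of, horizon_days=horizon_days)

    def __len__(self) -> int:
        return len(self.records)


def predict_probability(
    model: BehaviorModel, incentive: float, context: str | None = None
) -> float:
    """Predicted compliance probability at a given incentive and context."""
    if incentive < 0:
        raise ValueError(f"incentive must be >= 0, got {incentive}")
    return float(expit(model.linear_predictor(incentive, context)))


def estimate_incentive(
    model: BehaviorModel,
    context: str | None = None,
    target: TargetProbability | float = TargetProbability(),
) -> float:
    """Invert the model: the incentive at which predicted compliance = ybar.

    Requires beta0 > 0 (the monotonicity assumption).  The returned value
    may be negative or arbitrarily large; clamping onto the feasible bid
    grid is the engine's job, not the model's.
    """
    if model.beta0 <= 0:
        raise IncentiveInsensitiveError(
            f"incentive-insensitive model: beta0={model.beta0} is not > 0"
        )
    ybar = target.ybar if isinstance(target, TargetProbability) else float(target)
    if not 0.0 < ybar < 1.0:
        raise ValueError(f"target probability must lie in (0, 1), got {ybar}")
    coef = model.context_coefs.get(context, 0.0) if context is not None else 0.0
    return float((logit(ybar) - model.intercept - coef) / model.beta0)


# ---------------------------------------------------------------------------
# Fitting


def _penalized_nll_and_grad(params, X, y, ridge):
    # params = [beta0, context coefs..., intercept]; ridge spares the intercept
    z = X @ params
    p = expit(z)
    # log(1 + exp(-s*z)) written stably via logaddexp
    nll = np.logaddexp(0.0, -np.where(y > 0, z, -z)).sum()
    slopes = params[:-1]
    nll += 0.5 * ridge * float(slopes @ slopes)
    grad = X.T @ (p - y)
    grad[:-1] += ridge * slopes
    return nll, grad


def fit_behavior_model(
    window: ObservationWindow, ridge: float = 1e-3
) -> BehaviorModel:
    """Penalized maximum-likelihood logistic fit on a windowed mission log.

    The design matrix is [bid, one-hot geohash contexts, 1]; the L2 penalty
    ``ridge`` applies to the bid coefficient and the context coefficients
    but not the intercept.  Optimization is deterministic (L-BFGS-B from a
    zero start with an analytic gradient), so identical windows always
    yield identical models.

    Raises
    ------
    InsufficientDataError
        If the window holds no records.
    """
    from .geo import one_hot_contexts  # deferred: geo has no heavy deps

    if len(window.records) == 0:
        raise InsufficientDataError("insufficient data: observation window is empty")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")

    labels, onehot = one_hot_contexts(window.records)
    bids = np.array([r.bid for r in window.records], dtype=float)
    y = np.array([1.0 if r.success else 0.0 for r in window.records])
    X = np.column_stack([bids, onehot, np.ones(len(bids))])

    x0 = np.zeros(X.shape[1])
    res = minimize(
        _penalized_nll_and_grad,
        x0,
        args=(X, y, ridge),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
    )
    params = res.x
    return BehaviorModel(
        beta0=float(params[0]),
        context_coefs={lab: float(c) for lab, c in zip(labels, params[1 : 1 + len(labels)])},
        intercept=float(params[-1]),
    )
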