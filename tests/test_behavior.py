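"""Behavior model: prediction, inversion, and the windowed penalized fit."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from amcm.behavior import (
    BehaviorModel,
    IncentiveInsensitiveError,
    InsufficientDataError,
    ObservationWindow,
    TargetProbability,
    estimate_incentive,
    fit_behavior_model,
    predict_probability,
)
from amcm.tracker import MissionRecord

from conftest import NOW, make_logistic_records


@pytest.mark.parametrize(
    "model,incentive,context,expected",
    [
        (BehaviorModel(beta0=0.0), 2.0, None, 0.5),
        (BehaviorModel(beta0=1.0, intercept=-2.0), 2.0, None, 0.5),
        # logistic(0.5*1 + 0.2 - 1) = logistic(-0.3)
        (
            BehaviorModel(beta0=0.5, context_coefs={"A": 0.2}, intercept=-1.0),
            1.0,
            "A",
            float(expit(-0.3)),
        ),
    ],
)
def test_predict_probability_examples(model, incentive, context, expected):
    assert predict_probability(model, incentive, context) == pytest.approx(
        expected, abs=1e-12
    )


def test_unknown_context_contributes_zero():
    m = BehaviorModel(beta0=1.0, context_coefs={"A": 5.0}, intercept=0.0)
    assert predict_probability(m, 1.0, "never-seen") == pytest.approx(expit(1.0))
    assert predict_probability(m, 1.0, None) == pytest.approx(expit(1.0))


@pytest.mark.parametrize(
    "model,context,ybar,expected",
    [
        (BehaviorModel(beta0=1.0), None, 0.5, 0.0),
        (BehaviorModel(beta0=0.5, context_coefs={"A": 0.2}, intercept=-1.0), "A", 0.5, 1.6),
    ],
)
def test_estimate_incentive_examples(model, context, ybar, expected):
    r = estimate_incentive(model, context, TargetProbability(ybar))
    assert r == pytest.approx(expected, abs=1e-12)
    assert predict_probability(model, max(r, 0.0), context) == pytest.approx(ybar)


def test_nonpositive_beta0_signals_insensitive_model():
    with pytest.raises(IncentiveInsensitiveError, match="incentive-insensitive"):
        estimate_incentive(BehaviorModel(beta0=0.0), None, TargetProbability())
    with pytest.raises(IncentiveInsensitiveError):
        estimate_incentive(BehaviorModel(beta0=-0.5))


@given(
    beta0=st.floats(0.05, 10.0),
    intercept=st.floats(-5.0, 5.0),
    coef=st.floats(-5.0, 5.0),
    ybar=st.floats(0.01, 0.99),
)
@settings(max_examples=200, derandomize=True)
def test_inversion_round_trip(beta0, intercept, coef, ybar):
    """predict(estimate(ybar)) recovers ybar to high precision for beta0 > 0."""
    m = BehaviorModel(beta0=beta0, context_coefs={"c": coef}, intercept=intercept)
    r = estimate_incentive(m, "c", TargetProbability(ybar))
    z = m.linear_predictor(r, "c")
    assert float(expit(z)) == pytest.approx(ybar, abs=1e-9)


@given(
    beta0=st.floats(0.1, 5.0),
    intercept=st.floats(-3.0, 3.0),
    r1=st.floats(0.0, 5.0),
    dr=st.floats(0.01, 3.0),
)
@settings(max_examples=100, derandomize=True)
def test_monotonicity_in_incentive(beta0, intercept, r1, dr):
    m = BehaviorModel(beta0=beta0, intercept=intercept)
    assert predict_probability(m, r1 + dr) > predict_probability(m, r1)


def test_estimate_decreases_in_intercept_and_context_coef():
    base = BehaviorModel(beta0=1.0, context_coefs={"c": 0.0}, intercept=0.0)
    hi_int = BehaviorModel(beta0=1.0, context_coefs={"c": 0.0}, intercept=0.5)
    hi_coef = BehaviorModel(beta0=1.0, context_coefs={"c": 0.5}, intercept=0.0)
    r0 = estimate_incentive(base, "c")
    assert estimate_incentive(hi_int, "c") < r0
    assert estimate_incentive(hi_coef, "c") < r0


def test_target_probability_bounds():
    with pytest.raises(ValueError):
        TargetProbability(0.0)
    with pytest.raises(ValueError):
        TargetProbability(1.0)


def test_window_rejects_stale_and_unsorted_records():
    stale = MissionRecord("p", NOW - timedelta(days=8), "c", 0.3, True)
    with pytest.raises(ValueError, match="outside window"):
        ObservationWindow((stale,), as_of=NOW, horizon_days=7)
    a = MissionRecord("p", NOW - timedelta(hours=1), "c", 0.3, True)
    b = MissionRecord("p", NOW - timedelta(hours=2), "c", 0.3, False)
    with pytest.raises(ValueError, match="sorted"):
        ObservationWindow((a, b), as_of=NOW)


def test_window_from_history_filters_to_horizon():
    recs = [
        MissionRecord("p", NOW - timedelta(days=d), "c", 0.3, True) for d in (10, 6, 1)
    ]
    w = ObservationWindow.from_history(recs, as_of=NOW, horizon_days=7)
    assert len(w) == 2


def test_fit_empty_window_raises():
    w = ObservationWindow((), as_of=NOW)
    with pytest.raises(InsufficientDataError, match="insufficient data"):
        fit_behavior_model(w)


def test_fit_recovers_generating_coefficient(rng):
    """On 500 simulated records the fitted beta0 lands near the true 1.0."""
    recs = make_logistic_records(500, beta0=1.0, intercept=-1.0, rng=rng)
    w = ObservationWindow.from_history(recs, as_of=NOW)
    m = fit_behavior_model(w)
    assert m.beta0 == pytest.approx(1.0, abs=0.3)


def test_fit_consistency_error_shrinks_with_window_size(rng):
    """Median |beta0_hat - beta0| decreases from n=50 to n=2000."""

    def median_err(n):
        errs = []
        for _ in range(7):
            recs = make_logistic_records(
                n, beta0=1.0, intercept=-1.0, rng=rng, spacing_minutes=2
            )
            m = fit_behavior_model(ObservationWindow.from_history(recs, as_of=NOW))
            errs.append(abs(m.beta0 - 1.0))
        return float(np.median(errs))

    assert median_err(2000) < median_err(50)


def test_fit_separated_window_stays_finite():
    """All-success outcomes: the ridge keeps coefficients finite and fitted
    probabilities above 0.5 at the observed bids."""
    recs = [
        MissionRecord("p", NOW - timedelta(minutes=60 - i), "c", 0.3 * (1 + i % 3), True)
        for i in range(12)
    ]
    w = ObservationWindow.from_history(recs, as_of=NOW)
    m = fit_behavior_model(w, ridge=1e-3)
    assert np.isfinite(m.beta0) and np.isfinite(m.intercept)
    for r in recs:
        assert predict_probability(m, r.bid, "c") > 0.5


def test_fit_is_deterministic(rng):
    recs = make_logistic_records(80, beta0=1.5, intercept=-2.0, rng=rng)
    w = ObservationWindow.from_history(recs, as_of=NOW)
    m1, m2 = fit_behavior_model(w), fit_behavior_model(w)
    assert m1 == m2


def _grid_search_fit(X, y, ridge, rounds=14, span=6.0, pts=9):
    """Brute-force oracle: iteratively refined grid search on the penalized NLL."""
    center = np.zeros(X.shape[1])
    half = span
    for _ in range(rounds):
        axes = [np.linspace(c - half, c + half, pts) for c in center]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, X.shape[1])
        Z = mesh @ X.T
        nll = np.logaddexp(0.0, -np.where(y > 0, Z, -Z)).sum(axis=1)
        nll += 0.5 * ridge * (mesh[:, :-1] ** 2).sum(axis=1)
        center = mesh[int(np.argmin(nll))]
        half *= 2.0 / (pts - 1)  # keep neighbors of the best point covered
    return center


def test_fit_matches_brute_force_grid_search(rng):
    """On tiny two-context windows the optimizer agrees with exhaustive search."""
    from amcm.geo import one_hot_contexts

    for trial in range(3):
        n = 16
        recs = []
        for i in range(n):
            ctx = "A" if i % 2 == 0 else "B"
            bid = float(rng.choice([0.3, 0.9, 1.5, 2.1]))
            p = expit(1.2 * bid - 1.0 + (0.4 if ctx == "A" else -0.4))
            recs.append(
                MissionRecord(
                    "p", NOW - timedelta(minutes=n - i), ctx, bid, bool(rng.random() < p)
                )
            )
        # guard against single-class draws, which drift under no penalty on eps
        if len({r.success for r in recs}) < 2:
            continue
        w = ObservationWindow.from_history(recs, as_of=NOW)
        m = fit_behavior_model(w, ridge=1e-3)
        labels, onehot = one_hot_contexts(w.records)
        X = np.column_stack(
            [[r.bid for r in w.records], onehot, np.ones(len(w.records))]
        )
        y = np.array([1.0 if r.success else 0.0 for r in w.records])
        oracle = _grid_search_fit(X, y, ridge=1e-3)
        fitted = np.array(
            [m.beta0, *[m.context_coefs[lab] for lab in labels], m.intercept]
        )
        assert np.allclose(fitted, oracle, atol=1e-4)


def test_fit_cross_checked_against_sklearn(rng):
    """Independent check: sklearn's ridge-penalized logistic fit (which also
    leaves the intercept unpenalized) lands on the same coefficients."""
    sklearn = pytest.importorskip("sklearn.linear_model")
    recs = make_logistic_records(120, beta0=1.5, intercept=-1.5, rng=rng)
    w = ObservationWindow.from_history(recs, as_of=NOW)
    ridge = 1e-3
    m = fit_behavior_model(w, ridge=ridge)
    X = np.array([[r.bid] for r in w.records])
    y = np.array([int(r.success) for r in w.records])
    sk = sklearn.LogisticRegression(
        C=1.0 / ridge, tol=1e-12, max_iter=20000
    ).fit(X, y)
    # single context: compare slope and the combined constant term
    assert m.beta0 == pytest.approx(float(sk.coef_[0][0]), abs=1e-4)
    const = m.intercept + m.context_coefs[recs[0].geohash]
    assert const == pytest.approx(float(sk.intercept_[0]), abs=1e-3)


def test_model_serialization_round_trip():
    m = BehaviorModel(beta0=1.2, context_coefs={"wy6wfm8": -0.3}, intercept=0.7)
    doc = m.to_dict()
    assert set(doc) == {"beta0", "intercept", "context_coefs"}
    assert BehaviorModel.from_dict(doc) == m
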