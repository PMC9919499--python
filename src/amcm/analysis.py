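"""Outcome analysis of mission logs.

Mirrors the study's analysis pipeline on any tidy mission log (real or
simulated): exclusion filtering, per-participant success rates with the
between-group Welch comparison, and assembly of the binomial GLMM model
frame.  The GLMM *fit* itself is delegated to statsmodels' variational
binomial mixed-model routine -- the contribution here is the frame, with
its fixed effects (bid, days since intervention onset, top-k location
indicators) and its nested grouping columns (participant, and location
within participant).

Two exclusion rules clean a log before analysis:

1. drop every mission dated on a participant's first intervention day
   (the day they manually switched mission delivery on, hence noisy);
2. drop ALL missions of any participant who has two or more consecutive
   intervention days with zero triggered missions (the signature of the
   client app not running).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geo import top_k_relabel

__all__ = [
    "ExclusionReport",
    "ParticipantSummary",
    "apply_exclusions",
    "success_rates",
    "group_stats",
    "welch_t_test",
    "shapiro_normality",
    "assemble_glmm_frame",
    "fit_glmm",
    "summarize_arms",
]

REQUIRED_COLUMNS = ("participant", "triggered_at", "geohash", "bid", "success")


def _as_frame(log) -> pd.DataFrame:
    if isinstance(log, pd.DataFrame):
        df = log.copy()
    else:
        from .simulator import records_to_frame

        df = records_to_frame(list(log))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mission log is missing columns: {missing}")
    df["triggered_at"] = pd.to_datetime(df["triggered_at"])
    return df


@dataclass
class ExclusionReport:
    """Bookkeeping of the exclusion pipeline: counts must conserve."""

    n_input: int
    removed_first_day: int
    removed_gap: int
    gap_participants: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.removed_first_day - self.removed_gap

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_first_day": self.removed_first_day,
            "removed_gap": self.removed_gap,
            "n_retained": self.n_retained,
            "gap_participants": list(self.gap_participants),
        }


def apply_exclusions(
    log,
    intervention_start: Mapping[str, object],
    study_end: Optional[object] = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Filter a mission log by the two exclusion rules.

    ``intervention_start`` maps each participant to their first
    intervention day (date or datetime).  Rule 2 scans the calendar days
    strictly after that first day up to ``study_end`` (default: the last
    mission date anywhere in the log); a participant with >= 2 consecutive
    zero-mission days in that span loses all their missions.  The
    operation is idempotent: re-filtering a filtered log removes nothing.
    """
    df = _as_frame(log)
    starts = {
        p: pd.Timestamp(ts).normalize() for p, ts in dict(intervention_start).items()
    }
    dates = df["triggered_at"].dt.normalize()

    first_day_mask = df.apply(
        lambda r: starts.get(r["participant"]) is not None
        and pd.Timestamp(r["triggered_at"]).normalize() == starts[r["participant"]],
        axis=1,
    ) if len(df) else pd.Series([], dtype=bool)
    removed_first = int(first_day_mask.sum())
    kept = df[~first_day_mask] if len(df) else df

    end = (
        pd.Timestamp(study_end).normalize()
        if study_end is not None
        else (dates.max() if len(df) else None)
    )
    gap_participants: list[str] = []
    if end is not None:
        for participant, start in starts.items():
            span = pd.date_range(start + pd.Timedelta(days=1), end, freq="D")
            if len(span) < 2:
                continue
            have = set(
                kept.loc[kept["participant"] == participant, "triggered_at"]
                .dt.normalize()
                .unique()
            )
            run = 0
            for day in span:
                run = run + 1 if day not in have else 0
                if run >= 2:
                    gap_participants.append(participant)
                    break
    removed_gap = int(kept["participant"].isin(gap_participants).sum()) if len(kept) else 0
    filtered = kept[~kept["participant"].isin(gap_participants)].reset_index(drop=True)

    report = ExclusionReport(
        n_input=len(df),
        removed_first_day=removed_first,
        removed_gap=removed_gap,
        gap_participants=sorted(set(gap_participants)),
    )
    return filtered, report


@dataclass(frozen=True)
class ParticipantSummary:
    """One participant's mission tally and success rate."""

    participant: str
    n_missions: int
    n_failures: int

    @property
    def success_rate(self) -> float:
        return (self.n_missions - self.n_failures) / self.n_missions


def success_rates(log) -> list[ParticipantSummary]:
    """Per-participant success summaries.

    The group-level mean/SD downstream is computed over these
    participant-level rates, never over pooled missions, so participants
    with many missions do not dominate.
    """
    df = _as_frame(log)
    out: list[ParticipantSummary] = []
    for participant, sub in df.groupby("participant", sort=True):
        n = len(sub)
        if n == 0:
            continue
        failures = int((~sub["success"].astype(bool)).sum())
        out.append(ParticipantSummary(str(participant), n, failures))
    return out


def group_stats(summaries: Sequence[ParticipantSummary]) -> dict:
    rates = np.array([s.success_rate for s in summaries], dtype=float)
    return {
        "n_participants": len(rates),
        "n_missions": int(sum(s.n_missions for s in summaries)),
        "mean": float(rates.mean()) if len(rates) else float("nan"),
        "sd": float(rates.std(ddof=1)) if len(rates) > 1 else float("nan"),
    }


def welch_t_test(rates_a: Sequence[float], rates_b: Sequence[float]):
    """Welch's two-sample t test with Welch-Satterthwaite degrees of freedom.

    Does not assume equal variances; returns ``(t, df, p)`` with a
    two-sided p value.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate variance: both groups are constant")
    na, nb = len(a), len(b)
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def shapiro_normality(values: Sequence[float]) -> dict:
    """Shapiro-Wilk normality check (delegated to scipy), reported as-is."""
    w, p = stats.shapiro(np.asarray(values, dtype=float))
    return {"W": float(w), "p": float(p)}


def assemble_glmm_frame(
    log,
    k: int = 5,
    intervention_start: Optional[Mapping[str, object]] = None,
) -> pd.DataFrame:
    """Build the binomial GLMM model frame from a mission log.

    Columns: ``success`` (0/1 outcome); fixed effects ``bid`` and
    ``days_since_onset`` (zero-based: a mission on the first intervention
    day gets 0); one indicator column per top-k location label (via
    frequency relabeling, "other" as the reference); and grouping columns
    ``participant``, ``location_label`` and ``participant_location`` for
    the nested random intercepts.
    """
    df = _as_frame(log)
    if len(df) == 0:
        raise ValueError("mission log is empty")
    labels = top_k_relabel(
        list(df[["geohash", "triggered_at"]].itertuples(index=False, name=None)), k=k
    )
    onset: dict[str, pd.Timestamp] = {}
    if intervention_start is not None:
        onset = {p: pd.Timestamp(ts).normalize() for p, ts in dict(intervention_start).items()}
    first_seen = df.groupby("participant")["triggered_at"].min().dt.normalize()

    frame = pd.DataFrame(
        {
            "success": df["success"].astype(bool).astype(int),
            "bid": df["bid"].astype(float),
            "participant": df["participant"].astype(str),
        }
    )
    day0 = df["participant"].map(lambda p: onset.get(p, first_seen[p]))
    frame["days_since_onset"] = (
        (df["triggered_at"].dt.normalize() - day0).dt.days.astype(int)
    )
    frame["location_label"] = df["geohash"].map(labels)
    present = [
        f"top-{i}" for i in range(1, k + 1) if (frame["location_label"] == f"top-{i}").any()
    ]
    for lab in present:
        frame[lab.replace("-", "_")] = (frame["location_label"] == lab).astype(int)
    frame["participant_location"] = (
        frame["participant"] + ":" + frame["location_label"]
    )
    return frame


def fit_glmm(frame: pd.DataFrame):
    """Fit the binomial mixed model on an assembled frame (delegated).

    Uses statsmodels' variational binomial mixed GLM with random
    intercepts for participant and for location nested within
    participant.  Returns the fitted result object unchanged; odds ratios
    are exp of the fixed-effect posterior means.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    indicator_cols = [c for c in frame.columns if c.startswith("top_")]
    fixed = " + ".join(["bid", "days_since_onset", *indicator_cols]) or "1"
    formula = f"success ~ {fixed}"
    vc_formulas = {
        "participant": "0 + C(participant)",
        "participant_location": "0 + C(participant_location)",
    }
    model = BinomialBayesMixedGLM.from_formula(formula, vc_formulas, frame)
    return model.fit_vb()


def glmm_odds_ratios(result) -> pd.DataFrame:
    """Fixed-effect odds ratios (posterior mean +- 2 SD interval) from a fit."""
    names = result.model.fep_names
    mean = result.fe_mean
    sd = result.fe_sd
    return pd.DataFrame(
        {
            "coef": mean,
            "sd": sd,
            "odds_ratio": np.exp(mean),
            "or_low": np.exp(mean - 2 * sd),
            "or_high": np.exp(mean + 2 * sd),
        },
        index=names,
    )


def summarize_arms(
    logs: Mapping[str, object],
    intervention_start: Mapping[str, object],
) -> dict:
    """Per-arm exclusion + success-rate summary, with the Welch comparison.

    The one-stop entry point behind the ``analyze`` CLI subcommand.
    """
    summary: dict = {"arms": {}}
    arm_rates: dict[str, list[float]] = {}
    for arm, log in logs.items():
        filtered, report = apply_exclusions(log, intervention_start)
        summaries = success_rates(filtered) if len(filtered) else []
        rates = [s.success_rate for s in summaries]
        arm_rates[arm] = rates
        entry = {"exclusions": report.as_dict(), **group_stats(summaries)}
        if len(rates) >= 3:
            entry["shapiro"] = shapiro_normality(rates)
        summary["arms"][arm] = entry
    arms = list(logs)
    if len(arms) == 2:
        a, b = arms
        try:
            t, df, p = welch_t_test(arm_rates[a], arm_rates[b])
            summary["welch"] = {"groups": [a, b], "t": t, "df": df, "p": p}
        except ValueError as err:
            summary["welch"] = {"groups": [a, b], "error": str(err)}
    return summary
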