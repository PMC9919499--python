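# Methods

## The behavior model and incentive estimation

The engine assumes a user's mission compliance is Bernoulli with
probability σ(β₀·r + β_c + ε), where r is the loss-framed bid in dollars,
β_c the coefficient of the one-hot location context (a 7-character geohash
cell, ≈150 m), and ε the intercept. β₀ > 0 encodes the monotonicity
assumption that a larger deduction never makes compliance less likely.
Under that assumption the model inverts in closed form at a target
probability ȳ: r̂ = (logit(ȳ) − ε − β_c)/β₀.

Fitting maximizes the penalized log-likelihood with an L2 ridge (default
1e-3) on β₀ and the context coefficients, never on the intercept. The
penalty exists for one reason: the deployed engine refits after every
mission on a 7-day window that may hold a handful of records with a single
outcome class or perfectly separable bids, and the unpenalized MLE
diverges there. Optimization is deterministic — L-BFGS-B from a zero
start with an analytic gradient and tight tolerances — so identical
windows always give identical models; the convex penalty resolves
likelihood ties. On an all-success window the intercept is unpenalized and
therefore converges only to a large finite value at the gradient
tolerance; predicted probabilities at observed bids exceed 0.5, which is
the behavior the engine needs (bid low, nothing to learn).

Contexts never seen in the window contribute coefficient 0 at prediction
and inversion time: one-hot factoring cannot produce coefficients for
unvisited cells, and zero is the only neutral choice. Recency is a hard
7-day cutoff with no decay weighting; the window is anchored at bid time,
not at day boundaries.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| ȳ | 0.5 | target compliance probability of the inversion; 0.5 keeps adherence deliberately uncertain and explores cheap bids |
| window | 7 days | recency horizon of the refit |
| ridge | 1e-3 | L2 penalty on slope coefficients (not the intercept) |
| grid | $0.30–$3.00, step $0.30 | feasible bids; nearest-grid snap, midpoints round up (toward the stronger reinforcer) |
| min_observations | 5 | records required before the engine trusts a fit |
| daily budget | $1.50 = 100 points | loss-framed allowance, restored each morning |

### Fallbacks of the adaptive policy

The inversion requires a usable fit. The policy bids the grid minimum on
cold start (fewer than `min_observations` windowed records), on an
all-success window, and when the fitted β₀ is non-positive (the model
contradicts its own monotonicity assumption; the cheapest bid is the
conservative choice under loss framing, and the next observations will
refresh the window). An all-failure window of at least
`min_observations` records instead **escalates**: it bids one grid step
above the largest recently rejected bid, clamped at the maximum. A
single-class window cannot identify β₀, so inversion is unavailable either
way, but the two degenerate windows carry opposite information — all
successes say the floor is already enough, all failures say every amount
tried so far is insufficient. Escalation is the mechanism's documented
response to consecutive rejections and is what lets the engine climb away
from a floor a hard-to-motivate user simply ignores; bidding the minimum
there would trap an all-failure history at the minimum forever.

## Tracking and mission mechanics

Minute-level step counts classify mobility: <10 steps stationary, >45
moving, 10–45 an intentionally ambiguous transition band. A prompt is
scheduled 50 minutes after a stationary onset and canceled by *any*
minute with ≥10 steps — the cancellation threshold is deliberately looser
than the "moving" class. A triggered mission lasts 10 minutes and
succeeds on the first >45-step minute; otherwise it fails, the bid is
deducted (clamped at the remaining balance — the balance never goes
negative), and the next prompt is rescheduled 50 minutes after expiry.
Missions trigger only inside the participant's 9-hour daily window. A
prompt whose countdown expired before the window opens fires at the first
eligible in-window minute.

Pure failure cycles are 60 minutes (50 wait + 10 mission), so a fully
sedentary 9-hour day yields exactly 9 missions at minutes 50, 110, …, 530.
Fast success cycles are shorter (≈51–52 minutes) and could admit an 11th
trigger, so the documented bound of at most 10 missions per day is
enforced as an explicit cap. Prompts keep being delivered after the budget
is exhausted; only the collectible deduction clamps to zero — stopping
prompts would leave a broke participant unchallenged for the rest of the
day.

## The synthetic-data generator

No mission data are deposited, so the simulator is first-class code, and
its defaults are the study conditions, not tuning knobs.

**Responder archetypes.** Three ground-truth compliance models:
*logistic* (the engine's own assumed form, with per-dollar slope, context
effects, intercept), *insensitive* (fixed compliance probability — the
intrinsically motivated user who never checks the amount), and
*threshold* (high/low compliance around a personal cutoff; the cutoff's
lower anchor is $0.15, an amount a real user named as their personal
floor). Trial participants are drawn 40/40/20% from these types —
interviews suggest bid-insensitive users are common and threshold users a
sizable minority. Logistic responders draw their 50%-compliance incentive
uniformly on $0.60–$2.40 (inside the grid) and mild context effects
(SD 0.3 on the log-odds scale).

**Step streams.** A two-state sedentary/active Markov chain at minute
resolution with geometric dwell (means 60 and 10 minutes), a transition
minute (10–45 steps) inserted at every switch, and uniform step counts
inside each band (0–9 sedentary, 46–120 active). Only the band boundaries
are empirically grounded; the within-band distributions and dwell means
are modeling choices, so passing tests say the machinery is correct, not
that real streams look like this.

**Locations.** One cell per sedentary bout, drawn from a six-cell
multinomial whose first five weights (60.3/15.4/7.7/4.8/3.2%) follow the
observed per-location shares of adaptive-arm missions, with the remainder
on a catch-all cell, so simulated logs are as top-heavy as real ones.

**Trials.** Two arms (fixed $0.30 vs adaptive) over 21 days with a 7-day
mission-free baseline by default. Both arms share participant profiles and
step streams (all randomness flows from one root seed through splittable
generators), so outcome differences are attributable to the bidding policy
alone. At mission trigger the responder profile decides the outcome given
the bid and context; the tracker applies that decision on the mission's
clock (success adjudicated the next minute, failure at the 10-minute
expiry). Without such an oracle the tracker adjudicates purely from steps,
which is the deployed behavior.

## Analysis pipeline

Exclusion rule 1 drops missions on each participant's first intervention
day; rule 2 drops all missions of a participant with ≥2 consecutive
zero-mission intervention days, scanned from the day after the first
intervention day (whose missions rule 1 removes by construction) to the
study end (default: the last mission date in the log). The report's counts
conserve, and the operation is idempotent.

Success rates are participant-level ratios; group means and SDs are taken
over participants, never pooled missions. The Welch statistic, its
Welch–Satterthwaite degrees of freedom and the two-sided p value are
computed from the explicit formulas (scipy's implementation serves as an
independent cross-check in the tests). Normality checks are delegated to
scipy's Shapiro–Wilk.

The GLMM frame has the binary success outcome; fixed effects bid,
days-since-onset, and top-k location indicators (k=5; frequency ties in
the relabeling break by earliest first mission, then code, for
determinism); and grouping columns for participant and location nested
within participant. Days since onset are zero-based, which makes the
intercept interpretable at onset. Fitting is delegated to statsmodels'
variational binomial mixed GLM and reported as-is; the package's
contribution is the frame, not the estimator.

## Problem sizes and numerical choices

The test suite and acceptance checks run at deliberately modest scale:
parameter-recovery fits use windows of 50–2000 records; closed-loop
convergence uses 20 seeded runs of 200 missions; the trial-level budget
audit uses 2 arms × 10 participants × 14 days; stream statistics average
300 seeded 9-hour days. The convergence scenario uses a single-location
responder with no context effects: the quantity under test is the bid's
convergence to a known unconditional 50%-compliance incentive, and
nuisance context dimensions would make that target ambiguous (with
multiple sparsely visited cells the per-cell fits are noisy, which is a
property of the method worth knowing — the real deployment saw its
incentive coefficients scatter around zero — but it is not the quantity
this check measures).

Exact midpoint bids discretize upward. Bid-grid membership uses a 1e-9
tolerance. The inversion round-trip is exact to better than 1e-9 over the
parameter ranges the engine produces.

## Known limitations

The generator does not model attrition, notification latency beyond the
10-minute window, app malfunction, or mid-bout movement between cells.
Each participant has an independent model — no hierarchical pooling, by
design. The logistic family is the only response model the engine fits,
even though two of the three simulated archetypes violate it; that
mismatch is intentional, since it is precisely the regime the method faced
in the field. Geohash cells carry no semantics (home/work), and real
step-stream distributions are unknown, so the Markov-chain generator is a
structural stand-in rather than a calibrated one.
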