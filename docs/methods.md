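# Methods

## The model

`pairctmc` models the joint movements of a pair of foraging fish — labelled
*bold* and *shy* by temperament score — as a continuous-time Markov chain
(CTMC) observed at exact transition times. Each fish is either under cover
or out in an exposed foraging area, and the pair's state carries four
binary variables: the two *location* variables, the identity of the fish
that *initiated* the most recent trip out of cover, and a *joined* flag
recording whether the initiator's partner has also left cover on that trip.
Two feasibility rules cut the 16 combinations down to 12 states: when both
fish are out the partner has necessarily joined, and an unjoined solo
excursion can only belong to the initiator. Transitions are single-mover
(one fish leaves or returns at a time), so each state has exactly two
outgoing edges and the graph has 24 directed transitions q_{i,j}.

Status updates are deterministic: a departure from a both-covered state
opens a new trip (initiator := mover, joined := false); the non-initiator
leaving cover while the initiator is out sets joined := true; every other
move carries the status variables over unchanged. Social roles therefore
persist through termination attempts and re-joinings, and reset only when
both fish are back under cover and someone starts a new trip.

### Model variants as parameter tying

Model comparison is expressed through *tying schemes* that map the 24 edges
onto shared rate classes:

| scheme           | free intensities | what a rate may depend on                     |
|------------------|------------------|-----------------------------------------------|
| `full`           | 24               | locations, initiator identity, joined flag    |
| `initiator_only` | 16               | locations and initiator identity              |
| `memory_free`    | 8                | the two locations only                        |

A separate 8-state *one-step memory* space pairs each location combination
with the immediately preceding one, so the influence of leading or
following persists over at most one change in location. It is not nested
in the 12-state family (its states are not a coarsening of the 12) and is
compared by AIC; the nested variants are compared by likelihood-ratio
tests (full vs memory-free: 16 df; full vs initiator-only: 8 df).

### Likelihood

With exactly observed event times the log-likelihood decomposes over
sojourns: a sojourn of length t in state s contributes −(total exit rate
of s)·t, and each observed transition adds log of its edge's rate. The
final sojourn of each session is right-censored and contributes exposure
only. Under a tying scheme the sufficient statistics are per-class event
counts n_c and exposures T_c, so without covariates the MLE is the closed
form q̂_c = n_c / T_c. Classes with exposure but no events have MLE zero
and are reported as such (they stay in the parameter count); classes with
no exposure are flagged non-estimable and excluded with a warning.

The interval before a session's first event has well-defined locations but
unobservable status variables. It is emitted as an `unknown` prefix visit
that carries no likelihood exposure, and the first departure defines the
first initiator with joined = false. This avoids inventing a status for
unobserved history at the cost of discarding, on average, under a minute
of exposure per hour-long session.

### Covariates

Pair-level temperament scores x_B and x_S enter log-linearly: for pair p
and class c,

    q_{p,c} = exp(theta_c + sum_v gamma_{v,c} (x_{v,p} − mean_v)).

Each coefficient belongs to one class, so adding both covariates to all 24
classes adds 48 parameters, one covariate adds 24, and the
"own-effects-only" restriction (each score affects only its own fish's
moves) removes 24 from the 48. Covariates are centred at their across-pair
mean by default — the convention of standard multistate software — so
baselines describe an average pair; the offsets are stored in the fit. Raw
scores are used by default with an optional log transform (scores are rate
ratios and right-skewed). The likelihood then still separates into
independent Poisson-regression-like blocks per class; it is maximised
jointly by L-BFGS on the log scale (positivity by construction), with
analytic gradients, an optional multi-start, and a gradient-norm tolerance
of 1e-8 judged relative to the total event count (the gradient is in
event-count units). A covariate with no between-pair contrast raises a
degenerate-design error rather than returning an unidentified estimate.

### Inference

Uncertainty is quantified by a nonparametric bootstrap that resamples
*pairs* (the independent sampling units, each with all its sessions) with
replacement — 1000 replicates and percentile intervals by default.
Two-sided p-values for intensity ratios are twice the smaller tail of the
replicate distribution around 1, floored at 2/B. Replicates on which the
estimator fails (e.g. a degenerate resample) are recorded and redrawn up
to a retry bound. A parametric alternative — simulating replicates from
the fitted model — can be plugged in through the same estimator interface.

### Sequence statistics

Temperament is the ratio of a fish's leave-cover to return-to-cover
intensity in the two-state individual model (unit-free). Initiation events
are first departures from a both-covered pair; success means the partner
joined before both fish were back under cover. Per pair, the ordered
initiator labels are tested for clumping with the Wald–Wolfowitz runs z
(negative z = fewer runs than expected); across pairs, the count of
negative-z pairs is tested against one half with an exact two-sided
binomial test (doubled smaller tail, capped at 1). The runs sequence
includes failed initiations by default — an initiation is any first
departure — with a flag to restrict to successful ones. Trips still
unresolved at the session end are treated as right-censored: they keep
their likelihood exposure but are dropped from sequence statistics.

## The synthetic-data generator

No raw observations are distributed with the original experiment, so the
generator produces session logs with the structure the analysis assumes:
exact Gillespie simulation of the 12-state chain (exponential sojourns,
next edge proportional to its intensity), started both-covered with the
same unknown-status convention the encoder uses (the first mover is drawn
from each fish's mean initiation intensity). The default study design
mirrors the emulated experiment: 20 pairs, two one-hour transparent-
partition sessions each, bold/shy labels assigned by ordering two
log-normal temperament draws per pair.

The default intensities are illustrative package fixtures, not estimates
from the original study (which are unpublished). They were chosen once so
that (a) a simulated fish completes about 54 trips per hour in the
stationary regime, and (b) the qualitative orderings the model is meant to
express hold: bold fish leave cover more readily than shy fish; both fish
join an exposed partner faster than they initiate; both return more slowly
while their partner is still out; initiators are more resolute than
followers (e.g. q_{10,12} > q_{6,7}); fish follow a partner's termination
faster when the partner initiated (q_{11,4} > q_{8,3}); and a successful
initiation raises the propensity to initiate again (q_{3,5} > q_{4,5},
q_{4,9} > q_{3,9}). The relative magnitudes also keep re-joining moderate
(about one position change per joint trip, range 0–10 in an hour-scale
session). Time units are seconds in logs and per-minute intensities in
fits, which keeps rate magnitudes readable at this trip frequency.

Randomness is disciplined through one root seed and `numpy` seed-sequence
spawning per pair and session, and the truth record written alongside each
dataset suffices to recompute every generated rate.

What the generator does *not* emulate: diurnal or satiation trends
(rates are time-homogeneous), measurement error in event times (times are
exact), non-exponential sojourns, and any behavioural coupling beyond the
12-state memory structure. Passing tests therefore show that the
estimators recover the truth *under the model's own assumptions*, not that
real fish satisfy them.

## Numerical and design choices

- **State numbering.** The canonical numbering of the 12 states is fixed
  so that every transition subscript used in reporting (q_{1,5}, q_{5,6},
  q_{6,8}, q_{10,12}, ...) resolves to an edge of the space; this is
  enforced by a unit test.
- **One-step-memory topology.** The 8 states are the location combinations
  paired with their feasible single-mover predecessors; an edge's successor
  remembers the edge's source combination. This is the unique single-mover
  reading of the construction.
- **Simultaneous timestamps** are rejected as malformed (single-mover
  dynamics need a strict order); a deterministic epsilon-offset repair is
  available for digitised logs.
- **Session pooling.** Sessions of one pair are pooled into one likelihood
  unit by default (pairs are the independent units); a flag treats each
  session separately.
- **Zero-event classes** are estimated at zero and excluded from log-scale
  optimisation; bootstrap intervals for them come out as [0, upper].
- **LRT statistics** are clamped at zero when tiny negative values arise
  from floating-point round-off; a materially negative statistic triggers a
  non-convergence warning instead of being silently accepted.
- **Comparing across spaces.** The 12-state and 8-state models assign
  density to the same observed event stream (each state has one edge per
  fish), so their AICs are directly comparable; the data fingerprint
  hashes observation times only, which are invariant across encodings of
  the same logs, and comparisons across different datasets are refused.

## Problem sizes used in the shipped checks

The structural checks are exact and instantaneous. The statistical checks
are simulation-scaled: estimator equivalence uses 50 small studies; the
encoder round-trip uses 1,000 short sessions; null calibration uses 300
studies of 3 pairs x 1 hour generated under the memory-free model (the
full-vs-memory-free LRT is then compared to chi-squared(16) and its size
at 0.05 is checked); bootstrap coverage uses 100 studies of 20 pairs x 2
hours with a true log-linear effect of 0.35 on the partner-join class and
B = 200 bootstrap replicates. These sizes give stable pass/fail behaviour
while keeping a laptop-scale runtime.

## Known limitations

- The exact-times likelihood does not handle panel (interval-censored)
  observation; it assumes the event times themselves are recorded.
- Percentile bootstrap intervals with 20 pairs sit near the lower edge of
  nominal coverage (around 90-95% in the shipped calibration); BCa or
  basic intervals are not implemented.
- The bootstrap treats the pair as the only resampling unit; with many
  sessions per pair a two-stage scheme might be preferable.
- Tied coefficients across classes (e.g. one shared covariate effect for
  all of a fish's moves) are not implemented; each coefficient is
  class-specific, as in the reported analyses.
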