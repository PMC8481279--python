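# Methods

This note records the modelling conventions, defaults and numerical
choices behind the package, and what the synthetic components can and
cannot establish.

## Decision kernel

Agents revise strategies synchronously under logit learning with payoff
weights `b` (coordination), `k` (inertia) and `r` (trend-seeking)
constrained to `b + k + r = 1`.  Because of that convex-combination
constraint the two payoffs always satisfy `π(0) + π(1) = 1`, so the
adoption probability is evaluated in the numerically stable logistic
form `1/(1 + exp(−β(2π(1) − 1)))`; the argument is bounded by `β`, so
no overflow is possible for any finite rationality.  For every finite
`β` the probability is strictly inside `(0, 1)`, which makes every
strategy configuration reachable and full diffusion an
almost-sure event — the quantity of interest is *when*, not *whether*.

Conventions:

* **Initial trend.** No round precedes the initial state, so the
  previous-strategy vector is initialised equal to the current one and
  the first update sees a neutral trend term (½).  We verified that the
  alternative convention (treating the committed minority as having
  just switched) changes the headline statistics by well under 1%.
* **Committed minority.** Implemented by freezing those agents at the
  alternative through a mask rather than by `k=1, β=∞`; the induced
  dynamics on the regular agents are identical and no infinite
  arithmetic is needed.
* **Explorer count.** `round-half-up(ρ_e · n_regular)`, deterministic;
  agents are ordered `[committed | explorers | non-explorers]`.
* **Randomness.** One uniform variate per regular agent per round,
  consumed in fixed agent order — trajectories are bit-reproducible per
  seed, and a per-agent scalar loop driven by the same variates
  reproduces the vectorised update exactly (tested).

## Simulation and campaigns

Default run controls: full-diffusion threshold 0.99, take-off threshold
0.4 (robustness variants 0.35/0.45 supported), step cap 50,000.  Runs
reaching the cap are *censored*: their take-off time is reported at the
cap with a flag, and they are excluded from campaign means of `T̄`/`ΔT`
(the count is reported separately).  Campaign confidence intervals are
normal-approximation 95% intervals over replicates — undefined (and
flagged) below two uncensored replicates.  Child seeds derive
deterministically from the master seed, so campaigns are reproducible
and cells independent.

Switching rates discount the final revision into consensus.  Since full
diffusion is declared at 99%, a handful of agents may still hold the
status quo at `T*`; such an agent made no final switch, so the discount
is applied only to agents finishing on the alternative (and rates are
floored at zero).  The aggregate "rounds per switch" is the reciprocal
of the mean rate over regular agents and replicates — the alternative
reading (mean of reciprocals) is dominated by near-zero rates and is
not used.

## Trial records and classification

Trial records hold a rounds × 12 strategy matrix (entries 0/1/missing),
seat roles, the Stage II start round and the consensus round; CSV files
use 1-based round labels while simulation time is 0-based.

Cleaning rules: a seat that never played is a *dropout* (its plays are
the majority-following replacement bot's); missing more than 20% of
rounds is *missed rounds*; playing the status quo in every round *and*
holding it for two consecutive rounds while all eleven other players
are on the alternative is *totally stubborn*.  A trial is excluded only
when it both contains a missed-rounds participant and has more than a
third of its recruits behaving irregularly.

Switch events are classified against the other players' strategies in
the **previous** round — what was on screen when the choice was made;
the same-round convention is available via a switch (`info="current"`).
With eleven fellow players a tie is impossible in the 12-seat geometry,
but other group sizes can tie; ties count toward neither minority nor
majority.  Comparisons never span a missing round: no switch can be
attributed to an unobserved decision.  The empirical `T*` is the round
at which all regular participants first hold the alternative (scanning
Stage II only), 24 when never; without a final consensus the final-
switch discount is dropped.  A participant path of 24 recorded rounds
has at most 23 observable transitions, since no round-zero state exists
for trial data.  Class statistics use the sample standard deviation
(ddof = 1).

## Synthetic trials

The generator emulates the 12-seat experiment: 8–10 participants
(uniformly drawn when unspecified) plus committed bots to fill 12
seats.  Stage I starts from uniformly random participant choices; all
but one committed bot chase the previous-round participant majority
while one contrarian opposes it, and the strategy on which all humans
and the majority bots coincide is relabelled 0.  Stage II bots push the
alternative until full visible consensus or round 24.  Default
irregularity rates mirror the experiment's incidence: per-seat dropout
probability 0.18 (32 of 180 recruits), per-round miss probability 0.01,
stubborn probability 0.01; the default explorer share is 0.62 (74 of
119 cleaned participants).  Stubborn seats repeat their first choice
forever, which also pins the Stage I outcome to their side whenever
Stage I converges.

What the generator does *not* reproduce: human Stage I play.  Real
groups settled on a status quo within 1–3 rounds; model-driven Stage I
from random starts typically needs 2–10.  Its contract is structural
and distributional plausibility (valid records, a near-zero switching
peak with a broad tail, mostly-diffusing trials), not fidelity to human
consensus formation — conclusions about real Stage I behaviour cannot
be drawn from it.

## Calibration

Each retained trial becomes a deterministic replay scenario:
mechanical seats (committed bots, dropout bots, stubborn and
missed-rounds participants) are hardcoded to their observed visible
paths — padded with their last value out to round 24 for replicates
that outlast the real group — while regular seats are re-simulated from
the Stage II start at candidate class parameters, starting on the
status quo.  A simulated seat's observed Stage I switches are fixed
data of the trial and are added to its simulated count, so simulated
switching rates follow the same full-game convention as the empirical
ones.  Trials that never established a status quo cannot be replayed
and are dropped from calibration.

The cost is the weighted absolute error between empirical and simulated
class means and standard deviations of the switching rate, with weights
`(1, 0.5, 1, 1.5)` balancing the two classes (`a1 + a3 = a2 + a4`); the
non-explorer mean carries less weight because it sits near zero and
carries little information, its standard deviation correspondingly
more.  The search is exhaustive over a regular lattice —
`β ∈ [0, 10]` step 0.2, weights step 0.01 with `b = 1 − k − r ≥ 0` at
full scale; that lattice is expressible but combinatorially large, so
coarse sub-lattices are the supported desk-scale mode.  Ties break to
the lexicographically smallest parameter vector and the runner-up
minimum is reported.  By default all lattice points share one seed
stream per scenario (common random numbers), trading a small bias in
absolute cost levels for much lower comparison variance; independent
streams are a flag away.

## Problem sizes and observed behaviour

The shipped tests and the reproduction script use 50 replicates for the
n=200 switching-rate statistics, 20 replicates per cell at n=1000 for
the take-off bound, 5 capped runs for the censoring regime, 10,000
replicates for the geometric oracle, and a 3^5 sub-lattice at 200
replicates per scenario for parameter recovery — sizes chosen so each
experiment completes in seconds to a couple of minutes on one CPU while
leaving Monte Carlo error well inside the asserted tolerances.

At the calibrated parameters the model shows delayed take-off with an
explosive transition, take-off delay decreasing in the explorer
fraction, a bounded transition time as the population grows, a
switching-rate distribution with a dominant near-zero peak and a broad
tail, and the no-diffusion regime below a critical committed-minority
fraction.  The computed rounds-per-switch statistic at `ρ_e = 0.2`
comes out near 19 (about 12–15% above the reference value of 17 for
this setting) and near 10.3–10.5 at `ρ_e = 0.6` (reference 11); the
take-off and censoring regimes reproduce comfortably within their
bounds.

## Known limitations

* Well-mixed populations only: no interaction networks, asynchronous or
  pairwise updates, or more than two strategies.
* The trend and inertia terms are memory-one; long-memory variants are
  out of scope.
* Calibration at the full paper-scale lattice is computationally heavy
  by design (exhaustive search); only sub-lattice searches are exercised
  by the test suite.
* The empirical-data checks require the deposited trial dataset
  converted to the documented CSV schema; without it they cannot run.
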