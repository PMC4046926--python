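# Methods

This note documents the model, the numerical choices, and the limits of what
the simulations show. It states no numbers that the test suite or
`scripts/acceptance.py` do not themselves compute.

## Environment

The stimulus-reinforcement association is a three-state Markov chain over
`(r, n, p)` with per-time-bin transition probabilities. Direct `r ↔ p` jumps
are excluded, so a conditioned association always relaxes through the neutral
state; this guarantees the conditioned-response probability decays
monotonically toward its asymptote instead of overshooting to the opposite
response. Defaults: `a_rn = a_pn = 0.05`, `a_nr = a_np = 0.005`, giving
stationary probabilities `π = (1/12, 10/12, 1/12)`, mean conditioned-state
dwell of 20 bins, neutral-state probability `p_n ≈ 0.83`, and average reward
`ρ = π_r − π_p = 0` with reinforcements ±1. These are package choices for a
symmetric, slowly changing world; every qualitative claim tested is
parameter-robust, and the defaults are plain config values.

The `(p_n, ρ, timescale)` re-parametrization solves the stationary
distribution from `π_n = p_n` and `reward_pos·π_r + reward_neg·π_p = ρ`, then
recovers rates from detailed balance, which holds exactly for this
birth-death-like chain. Four rates minus three constraints leave one degree
of freedom; the default convention sets both conditioned-state leaving rates
equal to the timescale rate, with an override for asymmetric chains.

Emissions under approach are deterministic in `r` and `p` and nearly
deterministic in `n` (0.99 / 0.005 / 0.005); avoidance always emits the
neutral signal. The spurious `n`-state reinforcements model odor-unrelated
reward and punishment and keep the filter well-defined after any observation
sequence the environment can actually produce.

Within a time bin the order is: act → emit reinforcement from the current
state → state transition. This makes "conditioning in bin t" unambiguous and
matches the filter's correct-then-predict convention below.

## Belief filter

The belief is updated by Bayes correction with the `(action, signal)`
likelihood followed by one prediction step through the transition matrix,
`b' ∝ (b ∘ O(a, y)) P`. With this order, an avoid step is exactly `b ↦ bP`,
the stationary distribution is a fixed point of the avoid update, and
"forgetting" is literally the mixing of the chain. The alternative
(predict-then-correct) convention yields different one-step transients; the
choice here is the one under which drift and conditioning compose cleanly,
and it is applied consistently everywhere (filter, DP children, LP kernel).
Zero-likelihood observations raise rather than renormalize silently.

Conditioning protocols are belief clamps: one approach update with the
implied signal per pairing; the environment is not co-simulated during
training or testing, because the experiment defines which state the animal
experiences. Delay `d` means `d` avoid updates after the last pairing; the
fraction at `d = 0` is taken immediately after the pairing's own prediction
step.

## Costs and the closed-form max

Response costs are i.i.d. exponential with scale 0.3 (in units of the unit
reinforcement). Decisions depend only on the cost difference, which is
Laplace(0, scale). The scale default is chosen so that conditioning saturates
near 1 (a freshly conditioned agent almost always emits the conditioned
response) while the forgetting curve remains smooth rather than step-like;
both regimes are exercised in tests by varying the scale.

The provident recursion needs `E[max(A − c_ap, B − c_av)]`. Pathwise,
`max(A − c_ap, B − c_av) = −c_ap + max(A, B + Δ)` with `Δ = c_ap − c_av`, so
by linearity the expectation splits into the mean cost and
`E[max(A, B + Δ)] = max(A, B) + (scale/2)·e^{−|A−B|/scale}`, derived by
splitting the Laplace density at the crossing point and validated against
piecewise adaptive quadrature (split at both integrand kinks, tails truncated
at 60 decay lengths) to 1e-8 over a grid of arguments and scales.

## Policies

**Greedy** thresholds the immediate expected reinforcement against the cost
difference; ties break toward approach everywhere in the package, because
approach is the information-gathering action.

**Provident (DP)** iterates optimal finite-horizon values `K = 5` times with
discount `γ = 0.95` and defines the stationary policy from the last
iteration. The expansion tree has four children per node (three approach
outcomes, one avoid outcome); it is evaluated level-wise on arrays so that a
batch of beliefs costs the same number of numpy operations as one. Horizons
above 7 are refused (4^K growth). The decision threshold
`Q_ap(b) − Q_av(b)` is cached per belief, making the per-agent decision one
comparison with the sampled cost difference. γ-sensitivity (measured by the
paired free-run comparison below, 120 runs per setting): the
provident-minus-greedy gap per 1000-step run is ≈1.1 at γ=0.9, ≈1.2 at
γ=0.95, ≈1.2 at γ=0.99 — the information bonus grows mildly with γ, and
K = 5 truncation is the binding approximation.

**Provident (LP)** quantizes the belief simplex on a square lattice
(spacing 1/20) in `(b_r, b_p)` and the cost-difference line into 11
equal-mass Laplace intervals (odd, so one bin straddles zero). Off-lattice
updated beliefs are assigned to the vertices of the enclosing lattice
triangle with barycentric weights, so the expected rounded belief is exact.
Per-bin rewards use conditional mean costs, available in closed form because
`c_ap | Δ` is a shifted exponential: `E[c_ap|Δ] = max(0, −Δ) + scale/2`. The
average-reward occupation-measure LP is solved with HiGHS; the balance-row
duals give the bias function, which is valid only on the support of the
optimal stationary measure, so it is completed on transient states by
relative value iteration seeded from the duals before the deterministic
policy is read off. The same finite MDP solved by relative value iteration
from scratch is the independent cross-check in the test suite.

**Baselines.** "No forgetting": a greedy agent whose belief is corrected by
informative signals but never pushed through the transition matrix — its
memory is frozen between reinforcements, so its forgetting curve is flat.
"Immediate forgetting": decisions by costs alone. Both are package
constructions (the comparison concepts they operationalize are standard, but
their precise definitions are ours), plus constant always-approach /
always-avoid policies.

## Free-run comparisons

`evaluate_total_reward` simulates the closed loop (state from stationarity,
belief from the stationary belief, costs redrawn per bin). Policy comparisons
use common random numbers: every policy sees the same per-run seed, and since
the environment is action-independent and each bin consumes a fixed number of
draws, the hidden-state trajectory is identical across policies within a run.
Comparisons are therefore reported as paired per-run differences with their
s.e.m.; the unpaired between-run spread (driven by the dwell-time history of
the chain) is an order of magnitude larger than the policy effect at the
default parameters. Default problem size: 40 runs of 1000 bins. At these
parameters the provident-minus-greedy gap is small (≈1 reward unit per 1000
bins) and positive; resolving it beyond ~2 standard errors needs more than 40
paired runs, which is reported as measured rather than embellished.

## Mechanistic agent

Two strengths relax as `w ← w + α(w_base − w)` per silent bin; reward sets
`(w_ap, w_av) = (w_max_ap, 0)`, punishment the mirror image. The decision is
`w_ap − w_av + noise > 0` with Laplace noise reusing the cost-difference
scale, so mechanistic and belief-based agents face identical decision
stochasticity. Its forgetting curves are closed-form (geometric decay through
a Laplace CDF). Fitting minimizes the summed squared deviation of the
appetitive and aversive curves jointly: Nelder-Mead from a few structured
starts (covering both decay orderings, since the rise of one channel can
mimic the decay of the other) plus 10 seeded random starts, each polished by
bounded least squares; greedy mode constrains the two decay rates to be
equal. Fitting the provident curves requires
`α_av > α_ap` — the mechanistic translation of faster aversive forgetting.

## Extended model

A hidden two-state meta variable (slow/fast) selects the chain's rates; its
own transitions (`q_sf = q_fs = 0.001` per extended bin) are independent of
the environmental transition within a bin, the simplest joint kernel
consistent with a rate-setting meta variable. Ten extended bins equal one
basic bin; slow rates are the basic rates divided by ten (per extended bin),
fast rates ten times the slow ones. Spaced training keeps its 9-basic-bin
waits (90 extended bins of drift between pairings), while massed and reversal
pack pairings into consecutive extended bins — the point of the finer
discretization is that those pairings follow each other faster than one basic
bin. Test decisions use the greedy policy on the marginal environmental
belief. Spaced training concentrates the posterior on the slow mode, reversal
on the fast mode, and the half-gap delays order spaced > massed > reversal.

## Simulation conventions and sizes

Forgetting curves: the belief trajectory is deterministic given the protocol,
so all agents share one belief per delay and the curve is binomial; each
agent is tested once with fresh costs (2000 agents per delay point, binomial
standard errors). For threshold policies the exact fraction (Laplace CDF at
the threshold) is used as the direct-computation oracle and as the fitting
target. Delay grids default to 21 roughly log-spaced integers in [0, 200]
basic bins. The half-gap delay (delay at which a curve has covered half the
gap from its initial value to its large-delay asymptote, linearly
interpolated) summarizes forgetting speed; its standard error in tests comes
from the delta method through the local slope.

## What the synthetic conditions do not show

All results are in model time bins with unit reinforcements; no mapping to
hours or to real fly performance indices is attempted, and no behavioral data
are fitted. The environment parameters are not calibrated to any dataset:
passing tests show the normative mechanisms (information bonus, volatility
inference) behave as claimed under the stated conditions, not that these
parameter values describe *Drosophila*. The belief clamp idealizes
conditioning as noise-free experiences of defined states; real conditioning
trials would update beliefs through the same filter but with sampled
signals. The one-decision-per-agent test convention matches
fraction-of-animals read-outs, not repeated-choice designs.
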