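# Methods

## The decision problem

`riskforage` models a forager that must balance energetic gain against
predation risk while paying for the act of deciding itself.  The environment
has two hidden binary telegraph processes:

* **predator**: absent ⇄ present with switching rates `gamma_AP`, `gamma_PA`
  (per second);
* **habitat quality**: good ⇄ bad with rates `gamma_GB`, `gamma_BG`.

The animal always knows its **location** — a safe *refuge* (actions: rest,
assess, transit) or a foraging *patch* (feed, assess, freeze, escape) — but
must infer the hidden states from observations:

* a passive **indirect cue** `o_i`, available during every activity except
  rest, emitted per step with probability `lambda_oi_plus*dt` when the
  predator is present and `lambda_oi_minus*dt` when absent;
* an active **direct cue** `o_d`, available only while assessing, with rates
  `lambda_od_plus` / `lambda_od_minus`;
* while feeding, encounters with rich/poor food patches at habitat-dependent
  rates (`rho_rG`, `rho_pG`, `rho_rB`, `rho_pB`), which both pay reward
  (`r_feed_rich`, `r_feed_poor` per second) and inform about habitat quality.

While the animal is exposed — in the patch, or in transit to it — a present
predator detects (and thereby catches) it at an action-dependent rate
`delta_a`, ordered so that freezing is safest and escaping/transiting most
exposed.  A capture collects the one-off penalty `r_pred`, truncates the
current activity and returns the animal to the refuge (predation is a severe
injury, not termination); the predator belief is set to certainty of
presence, since the encounter was experienced directly.

Choices are **activities**: a pair (action `a`, duration `tau`) with `tau`
drawn from `tau_set` (default 1–15 s).  Every decision epoch — including the
first — charges the decision cost `c_d`, a scalar standing in for the
computational and metabolic cost of deliberation.  Future reward is
discounted exponentially at rate `alpha` (default 0.1/s), applied per step as
`exp(-alpha*dt)` so that a commitment of `tau` seconds compounds to
`exp(-alpha*tau)`.

### Belief state and filtering

The pair `(beta_P, beta_G)` — the posterior probabilities that the predator
is present and the habitat good — is a sufficient statistic.  Without
observations each component relaxes exponentially toward its chain's
stationary probability; within a step the filter uses the short-step form
`beta' = beta*exp(-gamma_out*dt) + (1-beta)*(1-exp(-gamma_in*dt))`, which is
exactly the one-step transition of the discretized chain.  Observations enter
by two-hypothesis Bayes rule with per-step likelihoods `lambda*dt` for an
emission and the complement `1 - lambda*dt` for an omission on an available
channel; unavailable channels contribute nothing.  Omission likelihoods use
complements because that is the only convention under which the per-channel
outcome probabilities sum to one and the induced belief transition conserves
probability.  The filter deliberately updates on cues only: surviving an
exposed step is not treated as evidence of absence.  This keeps the agent's
inference exactly as cheap and local as the cue model, at the price of a
slight pessimism — simulated returns of a solved policy in the generative
world run marginally above the solver's value function.

## Solving the belief SMDP

Beliefs are discretized on a regular grid of resolution `d_beta` (default
0.01, i.e. 101×101 points per location).  For each (location, action) a
sparse one-step operator enumerates every joint outcome — capture × cue
combination × feed encounter — with its probability under the
belief-mixture, its exact posterior mapped back to the grid, and its reward.
Two grid mappings are available: **bilinear** interpolation over the four
surrounding points (default; smooth value estimates) and **nearest**
neighbour (reproduces the blocky region boundaries typical of coarse
discretizations).  Branch probabilities sum to one at every grid point by
construction, which the test suite asserts.

Value iteration then solves

    V(b) = max_{(a, tau)} [ -c_d + Q_{a,tau}(b) ]

where `Q` is a backward recursion over the committed steps, with capture
branches continuing from the refuge value and location changes (transit,
escape) applied at the end of the commitment.  For an **interruptible**
policy the recursion takes `max(W_k, V)` at every interior commitment time:
interrupting is free, and the value of re-deciding already contains the
`-c_d` of the triggered decision.  Iteration stops when the sup-norm change
falls below `tol` (default 1e-8, well inside the per-step contraction
`exp(-alpha*dt) ≈ 0.905`); non-convergence within `max_iter` is reported with
the final residual.

Numerical conventions:

* **Tie-breaking.**  Among value-equivalent activities (within `tie_tol`,
  default 1e-6, chosen above the converged residual), duration ties resolve
  to the *shortest* commitment for non-interruptible policies — flexibility
  costs nothing — and to the *longest* for interruptible ones, where longer
  provisional commitments schedule fewer decisions and interruption is free.
  Remaining ties use a fixed action order (rest, feed, assess, freeze,
  transit, escape).  This makes policy extraction bit-reproducible.
* **Interrupt trigger.**  In simulation an activity is interrupted when the
  interpolated value of re-deciding exceeds the committed continuation value
  by more than 1e-6 — strictly above the convergence residual, so numerical
  noise cannot fire spurious (and costly) re-decisions.
* **Warm starts.**  Sweeps over `c_d` or cue reliabilities reuse the step
  operators (which do not depend on `c_d`) and warm-start each solve from the
  neighbouring cost's value function.

## Default parameters

Rewards per second: `r_feed_rich = 2`, `r_feed_poor = 1`, `r_rest = 0`,
`r_transit = r_assess = r_freeze = -0.1`, `r_escape = -1`; capture penalty
`r_pred = -100`.  Detection rates: `delta_feed = delta_transit =
delta_escape = 0.05`, `delta_assess = 0.02`, `delta_freeze = 0.01`, zero for
refuge rest/assess.  Cue rates: `lambda_oi = 0.5/0.1`, `lambda_od = 0.9/0.1`
(present/absent).  Encounter rates: `rho_rG = 0.8, rho_pG = 0.2` (good),
`rho_rB = 0.2, rho_pB = 0.8` (bad).  Habitat switching `gamma_GB = gamma_BG
= 0.01`/s.

**Predator switching defaults to `gamma_AP = gamma_PA = 0.01`/s**, the same
timescale as the habitat process (mean dwell ≈ 100 s).  This is a considered
modelling choice: with much faster predator switching (for example 0.1/s,
i.e. ~10 s dwells) the patch economics collapse — a fresh arrival occurs
every ~10 s, the cue-driven filter needs one or two seconds to notice it, and
at `delta_feed = 0.05` against a −100 penalty that lag costs roughly −10 per
presence episode, wiping out the ~+15 feeding margin of an absence episode.
The optimal policy then degenerates to resting in the refuge from the
uncertain belief (0.5, 0.5) onward, and every downstream comparison becomes
vacuous.  At 0.01/s the solved policy shows the full behavioural repertoire:
transit/assess/rest bands in the refuge, feed/assess/defence bands in the
patch, and withdrawal-then-return under scripted predator episodes.  The rate
remains an ordinary configuration field for users who want the harsher
regime.

With effective escape, freezing is dominated by escaping at these defaults
(waiting out a ~100 s presence frozen in the patch is worse than paying the
escape cost once); freeze takes over the entire defensive region when escape
is configured as ineffectual (`escape_effective: false`, which leaves the
animal in the patch at the end of the manoeuvre).

## The single-location model

The stripped-down model isolates the commitment/interruption trade-off: one
location, predator arrives at `p_arrive = 0.01` per step and stays, catch
probability `p_catch = 0.1` per step while present, feed pays +1 per step,
catch −100, escape and capture terminate, objective undiscounted total
reward.  Feeding receives the indirect cue and assessing additionally the
direct cue, at the same per-step rates as the full model (0.5/0.1 and
0.9/0.1).  Value iteration runs on the 1-D belief grid with terminal
branches.

The qualitative policy is: feed at low `beta`, assess at intermediate,
escape at high `beta`, with minimal durations when decisions are free and
maximal feed/assess commitments once `c_d > 0` and interruption is allowed.
The exact escape boundary is sensitive to the assess cue reliability: with
the default, highly informative direct cue (0.9 vs 0.1 per step) a single
clean assessment nearly resolves the predator state, so tolerating risk up to
`beta ≈ 0.71` before escaping is optimal.  Less reliable assessment pulls the
boundary down toward 0.5.  Because the cue rates are free parameters of this
reduced model, the boundary location should be read as conditional on them;
the band ordering and the duration/interruption structure are the robust
predictions.

## Simulation harness

Protocol trials script the predator (default: 2 min absent, 2 min present,
2 min absent) while the habitat runs free.  Trials start in the refuge,
predator absent, habitat drawn from its stationary distribution, beliefs at
the stationary point (0.5, 0.5); an activity in progress when a scripted
segment flips simply continues.  Total reward per trial includes all decision
costs paid.

All randomness flows through named, step-indexed uniform streams
(`EventStreams`): the draw for channel *c* at step *t* depends only on
(seed, *c*, *t*).  Two policies simulated at the same trial seed therefore
face byte-identical worlds even though they consume different channels —
common random numbers, which removes between-policy sampling noise from
reward ratios.  Trial *i* of a batch uses the stream keyed (seed, *i*).

Reported experiment sizes: 1000 matched trials for the single-location
comparison; 200 matched protocol trials per decision cost for the full-model
ratio sweep (100 on the high-cost extension where both policies have
collapsed to rest and the comparison is exact); behaviour summaries use 100
instantiations of 15-minute runs.  These sizes put the Monte-Carlo standard
error of the ratio well below the effects of interest.

What the generative simulator does *not* emulate: spatial structure,
predator behaviour conditioned on the animal, resource depletion, satiation
or starvation state, and learning.  Conclusions from the simulations are
about this stylized environment; passing tests demonstrate internal
consistency (solver ↔ filter ↔ simulator) and the qualitative phenomena, not
ecological realism.

## Interruption thresholds

For an interruptible policy, the set of beliefs at which a committed
activity should be abandoned is summarized per activity by thresholds on
`beta_P` at fixed `beta_G`: the package scans each grid column and reports
the boundary of the continuation region — where the committed value with the
full `tau_max` remaining steps still matches the value of re-deciding —
restricted to the contiguous run containing the activity's initiation set.
Feed has an upper threshold only; assess has both.  Thresholds are fitted by
unweighted least squares as planes `theta ≈ w0 + w1*beta_G + w2*c_d`
(missing boundaries excluded, not imputed), and the fitted planes drive a
cheap interruption rule — interrupt when `beta_P` exits the predicted box —
whose matched-trial performance sits within Monte-Carlo error of the exact
interrupt condition.  Columns where an activity is never initiated are
flagged empty rather than fitted.

## Known limitations

* The grid filter/solver pair is consistent but the filter itself is not the
  exact Bayes filter of the generative world (no survival conditioning), so
  value functions understate realized returns slightly.
* Threshold extraction assumes the continuation region in each column is a
  single interval around the initiation set; exotic parameter settings that
  fragment it would need the extraction revisited.
* The undiscounted single-location model relies on the capture/escape leak
  for convergence; setting both `p_arrive` and `p_catch` to zero would make
  the fixed point improper.
* Policy lookups in simulation use the nearest grid point while values are
  interpolated; at `d_beta = 0.01` the induced boundary jitter is below the
  Monte-Carlo noise of the reported metrics.
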