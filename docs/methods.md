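# Methods

This note records the model implemented by `trustinfer`, the design choices
made where several formulations were defensible, the defaults and why they
are what they are, and what the simulations do and do not demonstrate.

## 1. The generative model of one round

A round is a two-time-step episode over a hidden space
S = {start, cc, dc, cd, dd} × {p, n}: the observable component is the stage
of the exchange (start, then the realized action pair, self's action first),
the latent component is the partner's esteem trait, prosocial (p) or
antisocial (n).  The agent's model *m* comprises:

* **Likelihood A** (5×10): a deterministic projection onto the observable
  component.  The trait is never observed directly; only behavior is.
  ("Identity mapping" here means identity on the observable component — a
  10×10 identity is impossible with 5 observables.)
* **Transitions B(u)** (2 pages, 10×10, column-stochastic): from `(start, e)`
  the self's action u leads to `((u, u^o), e)` with the modeled other's
  response probability (below); outcome states are absorbing within a
  round; cross-trait entries are structurally zero (traits cannot change —
  that is what makes them traits).
* **Goal prior** `P(s_T | m) = σ(r(s_T), β)`: a softmax of per-state
  utilities.  For the self these are the esteem-augmented returns of §2
  with β = 1, because the reward sensitivity β_r is already inside the
  utilities — exposing both and setting both would double-count
  sensitivity.  The two start states are assigned probability exactly 0
  (they never materialize as outcomes) and the remaining eight entries are
  renormalized.
* **Precision prior** `γ ~ Gamma(shape α = 8, scale θ = 1)` (prior mean
  αθ = 8).  Internally the gamma is carried as (shape, rate = 1/θ).
* **Horizon 1** with policies {(cooperate,), (defect,)}.  The engine accepts
  arbitrary control sequences; the trust round needs only length-1 ones.

## 2. Utilities, the social Pavlovian bias, and the naive other

With monetary returns r^s, r^o (defaults: the 2×2 tables
r^s = [[26,10],[21,18]], r^o = [[26,42],[7,10]] indexed self action × other
action) the augmented return of a player is

    r = β_r · money + s · (e^s + e^o),   s = +1 if the player's own action is
                                          cooperate, −1 if defect.

Cooperation earns the total esteem in the room; defection forfeits it,
irrespective of the instrumental outcome — a social Pavlovian bias.  The
self's own esteem e^s defaults to 0 (neutral self-representation), and the
self uses its own self-esteem to model what the other believes about it.

The monetary tables can alternatively be generated from a wage w = 20 units
of play money, venture gain g = 3 and investment/return fractions:
r^s = w − w f^s + w f^s f^o, r^o = w f^s g − w f^s f^o (the pot
w(1 + f^s(g−1)) depends only on the self's investment).  The printed default
tables are not jointly consistent with any single fraction quadruple, so the
tables are the primary configuration; supplying fractions as well triggers a
consistency check.

The **naive other** performs no inference: it softmaxes its own two
augmented returns given the self's realized action,
`P(u^o | u^s, e^s, e^o) ∝ exp(r^o)`, acting after observing the self's
choice (the investor–trustee order).  The same rule, applied per trait, is
what the self embeds in B(u).

## 3. Default esteem values and the calibration of β_r

Only the *signs* of the esteem values and the qualitative preference
structure are prescribed; the magnitudes are calibrated.  Two within-block
ranking properties pin down an asymmetry.  Writing E_p = e^s + e_p,
E_n = e^s + e_n and using the default returns:

* "forgiving toward the prosocial": (cd,p) must beat (dc,p), i.e.
  10β_r + E_p > 21β_r − E_p  ⟺  2E_p > 11β_r;
* mutual cooperation must still top exploitation in the antisocial block:
  (cc,n) above (dc,n), i.e. 26β_r + E_n > 21β_r − E_n  ⟺  5β_r > −2E_n.

With e^s = 0 these require e_p / |e_n| > 11/5.  We ship a 6:1 ratio
(e_p = 0.72, e_n = −0.12); a pronounced ratio also makes the *prior* policy
evaluation lean cooperative under an agnostic trait belief (the attainable
outcomes of the prosocial branch sit close to the goal distribution), the
"benefit of the doubt" behavior the model is meant to exhibit.

The absolute scale is tied to β_r by a dispersion calibration: β_r is the
largest value at which no modeled response probability exceeds 0.8 across
all (self action, trait) cells, so that simulated choices stay variable
rather than deterministic.  Each response gap is linear in β_r, so the
feasible set is an interval (it does *not* extend to β_r = 0: with the 6:1
esteem the prosocial gap alone breaches the cap at low sensitivity); the
calibration intersects the per-cell intervals exactly and polishes the upper
boundary by bisection to 1e-6.  The result, β_r = (ln 4 − 2|e_n|)/16 ≈
0.07164, lands inside the ordering window (2|e_n|/5, 2e_p/11) ≈
(0.048, 0.131).  The shipped response table is then

    P(defect | self c, other n) = 0.800   P(defect | self c, other p) = 0.427
    P(defect | self d, other n) = 0.612   P(defect | self d, other p) = 0.227

Note the resulting magnitudes: a symmetric ±1 esteem pair is infeasible both
for the calibration (σ(2) ≈ 0.88 > 0.8 at β_r = 0) and for the two ranking
properties simultaneously, which is why the defaults are asymmetric.

## 4. The variational engine

Beliefs are mean-field sufficient statistics μ = (ŝ₀…ŝ_t, û, γ̂): categorical
state beliefs per observed time, a categorical policy belief, and a gamma
precision belief (whose shape stays at α).  The value matrix
Q[i, j] = −KL[P(s_T | s_j, ũ_i) ‖ P(s_T | m)] ≤ 0 is computed by pushing a
point mass through the B pages; goal-prior zeros are floored at 1e-16 before
the log so the divergence stays defined for arbitrary user models (the
trust model never predicts a zero-goal state).

One observation step cycles, in this order and in the log domain,

    ŝ_t ← σ(ln A-evidence + ln(B(a) ŝ_{t−1}) + γ̂ Qᵀ û)      (at t = 0 the
                                     transition term is the initial belief)
    û  ← σ(γ̂ Q ŝ_t)
    q(γ) = Gamma(α, 1/θ − ûᵀ Q ŝ_t),  γ̂ = α / rate

until |ΔF| < 1e-6 or 64 sweeps (then flagged non-converged; never observed
in practice — the trust model converges in ≤ 6 sweeps).

**Normalization convention.**  The step joint treats the Boltzmann policy
factor with a *single* normalizing constant over (state, policy, γ):
`P(o, s, ũ, γ) ∝ A[o,s] · prior(s) · exp(γ Q(ũ,s)) · p(γ)`.  Conditioned on
(s, γ) this is exactly the softmax policy prior `σ(−γ KL)`; its advantage is
that the three updates above become *exact* coordinate descent on the
variational free energy

    F = E_Q[ln Q − ln P] = ŝ·(ln ŝ − ln A − ln prior) + û·ln û
        − γ̂ ûᵀQŝ + KL[q(γ) ‖ p(γ)] + ln C,

so the free-energy trace is monotone non-increasing by construction, and
the normalizer and step evidence have closed forms through the gamma moment
generating function, C = Σ_{s,ũ} prior(s)·(λ₀/(λ₀ − Q))^α.  The bound
F ≥ −ln P(o | m) is verified in the tests against an independent oracle
(state/policy enumeration plus 64-node generalized Gauss–Laguerre
quadrature over γ); with a per-state softmax normalization instead, the
textbook updates are only approximate descent and none of this is exact.
A side effect, intended in this model family, is that states from which
goals are reachable are a priori slightly more plausible — expected value
biases perception.

**Filtering.**  State beliefs never look forward: each observation is
assimilated against the predictive prior B(a)ŝ (past beliefs are frozen),
and the reported free energy is the current step's.  With γ fixed at 0 the
update is exact forward Bayesian filtering (verified against a hand-rolled
filter).

**End of a round (no decisions remaining).**  The policy set is empty, so
the state update carries no prospective value term — with a deterministic A
it is a pure Bayes step.  Precision, however, is re-evaluated against the
*realized* value, rate = 1/θ − ŝ·ln P(s_T | m): confidence tracks how close
to the goals the round actually landed.  This produces the within-round
precision jumps — γ̂ ≈ 3.9 after mutual cooperation versus ≈ 2.0 after
mutual defection — on top of the slow between-round drift.

## 5. Two belief streams in iterated play

Within a round the value-coupled updates exhibit a strong positive feedback:
optimistic trait beliefs favor cooperation, cooperation raises expected
value, value raises precision, and precision amplifies the perceptual bias.
From an agnostic prior the coupled equilibrium is decidedly cooperative
(P(cooperate) ≈ 0.998) — the model's "benefit of the doubt" — and once the
carried belief passes ≈ 0.93 antisocial it snaps to a defecting equilibrium
(P(cooperate) ≈ 0.067).

That perceptual tilt is preference, not evidence.  If the tilted belief
were carried between rounds it would compound (≈ γ̂(e_p − e_n) logits per
round, an order of magnitude more than the evidence a round provides) and
the agent would lock into data-independent optimism.  The package therefore
separates:

* the **action-guiding stream** — full coupled inference; supplies the
  policy probabilities, the sampled action and the precision trajectory;
* the **evidential stream** — the exact Bayes update of the carried trait
  prior by the observed action pair (equivalently, inference with γ = 0).

Only the evidential posterior is carried across rounds (and recorded as
`trait_posterior`).  This keeps the carried belief a martingale under the
agent's own model — averaging the posterior over the model's own predictive
distribution of outcomes recovers the prior exactly, which the tests check —
while all within-round behavior remains fully value-coupled.

**Precision across rounds.**  The gamma *posterior* rate is 1/θ plus the
(positive) value deficit −ûᵀQŝ; carrying it forward as the next prior would
add another deficit every round, growing the rate linearly and collapsing
γ̂ → 0 over a 32-round game — the opposite of the slow, smooth evolution
the model is meant to show.  The default therefore resets the precision
prior each round (a `carry_precision` toggle implements the accumulating
variant for completeness).  Expected precision still evolves slowly across
rounds — from ≈ 4.3 under agnosticism to ≈ 3.2 once the partner is known
and the agent defects — because beliefs and policies sharpen, while
within-round, outcome-driven jumps are an order of magnitude larger
(mean between-round drift ≈ 0.11 versus mean within-round jump ≈ 0.95 in
the 100-seed study).

## 6. Simulation study and what it shows

The shipped study conditions are: default payoffs and calibrated esteem/β_r,
α = 8, θ = 1, an antisocial naive other, agnostic (0.5/0.5) initial trait
prior, 32 rounds, 100 seeds (one root seed spawning independent substreams
for the two players' choices).  Under these conditions the package
reproduces, and its tests assert:

* the preference pattern of the goal prior (mutual cooperation best, more so
  with a prosocial partner; forgiveness toward prosocial, exploitation of
  antisocial in the second-best positions);
* single-round behavior: cooperation favored despite agnosticism; mutual
  defection shifts belief toward the antisocial trait (P ≈ 0.73);
* iterated play: median final P(antisocial) > 0.9 (≈ 0.9999), confidence at
  the 0.9 threshold in a median of ≈ 7 rounds, cooperation falling from
  ≈ 0.66 in the first half to ≈ 0.17 in the second, and smooth carried
  precision relative to within-round jumps.

These are *qualitative* reproductions of simulation behavior, not fits to
data.  The naive other emulates a fixed-disposition partner with a one-shot
softmax response; it does not emulate human trustees (no learning, no
reciprocity tracking, no inference about the self).  Passing tests
demonstrate internal consistency of the model and engine and the stated
dynamics under the shipped conditions — not predictive validity for human
exchanges.

## 7. Numerical choices and degenerate inputs

* All softmax/normalization in the log domain with max subtraction;
  |β·value| up to 700 is safe.
* Goal-prior log floor 1e-16; KL with `0·log 0 = 0`; KL raises a dedicated
  error when the second argument lacks support.
* Convergence: |ΔF| < 1e-6, cap 64 sweeps; F monotone to machine precision
  (tested at 1e-8).
* Action sampling by inverse CDF over policies in declared order with a
  single uniform draw; one root seed, two spawned substreams per game.
* Validation is reporting, not raising: `validate_model` lists every
  violated invariant (column sums off by > 1e-9, cross-trait transitions
  where traits are declared conserved, unnormalized priors, shape
  mismatches); model constructors abort on a non-empty report.
* Degenerate inputs: observations impossible under every state raise an
  inference error; a point-mass trait prior is immovable (trait
  conservation plus deterministic observables); zero-investment rounds
  return the bare wage.

## 8. Known limitations

* Single-round planning horizon; no multi-step lookahead or recursive
  theory of mind (the other does not model the self).
* Two esteem levels and two actions; the full investor–trustee stake space
  is out of scope.
* The coupled policy equilibrium is bistable under the shipped calibration,
  so per-round cooperation probabilities move in large steps rather than
  smoothly; the *realized* action frequencies still decline smoothly in
  aggregate.
* The evidential/action-guiding split is a modelling commitment of this
  package (see §5); alternatives (carrying the coupled posterior, or
  damping the perceptual bias) are not explored.
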