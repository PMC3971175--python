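# trustinfer

Active-inference agents for iterated trust games: a discrete-state
variational-Bayes agent whose goals are softmax prior beliefs over outcomes
plays a simplified two-choice Trust game against a naive partner whose
prosocial or antisocial disposition is a hidden trait to be inferred from
behavior.

The package is aimed at computational psychiatry and cognitive-modelling
researchers who want a small, fully inspectable implementation of
interpersonal ("theory of mind") inference under the active-inference
framework: goals as priors, policy selection by divergence minimization, and
Bayes-optimal inference of the precision (confidence) of policy beliefs.

## The model

One round of the simplified Trust game has a starting state and four
outcomes (cc, dc, cd, dd — self's action then other's action, c = cooperate,
d = defect), with a 2×2 matrix of monetary returns `r^s`, `r^o` for the two
players (defaults: `r^s = [[26,10],[21,18]]`, `r^o = [[26,42],[7,10]]`,
generated by a wage w = 20 invested in a venture with gain g = 3).  Money is
augmented by a scalar *esteem* trait e — the social Pavlovian bias:

    utility = β_r · money + s · (e^s + e^o),     s = +1 if own action is c, −1 if d

The other's esteem is hidden, taking a prosocial (p) or antisocial (n)
value, which yields a 10-state hidden space (5 observables × 2 traits).  The
self's generative model comprises

* a likelihood **A** (deterministic projection of the observable component),
* controlled transitions **B**(u) in which the trait never changes and, from
  the start state, the outcome follows the modeled other's softmax response
  `P(u^o | u^s, e^s, e^o) ∝ exp(r^o)`,
* a goal prior `P(s_T | m) = σ(r(s_T), β)` — preferred outcomes are a priori
  plausible,
* a gamma prior `Γ(α = 8, θ = 1)` over the policy precision γ.

Policies ũ are valued by `−KL[P(s_T | s_t, ũ) ‖ P(s_T | m)]`, collected in a
value matrix **Q**, and beliefs μ = (ŝ₀…ŝ_t, û, γ̂) are optimized by cycling
the variational fixed-point updates

    ŝ_t ← σ(ln A-evidence + ln B ŝ_{t−1} + γ̂ Qᵀ û)
    û  ← σ(γ̂ Q ŝ_t)
    q(γ) = Gamma(α, 1/θ − ûᵀ Q ŝ_t)

until the variational free energy `F ≈ −ln P(õ | m)` stops falling.  Actions
are sampled from û; the other responds; posterior beliefs about the partner
become the next round's priors.  See `docs/methods.md` for derivations,
parameter choices and caveats.

## Worked example

```sh
$ trustinfer round --observe dd
goal prior over hidden states:
  start,p  0.0000
     cc,p  0.3474
     dc,p  0.0575
     cd,p  0.1104
     dd,p  0.0464
  start,n  0.0000
     cc,n  0.1500
     dc,n  0.1332
     cd,n  0.0477
     dd,n  0.1075
policy belief at start (agnostic): P(cooperate)=0.9984 P(defect)=0.0016  gamma_hat=4.2783
after observing 'dd': P(prosocial)=0.2707 P(antisocial)=0.7293  gamma_hat=1.9676
```

Reading the numbers: mutual cooperation with a prosocial partner is the most
preferred outcome (0.347) and more preferred than with an antisocial one
(0.150); within the prosocial block the second-best outcome is to cooperate
even though the other defects (cd,p = 0.110 > dc,p = 0.058), while within
the antisocial block it is to defect while the other cooperates
(dc,n = 0.133).  From an agnostic trait prior the agent gives the partner
the benefit of the doubt and prefers to cooperate; after observing mutual
defection the evidential posterior implicates the antisocial trait (0.729)
and the outcome-evaluated precision drops (1.97 versus 4.28 at the start of
the round — a disappointing round lowers confidence).

A full game against the antisocial naive other:

```sh
$ trustinfer run --rounds 32 --seed 1 --out trace.csv
wrote 32 rounds to trace.csv
cooperation rate 0.281; final P(antisocial) = 1.000; rounds to 90% confidence: 4
```

The per-round CSV contains the carried trait beliefs, policy probabilities,
precision and free energy; over roughly the first ten rounds the agent
becomes confident the partner is antisocial and its cooperation collapses.
The same can be done from Python:

```python
from trustinfer import TrustConfig, run_game, summarize_trace
trace = run_game(TrustConfig(seed=1))
print(summarize_trace(trace)["table"].head())
```

`trustinfer calibrate` reports the shipped reward sensitivity
(β_r ≈ 0.0716, chosen so no modeled response probability exceeds 0.8) and
the resulting response table; `trustinfer validate` checks a configuration
and the model it induces; `trustinfer fixtures` emits random valid test
models.

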