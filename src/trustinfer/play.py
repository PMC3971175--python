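"""Drive single rounds and iterated games of the simplified trust task.

The self acts by active inference; the naive other responds with a one-shot
softmax of its own augmented returns.  At the end of each round the self's
posterior beliefs about the partner become the priors for the next round,
emulating Bayesian trait learning across the game.

Two belief streams coexist within a round and both are recorded:

* the *action-guiding* stream — the full variational state, where expected
  policy value biases perception (benefit of the doubt) and precision scales
  choice; it produces the policy probabilities, the sampled action and the
  precision trajectory;
* the *evidential* stream — the exact Bayes update of the carried trait
  prior by the observed action pair; it is what carries over between rounds.

Keeping the carried belief purely evidential makes the trait posterior a
martingale under the agent's own model and prevents the preference-driven
perceptual tilt from compounding across rounds into data-independent
optimism or cynicism; docs/methods.md discusses the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import __version__
from .engine import BeliefState, infer, sample_action
from .generative import PrecisionPrior, ValidationError
from .trust import (
    ACTIONS,
    TRAITS,
    EsteemConfig,
    PayoffConfig,
    TrustConfig,
    build_self_model,
    opponent_response_distribution,
)

__all__ = [
    "OtherAgent",
    "RoundRecord",
    "GameTrace",
    "play_round",
    "carry_over",
    "run_game",
    "summarize_trace",
]


@dataclass(frozen=True)
class OtherAgent:
    """The naive opponent: a fixed trait and a one-shot softmax response rule."""

    true_trait: str = "n"
    esteem_value: float | None = None
    beta_r: float | None = None
    believed_self_esteem: float = 0.0

    def __post_init__(self):
        if self.true_trait not in TRAITS:
            raise ValidationError("true_trait must be 'p' or 'n'")
        if self.esteem_value is not None:
            positive = self.esteem_value > 0
            if positive != (self.true_trait == "p"):
                raise ValidationError("esteem_value sign must match the trait")

    def response_distribution(self, u_self: str, cfg: TrustConfig) -> np.ndarray:
        esteem = cfg.esteem
        if self.esteem_value is not None:
            if self.true_trait == "p":
                esteem = replace(esteem, e_prosocial=self.esteem_value)
            else:
                esteem = replace(esteem, e_antisocial=self.esteem_value)
        if self.beta_r is not None:
            esteem = replace(esteem, beta_r=self.beta_r)
        return opponent_response_distribution(
            u_self, esteem, cfg.payoffs, self.true_trait,
            e_self_believed=self.believed_self_esteem,
        )

    def respond(self, u_self: str, cfg: TrustConfig, rng: np.random.Generator) -> str:
        probs = self.response_distribution(u_self, cfg)
        return ACTIONS[int(np.searchsorted(np.cumsum(probs), rng.random(), side="right").clip(0, 1))]


@dataclass(frozen=True)
class RoundRecord:
    """Everything the self believed and did during one round."""

    round_index: int
    action_self: str
    action_other: str
    observation_label: str
    trait_posterior: tuple  # (P(p), P(n)), evidential
    policy_probs: tuple  # (P(cooperate), P(defect)) before the outcome
    gamma_hat: float  # precision after the outcome evaluation
    gamma_hat_start: float  # precision at the decision point
    free_energy_final: float
    n_vb_iterations: int


@dataclass(frozen=True)
class GameTrace:
    """A full iterated game: config, seed and one record per round."""

    config: TrustConfig
    seed: int
    records: tuple
    version: str = __version__

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) != self.config.n_rounds:
            raise ValidationError("record count must equal n_rounds")


def _bayes_trait_update(
    trait_prior, u_self: str, u_other: str, cfg: TrustConfig
) -> np.ndarray:
    """Exact posterior over (p, n) after seeing the other's response."""
    prior = np.asarray(trait_prior, dtype=float)
    like = np.array(
        [
            opponent_response_distribution(u_self, cfg.esteem, cfg.payoffs, t)[
                ACTIONS.index(u_other)
            ]
            for t in TRAITS
        ]
    )
    post = prior * like
    total = post.sum()
    if total <= 0:
        raise ValidationError("trait posterior lost all support")
    return post / total


def play_round(
    trait_prior,
    cfg: TrustConfig,
    other: OtherAgent,
    carry: tuple | None = None,
    rng: np.random.Generator | None = None,
    round_index: int = 0,
    tol: float = 1e-6,
    max_iter: int = 64,
):
    """Play one round; return (record, trait_posterior, precision_carry).

    ``carry`` is an optional (shape, rate) pair used as this round's
    precision prior; ``rng`` must supply two independent substreams (self,
    other) or a single generator used sequentially.
    """
    prior = np.asarray(trait_prior, dtype=float)
    if prior.shape != (2,) or abs(prior.sum() - 1.0) > 1e-9:
        raise ValidationError("trait_prior must be a distribution over (p, n)")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rng_self, rng_other = (rng if isinstance(rng, (tuple, list)) else (rng, rng))

    round_cfg = cfg
    if carry is not None:
        shape, rate = carry
        round_cfg = replace(cfg, precision_prior=PrecisionPrior(shape, 1.0 / rate))

    model = build_self_model(round_cfg, esteem_belief=prior)

    # decision point: assimilate the start observation, choose
    b_start = infer(model, ["start"], tol=tol, max_iter=max_iter)
    policy_probs = tuple(float(x) for x in b_start.u_hat)
    gamma_start = b_start.gamma_hat
    a_self = sample_action(b_start, rng_self)
    a_other = other.respond(a_self, cfg, rng_other)
    outcome = a_self + a_other

    # full-round variational pass: outcome assimilation + precision re-evaluation
    b_end = infer(model, ["start", outcome], actions=[a_self], tol=tol, max_iter=max_iter)

    # evidential trait posterior carried to the next round
    trait_post = _bayes_trait_update(prior, a_self, a_other, cfg)

    record = RoundRecord(
        round_index=round_index,
        action_self=a_self,
        action_other=a_other,
        observation_label=outcome,
        trait_posterior=tuple(float(x) for x in trait_post),
        policy_probs=policy_probs,
        gamma_hat=b_end.gamma_hat,
        gamma_hat_start=gamma_start,
        free_energy_final=float(b_end.surprise),
        n_vb_iterations=int(b_start.n_iterations),
    )
    precision_carry = tuple(b_end.gamma_posterior)
    return record, trait_post, precision_carry


def carry_over(trait_posterior, precision_posterior):
    """Map end-of-round posteriors onto the next round's priors.

    The trait posterior spreads over the two start states; the precision
    posterior's (shape, rate) becomes the next gamma prior.  Idempotent in
    the sense that chaining two carries equals one carry of the later
    posterior.
    """
    prior = np.asarray(trait_posterior, dtype=float)
    if abs(prior.sum() - 1.0) > 1e-9 or np.any(prior < 0):
        raise ValidationError("trait_posterior must be normalized")
    return prior.copy(), tuple(precision_posterior)


def run_game(cfg: TrustConfig, tol: float = 1e-6, max_iter: int = 64) -> GameTrace:
    """Play ``cfg.n_rounds`` sequential rounds from an agnostic trait prior.

    One root seed spawns independent substreams for the self's and the
    other's choices; the trace is bit-reproducible from (config, seed).
    """
    ss = np.random.SeedSequence(cfg.seed)
    child_self, child_other = ss.spawn(2)
    rng_self = np.random.default_rng(child_self)
    rng_other = np.random.default_rng(child_other)

    other = OtherAgent(true_trait=cfg.other_true_esteem)
    trait_prior = np.array([0.5, 0.5])
    precision_carry = None
    records = []
    for k in range(cfg.n_rounds):
        record, trait_post, prec_post = play_round(
            trait_prior, cfg, other,
            carry=precision_carry,
            rng=(rng_self, rng_other),
            round_index=k,
            tol=tol,
            max_iter=max_iter,
        )
        records.append(record)
        trait_prior, carried_prec = carry_over(trait_post, prec_post)
        if cfg.carry_precision:
            precision_carry = carried_prec
    return GameTrace(config=cfg, seed=cfg.seed, records=records)


def summarize_trace(trace: GameTrace, confidence: float = 0.9) -> dict:
    """Tidy per-round table plus whole-game aggregates.

    ``rounds_to_confidence`` is the first 1-based round after which the
    posterior probability of the other's true trait exceeds ``confidence``
    (None if never reached).
    """
    rows = []
    for r in trace.records:
        rows.append(
            {
                "round": r.round_index + 1,
                "action_self": r.action_self,
                "action_other": r.action_other,
                "observation": r.observation_label,
                "p_prosocial": r.trait_posterior[0],
                "p_antisocial": r.trait_posterior[1],
                "p_cooperate": r.policy_probs[0],
                "gamma_hat": r.gamma_hat,
                "gamma_hat_start": r.gamma_hat_start,
                "free_energy": r.free_energy_final,
                "n_iter": r.n_vb_iterations,
            }
        )
    table = pd.DataFrame(rows)
    true_trait = trace.config.other_true_esteem
    col = "p_antisocial" if true_trait == "n" else "p_prosocial"
    hit = table.index[table[col] > confidence]
    return {
        "table": table,
        "cooperation_rate": float((table["action_self"] == "c").mean()),
        "final_p_true_trait": float(table[col].iloc[-1]),
        "rounds_to_confidence": int(table.loc[hit[0], "round"]) if len(hit) else None,
        "confidence_threshold": confidence,
    }
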