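"""The simplified two-choice Trust game and the self's generative model.

One round: the self earns a wage ``w``, invests a high or low fraction of it
(cooperate / defect) in a joint venture that multiplies the investment by a
gain ``g``; the other then returns a fraction of the invested amount (high =
cooperate, low = defect).  With only two levels per player the round reduces
to a 2x2 matrix of monetary returns.

On top of the money, both players carry a scalar "esteem" trait — how good a
person one is.  The other's esteem is hidden and takes one of two values,
prosocial (``p``, positive) or antisocial (``n``, negative).  Esteem enters
utility as a social Pavlovian bias: a player's own cooperative act earns the
total esteem in the room, a defecting act forfeits it,

    utility = beta_r * money + sign * (e_self + e_other),

with sign +1 when that player's own action is cooperate and -1 when it is
defect.  A naive other simply softmaxes its two augmented returns; the self
builds a full 10-hidden-state generative model (5 observables x 2 traits)
and infers the trait from behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .generative import (
    GenerativeModel,
    ObservationModel,
    OutcomePrior,
    PrecisionPrior,
    StateSpace,
    TransitionModel,
    ValidationError,
    softmax,
    validate_model,
)

__all__ = [
    "COOPERATE",
    "DEFECT",
    "ACTIONS",
    "TRAITS",
    "OBSERVABLES",
    "HIDDEN_LABELS",
    "PayoffConfig",
    "EsteemConfig",
    "TrustConfig",
    "monetary_returns",
    "augmented_utility",
    "opponent_response_distribution",
    "build_self_model",
    "self_preference_ordering",
    "calibrate_beta_r",
]

COOPERATE = "c"
DEFECT = "d"
ACTIONS = (COOPERATE, DEFECT)
TRAITS = ("p", "n")

# Observable labels: start, then action pairs "<self><other>" in the order
# cc, dc, cd, dd (other's action varies fastest), matching the canonical
# numbering o1..o5.  Hidden labels are observables crossed with the other's
# trait, prosocial block first.
OBSERVABLES = ("start", "cc", "dc", "cd", "dd")
HIDDEN_LABELS = tuple((o, t) for t in TRAITS for o in OBSERVABLES)

_AIDX = {COOPERATE: 0, DEFECT: 1}


@dataclass(frozen=True)
class PayoffConfig:
    """Monetary structure of one round.

    The 2x2 tables are indexed ``[self action][other action]`` with 0 =
    cooperate, 1 = defect, and are the primary configuration; the
    wage/gain/fraction parameterization is an optional generator checked for
    consistency when both are supplied.
    """

    wage: float = 20.0
    gain: float = 3.0
    return_self: tuple = ((26.0, 10.0), (21.0, 18.0))
    return_other: tuple = ((26.0, 42.0), (7.0, 10.0))
    fractions_self: tuple | None = None  # (f_high, f_low)
    fractions_other: tuple | None = None  # (f_high, f_low)

    def __post_init__(self):
        rs = tuple(tuple(float(x) for x in row) for row in self.return_self)
        ro = tuple(tuple(float(x) for x in row) for row in self.return_other)
        object.__setattr__(self, "return_self", rs)
        object.__setattr__(self, "return_other", ro)
        for tbl, name in ((rs, "return_self"), (ro, "return_other")):
            if len(tbl) != 2 or any(len(r) != 2 for r in tbl):
                raise ValidationError(f"{name} must be a 2x2 table")
            if not all(math.isfinite(x) for r in tbl for x in r):
                raise ValidationError(f"{name} must be finite")
        if (self.fractions_self is None) != (self.fractions_other is None):
            raise ValidationError("supply both fraction pairs or neither")
        if self.fractions_self is not None:
            fs = tuple(float(x) for x in self.fractions_self)
            fo = tuple(float(x) for x in self.fractions_other)
            object.__setattr__(self, "fractions_self", fs)
            object.__setattr__(self, "fractions_other", fo)
            for f in fs:
                if not 0.0 < f <= 1.0:
                    raise ValidationError("self investment fractions must lie in (0, 1]")
            self._check_fraction_consistency(fs, fo)

    def _check_fraction_consistency(self, fs, fo):
        for i, f_s in enumerate(fs):
            for j, f_o in enumerate(fo):
                r_s, r_o = monetary_returns(self.wage, self.gain, f_s, f_o)
                if not (
                    math.isclose(r_s, self.return_self[i][j], abs_tol=1e-6)
                    and math.isclose(r_o, self.return_other[i][j], abs_tol=1e-6)
                ):
                    raise ValidationError(
                        f"return tables disagree with wage/gain/fraction generator in cell "
                        f"({ACTIONS[i]}, {ACTIONS[j]}): generated ({r_s:.6g}, {r_o:.6g}), "
                        f"configured ({self.return_self[i][j]:.6g}, {self.return_other[i][j]:.6g})"
                    )

    def returns(self, u_self: str, u_other: str) -> tuple[float, float]:
        i, j = _AIDX[u_self], _AIDX[u_other]
        return self.return_self[i][j], self.return_other[i][j]


# Shipped esteem defaults.  The two within-block "second best" preference
# statements pin down an asymmetry: forgiveness toward a prosocial partner
# needs 2*e_p > 11*beta_r while ranking mutual cooperation above exploitation
# in the antisocial block needs 5*beta_r > 2*|e_n|, hence e_p/|e_n| > 11/5.
# We use a 6:1 ratio, with the absolute scale tied to beta_r through
# calibrate_beta_r (max response probability 0.8).  See docs/methods.md.
_E_PROSOCIAL = 0.72
_E_ANTISOCIAL = -0.12
_BETA_R = (math.log(4.0) - 2 * abs(_E_ANTISOCIAL)) / 16.0


@dataclass(frozen=True)
class EsteemConfig:
    """Esteem values and reward sensitivity entering the augmented utilities."""

    e_prosocial: float = _E_PROSOCIAL
    e_antisocial: float = _E_ANTISOCIAL
    e_self: float = 0.0
    beta_r: float = _BETA_R

    def __post_init__(self):
        if not (self.e_prosocial > 0.0 > self.e_antisocial):
            raise ValidationError("need e_prosocial > 0 > e_antisocial")
        if self.beta_r <= 0:
            raise ValidationError("beta_r must be > 0")

    def esteem_of(self, trait: str) -> float:
        if trait == "p":
            return self.e_prosocial
        if trait == "n":
            return self.e_antisocial
        raise ValidationError(f"unknown trait {trait!r}")


@dataclass(frozen=True)
class TrustConfig:
    """One fully parameterized iterated game."""

    payoffs: PayoffConfig = field(default_factory=PayoffConfig)
    esteem: EsteemConfig = field(default_factory=EsteemConfig)
    precision_prior: PrecisionPrior = field(default_factory=PrecisionPrior)
    n_rounds: int = 32
    seed: int = 0
    other_true_esteem: str = "n"
    carry_precision: bool = False

    def __post_init__(self):
        if self.n_rounds < 1:
            raise ValidationError("n_rounds must be >= 1")
        if self.other_true_esteem not in TRAITS:
            raise ValidationError("other_true_esteem must be 'p' or 'n'")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def monetary_returns(w: float, g: float, f_self: float, f_other: float) -> tuple[float, float]:
    """Returns of one exchange: invest ``w*f_self``, venture multiplies by ``g``,
    the other sends back the fraction ``f_other`` of the *invested* amount.

    The pot ``w*(1 + f_self*(g-1))`` depends only on the self's investment.
    """
    if w <= 0 or g <= 0:
        raise ValidationError("wage and gain must be > 0")
    if not 0.0 <= f_self <= 1.0:
        raise ValidationError("f_self must lie in [0, 1]")
    if f_other < 0:
        raise ValidationError("f_other must be >= 0")
    invested = w * f_self
    returned = invested * f_other
    r_self = w - invested + returned
    r_other = invested * g - returned
    return r_self, r_other


def augmented_utility(
    player: str,
    u_self: str,
    u_other: str,
    cfg: EsteemConfig,
    payoffs: PayoffConfig,
    trait: str,
) -> float:
    """Esteem-augmented return for one cell of the round matrix.

    The esteem term ``e_self + e_other`` is added when the *player's own*
    action is cooperate and subtracted when it is defect; ``trait`` selects
    the other's esteem value.
    """
    if player not in ("self", "other"):
        raise ValidationError("player must be 'self' or 'other'")
    if u_self not in ACTIONS or u_other not in ACTIONS:
        raise ValidationError("actions must be 'c' or 'd'")
    r_self, r_other = payoffs.returns(u_self, u_other)
    money = r_self if player == "self" else r_other
    own_action = u_self if player == "self" else u_other
    sign = 1.0 if own_action == COOPERATE else -1.0
    esteem_total = cfg.e_self + cfg.esteem_of(trait)
    return cfg.beta_r * money + sign * esteem_total


def opponent_response_distribution(
    u_self: str,
    cfg: EsteemConfig,
    payoffs: PayoffConfig,
    trait: str,
    e_self_believed: float | None = None,
) -> np.ndarray:
    """Softmax response of a naive other over (cooperate, defect).

    The other weighs only its own augmented returns for the current round.
    The self-esteem entering the other's utility is the self's own (neutral)
    self-esteem — the self models the other's beliefs with its own.
    """
    esteem = cfg if e_self_believed is None else replace(cfg, e_self=e_self_believed)
    utilities = [
        augmented_utility("other", u_self, u_other, esteem, payoffs, trait)
        for u_other in ACTIONS
    ]
    return softmax(np.asarray(utilities), beta=1.0)


def _self_utilities(cfg: EsteemConfig, payoffs: PayoffConfig) -> np.ndarray:
    """Self's augmented utilities over the 10 hidden states (start cells 0)."""
    u = np.zeros(len(HIDDEN_LABELS))
    for k, (obs, trait) in enumerate(HIDDEN_LABELS):
        if obs == "start":
            continue
        u[k] = augmented_utility("self", obs[0], obs[1], cfg, payoffs, trait)
    return u


def build_self_model(cfg: TrustConfig, esteem_belief=(0.5, 0.5)) -> GenerativeModel:
    """Assemble the self's 10-state generative model for one round.

    * A: deterministic 5x10 projection onto the observable component.
    * B: one page per self action; from a start state the pair outcome is
      drawn from the modeled other's softmax response given that trait;
      outcome states are absorbing; traits never change.
    * goal prior: softmax (beta = 1; reward sensitivity is already inside the
      utilities) over the 10 augmented self utilities, start states zeroed
      and the rest renormalized.
    * initial belief: ``esteem_belief`` spread over the two start states.
    * horizon 1 with policies (cooperate,) and (defect,).
    """
    belief = np.asarray(esteem_belief, dtype=float)
    if belief.shape != (2,) or not math.isclose(belief.sum(), 1.0, abs_tol=1e-9):
        raise ValidationError("esteem_belief must be a normalized distribution over (p, n)")

    space = StateSpace(HIDDEN_LABELS, OBSERVABLES, conserved_traits=True)
    n = space.n_hidden

    A = np.zeros((space.n_observable, n))
    for k, lab in enumerate(HIDDEN_LABELS):
        A[space.observable_index(lab[0]), k] = 1.0

    B = np.zeros((2, n, n))
    for a_i, u_self in enumerate(ACTIONS):
        for k, (obs, trait) in enumerate(HIDDEN_LABELS):
            if obs == "start":
                resp = opponent_response_distribution(u_self, cfg.esteem, cfg.payoffs, trait)
                for u_other, prob in zip(ACTIONS, resp):
                    tgt = space.hidden_index((u_self + u_other, trait))
                    B[a_i, tgt, k] = prob
            else:  # outcomes are absorbing within a round
                B[a_i, k, k] = 1.0

    utilities = _self_utilities(cfg.esteem, cfg.payoffs)
    goal = softmax(utilities, beta=1.0)
    start_idx = [space.hidden_index(("start", t)) for t in TRAITS]
    goal[start_idx] = 0.0
    goal = goal / goal.sum()

    b0 = np.zeros(n)
    for t, w in zip(TRAITS, belief):
        b0[space.hidden_index(("start", t))] = w

    model = GenerativeModel(
        space=space,
        obs=ObservationModel(A),
        trans=TransitionModel(B, control_labels=ACTIONS),
        goal=OutcomePrior(
            goal,
            beta=1.0,
            returns=utilities,
            never_outcome=tuple(("start", t) for t in TRAITS),
        ),
        prec=cfg.precision_prior,
        horizon=1,
        initial_belief=b0,
        policies=((COOPERATE,), (DEFECT,)),
    )
    report = validate_model(model)
    if report:
        raise ValidationError("constructed trust model is malformed: " + "; ".join(report))
    return model


def self_preference_ordering(cfg: TrustConfig) -> list[tuple]:
    """Hidden-state labels sorted by goal-prior probability, best first."""
    model = build_self_model(cfg)
    order = np.argsort(-model.goal.p_final, kind="stable")
    return [model.space.hidden_labels[i] for i in order]


def calibrate_beta_r(
    payoffs: PayoffConfig,
    esteem: EsteemConfig,
    max_prob: float = 0.8,
    upper: float = 64.0,
    tol: float = 1e-6,
) -> float:
    """Largest reward sensitivity keeping the other's responses well dispersed.

    Finds the largest ``beta_r`` (bisection to ``tol``) such that no entry of
    the other's response distribution exceeds ``max_prob`` over all
    (self action, trait) combinations.  The feasible region need not reach
    down to zero — a large esteem gap alone can breach the cap at low
    sensitivity — so the search first grids the range for feasible points and
    then bisects the upper boundary of the last feasible interval.  Raises if
    no sensitivity is feasible (the esteem scale must then shrink).
    """
    if not 0.5 < max_prob < 1.0:
        raise ValidationError("max_prob must lie in (0.5, 1)")

    def worst(beta: float) -> float:
        e = replace(esteem, beta_r=max(beta, 1e-12))
        probs = [
            opponent_response_distribution(u, e, payoffs, t).max()
            for u in ACTIONS
            for t in TRAITS
        ]
        return max(probs)

    # Each response gap is linear in beta_r, so |gap| <= logit(max_prob) cuts
    # out one interval per (self action, trait) cell; their intersection is the
    # feasible interval.  Locate it exactly, then bisect the upper boundary.
    cap = math.log(max_prob / (1.0 - max_prob))
    lo_feas, hi_feas = 0.0, upper
    for u_self in ACTIONS:
        for trait in TRAITS:
            def gap(beta):
                e = replace(esteem, beta_r=max(beta, 1e-300))
                u = [
                    augmented_utility("other", u_self, uo, e, payoffs, trait)
                    for uo in ACTIONS
                ]
                return u[1] - u[0]

            g0, g1 = gap(0.0), gap(1.0)
            slope = g1 - g0
            if slope == 0.0:
                if abs(g0) > cap:
                    lo_feas, hi_feas = 1.0, 0.0  # empty
            else:
                a, b = sorted(((-cap - g0) / slope, (cap - g0) / slope))
                lo_feas, hi_feas = max(lo_feas, a), min(hi_feas, b)
    if lo_feas > hi_feas:
        raise ValidationError(
            f"infeasible calibration: no sensitivity in [0, {upper}] keeps every "
            f"response probability at or below {max_prob}"
        )
    if hi_feas >= upper:
        return upper
    lo, hi = 0.5 * (lo_feas + hi_feas), upper
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if worst(mid) <= max_prob:
            lo = mid
        else:
            hi = mid
    return float(lo)
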