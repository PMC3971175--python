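"""Experiment configuration: a versioned, human-editable YAML-subset schema.

Every field has a documented default (the standard 2x2 returns, wage 20, gain 3,
gamma prior shape 8 / scale 1, calibrated reward sensitivity); the loader
fills gaps, rejects unknown keys, and logs the provenance of each defaulted
field.  Configs round-trip losslessly through :func:`save_config` /
:func:`load_config`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .generative import PrecisionPrior, ValidationError
from .trust import EsteemConfig, PayoffConfig, TrustConfig, calibrate_beta_r

__all__ = ["SCHEMA_VERSION", "RunConfig", "load_config", "save_config", "config_to_dict"]

log = logging.getLogger("trustinfer.config")

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """A TrustConfig plus engine and output settings."""

    trust: TrustConfig = field(default_factory=TrustConfig)
    tolerance: float = 1e-6
    max_iterations: int = 64
    trace_path: str | None = None
    trace_format: str = "csv"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValidationError("engine.tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValidationError("engine.max_iterations must be >= 1")
        if self.trace_format not in ("csv", "json"):
            raise ValidationError("output.format must be 'csv' or 'json'")


def _take(section: dict, path: str, key: str, default, defaulted: list):
    if key in section:
        return section.pop(key)
    defaulted.append(f"{path}.{key}={default!r}")
    return default


def _reject_unknown(section: dict, path: str):
    if section:
        raise ValidationError(f"unknown config key(s) under {path}: {sorted(section)}")


def _build(data: dict) -> RunConfig:
    defaulted: list[str] = []
    data = dict(data or {})

    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValidationError(f"unsupported schema_version {version!r}")

    pay = dict(data.pop("payoffs", {}) or {})
    kwargs = {}
    kwargs["wage"] = float(_take(pay, "payoffs", "wage", 20.0, defaulted))
    kwargs["gain"] = float(_take(pay, "payoffs", "gain", 3.0, defaulted))
    kwargs["return_self"] = _take(
        pay, "payoffs", "return_self", [[26.0, 10.0], [21.0, 18.0]], defaulted
    )
    kwargs["return_other"] = _take(
        pay, "payoffs", "return_other", [[26.0, 42.0], [7.0, 10.0]], defaulted
    )
    for k in ("fractions_self", "fractions_other"):
        v = pay.pop(k, None)
        if v is not None:
            kwargs[k] = tuple(float(x) for x in v)
    _reject_unknown(pay, "payoffs")
    try:
        payoffs = PayoffConfig(**kwargs)
    except ValidationError as err:
        raise ValidationError(f"payoffs: {err}") from err

    est = dict(data.pop("esteem", {}) or {})
    defaults = EsteemConfig()
    e_p = float(_take(est, "esteem", "e_prosocial", defaults.e_prosocial, defaulted))
    e_n = float(_take(est, "esteem", "e_antisocial", defaults.e_antisocial, defaulted))
    e_s = float(_take(est, "esteem", "e_self", defaults.e_self, defaulted))
    beta_r = est.pop("beta_r", None)
    _reject_unknown(est, "esteem")
    if beta_r is None:
        # calibrate the reward sensitivity so the modeled other's responses
        # stay well dispersed (no response probability above 0.8)
        probe = EsteemConfig(e_prosocial=e_p, e_antisocial=e_n, e_self=e_s, beta_r=1e-6)
        beta_r = calibrate_beta_r(payoffs, probe, max_prob=0.8)
        defaulted.append(f"esteem.beta_r={beta_r:.6g} (calibrated, max response prob 0.8)")
    try:
        esteem = EsteemConfig(e_prosocial=e_p, e_antisocial=e_n, e_self=e_s, beta_r=float(beta_r))
    except ValidationError as err:
        raise ValidationError(f"esteem: {err}") from err

    prec = dict(data.pop("precision_prior", {}) or {})
    shape = float(_take(prec, "precision_prior", "shape", 8.0, defaulted))
    scale = float(_take(prec, "precision_prior", "scale", 1.0, defaulted))
    _reject_unknown(prec, "precision_prior")
    try:
        precision = PrecisionPrior(shape, scale)
    except ValidationError as err:
        raise ValidationError(f"precision_prior: {err}") from err

    game = dict(data.pop("game", {}) or {})
    n_rounds = _take(game, "game", "n_rounds", 32, defaulted)
    seed = _take(game, "game", "seed", 0, defaulted)
    other = _take(game, "game", "other_true_esteem", "n", defaulted)
    carry = bool(_take(game, "game", "carry_precision", False, defaulted))
    _reject_unknown(game, "game")
    if not isinstance(n_rounds, int) or n_rounds < 1:
        raise ValidationError(f"game.n_rounds must be a positive integer, got {n_rounds!r}")
    try:
        trust = TrustConfig(
            payoffs=payoffs,
            esteem=esteem,
            precision_prior=precision,
            n_rounds=n_rounds,
            seed=int(seed),
            other_true_esteem=other,
            carry_precision=carry,
        )
    except ValidationError as err:
        raise ValidationError(f"game: {err}") from err

    eng = dict(data.pop("engine", {}) or {})
    tol = float(_take(eng, "engine", "tolerance", 1e-6, defaulted))
    max_iter = int(_take(eng, "engine", "max_iterations", 64, defaulted))
    _reject_unknown(eng, "engine")

    out = dict(data.pop("output", {}) or {})
    trace_path = _take(out, "output", "trace_path", None, defaulted)
    trace_format = _take(out, "output", "format", "csv", defaulted)
    _reject_unknown(out, "output")

    log_level = data.pop("log_level", "INFO")
    _reject_unknown(data, "<root>")

    for line in defaulted:
        log.debug("config default applied: %s", line)

    return RunConfig(
        trust=trust,
        tolerance=tol,
        max_iterations=max_iter,
        trace_path=trace_path,
        trace_format=trace_format,
        log_level=str(log_level),
    )


def load_config(path=None, data: dict | None = None) -> RunConfig:
    """Load and validate a run configuration from YAML (or a parsed dict)."""
    if path is not None:
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text) or {}
        except yaml.YAMLError as err:
            raise ValidationError(f"config parse error in {path}: {err}") from err
    return _build(data or {})


def config_to_dict(cfg: RunConfig) -> dict:
    """Full explicit dict form of a RunConfig (inverse of the loader)."""
    t = cfg.trust
    d = {
        "schema_version": SCHEMA_VERSION,
        "game": {
            "n_rounds": t.n_rounds,
            "seed": t.seed,
            "other_true_esteem": t.other_true_esteem,
            "carry_precision": t.carry_precision,
        },
        "payoffs": {
            "wage": t.payoffs.wage,
            "gain": t.payoffs.gain,
            "return_self": [list(r) for r in t.payoffs.return_self],
            "return_other": [list(r) for r in t.payoffs.return_other],
        },
        "esteem": {
            "e_prosocial": t.esteem.e_prosocial,
            "e_antisocial": t.esteem.e_antisocial,
            "e_self": t.esteem.e_self,
            "beta_r": t.esteem.beta_r,
        },
        "precision_prior": {
            "shape": t.precision_prior.shape,
            "scale": t.precision_prior.scale,
        },
        "engine": {
            "tolerance": cfg.tolerance,
            "max_iterations": cfg.max_iterations,
        },
        "output": {
            "trace_path": cfg.trace_path,
            "format": cfg.trace_format,
        },
        "log_level": cfg.log_level,
    }
    if t.payoffs.fractions_self is not None:
        d["payoffs"]["fractions_self"] = list(t.payoffs.fractions_self)
        d["payoffs"]["fractions_other"] = list(t.payoffs.fractions_other)
    return d


def save_config(cfg: RunConfig, path) -> None:
    """Write a config as YAML; ``load_config`` recovers an equal RunConfig."""
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
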