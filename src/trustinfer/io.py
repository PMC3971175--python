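"""Trace serialization: tidy per-round CSV and lossless JSON.

CSV is the canonical analysis output (one row per round, stable column
order, floats at 12 significant digits).  JSON additionally embeds the full
configuration, seed and version stamp, so a game can be reconstructed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import RunConfig, config_to_dict, load_config
from .generative import ValidationError
from .play import GameTrace, RoundRecord

__all__ = ["CSV_COLUMNS", "write_trace", "read_trace"]

CSV_COLUMNS = (
    "round",
    "action_self",
    "action_other",
    "observation",
    "p_prosocial",
    "p_antisocial",
    "p_cooperate",
    "gamma_hat",
    "free_energy",
    "n_iter",
    "gamma_hat_start",
)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _rows(trace: GameTrace):
    for r in trace.records:
        yield {
            "round": r.round_index + 1,
            "action_self": r.action_self,
            "action_other": r.action_other,
            "observation": r.observation_label,
            "p_prosocial": r.trait_posterior[0],
            "p_antisocial": r.trait_posterior[1],
            "p_cooperate": r.policy_probs[0],
            "gamma_hat": r.gamma_hat,
            "free_energy": r.free_energy_final,
            "n_iter": r.n_vb_iterations,
            "gamma_hat_start": r.gamma_hat_start,
        }


def write_trace(trace: GameTrace, path, fmt: str = "csv") -> None:
    """Serialize a game trace to ``path`` as CSV or JSON."""
    path = Path(path)
    if fmt == "csv":
        lines = [",".join(CSV_COLUMNS)]
        for row in _rows(trace):
            lines.append(
                ",".join(
                    _fmt(row[c]) if isinstance(row[c], float) else str(row[c])
                    for c in CSV_COLUMNS
                )
            )
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = {
            "version": trace.version,
            "seed": trace.seed,
            "config": config_to_dict(RunConfig(trust=trace.config)),
            "records": [
                {
                    "round_index": r.round_index,
                    "action_self": r.action_self,
                    "action_other": r.action_other,
                    "observation_label": r.observation_label,
                    "trait_posterior": [float(x) for x in r.trait_posterior],
                    "policy_probs": [float(x) for x in r.policy_probs],
                    "gamma_hat": r.gamma_hat,
                    "gamma_hat_start": r.gamma_hat_start,
                    "free_energy_final": r.free_energy_final,
                    "n_vb_iterations": r.n_vb_iterations,
                }
                for r in trace.records
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        raise ValidationError(f"unknown trace format {fmt!r}")


def read_trace(path, fmt: str = "csv"):
    """Invert :func:`write_trace`.

    CSV yields the tidy :class:`pandas.DataFrame`; JSON reconstructs the full
    :class:`GameTrace`.
    """
    path = Path(path)
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        payload = json.loads(path.read_text())
        run_cfg = load_config(data=payload["config"])
        records = [
            RoundRecord(
                round_index=r["round_index"],
                action_self=r["action_self"],
                action_other=r["action_other"],
                observation_label=r["observation_label"],
                trait_posterior=tuple(r["trait_posterior"]),
                policy_probs=tuple(r["policy_probs"]),
                gamma_hat=r["gamma_hat"],
                gamma_hat_start=r["gamma_hat_start"],
                free_energy_final=r["free_energy_final"],
                n_vb_iterations=r["n_vb_iterations"],
            )
            for r in payload["records"]
        ]
        return GameTrace(
            config=run_cfg.trust,
            seed=payload["seed"],
            records=records,
            version=payload["version"],
        )
    raise ValidationError(f"unknown trace format {fmt!r}")
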