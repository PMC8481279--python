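"""Readers and writers for the package's file formats.

Trial datasets travel as long-format CSV with one row per (trial, round,
seat): columns ``trial_id, round, seat_id, role, strategy,
stage2_start, consensus_round``.  Rounds are 1-based in files (matching
the experiment's round 1..24) and strategies are ``0``, ``1`` or ``NA``.
Campaign replicates are tidy CSV; summaries, calibration results and run
manifests are JSON; configurations are YAML.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trials import TrialRecord

__all__ = [
    "read_trials_csv",
    "write_trials_csv",
    "read_fraction_series_csv",
    "load_yaml_config",
    "write_json",
    "RunManifest",
]

_TRIAL_COLUMNS = ["trial_id", "round", "seat_id", "role",
                  "strategy", "stage2_start", "consensus_round"]


def write_trials_csv(records: list[TrialRecord], path) -> None:
    """Write trials in the long-format schema (deterministic row order)."""
    rows = []
    for rec in records:
        s2 = "" if rec.stage2_start is None else rec.stage2_start
        cr = "" if rec.consensus_round is None else rec.consensus_round
        for t in range(rec.n_rounds):
            for seat in range(rec.n_seats):
                val = rec.strategies[t, seat]
                rows.append({
                    "trial_id": rec.trial_id,
                    "round": t + 1,
                    "seat_id": seat,
                    "role": rec.roles[seat],
                    "strategy": "NA" if np.isnan(val) else int(val),
                    "stage2_start": s2,
                    "consensus_round": cr,
                })
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials_csv(path) -> list[TrialRecord]:
    """Read the long-format trial schema back into records.

    Raises a ``ValueError`` naming the offending row for any strategy
    value outside {0, 1, NA}.
    """
    df = pd.read_csv(path, dtype={"strategy": str}, keep_default_na=False)
    missing = set(_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    records = []
    for trial_id, grp in df.groupby("trial_id", sort=False):
        n_rounds = int(grp["round"].max())
        seats = sorted(grp["seat_id"].unique())
        n_seats = len(seats)
        strategies = np.full((n_rounds, n_seats), np.nan)
        roles = [""] * n_seats
        for row in grp.itertuples():
            raw = row.strategy.strip()
            if raw in ("NA", ""):
                val = np.nan
            elif raw in ("0", "1", "0.0", "1.0"):
                val = float(raw)
            else:
                raise ValueError(
                    f"invalid strategy {raw!r} at row {row.Index} "
                    f"(trial {trial_id}, round {row.round}, seat {row.seat_id})"
                )
            strategies[int(row.round) - 1, int(row.seat_id)] = val
            roles[int(row.seat_id)] = row.role

        def _opt(col: str) -> int | None:
            raw = str(grp[col].iloc[0]).strip()
            return None if raw in ("", "NA", "nan") else int(float(raw))

        records.append(TrialRecord(
            trial_id=str(trial_id),
            strategies=strategies,
            roles=roles,
            stage2_start=_opt("stage2_start"),
            consensus_round=_opt("consensus_round"),
        ))
    return records


def read_fraction_series_csv(path) -> np.ndarray:
    """Read an adopter-fraction series (column ``fraction``, one row per
    round starting at t=0)."""
    df = pd.read_csv(path)
    if "fraction" not in df.columns:
        raise ValueError("fraction-series CSV needs a 'fraction' column")
    return df["fraction"].to_numpy(dtype=float)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


@dataclass
class RunManifest:
    """Provenance record written next to every CLI artifact."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        write_json(self.__dict__, path)
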