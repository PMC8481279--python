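"""Committed-minority scenarios: single runs and Monte Carlo campaigns.

A run starts with the committed minority on the alternative and every
regular agent on the status quo, applies synchronous logit-learning
updates, and stops at full diffusion (population-wide adopter fraction at
or above the full-diffusion threshold) or at the step cap (censored).
Campaigns replicate runs over a grid of population specs and aggregate
the diffusion observables with normal-approximation confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import synchronous_step
from .metrics import DiffusionSummary, summarize_trajectory
from .params import PopulationSpec, PopulationState

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "CampaignResults",
    "build_population",
    "run_simulation",
    "run_campaign",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class SimulationConfig:
    """Run controls.

    ``max_steps`` caps every run at 50,000 rounds by default; a run that
    never reaches ``full_diffusion_threshold`` (0.99) within the cap is
    censored.  ``takeoff_threshold`` (0.4; robustness variants 0.35/0.45)
    only affects the summary statistics, not the stopping rule.
    """

    max_steps: int = 50_000
    full_diffusion_threshold: float = 0.99
    takeoff_threshold: float = 0.4
    seed: int | None = None
    record_full_history: bool = False

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not 0 < self.takeoff_threshold < self.full_diffusion_threshold <= 1:
            raise ValueError(
                "need 0 < takeoff_threshold < full_diffusion_threshold <= 1"
            )


@dataclass(eq=False)
class Trajectory:
    """One simulated run.

    Stores the adopter-fraction series and per-agent switch counters —
    sufficient for every diffusion observable — plus the full round-by-
    agent history only when requested.
    """

    fractions: np.ndarray
    switch_counts: np.ndarray
    final_x: np.ndarray
    censored: bool
    spec: PopulationSpec
    config: SimulationConfig
    seed: int | None
    history: np.ndarray | None = None

    def summary(self, takeoff_threshold: float | None = None) -> DiffusionSummary:
        return summarize_trajectory(self, takeoff_threshold)


def build_population(spec: PopulationSpec) -> PopulationState:
    """Initial state: committed agents on the alternative, regulars on the
    status quo, and a neutral trend (``x_prev = x_curr``)."""
    x0 = spec.committed_mask.astype(np.int8)
    return PopulationState(t=0, x_curr=x0, x_prev=x0.copy(), committed_mask=spec.committed_mask)


def run_simulation(spec: PopulationSpec, config: SimulationConfig) -> Trajectory:
    """Run one trajectory to full diffusion or the step cap.

    Identical (spec, config) including the seed give bit-identical
    trajectories: one uniform variate per regular agent per round is
    consumed in fixed agent order.
    """
    rng = np.random.default_rng(config.seed)
    state = build_population(spec)
    fractions = [state.adopter_fraction]
    switch_counts = np.zeros(spec.n, dtype=np.int64)
    history = [state.x_curr.copy()] if config.record_full_history else None

    censored = False
    if fractions[0] < config.full_diffusion_threshold:
        for _ in range(config.max_steps):
            prev_x = state.x_curr
            state = synchronous_step(state, spec, rng)
            switch_counts += np.abs(state.x_curr.astype(np.int64) - prev_x.astype(np.int64))
            fractions.append(state.adopter_fraction)
            if history is not None:
                history.append(state.x_curr.copy())
            if fractions[-1] >= config.full_diffusion_threshold:
                break
        else:
            censored = True

    return Trajectory(
        fractions=np.asarray(fractions),
        switch_counts=switch_counts,
        final_x=state.x_curr.copy(),
        censored=censored,
        spec=spec,
        config=config,
        seed=config.seed,
        history=np.asarray(history) if history is not None else None,
    )


def _spawn_seeds(master_seed: int | None, count: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(count) % (2**31)]


@dataclass
class CampaignResults:
    """Replicate-level records plus per-cell aggregation of a campaign."""

    replicates: pd.DataFrame
    config: SimulationConfig
    reps: int

    def to_frame(self) -> pd.DataFrame:
        return self.replicates.copy()

    def summary(self) -> pd.DataFrame:
        """Per-cell means with 95% normal-approximation half-widths.

        Censored runs are excluded from the T̄/ΔT/switching-rate means and
        counted in ``n_censored``; cells with fewer than two uncensored
        replicates get NaN half-widths (``ci_defined`` False).
        """
        rows = []
        for cell, grp in self.replicates.groupby("cell", sort=True):
            ok = grp[~grp["censored"]]
            m = len(ok)
            row = {
                "cell": cell,
                "n": grp["n"].iloc[0],
                "committed_count": grp["committed_count"].iloc[0],
                "rho_e": grp["rho_e"].iloc[0],
                "n_reps": len(grp),
                "n_censored": int(grp["censored"].sum()),
                "ci_defined": m >= 2,
            }
            for col in ("t_bar", "delta_t", "mean_y"):
                vals = ok[col].to_numpy(dtype=float)
                row[f"mean_{col}"] = vals.mean() if m else np.nan
                row[f"ci95_{col}"] = (
                    _Z95 * vals.std(ddof=1) / np.sqrt(m) if m >= 2 else np.nan
                )
            row["rounds_per_switch"] = (
                1.0 / row["mean_mean_y"] if m and row["mean_mean_y"] > 0 else np.nan
            )
            rows.append(row)
        return pd.DataFrame(rows)


def run_campaign(
    spec_grid: list[PopulationSpec],
    config: SimulationConfig,
    reps: int,
) -> CampaignResults:
    """Monte Carlo campaign over a grid of population specs.

    Child seeds for each (cell, replicate) derive deterministically from
    ``config.seed``, so campaigns are reproducible and cells independent.
    """
    if not spec_grid:
        raise ValueError("spec_grid must contain at least one PopulationSpec")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seeds = _spawn_seeds(config.seed, len(spec_grid) * reps)
    records = []
    idx = 0
    for cell, spec in enumerate(spec_grid):
        for rep in range(reps):
            cfg = SimulationConfig(
                max_steps=config.max_steps,
                full_diffusion_threshold=config.full_diffusion_threshold,
                takeoff_threshold=config.takeoff_threshold,
                seed=seeds[idx],
                record_full_history=False,
            )
            idx += 1
            traj = run_simulation(spec, cfg)
            summ = traj.summary()
            records.append(
                {
                    "cell": cell,
                    "rep": rep,
                    "seed": cfg.seed,
                    "n": spec.n,
                    "committed_count": spec.committed_count,
                    "rho_e": spec.rho_e,
                    "t_star": summ.t_star,
                    "t_bar": summ.t_bar,
                    "delta_t": summ.delta_t,
                    "censored": summ.censored,
                    "mean_y": (
                        float(np.nanmean(summ.y))
                        if summ.y.size and not np.isnan(summ.y).all()
                        else np.nan
                    ),
                }
            )
    return CampaignResults(replicates=pd.DataFrame(records), config=config, reps=reps)
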