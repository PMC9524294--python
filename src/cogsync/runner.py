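"""The 2x2 model-variant grid (Learn x Sync) over many seeded agents.

Each *agent* is one seeded experiment design plus one pass of a model
variant through it, with weights persisting across trials.  A grid run
shares each agent's design across all four variants (the variants are
counterparts seeing identical trial sequences) and differs only in the
learning rate (0 vs ``beta_learn``) and in whether the MFC amplitude may
build up within a trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .engine import make_tags, run_trial
from .learning import RWParams, rw_update
from .paradigms import ExperimentDesign, generate_design
from typing import Sequence

__all__ = ["VariantSpec", "VARIANTS", "run_agent", "run_grid", "summarize"]


@dataclass(frozen=True)
class VariantSpec:
    """One cell of the Learn x Sync grid."""

    learn: bool
    sync: bool

    @property
    def name(self) -> str:
        return ("Sync" if self.sync else "NoSync") + "/" + (
            "Learn" if self.learn else "NoLearn"
        )


VARIANTS: tuple[VariantSpec, ...] = (
    VariantSpec(learn=False, sync=False),
    VariantSpec(learn=True, sync=False),
    VariantSpec(learn=False, sync=True),
    VariantSpec(learn=True, sync=True),
)

_VARIANT_KEYS = {
    "nosync_nolearn": VARIANTS[0],
    "nosync_learn": VARIANTS[1],
    "sync_nolearn": VARIANTS[2],
    "sync_learn": VARIANTS[3],
}


def variant_from_key(key: str) -> VariantSpec:
    try:
        return _VARIANT_KEYS[key]
    except KeyError:
        raise ValueError(
            f"unknown variant {key!r}; choose from {sorted(_VARIANT_KEYS)}"
        ) from None


def run_agent(
    design: ExperimentDesign,
    variant: VariantSpec,
    seed: int | np.random.SeedSequence,
    config: SimulationConfig | None = None,
    agent: int = 0,
    return_weights: bool = False,
):
    """Run one variant through one design; returns the per-trial table.

    Weights start from the design's initial matrix and persist across all
    trials and blocks; with ``variant.learn`` the Rescorla-Wagner update is
    applied after every trial, otherwise the matrix never changes.
    """
    config = config or SimulationConfig()
    cfg = config.engine_config()
    rng = np.random.default_rng(seed)
    ctrl = config.control_state(sync_enabled=variant.sync)
    beta = config.beta_learn if variant.learn else 0.0
    W = design.initial_weights.copy()

    rows = []
    for trial in design.trials:
        tags = make_tags(design.paradigm, trial, variant.sync, design.n_inputs)
        res = run_trial(W, trial, tags, ctrl, cfg, rng)
        if beta > 0.0:
            target = np.zeros(design.n_outputs)
            target[trial.target_output] = 1.0
            W = rw_update(W, res.x_in_max, res.x_out_max, RWParams(beta, target))
        row = {
            "agent": agent,
            "paradigm": design.paradigm,
            "variant": variant.name,
            "block": trial.block,
            "trial": trial.index,
            "stimulus_id": trial.stimulus_id,
            "target": trial.target_output,
            "rt": res.rt,
            "response": res.response,
            "correct": res.correct,
            "omission": res.omission,
            "theta_power": res.theta_power,
        }
        for k, v in trial.labels.items():
            if k != "block_units":
                row[k] = v
        rows.append(row)
    table = pd.DataFrame(rows)
    table["error"] = (~table["correct"]).astype(float)
    if return_weights:
        return table, W
    return table


def run_grid(
    paradigm: str,
    n_agents: int,
    base_seed: int,
    config: SimulationConfig | None = None,
    variants: Sequence[VariantSpec] = VARIANTS,
) -> pd.DataFrame:
    """Run the variant grid over ``n_agents`` seeded designs.

    Agent ``a`` uses design seed ``base_seed + a``; all variants of an
    agent share that design (identical stimuli and trial order).  For the
    Stroop paradigm the starting task alternates across agents.  Engine
    randomness is a per-(agent, variant) substream of the agent seed, so
    runs are order-independent.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    config = config or SimulationConfig()
    tables = []
    for a in range(n_agents):
        agent_seed = base_seed + a
        kwargs = config.generator_kwargs(paradigm)
        if paradigm == "stroop":
            kwargs["start_task"] = "word" if a % 2 == 0 else "color"
        design = generate_design(paradigm, agent_seed, **kwargs)
        for v_idx, variant in enumerate(variants):
            ss = np.random.SeedSequence((agent_seed, v_idx))
            tables.append(
                run_agent(design, variant, ss, config=config, agent=a)
            )
    return pd.concat(tables, ignore_index=True)


_METRICS = {"rt": "rt", "error": "error", "theta_power": "theta_power"}


def summarize(
    table: pd.DataFrame,
    grouping: Sequence[str],
    metrics: Sequence[str] = ("rt", "error", "theta_power"),
) -> pd.DataFrame:
    """Across-agent means and 95% CIs of per-agent metric means.

    Per-agent means are taken first within each group, then averaged over
    agents; the CI half-width is ``1.96 * sd / sqrt(n)`` with the sample
    standard deviation over agents.
    """
    grouping = list(grouping)
    missing = [g for g in grouping if g not in table.columns]
    if missing:
        raise ValueError(f"grouping labels not in table: {missing}")
    if table.empty:
        raise ValueError("cannot summarize an empty table")
    per_agent = table.groupby(["agent"] + grouping, observed=True)[list(metrics)].mean()
    rows = []
    for key, grp in per_agent.groupby(grouping, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        n = len(grp)
        row = dict(zip(grouping, key))
        row["n"] = n
        for m in metrics:
            vals = grp[m].to_numpy()
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            row[f"mean_{m}"] = mean
            row[f"ci95_{m}"] = 1.96 * sd / np.sqrt(n) if n > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
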