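"""Seeded generators for the three action-control experiment designs.

Each generator is a pure function of its seed and returns an
:class:`ExperimentDesign`: an ordered list of trials plus layer sizes and
the initial weight matrix.  The designs emulate the statistical structure
of the original experiments (stimulus counts, block schedules, repetition
and congruency structure); trial orders are seeded shuffles rather than
replays of human participants' sequences.

Paradigms
---------
extensive
    36 single-unit stimuli (one repeating set of 4, eight novel sets of 4)
    over 16 blocks x 32 trials; 2 stimuli per block map to each of the two
    responses; half the blocks carry the repeating set with a constant
    mapping.  Initial weights ~ U(0, 0.1) over the 36 x 2 matrix.
stroop
    4 words x 4 colors = 16 stimuli; inputs 1-4 words, 5-8 colors, 9-10
    task units; 32 blocks x 16 trials with the relevant dimension constant
    over runs of 4 blocks.  Word->matching-output weights are hard-biased
    above color->matching-output weights so the reading advantage is built
    in; everything else ~ U(0, 0.01).
wcst
    4 colors x 4 numbers x 4 shapes = 64 stimuli; inputs 1-4 / 5-8 / 9-12
    per dimension; 36 blocks x 64 trials with the relevant dimension
    rotating color -> number -> shape every 3 blocks, four full cycles.
    Initial weights ~ U(0, 0.01).

Output unit ``k`` corresponds to value ``k`` of every stimulus dimension,
which is what makes "a dimension points to a response" well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "ExperimentDesign",
    "gen_extensive",
    "gen_stroop",
    "gen_wcst",
    "congruency_level",
    "validate_design",
    "design_to_frame",
    "design_from_frame",
    "save_design",
    "load_design",
]

PARADIGMS = ("extensive", "stroop", "wcst")

N_VALUES = 4  # values per stimulus dimension in stroop/wcst
WCST_DIMS = ("color", "number", "shape")


@dataclass(frozen=True)
class TrialRecord:
    """One trial: active inputs, desired response and condition labels."""

    index: int
    block: int
    stimulus_id: str
    active_inputs: tuple[int, ...]
    target_output: int
    labels: dict[str, Any] = field(default_factory=dict)


@dataclass
class ExperimentDesign:
    paradigm: str
    trials: list[TrialRecord]
    n_inputs: int
    n_outputs: int
    initial_weights: np.ndarray
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# Study 1: extensive learning


def gen_extensive(
    seed: int,
    n_blocks: int = 16,
    reps_per_stimulus: int = 8,
    init_weight_max: float = 0.1,
) -> ExperimentDesign:
    """Extensive-learning design: 16 blocks x 32 trials, 36 unique stimuli.

    Stimuli 0-3 form the repeating set, carried by half the blocks with a
    constant response mapping; each of the remaining 8 blocks introduces a
    fresh set of 4 stimuli.  Within every block each stimulus appears
    ``reps_per_stimulus`` times in shuffled order, and 2 stimuli map to
    each response side.
    """
    rng = np.random.default_rng(seed)
    n_inputs, n_outputs = 4 + 4 * (n_blocks // 2), 2
    W0 = rng.uniform(0.0, init_weight_max, size=(n_inputs, n_outputs))

    repeating = [True] * (n_blocks // 2) + [False] * (n_blocks // 2)
    rng.shuffle(repeating)
    repeating_set = (0, 1, 2, 3)
    repeating_map = dict(zip(repeating_set, rng.permutation([0, 0, 1, 1])))

    trials: list[TrialRecord] = []
    seen_total: dict[int, int] = {}
    next_novel = 4
    for b, is_rep in enumerate(repeating):
        if is_rep:
            stim_set, mapping = repeating_set, repeating_map
        else:
            stim_set = tuple(range(next_novel, next_novel + 4))
            next_novel += 4
            mapping = dict(zip(stim_set, rng.permutation([0, 0, 1, 1])))
        order = rng.permutation(np.repeat(stim_set, reps_per_stimulus))
        seen_block: dict[int, int] = {}
        for s in order:
            s = int(s)
            seen_block[s] = seen_block.get(s, 0) + 1
            seen_total[s] = seen_total.get(s, 0) + 1
            trials.append(
                TrialRecord(
                    index=len(trials),
                    block=b,
                    stimulus_id=f"S{s:02d}",
                    active_inputs=(s,),
                    target_output=int(mapping[s]),
                    labels={
                        "condition": "repeating" if is_rep else "novel",
                        "stimulus_number": seen_block[s],
                        "times_seen": seen_total[s],
                        "block_units": stim_set,
                    },
                )
            )
    return ExperimentDesign("extensive", trials, n_inputs, n_outputs, W0, seed)


# ---------------------------------------------------------------------------
# Study 2: Stroop


def gen_stroop(
    seed: int,
    start_task: str = "word",
    n_runs: int = 8,
    blocks_per_run: int = 4,
    w_word: float = 0.3,
    w_color: float = 0.1,
    init_weight_max: float = 0.01,
) -> ExperimentDesign:
    """Stroop design: 32 blocks x 16 word-x-color stimuli, 4-block task runs.

    Inputs 0-3 are word units, 4-7 color units, 8-9 task units (word/color).
    Exactly three inputs are active per trial.  Weights from word unit k to
    output k start at ``w_word`` and from color unit k to output k at
    ``w_color`` (word reading prepotent); all other weights ~ U(0, 0.01).
    """
    if start_task not in ("word", "color"):
        raise ValueError("start_task must be 'word' or 'color'")
    rng = np.random.default_rng(seed)
    n_inputs, n_outputs = 10, 4
    W0 = rng.uniform(0.0, init_weight_max, size=(n_inputs, n_outputs))
    for k in range(N_VALUES):
        W0[k, k] = w_word
        W0[N_VALUES + k, k] = w_color

    stimuli = [(w, c) for w in range(N_VALUES) for c in range(N_VALUES)]
    tasks = [start_task, "color" if start_task == "word" else "word"]
    trials: list[TrialRecord] = []
    for b in range(n_runs * blocks_per_run):
        run = b // blocks_per_run
        relevant = tasks[run % 2]
        order = rng.permutation(len(stimuli))
        for idx in order:
            w, c = stimuli[idx]
            task_unit = 8 if relevant == "word" else 9
            trials.append(
                TrialRecord(
                    index=len(trials),
                    block=b,
                    stimulus_id=f"w{w}c{c}",
                    active_inputs=(w, N_VALUES + c, task_unit),
                    target_output=w if relevant == "word" else c,
                    labels={
                        "relevant_dimension": relevant,
                        "congruent": w == c,
                        "task_run": run + 1,
                        "block_in_run": b % blocks_per_run + 1,
                    },
                )
            )
    return ExperimentDesign("stroop", trials, n_inputs, n_outputs, W0, seed)


# ---------------------------------------------------------------------------
# Study 3: WCST


def congruency_level(stimulus: tuple[int, int, int], relevant_dim: str) -> str:
    """Congruency of a (color, number, shape) triple given the relevant dimension.

    none
        both irrelevant values equal the correct response value;
    medium
        exactly one irrelevant value does;
    high_same
        neither does and the two irrelevant values agree on one incorrect
        response;
    high_different
        neither does and they point to two different incorrect responses.
    """
    if relevant_dim not in WCST_DIMS:
        raise ValueError(f"unknown dimension: {relevant_dim!r}")
    values = dict(zip(WCST_DIMS, stimulus))
    correct = values[relevant_dim]
    others = [v for d, v in values.items() if d != relevant_dim]
    n_match = sum(v == correct for v in others)
    if n_match == 2:
        return "none"
    if n_match == 1:
        return "medium"
    return "high_same" if others[0] == others[1] else "high_different"


def gen_wcst(
    seed: int,
    n_cycles: int = 4,
    blocks_per_dim: int = 3,
    init_weight_max: float = 0.01,
) -> ExperimentDesign:
    """WCST design: 36 blocks x 64 stimuli, dimension rotating every 3 blocks.

    Inputs 0-3 color, 4-7 number, 8-11 shape; no task units (the tagged
    dimension is scheduled, not cued).  Targets follow the relevant
    dimension's value; every trial is labelled with its congruency level.
    """
    rng = np.random.default_rng(seed)
    n_inputs, n_outputs = 12, 4
    W0 = rng.uniform(0.0, init_weight_max, size=(n_inputs, n_outputs))

    stimuli = [
        (c, n, s)
        for c in range(N_VALUES)
        for n in range(N_VALUES)
        for s in range(N_VALUES)
    ]
    trials: list[TrialRecord] = []
    n_blocks = n_cycles * len(WCST_DIMS) * blocks_per_dim
    for b in range(n_blocks):
        dim_run = b // blocks_per_dim  # 0..11
        relevant = WCST_DIMS[dim_run % len(WCST_DIMS)]
        order = rng.permutation(len(stimuli))
        for idx in order:
            c, n, s = stimuli[idx]
            target = {"color": c, "number": n, "shape": s}[relevant]
            trials.append(
                TrialRecord(
                    index=len(trials),
                    block=b,
                    stimulus_id=f"c{c}n{n}s{s}",
                    active_inputs=(c, N_VALUES + n, 2 * N_VALUES + s),
                    target_output=target,
                    labels={
                        "relevant_dimension": relevant,
                        "congruency_level": congruency_level((c, n, s), relevant),
                        "dim_run": dim_run + 1,
                        "block_in_run": b % blocks_per_dim + 1,
                        "cycle": dim_run // len(WCST_DIMS) + 1,
                    },
                )
            )
    return ExperimentDesign("wcst", trials, n_inputs, n_outputs, W0, seed)


GENERATORS = {"extensive": gen_extensive, "stroop": gen_stroop, "wcst": gen_wcst}


def generate_design(paradigm: str, seed: int, **kwargs: Any) -> ExperimentDesign:
    """Dispatch to the paradigm's generator."""
    try:
        gen = GENERATORS[paradigm]
    except KeyError:
        raise ValueError(f"unknown paradigm: {paradigm!r}") from None
    return gen(seed, **kwargs)


# ---------------------------------------------------------------------------
# Validation and serialization


def validate_design(design: ExperimentDesign) -> None:
    """Check the structural invariants of a design; raise ValueError if violated."""
    n_active = {"extensive": 1, "stroop": 3, "wcst": 3}[design.paradigm]
    if design.initial_weights.shape != (design.n_inputs, design.n_outputs):
        raise ValueError("initial weight shape does not match layer sizes")
    for t in design.trials:
        if len(t.active_inputs) != n_active:
            raise ValueError(f"trial {t.index}: expected {n_active} active inputs")
        if not all(0 <= i < design.n_inputs for i in t.active_inputs):
            raise ValueError(f"trial {t.index}: active input out of range")
        if not 0 <= t.target_output < design.n_outputs:
            raise ValueError(f"trial {t.index}: target out of range")
    counts = {}
    if design.paradigm == "extensive":
        if design.n_trials != 512:
            raise ValueError("extensive design must have 512 trials")
        for t in design.trials:
            counts[(t.block, t.stimulus_id)] = counts.get((t.block, t.stimulus_id), 0) + 1
        if any(c != 8 for c in counts.values()):
            raise ValueError("every stimulus must appear 8 times in its block")
    elif design.paradigm in ("stroop", "wcst"):
        for t in design.trials:
            counts[(t.block, t.stimulus_id)] = counts.get((t.block, t.stimulus_id), 0) + 1
        if any(c != 1 for c in counts.values()):
            raise ValueError("each block must be a permutation of the stimulus set")


def design_to_frame(design: ExperimentDesign) -> pd.DataFrame:
    """Flatten the trial list to a DataFrame (one row per trial)."""
    rows = []
    for t in design.trials:
        row = {
            "index": t.index,
            "block": t.block,
            "stimulus_id": t.stimulus_id,
            "active_inputs": ",".join(map(str, t.active_inputs)),
            "target_output": t.target_output,
        }
        for k, v in t.labels.items():
            row[k] = ",".join(map(str, v)) if isinstance(v, tuple) else v
        rows.append(row)
    return pd.DataFrame(rows)


_TUPLE_LABELS = {"block_units"}
_INT_LABELS = {"stimulus_number", "times_seen", "task_run", "block_in_run", "dim_run", "cycle"}


def design_from_frame(
    frame: pd.DataFrame,
    paradigm: str,
    n_inputs: int,
    n_outputs: int,
    initial_weights: np.ndarray,
    seed: int,
) -> ExperimentDesign:
    """Rebuild an ExperimentDesign from its flattened trial table."""
    base = {"index", "block", "stimulus_id", "active_inputs", "target_output"}
    label_cols = [c for c in frame.columns if c not in base]
    trials = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        labels: dict[str, Any] = {}
        for c in label_cols:
            v = d[c]
            if c in _TUPLE_LABELS:
                v = tuple(int(x) for x in str(v).split(","))
            elif c in _INT_LABELS:
                v = int(v)
            elif isinstance(v, (bool, np.bool_)):
                v = bool(v)
            elif str(v) in ("True", "False"):
                v = str(v) == "True"
            labels[c] = v
        trials.append(
            TrialRecord(
                index=int(d["index"]),
                block=int(d["block"]),
                stimulus_id=str(d["stimulus_id"]),
                active_inputs=tuple(int(x) for x in str(d["active_inputs"]).split(",")),
                target_output=int(d["target_output"]),
                labels=labels,
            )
        )
    return ExperimentDesign(paradigm, trials, n_inputs, n_outputs, initial_weights, seed)


def save_design(design: ExperimentDesign, path: str | Path) -> None:
    """Write a design as ``<path>.trials.csv`` and ``<path>.weights.csv``."""
    path = Path(path)
    design_to_frame(design).to_csv(
        path.with_suffix(".trials.csv"), index=False
    )
    header = f"paradigm={design.paradigm} seed={design.seed} shape={design.initial_weights.shape}"
    np.savetxt(
        path.with_suffix(".weights.csv"),
        design.initial_weights,
        delimiter=",",
        header=header,
        fmt="%.17g",
    )


def load_design(path: str | Path, paradigm: str, seed: int) -> ExperimentDesign:
    """Reload a design saved by :func:`save_design` (bit-exact round trip)."""
    path = Path(path)
    frame = pd.read_csv(path.with_suffix(".trials.csv"))
    W0 = np.loadtxt(path.with_suffix(".weights.csv"), delimiter=",")
    if W0.ndim == 1:
        W0 = W0[:, None]
    return design_from_frame(frame, paradigm, W0.shape[0], W0.shape[1], W0, seed)
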