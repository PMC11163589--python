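"""Randomized, balanced trial schedules for the looming-bias experiments.

The adult design crosses 2 attentional states (passive, active) x 2 distance
cues (intensity, spectral) x 4 motion classes (looming, receding, and static
trials rendered with either the near or the far onset), yielding 16 condition
cells. The newborn design is passive-only with 4 cells (cue x moving/static).
Cue type and presentation side are constant within a block; the moving/static
mix is randomized within blocks. The cue-transition ("change") time of moving
trials is jittered uniformly within +/-50 ms of 600 ms to reduce temporal
predictability of the change event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

Attention = Literal["active", "passive"]
Cue = Literal["intensity", "spectral"]
Motion = Literal["looming", "receding", "static_near_onset", "static_far_onset"]
Side = Literal["left", "right"]

#: Motion classes that render a cue transition.
MOVING = ("looming", "receding")
#: Motion classes without a transition (catch trials).
STATIC = ("static_near_onset", "static_far_onset")

CHANGE_TIME_NOMINAL = 0.6
CHANGE_TIME_JITTER = 0.05
ISI_ACTIVE_NOMINAL = 0.8
ISI_ACTIVE_JITTER = 0.05
ISI_PASSIVE = 0.5
DEFAULT_BLOCK_LENGTH = 50


class InvalidDesignError(ValueError):
    """Raised when a schedule request violates the factorial balance rules."""


@dataclass(frozen=True)
class TrialSpec:
    """One experimental trial.

    ``change_time`` is defined for every trial for bookkeeping symmetry, but
    no transition is rendered for static trials.
    """

    attention: Attention
    cue: Cue
    motion: Motion
    side: Side
    change_time: float
    isi: float
    block_id: int

    @property
    def is_moving(self) -> bool:
        return self.motion in MOVING

    @property
    def condition(self) -> tuple[str, str, str]:
        return (self.attention, self.cue, self.motion)


@dataclass
class TrialSchedule:
    """Ordered trial sequence with the seed that generated it."""

    trials: list[TrialSpec]
    seed: int
    design: Literal["adult", "newborn"]
    block_length: int = DEFAULT_BLOCK_LENGTH

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.trials])

    def to_tsv(self, path: str | Path) -> None:
        """Write one row per trial plus a JSON sidecar with the metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {
            "seed": self.seed,
            "design": self.design,
            "block_length": self.block_length,
            "n_trials": len(self),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TrialSchedule":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text()
        )
        trials = [
            TrialSpec(
                attention=row.attention,
                cue=row.cue,
                motion=row.motion,
                side=row.side,
                change_time=float(row.change_time),
                isi=float(row.isi),
                block_id=int(row.block_id),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(
            trials=trials,
            seed=int(meta["seed"]),
            design=meta["design"],
            block_length=int(meta["block_length"]),
        )


def _jittered(rng: np.random.Generator, nominal: float, jitter: float) -> float:
    return float(rng.uniform(nominal - jitter, nominal + jitter))


def _blocked_trials(
    rng: np.random.Generator,
    attention: Attention,
    trials_per_condition: int,
    block_length: int,
    block_id_start: int,
    cells: dict[tuple[Cue], list[tuple[Motion, int]]] | None = None,
) -> tuple[list[TrialSpec], int]:
    """Lay out one attentional part: blocks homogeneous in (cue, side).

    Within each (cue, side) stratum the motion labels are shuffled and then
    chunked into blocks, so the moving/static mix is randomized while exact
    factorial balance is preserved over the stratum.
    """
    trials: list[TrialSpec] = []
    block_id = block_id_start
    strata: list[tuple[Cue, Side, list[Motion]]] = []
    for cue in ("intensity", "spectral"):
        for side in ("left", "right"):
            motions: list[Motion] = []
            for motion in MOVING + STATIC:
                motions.extend([motion] * (trials_per_condition // 2))
            strata.append((cue, side, motions))
    # Randomize the order in which (cue, side) blocks are presented.
    order = rng.permutation(len(strata))
    for idx in order:
        cue, side, motions = strata[idx]
        motions = list(np.array(motions)[rng.permutation(len(motions))])
        for start in range(0, len(motions), block_length):
            chunk = motions[start : start + block_length]
            for motion in chunk:
                trials.append(
                    TrialSpec(
                        attention=attention,
                        cue=cue,
                        motion=motion,
                        side=side,
                        change_time=_jittered(
                            rng, CHANGE_TIME_NOMINAL, CHANGE_TIME_JITTER
                        ),
                        isi=(
                            _jittered(rng, ISI_ACTIVE_NOMINAL, ISI_ACTIVE_JITTER)
                            if attention == "active"
                            else ISI_PASSIVE
                        ),
                        block_id=block_id,
                    )
                )
            block_id += 1
    return trials, block_id


def build_adult_schedule(
    seed: int,
    trials_per_condition: int,
    block_length: int = DEFAULT_BLOCK_LENGTH,
) -> TrialSchedule:
    """Build the adult schedule: 16 cells x ``trials_per_condition`` trials.

    The passive part precedes the active part (all listeners start passive,
    to preserve naivety). Half of all trials are static catch trials; within
    moving trials half loom and half recede; within each condition cell half
    the trials are presented from each side.

    Parameters
    ----------
    seed
        Seed for the schedule RNG; identical seeds give identical schedules.
    trials_per_condition
        Trials per (attention x cue x motion) cell. Must be even so the
        left/right split is exact. The full study used 100 (1600 trials).
    block_length
        Trials per block; cue and side are constant within a block.
    """
    if trials_per_condition <= 0 or trials_per_condition % 2:
        raise InvalidDesignError(
            "trials_per_condition must be a positive even integer, got "
            f"{trials_per_condition}"
        )
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    block_id = 0
    for attention in ("passive", "active"):  # passive first, always
        part, block_id = _blocked_trials(
            rng, attention, trials_per_condition, block_length, block_id
        )
        trials.extend(part)
    return TrialSchedule(trials=trials, seed=seed, design="adult",
                         block_length=block_length)


def build_newborn_schedule(
    seed: int,
    trials_per_condition: int,
    block_length: int = DEFAULT_BLOCK_LENGTH,
) -> TrialSchedule:
    """Build the passive-only newborn schedule: 4 cells x ``trials_per_condition``.

    The 4 condition cells are cue x {moving, static}; within a moving cell
    looming and receding each take half the trials, within a static cell the
    near- and far-onset renderings each take half, and each cell is balanced
    over sides. At the study's setting of 100 trials per cell this yields
    400 trials with ISI fixed at 0.5 s.
    """
    if trials_per_condition <= 0 or trials_per_condition % 2:
        raise InvalidDesignError(
            "trials_per_condition must be a positive even integer, got "
            f"{trials_per_condition}"
        )
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    block_id = 0
    half = trials_per_condition // 2
    strata: list[tuple[Cue, Side, list[Motion]]] = []
    for cue in ("intensity", "spectral"):
        for side in ("left", "right"):
            motions: list[Motion] = []
            # Each (cue, side) stratum carries half of both cells for this cue.
            for subtypes in (MOVING, STATIC):
                per_subtype = half // 2
                remainder = half - 2 * per_subtype
                counts = [per_subtype + (1 if i < remainder else 0)
                          for i in range(2)]
                if side == "right":
                    counts = counts[::-1]  # balance odd remainders over sides
                for motion, count in zip(subtypes, counts):
                    motions.extend([motion] * count)
            strata.append((cue, side, motions))
    order = rng.permutation(len(strata))
    for idx in order:
        cue, side, motions = strata[idx]
        motions = list(np.array(motions)[rng.permutation(len(motions))])
        for start in range(0, len(motions), block_length):
            chunk = motions[start : start + block_length]
            for motion in chunk:
                trials.append(
                    TrialSpec(
                        attention="passive",
                        cue=cue,
                        motion=motion,
                        side=side,
                        change_time=_jittered(
                            rng, CHANGE_TIME_NOMINAL, CHANGE_TIME_JITTER
                        ),
                        isi=ISI_PASSIVE,
                        block_id=block_id,
                    )
                )
            block_id += 1
    return TrialSchedule(trials=trials, seed=seed, design="newborn",
                         block_length=block_length)


@dataclass
class BalanceReport:
    """Outcome of :func:`validate_schedule`; report-only, never raises."""

    condition_counts: pd.Series
    side_counts: pd.Series
    jitter_violations: list[int] = field(default_factory=list)
    block_violations: list[int] = field(default_factory=list)
    balance_violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (
            self.jitter_violations
            or self.block_violations
            or self.balance_violations
        )


def validate_schedule(schedule: TrialSchedule) -> BalanceReport:
    """Check factorial balance, jitter range and block homogeneity.

    Returns a report flagging any violated invariant; generator output must
    always pass.
    """
    if not schedule.trials:
        raise ValueError("empty schedule")
    df = schedule.to_frame()
    condition_counts = df.groupby(
        ["attention", "cue", "motion"], observed=True
    ).size()
    side_counts = df.groupby(
        ["attention", "cue", "motion", "side"], observed=True
    ).size()

    balance_violations: list[str] = []
    if condition_counts.nunique() != 1:
        balance_violations.append("unequal condition-cell counts")
    for cond, sub in df.groupby(["attention", "cue", "motion"], observed=True):
        sides = sub["side"].value_counts()
        if sides.get("left", 0) != sides.get("right", 0):
            balance_violations.append(f"left/right imbalance in {cond}")

    lo = CHANGE_TIME_NOMINAL - CHANGE_TIME_JITTER
    hi = CHANGE_TIME_NOMINAL + CHANGE_TIME_JITTER
    moving = df["motion"].isin(MOVING)
    bad_jitter = df.index[
        moving & ~df["change_time"].between(lo, hi)
    ].tolist()

    block_violations: list[int] = []
    for block_id, sub in df.groupby("block_id"):
        if sub["cue"].nunique() > 1 or sub["side"].nunique() > 1:
            block_violations.append(int(block_id))
        if sub["attention"].nunique() > 1:
            block_violations.append(int(block_id))

    return BalanceReport(
        condition_counts=condition_counts,
        side_counts=side_counts,
        jitter_violations=bad_jitter,
        block_violations=sorted(set(block_violations)),
        balance_violations=balance_violations,
    )
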