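"""Perseveration-experiment protocol: trial sequences, inputs, motor memory.

A condition consists of four lateral training trials (T1–T4), in which the
object is presented on one side, followed by two neutral trials (N1, N2)
with the object at midline.  In the control condition training is on the
preferred side; in the test condition on the nonpreferred side.

Sensory input is 6.0 to the site on the presentation side and 1.0 to the
other site in lateral trials, and 6.0 to both sites in neutral trials.
Each selection adds a memory input of 1.2 to the chosen limb's site for all
subsequent trials of the same condition; memory is cleared before and
between conditions.  Input drives are fixed before each trial and held
constant during its integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    NONPREFERRED,
    PREFERRED,
    ModelParameters,
    TrialOutcome,
    select_limb,
    simulate_trial,
)

__all__ = [
    "TRIAL_LABELS",
    "TRAINING_LABELS",
    "NEUTRAL_LABELS",
    "CONDITIONS",
    "TrialSpec",
    "ConditionSpec",
    "MemoryState",
    "SensoryScheme",
    "TrialRecord",
    "ParticipantResult",
    "build_condition",
    "trial_drive",
    "update_memory",
    "reset_memory",
    "participant_rng",
    "run_participant",
]

TRAINING_LABELS = ("T1", "T2", "T3", "T4")
NEUTRAL_LABELS = ("N1", "N2")
TRIAL_LABELS = TRAINING_LABELS + NEUTRAL_LABELS
CONDITIONS = ("control", "test")

_LATERALITIES = ("preferred_side", "nonpreferred_side", "neutral")


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the protocol: its label and where the object appears."""

    label: str
    laterality: str

    def __post_init__(self) -> None:
        if self.label not in TRIAL_LABELS:
            raise ValueError(f"unknown trial label {self.label!r}")
        if self.laterality not in _LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.label in NEUTRAL_LABELS and self.laterality != "neutral":
            raise ValueError(f"neutral trial {self.label} must have neutral laterality")
        if self.label in TRAINING_LABELS and self.laterality == "neutral":
            raise ValueError(f"training trial {self.label} must be lateral")


@dataclass(frozen=True)
class ConditionSpec:
    """An ordered six-trial condition (4 training + 2 neutral)."""

    name: str
    trials: tuple[TrialSpec, ...]

    def __post_init__(self) -> None:
        if self.name not in CONDITIONS:
            raise ValueError(f"unknown condition {self.name!r}")
        if tuple(t.label for t in self.trials) != TRIAL_LABELS:
            raise ValueError("condition must contain trials T1..T4, N1, N2 in order")


def build_condition(name: str) -> ConditionSpec:
    """Return the six-trial sequence for ``control`` or ``test``.

    Control trains the preferred side, test the nonpreferred side; both end
    with two neutral (midline) trials.
    """
    if name not in CONDITIONS:
        raise ValueError(f"unknown condition {name!r}; expected one of {CONDITIONS}")
    side = "preferred_side" if name == "control" else "nonpreferred_side"
    trials = tuple(TrialSpec(lbl, side) for lbl in TRAINING_LABELS) + tuple(
        TrialSpec(lbl, "neutral") for lbl in NEUTRAL_LABELS
    )
    return ConditionSpec(name=name, trials=trials)


@dataclass(frozen=True)
class MemoryState:
    """Accumulated motor-memory input per site.

    Each completed trial adds ``increment`` to the selected site's memory,
    so ``m_p/increment + m_np/increment`` equals the number of completed
    trials in the current condition (when ``increment > 0``).
    """

    m_p: float = 0.0
    m_np: float = 0.0
    increment: float = 1.2

    def __post_init__(self) -> None:
        if self.m_p < 0 or self.m_np < 0:
            raise ValueError("memory inputs must be nonnegative")
        if self.increment < 0:
            raise ValueError("memory increment must be nonnegative")


@dataclass(frozen=True)
class SensoryScheme:
    """Sensory-input strengths: strong to the cued/neutral side, weak otherwise."""

    strong: float = 6.0
    weak: float = 1.0

    def __post_init__(self) -> None:
        if not self.strong > self.weak >= 0:
            raise ValueError("require strong > weak >= 0")


def reset_memory(increment: float = 1.2) -> MemoryState:
    """Fresh memory state (both sites at zero), as before/between conditions."""
    return MemoryState(0.0, 0.0, increment)


def update_memory(memory: MemoryState, outcome: TrialOutcome) -> MemoryState:
    """Add the memory increment to the site of the limb just selected."""
    if outcome.selected == PREFERRED:
        return MemoryState(memory.m_p + memory.increment, memory.m_np, memory.increment)
    return MemoryState(memory.m_p, memory.m_np + memory.increment, memory.increment)


def trial_drive(spec: TrialSpec, scheme: SensoryScheme,
                memory: MemoryState) -> tuple[float, float]:
    """Total input (sensory + memory) to each site for one trial."""
    if spec.laterality == "neutral":
        sens_p = sens_np = scheme.strong
    elif spec.laterality == "preferred_side":
        sens_p, sens_np = scheme.strong, scheme.weak
    else:
        sens_p, sens_np = scheme.weak, scheme.strong
    return sens_p + memory.m_p, sens_np + memory.m_np


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial: its spec, outcome, and the memory that drove it."""

    spec: TrialSpec
    outcome: TrialOutcome
    m_p: float
    m_np: float
    drive_p: float
    drive_np: float


@dataclass(frozen=True)
class ParticipantResult:
    """All trials of one (simulated) participant across both conditions."""

    participant: int
    age_group: str
    trials: dict[str, tuple[TrialRecord, ...]]  # condition name -> 6 records
    seed: int | None = None

    def selections(self, condition: str) -> tuple[str, ...]:
        return tuple(r.outcome.selected for r in self.trials[condition])

    def training_selections(self, condition: str) -> tuple[str, ...]:
        return self.selections(condition)[: len(TRAINING_LABELS)]


def participant_rng(seed: int, participant: int) -> np.random.Generator:
    """Deterministic, order-independent substream for one participant."""
    return np.random.default_rng(np.random.SeedSequence((seed, participant)))


def _run_condition(cond: ConditionSpec, params: ModelParameters,
                   scheme: SensoryScheme, rng: np.random.Generator,
                   memory_increment: float) -> tuple[TrialRecord, ...]:
    memory = reset_memory(memory_increment)
    records = []
    for spec in cond.trials:
        drive_p, drive_np = trial_drive(spec, scheme, memory)
        outcome, _ = simulate_trial(params, drive_p, drive_np, rng)
        records.append(TrialRecord(spec, outcome, memory.m_p, memory.m_np,
                                   drive_p, drive_np))
        memory = update_memory(memory, outcome)
    return tuple(records)


def run_participant(params: ModelParameters,
                    scheme: SensoryScheme | None = None,
                    rng: np.random.Generator | None = None,
                    *,
                    condition_order: tuple[str, str] = ("control", "test"),
                    memory_increment: float = 1.2,
                    participant: int = 0,
                    age_group: str = "custom",
                    seed: int | None = None) -> ParticipantResult:
    """Run one simulated participant through both conditions.

    Memory is reset before each condition and carried from trial to trial
    within it.  Setting ``memory_increment=0`` disables the memory trace
    (useful for probing its causal role in perseveration).
    """
    if sorted(condition_order) != sorted(CONDITIONS):
        raise ValueError(f"condition_order must be a permutation of {CONDITIONS}")
    scheme = scheme or SensoryScheme()
    if rng is None:
        rng = participant_rng(seed if seed is not None else 0, participant)
    trials: dict[str, tuple[TrialRecord, ...]] = {}
    for name in condition_order:
        trials[name] = _run_condition(build_condition(name), params, scheme,
                                      rng, memory_increment)
    return ParticipantResult(participant=participant, age_group=age_group,
                             trials=trials, seed=seed)
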