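"""Delayed-match-to-sample (DMTS) task with an escape (decline) option.

A trial runs through four phases.  *Study*: one of five one-hot 5-bit
target patterns is shown (three repeated steps).  *Delay*: the distractor
00000 is shown ``N_delay`` times (three steps each), where ``N_delay`` is
drawn from the heavy-tailed law ``floor(-1 / (lambda * ln R)) + 1``.
*Choice* (offered with probability 2/3, four steps): the agent sees a
constant value CV on every pattern input plus the choice-phase signal; if
its decline output exceeds 1/3 it declines the test for a small reward
(0.3).  *Test*: the five patterns are shown successively in random order;
the first whose answer output exceeds 1/3 is the agent's answer — correct
earns 1.0, anything else 0.0.

Unsolvable trials show the distractor in the study phase; declining is then
the only rewarded response (1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .network import SIGMA_INPUT, SIGMA_NEURON

PHASES = ("study", "delay", "choice", "test")

PATTERNS = tuple(
    "".join("1" if j == 4 - i else "0" for j in range(5)) for i in range(5)
)  # 00001, 00010, 00100, 01000, 10000
DISTRACTOR = "00000"


class ConfigError(ValueError):
    """Invalid task or run configuration."""


@dataclass
class TaskConfig:
    """All task constants, defaulting to the standard study conditions."""

    lambda_: float = 0.7          # delay-distribution shape
    cv: float = 0.25              # constant input during the choice phase
    p_choice: float = 2.0 / 3.0   # probability the choice phase is offered
    reward_decline: float = 0.3
    reward_correct: float = 1.0
    reward_none: float = 0.0
    threshold: float = 1.0 / 3.0  # decision threshold on both outputs
    reps_choice: int = 4          # input repetitions in the choice phase
    reps_other: int = 3           # input repetitions elsewhere
    sigma_input: float = SIGMA_INPUT
    sigma_neuron: float = SIGMA_NEURON
    fixed_delay: Optional[int] = None  # override delay sampling (assays)
    reset_mode: str = "genome"

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ConfigError("lambda_ must be positive")
        if not 0 < self.p_choice < 1:
            raise ConfigError("p_choice must lie strictly between 0 and 1")
        if self.fixed_delay is not None and self.fixed_delay < 1:
            raise ConfigError("fixed_delay must be >= 1")


@dataclass
class TrialOutcome:
    """Per-trial record: stimulus, decisions and reward."""

    target: str
    delay_steps: int
    choice_offered: bool
    declined: bool
    answered_pattern: Optional[str]
    reward: float
    unsolvable: bool
    correct: bool = False

    def as_row(self) -> dict:
        return {
            "target": self.target,
            "delay": self.delay_steps,
            "offered": self.choice_offered,
            "declined": self.declined,
            "answer": self.answered_pattern or "",
            "reward": self.reward,
            "unsolvable": self.unsolvable,
            "correct": self.correct,
        }


def outcomes_to_frame(outcomes: Sequence[TrialOutcome]) -> pd.DataFrame:
    """Tabulate trial outcomes, one row per trial (CSV-ready)."""
    return pd.DataFrame([o.as_row() for o in outcomes])


@runtime_checkable
class Agent(Protocol):
    """Protocol shared by neural and scripted agents.

    ``reset()`` is called once per trial; ``observe(block)`` receives one
    phase presentation as an array of shape ``(reps, 7)`` and returns the
    final ``(decline_output, answer_output)`` pair, each in [-1, 1].
    """

    def reset(self) -> None: ...

    def observe(self, block: np.ndarray) -> tuple[float, float]: ...


def sample_delay(lambda_: float, rng: np.random.Generator) -> int:
    """Number of distractor presentations: ``floor(-1/(lambda*ln R)) + 1``
    with R uniform on the open interval (0, 1).

    P(N <= k) = exp(-1/(lambda*k)), so small lambda_ stretches the tail.
    """
    if lambda_ <= 0:
        raise ConfigError("lambda_ must be positive")
    r = rng.random()
    while r == 0.0:  # open interval: avoid log(0)
        r = rng.random()
    return int(np.floor(-1.0 / (lambda_ * np.log(r)))) + 1


def encode_inputs(phase: str, pattern: Optional[str], cfg: TaskConfig) -> np.ndarray:
    """Encode one presentation as the 7 input values:
    five pattern bits, the choice-phase signal, and the bias (always 1)."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if phase in ("study", "test"):
        if pattern is None:
            raise ValueError(f"{phase} phase requires a pattern")
        bits = _bits(pattern)
        return np.concatenate([bits, [0.0, 1.0]])
    if pattern is not None:
        raise ValueError(f"{phase} phase takes no pattern")
    if phase == "delay":
        return np.concatenate([_bits(DISTRACTOR), [0.0, 1.0]])
    # choice: CV on every pattern input, signal on
    return np.concatenate([np.full(5, cfg.cv), [1.0, 1.0]])


def _bits(pattern: str) -> np.ndarray:
    if len(pattern) != 5 or set(pattern) - {"0", "1"}:
        raise ValueError(f"bad pattern {pattern!r}")
    return np.array([float(b) for b in pattern])


def decode_choice(output_value: float, threshold: float = 1.0 / 3.0) -> str:
    """'decline' iff the output strictly exceeds the threshold, else 'take'."""
    if not np.isfinite(output_value):
        raise ValueError("non-finite output value")
    return "decline" if output_value > threshold else "take"


def _block(phase: str, pattern: Optional[str], cfg: TaskConfig, reps: int) -> np.ndarray:
    return np.tile(encode_inputs(phase, pattern, cfg), (reps, 1))


def run_trial(
    agent: Agent,
    cfg: TaskConfig,
    unsolvable: bool = False,
    force_skip_choice: bool = False,
    rng: Optional[np.random.Generator] = None,
    test_after_decline: bool = False,
    force_offer_choice: bool = False,
) -> TrialOutcome:
    """Run one full trial and return its outcome.

    ``test_after_decline=True`` runs the test phase even after a decline,
    recording the counterfactual answer without touching the reward (used
    by the behavioral assays).  Decisions are read from the agent's outputs
    after the last repetition of the relevant presentation block.
    """
    if rng is None:
        raise ValueError("run_trial requires an rng")
    recorder = getattr(agent, "recorder", None)

    target = DISTRACTOR if unsolvable else PATTERNS[rng.integers(5)]
    agent.reset()

    def present(phase: str, pattern: Optional[str], reps: int) -> tuple[float, float]:
        if recorder is not None:
            recorder.phase = phase
        return agent.observe(_block(phase, pattern, cfg, reps))

    present("study", target, cfg.reps_other)
    n_delay = cfg.fixed_delay if cfg.fixed_delay is not None else sample_delay(
        cfg.lambda_, rng
    )
    for _ in range(n_delay):
        present("delay", None, cfg.reps_other)

    if force_skip_choice and force_offer_choice:
        raise ValueError("cannot both force and skip the choice phase")
    offered = force_offer_choice or (
        (not force_skip_choice) and rng.random() < cfg.p_choice
    )
    declined = False
    if offered:
        decline_out, _ = present("choice", None, cfg.reps_choice)
        declined = decode_choice(decline_out, cfg.threshold) == "decline"

    answered: Optional[str] = None
    if not declined or test_after_decline:
        order = rng.permutation(5)
        for idx in order:
            _, answer_out = present("test", PATTERNS[idx], cfg.reps_other)
            if answer_out > cfg.threshold:
                answered = PATTERNS[idx]
                break  # the task ends at the first selection

    if declined:
        reward = cfg.reward_correct if unsolvable else cfg.reward_decline
        correct = False
    elif answered == target:
        reward = cfg.reward_correct
        correct = True
    else:
        reward = cfg.reward_none
        correct = False

    return TrialOutcome(
        target=target,
        delay_steps=n_delay,
        choice_offered=offered,
        declined=declined,
        answered_pattern=answered,
        reward=reward,
        unsolvable=unsolvable,
        correct=correct,
    )
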