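"""Agents: the neural phenotype wrapper and scripted baselines.

Scripted agents honor the same observe/decide protocol as the network but
bypass it entirely, so the task environment can be tested against policies
with analytically known expected rewards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import network as net
from .network import (
    Genome,
    MODULATORY,
    MAX_NEURONS,
    N_INPUTS,
    N_UNITS,
    OUTPUT_NEURONS,
    PlasticityRule,
    STANDARD,
    build_phenotype,
    step_network,
)
from .task import DISTRACTOR, TaskConfig


@dataclass
class TraceStep:
    """One network step of a recorded trial."""

    step: int
    phase: str
    inputs: np.ndarray
    outputs: np.ndarray
    modulation_sums: np.ndarray
    weights: np.ndarray


class TraceRecorder:
    """Collects per-step network state; attach to a :class:`NetworkAgent`.

    The surrounding trial runner labels the current phase before each
    presentation block.
    """

    def __init__(self) -> None:
        self.phase: str = ""
        self.steps: list[TraceStep] = []

    def record(self, inputs: np.ndarray, state: net.NetworkState) -> None:
        self.steps.append(
            TraceStep(
                step=len(self.steps),
                phase=self.phase,
                inputs=np.array(inputs, dtype=float),
                outputs=state.outputs.copy(),
                modulation_sums=state.modulation_sums.copy(),
                weights=state.weights.copy(),
            )
        )


class NetworkAgent:
    """Runs a genome's phenotype through the task protocol.

    The agent owns its noise stream (``rng``); ``reset()`` rebuilds the
    phenotype for a fresh trial, re-randomizing the neuron outputs (and,
    in ``reset_mode='random_weights'``, the weights).
    """

    def __init__(
        self,
        genome: Genome,
        rng: Optional[np.random.Generator] = None,
        sigma_input: float = net.SIGMA_INPUT,
        sigma_neuron: float = net.SIGMA_NEURON,
        reset_mode: str = "genome",
        recorder: Optional[TraceRecorder] = None,
    ) -> None:
        self.genome = genome
        self.rng = rng
        self.sigma_input = sigma_input
        self.sigma_neuron = sigma_neuron
        self.reset_mode = reset_mode
        self.recorder = recorder
        self.state: Optional[net.NetworkState] = None

    @classmethod
    def for_task(
        cls, genome: Genome, cfg: TaskConfig, rng: Optional[np.random.Generator],
        recorder: Optional[TraceRecorder] = None,
    ) -> "NetworkAgent":
        return cls(
            genome,
            rng=rng,
            sigma_input=cfg.sigma_input,
            sigma_neuron=cfg.sigma_neuron,
            reset_mode=cfg.reset_mode,
            recorder=recorder,
        )

    def reset(self) -> None:
        self.state = build_phenotype(
            self.genome, rng=self.rng, reset_mode=self.reset_mode
        )

    def observe(self, block: np.ndarray) -> tuple[float, float]:
        if self.state is None:
            raise RuntimeError("agent not reset before observe")
        for row in block:
            step_network(
                self.state,
                row,
                rng=self.rng,
                sigma_input=self.sigma_input,
                sigma_neuron=self.sigma_neuron,
            )
            if self.recorder is not None:
                self.recorder.record(row, self.state)
        out = self.state.neuron_outputs
        return float(out[OUTPUT_NEURONS[0]]), float(out[OUTPUT_NEURONS[1]])


# ---------------------------------------------------------------------------
# scripted baselines


class _Scripted:
    """Base class tracking phase structure from the raw input stream.

    Blocks are classified from the input layout alone: the first block is
    the study presentation; a block with the choice signal on is the choice
    phase; later signal-off blocks are delay (all-zero bits) or test
    presentations (a one-hot pattern).
    """

    def __init__(self) -> None:
        self.reset()

    def reset(self) -> None:
        self._block_count = 0
        self._study_bits: Optional[np.ndarray] = None
        self._test_seen = 0

    def observe(self, block: np.ndarray) -> tuple[float, float]:
        row = np.asarray(block)[-1]
        bits, signal = row[:5], row[5]
        first = self._block_count == 0
        self._block_count += 1
        if first:
            self._study_bits = np.round(bits)
            return self._respond(kind="study", bits=bits)
        if signal > 0.5:
            return self._respond(kind="choice", bits=bits)
        if np.round(bits).sum() == 0:
            return self._respond(kind="delay", bits=bits)
        self._test_seen += 1
        return self._respond(kind="test", bits=np.round(bits))

    def _respond(self, kind: str, bits: np.ndarray) -> tuple[float, float]:
        raise NotImplementedError


class AlwaysDecline(_Scripted):
    """Declines whenever offered; never answers a test."""

    def _respond(self, kind, bits):
        return (1.0, -1.0)


class ConstantOutput(_Scripted):
    """Emits a fixed value on both outputs at all times."""

    def __init__(self, value: float) -> None:
        self.value = float(value)
        super().__init__()

    def _respond(self, kind, bits):
        return (self.value, self.value)


class RandomAnswer(_Scripted):
    """Always takes the test and answers a uniformly random pattern.

    Accepts the k-th test presentation with probability 1/(5-k+1), which
    makes each of the five patterns equally likely regardless of the
    presentation order (chance accuracy exactly 1/5).
    """

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        super().__init__()

    def _respond(self, kind, bits):
        if kind == "test":
            remaining = 5 - self._test_seen + 1
            if self.rng.random() < 1.0 / remaining:
                return (-1.0, 1.0)
            return (-1.0, -1.0)
        return (-1.0, -1.0)


class PerfectOracle(_Scripted):
    """Remembers the study pattern exactly; answers only the match.

    On unsolvable trials (study pattern 00000) it declines when offered and
    answers nothing when forced.
    """

    def _respond(self, kind, bits):
        solvable = self._study_bits is not None and self._study_bits.sum() > 0
        if kind == "choice":
            return ((-1.0, -1.0) if solvable else (1.0, -1.0))
        if kind == "test" and solvable and np.array_equal(bits, self._study_bits):
            return (-1.0, 1.0)
        return (-1.0, -1.0)


def scripted_agent(
    policy: str,
    rng: Optional[np.random.Generator] = None,
    value: float = 0.0,
):
    """Build a scripted baseline by name: ``always_decline``,
    ``always_take_random`` (needs ``rng``), ``perfect_oracle``, or
    ``constant_output`` (uses ``value``)."""
    if policy == "always_decline":
        return AlwaysDecline()
    if policy == "always_take_random":
        if rng is None:
            raise ValueError("always_take_random requires an rng")
        return RandomAnswer(rng)
    if policy == "perfect_oracle":
        return PerfectOracle()
    if policy == "constant_output":
        return ConstantOutput(value)
    raise ValueError(f"unknown policy {policy!r}")


# ---------------------------------------------------------------------------
# toy genomes


def _random_rule(rng: np.random.Generator, eta_range: float) -> PlasticityRule:
    a, b, c, d = (float(v) for v in rng.uniform(-1, 1, 4))
    return PlasticityRule(
        eta=float(rng.uniform(-eta_range, eta_range)), A=a, B=b, C=c, D=d
    )


def make_toy_genome(spec: str, seed: Optional[int] = None) -> Genome:
    """Deterministic small genomes for unit tests and demos.

    ``zero``
        All-zero weights, only the two output neurons active.
    ``minimal_modulated``
        One standard connection (input 0 -> decline neuron) whose
        plasticity is gated by a single modulatory neuron driven from
        input 1; pure-Hebbian rule (A=1, eta=1).
    ``full_random``
        All 16 neurons active, weights and parameters uniform over the
        full genotype ranges, types random (outputs stay standard);
        requires ``seed``.
    """
    if spec == "zero":
        return Genome()
    if spec == "minimal_modulated":
        g = Genome()
        g.neuron_active[2] = True
        g.neuron_type[2] = MODULATORY
        g.weights[0, OUTPUT_NEURONS[0]] = 1.0   # input 0 -> std output 0
        g.weights[1, 2] = 1.0                   # input 1 drives the modulator
        g.weights[N_INPUTS + 2, OUTPUT_NEURONS[0]] = 1.0  # modulator gates it
        g.rule = PlasticityRule(eta=1.0, A=1.0)
        return g.validate()
    if spec == "full_random":
        if seed is None:
            raise ValueError("full_random requires a seed")
        rng = np.random.default_rng(seed)
        g = Genome(
            weights=rng.uniform(-100.0, 100.0, (N_UNITS, MAX_NEURONS)),
            neuron_active=np.ones(MAX_NEURONS, dtype=bool),
            neuron_type=rng.integers(0, 2, MAX_NEURONS).astype(np.int8),
            rule=_random_rule(rng, eta_range=100.0),
        )
        for k in OUTPUT_NEURONS:
            g.neuron_type[k] = STANDARD
        return g.validate()
    raise ValueError(f"unknown fixture {spec!r}")


def random_genome(rng: np.random.Generator, n_hidden: int = 2) -> Genome:
    """Random initial genome: the two output neurons plus ``n_hidden``
    random-type neurons, genotype weights uniform in [-1, 1] (mostly inside
    the dead zone, so initial phenotypes are sparse), eta uniform in
    [-10, 10] and A..D uniform in [-1, 1]."""
    g = Genome(
        weights=rng.uniform(-1.0, 1.0, (N_UNITS, MAX_NEURONS)),
        rule=_random_rule(rng, eta_range=10.0),
    )
    for k in range(2, 2 + n_hidden):
        g.neuron_active[k] = True
        g.neuron_type[k] = rng.integers(0, 2)
    return g.validate()


# ---------------------------------------------------------------------------
# closed-form expected fitness of the scripted policies


def expected_scripted_fitness(policy, ga_cfg, task_cfg: TaskConfig, value: float = 0.0) -> float:
    """Exact expected total reward of a scripted policy over one evaluation
    schedule (T trials of which U are unsolvable, choice offered with
    probability ``p_choice``)."""
    T, U = ga_cfg.tasks_per_eval, ga_cfg.unsolvable_per_eval
    p = task_cfg.p_choice
    r_dec, r_big = task_cfg.reward_decline, task_cfg.reward_correct
    if policy == "always_decline":
        # declines when offered; earns nothing on forced trials
        return U * p * r_big + (T - U) * p * r_dec
    if policy == "always_take_random":
        # uniform answer: 1/5 correct on solvable, never correct on unsolvable
        return (T - U) * (1.0 / 5.0) * r_big
    if policy == "perfect_oracle":
        # perfect on solvable; declines unsolvable when offered
        return (T - U) * r_big + U * p * r_big
    if policy == "constant_output":
        if value > task_cfg.threshold:
            # declines when offered; forced: selects the first test pattern
            return (
                p * (U * r_big + (T - U) * r_dec)
                + (1 - p) * (T - U) * (1.0 / 5.0) * r_big
            )
        return 0.0
    raise ValueError(f"no closed form for policy {policy!r}")
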