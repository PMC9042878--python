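"""Neuromodulated recurrent network: genotype, phenotype mapping, dynamics.

The network is a discrete-time recurrent net of tanh units.  Besides the
seven input units (five pattern bits, a choice-phase signal, and a constant
bias) it holds up to 16 evolvable neurons, each either *standard* or
*modulatory*.  Standard neurons drive activation sums ``a_i``; modulatory
neurons drive modulation sums ``m_i`` instead, and ``tanh(m_i)`` gates the
plasticity (learning rate) of every connection into neuron ``i``:

    a_i = sum_{j in Std} w_ji * o_j
    m_i = sum_{j in Mod} w_ji * o_j
    o_i = tanh(a_i + noise)
    dw_ji = tanh(m_i) * eta * (A*o_j*o_i + B*o_j + C*o_i + D)

The extended-Hebbian coefficients ``A..D``, the learning rate ``eta``, the
weight matrix, per-neuron types and an active mask constitute the genome.
Genotype weights live in [-100, 100] and map to phenotype weights through a
cube with a dead zone (``10*w**3``, zero when ``|w**3| < 0.1``), clipped to
the hard weight range [-10, 10]; ``A..D`` map through the analogous plain
cube, and ``eta`` passes through unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

N_INPUTS = 7
MAX_NEURONS = 16
N_UNITS = N_INPUTS + MAX_NEURONS
#: indices (into the neuron axis) of the two designated output neurons:
#: 0 decides decline/take, 1 answers the memory test.
OUTPUT_NEURONS = (0, 1)
WEIGHT_BOUND = 10.0
GENO_WEIGHT_BOUND = 100.0
DEAD_ZONE = 0.1

STANDARD = 0
MODULATORY = 1

SIGMA_INPUT = 0.1
SIGMA_NEURON = 0.0001


class InvalidGenomeError(ValueError):
    """A genome violates its structural or range invariants."""


@dataclass(frozen=True)
class PlasticityRule:
    """Coefficients of the extended Hebbian rule (genotype or phenotype).

    ``eta`` is used directly in both genotype and phenotype; ``A..D`` are
    genotype values in [-1, 1] that map to the phenotype through the
    dead-zoned cube.
    """

    eta: float = 0.0
    A: float = 0.0
    B: float = 0.0
    C: float = 0.0
    D: float = 0.0

    def to_phenotype(self) -> "PlasticityRule":
        return PlasticityRule(
            eta=self.eta,
            A=genotype_to_phenotype_param(self.A),
            B=genotype_to_phenotype_param(self.B),
            C=genotype_to_phenotype_param(self.C),
            D=genotype_to_phenotype_param(self.D),
        )

    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.A, self.B, self.C, self.D)


def _as_array(x, shape, dtype) -> np.ndarray:
    a = np.asarray(x, dtype=dtype)
    if a.shape != shape:
        raise InvalidGenomeError(f"expected shape {shape}, got {a.shape}")
    return a


@dataclass
class Genome:
    """Evolvable genotype of one agent.

    ``weights`` has one row per presynaptic unit (7 inputs followed by the
    16 neuron slots) and one column per postsynaptic neuron slot.  Inactive
    slots keep their rows/columns in the matrix so that crossover between
    parents of different topology stays well defined; they are masked out
    when the phenotype is built.
    """

    weights: np.ndarray = field(
        default_factory=lambda: np.zeros((N_UNITS, MAX_NEURONS))
    )
    neuron_active: np.ndarray = field(
        default_factory=lambda: _default_active()
    )
    neuron_type: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_NEURONS, dtype=np.int8)
    )
    rule: PlasticityRule = field(default_factory=PlasticityRule)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = _as_array(self.weights, (N_UNITS, MAX_NEURONS), float)
        self.neuron_active = _as_array(self.neuron_active, (MAX_NEURONS,), bool)
        self.neuron_type = _as_array(self.neuron_type, (MAX_NEURONS,), np.int8)

    @property
    def n_active(self) -> int:
        return int(self.neuron_active.sum())

    def validate(self) -> "Genome":
        """Check all genome invariants; raise :class:`InvalidGenomeError`."""
        if not np.all(np.isfinite(self.weights)):
            raise InvalidGenomeError("non-finite genotype weight")
        if np.any(np.abs(self.weights) > GENO_WEIGHT_BOUND):
            raise InvalidGenomeError("genotype weight outside [-100, 100]")
        if self.n_active > MAX_NEURONS:
            raise InvalidGenomeError("more than 16 active neurons")
        for k in OUTPUT_NEURONS:
            if not self.neuron_active[k]:
                raise InvalidGenomeError(f"output neuron {k} inactive")
            if self.neuron_type[k] != STANDARD:
                raise InvalidGenomeError(f"output neuron {k} not standard")
        for p in self.rule.coefficients():
            if not np.isfinite(p) or abs(p) > 1:
                raise InvalidGenomeError("rule coefficient outside [-1, 1]")
        if not np.isfinite(self.rule.eta) or abs(self.rule.eta) > GENO_WEIGHT_BOUND:
            raise InvalidGenomeError("eta outside [-100, 100]")
        return self

    def copy(self) -> "Genome":
        return Genome(
            weights=self.weights.copy(),
            neuron_active=self.neuron_active.copy(),
            neuron_type=self.neuron_type.copy(),
            rule=replace(self.rule),
            meta=dict(self.meta),
        )

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "neuron_active": self.neuron_active.astype(int).tolist(),
            "neuron_type": self.neuron_type.astype(int).tolist(),
            "eta": float(self.rule.eta),
            "A": float(self.rule.A),
            "B": float(self.rule.B),
            "C": float(self.rule.C),
            "D": float(self.rule.D),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Genome":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            neuron_active=np.asarray(d["neuron_active"], dtype=bool),
            neuron_type=np.asarray(d["neuron_type"], dtype=np.int8),
            rule=PlasticityRule(
                eta=d["eta"], A=d["A"], B=d["B"], C=d["C"], D=d["D"]
            ),
            meta=d.get("meta", {}),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "Genome":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _default_active() -> np.ndarray:
    a = np.zeros(MAX_NEURONS, dtype=bool)
    for k in OUTPUT_NEURONS:
        a[k] = True
    return a


def genotype_to_phenotype_weight(w_geno):
    """Map genotype weight(s) in [-100, 100] to phenotype weights in [-10, 10].

    ``w -> 10*w**3`` with a dead zone (``0`` when ``|w**3| < 0.1``); the
    result is clipped to the hard weight range since the genotype range
    would otherwise exceed it.
    """
    w = np.asarray(w_geno, dtype=float)
    if not np.all(np.isfinite(w)):
        raise InvalidGenomeError("non-finite genotype weight")
    cubed = w**3
    out = np.where(
        np.abs(cubed) < DEAD_ZONE,
        0.0,
        np.clip(10.0 * cubed, -WEIGHT_BOUND, WEIGHT_BOUND),
    )
    return out if out.ndim else float(out)


def genotype_to_phenotype_param(p_geno):
    """Map a rule coefficient in [-1, 1] through the dead-zoned cube."""
    p = np.asarray(p_geno, dtype=float)
    if not np.all(np.isfinite(p)):
        raise InvalidGenomeError("non-finite rule coefficient")
    cubed = p**3
    out = np.where(np.abs(cubed) < DEAD_ZONE, 0.0, cubed)
    return out if out.ndim else float(out)


@dataclass
class NetworkState:
    """Phenotype of one agent during a trial.

    ``weights`` mirrors the genome shape; ``outputs`` holds one entry per
    unit (inputs first).  ``activation_sums`` and ``modulation_sums`` keep
    the most recent ``a_i`` / ``m_i`` per neuron slot, mainly for tracing.
    """

    weights: np.ndarray
    outputs: np.ndarray
    rule: PlasticityRule
    neuron_active: np.ndarray
    neuron_type: np.ndarray
    activation_sums: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_NEURONS)
    )
    modulation_sums: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_NEURONS)
    )

    @property
    def neuron_outputs(self) -> np.ndarray:
        return self.outputs[N_INPUTS:]

    def _presyn_selectors(self) -> tuple[np.ndarray, np.ndarray]:
        """0/1 vectors over the 23 presynaptic units selecting standard
        sources (inputs count as standard) and modulatory sources."""
        std = np.zeros(N_UNITS)
        std[:N_INPUTS] = 1.0
        active = self.neuron_active
        std[N_INPUTS:] = active & (self.neuron_type == STANDARD)
        mod = np.zeros(N_UNITS)
        mod[N_INPUTS:] = active & (self.neuron_type == MODULATORY)
        return std, mod

    def modulated_neurons(self) -> np.ndarray:
        """Boolean mask of neurons with >= 1 incoming modulatory connection.

        Only the connections of these neurons are plastic: an unmodulated
        neuron keeps its incoming weights for the whole trial.
        """
        _, mod = self._presyn_selectors()
        has_mod_in = np.any((self.weights != 0.0) & (mod[:, None] > 0), axis=0)
        return has_mod_in & self.neuron_active


def build_phenotype(
    genome: Genome,
    rng: Optional[np.random.Generator] = None,
    reset_mode: str = "genome",
) -> NetworkState:
    """Express a genome as a runnable network state.

    ``reset_mode='genome'`` (default) maps genotype weights through the
    dead-zoned cube; ``'random_weights'`` instead draws phenotype weights
    uniformly in [-10, 10] (fresh random weights at every trial start).
    Neuron outputs start uniform in (-1, 1) when ``rng`` is given, else 0.
    """
    genome.validate()
    if reset_mode == "genome":
        w = genotype_to_phenotype_weight(genome.weights)
    elif reset_mode == "random_weights":
        if rng is None:
            raise ValueError("reset_mode='random_weights' requires an rng")
        w = rng.uniform(-WEIGHT_BOUND, WEIGHT_BOUND, (N_UNITS, MAX_NEURONS))
    else:
        raise ValueError(f"unknown reset_mode {reset_mode!r}")
    w = np.array(w, dtype=float)
    active = genome.neuron_active
    w[:, ~active] = 0.0
    w[N_INPUTS:][~active, :] = 0.0

    outputs = np.zeros(N_UNITS)
    if rng is not None:
        outputs[N_INPUTS:] = rng.uniform(-1.0, 1.0, MAX_NEURONS)
        outputs[N_INPUTS:][~active] = 0.0
    return NetworkState(
        weights=w,
        outputs=outputs,
        rule=genome.rule.to_phenotype(),
        neuron_active=active.copy(),
        neuron_type=genome.neuron_type.copy(),
    )


def step_network(
    state: NetworkState,
    external_inputs,
    rng: Optional[np.random.Generator] = None,
    sigma_input: float = SIGMA_INPUT,
    sigma_neuron: float = SIGMA_NEURON,
) -> NetworkState:
    """Advance the network one synchronous step (in place; returns state).

    All new outputs are computed from the previous step's outputs.  Input
    units emit the supplied value plus Gaussian noise (sd ``sigma_input``);
    every neuron adds Gaussian noise (sd ``sigma_neuron``) to its activation
    sum before the tanh.  After the activation pass the extended-Hebbian
    update is applied to every connection whose postsynaptic neuron is
    modulated.  Pass ``rng=None`` (or zero sigmas) to disable noise.
    """
    x = np.asarray(external_inputs, dtype=float)
    if x.shape != (N_INPUTS,):
        raise ValueError(f"expected {N_INPUTS} external inputs, got {x.shape}")

    o_prev = state.outputs
    std_sel, mod_sel = state._presyn_selectors()
    W = state.weights
    a = (o_prev * std_sel) @ W
    m = (o_prev * mod_sel) @ W
    if rng is not None and sigma_neuron > 0:
        a = a + rng.normal(0.0, sigma_neuron, MAX_NEURONS)
    o_neu = np.where(state.neuron_active, np.tanh(a), 0.0)

    o_in = x.copy()
    if rng is not None and sigma_input > 0:
        o_in += rng.normal(0.0, sigma_input, N_INPUTS)

    state.activation_sums = a
    state.modulation_sums = m
    state.outputs = np.concatenate([o_in, o_neu])

    # plasticity pass on the just-computed outputs
    modulated = state.modulated_neurons()
    if modulated.any() and state.rule.eta != 0.0:
        deltas = _hebbian_deltas(state.outputs, m, state.rule)
        deltas[:, ~modulated] = 0.0
        # connections from inactive slots do not exist
        inactive_rows = np.zeros(N_UNITS, dtype=bool)
        inactive_rows[N_INPUTS:] = ~state.neuron_active
        deltas[inactive_rows, :] = 0.0
        apply_weight_updates(state, deltas)
    return state


def _hebbian_deltas(outputs: np.ndarray, m: np.ndarray, rule: PlasticityRule) -> np.ndarray:
    o_pre = outputs  # all 23 units can be presynaptic
    o_post = outputs[N_INPUTS:]
    gate = np.tanh(m)
    hebb = (
        rule.A * np.outer(o_pre, o_post)
        + rule.B * o_pre[:, None]
        + rule.C * o_post[None, :]
        + rule.D
    )
    return gate[None, :] * rule.eta * hebb


def compute_hebbian_delta(o_j: float, o_i: float, m_i: float, rule: PlasticityRule) -> float:
    """Extended Hebbian weight change for a single connection:
    ``tanh(m_i) * eta * (A*o_j*o_i + B*o_j + C*o_i + D)``."""
    return float(
        np.tanh(m_i)
        * rule.eta
        * (rule.A * o_j * o_i + rule.B * o_j + rule.C * o_i + rule.D)
    )


def apply_weight_updates(state: NetworkState, deltas: np.ndarray) -> NetworkState:
    """Add ``deltas`` to the weights and clip to the hard range [-10, 10]."""
    np.clip(
        state.weights + deltas, -WEIGHT_BOUND, WEIGHT_BOUND, out=state.weights
    )
    return state
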