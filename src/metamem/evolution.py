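"""Genetic algorithm over network genomes.

Each generation: every individual is scored by summing its rewards over T
trials (U of them unsolvable once the guided phase is over); the population
array is cut into consecutive circular segments of 5 at a random offset;
the best of each segment parents 5 children, each a copy of the parent or
(with probability 0.1) a submatrix crossover with a random partner; every
child then undergoes per-gene Gaussian mutation and structural
insert/delete/duplicate neuron operators.  During the first 100 guided
generations the choice phase is force-skipped and no unsolvable trials
occur, which bootstraps plain memory before the escape option matters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .agents import NetworkAgent, random_genome
from .network import (
    Genome,
    MAX_NEURONS,
    N_INPUTS,
    N_UNITS,
    OUTPUT_NEURONS,
    PlasticityRule,
    STANDARD,
)
from .task import TaskConfig, TrialOutcome, run_trial

log = logging.getLogger(__name__)


@dataclass
class GAConfig:
    """Evolutionary parameters (defaults are the standard run settings)."""

    pop_size: int = 300
    generations: int = 1000
    tasks_per_eval: int = 300       # T: trials per fitness evaluation
    unsolvable_per_eval: int = 50   # U: unsolvable trials among T
    segment_size: int = 5
    p_crossover: float = 0.1
    p_param_mutation: float = 0.1   # per-gene mutation probability
    sigma_weight_mut: float = 0.3
    sigma_eta_mut: float = 3.0
    p_insert: float = 0.04
    p_delete: float = 0.06
    p_duplicate: float = 0.02
    guided_generations: int = 100   # choice phase force-skipped early on
    max_neurons: int = MAX_NEURONS
    n_init_hidden: int = 2
    checkpoint_every: int = 50
    shared_schedule: bool = False   # same trial schedule for all individuals

    def __post_init__(self) -> None:
        if self.pop_size % self.segment_size:
            raise ValueError("pop_size must be divisible by segment_size")
        if self.unsolvable_per_eval > self.tasks_per_eval:
            raise ValueError("U must not exceed T")


@dataclass
class Individual:
    genome: Genome
    fitness: float = float("nan")


def evaluate_fitness(
    genome: Genome,
    cfg: GAConfig,
    task_cfg: TaskConfig,
    generation: int,
    rng: np.random.Generator,
    return_outcomes: bool = False,
):
    """Total reward of one genome over the T-trial schedule.

    In the guided phase (``generation < guided_generations``) all trials
    are solvable and the choice phase is skipped; afterwards exactly U of
    the T trials are unsolvable, at random positions.  The network is
    rebuilt (reset) at the start of every trial.
    """
    guided = generation < cfg.guided_generations
    T = cfg.tasks_per_eval
    flags = np.zeros(T, dtype=bool)
    task_rng, noise_rng = rng.spawn(2)
    if not guided:
        flags[task_rng.choice(T, size=cfg.unsolvable_per_eval, replace=False)] = True

    agent = NetworkAgent.for_task(genome, task_cfg, noise_rng)
    outcomes: list[TrialOutcome] = []
    total = 0.0
    for t in range(T):
        out = run_trial(
            agent,
            task_cfg,
            unsolvable=bool(flags[t]),
            force_skip_choice=guided,
            rng=task_rng,
        )
        total += out.reward
        if return_outcomes:
            outcomes.append(out)
    if return_outcomes:
        return total, outcomes
    return total


def segment_select(
    fitnesses: np.ndarray, segment_size: int, rng: np.random.Generator
) -> tuple[int, list[int]]:
    """Best-of-segment parent selection on the population array.

    The array is cut into consecutive circular segments of ``segment_size``
    starting at a uniformly random offset; the fittest member of each
    segment (ties: lowest array index) parents that segment.  Returns the
    offset and one parent index per segment.
    """
    n = len(fitnesses)
    if n % segment_size:
        raise ValueError("population size must be divisible by segment_size")
    offset = int(rng.integers(n))
    parents = []
    for s in range(n // segment_size):
        idx = (offset + segment_size * s + np.arange(segment_size)) % n
        seg_fit = np.asarray(fitnesses)[idx]
        best = seg_fit.max()
        winners = idx[seg_fit == best]
        parents.append(int(winners.min()))  # lowest-array-index tie break
    return offset, parents


def crossover(parent_a: Genome, partner: Genome, rng: np.random.Generator) -> Genome:
    """Submatrix crossover plus uniform crossover of the rule parameters.

    Random r, c are drawn from [1, n_rows] and [1, n_cols]; the child takes
    parent_a's weight matrix with the top-left r x c block replaced by the
    partner's.  Each of eta, A..D comes from either parent with equal
    probability.  Neuron types and the active mask come from parent_a.
    """
    child = parent_a.copy()
    r = int(rng.integers(1, N_UNITS + 1))
    c = int(rng.integers(1, MAX_NEURONS + 1))
    child.weights[:r, :c] = partner.weights[:r, :c]
    vals = {}
    for name in ("eta", "A", "B", "C", "D"):
        src = partner if rng.random() < 0.5 else parent_a
        vals[name] = getattr(src.rule, name)
    child.rule = PlasticityRule(**vals)
    return child


def mutate(g: Genome, cfg: GAConfig, rng: np.random.Generator) -> Genome:
    """Per-gene Gaussian mutation, clipped to the genotype ranges.

    Each weight and each of A..D mutates independently with probability
    ``p_param_mutation`` by Gaussian(0, 0.3); eta by Gaussian(0, 3.0).
    """
    out = g.copy()
    p = cfg.p_param_mutation
    mask = rng.random(out.weights.shape) < p
    out.weights[mask] += rng.normal(0.0, cfg.sigma_weight_mut, int(mask.sum()))
    np.clip(out.weights, -100.0, 100.0, out=out.weights)

    vals = {}
    for name in ("A", "B", "C", "D"):
        v = getattr(out.rule, name)
        if rng.random() < p:
            v += rng.normal(0.0, cfg.sigma_weight_mut)
        vals[name] = float(np.clip(v, -1.0, 1.0))
    eta = out.rule.eta
    if rng.random() < p:
        eta += rng.normal(0.0, cfg.sigma_eta_mut)
    out.rule = PlasticityRule(eta=float(np.clip(eta, -100.0, 100.0)), **vals)
    return out


def structural_mutation(
    g: Genome,
    cfg: GAConfig,
    rng: np.random.Generator,
    return_ops: bool = False,
):
    """Insert / delete / duplicate neurons (probabilities 0.04 / 0.06 / 0.02).

    Insertion (one trial per call) activates a free slot with genotype
    weights uniform in [-1, 1] and a random type; deletion and duplication
    are independent per-neuron trials.  Operations that would exceed the
    16-neuron cap are skipped; the designated output neurons are never
    deleted and never change type.  With ``return_ops`` the counts of
    applied operators are returned alongside the genome.
    """
    out = g.copy()
    ops = {"insert": 0, "delete": 0, "duplicate": 0}

    if rng.random() < cfg.p_insert:
        slot = _free_slot(out)
        if slot is not None:
            _set_random_neuron(out, slot, rng)
            ops["insert"] += 1

    for k in np.flatnonzero(g.neuron_active):
        if k in OUTPUT_NEURONS:
            continue
        if rng.random() < cfg.p_delete:
            _delete_neuron(out, int(k))
            ops["delete"] += 1

    for k in np.flatnonzero(g.neuron_active):
        if rng.random() < cfg.p_duplicate:
            if not out.neuron_active[k]:
                continue  # deleted above in this same call
            slot = _free_slot(out)
            if slot is not None:
                _duplicate_neuron(out, int(k), slot)
                ops["duplicate"] += 1

    if return_ops:
        return out, ops
    return out


def _free_slot(g: Genome) -> Optional[int]:
    free = np.flatnonzero(~g.neuron_active)
    return int(free[0]) if free.size else None


def _set_random_neuron(g: Genome, slot: int, rng: np.random.Generator) -> None:
    g.weights[:, slot] = rng.uniform(-1.0, 1.0, N_UNITS)
    g.weights[N_INPUTS + slot, :] = rng.uniform(-1.0, 1.0, MAX_NEURONS)
    g.neuron_type[slot] = rng.integers(0, 2)
    g.neuron_active[slot] = True


def _delete_neuron(g: Genome, k: int) -> None:
    g.neuron_active[k] = False
    g.neuron_type[k] = STANDARD
    g.weights[:, k] = 0.0
    g.weights[N_INPUTS + k, :] = 0.0


def _duplicate_neuron(g: Genome, k: int, slot: int) -> None:
    g.weights[:, slot] = g.weights[:, k]
    g.weights[N_INPUTS + slot, :] = g.weights[N_INPUTS + k, :]
    g.weights[N_INPUTS + slot, slot] = g.weights[N_INPUTS + k, k]
    g.neuron_type[slot] = g.neuron_type[k]
    g.neuron_active[slot] = True


@dataclass
class EvolveResult:
    history: pd.DataFrame
    population: list[Individual]
    best_genome: Genome
    best_fitness: float


def evolve(
    cfg: GAConfig,
    task_cfg: TaskConfig,
    seed: int,
    out_dir: Optional[Path] = None,
) -> EvolveResult:
    """Run the full GA and return the history and the final population.

    With ``out_dir`` set, writes ``generations.csv``, the best genome and a
    config manifest at every checkpoint.  Fully reproducible from ``seed``.
    """
    root = np.random.default_rng(seed)
    ga_rng = root.spawn(1)[0]
    pop = [
        Individual(random_genome(ga_rng, cfg.n_init_hidden))
        for _ in range(cfg.pop_size)
    ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_manifest(out_dir, cfg, task_cfg, seed)

    rows = []
    best_ever: Optional[Individual] = None
    for gen in range(cfg.generations):
        if cfg.shared_schedule:
            shared = root.spawn(1)[0]
            eval_rngs = [
                np.random.default_rng(shared.bit_generator.seed_seq)
                for _ in pop
            ]
        else:
            eval_rngs = root.spawn(len(pop))
        for ind, erng in zip(pop, eval_rngs):
            ind.fitness = evaluate_fitness(
                ind.genome, cfg, task_cfg, gen, erng
            )
        fits = np.array([ind.fitness for ind in pop])
        gen_best = int(np.argmax(fits))
        if best_ever is None or fits[gen_best] >= best_ever.fitness:
            best_ever = Individual(pop[gen_best].genome.copy(), float(fits[gen_best]))
        rows.append(
            {
                "generation": gen,
                "best": float(fits.max()),
                "mean": float(fits.mean()),
                "sd": float(fits.std()),
            }
        )
        log.info(
            "gen %d: best %.2f mean %.2f", gen, fits.max(), fits.mean()
        )

        _, parents = segment_select(fits, cfg.segment_size, ga_rng)
        children: list[Individual] = []
        for p_idx in parents:
            parent = pop[p_idx].genome
            for _ in range(cfg.segment_size):
                if ga_rng.random() < cfg.p_crossover:
                    partner = pop[int(ga_rng.integers(len(pop)))].genome
                    child = crossover(parent, partner, ga_rng)
                else:
                    child = parent.copy()
                child = mutate(child, cfg, ga_rng)
                child = structural_mutation(child, cfg, ga_rng)
                children.append(Individual(child))
        pop = children

        if out_dir is not None and (
            (gen + 1) % cfg.checkpoint_every == 0 or gen == cfg.generations - 1
        ):
            _checkpoint(out_dir, rows, best_ever, seed, gen)

    history = pd.DataFrame(rows)
    if out_dir is not None:
        _checkpoint(out_dir, rows, best_ever, seed, cfg.generations - 1)
    return EvolveResult(
        history=history,
        population=pop,
        best_genome=best_ever.genome,
        best_fitness=best_ever.fitness,
    )


def _write_manifest(out_dir: Path, cfg: GAConfig, task_cfg: TaskConfig, seed: int) -> None:
    manifest = {
        "seed": seed,
        "ga_config": asdict(cfg),
        "task_config": asdict(task_cfg),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _checkpoint(out_dir: Path, rows, best: Individual, seed: int, gen: int) -> None:
    pd.DataFrame(rows).to_csv(out_dir / "generations.csv", index=False)
    g = best.genome.copy()
    g.meta.update({"seed": seed, "generation": gen, "fitness": best.fitness})
    g.save(out_dir / "best_genome.json")
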