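"""Behavioral assays and mechanism tracing for evolved (or scripted) agents.

The central comparison is between three test protocols at matched delays:

* forced — the choice phase is skipped, the agent must take the test;
* chosen — the choice phase is offered and the agent elects to take;
* declined (counterfactual) — the agent declines, but the test is run
  anyway, without reward, to see what it *would* have answered.

An agent that monitors its own memory should be more accurate on tests it
chose to take than on forced tests, less accurate on tests it declined, and
should decline more often as the delay (hence forgetting) grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .agents import NetworkAgent, TraceRecorder, TraceStep
from .network import Genome, N_INPUTS
from .task import Agent, TaskConfig, TrialOutcome, run_trial


@dataclass
class BehaviorSummary:
    """Per (delay, pattern) aggregate of the three protocols.

    ``table`` columns: delay, pattern, counts and accuracies for the
    forced / chosen / declined protocols, and the take/decline split on
    choice-offered trials.
    """

    table: pd.DataFrame
    n_trials: int

    def by_delay(self) -> pd.DataFrame:
        """Collapse patterns, keeping one row per delay."""
        t = self.table
        cols = [
            "n_forced", "correct_forced", "n_offered", "n_taken",
            "n_declined", "correct_chosen", "correct_declined",
        ]
        g = t.groupby("delay", as_index=False)[cols].sum()
        return _add_rates(g)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _add_rates(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        df["accuracy_forced"] = df.correct_forced / df.n_forced
        df["accuracy_chosen"] = df.correct_chosen / df.n_taken
        df["accuracy_declined"] = df.correct_declined / df.n_declined
        df["p_take"] = df.n_taken / df.n_offered
        df["p_decline"] = df.n_declined / df.n_offered
    return df


def _make_agent(agent_or_genome, cfg, rng, recorder=None):
    if isinstance(agent_or_genome, Genome):
        return NetworkAgent.for_task(agent_or_genome, cfg, rng, recorder=recorder)
    return agent_or_genome


def run_behavior_assay(
    agent_or_genome: Union[Genome, Agent],
    n_trials: int,
    delays: Sequence[int],
    cfg: Optional[TaskConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> BehaviorSummary:
    """Probe an agent with ``n_trials`` forced and ``n_trials`` offered
    solvable trials at each fixed delay, aggregating by delay and pattern.

    Offered trials split into chosen and declined according to the agent's
    own choice; declined trials run the counterfactual test (no reward).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfg = cfg or TaskConfig()
    rng = rng if rng is not None else np.random.default_rng()
    task_rng, noise_rng = rng.spawn(2)
    agent = _make_agent(agent_or_genome, cfg, noise_rng)

    counts: dict[tuple[int, str], dict[str, int]] = {}

    def bucket(delay: int, pattern: str) -> dict:
        key = (delay, pattern)
        if key not in counts:
            counts[key] = dict(
                n_forced=0, correct_forced=0, n_offered=0, n_taken=0,
                n_declined=0, correct_chosen=0, correct_declined=0,
            )
        return counts[key]

    for delay in delays:
        dcfg = TaskConfig(**{**cfg.__dict__, "fixed_delay": int(delay)})
        for forced in (True, False):
            for _ in range(n_trials):
                out = run_trial(
                    agent,
                    dcfg,
                    unsolvable=False,
                    force_skip_choice=forced,
                    force_offer_choice=not forced,
                    rng=task_rng,
                    test_after_decline=True,
                )
                b = bucket(delay, out.target)
                if forced:
                    b["n_forced"] += 1
                    b["correct_forced"] += int(out.correct)
                else:
                    b["n_offered"] += 1
                    counterfactual_hit = out.answered_pattern == out.target
                    if out.declined:
                        b["n_declined"] += 1
                        b["correct_declined"] += int(counterfactual_hit)
                    else:
                        b["n_taken"] += 1
                        b["correct_chosen"] += int(out.correct)

    rows = [
        {"delay": d, "pattern": p, **c} for (d, p), c in sorted(counts.items())
    ]
    return BehaviorSummary(table=_add_rates(pd.DataFrame(rows)), n_trials=n_trials)


def decline_rate_by_delay(
    summary: BehaviorSummary, alpha: float = 0.05
) -> pd.DataFrame:
    """Decline probability per delay with Clopper-Pearson confidence bounds.

    Delays with no choice-offered trials are reported with NaN rates rather
    than zero.
    """
    g = summary.by_delay()
    if len(g) < 2:
        raise ValueError("need summaries for at least 2 delay values")
    lo, hi = [], []
    for _, row in g.iterrows():
        n, k = int(row.n_offered), int(row.n_declined)
        if n == 0:
            lo.append(np.nan)
            hi.append(np.nan)
            continue
        ci = stats.binomtest(k, n).proportion_ci(
            confidence_level=1 - alpha, method="exact"
        )
        lo.append(ci.low)
        hi.append(ci.high)
    out = g[["delay", "n_offered", "n_declined", "p_decline"]].copy()
    out["ci_low"] = lo
    out["ci_high"] = hi
    return out


def record_trace(
    genome: Genome,
    cfg: Optional[TaskConfig] = None,
    rng: Optional[np.random.Generator] = None,
    unsolvable: bool = False,
    force_skip_choice: bool = False,
    force_offer_choice: bool = False,
    test_after_decline: bool = False,
) -> tuple[list[TraceStep], TrialOutcome]:
    """Run one trial while logging every network step.

    Returns the step records (phase, inputs, all unit outputs, modulation
    sums, full weight snapshot) together with the trial outcome.  Tracing
    never alters rewards or decisions.
    """
    cfg = cfg or TaskConfig()
    rng = rng if rng is not None else np.random.default_rng()
    task_rng, noise_rng = rng.spawn(2)
    recorder = TraceRecorder()
    agent = NetworkAgent.for_task(genome, cfg, noise_rng, recorder=recorder)
    outcome = run_trial(
        agent,
        cfg,
        unsolvable=unsolvable,
        force_skip_choice=force_skip_choice,
        force_offer_choice=force_offer_choice,
        rng=task_rng,
        test_after_decline=test_after_decline,
    )
    return recorder.steps, outcome


def trace_to_frame(steps: Sequence[TraceStep]) -> pd.DataFrame:
    """Tidy long-format trace: one row per (step, unit/connection, quantity)."""
    rows = []
    for s in steps:
        for i, v in enumerate(s.inputs):
            rows.append((s.step, s.phase, f"in_{i}", "input", v))
        for i, v in enumerate(s.outputs[N_INPUTS:]):
            rows.append((s.step, s.phase, f"neuron_{i}", "output", v))
        for i, v in enumerate(s.modulation_sums):
            rows.append((s.step, s.phase, f"neuron_{i}", "modulation_sum", v))
        nz = np.argwhere(s.weights != 0.0)
        for j, i in nz:
            rows.append((s.step, s.phase, f"w_{j}_{i}", "weight", s.weights[j, i]))
    return pd.DataFrame(
        rows, columns=["step", "phase", "unit", "quantity", "value"]
    )
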