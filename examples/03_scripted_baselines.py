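"""Check the task's reward accounting against closed-form expectations.

Scripted agents have analytically known expected fitness over the standard
schedule (T=300 trials, U=50 unsolvable, choice offered with p=2/3):
always-decline earns 50*2/3 + 250*2/3*0.3 = 83.33 and a uniform random
answerer earns 250/5 = 50.  Monte-Carlo totals should match.
"""

import numpy as np

from metamem import (
    GAConfig,
    TaskConfig,
    expected_scripted_fitness,
    run_trial,
    scripted_agent,
)

ga, cfg = GAConfig(), TaskConfig(fixed_delay=1)
rng = np.random.default_rng(1)
T, U = ga.tasks_per_eval, ga.unsolvable_per_eval

for policy in ["always_decline", "always_take_random", "perfect_oracle"]:
    totals = []
    for _ in range(20):
        agent = scripted_agent(policy, rng=rng)
        flags = np.zeros(T, dtype=bool)
        flags[rng.choice(T, U, replace=False)] = True
        totals.append(
            sum(run_trial(agent, cfg, unsolvable=bool(f), rng=rng).reward
                for f in flags)
        )
    mc = np.mean(totals)
    exact = expected_scripted_fitness(policy, ga, TaskConfig())
    print(f"{policy:20s} monte-carlo {mc:7.2f}   closed form {exact:7.2f}")

# Agreement here validates the reward rules, the 2/3 choice-phase rate and
# the unsolvable-trial bookkeeping in one shot.
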