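"""Behavioral assay: forced vs chosen vs declined accuracy, decline by delay.

The metamemory signature is (i) higher accuracy on tests the agent chose to
take than on forced tests, (ii) lower counterfactual accuracy on declined
tests, and (iii) a decline rate that grows with the delay.  A scripted agent
that declines with probability delay/(delay+10) and remembers nothing shows
the third signature only — useful to see what the summary looks like.
"""

import numpy as np

from metamem import TaskConfig, decline_rate_by_delay, run_behavior_assay
from metamem.agents import _Scripted


class ForgetfulDecliner(_Scripted):
    """Declines more with longer delays; answers at random when testing."""

    def __init__(self, rng):
        self.rng = rng
        self._delay_blocks = 0
        super().__init__()

    def reset(self):
        super().reset()
        self._delay_blocks = 0

    def _respond(self, kind, bits):
        if kind == "delay":
            self._delay_blocks += 1
        if kind == "choice":
            d = self._delay_blocks
            return (1.0 if self.rng.random() < d / (d + 10) else -1.0, -1.0)
        if kind == "test":
            remaining = 5 - self._test_seen + 1
            return (-1.0, 1.0 if self.rng.random() < 1 / remaining else -1.0)
        return (-1.0, -1.0)


rng = np.random.default_rng(2)
summary = run_behavior_assay(
    ForgetfulDecliner(rng), n_trials=400, delays=[1, 5, 20, 40],
    cfg=TaskConfig(), rng=rng,
)
cols = ["delay", "accuracy_forced", "accuracy_chosen", "accuracy_declined",
        "p_decline"]
print(summary.by_delay()[cols].round(3).to_string(index=False))
print()
print(decline_rate_by_delay(summary).round(3).to_string(index=False))

# Accuracies hover at chance (0.2) in all three protocols — this agent has
# no memory — while p_decline climbs with delay and its confidence interval
# brackets the scripted ground truth d/(d+10).
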