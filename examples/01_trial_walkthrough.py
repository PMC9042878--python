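"""Walk through single trials of the delayed-match-to-sample task.

A trial is: study (a one-hot 5-bit target), delay (the 00000 distractor a
random number of times), an optional choice phase (decline the test for a
guaranteed 0.3, or take it), and the test (answer the target among the five
patterns for 1.0).  On unsolvable trials the study stimulus is the
distractor and only declining pays (1.0).
"""

import numpy as np

from metamem import TaskConfig, run_trial, scripted_agent

rng = np.random.default_rng(0)
cfg = TaskConfig()

oracle = scripted_agent("perfect_oracle")
out = run_trial(oracle, cfg, rng=rng, force_skip_choice=True)
print("forced trial, perfect memory :", out.as_row())

out = run_trial(oracle, cfg, rng=rng, force_offer_choice=True)
print("offered trial, perfect memory:", out.as_row())

out = run_trial(oracle, cfg, unsolvable=True, rng=rng, force_offer_choice=True)
print("unsolvable trial, oracle     :", out.as_row())

decliner = scripted_agent("always_decline")
out = run_trial(decliner, cfg, rng=rng, force_offer_choice=True)
print("solvable trial, always-decline:", out.as_row())

# The rewards above are the full reward menu: 1.0 for a correct match or a
# justified decline on an unsolvable trial, 0.3 for declining a solvable
# trial, 0.0 otherwise.
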