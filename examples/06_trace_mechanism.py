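"""Record a full per-step trace of one trial for mechanism inspection.

Every network step logs the phase, the seven input values, all neuron
outputs, the modulation sums and a snapshot of the weight matrix — the raw
material for asking *how* an evolved network stores a pattern and decides
to decline (e.g., which modulatory neuron gates which connections).
"""

import numpy as np

from metamem import TaskConfig, make_toy_genome, record_trace, trace_to_frame

cfg = TaskConfig(fixed_delay=3)
steps, outcome = record_trace(
    make_toy_genome("full_random", seed=5), cfg, np.random.default_rng(3),
    force_offer_choice=True,
)

print("outcome:", outcome.as_row())
print(f"{len(steps)} steps recorded; phases:",
      " ".join(dict.fromkeys(s.phase for s in steps)))

df = trace_to_frame(steps)
print("\ntidy trace (first rows):")
print(df.head(8).to_string(index=False))
print(f"\n{len(df)} rows total; quantities: {sorted(df.quantity.unique())}")

# Weight rows only list nonzero connections; plotting 'output' of the two
# output neurons against 'phase' shows when the decline decision forms.
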