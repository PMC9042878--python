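"""Show neuromodulated gating on a minimal three-unit network.

One standard connection (input 0 -> decline neuron) is gated by a single
modulatory neuron driven from input 1.  While the modulator is silent the
extended-Hebbian update is multiplied by tanh(0) = 0 and every weight is
frozen; once the modulator activates, the weights into the gated neuron
start to move.
"""

import numpy as np

from metamem import build_phenotype, make_toy_genome, step_network

g = make_toy_genome("minimal_modulated")
state = build_phenotype(g)  # noise off, deterministic

print("step  modulator_drive  m_0      w(in1->n0)")
for step in range(10):
    drive = 0.0 if step < 5 else 1.0  # switch the modulator on at step 5
    step_network(state, [0.5, drive, 0, 0, 0, 0, 1], rng=None)
    print(
        f"{step:4d}  {drive:15.1f}  {state.modulation_sums[0]:7.3f}"
        f"  {state.weights[1, 0]:9.5f}"
    )

# w(in1->n0) stays exactly 0 while the modulation sum m_0 is 0, then grows
# once the modulatory neuron fires: plasticity is controlled, not constant.
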