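# metamem

Evolving metamemory in recurrent neural networks with neuromodulated
synaptic plasticity.

Metamemory — knowing whether you remember something — is probed in animals
with the delayed-match-to-sample (DMTS) paradigm plus an *escape option*: a
subject that can read the state of its own memory should decline the memory
test (for a small guaranteed reward) exactly when its trace has degraded,
and its accuracy on tests it *chose* to take should beat its accuracy on
forced tests. `metamem` is a constructive-modelling toolkit for this
question: it evolves small recurrent networks whose synaptic plasticity is
gated by dedicated modulatory neurons, runs them through the DMTS task with
the escape option, and provides the behavioral assays and full state
tracing needed to dissect how an evolved network monitors its own memory.

It is a library first (importable API plus the narrative scripts in
`examples/`), with a thin `metamem` command-line front end for long
evolution runs.

## Model

Each agent is a discrete-time recurrent network of tanh units: 7 inputs
(five pattern bits, a choice-phase signal, a constant bias) and up to 16
evolvable neurons, each *standard* or *modulatory*. Standard sources drive
the activation sum, modulatory sources drive a separate modulation sum:

    a_i = Σ_{j∈Std} w_ji · o_j        o_i = tanh(a_i + noise)
    m_i = Σ_{j∈Mod} w_ji · o_j

and the modulation gates an extended Hebbian weight update, applied each
step to every connection into a modulated neuron, with weights hard-clipped
to [-10, 10]:

    Δw_ji = tanh(m_i) · η · (A·o_j·o_i + B·o_j + C·o_i + D)

Because modulatory neurons can themselves be modulated, *second-order*
plasticity (learning of learning) can evolve — the ingredient associated
with memory monitoring in the narrow, second-order-representation sense.

The genome holds a genotype weight matrix in [-100, 100], per-neuron
type/active flags, and the rule parameters (η, A, B, C, D). Genotype
weights map to the phenotype through a cube with a dead zone
(`10·w³`, zero when `|w³| < 0.1`); A–D map through the plain dead-zoned
cube. A genetic algorithm (best-of-segment selection on segments of 5,
submatrix crossover, per-gene Gaussian mutation, insert/delete/duplicate
neuron operators) maximizes total reward over 300 trials per evaluation,
50 of them unsolvable (study stimulus `00000`, only declining pays).
The trial delay is drawn as `N_delay = ⌊-1/(λ·ln R)⌋ + 1` with λ = 0.7.

## Worked example

Reward accounting against closed-form baselines
(`python examples/03_scripted_baselines.py`):

```
always_decline       monte-carlo   84.11   closed form   83.33
always_take_random   monte-carlo   52.00   closed form   50.00
perfect_oracle       monte-carlo  283.15   closed form  283.33
```

An agent that always declines earns `50·⅔·1.0 + 250·⅔·0.3 = 83.33` in
expectation over the 300-trial schedule; a uniform random answerer earns
chance level `250/5 = 50`; a perfect memory earns `250 + 50·⅔ = 283.33`.
The Monte-Carlo totals produced by the simulator match, which validates the
reward rules, the 2/3 choice-phase rate and the unsolvable bookkeeping.

Neuromodulated gating on a minimal network
(`python examples/02_plasticity_gating.py`): while the modulatory neuron is
silent the gated weight stays exactly 0; two steps after the modulator's
drive switches on, `m_0` jumps to 10 and the weight starts to grow
(0 → 0.99991 → 1.99991 → …) — plasticity is under the network's own
control, which is what the decline circuit exploits.

A small evolution run (`python examples/04_evolve_small.py`, 50 agents,
20 generations, guided trials) lifts mean fitness from 4.72 to 6.04 with
the best agent at 14/30 correct — selection gets traction even at desk
scale. `examples/05_behavior_assay.py` and `examples/06_trace_mechanism.py`
show the behavioral summary (forced/chosen/declined accuracy, decline rate
by delay with confidence intervals) and the per-step trace export.

For a real run, use the CLI:

```sh
metamem evolve --seed 42 --out rundir/          # defaults: N=300, G=1000
metamem assay --genome rundir/best_genome.json --delay 40 --n 1000
metamem trace --genome rundir/best_genome.json --out trace.csv
```

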