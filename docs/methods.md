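# Methods

## Network dynamics

Units are updated synchronously: at each step every neuron computes its new
output from the *previous* step's outputs, so signals take one step per
connection to propagate (this is why each stimulus is presented for several
steps). Input units are pure sources — no tanh, no incoming connections —
and emit the supplied value plus Gaussian noise (σ = 0.1). Every neuron
adds Gaussian noise (σ = 0.0001) to its activation sum before the tanh; the
noise exists to select for robust solutions, not to drive dynamics.
Modulatory neurons compute their output exactly like standard neurons
(`o = tanh(a)`), but their outgoing signals accumulate into the target's
modulation sum `m_i` instead of its activation sum. Recurrent connections
and self-connections are allowed; modulatory neurons may modulate other
modulatory neurons, which is what makes second-order plasticity possible.

One step is: activation pass, then plasticity pass using the just-computed
outputs and modulation sums. A connection is plastic only if its
postsynaptic neuron currently has at least one nonzero incoming weight from
an active modulatory neuron; the update then applies to *all* of that
neuron's incoming connections (from inputs, standard and modulatory
sources alike). Weights are clipped to [-10, 10] after every update; this
clip, together with the bounded outputs, is the only stability mechanism
and is asserted as an invariant in the tests.

## Genotype → phenotype

Genotype weights live in [-100, 100] and map through `10·w³` with a dead
zone (`|w³| < 0.1` → 0, i.e. |w| < 0.464). The dead zone lets evolution
prune connections continuously; the cube expands resolution near zero.
Since the mapping can reach ±10⁵ at the genotype extremes, mapped weights
are clipped to the hard [-10, 10] range — we treat the weight range as
absolute. Rule coefficients A–D map through the same dead-zoned cube
without the ×10; η is used as-is.

Trial reset: by default a trial starts from the genome-derived phenotype
weights with neuron outputs drawn uniformly from (-1, 1). An alternative
reading — fresh *weights* uniform in [-10, 10] each trial, with the genome
then only contributing topology and the rule — is available as
`TaskConfig(reset_mode="random_weights")`; both are tested. We default to
the genome-derived mode because otherwise the evolved weight values would
never be expressed.

## Task

Defaults: λ = 0.7, CV = 0.25, p(choice offered) = 2/3, rewards
1.0 / 0.3 / 0.0, decision threshold 1/3, presentations repeated 3 steps
(4 in the choice phase). The decline decision is read from output neuron 0
after the last repetition of the choice block, the test answer from output
neuron 1 after each test-pattern block; the first pattern whose answer
output *strictly* exceeds 1/3 ends the trial. The decline rule is likewise
strict (`> 1/3` declines; exactly 1/3 takes), chosen to match the
test-phase rule's direction. Delay sampling draws R from the open interval
(0, 1) so the formula is always defined; each of the `N_delay` distractor
presentations lasts the usual 3 steps. Unsolvable trials differ only in
the study stimulus (the distractor) and the reward rule — delay and choice
phases run normally.

## Genetic algorithm

Fitness is the summed reward over T = 300 trials (U = 50 unsolvable at
uniformly random positions). During the first 100 generations evolution is
guided: the choice phase is force-skipped and no unsolvable trials occur,
so plain memory can evolve before the escape option is worth anything.
Selection partitions the population array into consecutive circular
segments of 5 at a uniformly random offset; the fittest member of each
segment (ties: lowest array index) emits 5 children — a copy, or with
probability 0.1 a crossover with a partner drawn uniformly from the whole
population. Crossover swaps the top-left r×c genotype submatrix
(r, c uniform over the matrix dimensions) and performs uniform crossover on
(η, A, B, C, D); neuron types and the active mask come from the first
parent. Mutation is per-gene: probability 0.1 of adding Gaussian noise
(σ = 0.3 for weights and A–D, σ = 3.0 for η), clipped to the genotype
ranges. Structural operators: one insertion trial per call (p = 0.04,
new neuron gets genotype weights uniform in [-1, 1] — mostly inside the
dead zone, so it starts nearly disconnected — and a random type), and
per-neuron deletion (0.06) and duplication (0.02) trials; operations that
would exceed 16 active neurons are skipped, and the two output neurons are
never deleted and always standard. Parents do not survive unmutated: every
slot in the next generation is a (mutated) child.

Genomes keep a fixed-shape (7+16) × 16 matrix with an active mask, so
crossover between different topologies is always well defined; deletion
zeroes the neuron's genotype row and column.

Initial population: output neurons plus 2 random-type hidden neurons,
genotype weights uniform in [-1, 1] (sparse phenotypes, like inserted
neurons), A–D uniform in [-1, 1], η uniform in [-10, 10] — large enough to
express strong learning after a few mutations without starting saturated.

## Randomness and determinism

All randomness flows through numpy PCG64 generators. A run derives
independent named streams (noise / task / GA) from one master seed;
fitness evaluation spawns per-individual child streams each generation, so
trial schedules and delays are resampled per individual per generation
(a `shared_schedule` option evaluates all individuals on identical streams
for variance reduction). Identical seeds give bitwise-identical
trajectories, histories and genomes; float comparisons in tests use 1e-9
relative tolerance.

## Behavioral assays

`run_behavior_assay` probes an agent at fixed delays (overriding the delay
law) with matched forced and choice-offered trial counts. Offered trials
split into chosen and declined by the agent's own decision; declined trials
run the test counterfactually — the answer is recorded, the reward stays
the 0.3 decline reward — so declined-test accuracy is measurable exactly as
"what would it have answered". Decline-rate curves carry Clopper–Pearson
intervals; empty delay bins are reported as missing, not zero. The trial
count behind a summary is a parameter, reported alongside the intervals.

## What the synthetic baselines show (and don't)

The scripted agents (always-decline, uniform-random answerer, perfect
oracle, constant output) have closed-form expected fitness, so the task
environment — rewards, choice-phase rate, unsolvable bookkeeping, delay
law — is validated independently of any network. Passing those checks says
nothing about whether a *particular* evolved network implements memory
monitoring; that question needs the assays (chosen > forced accuracy,
decline rising with delay) and trace inspection of the evolved genome, and
ultimately a human reading of the mechanism. Desk-scale evolution runs
(N = 50, G = 30, guided trials with delay 1 and noise off; T = 30) show
selection traction only; emergence of a full decline circuit requires runs
near the default scale (N = 300, G = 1000), and even there is a rare event
across seeds.

## Numerical choices and edge cases

- Decision thresholds are strict inequalities; an output of exactly 1/3
  takes the trial / does not select a pattern.
- The delay draw rejects R = 0 and resamples (measure-zero event).
- Weight clipping is applied after every plasticity pass, and the
  genotype clip after every mutation, so no operator can leave the legal
  ranges (property-tested).
- A modulated neuron whose modulatory input weight is driven to exactly 0
  mid-trial stops being plastic from the next step on; modulation status
  is recomputed from the current weights every step.
- Inactive neuron slots are masked out of the phenotype (rows, columns and
  plasticity), but their genotype entries persist and may be re-expressed
  by a later insertion, which overwrites them.

## Limitations

Rate-based, discrete-time dynamics only (no spiking, no continuous-time
integration); single-threaded evaluation; the assays quantify behavior but
do not automate the mechanistic classification of metamemory — the trace
exports are the input to that analysis, not its output.
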