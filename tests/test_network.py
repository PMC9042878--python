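"""Unit and property tests for the network dynamics and phenotype mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metamem import (
    Genome,
    InvalidGenomeError,
    PlasticityRule,
    apply_weight_updates,
    build_phenotype,
    compute_hebbian_delta,
    genotype_to_phenotype_param,
    genotype_to_phenotype_weight,
    make_toy_genome,
    step_network,
)
from metamem.network import MAX_NEURONS, MODULATORY, N_INPUTS, N_UNITS


class TestPhenotypeMapping:
    @pytest.mark.parametrize(
        "geno,pheno",
        [
            (1.0, 10.0),
            (0.4, 0.0),        # 0.4**3 = 0.064, inside the dead zone
            (-0.6, -2.16),
            (2.0, 10.0),       # 10*8 clipped to the hard weight range
            (-2.0, -10.0),
            (0.0, 0.0),
        ],
    )
    def test_weight_mapping(self, geno, pheno):
        assert genotype_to_phenotype_weight(geno) == pytest.approx(pheno)

    @pytest.mark.parametrize(
        "geno,pheno", [(0.4, 0.0), (1.0, 1.0), (-0.8, -0.512), (0.0, 0.0)]
    )
    def test_param_mapping(self, geno, pheno):
        assert genotype_to_phenotype_param(geno) == pytest.approx(pheno)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidGenomeError):
            genotype_to_phenotype_weight(float("nan"))
        with pytest.raises(InvalidGenomeError):
            genotype_to_phenotype_param(float("inf"))

    @given(st.floats(-100, 100))
    def test_weight_mapping_stays_in_range_with_dead_zone(self, w):
        p = genotype_to_phenotype_weight(w)
        assert abs(p) <= 10.0
        if abs(w**3) < 0.1:
            assert p == 0.0
        else:
            assert p != 0.0 or w == 0.0

    def test_vectorized_matches_scalar(self, rng):
        ws = rng.uniform(-100, 100, 50)
        vec = genotype_to_phenotype_weight(ws)
        assert np.allclose(vec, [genotype_to_phenotype_weight(w) for w in ws])


class TestBuildPhenotype:
    def test_zero_genome_is_all_zero(self):
        st_ = build_phenotype(make_toy_genome("zero"))
        assert not st_.weights.any()
        assert st_.rule.coefficients() == (0.0, 0.0, 0.0, 0.0)

    def test_single_weight_mapped(self):
        g = Genome()
        g.weights[0, 0] = 1.0
        st_ = build_phenotype(g)
        assert st_.weights[0, 0] == 10.0
        assert np.count_nonzero(st_.weights) == 1

    def test_inactive_neuron_masked(self, rng):
        g = make_toy_genome("full_random", seed=3)
        k = 5
        g.neuron_active[k] = False
        st_ = build_phenotype(g)
        assert not st_.weights[:, k].any()
        assert not st_.weights[N_INPUTS + k, :].any()

    def test_random_outputs_respect_active_mask(self, rng):
        g = make_toy_genome("minimal_modulated")
        st_ = build_phenotype(g, rng=rng)
        out = st_.neuron_outputs
        assert np.all(np.abs(out[[0, 1, 2]]) <= 1)
        assert not out[3:].any()

    def test_random_weight_reset_mode(self, rng):
        g = make_toy_genome("zero")
        st_ = build_phenotype(g, rng=rng, reset_mode="random_weights")
        active_cols = st_.weights[:, g.neuron_active]
        assert np.all(np.abs(active_cols) <= 10)
        assert active_cols.any()  # actually randomized, not zero

    def test_invalid_genome_rejected(self):
        g = Genome()
        g.neuron_active[0] = False  # output neuron must stay active
        with pytest.raises(InvalidGenomeError):
            build_phenotype(g)
        g2 = Genome()
        g2.weights[0, 0] = 101.0
        with pytest.raises(InvalidGenomeError):
            build_phenotype(g2)


class TestStepNetwork:
    def test_zero_network_stays_silent(self):
        st_ = build_phenotype(make_toy_genome("zero"))
        step_network(st_, np.zeros(7), rng=None)
        assert not st_.neuron_outputs.any()

    def test_saturated_connection(self):
        # one w=10 connection from an input held at 1 -> tanh(10)
        g = Genome()
        g.weights[0, 0] = 1.0
        st_ = build_phenotype(g)
        step_network(st_, [1, 0, 0, 0, 0, 0, 0], rng=None)  # latches input
        step_network(st_, [1, 0, 0, 0, 0, 0, 0], rng=None)
        assert st_.neuron_outputs[0] == pytest.approx(math.tanh(10.0), rel=1e-12)

    def test_modulatory_source_feeds_m_not_a(self):
        # neuron 2 (modulatory) is the only presynaptic unit of neuron 0:
        # neuron 0 must stay at activation 0 while m_0 follows the modulator
        g = Genome()
        g.neuron_active[2] = True
        g.neuron_type[2] = MODULATORY
        g.weights[1, 2] = 1.0                    # input 1 drives the modulator
        g.weights[N_INPUTS + 2, 0] = 1.0          # modulator -> neuron 0
        st_ = build_phenotype(g)
        x = [0, 1, 0, 0, 0, 0, 0]
        for _ in range(3):
            step_network(st_, x, rng=None)
        assert st_.activation_sums[0] == 0.0
        assert st_.modulation_sums[0] == pytest.approx(10 * math.tanh(10.0))
        assert st_.neuron_outputs[0] == 0.0

    def test_std_mod_separation_moves_contribution_exactly(self, rng):
        # flipping a presynaptic neuron's type moves its term from a_i to m_i
        g = make_toy_genome("full_random", seed=7)
        g.rule = PlasticityRule()  # freeze weights to isolate the sums
        j = 4
        g.neuron_type[j] = 0
        sa = build_phenotype(g)
        sb = build_phenotype(g.copy())
        sb.neuron_type[j] = MODULATORY
        out = np.zeros(N_UNITS)
        out[N_INPUTS:] = rng.uniform(-1, 1, MAX_NEURONS)
        sa.outputs = out.copy()
        sb.outputs = out.copy()
        x = rng.uniform(-1, 1, 7)
        step_network(sa, x, rng=None)
        step_network(sb, x, rng=None)
        contrib = out[N_INPUTS + j] * sa.weights[N_INPUTS + j, :]
        assert np.allclose(sa.activation_sums - contrib, sb.activation_sums)
        assert np.allclose(sa.modulation_sums + contrib, sb.modulation_sums)

    def test_wrong_arity_rejected(self):
        st_ = build_phenotype(make_toy_genome("zero"))
        with pytest.raises(ValueError):
            step_network(st_, [1, 2, 3], rng=None)

    def test_determinism_bitwise(self):
        g = make_toy_genome("full_random", seed=11)
        trajs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            st_ = build_phenotype(g, rng=rng)
            traj = []
            for _ in range(20):
                step_network(st_, [1, 0, 1, 0, 0, 1, 1], rng=rng)
                traj.append(st_.outputs.copy())
            trajs.append(np.array(traj))
        assert np.array_equal(trajs[0], trajs[1])


class TestHebbianRule:
    def test_zero_modulation_means_zero_delta(self):
        rule = PlasticityRule(eta=5.0, A=1.0, B=0.5, C=-0.5, D=1.0)
        assert compute_hebbian_delta(0.9, -0.9, 0.0, rule) == 0.0

    def test_saturated_gate_limit(self):
        rule = PlasticityRule(eta=1.0, D=1.0)
        assert compute_hebbian_delta(0.0, 0.0, 1e3, rule) == pytest.approx(1.0)

    def test_hand_worked_value(self):
        rule = PlasticityRule(eta=2.0, A=1.0)
        m = math.atanh(0.5)
        assert compute_hebbian_delta(1.0, 1.0, m, rule) == pytest.approx(1.0)

    def test_agrees_with_independent_scalar_form(self, rng):
        # independent re-implementation in plain python floats
        def oracle(oj, oi, mi, eta, A, B, C, D):
            return math.tanh(mi) * eta * (A * oj * oi + B * oj + C * oi + D)

        for _ in range(10_000):
            oj, oi = rng.uniform(-1, 1, 2)
            mi = rng.uniform(-50, 50)
            eta = rng.uniform(-100, 100)
            A, B, C, D = rng.uniform(-1, 1, 4)
            rule = PlasticityRule(eta=eta, A=A, B=B, C=C, D=D)
            assert compute_hebbian_delta(oj, oi, mi, rule) == pytest.approx(
                oracle(oj, oi, mi, eta, A, B, C, D), rel=1e-9, abs=1e-12
            )


class TestPlasticity:
    def test_clip_at_bound(self):
        st_ = build_phenotype(make_toy_genome("zero"))
        st_.weights[0, 0] = 9.5
        deltas = np.zeros_like(st_.weights)
        deltas[0, 0] = 2.0
        apply_weight_updates(st_, deltas)
        assert st_.weights[0, 0] == 10.0

    def test_zero_delta_identity(self):
        st_ = build_phenotype(make_toy_genome("minimal_modulated"))
        before = st_.weights.copy()
        apply_weight_updates(st_, np.zeros_like(before))
        assert np.array_equal(st_.weights, before)

    def test_unmodulated_neuron_frozen(self):
        # neuron 1 has inputs but no incoming modulatory connection;
        # a pure-decay rule (D=-1) erodes only the modulated neuron's weights
        g = make_toy_genome("minimal_modulated")
        g.weights[0, 1] = 1.0  # input 0 -> output neuron 1, unmodulated
        g.rule = PlasticityRule(eta=1.0, D=-1.0)
        st_ = build_phenotype(g)
        for _ in range(10):
            step_network(st_, [1, 1, 0, 0, 0, 0, 1], rng=None)
        assert st_.weights[0, 1] == 10.0  # untouched by plasticity
        assert st_.weights[0, 0] < 10.0  # the gated connection decayed

    def test_gating_frozen_when_modulator_silent(self):
        # with the modulatory neuron's drive off, all weights stay constant
        g = make_toy_genome("minimal_modulated")
        st_ = build_phenotype(g)
        x_off = [1, 0, 0, 0, 0, 0, 1]  # input 1 (modulator drive) off
        snaps = []
        for _ in range(10):
            step_network(st_, x_off, rng=None)
            snaps.append(st_.weights.copy())
        assert all(np.array_equal(snaps[0], s) for s in snaps[1:])

    def test_weight_bound_under_stress(self, rng):
        # extreme eta, saturating rule: weights must never leave [-10, 10]
        for seed in range(3):
            g = make_toy_genome("full_random", seed=seed)
            g.rule = PlasticityRule(eta=100.0, A=1.0, B=1.0, C=1.0, D=1.0)
            st_ = build_phenotype(g, rng=rng)
            for _ in range(200):
                step_network(st_, rng.uniform(-1, 1, 7), rng=rng)
                assert np.max(np.abs(st_.weights)) <= 10.0


class TestGenomeSerialization:
    def test_json_round_trip_lossless(self, tmp_path, rng):
        g = make_toy_genome("full_random", seed=21)
        g.meta = {"seed": 21, "generation": 7}
        path = tmp_path / "genome.json"
        g.save(path)
        g2 = Genome.load(path)
        assert np.array_equal(g.weights, g2.weights)
        assert np.array_equal(g.neuron_active, g2.neuron_active)
        assert np.array_equal(g.neuron_type, g2.neuron_type)
        assert g.rule == g2.rule
        assert g.meta == g2.meta
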