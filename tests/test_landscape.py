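"""Maximum-entropy fitting, energy landscape minima/basins, warning indices."""

import numpy as np
import pytest

from microdyn.landscape import (
    LandscapeError,
    PairwiseMaxEnt,
    basin_labels,
    basin_of,
    binarize,
    energy,
    energy_gap,
    enumerate_states,
    find_stable_states,
    stable_state_entropy,
    state_energies,
    state_index,
)
from tests.conftest import make_table


def random_model(rng, s, h_scale=1.0, j_scale=0.5):
    h = rng.normal(0, h_scale, s)
    J = rng.normal(0, j_scale, (s, s))
    J = (J + J.T) / 2
    np.fill_diagonal(J, 0)
    return PairwiseMaxEnt().set_parameters(h, J)


class TestBinarize:
    def test_occurrence_bounds_inclusive(self):
        # 100 samples: taxon A present 99% (excluded), B 2% (retained), C 50%
        arr = np.zeros((100, 3))
        arr[:99, 0] = 1.0
        arr[:2, 1] = 1.0
        arr[:50, 2] = 1.0
        bcm = binarize(make_table({1: arr}))
        assert bcm.taxon_ids == ["T001", "T002"]

    def test_tiny_positive_concentration_counts_as_presence(self):
        arr = np.zeros((10, 2))
        arr[:5, 0] = 1e-9
        arr[:5, 1] = 1.0
        bcm = binarize(make_table({1: arr}))
        assert (bcm.matrix[:5] == 1).all()

    def test_no_taxa_retained_is_an_error(self):
        arr = np.ones((10, 1))  # 100% occurrence: filtered out
        with pytest.raises(LandscapeError):
            binarize(make_table({1: arr}))


class TestEnergy:
    def test_all_zero_state_has_zero_energy(self, rng):
        m = random_model(rng, 4)
        assert m.energy([0, 0, 0, 0]) == 0.0

    def test_direct_substitution_two_taxa(self):
        m = PairwiseMaxEnt().set_parameters([1.0, 0.0], [[0, 2.0], [2.0, 0]])
        assert m.energy([1, 1]) == pytest.approx(-3.0)

    def test_null_model_is_flat(self):
        m = PairwiseMaxEnt().set_parameters(np.zeros(3), np.zeros((3, 3)))
        states = enumerate_states(3)
        assert np.allclose(state_energies(states, m.h_, m.J_), 0.0)

    def test_length_mismatch_fails(self, rng):
        with pytest.raises(ValueError):
            random_model(rng, 4).energy([1, 0])


class TestStateProbabilities:
    def test_single_taxon_no_bias_is_uniform(self):
        m = PairwiseMaxEnt().set_parameters([0.0], [[0.0]])
        assert np.allclose(m.state_probabilities(), [0.5, 0.5])

    def test_two_taxa_null_model_is_quarter_each(self):
        m = PairwiseMaxEnt().set_parameters(np.zeros(2), np.zeros((2, 2)))
        assert np.allclose(m.state_probabilities(), 0.25)

    def test_matches_bruteforce_oracle(self, rng):
        s = 6
        m = random_model(rng, s)
        p = m.state_probabilities()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        # term-by-term oracle
        weights = []
        for k in range(2**s):
            sigma = [(k >> i) & 1 for i in range(s)]
            e = -sum(m.h_[i] * sigma[i] for i in range(s)) - sum(
                m.J_[i, j] * sigma[i] * sigma[j]
                for i in range(s) for j in range(i + 1, s)
            )
            weights.append(np.exp(-e))
        oracle = np.asarray(weights) / np.sum(weights)
        assert np.allclose(p, oracle)


class TestFitMaxent:
    def test_uniform_data_fits_null_model(self, rng):
        x = (rng.random((10_000, 5)) < 0.5).astype(int)
        m = PairwiseMaxEnt(tol=1e-4).fit(x)
        assert np.abs(m.h_).max() < 0.15
        assert np.abs(m.J_).max() < 0.15

    def test_moments_match_empirical_at_convergence(self, rng):
        s = 5
        truth = random_model(rng, s)
        from microdyn.simulate import IsingSpec, sample_ising

        x = sample_ising(IsingSpec(h=truth.h_, J=truth.J_, n_samples=5000, seed=0))
        m = PairwiseMaxEnt(tol=1e-5).fit(x)
        assert m.converged_
        p = m.state_probabilities()
        sf = enumerate_states(s).astype(float)
        model_m1 = p @ sf
        emp_m1, _ = m.empirical_moments_
        assert np.abs(model_m1 - emp_m1).max() < 1e-4

    def test_zero_cooccurrence_stays_finite(self):
        # two taxa never co-occur: pseudocount keeps the fit finite
        x = np.array([[1, 0], [0, 1]] * 50)
        m = PairwiseMaxEnt(max_iter=2000).fit(x)
        assert np.all(np.isfinite(m.h_)) and np.all(np.isfinite(m.J_))
        assert m.J_[0, 1] < 0  # strong avoidance


class TestStableStates:
    def test_positive_bias_gives_all_ones_minimum(self):
        m = PairwiseMaxEnt().set_parameters(np.full(4, 5.0), np.zeros((4, 4)))
        minima = find_stable_states(m)
        assert len(minima) == 1
        assert (minima[0] == 1).all()

    def test_flat_landscape_has_no_strict_minima(self):
        m = PairwiseMaxEnt().set_parameters(np.zeros(3), np.zeros((3, 3)))
        assert find_stable_states(m) == []

    def test_two_guild_block_model_has_two_minima(self):
        s = 6
        h = np.full(s, 1.0)
        J = np.zeros((s, s))
        for i in range(s):
            for j in range(s):
                if i != j:
                    J[i, j] = 1.0 if (i < 3) == (j < 3) else -3.0
        m = PairwiseMaxEnt().set_parameters(h, J)
        minima = find_stable_states(m)
        codes = sorted(state_index(x) for x in minima)
        assert codes == [0b000111, 0b111000]

    def test_matches_exhaustive_neighbor_oracle(self, rng):
        for _ in range(20):
            m = random_model(rng, 6)
            states = enumerate_states(6)
            e = state_energies(states, m.h_, m.J_)
            oracle = []
            for k in range(64):
                neigh = [k ^ (1 << i) for i in range(6)]
                if all(e[k] < e[n] for n in neigh):
                    oracle.append(k)
            found = sorted(state_index(x) for x in find_stable_states(m))
            assert found == sorted(oracle)


class TestBasins:
    def test_minimum_maps_to_itself(self, rng):
        m = random_model(rng, 5)
        for minimum in find_stable_states(m):
            assert (basin_of(minimum, m) == minimum).all()

    def test_one_flip_above_unique_minimum(self):
        m = PairwiseMaxEnt().set_parameters(np.full(3, 4.0), np.zeros((3, 3)))
        assert (basin_of([1, 1, 0], m) == [1, 1, 1]).all()

    def test_labels_partition_state_space_at_s8(self, rng):
        m = random_model(rng, 8)
        labels = basin_labels(m)
        states = enumerate_states(8)
        e = state_energies(states, m.h_, m.J_)
        minima_idx = {state_index(x) for x in find_stable_states(m)}
        assert set(np.unique(labels)) == minima_idx
        # every state's label agrees with explicit steepest descent
        for k in [0, 17, 100, 255, 200]:
            assert labels[k] == state_index(basin_of(states[k], m))


class TestWarningIndices:
    def double_well(self):
        return PairwiseMaxEnt().set_parameters([2.0, 2.0], [[0, -4.0], [-4.0, 0]])

    def test_energy_gap_zero_at_minimum(self):
        m = self.double_well()
        assert energy_gap([1, 0], m) == 0.0

    def test_energy_gap_is_one_flip_energy_difference(self):
        m = self.double_well()
        # (1,1) descends to (1,0) or (0,1): dH = H(1,1) - H(1,0) = 0 - (-2)
        assert energy_gap([1, 1], m) == pytest.approx(2.0)

    def test_entropy_zero_for_single_minimum(self):
        m = PairwiseMaxEnt().set_parameters(np.full(3, 5.0), np.zeros((3, 3)))
        assert stable_state_entropy([0, 1, 0], m, n_walks=200, seed=0) == 0.0

    def test_entropy_near_zero_deep_in_a_well(self):
        m = PairwiseMaxEnt().set_parameters([8.0, 8.0], [[0, -20.0], [-20.0, 0]])
        assert stable_state_entropy([1, 0], m, n_walks=500, seed=1) == 0.0

    def test_entropy_bounded_by_log_n_minima(self, rng):
        for _ in range(5):
            m = random_model(rng, 5)
            minima = find_stable_states(m)
            if not minima:
                continue
            start = enumerate_states(5)[rng.integers(32)]
            h = stable_state_entropy(start, m, n_walks=300, seed=2)
            assert 0.0 <= h <= np.log(len(minima)) + 1e-12

    def test_no_minima_fails(self):
        m = PairwiseMaxEnt().set_parameters(np.zeros(2), np.zeros((2, 2)))
        with pytest.raises(LandscapeError):
            stable_state_entropy([0, 0], m, n_walks=10, seed=0)
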