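"""Shot sampling, readout-noise injection and M3-style correction."""

import numpy as np
import pytest

from conftest import random_state_vector
from vqchead.embeddings import angle_embed
from vqchead.mitigation import (
    ReadoutCalibration,
    ShotHistogram,
    apply_readout_noise,
    clip_and_renormalize,
    expectations_from_histogram,
    mitigate,
    sample_shots,
    total_variation,
)
from vqchead.statevector import PureState, pauli_z_expectations, plus_state, zero_state


class TestShotHistogram:
    def test_counts_must_sum_to_shots(self):
        with pytest.raises(ValueError):
            ShotHistogram(1, {"0": 5}, 10)

    def test_keys_must_be_bitstrings_of_right_length(self):
        with pytest.raises(ValueError):
            ShotHistogram(2, {"012": 10}, 10)

    def test_json_round_trip(self):
        h = ShotHistogram(2, {"00": 3, "11": 7}, 10)
        back = ShotHistogram.from_json(h.to_json())
        assert back.counts == h.counts and back.shots == 10


class TestSampling:
    def test_deterministic_state_gives_single_outcome(self):
        h = sample_shots(zero_state(1), 1000, seed=0)
        assert h.counts == {"0": 1000}

    def test_uniform_state_binomial_bounds(self):
        h = sample_shots(plus_state(2), 100_000, seed=1)
        sigma = np.sqrt(100_000 * 0.25 * 0.75)
        for key in ("00", "01", "10", "11"):
            assert abs(h.counts[key] - 25_000) <= 3 * sigma

    def test_same_seed_same_histogram(self, rng):
        s = PureState(3, random_state_vector(rng, 3))
        assert sample_shots(s, 500, seed=9).counts == \
               sample_shots(s, 500, seed=9).counts

    def test_zero_shots_rejected(self):
        with pytest.raises(ValueError):
            sample_shots(zero_state(1), 0)


class TestHistogramExpectations:
    def test_balanced_parity_pair(self):
        h = ShotHistogram(2, {"00": 500, "11": 500}, 1000)
        assert np.allclose(expectations_from_histogram(h), [0.0, 0.0])

    def test_all_zero_outcomes(self):
        h = ShotHistogram(1, {"0": 1000}, 1000)
        assert np.allclose(expectations_from_histogram(h), [1.0])

    def test_bitstring_orientation(self):
        # "10" = qubit 1 in state 1, qubit 0 in state 0
        h = ShotHistogram(2, {"10": 10}, 10)
        assert np.allclose(expectations_from_histogram(h), [1.0, -1.0])

    def test_converges_to_analytic_z(self, rng):
        state = angle_embed(rng.standard_normal(3))
        exact = pauli_z_expectations(state)
        h = sample_shots(state, 100_000, seed=2)
        est = expectations_from_histogram(h)
        assert np.all(np.abs(est) <= 1.0)
        assert np.abs(est - exact).max() <= 3.0 / np.sqrt(100_000)


class TestCalibration:
    def test_columns_must_be_stochastic(self):
        bad = np.array([[[0.9, 0.1], [0.2, 0.9]]])
        with pytest.raises(ValueError):
            ReadoutCalibration(bad)

    def test_json_round_trip(self):
        c = ReadoutCalibration.uniform_flip(3, 0.1)
        back = ReadoutCalibration.from_json(c.to_json())
        assert np.allclose(back.matrices, c.matrices)


class TestNoiseInjection:
    def test_identity_calibration_is_noop(self, rng):
        h = sample_shots(PureState(3, random_state_vector(rng, 3)), 2000, 3)
        noisy = apply_readout_noise(h, ReadoutCalibration.uniform_flip(3, 0.0), 4)
        assert noisy.counts == h.counts

    def test_symmetric_half_flip_randomizes(self):
        h = ShotHistogram(1, {"0": 1_000_000}, 1_000_000)
        noisy = apply_readout_noise(h, ReadoutCalibration.uniform_flip(1, 0.5), 5)
        sigma = np.sqrt(1e6 * 0.25)
        assert abs(noisy.counts["0"] - 500_000) <= 3 * sigma

    def test_deterministic_inversion(self):
        calib = ReadoutCalibration(np.array([
            [[1.0, 0.0], [0.0, 1.0]],     # qubit 0: faithful
            [[0.0, 1.0], [1.0, 0.0]],     # qubit 1: always flips
        ]))
        h = ShotHistogram(2, {"00": 10}, 10)
        noisy = apply_readout_noise(h, calib, 6)
        assert noisy.counts == {"10": 10}

    def test_shot_total_preserved(self, rng):
        h = sample_shots(PureState(2, random_state_vector(rng, 2)), 5000, 7)
        noisy = apply_readout_noise(h, ReadoutCalibration.uniform_flip(2, 0.2), 8)
        assert sum(noisy.counts.values()) == 5000


class TestMitigation:
    def test_identity_calibration_returns_frequencies(self):
        h = ShotHistogram(2, {"00": 250, "11": 750}, 1000)
        quasi = mitigate(h, ReadoutCalibration.uniform_flip(2, 0.0))
        assert quasi["00"] == pytest.approx(0.25)
        assert quasi["11"] == pytest.approx(0.75)

    def test_one_qubit_exact_inversion(self):
        # noisy frequencies (0.9, 0.1) under p=0.1 symmetric flip -> (1, 0)
        h = ShotHistogram(1, {"0": 900, "1": 100}, 1000)
        quasi = mitigate(h, ReadoutCalibration.uniform_flip(1, 0.1))
        assert quasi["0"] == pytest.approx(1.0, abs=1e-12)
        assert quasi["1"] == pytest.approx(0.0, abs=1e-12)

    def test_quasi_probabilities_sum_to_one(self, rng):
        state = PureState(3, random_state_vector(rng, 3))
        calib = ReadoutCalibration.uniform_flip(3, 0.08)
        noisy = apply_readout_noise(sample_shots(state, 4000, 1), calib, 2)
        quasi = mitigate(noisy, calib)
        assert abs(sum(quasi.values()) - 1.0) < 1e-6

    def test_singular_calibration_rejected(self):
        h = ShotHistogram(1, {"0": 10}, 10)
        with pytest.raises(np.linalg.LinAlgError):
            mitigate(h, ReadoutCalibration.uniform_flip(1, 0.5))

    def test_noise_then_mitigation_beats_raw_noise(self, rng):
        """TV distance to the true distribution drops after correction."""
        calib = ReadoutCalibration.uniform_flip(3, 0.1)
        wins = 0
        for trial in range(20):
            state = angle_embed(rng.standard_normal(3))
            truth = {format(i, "03b"): p
                     for i, p in enumerate(state.probabilities) if p > 0}
            clean = sample_shots(state, 100_000, 100 + trial)
            noisy = apply_readout_noise(clean, calib, 200 + trial)
            quasi = mitigate(noisy, calib)
            tv_raw = total_variation(noisy.frequencies(), truth)
            tv_fix = total_variation(quasi, truth)
            wins += tv_fix < tv_raw
        assert wins >= 19

    def test_error_shrinks_with_more_shots(self):
        calib = ReadoutCalibration.uniform_flip(2, 0.1)
        state = angle_embed(np.array([0.7, -0.4]))
        truth = {format(i, "02b"): p
                 for i, p in enumerate(state.probabilities)}

        def tv_at(shots, seed):
            noisy = apply_readout_noise(sample_shots(state, shots, seed),
                                        calib, seed + 1)
            return total_variation(mitigate(noisy, calib), truth)

        small = np.mean([tv_at(1000, s) for s in range(5)])
        large = np.mean([tv_at(100_000, 50 + s) for s in range(5)])
        assert large < small

    def test_clip_and_renormalize_is_simplex_projection(self):
        quasi = {"0": 1.02, "1": -0.02}
        fixed = clip_and_renormalize(quasi)
        assert fixed["0"] == pytest.approx(1.0)
        assert fixed["1"] == 0.0
        assert sum(fixed.values()) == pytest.approx(1.0)


class TestShotConvergenceRate:
    def test_three_sigma_bound_holds_in_99_percent_of_trials(self):
        """|empirical <Z> - exact <Z>| <= 3/sqrt(shots) almost always."""
        shots = 1000
        bound = 3.0 / np.sqrt(shots)
        rng = np.random.default_rng(77)
        hits = 0
        trials = 300
        for _ in range(trials):
            state = angle_embed(rng.standard_normal(4))
            exact = pauli_z_expectations(state)
            est = expectations_from_histogram(sample_shots(state, shots, rng))
            hits += np.abs(est - exact).max() <= bound
        assert hits / trials >= 0.99
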