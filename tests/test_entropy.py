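"""Entropy systems and the entropy-variation encoding.

The reference values come from the brute-force oracles in conftest.py,
which re-tally probability matrices with dictionaries and evaluate the
entropy definitions literally.
"""

import numpy as np
import pytest

from butyrsite import (
    ALPHABET,
    EntropySystem,
    augmented_system,
    build_system,
    encode_fragment,
    entropy_of_position,
    entropy_of_residue,
    iee_feature_names,
)
from butyrsite.entropy import IEEEncoder


class TestBuildSystem:
    def test_hand_tallied_probabilities(self, toy_pos_windows):
        system = build_system(toy_pos_windows)  # {"AKA", "CKA"}
        p = system.probabilities
        a, c, k = ALPHABET.index("A"), ALPHABET.index("C"), ALPHABET.index("K")
        assert p[a, 0] == 0.5 and p[c, 0] == 0.5
        assert p[k, 1] == 1.0
        assert p[a, 2] == 1.0

    def test_single_fragment_gives_point_masses(self):
        system = build_system(["AKA"])
        assert ((system.probabilities == 0) | (system.probabilities == 1)).all()
        assert (system.probabilities.max(axis=0) == 1).all()

    def test_column_sums_equal_one(self, toy_pos_windows):
        system = build_system(toy_pos_windows)
        np.testing.assert_allclose(system.probabilities.sum(axis=0), 1.0)

    def test_empty_and_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_system([])
        with pytest.raises(ValueError, match="inconsistent"):
            build_system(["AKA", "AAKAA"])


class TestEntropies:
    def test_hand_values_on_toy_system(self, toy_pos_windows):
        system = build_system(toy_pos_windows)
        # only position 1 contributes to A's profile: -0.5 log2 0.5 = 0.5
        assert entropy_of_residue(system, "A") == pytest.approx(0.5)
        assert entropy_of_position(system, 1) == pytest.approx(1.0)
        assert entropy_of_position(system, 2) == 0.0
        assert entropy_of_position(system, 3) == 0.0

    def test_absent_and_deterministic_residues_have_zero_entropy(
        self, toy_pos_windows
    ):
        system = build_system(toy_pos_windows)
        assert entropy_of_residue(system, "W") == 0.0  # never occurs
        assert entropy_of_residue(system, "K") == 0.0  # probability 1 at center

    def test_uniform_column_reaches_log2_21(self):
        windows = [f"{aa}KA" for aa in ALPHABET]
        system = build_system(windows)
        assert entropy_of_position(system, 1) == pytest.approx(np.log2(21))

    def test_unknown_residue_and_position_rejected(self, toy_pos_windows):
        system = build_system(toy_pos_windows)
        with pytest.raises(ValueError, match="outside the alphabet"):
            entropy_of_residue(system, "B")
        with pytest.raises(ValueError, match="out of range"):
            entropy_of_position(system, 4)

    def test_oracle_agreement_on_random_systems(self, oracles):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 11))
            length = int(rng.choice([3, 5, 7, 9]))
            windows = oracles["random_windows"](rng, n, length)
            system = build_system(windows)
            residue = str(rng.choice(list(ALPHABET)))
            position = int(rng.integers(1, length + 1))
            assert entropy_of_residue(system, residue) == pytest.approx(
                oracles["residue_entropy"](windows, residue), abs=1e-12
            )
            assert entropy_of_position(system, position) == pytest.approx(
                oracles["position_entropy"](windows, position - 1), abs=1e-12
            )

    def test_entropies_nonnegative_and_bounded(self, oracles):
        rng = np.random.default_rng(7)
        windows = oracles["random_windows"](rng, 10, 9)
        system = build_system(windows)
        assert (system.residue_entropies() >= 0).all()
        assert (system.position_entropies() >= 0).all()
        assert (system.position_entropies() <= np.log2(21) + 1e-12).all()


class TestAugmentedSystem:
    def test_counts_and_sample_size_increment(self, toy_pos_windows):
        system = build_system(toy_pos_windows)
        augmented = augmented_system(system, "AKC")
        assert augmented.n_samples == 3
        assert (augmented.counts.sum(axis=0) == 3).all()
        # the input system is untouched
        assert system.n_samples == 2
        assert (system.counts.sum(axis=0) == 2).all()

    def test_duplicate_sample_shifts_probabilities(self, toy_pos_windows):
        system = build_system(toy_pos_windows)
        augmented = augmented_system(system, "AKA")
        a = ALPHABET.index("A")
        assert augmented.probabilities[a, 0] == pytest.approx(2 / 3)

    def test_double_augment_differs_from_single(self, toy_pos_windows):
        system = build_system(toy_pos_windows)
        once = augmented_system(system, "AKA")
        twice = augmented_system(once, "AKA")
        assert twice.n_samples == once.n_samples + 1

    def test_length_mismatch_rejected(self, toy_pos_windows):
        system = build_system(toy_pos_windows)
        with pytest.raises(ValueError, match="length"):
            augmented_system(system, "AAKAA")


class TestEncodeFragment:
    def test_vector_layout(self, toy_pos_windows, toy_neg_windows):
        pos = build_system(toy_pos_windows)
        neg = build_system(toy_neg_windows, "negative")
        vector = encode_fragment(pos, neg, "AKC")
        assert vector.shape == (21 + 3,)
        assert len(iee_feature_names(3)) == 24

    def test_point_mass_duplicate_reduces_to_negative_variation(
        self, toy_neg_windows
    ):
        # a 1-sample system is unchanged by re-adding its only member,
        # so the positive variation vanishes and the code reduces to -NVIE*
        pos = build_system(["AKA"])
        neg = build_system(toy_neg_windows, "negative")
        vector = encode_fragment(pos, neg, "AKA")
        neg_aug = augmented_system(neg, "AKA")
        nviea = neg.residue_entropies() - neg_aug.residue_entropies()
        nviep = neg.position_entropies() - neg_aug.position_entropies()
        np.testing.assert_allclose(vector, -np.concatenate([nviea, nviep]))

    def test_purity(self, toy_pos_windows, toy_neg_windows):
        pos = build_system(toy_pos_windows)
        neg = build_system(toy_neg_windows, "negative")
        first = encode_fragment(pos, neg, "AKC")
        second = encode_fragment(pos, neg, "AKC")
        np.testing.assert_array_equal(first, second)
        assert pos.n_samples == 2 and neg.n_samples == 2  # no mutation

    def test_toy_vector_matches_bruteforce_oracle(
        self, oracles, toy_pos_windows, toy_neg_windows
    ):
        pos = build_system(toy_pos_windows)
        neg = build_system(toy_neg_windows, "negative")
        expected = oracles["encode"](toy_pos_windows, toy_neg_windows, "AKC")
        np.testing.assert_allclose(
            encode_fragment(pos, neg, "AKC"), expected, atol=1e-12
        )

    def test_oracle_agreement_on_random_systems(self, oracles):
        rng = np.random.default_rng(3)
        for _ in range(30):
            length = int(rng.choice([3, 5, 7, 9]))
            pos_windows = oracles["random_windows"](rng, int(rng.integers(1, 11)), length)
            neg_windows = oracles["random_windows"](rng, int(rng.integers(1, 11)), length)
            fragment = oracles["random_windows"](rng, 1, length)[0]
            pos = build_system(pos_windows)
            neg = build_system(neg_windows, "negative")
            np.testing.assert_allclose(
                encode_fragment(pos, neg, fragment),
                oracles["encode"](pos_windows, neg_windows, fragment),
                atol=1e-12,
            )

    def test_swapping_systems_negates_the_vector(
        self, toy_pos_windows, toy_neg_windows
    ):
        pos = build_system(toy_pos_windows)
        neg = build_system(toy_neg_windows, "negative")
        forward = encode_fragment(pos, neg, "AKC")
        neg2 = build_system(toy_neg_windows, "positive")
        pos2 = build_system(toy_pos_windows, "negative")
        backward = encode_fragment(neg2, pos2, "AKC")
        np.testing.assert_allclose(forward, -backward, atol=1e-15)


class TestSerialization:
    def test_system_round_trip(self, tmp_path, toy_pos_windows):
        system = build_system(toy_pos_windows)
        system.save(tmp_path / "system_positive")
        restored = EntropySystem.load(tmp_path / "system_positive")
        np.testing.assert_array_equal(restored.counts, system.counts)
        assert restored.n_samples == system.n_samples
        assert restored.polarity == system.polarity


class TestIEEEncoder:
    def test_fit_transform_shapes_and_names(self, oracles):
        rng = np.random.default_rng(5)
        windows = oracles["random_windows"](rng, 12, 9)
        y = np.array([1] * 6 + [0] * 6)
        enc = IEEEncoder().fit(windows, y)
        matrix = enc.transform(windows)
        assert matrix.shape == (12, 21 + 9)
        assert list(enc.get_feature_names_out()) == iee_feature_names(9)

    def test_leave_one_out_differs_from_shared_transform(self, oracles):
        rng = np.random.default_rng(9)
        windows = oracles["random_windows"](rng, 12, 9)
        y = np.array([1] * 6 + [0] * 6)
        enc = IEEEncoder().fit(windows, y)
        shared = enc.transform(windows)
        loo = enc.transform_training(windows, y)
        assert not np.allclose(shared, loo)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            IEEEncoder().fit(["AKA", "CKA"], [1, 1])
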