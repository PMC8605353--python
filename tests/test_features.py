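import numpy as np
import pytest

from rbpsite.features import (ContextFeaturizer, build_kmer_tensor,
                              dinucleotide_window_densities, fscore_rank,
                              project_sequence, structure_triplet_densities)


class TestDinucleotideDensities:
    def test_homopolymer_window(self):
        dens = dinucleotide_window_densities("AAAA", 4)
        assert dens.shape == (1, 16)
        assert dens[0, 0] == 1.0  # AA
        assert dens[0, 1:].sum() == 0.0

    def test_alternating_window(self):
        dens = dinucleotide_window_densities("ACAC", 4)[0]
        ac = 0 * 4 + 1
        ca = 1 * 4 + 0
        assert dens[ac] == pytest.approx(2 / 3)
        assert dens[ca] == pytest.approx(1 / 3)

    def test_densities_sum_to_one_on_n_free_windows(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGU"), size=60))
            w = int(rng.choice([17, 21, 31, 45]))
            dens = dinucleotide_window_densities(seq, w)
            assert np.allclose(dens.sum(axis=1), 1.0)

    def test_window_with_n_is_nan(self):
        dens = dinucleotide_window_densities("AANAA", 5)
        assert np.isnan(dens).all()

    def test_window_larger_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_window_densities("ACGU", 10)


class TestKmerTensor:
    def test_row_counts(self):
        seqs = ["ACGUACGUACGUACG"] * 3
        assert build_kmer_tensor(seqs, 5).n_rows == 1024
        assert build_kmer_tensor(seqs, 7).n_rows == 16384

    def test_position_count_is_length_minus_k_plus_one(self):
        seqs = ["ACGUACGUACGUACG"] * 2  # length 15
        assert build_kmer_tensor(seqs, 7).n_positions == 9

    def test_identical_training_set_budget_zero_gives_ones(self):
        seqs = ["ACGUACGUAC"] * 5
        tensor = build_kmer_tensor(seqs, 5, mismatch_budget=0)
        assert np.array_equal(project_sequence(tensor, seqs[0]),
                              np.ones(tensor.n_positions))

    def test_cells_are_probabilities(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), size=20)) for _ in range(8)]
        tensor = build_kmer_tensor(seqs, 5)
        assert tensor.probs.min() >= 0.0 and tensor.probs.max() <= 1.0

    def test_cell_matches_direct_hamming_count(self, rng):
        """Tensor cells equal a direct per-position Hamming-ball count."""
        from rbpsite.kmercode import hamming_distance

        seqs = ["".join(rng.choice(list("ACGU"), size=12)) for _ in range(6)]
        tensor = build_kmer_tensor(seqs, 5, mismatch_budget=2)
        query = "ACGUA"
        for p in range(tensor.n_positions):
            direct = sum(hamming_distance(s[p : p + 5], query) <= 2
                         for s in seqs) / len(seqs)
            from rbpsite.kmercode import encode_kmer

            assert tensor.probs[encode_kmer(query), p] == pytest.approx(direct)

    def test_projection_of_distant_sequence_is_zero(self):
        tensor = build_kmer_tensor(["A" * 12], 5, mismatch_budget=0)
        assert np.array_equal(project_sequence(tensor, "C" * 12),
                              np.zeros(tensor.n_positions))

    def test_projection_separates_planted_from_background(self, rng):
        motif = "ACGUACG"
        train = []
        for _ in range(40):
            s = list("".join(rng.choice(list("ACGU"), size=21)))
            s[7:14] = motif
            train.append("".join(s))
        tensor = build_kmer_tensor(train, 7)
        bg = ["".join(rng.choice(list("ACGU"), size=21)) for _ in range(40)]
        pos_vals = np.mean([project_sequence(tensor, s)[7] for s in train])
        bg_vals = np.mean([project_sequence(tensor, s)[7] for s in bg])
        assert pos_vals > bg_vals + 0.3

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_tensor(["ACGUACGU", "ACGUACG"], 5)


class TestStructureTriplets:
    def test_alphabet_size(self):
        assert structure_triplet_densities("." * 10).shape == (27,)

    def test_unpaired_run(self):
        dens = structure_triplet_densities("....")
        assert dens[0] == 1.0 and dens[1:].sum() == 0.0

    def test_open_run(self):
        dens = structure_triplet_densities("((((")
        idx = 1 * 9 + 1 * 3 + 1  # "((("
        assert dens[idx] == 1.0

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError):
            structure_triplet_densities("..X.")


class TestFScore:
    def test_identical_classes_give_zero(self):
        X = np.ones((10, 3))
        y = np.array([1] * 5 + [0] * 5)
        stats = fscore_rank(X, y)
        assert np.allclose(stats.fscores, 0.0)

    def test_printed_formula_example(self):
        X = np.array([[1.0], [1.0], [0.0], [0.0], [0.0], [0.0]])
        y = np.array([1, 1, 1, 0, 0, 0])
        stats = fscore_rank(X, y)
        assert stats.fscores[0] == pytest.approx(2 / 3, rel=1e-9)

    def test_label_swap_invariance(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.integers(0, 2, size=30)
        while len(set(y)) < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
            y = rng.integers(0, 2, size=30)
        a = fscore_rank(X, y).fscores
        b = fscore_rank(X, 1 - y).fscores
        assert np.allclose(a, b)

    def test_matches_direct_formula_on_random_matrices(self, rng):
        """Independent oracle: direct transliteration of the F equation."""
        for _ in range(100):
            n_pos = int(rng.integers(2, 12))
            n_neg = int(rng.integers(2, 12))
            d = int(rng.integers(1, 6))
            Xp = rng.normal(size=(n_pos, d))
            Xn = rng.normal(size=(n_neg, d))
            X = np.vstack([Xp, Xn])
            y = np.array([1] * n_pos + [0] * n_neg)
            got = fscore_rank(X, y).fscores
            for i in range(d):
                xp, xn = Xp[:, i], Xn[:, i]
                xall = X[:, i]
                num = (xp.mean() - xall.mean()) ** 2 + (xn.mean() - xall.mean()) ** 2
                den = (((xp - xp.mean()) ** 2).sum() / (n_pos - 1)
                       + ((xn - xn.mean()) ** 2).sum() / (n_neg - 1))
                assert got[i] == pytest.approx(num / (den + 1e-12), abs=1e-10)

    def test_single_instance_class_rejected(self):
        with pytest.raises(ValueError):
            fscore_rank(np.ones((3, 2)), np.array([1, 0, 0]))


class TestContextFeaturizer:
    def make_data(self, rng, n=30, length=56):
        motif = "ACGUAC"
        seqs, labels = [], []
        for i in range(n):
            s = list("".join(rng.choice(list("ACGU"), size=length)))
            if i % 2 == 0:
                s[25:31] = motif
                labels.append(1)
            else:
                labels.append(0)
            seqs.append("".join(s))
        return seqs, np.array(labels)

    def test_schema_stable_across_transform_calls(self, rng):
        seqs, labels = self.make_data(rng)
        fz = ContextFeaturizer(window_size=17)
        fz.fit(seqs, labels)
        a = fz.transform(seqs[:5])
        b = fz.transform(seqs[5:10])
        assert a.shape[1] == b.shape[1] == fz.n_features_
        assert len(fz.feature_names_) == fz.n_features_

    def test_disabling_heptamers_shrinks_by_block_length(self, rng):
        seqs, labels = self.make_data(rng)
        full = ContextFeaturizer(window_size=17).fit(seqs, labels)
        no7 = ContextFeaturizer(window_size=17, use_heptamer=False).fit(seqs, labels)
        heptamer_block = len(seqs[0]) - 7 + 1
        assert full.n_features_ - no7.n_features_ == heptamer_block

    def test_strict_columns_compatibility_flag(self, rng):
        seqs, labels = self.make_data(rng)
        strict = ContextFeaturizer(window_size=17, strict_columns=True).fit(
            seqs, labels)
        standard = ContextFeaturizer(window_size=17).fit(seqs, labels)
        assert standard.n_features_ - strict.n_features_ == 2  # one per tensor

    def test_tensors_built_from_training_positives_only(self, rng):
        """No test-set leakage: tensors depend only on (train, positive)."""
        seqs, labels = self.make_data(rng)
        fz1 = ContextFeaturizer(window_size=17).fit(seqs, labels)
        # perturbing a NEGATIVE leaves the tensors unchanged
        seqs2 = list(seqs)
        neg_idx = int(np.nonzero(labels == 0)[0][0])
        seqs2[neg_idx] = "U" * len(seqs[0])
        fz2 = ContextFeaturizer(window_size=17).fit(seqs2, labels)
        assert np.array_equal(fz1.tensors_[7].probs, fz2.tensors_[7].probs)
        # perturbing a POSITIVE changes them
        seqs3 = list(seqs)
        pos_idx = int(np.nonzero(labels == 1)[0][0])
        seqs3[pos_idx] = "U" * len(seqs[0])
        fz3 = ContextFeaturizer(window_size=17).fit(seqs3, labels)
        assert not np.array_equal(fz1.tensors_[7].probs, fz3.tensors_[7].probs)

    def test_length_mismatch_rejected(self, rng):
        seqs, labels = self.make_data(rng)
        fz = ContextFeaturizer(window_size=17).fit(seqs, labels)
        with pytest.raises(ValueError):
            fz.transform(["ACGU" * 10])

    def test_structure_block_appended_only_when_enabled(self, rng):
        seqs, labels = self.make_data(rng)
        fz = ContextFeaturizer(window_size=17, use_structure=True).fit(seqs, labels)
        structures = ["." * len(seqs[0])] * 3
        X = fz.transform(seqs[:3], structures=structures)
        assert X.shape[1] == fz.n_features_
        assert fz.feature_names_[-27].startswith("struct_")
        with pytest.raises(ValueError):
            fz.transform(seqs[:3])  # structures required once enabled
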