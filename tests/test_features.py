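import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqddg.features import (
    PHYSCHEM_NAMES,
    FeatureConfig,
    PhyschemTable,
    assemble_feature_vector,
    neighbor_conservation_scores,
    physicochemical_features,
    psepssm_vector,
    sequence_neighbor_labels,
)
from seqddg.pssm import ALPHABET, NormalizedPSSM, PSSM
from seqddg.seqdata import Mutation, ProteinSequence
from seqddg.synth import synth_pssm, synth_sequence


def naive_psepssm(P, lag_max):
    """Independent brute-force oracle: explicit double loop over the definition."""
    L, _ = P.shape
    out = []
    for j in range(20):
        out.append(sum(P[i, j] for i in range(L)) / L)
    for g in range(1, lag_max + 1):
        for j in range(20):
            acc = 0.0
            for i in range(L - g):
                acc += (P[i, j] - P[i + g, j]) ** 2
            out.append(acc / (L - g))
    return np.array(out)


def _npssm(mat):
    return NormalizedPSSM("t", np.asarray(mat, dtype=float))


class TestPsePSSM:
    def test_constant_matrix_has_zero_lag_terms(self):
        v = psepssm_vector(_npssm(np.full((9, 20), 0.37)), lag_max=2)
        assert np.allclose(v[:20], 0.37)
        assert np.allclose(v[20:], 0.0)
        assert len(v) == 60

    def test_two_row_hand_example(self):
        mat = np.zeros((2, 20))
        mat[1, 0] = 1.0  # column 0 is (0, 1)
        v = psepssm_vector(_npssm(mat), lag_max=1)
        assert v[0] == pytest.approx(0.5)  # mean
        assert v[20] == pytest.approx(1.0)  # (0-1)^2 / (2-1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True)
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((12, 20))
        fast = psepssm_vector(_npssm(P), lag_max=7)
        assert np.max(np.abs(fast - naive_psepssm(P, 7))) < 1e-12

    def test_lag_at_least_length_is_an_error(self):
        with pytest.raises(ValueError, match="lag_max"):
            psepssm_vector(_npssm(np.zeros((5, 20))), lag_max=5)


class TestNeighborConservation:
    def test_default_length_is_140(self):
        P = np.random.default_rng(0).random((20, 20))
        v = neighbor_conservation_scores(_npssm(P), Mutation("A", 10, "G"), 3)
        assert len(v) == 140

    def test_central_window_covers_whole_short_protein(self):
        P = np.random.default_rng(1).random((7, 20))
        v = neighbor_conservation_scores(_npssm(P), Mutation("A", 4, "G"), 3)
        assert np.array_equal(v, P.ravel())

    def test_terminal_mutation_zero_padded(self):
        P = np.random.default_rng(2).random((10, 20))
        v = neighbor_conservation_scores(_npssm(P), Mutation("A", 1, "G"), 3)
        assert np.all(v[:60] == 0)  # 3 padded rows before the terminus
        assert np.array_equal(v[60:], P[:4].ravel())

    def test_depends_on_position_not_mutant_residue(self):
        P = np.random.default_rng(3).random((15, 20))
        a = neighbor_conservation_scores(_npssm(P), Mutation("A", 8, "G"), 3)
        b = neighbor_conservation_scores(_npssm(P), Mutation("A", 8, "W"), 3)
        assert np.array_equal(a, b)


class TestSequenceNeighbors:
    def test_interior_site_reads_off_neighbors(self):
        seq = ProteinSequence("p", "ACDEFGHIKLM")
        v = sequence_neighbor_labels(seq, Mutation("G", 6, "A"), span=5)
        expected = [ALPHABET.index(c) for c in "ACDEF"] + [
            ALPHABET.index(c) for c in "HIKLM"
        ]
        assert list(v) == expected

    def test_terminal_site_gets_pad_labels(self):
        seq = ProteinSequence("p", "ACDEFGHIKLM")
        v = sequence_neighbor_labels(seq, Mutation("A", 1, "G"), span=5)
        assert list(v[:5]) == [20] * 5
        assert list(v[5:]) == [ALPHABET.index(c) for c in "CDEFG"]

    def test_length_is_twice_span(self):
        seq = ProteinSequence("p", "ACDEFGHIKLM")
        for span in (1, 3, 5):
            assert len(sequence_neighbor_labels(seq, Mutation("G", 6, "A"), span)) == 2 * span

    def test_one_hot_expansion(self):
        seq = ProteinSequence("p", "ACDEFGHIKLM")
        v = sequence_neighbor_labels(seq, Mutation("A", 1, "G"), span=2, one_hot=True)
        assert len(v) == 80
        assert v[:40].sum() == 0  # two pad neighbors -> all-zero indicators
        assert v[40:].sum() == 2


class TestPhyschem:
    def test_nine_features_in_fixed_order(self):
        v = physicochemical_features(Mutation("R", 175, "H"))
        assert len(v) == len(PHYSCHEM_NAMES) == 9

    def test_net_terms_are_antisymmetric(self):
        fwd = physicochemical_features(Mutation("G", 10, "A"))
        rev = physicochemical_features(Mutation("A", 10, "G"))
        for idx in (0, 1, 3):  # net volume, net hydrophobicity, net flexibility
            assert fwd[idx] == pytest.approx(-rev[idx])

    def test_small_to_large_has_positive_net_volume(self):
        t = PhyschemTable()
        v = physicochemical_features(Mutation("A", 1, "V"), t)
        assert v[0] == pytest.approx(t.volume["V"] - t.volume["A"])
        assert v[0] > 0

    def test_categorical_codes_follow_mutant(self):
        t = PhyschemTable()
        v = physicochemical_features(Mutation("A", 1, "W"), t)
        assert v[4] == t.chem_class["W"]
        assert v[2] == 7 * t.chem_class["A"] + t.chem_class["W"]

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            PhyschemTable(volume={"A": 88.6})


class TestAssembly:
    def _inputs(self, length=30, pos=15):
        rng = np.random.default_rng(7)
        seq = synth_sequence(length, rng, pid="p")
        p = synth_pssm(seq, 8.0, seed=11)
        wt = seq.residue_at(pos)
        mut = "A" if wt != "A" else "G"
        return seq, p, Mutation(wt, pos, mut)

    def test_default_length_and_group_counts(self):
        seq, p, m = self._inputs()
        fv = assemble_feature_vector(seq, p, m)
        assert len(fv.values) == 319
        counts = {}
        for g, _ in fv.schema:
            counts[g] = counts.get(g, 0) + 1
        assert counts == {"psepssm": 160, "neighbor_cs": 140,
                          "seq_neighbor": 10, "physchem": 9}

    def test_same_site_mutations_differ_only_in_physchem(self):
        seq, p, m = self._inputs()
        other = Mutation(m.wt, m.pos, "W" if m.mut != "W" else "Y")
        a = assemble_feature_vector(seq, p, m).values
        b = assemble_feature_vector(seq, p, other).values
        assert np.array_equal(a[:310], b[:310])  # psepssm+neighbor_cs+seq_neighbor
        assert not np.array_equal(a[310:], b[310:])

    def test_deterministic(self):
        seq, p, m = self._inputs()
        a = assemble_feature_vector(seq, p, m).values
        b = assemble_feature_vector(seq, p, m).values
        assert np.array_equal(a, b)

    def test_invalid_mutation_rejected(self):
        seq, p, m = self._inputs()
        bad = Mutation("A" if m.wt != "A" else "G", m.pos, "C")
        with pytest.raises(ValueError, match="does not validate"):
            assemble_feature_vector(seq, p, bad)

    @given(
        lag_max=st.integers(1, 9),
        flank=st.integers(0, 4),
        span=st.integers(0, 6),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_length_closed_form_across_configs(self, lag_max, flank, span):
        cfg = FeatureConfig(lag_max=lag_max, window_flank=flank, neighbor_span=span)
        seq, p, m = self._inputs(length=40, pos=20)
        fv = assemble_feature_vector(seq, p, m, cfg)
        expected = (20 + 20 * lag_max) + 20 * (2 * flank + 1) + 2 * span + 9
        assert len(fv.values) == expected == len(cfg.schema())
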