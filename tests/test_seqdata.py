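import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqddg.seqdata import (
    AMINO_ACIDS,
    InvalidMutationError,
    Mutation,
    MutationDataset,
    MutationParseError,
    MutationRecord,
    ProteinSequence,
    filter_unknown_residues,
    format_mutation,
    homology_partition,
    parse_mutation,
    read_fasta,
    sequence_identity,
    validate_mutation_against_sequence,
    write_fasta,
)


class TestParseMutation:
    @pytest.mark.parametrize(
        "spec,expected",
        [("R175H", ("R", 175, "H")), ("A1G", ("A", 1, "G")), ("W999C", ("W", 999, "C"))],
    )
    def test_valid_specs(self, spec, expected):
        m = parse_mutation(spec)
        assert (m.wt, m.pos, m.mut) == expected

    @pytest.mark.parametrize("spec", ["", "175H", "R175", "R17.5H", "rh175h", "R0H "])
    def test_malformed_specs_name_the_offender(self, spec):
        with pytest.raises((MutationParseError, ValueError)):
            parse_mutation(spec)

    def test_silent_substitution_rejected(self):
        with pytest.raises(InvalidMutationError):
            parse_mutation("A5A")

    @given(
        wt=st.sampled_from(AMINO_ACIDS),
        pos=st.integers(min_value=1, max_value=99999),
        mut=st.sampled_from(AMINO_ACIDS),
    )
    @settings(max_examples=100, derandomize=True)
    def test_format_parse_roundtrip(self, wt, pos, mut):
        if wt == mut:
            return
        m = Mutation(wt, pos, mut)
        assert parse_mutation(format_mutation(m)) == m


class TestValidation:
    @pytest.mark.parametrize(
        "seq,spec,ok",
        [("ACDEF", "A1G", True), ("ACDEF", "C1G", False), ("ACDEF", "A9G", False),
         ("ACDEF", "F5A", True)],
    )
    def test_mutation_against_sequence(self, seq, spec, ok):
        s = ProteinSequence("p", seq)
        assert validate_mutation_against_sequence(s, parse_mutation(spec)) is ok

    def test_dataset_rejects_mismatched_record(self):
        seqs = {"p": ProteinSequence("p", "ACDEF")}
        rec = MutationRecord("p", Mutation("C", 1, "G"), 0.0)
        with pytest.raises(ValueError, match="does not match"):
            MutationDataset([rec], seqs)

    def test_sequence_alphabet_enforced(self):
        with pytest.raises(ValueError):
            ProteinSequence("p", "ACDB")
        # X tolerated pre-filtering
        assert len(ProteinSequence("p", "ACXDE")) == 5


class TestFilterUnknownResidues:
    def _ds(self):
        seqs = {"p": ProteinSequence("p", "ACXDE")}
        recs = [
            MutationRecord("p", Mutation("A", 1, "G"), 0.1),
            MutationRecord("p", Mutation("C", 2, "X"), 0.2),  # mutant unknown
            MutationRecord("p", Mutation("X", 3, "G"), 0.3),  # wild-type unknown
            MutationRecord("p", Mutation("D", 4, "E"), 0.4),
        ]
        return MutationDataset(recs, seqs)

    def test_removes_x_records_preserving_order(self):
        out = filter_unknown_residues(self._ds())
        assert [str(r.mutation) for r in out.records] == ["A1G", "D4E"]

    def test_idempotent(self):
        once = filter_unknown_residues(self._ds())
        twice = filter_unknown_residues(once)
        assert [r.mutation for r in twice.records] == [r.mutation for r in once.records]

    def test_empty_dataset_is_identity(self):
        ds = MutationDataset([], {"p": ProteinSequence("p", "ACDE")})
        assert len(filter_unknown_residues(ds)) == 0


class TestSequenceIdentity:
    def test_identical_sequences_are_100(self):
        a = ProteinSequence("a", "MKTAYIAKQR")
        assert sequence_identity(a, a) == 100.0

    def test_single_mismatch_no_gaps(self):
        # global alignment, no gap opened: 3 identities over length 4
        a, b = ProteinSequence("a", "ACDE"), ProteinSequence("b", "ACDF")
        assert sequence_identity(a, b) == pytest.approx(75.0)

    def test_totally_dissimilar_is_0(self):
        a, b = ProteinSequence("a", "AAAA"), ProteinSequence("b", "WWWW")
        assert sequence_identity(a, b) == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        mk = lambda pid: ProteinSequence(
            pid, "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, rng.integers(5, 30)))
        )
        a, b = mk("a"), mk("b")
        r = sequence_identity(a, b)
        assert 0.0 <= r <= 100.0
        assert r == pytest.approx(sequence_identity(b, a))
        assert (r == 100.0) == (a.residues == b.residues)


class TestHomologyPartition:
    def test_nonhomologous_proteins_split_at_fraction(self, toy_dataset):
        # extend to 10 proteins with one record each via two copies of fixture pattern
        train, test = homology_partition(toy_dataset, 0.2, 30.0, seed=1)
        assert len(test) == 1 and len(train) == 4

    def test_partition_is_exact(self, toy_dataset):
        train, test = homology_partition(toy_dataset, 0.4, 30.0, seed=3)
        all_keys = {(r.protein_id, str(r.mutation)) for r in toy_dataset.records}
        tr = {(r.protein_id, str(r.mutation)) for r in train.records}
        te = {(r.protein_id, str(r.mutation)) for r in test.records}
        assert tr | te == all_keys and not (tr & te)
        assert not (set(train.protein_ids()) & set(test.protein_ids()))

    def test_identical_proteins_never_split(self):
        seq = ProteinSequence("a", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        seqs = {"a": seq, "b": ProteinSequence("b", seq.residues),
                "c": ProteinSequence("c", "GWLDFWDDPNCVHHRRTGWPLLLPHGYEYKQMG")}
        recs = [MutationRecord(p, Mutation(seqs[p].residue_at(3), 3,
                                           "A" if seqs[p].residue_at(3) != "A" else "G"),
                               0.0) for p in seqs]
        ds = MutationDataset(recs, seqs)
        for seed in range(8):
            train, test = homology_partition(ds, 0.34, 30.0, seed=seed)
            sides = [set(d.protein_ids()) for d in (train, test)]
            # a and b are identical: must land on the same side
            assert ({"a", "b"} <= sides[0]) or ({"a", "b"} <= sides[1])

    def test_deterministic_given_seed(self, toy_dataset):
        one = homology_partition(toy_dataset, 0.4, 30.0, seed=9)
        two = homology_partition(toy_dataset, 0.4, 30.0, seed=9)
        assert [r.mutation for r in one[1].records] == [r.mutation for r in two[1].records]

    def test_all_homologous_is_infeasible(self):
        base = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        seqs = {p: ProteinSequence(p, base) for p in ("a", "b", "c")}
        recs = [MutationRecord(p, Mutation("M", 1, "A"), 0.0) for p in seqs]
        ds = MutationDataset(recs, seqs)
        with pytest.raises(ValueError, match="no valid"):
            homology_partition(ds, 0.34, 30.0, seed=0)


class TestIO:
    def test_fasta_roundtrip(self, tmp_path, toy_dataset):
        path = tmp_path / "seqs.fasta"
        write_fasta(toy_dataset.sequences, path, width=13)  # force wrapping
        back = read_fasta(path)
        assert {k: v.residues for k, v in back.items()} == {
            k: v.residues for k, v in toy_dataset.sequences.items()
        }

    def test_dataset_csv_roundtrip(self, tmp_path, toy_dataset):
        path = tmp_path / "ds.csv"
        toy_dataset.to_csv(path)
        back = MutationDataset.from_csv(path, toy_dataset.sequences)
        assert [(r.protein_id, str(r.mutation), r.target) for r in back.records] == [
            (r.protein_id, str(r.mutation), r.target) for r in toy_dataset.records
        ]
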