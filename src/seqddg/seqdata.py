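"""Sequences, mutations, dataset I/O, and homology-aware partitioning.

Positions are 1-based throughout, matching the WposM mutation notation
(e.g. ``R175H`` = Arg at position 175 replaced by His).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class MutationParseError(ValueError):
    """Raised when a WposM mutation specification cannot be parsed."""


class InvalidMutationError(ValueError):
    """Raised when a parsed mutation is not a real substitution (wt == mut)."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein chain: an identifier plus its one-letter residue string.

    ``X`` (unknown residue) is tolerated so that raw datasets can be loaded
    and then cleaned with :func:`filter_unknown_residues`.
    """

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside 1..{len(self.residues)}")
        return self.residues[pos - 1]


@dataclass(frozen=True)
class Mutation:
    """A single amino-acid substitution: wild-type residue, 1-based position, mutant."""

    wt: str
    pos: int
    mut: str

    def __post_init__(self):
        for r, label in ((self.wt, "wild-type"), (self.mut, "mutant")):
            if r not in AMINO_ACIDS + "X":
                raise ValueError(f"{label} residue {r!r} is not an amino acid")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.wt == self.mut:
            raise InvalidMutationError(
                f"{self.wt}{self.pos}{self.mut}: wild-type and mutant residues are equal"
            )

    def __str__(self) -> str:
        return f"{self.wt}{self.pos}{self.mut}"


@dataclass(frozen=True)
class MutationRecord:
    """One dataset entry: a mutation in a protein plus its measured target.

    ``target_kind`` is ``"ddg"`` for a folding free-energy change in kcal/mol
    (positive = destabilizing under this package's convention) or
    ``"stability_score"`` for a deep-mutational-scan stability readout
    (~1 = wild-type-like).
    """

    protein_id: str
    mutation: Mutation
    target: float
    target_kind: str = "ddg"

    def __post_init__(self):
        if self.target_kind not in ("ddg", "stability_score"):
            raise ValueError(f"unknown target_kind {self.target_kind!r}")
        if not np.isfinite(self.target):
            raise ValueError(f"target for {self.protein_id} {self.mutation} not finite")


@dataclass
class MutationDataset:
    """An ordered collection of mutation records with their protein sequences."""

    records: list[MutationRecord] = field(default_factory=list)
    sequences: dict[str, ProteinSequence] = field(default_factory=dict)

    def __post_init__(self):
        for rec in self.records:
            seq = self.sequences.get(rec.protein_id)
            if seq is None:
                raise ValueError(f"record {rec.mutation} references unknown protein "
                                 f"{rec.protein_id!r}")
            if not validate_mutation_against_sequence(seq, rec.mutation):
                raise ValueError(
                    f"mutation {rec.mutation} does not match sequence {rec.protein_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def targets(self) -> np.ndarray:
        return np.array([r.target for r in self.records], dtype=float)

    def protein_ids(self) -> list[str]:
        """Distinct protein ids in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.protein_id, None)
        return list(seen)

    def subset(self, protein_ids) -> "MutationDataset":
        """Records (order preserved) belonging to the given proteins."""
        keep = set(protein_ids)
        recs = [r for r in self.records if r.protein_id in keep]
        seqs = {pid: self.sequences[pid] for pid in keep}
        return MutationDataset(recs, seqs)

    # ---- I/O: CSV dialect has columns protein_id,mutation,target,target_kind
    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "protein_id": [r.protein_id for r in self.records],
                "mutation": [str(r.mutation) for r in self.records],
                "target": [r.target for r in self.records],
                "target_kind": [r.target_kind for r in self.records],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sequences: dict[str, ProteinSequence]) -> "MutationDataset":
        df = pd.read_csv(path)
        required = {"protein_id", "mutation", "target"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataset CSV missing columns {sorted(missing)}")
        records = []
        for row in df.itertuples(index=False):
            kind = getattr(row, "target_kind", "ddg")
            records.append(
                MutationRecord(
                    protein_id=str(row.protein_id),
                    mutation=parse_mutation(str(row.mutation)),
                    target=float(row.target),
                    target_kind=str(kind),
                )
            )
        return cls(records, dict(sequences))


def parse_mutation(spec: str) -> Mutation:
    """Parse a ``WposM`` mutation string such as ``"R175H"``.

    Raises :class:`MutationParseError` for malformed input and
    :class:`InvalidMutationError` when wild-type and mutant coincide.
    """
    m = _MUTATION_RE.match(spec.strip())
    if m is None:
        raise MutationParseError(f"cannot parse mutation spec {spec!r} (expected WposM)")
    return Mutation(wt=m.group(1), pos=int(m.group(2)), mut=m.group(3))


def format_mutation(m: Mutation) -> str:
    """Inverse of :func:`parse_mutation`."""
    return str(m)


def validate_mutation_against_sequence(seq: ProteinSequence, m: Mutation) -> bool:
    """True iff the mutation position is in range and the wild-type residue matches."""
    return 1 <= m.pos <= len(seq) and seq.residue_at(m.pos) == m.wt


def filter_unknown_residues(ds: MutationDataset) -> MutationDataset:
    """Drop records whose wild-type or mutant residue is the unknown code ``X``.

    Also drops records whose sequence position holds ``X``. Survivor order is
    preserved and the number removed is logged. Idempotent.
    """
    survivors = []
    for rec in ds.records:
        seq = ds.sequences[rec.protein_id]
        if rec.mutation.wt == "X" or rec.mutation.mut == "X":
            continue
        if seq.residue_at(rec.mutation.pos) == "X":
            continue
        survivors.append(rec)
    n_removed = len(ds.records) - len(survivors)
    if n_removed:
        logger.info("filter_unknown_residues: removed %d record(s) with 'X'", n_removed)
    return MutationDataset(survivors, dict(ds.sequences))


def _aligner() -> PairwiseAligner:
    # Simple reproducible scheme: match +1, mismatch 0, gap -1 (global).
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    return a


def sequence_identity(a: ProteinSequence, b: ProteinSequence) -> float:
    """Global-alignment sequence identity between two proteins, in percent.

    Needleman-Wunsch with match +1 / mismatch 0 / gap -1; identity is
    100 x (identical aligned positions) / (alignment length, gaps included).
    Symmetric, in [0, 100], and 100 iff the sequences are identical.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot compute identity of an empty sequence")
    if a.residues == b.residues:
        return 100.0
    # co-optimal alignments can differ between argument orders; canonicalize
    # the pair so the result is symmetric by construction
    s, t = sorted((a.residues, b.residues))
    aln = _aligner().align(s, t)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length


def homology_partition(
    ds: MutationDataset,
    test_fraction: float,
    identity_threshold: float = 30.0,
    seed: int = 0,
) -> tuple[MutationDataset, MutationDataset]:
    """Split a dataset by protein into train/test with a homology screen.

    No protein contributes to both sides, and every test protein has pairwise
    sequence identity below ``identity_threshold`` (percent) against every
    train protein, guarding against homology leakage. The split is greedy:
    proteins are shuffled by ``seed`` and moved to the test pool while the
    identity constraint holds and the test record count stays at or below
    ``test_fraction`` of the total. Deterministic given the seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0,1)")
    if not 0 < identity_threshold <= 100:
        raise ValueError("identity_threshold must be in (0,100]")
    pids = ds.protein_ids()
    if len(pids) < 2:
        raise ValueError("need at least two proteins to partition")
    rng = np.random.default_rng(seed)
    order = [pids[i] for i in rng.permutation(len(pids))]
    n_records = {pid: sum(1 for r in ds.records if r.protein_id == pid) for pid in pids}
    target = test_fraction * len(ds.records)

    # Identity is symmetric; cache pairs lazily.
    cache: dict[frozenset, float] = {}

    def ident(p: str, q: str) -> float:
        key = frozenset((p, q))
        if key not in cache:
            cache[key] = sequence_identity(ds.sequences[p], ds.sequences[q])
        return cache[key]

    test_pool: list[str] = []
    test_count = 0
    for pid in order:
        if test_count >= target:
            break
        remainder = [q for q in pids if q != pid and q not in test_pool]
        if all(ident(pid, q) < identity_threshold for q in remainder):
            test_pool.append(pid)
            test_count += n_records[pid]
    if not test_pool:
        raise ValueError(
            "no valid homology-aware split exists: every candidate test protein "
            f"shares >= {identity_threshold}% identity with the remainder"
        )
    train_pool = [pid for pid in pids if pid not in test_pool]
    return ds.subset(train_pool), ds.subset(test_pool)


# ---- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict[str, ProteinSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file."""
    out: dict[str, ProteinSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(sequences: dict[str, ProteinSequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences.values():
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def read_mutation_list(path) -> list[Mutation]:
    """Read a mutation-list file: one WposM spec per line, blank lines ignored."""
    muts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                muts.append(parse_mutation(line))
    return muts
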