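"""Feature encoders for single amino-acid substitutions.

Four descriptor groups are concatenated, in this fixed order, into one
feature vector per mutation:

``psepssm``
    Pseudo-PSSM of the whole protein: the 20 per-column means of the
    (normalized) PSSM followed, for each lag g = 1..lag_max, by the 20
    mean squared differences between PSSM entries g residues apart —
    capturing per-residue conservation and its sequence-order correlation.
    Length 20 + 20*lag_max (160 at the default lag_max = 7).
``neighbor_cs``
    Conservation scores around the mutation site: the PSSM rows of the site
    and its +-window_flank neighbors (the XXXCXXX window at the default
    flank of 3), flattened row-major; rows outside the sequence are zero
    rows. Length 20*(2*window_flank + 1) (140 at default).
``seq_neighbor``
    Identities of the neighbor_span residues left and right of the site,
    as ordinal labels 0..19 in PSI-BLAST column order, pad label 20 beyond
    the termini. Length 2*neighbor_span (10 at default).
``physchem``
    Nine physicochemical properties of the substitution (see
    :class:`PhyschemTable`). Length 9.

Default total: 160 + 140 + 10 + 9 = 319.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from seqddg.pssm import ALPHABET, PSSM, NormalizedPSSM, normalize_pssm
from seqddg.seqdata import (
    Mutation,
    MutationDataset,
    ProteinSequence,
    validate_mutation_against_sequence,
)

GROUPS = ("psepssm", "neighbor_cs", "seq_neighbor", "physchem")

# ---------------------------------------------------------------------------
# Physicochemical tables (versioned data, swappable without code change)
# ---------------------------------------------------------------------------

# Residue van-der-Waals volumes, A^3 (Zamyatnin-style scale).
_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Kyte-Doolittle hydropathy.
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Average chain flexibility index (Bhaskaran-Ponnuswamy scale).
_FLEXIBILITY = {
    "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346,
    "Q": 0.493, "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462,
    "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314, "P": 0.509,
    "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.420, "V": 0.386,
}

# Chemical class: 0 aliphatic, 1 aromatic, 2 sulfur, 3 hydroxyl,
# 4 basic, 5 acidic, 6 amide.
_CHEM_CLASS = {
    "A": 0, "G": 0, "I": 0, "L": 0, "P": 0, "V": 0,
    "F": 1, "W": 1, "Y": 1,
    "C": 2, "M": 2,
    "S": 3, "T": 3,
    "R": 4, "H": 4, "K": 4,
    "D": 5, "E": 5,
    "N": 6, "Q": 6,
}

# Size class by residue volume: 0 small, 1 medium, 2 large.
_SIZE_CLASS = {
    "G": 0, "A": 0, "S": 0, "C": 0, "D": 0, "P": 0, "N": 0, "T": 0,
    "E": 1, "V": 1, "Q": 1, "H": 1, "M": 1, "I": 1, "L": 1, "K": 1,
    "R": 2, "F": 2, "Y": 2, "W": 2,
}

# Polarity: 0 nonpolar, 1 polar uncharged, 2 charged.
_POLARITY = {
    "A": 0, "C": 0, "F": 0, "G": 0, "I": 0, "L": 0, "M": 0, "P": 0, "V": 0, "W": 0,
    "N": 1, "Q": 1, "S": 1, "T": 1, "Y": 1,
    "D": 2, "E": 2, "H": 2, "K": 2, "R": 2,
}

# Side-chain hydrogen bonding: 0 none, 1 donor, 2 acceptor, 3 donor+acceptor.
_HBOND = {
    "A": 0, "C": 0, "F": 0, "G": 0, "I": 0, "L": 0, "M": 0, "P": 0, "V": 0,
    "K": 1, "R": 1, "W": 1,
    "D": 2, "E": 2,
    "H": 3, "N": 3, "Q": 3, "S": 3, "T": 3, "Y": 3,
}

# Coarse hydrophobicity label: 0 hydrophobic, 1 neutral, 2 hydrophilic.
_HYDRO_LABEL = {
    "A": 0, "C": 0, "F": 0, "I": 0, "L": 0, "M": 0, "V": 0, "W": 0,
    "G": 1, "H": 1, "P": 1, "S": 1, "T": 1, "Y": 1,
    "D": 2, "E": 2, "K": 2, "N": 2, "Q": 2, "R": 2,
}

#: Fixed order of the nine physicochemical features.
PHYSCHEM_NAMES = (
    "net_volume",
    "net_hydrophobicity",
    "mutation_type",
    "net_flexibility",
    "chemical_property",
    "size",
    "polarity",
    "hydrogen_bond",
    "label_hydrophobicity",
)


@dataclass
class PhyschemTable:
    """Per-residue scales and class assignments used by the physchem encoder.

    "Net" properties are scale(mutant) - scale(wild-type); categorical
    properties are integer codes of the mutant residue's class, except
    ``mutation_type``, a class-transition code
    ``7 * chem_class(wt) + chem_class(mut)``.
    """

    version: str = "2024.1"
    volume: dict = field(default_factory=lambda: dict(_VOLUME))
    hydrophobicity: dict = field(default_factory=lambda: dict(_HYDROPATHY))
    flexibility: dict = field(default_factory=lambda: dict(_FLEXIBILITY))
    chem_class: dict = field(default_factory=lambda: dict(_CHEM_CLASS))
    size_class: dict = field(default_factory=lambda: dict(_SIZE_CLASS))
    polarity: dict = field(default_factory=lambda: dict(_POLARITY))
    hbond: dict = field(default_factory=lambda: dict(_HBOND))
    hydro_label: dict = field(default_factory=lambda: dict(_HYDRO_LABEL))

    def __post_init__(self):
        for name in ("volume", "hydrophobicity", "flexibility", "chem_class",
                     "size_class", "polarity", "hbond", "hydro_label"):
            table = getattr(self, name)
            missing = set("ACDEFGHIKLMNPQRSTVWY") - set(table)
            if missing:
                raise ValueError(f"physchem table {name!r} missing {sorted(missing)}")


@dataclass
class FeatureConfig:
    """Tunable parameters of the feature encoders.

    lag_max is the maximum pseudo-PSSM lag (sequence separation of the
    squared-difference terms); window_flank the half-width of the PSSM
    conservation window around the site; neighbor_span the number of sequence
    neighbors taken on each side.
    """

    lag_max: int = 7
    window_flank: int = 3
    neighbor_span: int = 5
    physchem_table: PhyschemTable = field(default_factory=PhyschemTable)
    pssm_normalization: str = "logistic"
    one_hot_neighbors: bool = False

    def __post_init__(self):
        if self.lag_max <= 0:
            raise ValueError("lag_max must be positive")
        if self.window_flank < 0 or self.neighbor_span < 0:
            raise ValueError("window_flank and neighbor_span must be >= 0")

    def schema(self) -> list[tuple[str, str]]:
        """Ordered (group, name) labels of the assembled feature vector."""
        labels: list[tuple[str, str]] = []
        for j in range(20):
            labels.append(("psepssm", f"mean_{ALPHABET[j]}"))
        for g in range(1, self.lag_max + 1):
            for j in range(20):
                labels.append(("psepssm", f"lag{g}_{ALPHABET[j]}"))
        for off in range(-self.window_flank, self.window_flank + 1):
            for j in range(20):
                labels.append(("neighbor_cs", f"off{off:+d}_{ALPHABET[j]}"))
        if self.one_hot_neighbors:
            for off in list(range(-self.neighbor_span, 0)) + list(
                range(1, self.neighbor_span + 1)
            ):
                for j in range(20):
                    labels.append(("seq_neighbor", f"off{off:+d}_is_{ALPHABET[j]}"))
        else:
            for off in list(range(-self.neighbor_span, 0)) + list(
                range(1, self.neighbor_span + 1)
            ):
                labels.append(("seq_neighbor", f"off{off:+d}"))
        for name in PHYSCHEM_NAMES:
            labels.append(("physchem", name))
        return labels

    def column_names(self) -> list[str]:
        return [f"{g}.{n}" for g, n in self.schema()]


@dataclass
class FeatureVector:
    """One mutation's assembled descriptor plus its (group, name) schema."""

    values: np.ndarray
    schema: list[tuple[str, str]]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.schema):
            raise ValueError(
                f"feature vector length {len(self.values)} != schema length "
                f"{len(self.schema)}"
            )


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

def psepssm_vector(n: NormalizedPSSM | PSSM, lag_max: int = 7) -> np.ndarray:
    """Pseudo-PSSM descriptor: 20 column means, then 20 lag terms per lag.

    The lag-g term for column j is the mean of (P[i,j] - P[i+g,j])^2 over
    i = 1..L-g, i.e. the average squared change of column-j scores between
    residues g apart. Requires lag_max < L.
    """
    P = np.asarray(n.matrix, dtype=float)
    L = P.shape[0]
    if lag_max >= L:
        raise ValueError(f"lag_max={lag_max} must be < sequence length L={L}")
    parts = [P.mean(axis=0)]
    for g in range(1, lag_max + 1):
        d = P[:-g, :] - P[g:, :]
        parts.append((d * d).mean(axis=0))
    return np.concatenate(parts)


def neighbor_conservation_scores(
    n: NormalizedPSSM | PSSM, m: Mutation, window_flank: int = 3
) -> np.ndarray:
    """PSSM rows of the mutation site and its flanking residues, flattened.

    Rows m.pos-flank .. m.pos+flank (1-based), row-major; positions falling
    outside the sequence contribute zero rows so dimensionality is fixed.
    """
    P = np.asarray(n.matrix, dtype=float)
    L = P.shape[0]
    if not 1 <= m.pos <= L:
        raise ValueError(f"mutation position {m.pos} outside PSSM of length {L}")
    rows = []
    for pos in range(m.pos - window_flank, m.pos + window_flank + 1):
        if 1 <= pos <= L:
            rows.append(P[pos - 1])
        else:
            rows.append(np.zeros(20))
    return np.concatenate(rows)


def sequence_neighbor_labels(
    seq: ProteinSequence, m: Mutation, span: int = 5, one_hot: bool = False
) -> np.ndarray:
    """Identities of the residues flanking the mutation site.

    Left neighbors outermost-first, then right neighbors innermost-first.
    Ordinal encoding (default): each label is the residue's index 0..19 in
    PSI-BLAST column order; positions beyond the termini (and unknown 'X')
    get the pad label 20. One-hot encoding expands each neighbor to a
    20-long indicator (all zero for pad).
    """
    L = len(seq)
    offsets = list(range(-span, 0)) + list(range(1, span + 1))
    labels = []
    for off in offsets:
        pos = m.pos + off
        if 1 <= pos <= L:
            labels.append(ALPHABET.find(seq.residue_at(pos)))  # X -> -1
        else:
            labels.append(-1)
    labels = [20 if l < 0 else l for l in labels]
    if not one_hot:
        return np.array(labels, dtype=float)
    out = np.zeros(len(offsets) * 20)
    for k, l in enumerate(labels):
        if l < 20:
            out[k * 20 + l] = 1.0
    return out


def physicochemical_features(m: Mutation, t: PhyschemTable | None = None) -> np.ndarray:
    """The nine physicochemical properties of a substitution (fixed order).

    Net volume / hydrophobicity / flexibility are mutant-minus-wild-type
    scale differences; the remaining entries are integer class codes (see
    :class:`PhyschemTable`).
    """
    t = t or PhyschemTable()
    wt, mut = m.wt, m.mut
    for r in (wt, mut):
        if r not in t.volume:
            raise KeyError(f"residue {r!r} absent from physicochemical table")
    return np.array(
        [
            t.volume[mut] - t.volume[wt],
            t.hydrophobicity[mut] - t.hydrophobicity[wt],
            7 * t.chem_class[wt] + t.chem_class[mut],
            t.flexibility[mut] - t.flexibility[wt],
            t.chem_class[mut],
            t.size_class[mut],
            t.polarity[mut],
            t.hbond[mut],
            t.hydro_label[mut],
        ],
        dtype=float,
    )


def assemble_feature_vector(
    seq: ProteinSequence,
    pssm: PSSM,
    m: Mutation,
    cfg: FeatureConfig | None = None,
) -> FeatureVector:
    """Concatenate the four feature groups for one mutation.

    Order: psepssm | neighbor_cs | seq_neighbor | physchem. The PSSM is
    normalized according to ``cfg.pssm_normalization`` before the first two
    groups are computed.
    """
    cfg = cfg or FeatureConfig()
    if not validate_mutation_against_sequence(seq, m):
        raise ValueError(f"mutation {m} does not validate against sequence {seq.id!r}")
    if len(pssm) != len(seq):
        raise ValueError(
            f"PSSM rows ({len(pssm)}) != sequence length ({len(seq)}) for {seq.id!r}"
        )
    norm = normalize_pssm(pssm, cfg.pssm_normalization)
    values = np.concatenate(
        [
            psepssm_vector(norm, cfg.lag_max),
            neighbor_conservation_scores(norm, m, cfg.window_flank),
            sequence_neighbor_labels(seq, m, cfg.neighbor_span, cfg.one_hot_neighbors),
            physicochemical_features(m, cfg.physchem_table),
        ]
    )
    return FeatureVector(values=values, schema=cfg.schema())


def featurize_dataset(
    ds: MutationDataset,
    pssms: dict[str, PSSM],
    cfg: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature table for a whole dataset: one row per record, schema columns.

    Per-protein blocks (pseudo-PSSM) are computed once per protein and
    reused. Column names are ``group.name``.
    """
    cfg = cfg or FeatureConfig()
    psepssm_cache: dict[str, np.ndarray] = {}
    norm_cache: dict[str, NormalizedPSSM] = {}
    rows = []
    for rec in ds.records:
        pid = rec.protein_id
        if pid not in pssms:
            raise KeyError(f"no PSSM supplied for protein {pid!r}")
        if pid not in norm_cache:
            if len(pssms[pid]) != len(ds.sequences[pid]):
                raise ValueError(f"PSSM/sequence length mismatch for {pid!r}")
            norm_cache[pid] = normalize_pssm(pssms[pid], cfg.pssm_normalization)
            psepssm_cache[pid] = psepssm_vector(norm_cache[pid], cfg.lag_max)
        seq = ds.sequences[pid]
        rows.append(
            np.concatenate(
                [
                    psepssm_cache[pid],
                    neighbor_conservation_scores(
                        norm_cache[pid], rec.mutation, cfg.window_flank
                    ),
                    sequence_neighbor_labels(
                        seq, rec.mutation, cfg.neighbor_span, cfg.one_hot_neighbors
                    ),
                    physicochemical_features(rec.mutation, cfg.physchem_table),
                ]
            )
        )
    return pd.DataFrame(np.array(rows), columns=cfg.column_names())
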