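"""Position-specific scoring matrices: PSI-BLAST ASCII parsing and normalization.

A PSSM is an L x 20 matrix of log-odds scores, one row per residue of the
protein, produced upstream by an iterative profile search (``psiblast
-out_ascii_pssm``). This package only consumes that output format; it never
runs the search. Columns are kept in the order printed in the ASCII file
(PSI-BLAST's native ARNDCQEGHILKMFPSTWYV), carried explicitly on the object
so downstream encoders never assume alphabetical order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: PSI-BLAST's native column order in ascii PSSM files.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"


class PSSMParseError(ValueError):
    """Raised when a PSI-BLAST ascii PSSM file cannot be parsed."""


@dataclass
class PSSM:
    """Log-odds scoring matrix aligned to a protein sequence.

    ``matrix`` has one row per residue (sequence order) and one column per
    amino acid in ``alphabet_order``. ``residues`` is the sequence read back
    from the file's residue column, when available.
    """

    protein_id: str
    matrix: np.ndarray
    alphabet_order: str = ALPHABET
    residues: str | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(f"PSSM matrix must be L x 20, got {self.matrix.shape}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PSSM contains non-finite entries")
        if len(self.alphabet_order) != 20:
            raise ValueError("alphabet_order must list 20 amino acids")

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass
class NormalizedPSSM:
    """A PSSM squashed to a bounded scale (logistic by default: entries in (0,1))."""

    protein_id: str
    matrix: np.ndarray
    alphabet_order: str = ALPHABET
    method: str = "logistic"

    def __len__(self) -> int:
        return self.matrix.shape[0]


def parse_psiblast_pssm(source, protein_id: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file (path, or open text stream).

    Only the first 20 numeric columns (the log-odds scores) of each residue
    row are used; the weighted-percentage block and the lambda/kappa footer
    are ignored. The column order is read from the header line.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        name = protein_id or "pssm"
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
        name = protein_id or str(source)

    alphabet = None
    rows: list[list[float]] = []
    residues: list[str] = []
    expected_idx = 1
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if alphabet is None:
            # Header: a run of >= 20 single-letter amino-acid column labels.
            letters = [t for t in tokens if len(t) == 1 and t.isalpha()]
            if len(letters) >= 20:
                alphabet = "".join(letters[:20])
            continue
        if not tokens[0].isdigit():
            if rows:
                break  # footer (K/Lambda block) reached
            continue
        if int(tokens[0]) != expected_idx:
            raise PSSMParseError(
                f"line {lineno}: residue index {tokens[0]} out of order "
                f"(expected {expected_idx})"
            )
        if len(tokens) < 2 or not tokens[1].isalpha():
            raise PSSMParseError(f"line {lineno}: missing residue letter")
        try:
            scores = [float(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-numeric score ({exc})") from None
        if len(scores) != 20:
            raise PSSMParseError(
                f"line {lineno}: expected 20 score columns, found {len(scores)}"
            )
        rows.append(scores)
        residues.append(tokens[1])
        expected_idx += 1

    if alphabet is None:
        raise PSSMParseError("no amino-acid header line found")
    if not rows:
        raise PSSMParseError("no residue rows found (truncated file?)")
    return PSSM(
        protein_id=name,
        matrix=np.array(rows, dtype=float),
        alphabet_order=alphabet,
        residues="".join(residues),
    )


def write_psiblast_pssm(p: PSSM, path) -> None:
    """Emit a PSSM in the PSI-BLAST ascii dialect (round-trips through the parser).

    Scores are written at integer precision when integral, mimicking
    PSI-BLAST output, otherwise with enough digits to round-trip.
    """
    residues = p.residues or "X" * len(p)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write("          " + "  ".join(p.alphabet_order) + "   "
                 + "  ".join(p.alphabet_order) + "\n")
        for i, row in enumerate(p.matrix, start=1):
            cells = []
            for v in row:
                cells.append(f"{int(v):3d}" if float(v).is_integer() else f"{v:.4f}")
            pct = " ".join(["  0"] * 20)
            fh.write(f"{i:5d} {residues[i - 1]}  " + " ".join(cells)
                     + "  " + pct + "  0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3176\n")


def normalize_pssm(p: PSSM, method: str = "logistic") -> NormalizedPSSM:
    """Squash log-odds scores to a common scale.

    ``logistic`` (default) applies 1/(1+exp(-x)) elementwise, mapping scores
    into (0,1) monotonically with 0 -> 0.5 — the convention of the pseudo-PSSM
    literature. ``identity`` passes raw scores through; ``zscore``
    standardises each column to zero mean / unit variance.
    """
    x = p.matrix
    if method == "logistic":
        out = 1.0 / (1.0 + np.exp(-x))
    elif method == "identity":
        out = x.copy()
    elif method == "zscore":
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        out = (x - x.mean(axis=0)) / sd
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return NormalizedPSSM(
        protein_id=p.protein_id,
        matrix=out,
        alphabet_order=p.alphabet_order,
        method=method,
    )
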