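"""Mature-sequence percent-identity matrices and a neighbor-joining tree.

Secreted bacterial proteins are compared on their mature sequence, i.e.
after removal of the signal peptide, because the signal peptide is cleaved
before the protein ever meets its extracytoplasmic folding environment.
Pairwise comparisons use Smith-Waterman local alignment with affine gap
penalties (Gotoh recurrences); percent identity is the fraction of
identical aligned columns, and 1 - identity/100 feeds a standard
neighbor-joining reconstruction whose branch lengths are proportional to
divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class MatureSequence:
    """A named protein sequence with its signal-peptide boundary.

    ``signal_peptide_end`` is the 0-based index of the first mature residue
    (0 means the sequence is already mature).
    """

    name: str
    residues: str
    signal_peptide_end: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.residues.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: non-amino-acid letters {sorted(bad)}")
        if not 0 <= self.signal_peptide_end < len(self.residues):
            raise ValueError(f"{self.name}: signal_peptide_end out of range")


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment: aligned strings with '-' gaps, score, and counts."""

    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    alignment_length: int
    start_a: int
    start_b: int
    len_a: int
    len_b: int


@dataclass(frozen=True)
class IdentityMatrix:
    names: tuple[str, ...]
    values: np.ndarray  # symmetric, diagonal 100, percent in [0, 100]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def write_tsv(self, path) -> None:
        self.to_dataframe().round(1).to_csv(path, sep="\t")


def trim_signal_peptide(seq: MatureSequence) -> MatureSequence:
    """Drop the signal peptide, keeping the name; already-mature input is unchanged."""
    return MatureSequence(seq.name, seq.residues[seq.signal_peptide_end :], 0)


def read_fasta(path, boundaries: Mapping[str, int] | None = None) -> list[MatureSequence]:
    """Read sequences, attaching user-supplied signal-peptide boundaries.

    ``boundaries`` maps record id to the 0-based mature start; ids absent
    from the map are taken as already mature.
    """
    boundaries = boundaries or {}
    return [
        MatureSequence(rec.id, str(rec.seq).upper(), boundaries.get(rec.id, 0))
        for rec in SeqIO.parse(path, "fasta")
    ]


def default_substitution_matrix():
    return substitution_matrices.load("BLOSUM62")


def smith_waterman(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal local alignment under affine gap penalties.

    The first residue of a gap costs ``gap_open``, each further residue
    ``gap_extend`` (both positive penalties).  Traceback is deterministic:
    at equal scores, diagonal is preferred over a gap in ``b`` (up) over a
    gap in ``a`` (left), and the highest-scoring cell with the smallest
    (row, column) index is chosen.  An alignment with no positive-scoring
    pair is reported as empty with score 0.
    """
    if not a or not b:
        raise ValueError("both sequences must be nonempty")
    if matrix is None:
        matrix = default_substitution_matrix()
    a = a.upper()
    b = b.upper()
    n, m = len(a), len(b)
    NEG = float("-inf")
    # H: best alignment ending at (i, j) with a[i-1] aligned to b[j-1] or 0
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b[j-1])
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a[i-1])
    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] - gap_open, Ei[j - 1] - gap_extend)
            Fi[j] = max(Hi1[j] - gap_open, Fi1[j] - gap_extend)
            s = matrix[ai, b[j - 1]]
            h = max(0.0, Hi1[j - 1] + s, Fi[j], Ei[j])
            Hi[j] = h
            if h > best:
                best, best_ij = h, (i, j)
    if best == 0.0:
        return AlignmentResult("", "", 0.0, 0, 0, 0, 0, n, m)

    # traceback with explicit state: 'H' (match), 'F' (gap in b), 'E' (gap in a)
    i, j = best_ij
    out_a: list[str] = []
    out_b: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if H[i][j] == 0.0:
                break
            s = matrix[a[i - 1], b[j - 1]]
            if H[i][j] == H[i - 1][j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            out_a.append(a[i - 1])
            out_b.append("-")
            opened = F[i][j] == H[i - 1][j] - gap_open
            i -= 1
            if opened:
                state = "H"
        else:  # E
            out_a.append("-")
            out_b.append(b[j - 1])
            opened = E[i][j] == H[i][j - 1] - gap_open
            j -= 1
            if opened:
                state = "H"
    out_a.reverse()
    out_b.reverse()
    aligned_a = "".join(out_a)
    aligned_b = "".join(out_b)
    n_identical = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    return AlignmentResult(
        aligned_a,
        aligned_b,
        float(best),
        n_identical,
        len(aligned_a),
        i,
        j,
        n,
        m,
    )


def percent_identity(
    aln: AlignmentResult, denominator_mode: str = "alignment_length"
) -> float:
    """Percent identity of a local alignment.

    ``alignment_length`` (default) divides by the number of alignment
    columns including gap columns; ``shorter_sequence_length`` divides by
    the length of the shorter input sequence.  An empty alignment is 0.
    """
    if denominator_mode == "alignment_length":
        denom = aln.alignment_length
    elif denominator_mode == "shorter_sequence_length":
        denom = min(aln.len_a, aln.len_b)
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denom == 0:
        return 0.0
    return 100.0 * aln.n_identical / denom


def identity_matrix(
    seqs: Sequence[MatureSequence],
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator_mode: str = "alignment_length",
) -> IdentityMatrix:
    """All-pairs percent identity of the mature sequences.

    Signal peptides are trimmed first; each unordered pair is aligned once,
    so the matrix is symmetric by construction and the diagonal is 100.
    """
    if matrix is None:
        matrix = default_substitution_matrix()
    mature = [trim_signal_peptide(s) for s in seqs]
    k = len(mature)
    values = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            aln = smith_waterman(
                mature[i].residues, mature[j].residues, matrix, gap_open, gap_extend
            )
            values[i, j] = values[j, i] = percent_identity(aln, denominator_mode)
    return IdentityMatrix(tuple(s.name for s in mature), values)


def identity_to_distance(m: IdentityMatrix) -> DistanceMatrix:
    """d = 1 - identity/100; zero diagonal."""
    d = 1.0 - m.values / 100.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(m.names))


def build_nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch-length estimates clamp to 0."""
    tree = nj(d, neg_as_zero=False)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.info("build_nj_tree: clamped %d negative branch lengths to 0", clamped)
    return tree


def write_newick(tree: TreeNode, path=None) -> str:
    text = str(tree).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
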