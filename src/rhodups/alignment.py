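"""Nucleotide alignments: container, FASTA IO, codon-position base
composition diagnostics and third-position RY recoding.

The composition test is the classical chi-squared homogeneity test on the
taxa x {A,C,G,T} count table at one codon position (gaps and ambiguity
codes excluded from the counts), the screen used to justify recoding
saturated third positions before tree inference.  RY recoding collapses
purines (A/G) to R and pyrimidines (C/T) to Y at selected codon positions,
discarding the within-purine / within-pyrimidine signal that carries most
compositional bias while retaining transversion information.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MultipleAlignment",
    "CompositionReport",
    "composition_homogeneity_test",
    "ry_recode",
    "IUPAC_STATES",
]

# IUPAC nucleotide codes -> compatible base sets.  Gaps are treated as
# fully missing ('N') wherever a state set is needed.
IUPAC_STATES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "?": "ACGT", "-": "ACGT",
}

_RY_MAP = {}
for _code, _states in IUPAC_STATES.items():
    if _code == "-":
        _RY_MAP[_code] = "-"
    elif set(_states) <= {"A", "G"}:
        _RY_MAP[_code] = "R"
    elif set(_states) <= {"C", "T"}:
        _RY_MAP[_code] = "Y"
    else:
        _RY_MAP[_code] = "N"


class MultipleAlignment:
    """An in-frame nucleotide multiple alignment.

    Parameters
    ----------
    records:
        Ordered ``(id, sequence)`` pairs; sequences must share one length
        and use IUPAC nucleotide codes plus ``-`` for gaps.
    frame_offset:
        0-based column index of the first codon position-1 column.
    """

    def __init__(self, records: Sequence[Tuple[str, str]], frame_offset: int = 0):
        if not records:
            raise ValueError("alignment needs at least one sequence")
        self.ids: List[str] = [r[0] for r in records]
        seqs = [r[1].upper() for r in records]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.length: int = lengths.pop()
        bad = set("".join(seqs)) - set(IUPAC_STATES)
        if bad:
            raise ValueError(f"non-IUPAC characters in alignment: {sorted(bad)}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if not 0 <= frame_offset < 3:
            raise ValueError("frame_offset must be 0, 1 or 2")
        self.frame_offset = frame_offset
        # (n_taxa, n_cols) array of single characters
        self.matrix = np.array([list(s) for s in seqs], dtype="U1")

    # -- basic accessors -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    def sequence(self, ident: str) -> str:
        return "".join(self.matrix[self.ids.index(ident)])

    def records(self) -> List[Tuple[str, str]]:
        return [(i, "".join(row)) for i, row in zip(self.ids, self.matrix)]

    def codon_position(self, column: int) -> Optional[int]:
        """1/2/3 for columns in frame; None for columns before the frame."""
        if column < self.frame_offset:
            return None
        return (column - self.frame_offset) % 3 + 1

    def codon_position_columns(self, position: int) -> np.ndarray:
        cols = np.arange(self.frame_offset + position - 1, self.length, 3)
        return cols

    def subset(self, idents: Iterable[str]) -> "MultipleAlignment":
        idents = list(idents)
        rows = [self.ids.index(i) for i in idents]
        return MultipleAlignment(
            [(i, "".join(self.matrix[r])) for i, r in zip(idents, rows)],
            frame_offset=self.frame_offset)

    # -- IO --------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path, frame_offset: int = 0) -> "MultipleAlignment":
        recs = [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
        return cls(recs, frame_offset=frame_offset)

    def to_fasta(self, path, wrap: int = 70) -> None:
        recs = [SeqRecord(Seq(s), id=i, description="") for i, s in self.records()]
        if wrap:
            SeqIO.write(recs, path, "fasta")
        else:
            SeqIO.write(recs, path, "fasta-2line")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<MultipleAlignment {self.n_taxa} taxa x {self.length} columns>"


@dataclass
class CompositionReport:
    """Chi-squared homogeneity of base composition at one codon position."""
    codon_position: int
    counts: pd.DataFrame          # taxa x A,C,G,T (ambiguities/gaps excluded)
    chi2: float
    df: int
    p_value: float
    dropped_taxa: List[str] = field(default_factory=list)

    def frequencies(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1)
        return self.counts.div(tot.replace(0, np.nan), axis=0)


def composition_homogeneity_test(aln: MultipleAlignment,
                                 codon_position: int) -> CompositionReport:
    """Taxa x base contingency chi-squared at one codon position.

    Expected counts come from the pooled marginal base frequencies.  Bases
    with zero pooled count contribute nothing.  Taxa with no countable base
    at the position are dropped (reported in ``dropped_taxa``), not an
    error.  Degrees of freedom follow the classical homogeneity convention
    ``(n_taxa - 1) * 3``.
    """
    if codon_position not in (1, 2, 3):
        raise ValueError("codon_position must be 1, 2 or 3")
    cols = aln.codon_position_columns(codon_position)
    sub = aln.matrix[:, cols]
    bases = "ACGT"
    counts = np.stack([(sub == b).sum(axis=1) for b in bases], axis=1).astype(float)
    keep = counts.sum(axis=1) > 0
    dropped = [i for i, k in zip(aln.ids, keep) if not k]
    counts = counts[keep]
    ids = [i for i, k in zip(aln.ids, keep) if k]
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa with countable bases")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row * col / counts.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = float(cells.sum())
    df = (len(ids) - 1) * 3
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    table = pd.DataFrame(counts, index=ids, columns=list(bases)).astype(int)
    return CompositionReport(codon_position, table, chi2, df, p, dropped)


def ry_recode(aln: MultipleAlignment,
              positions: Set[int] = frozenset({3})) -> MultipleAlignment:
    """Recode A/G -> R and C/T -> Y at the given codon positions.

    Ambiguity codes wholly within the purines map to R, wholly within the
    pyrimidines to Y, and codes spanning both to N, so exactly the
    purine/pyrimidine information survives.  Idempotent; columns at other
    codon positions are untouched.
    """
    mat = aln.matrix.copy()
    for pos in positions:
        cols = aln.codon_position_columns(pos)
        block = mat[:, cols]
        out = block.copy()
        for code, target in _RY_MAP.items():
            out[block == code] = target
        mat[:, cols] = out
    recs = [(i, "".join(row)) for i, row in zip(aln.ids, mat)]
    return MultipleAlignment(recs, frame_offset=aln.frame_offset)
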