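"""Spectral-tuning key sites of rhodopsin in bovine numbering.

Twelve amino-acid positions (83, 96, 102, 122, 183, 194, 195, 253, 261,
289, 292, 317) are classically implicated in shifting rhodopsin's
wavelength of maximal absorption; site 210 additionally shows a consistent
cysteine/valine split between "deep-sea" and "freshwater" rhodopsin
paralogs of eel-like fishes.  Query protein sequences are mapped onto the
packaged bovine rhodopsin reference (UniProt P02699) by global pairwise
alignment, and paralog pairs are compared site by site in bovine
coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "KeySiteTable",
    "bovine_reference",
    "map_to_bovine",
    "compare_paralog_key_sites",
    "translate_cds",
]

KEY_SITES = (83, 96, 102, 122, 183, 194, 195, 253, 261, 289, 292, 317)
EXTRA_SITES = (210,)


@dataclass(frozen=True)
class KeySiteTable:
    """Positions to inspect, in 1-based bovine rhodopsin coordinates."""
    key_sites: Tuple[int, ...] = KEY_SITES
    extra_sites: Tuple[int, ...] = EXTRA_SITES

    @property
    def all_sites(self) -> Tuple[int, ...]:
        return tuple(sorted(set(self.key_sites) | set(self.extra_sites)))


def bovine_reference() -> str:
    """The packaged bovine rhodopsin protein sequence (348 residues)."""
    text = resources.files("rhodups.data").joinpath("bovine_rh1.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines()
                   if not line.startswith(">"))


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass
class BovineMap:
    """Bovine position (1-based) -> query position (1-based)."""
    positions: Dict[int, int]
    coverage: float                 # mapped fraction of the key-site region
    mappable: bool

    def residue(self, query: str, bovine_pos: int) -> Optional[str]:
        q = self.positions.get(bovine_pos)
        return None if q is None else query[q - 1]


def map_to_bovine(protein: str, table: Optional[KeySiteTable] = None) -> BovineMap:
    """Globally align a rhodopsin protein to the bovine reference.

    Gapped columns are excluded from the coordinate map.  If fewer than
    half of the positions in the key-site region (bovine 83..317) align to
    query residues the map is flagged unmappable.
    """
    protein = protein.upper().replace("*", "X")
    if len(protein) < 50:
        raise ValueError("protein sequence too short to map (need >= 50 aa)")
    ref = bovine_reference()
    aln = _aligner().align(ref, protein)[0]
    positions: Dict[int, int] = {}
    for (rs, re_), (qs, qe) in zip(*aln.aligned):
        for k in range(re_ - rs):
            positions[rs + k + 1] = qs + k + 1
    table = table or KeySiteTable()
    lo, hi = min(table.all_sites), max(table.all_sites)
    region = range(lo, hi + 1)
    coverage = sum(1 for p in region if p in positions) / len(region)
    return BovineMap(positions, coverage, coverage >= 0.5)


def compare_paralog_key_sites(seq_a: str, seq_b: str,
                              table: Optional[KeySiteTable] = None,
                              labels: Tuple[str, str] = ("a", "b")) -> pd.DataFrame:
    """Site-by-site comparison of two rhodopsin paralogs at the key sites.

    Returns one row per site with the residues of both sequences, whether
    they differ, and whether the site is one of the twelve classical
    tuning sites or the extra site.  Sites unmapped in either sequence are
    reported ``indeterminate`` and excluded from difference counts.
    The comparison is symmetric in its two arguments.
    """
    table = table or KeySiteTable()
    map_a, map_b = map_to_bovine(seq_a, table), map_to_bovine(seq_b, table)
    if not (map_a.mappable and map_b.mappable):
        raise ValueError("sequence could not be mapped to the bovine reference "
                         f"(coverage {map_a.coverage:.2f} / {map_b.coverage:.2f})")
    clean_a = seq_a.upper().replace("*", "X")
    clean_b = seq_b.upper().replace("*", "X")
    rows = []
    for site in table.all_sites:
        ra = map_a.residue(clean_a, site)
        rb = map_b.residue(clean_b, site)
        status = ("indeterminate" if ra is None or rb is None
                  else ("differs" if ra != rb else "same"))
        rows.append({
            "site": site,
            "site_class": "key" if site in table.key_sites else "extra",
            labels[0]: ra or "-",
            labels[1]: rb or "-",
            "status": status,
        })
    return pd.DataFrame(rows)


def differing_sites(comparison: pd.DataFrame) -> Tuple[int, ...]:
    """Sites at which both residues are known and differ."""
    return tuple(comparison.loc[comparison["status"] == "differs", "site"])


def translate_cds(nucleotide: str, frame: int = 0) -> str:
    """Translate an in-frame coding nucleotide sequence (gaps stripped)."""
    seq = nucleotide.replace("-", "")[frame:]
    seq = seq[: len(seq) - len(seq) % 3]
    return str(Seq(seq).translate()).rstrip("*")
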