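"""Conservation of functional residues across a protein alignment.

Functional positions (e.g. the calcium-coordinating and
carbohydrate-binding residues of a lectin) are given in the numbering of
one reference sequence; they are mapped through a multiple alignment by
gap-aware cumulative counting, and each aligned sequence is reported as
identical to the reference or not, with an optional overlay marking
positions at which a missense allele segregates within the species.

The alignment itself is an input (any aligner may produce it); a
pairwise global protein aligner (BLOSUM62, affine gap open 10 / extend 1)
is provided so small analyses run without external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ResidueSet",
    "ConservationTable",
    "map_positions",
    "conservation",
    "align_pair",
    "read_alignment_fasta",
]


@dataclass
class ResidueSet:
    """Functional positions in the reference protein's 1-based numbering."""

    reference_id: str
    positions: list[int]
    role: str = ""  # e.g. "calcium" or "glycan"

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("residue positions must be unique")
        if any(p < 1 for p in self.positions):
            raise ValueError("residue positions are 1-based")


def _reference_columns(ref_aligned: str, positions: list[int]) -> dict[int, int]:
    """Map 1-based ungapped reference positions to alignment columns."""
    wanted = set(positions)
    out: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(ref_aligned):
        if ch == "-":
            continue
        res += 1
        if res in wanted:
            out[res] = col
    missing = wanted - set(out)
    if missing:
        raise ValueError(
            f"positions {sorted(missing)} beyond the ungapped reference "
            f"length ({res})"
        )
    return out


def map_positions(alignment: dict[str, str],
                  residue_set: ResidueSet) -> pd.DataFrame:
    """Residue of every sequence at each mapped reference position.

    A gap in a target sequence at the mapped column is reported as
    missing (None).  Rows: sequence id; columns: reference positions.
    """
    if residue_set.reference_id not in alignment:
        raise KeyError(f"reference {residue_set.reference_id!r} not in alignment")
    ref = alignment[residue_set.reference_id]
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences have unequal lengths")
    cols = _reference_columns(ref, residue_set.positions)
    data = {}
    for pos in residue_set.positions:
        col = cols[pos]
        data[pos] = {
            sid: (None if seq[col] == "-" else seq[col])
            for sid, seq in alignment.items()
        }
    return pd.DataFrame(data)


@dataclass
class ConservationTable:
    table: pd.DataFrame  # rows (sequence, position) with residue + flags
    role: str = ""

    def identical_count(self, sequence_id: str) -> int:
        sub = self.table[self.table["sequence"] == sequence_id]
        return int(sub["identical"].sum())


def conservation(alignment: dict[str, str], residue_set: ResidueSet,
                 polymorphic: dict[str, set[int]] | None = None) -> ConservationTable:
    """Identity-to-reference flags at the functional positions.

    ``polymorphic`` maps sequence id -> reference positions at which a
    missense allele segregates; those cells are flagged polymorphic (the
    residue shown is the reference allele's).
    """
    polymorphic = polymorphic or {}
    residues = map_positions(alignment, residue_set)
    ref_id = residue_set.reference_id
    rows = []
    for sid in alignment:
        for pos in residue_set.positions:
            aa = residues.loc[sid, pos]
            ref_aa = residues.loc[ref_id, pos]
            rows.append({
                "sequence": sid,
                "position": pos,
                "residue": aa,
                "missing": aa is None,
                "identical": (aa is not None and aa == ref_aa),
                "polymorphic": pos in polymorphic.get(sid, set()),
            })
    return ConservationTable(pd.DataFrame(rows), residue_set.role)


def align_pair(seq_a: str, seq_b: str, ids: tuple[str, str] = ("a", "b"),
               gap_open: float = 10.0, gap_extend: float = 1.0) -> dict[str, str]:
    """Global pairwise protein alignment (BLOSUM62, affine gaps)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return {ids[0]: a, ids[1]: b}


def read_alignment_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
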