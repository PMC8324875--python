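"""Assign amplicon sequencing reads to paralogues and estimate per-gene
transcript proportions.

One primer pair amplifies the homologous region of every gene copy; a
read is assigned by comparing its inter-primer sequence against the
per-gene reference amplicons.  The default is collapse-then-exact-match
(identical reads grouped first, groups assigned by exact identity),
which keeps misassignment essentially zero even at extreme mixture
proportions such as 99.9% / 0.1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "AmpliconPanel",
    "AssignmentResult",
    "quality_filter",
    "trim_primers",
    "collapse_identical",
    "assign",
    "assign_reads",
    "proportions",
]

AMBIGUOUS = "__ambiguous__"
UNASSIGNED = "__unassigned__"


@dataclass
class AmpliconPanel:
    """Per-gene expected amplicon (inter-primer) sequences plus the
    shared primer pair."""

    amplicons: dict[str, str]  # gene_id -> inter-primer sequence
    forward: str = ""
    reverse: str = ""  # primer sequence, as synthesised (revcomp at 3' end)

    def __post_init__(self) -> None:
        self.amplicons = {g: s.upper() for g, s in self.amplicons.items()}
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        seqs = list(self.amplicons.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("panel amplicon sequences are not pairwise distinct")


def mean_quality(qual: str, offset: int = 33) -> float:
    return sum(ord(c) - offset for c in qual) / len(qual) if qual else 0.0


def quality_filter(
    reads: list[tuple[str, str, str]], min_mean_q: float = 20.0
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Drop reads with mean Phred below threshold or containing N."""
    kept, stats = [], {"input": len(reads), "low_quality": 0, "contains_n": 0}
    for name, seq, qual in reads:
        if "N" in seq.upper():
            stats["contains_n"] += 1
        elif mean_quality(qual) < min_mean_q:
            stats["low_quality"] += 1
        else:
            kept.append((name, seq, qual))
    stats["retained"] = len(kept)
    return kept, stats


def _revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def trim_primers(seq: str, panel: AmpliconPanel) -> str | None:
    """Exact primer trimming: the read must start with the forward primer
    and end with the reverse complement of the reverse primer; otherwise
    the read is untrimmable (-> unassigned).  When the panel defines no
    primers the read is used as-is."""
    seq = seq.upper()
    if not panel.forward and not panel.reverse:
        return seq
    tail = _revcomp(panel.reverse)
    if seq.startswith(panel.forward) and seq.endswith(tail):
        return seq[len(panel.forward):len(seq) - len(tail)]
    return None


def collapse_identical(reads: list[tuple[str, str, str]],
                       panel: AmpliconPanel | None = None) -> list[tuple[str, int]]:
    """Group reads by identical (upcased, primer-trimmed) sequence.

    Untrimmable reads are grouped under their raw sequence prefixed with
    '!' so they can be routed to unassigned downstream.
    """
    groups: dict[str, int] = {}
    for _, seq, _ in reads:
        if panel is not None:
            trimmed = trim_primers(seq, panel)
            key = trimmed if trimmed is not None else "!" + seq.upper()
        else:
            key = seq.upper()
        groups[key] = groups.get(key, 0) + 1
    return sorted(groups.items(), key=lambda kv: (-kv[1], kv[0]))


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def assign(sequence: str, panel: AmpliconPanel, max_mismatch: int = 0) -> str:
    """Assign one (trimmed) unique sequence to a gene.

    Best match wins if unique and within ``max_mismatch``; equidistant
    best matches -> AMBIGUOUS; nothing within tolerance (or an
    untrimmable '!'-prefixed group, or a length mismatch) -> UNASSIGNED.
    """
    if sequence.startswith("!"):
        return UNASSIGNED
    sequence = sequence.upper()
    best: list[str] = []
    best_d = None
    for gene, ref in panel.amplicons.items():
        if len(ref) != len(sequence):
            continue
        d = _hamming(sequence, ref)
        if d > max_mismatch:
            continue
        if best_d is None or d < best_d:
            best, best_d = [gene], d
        elif d == best_d:
            best.append(gene)
    if not best:
        return UNASSIGNED
    return best[0] if len(best) == 1 else AMBIGUOUS


def assign_reads(reads: list[tuple[str, str, str]], panel: AmpliconPanel,
                 max_mismatch: int = 0,
                 min_mean_q: float = 20.0) -> "AssignmentResult":
    """Full pipeline: quality filter, primer trim + collapse, assign."""
    kept, stats = quality_filter(reads, min_mean_q)
    groups = collapse_identical(kept, panel)
    counts: dict[str, int] = {g: 0 for g in panel.amplicons}
    ambiguous = unassigned = 0
    for seq, n in groups:
        target = assign(seq, panel, max_mismatch)
        if target == AMBIGUOUS:
            ambiguous += n
        elif target == UNASSIGNED:
            unassigned += n
        else:
            counts[target] += n
    return proportions(counts, ambiguous, unassigned, filter_stats=stats)


@dataclass
class AssignmentResult:
    counts: dict[str, int]
    ambiguous: int
    unassigned: int
    percentages: dict[str, float]  # of assigned reads; empty if none assigned
    filter_stats: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.ambiguous + self.unassigned

    @property
    def assigned(self) -> int:
        return sum(self.counts.values())

    def table(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "count": c,
             "percentage": self.percentages.get(g, float("nan"))}
            for g, c in self.counts.items()
        ]
        rows.append({"gene": "(ambiguous)", "count": self.ambiguous,
                     "percentage": float("nan")})
        rows.append({"gene": "(unassigned)", "count": self.unassigned,
                     "percentage": float("nan")})
        return pd.DataFrame(rows)


def proportions(counts: dict[str, int], ambiguous: int = 0,
                unassigned: int = 0,
                filter_stats: dict[str, int] | None = None) -> AssignmentResult:
    """Per-gene percentage of assigned reads; ambiguous/unassigned are
    excluded from the denominator and reported separately.  With no
    assigned reads the percentages are empty (undefined), flagged by the
    empty dict."""
    assigned = sum(counts.values())
    percentages = (
        {g: 100.0 * c / assigned for g, c in counts.items()} if assigned else {}
    )
    return AssignmentResult(dict(counts), ambiguous, unassigned, percentages,
                            filter_stats or {})
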