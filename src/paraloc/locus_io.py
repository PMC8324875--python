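"""Data model and I/O for a multi-copy (paralogous) locus.

A locus is a single contig carrying several highly similar tandem gene
copies, plus repeat-mask intervals.  All internal coordinates are 0-based,
half-open; on-disk formats keep their native conventions (gene table and
VCF are 1-based, BED is 0-based half-open) and are converted at the
boundary.

Coordinate frames
-----------------
contig   : base pairs along the contig, strand-less.
CDS      : offset within the spliced coding sequence, in transcription
           order (reverse-complemented for minus-strand genes).
codon    : 1-based amino-acid residue number plus a 0..2 offset within
           the codon.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigSequence",
    "GeneModel",
    "Variant",
    "Sample",
    "SampleSet",
    "ParalogueLocus",
    "LocusValidationError",
    "ParseError",
    "read_locus",
    "write_locus",
    "read_vcf",
    "write_vcf",
    "extract_cds",
    "translate_cds",
    "contig_to_codon",
    "codon_to_contig",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


class LocusValidationError(ValueError):
    """An invariant of the locus data model is violated."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _check_intervals(intervals: Sequence[tuple[int, int]], upper: int, what: str) -> None:
    prev_end = -1
    for start, end in intervals:
        if not (0 <= start < end <= upper):
            raise LocusValidationError(
                f"{what} interval [{start}, {end}) outside [0, {upper})"
            )
        if start < prev_end:
            raise LocusValidationError(f"{what} intervals overlap or are unsorted")
        prev_end = end


@dataclass
class ContigSequence:
    """A contig with repeat-mask annotation.

    ``masked`` holds 0-based half-open intervals; soft-masked (lower-case)
    FASTA letters are upcased on input — the mask track is the single
    source of masking truth.
    """

    name: str
    residues: str
    masked: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise LocusValidationError(f"contig {self.name}: invalid residues {sorted(bad)}")
        self.masked = sorted((int(a), int(b)) for a, b in self.masked)
        _check_intervals(self.masked, len(self.residues), "mask")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """One gene: strand and its CDS exons as contig intervals.

    Exons are stored sorted by contig coordinate regardless of strand;
    transcription order is derived from the strand at extraction time.
    """

    gene_id: str
    strand: str
    cds_exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise LocusValidationError(f"gene {self.gene_id}: strand must be + or -")
        self.cds_exons = sorted((int(a), int(b)) for a, b in self.cds_exons)
        if not self.cds_exons:
            raise LocusValidationError(f"gene {self.gene_id}: no CDS exons")
        prev = -1
        for s, e in self.cds_exons:
            if s >= e:
                raise LocusValidationError(f"gene {self.gene_id}: empty exon [{s}, {e})")
            if s < prev:
                raise LocusValidationError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev = e
        if self.cds_length % 3 != 0:
            raise LocusValidationError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint: first exon start to last exon end."""
        return self.cds_exons[0][0], self.cds_exons[-1][1]


#: Genotype codes used throughout: number of alternate alleles carried by a
#: diploid sample, or None for a missing call.
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, None


@dataclass
class Variant:
    """A single-nucleotide (or parsed-but-unsupported indel) variant call."""

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    quality: float
    depth: int
    genotypes: dict[str, int | None] = field(default_factory=dict)
    alt_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise LocusValidationError("variant alleles must be non-empty")
        if self.ref == self.alt:
            raise LocusValidationError("ref and alt alleles are identical")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class Sample:
    sample_id: str
    population: str
    sample_class: str  # "inbred-strain" | "wild"


@dataclass
class SampleSet:
    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise LocusValidationError("sample_ids are not unique")

    def __iter__(self):
        return iter(self.samples)

    def by_id(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


@dataclass
class ParalogueLocus:
    """The coordinate frame for the whole analysis: contig + gene models."""

    contig: ContigSequence
    genes: dict[str, GeneModel]

    def __post_init__(self) -> None:
        n = len(self.contig)
        for g in self.genes.values():
            _check_intervals(g.cds_exons, n, f"gene {g.gene_id} exon")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{i}: BED line has fewer than 3 fields")
        try:
            out.append((parts[0], int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: non-integer BED coordinate") from exc
    return out


def _read_gene_table(path: str | Path) -> list[tuple[str, str, str, list[tuple[int, int]]]]:
    """Tab-separated gene table: gene_id, contig, strand, exons.

    The exon field is ``start-end[,start-end...]`` with 1-based inclusive
    coordinates on disk (GFF-like); converted here to 0-based half-open.
    """
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}:{i}: expected 4 tab-separated fields")
        gene_id, contig, strand, exon_field = parts
        exons = []
        for piece in exon_field.split(","):
            try:
                a, b = piece.split("-")
                start1, end1 = int(a), int(b)
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: malformed exon interval {piece!r}") from exc
            exons.append((start1 - 1, end1))
        rows.append((gene_id, contig, strand, exons))
    return rows


def read_locus(
    fasta_path: str | Path,
    gene_table_path: str | Path,
    mask_bed_path: str | Path | None = None,
) -> ParalogueLocus:
    """Load contig FASTA + gene table (+ optional mask BED) into a locus.

    All data-model invariants are enforced; a gene exon outside the contig
    or a CDS length not divisible by 3 raises :class:`LocusValidationError`.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ParseError(f"{fasta_path}: no FASTA records")
    rec = records[0]
    masked: list[tuple[int, int]] = []
    if mask_bed_path is not None:
        for chrom, start, end in _read_bed(mask_bed_path):
            if chrom == rec.id:
                masked.append((start, end))
    contig = ContigSequence(rec.id, str(rec.seq), masked)
    genes: dict[str, GeneModel] = {}
    for gene_id, chrom, strand, exons in _read_gene_table(gene_table_path):
        if chrom != contig.name:
            raise LocusValidationError(
                f"gene {gene_id} references contig {chrom!r}, FASTA has {contig.name!r}"
            )
        genes[gene_id] = GeneModel(gene_id, strand, exons)
    return ParalogueLocus(contig, genes)


def write_locus(locus: ParalogueLocus, fasta_path: str | Path,
                gene_table_path: str | Path, mask_bed_path: str | Path) -> None:
    """Write the locus back to FASTA + gene table + mask BED (round-trips)."""
    SeqIO.write(
        [SeqRecord(Seq(locus.contig.residues), id=locus.contig.name, description="")],
        str(fasta_path), "fasta",
    )
    lines = []
    for g in locus.genes.values():
        exon_field = ",".join(f"{s + 1}-{e}" for s, e in g.cds_exons)
        lines.append(f"{g.gene_id}\t{locus.contig.name}\t{g.strand}\t{exon_field}")
    Path(gene_table_path).write_text("\n".join(lines) + "\n")
    bed = "".join(
        f"{locus.contig.name}\t{s}\t{e}\n" for s, e in locus.contig.masked
    )
    Path(mask_bed_path).write_text(bed)


_GT_MAP = {(0, 0): HOM_REF, (0, 1): HET, (1, 0): HET, (1, 1): HOM_ALT}


def read_vcf(path: str | Path) -> tuple[list[Variant], list[Variant]]:
    """Read a VCF; returns ``(snvs, unsupported)``.

    Multi-allelic records are decomposed into biallelic variants.  Indel
    alleles are parsed but routed to the ``unsupported`` list (the analysis
    is SNV-only).  Per-sample alt fractions come from FORMAT/AD when
    present; site depth from INFO/DP or the summed sample DP.
    """
    import pysam

    snvs: list[Variant] = []
    unsupported: list[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            depth = rec.info.get("DP")
            if depth is None:
                depth = sum(
                    (rec.samples[s].get("DP") or 0) for s in sample_names
                )
            qual = rec.qual if rec.qual is not None else 0.0
            for ai, alt in enumerate(alts, start=1):
                genotypes: dict[str, int | None] = {}
                fractions: dict[str, float] = {}
                for s in sample_names:
                    call = rec.samples[s]
                    gt = call.get("GT")
                    if gt is None or any(a is None for a in gt):
                        genotypes[s] = MISSING
                    else:
                        n_alt = sum(1 for a in gt if a == ai)
                        n_known = sum(1 for a in gt if a in (0, ai))
                        genotypes[s] = n_alt if n_known == len(gt) else MISSING
                    ad = call.get("AD")
                    if ad is not None and ad[0] is not None:
                        total = sum(x or 0 for x in ad)
                        if total > 0:
                            fractions[s] = (ad[ai] or 0) / total
                v = Variant(rec.chrom, rec.pos - 1, rec.ref, alt,
                            float(qual), int(depth or 0), genotypes, fractions)
                (snvs if v.is_snv else unsupported).append(v)
    return snvs, unsupported


def write_vcf(path: str | Path, contig: str, contig_len: int,
              variants: Iterable[Variant], sample_ids: Sequence[str]) -> None:
    """Write variants as an uncompressed VCF v4.2 with GT/AD/DP genotypes."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={contig_len}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids),
    ]
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    for v in sorted(variants, key=lambda x: x.pos):
        fields = [
            v.contig, str(v.pos + 1), ".", v.ref, v.alt,
            f"{v.quality:g}", "PASS", f"DP={v.depth}", "GT:AD",
        ]
        for s in sample_ids:
            gt = v.genotypes.get(s, MISSING)
            frac = v.alt_fractions.get(s)
            if frac is None:
                frac = {HOM_REF: 0.0, HET: 0.5, HOM_ALT: 1.0}.get(gt, 0.0)
            # synthesise AD consistent with the site depth and alt fraction
            n = max(v.depth, 1)
            alt_reads = round(frac * n)
            fields.append(f"{gt_str[gt]}:{n - alt_reads},{alt_reads}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def extract_cds(locus: ParalogueLocus, gene_id: str) -> str:
    """Spliced CDS in transcription order (revcomp for minus strand)."""
    gene = locus.gene(gene_id)
    concat = "".join(locus.contig.residues[s:e] for s, e in gene.cds_exons)
    return revcomp(concat) if gene.strand == "-" else concat


def translate_cds(cds: str) -> str:
    """Translate with the standard code; internal stops kept as ``*``.

    Any codon containing an ambiguous base (N) translates to ``X``.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise LocusValidationError(f"CDS length {len(cds)} not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        out.append("X" if "N" in codon else GENETIC_CODE[codon])
    return "".join(out)


def peptide_length(protein: str) -> int:
    """Residues before the first stop (the reported peptide length)."""
    idx = protein.find("*")
    return len(protein) if idx < 0 else idx


def _cds_offset(gene: GeneModel, contig_pos: int) -> int | None:
    """Offset of a contig position within the spliced CDS, or None."""
    off = 0
    hit = None
    for s, e in gene.cds_exons:
        if s <= contig_pos < e:
            hit = off + (contig_pos - s)
            break
        off += e - s
    if hit is None:
        return None
    if gene.strand == "-":
        return gene.cds_length - 1 - hit
    return hit


def contig_to_codon(locus: ParalogueLocus, gene_id: str,
                    contig_pos: int) -> tuple[int, int] | None:
    """Map a contig position to (1-based codon index, 0..2 offset).

    Returns None for positions outside the gene's CDS (non-coding is a
    value, not an error).
    """
    off = _cds_offset(locus.gene(gene_id), contig_pos)
    if off is None:
        return None
    return off // 3 + 1, off % 3


def codon_to_contig(locus: ParalogueLocus, gene_id: str,
                    codon_index: int, offset: int) -> int:
    """Inverse of :func:`contig_to_codon` for positions inside the CDS."""
    gene = locus.gene(gene_id)
    cds_off = (codon_index - 1) * 3 + offset
    if not (0 <= cds_off < gene.cds_length):
        raise LocusValidationError(
            f"codon {codon_index} offset {offset} outside CDS of {gene_id}"
        )
    if gene.strand == "-":
        cds_off = gene.cds_length - 1 - cds_off
    for s, e in gene.cds_exons:
        if cds_off < e - s:
            return s + cds_off
        cds_off -= e - s
    raise AssertionError("unreachable")
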