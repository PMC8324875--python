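"""Ground-truthed synthetic paralogous locus.

Generates a contig carrying tandem, highly similar gene copies (emulating
a six-gene lectin family: 313-aa products, ~90% mutual CDS identity,
repeat-dense intergenic sequence), diploid strain genomes carrying
contiguous multi-gene deletions and injected SNVs, uniform short-read
placements at uneven mappability, and amplicon read mixtures at extreme
proportions.  Every output is reproducible bit-for-bit for a fixed seed,
and the returned :class:`LocusTruth` carries the exact ground truth used
by parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .locus_io import (
    GENETIC_CODE,
    STOP_CODONS,
    ContigSequence,
    GeneModel,
    HET,
    HOM_ALT,
    HOM_REF,
    ParalogueLocus,
    Variant,
    codon_to_contig,
    revcomp,
    translate_cds,
)

__all__ = [
    "FamilyConfig",
    "InjectedVariant",
    "StrainSpec",
    "StrainRealization",
    "LocusTruth",
    "generate_family",
    "realize_strain",
    "cohort_truth_vcf",
    "simulate_read_placements",
    "simulate_amplicon_reads",
    "write_fastq",
    "evolve_cds",
    "add_nonsynonymous_divergence",
    "sample_polymorphism",
    "make_prt_panel",
]

_BASES = "ACGT"
_NON_STOP = sorted(set(GENETIC_CODE) - STOP_CODONS)


@dataclass
class FamilyConfig:
    """Parameters of the simulated gene family.

    Defaults emulate the study locus: six genes of 942 bp CDS (313 amino
    acids plus a stop), four exons separated by 4 kb introns (~12.9 kb
    genomic span per gene), 75 kb intergenic spacers with a central
    repeat-masked block, giving a ~603 kb contig; target pairwise CDS
    identity 0.90.
    """

    n_genes: int = 6
    cds_len: int = 942
    n_exons: int = 4
    intron_len: int = 4000
    intergenic_len: int = 75_000
    pairwise_identity: float = 0.90
    masked_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_len % 3 != 0:
            raise ValueError("cds_len must be divisible by 3")
        if not (0.0 < self.pairwise_identity < 1.0):
            raise ValueError("pairwise_identity must be in (0, 1)")
        if not (0.0 <= self.masked_fraction < 1.0):
            raise ValueError("masked_fraction must be in [0, 1)")
        if self.n_genes < 1 or self.n_exons < 1:
            raise ValueError("n_genes and n_exons must be positive")


@dataclass
class InjectedVariant:
    """A codon-level variant injected into a strain.

    ``copies`` is the number of haplotypes carrying the alternate codon
    (1 = heterozygous, 2 = homozygous).
    """

    gene_id: str
    codon_index: int  # 1-based amino-acid position
    alt_codon: str
    copies: int = 2


@dataclass
class StrainSpec:
    """A diploid strain: per-haplotype deletions plus injected variants.

    ``deletions`` holds, for each of the two haplotypes, a list of
    contiguous runs of gene ids; each run is excised as one segment
    (gene span plus flanks), mirroring deletion patterns in which one
    haplotype may carry several separate contiguous deletion events.
    """

    strain_id: str
    deletions: tuple[list[list[str]], list[list[str]]] = (
        field(default_factory=lambda: ([], []))
    )
    injected_variants: list[InjectedVariant] = field(default_factory=list)
    population: str = "synthetic"
    sample_class: str = "inbred-strain"


@dataclass
class Haplotype:
    """One haplotype: retained reference intervals plus SNV substitutions."""

    kept: list[tuple[int, int]]  # reference intervals retained, sorted
    substitutions: dict[int, str] = field(default_factory=dict)

    def sequence(self, reference: str) -> str:
        parts = []
        for s, e in self.kept:
            seg = list(reference[s:e])
            for pos, alt in self.substitutions.items():
                if s <= pos < e:
                    seg[pos - s] = alt
            parts.append("".join(seg))
        return "".join(parts)

    def length(self) -> int:
        return sum(e - s for s, e in self.kept)


@dataclass
class StrainRealization:
    strain_id: str
    haplotypes: tuple[Haplotype, Haplotype]
    copy_number: dict[str, int]
    variants: list[Variant]
    deleted_spans: tuple[list[tuple[int, int]], list[tuple[int, int]]]


@dataclass
class LocusTruth:
    """Ground truth for recovery tests."""

    ancestral_cds: str
    gene_cds: dict[str, str]
    deletion_flank: int
    amplicon_forward: str
    amplicon_reverse: str
    amplicons: dict[str, str]  # full amplicon incl. primer sites
    strains: dict[str, StrainRealization] = field(default_factory=dict)
    amplicon_mixture: dict[str, float] = field(default_factory=dict)

    def amplicon_insert(self, gene_id: str) -> str:
        a = self.amplicons[gene_id]
        return a[len(self.amplicon_forward):len(a) - len(self.amplicon_reverse)]

    def copy_table(self) -> pd.DataFrame:
        rows = {
            sid: sr.copy_number for sid, sr in self.strains.items()
        }
        return pd.DataFrame(rows).T.loc[:, list(self.gene_cds)]


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------

def _per_gene_divergence(identity: float) -> float:
    """Per-site substitution probability so two independently mutated
    copies have the target expected identity: (1-p)^2 + p^2/3 = I."""
    # quadratic (4/3)p^2 - 2p + (1 - I) = 0, take the small root
    a, b, c = 4.0 / 3.0, -2.0, 1.0 - identity
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError(f"identity target {identity} unreachable")
    return (-b - math.sqrt(disc)) / (2 * a)


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + TAA."""
    body = rng.choice([c for c in _NON_STOP if c != "ATG"], size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _mutate_cds(cds: str, p: float, mutable: np.ndarray,
                rng: np.random.Generator) -> str:
    """Substitute each mutable site with probability p, never creating a
    stop codon in the reading frame."""
    seq = list(cds)
    hits = np.nonzero((rng.random(len(seq)) < p) & mutable)[0]
    for i in hits:
        codon_start = (i // 3) * 3
        options = []
        for b in _BASES:
            if b == seq[i]:
                continue
            trial = seq[codon_start:codon_start + 3]
            trial[i - codon_start] = b
            if "".join(trial) not in STOP_CODONS:
                options.append(b)
        if options:
            seq[i] = options[rng.integers(len(options))]
    return "".join(seq)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=n)])


def _split_exons(cds_len: int, n_exons: int) -> list[int]:
    base = cds_len // n_exons
    lens = [base] * n_exons
    lens[-1] += cds_len - base * n_exons
    return lens


# amplicon primer sites on the CDS (bp, half-open); held identical across
# paralogues so one primer pair amplifies every gene
_FWD_SITE = (36, 57)
_REV_SITE = (276, 301)


def generate_family(config: FamilyConfig) -> tuple[ParalogueLocus, LocusTruth]:
    """Build the locus: one ancestral CDS independently mutated per gene,
    genes placed on alternating strands with intronic/intergenic spacers
    and repeat-masked blocks.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n_codons = config.cds_len // 3
    ancestral = _random_orf(n_codons, rng)

    # sites held fixed: start codon, final stop, shared primer sites
    mutable = np.ones(config.cds_len, dtype=bool)
    mutable[:3] = False
    mutable[-3:] = False
    conserved = 6
    if config.cds_len >= _REV_SITE[1]:
        mutable[_FWD_SITE[0]:_FWD_SITE[1]] = False
        mutable[_REV_SITE[0]:_REV_SITE[1]] = False
        conserved += (_FWD_SITE[1] - _FWD_SITE[0]) + (_REV_SITE[1] - _REV_SITE[0])
    # compensate the held-fixed sites so overall identity hits the target
    m = int(mutable.sum())
    if m == 0:
        raise ValueError("no mutable sites")
    identity_mutable = (config.pairwise_identity * config.cds_len
                        - (config.cds_len - m)) / m
    if not (0.0 < identity_mutable < 1.0):
        raise ValueError(
            f"identity target {config.pairwise_identity} unreachable with "
            f"{m} mutable of {config.cds_len} sites"
        )
    p = _per_gene_divergence(identity_mutable)

    gene_cds: dict[str, str] = {}
    genes: dict[str, GeneModel] = {}
    contig_parts: list[str] = []
    masked: list[tuple[int, int]] = []
    cursor = 0

    def add_spacer() -> None:
        nonlocal cursor
        contig_parts.append(_random_dna(config.intergenic_len, rng))
        block = int(config.intergenic_len * config.masked_fraction)
        if block > 0:
            mid = cursor + config.intergenic_len // 2
            masked.append((mid - block // 2, mid - block // 2 + block))
        cursor += config.intergenic_len

    exon_lens = _split_exons(config.cds_len, config.n_exons)
    for gi in range(config.n_genes):
        add_spacer()
        gene_id = f"gene{gi + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        cds = _mutate_cds(ancestral, p, mutable, rng)
        gene_cds[gene_id] = cds

        # build the genomic block: exon pieces of the CDS separated by introns
        pieces, off = [], 0
        for el in exon_lens:
            pieces.append(cds[off:off + el])
            off += el
        block_parts, exon_local = [], []
        pos = 0
        for i, piece in enumerate(pieces):
            if i > 0:
                block_parts.append(_random_dna(config.intron_len, rng))
                pos += config.intron_len
            block_parts.append(piece)
            exon_local.append((pos, pos + len(piece)))
            pos += len(piece)
        block = "".join(block_parts)
        if strand == "-":
            n = len(block)
            block = revcomp(block)
            exon_local = sorted((n - e, n - s) for s, e in exon_local)
        exons = [(cursor + s, cursor + e) for s, e in exon_local]
        genes[gene_id] = GeneModel(gene_id, strand, exons)
        contig_parts.append(block)
        cursor += len(block)
    add_spacer()

    contig = ContigSequence("synthetic_contig", "".join(contig_parts), masked)
    locus = ParalogueLocus(contig, genes)

    # consistency: extraction must give back the constructed CDS
    from .locus_io import extract_cds
    for gid, cds in gene_cds.items():
        assert extract_cds(locus, gid) == cds

    fwd = ancestral[_FWD_SITE[0]:_FWD_SITE[1]]
    rev = revcomp(ancestral[_REV_SITE[0]:_REV_SITE[1]])
    amplicons = {
        gid: cds[_FWD_SITE[0]:_REV_SITE[1]] for gid, cds in gene_cds.items()
    } if config.cds_len >= _REV_SITE[1] else {}
    truth = LocusTruth(
        ancestral_cds=ancestral,
        gene_cds=gene_cds,
        deletion_flank=1000,
        amplicon_forward=fwd,
        amplicon_reverse=rev,
        amplicons=amplicons,
    )
    return locus, truth


# ---------------------------------------------------------------------------
# Strain realisation
# ---------------------------------------------------------------------------

def _subtract(intervals: list[tuple[int, int]],
              cuts: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        pieces = [(s, e)]
        for cs, ce in cuts:
            nxt = []
            for a, b in pieces:
                if ce <= a or cs >= b:
                    nxt.append((a, b))
                else:
                    if a < cs:
                        nxt.append((a, cs))
                    if ce < b:
                        nxt.append((ce, b))
            pieces = nxt
        out.extend(pieces)
    return sorted(out)


def realize_strain(locus: ParalogueLocus, truth: LocusTruth,
                   spec: StrainSpec, flank: int | None = None) -> StrainRealization:
    """Apply deletions and injected variants; record truth genotypes.

    Each contiguous run of deleted genes is excised from (first gene start
    − flank) to (last gene end + flank) so breakpoints fall in intergenic
    sequence.  A variant injected into a gene deleted on both haplotypes
    is a specification error.
    """
    if flank is None:
        flank = truth.deletion_flank
    order = list(locus.genes)
    contig_len = len(locus.contig)

    deleted_spans: list[list[tuple[int, int]]] = []
    deleted_sets: list[set[str]] = []
    for hap_runs in spec.deletions:
        spans, dset = [], set()
        for run in hap_runs:
            if not run:
                continue
            idx = sorted(order.index(g) for g in run)
            if idx != list(range(idx[0], idx[-1] + 1)):
                raise ValueError(
                    f"strain {spec.strain_id}: deletion run {run} is not "
                    "contiguous in gene order"
                )
            first, last = order[idx[0]], order[idx[-1]]
            s = max(0, locus.gene(first).span[0] - flank)
            e = min(contig_len, locus.gene(last).span[1] + flank)
            spans.append((s, e))
            dset.update(order[i] for i in range(idx[0], idx[-1] + 1))
        deleted_spans.append(sorted(spans))
        deleted_sets.append(dset)

    copy_number = {
        g: 2 - sum(g in dset for dset in deleted_sets) for g in order
    }

    haps = [
        Haplotype(kept=_subtract([(0, contig_len)], spans))
        for spans in deleted_spans
    ]

    variants: list[Variant] = []
    for iv in spec.injected_variants:
        if copy_number[iv.gene_id] == 0:
            raise ValueError(
                f"strain {spec.strain_id}: variant in {iv.gene_id} deleted "
                "on both haplotypes"
            )
        gene = locus.gene(iv.gene_id)
        ref_cds = truth.gene_cds[iv.gene_id]
        c0 = (iv.codon_index - 1) * 3
        ref_codon = ref_cds[c0:c0 + 3]
        if len(iv.alt_codon) != 3:
            raise ValueError("alt codon must be 3 bases")
        carriers = [h for h in range(2) if iv.gene_id not in deleted_sets[h]]
        target_haps = carriers[: iv.copies]
        if len(target_haps) < iv.copies:
            raise ValueError(
                f"strain {spec.strain_id}: {iv.gene_id} has only "
                f"{len(carriers)} intact copies, cannot inject {iv.copies}"
            )
        for off in range(3):
            if ref_codon[off] == iv.alt_codon[off]:
                continue
            pos = codon_to_contig(locus, iv.gene_id, iv.codon_index, off)
            ref_base = locus.contig.residues[pos]
            alt_base = (iv.alt_codon[off] if gene.strand == "+"
                        else revcomp(iv.alt_codon[off]))
            for h in target_haps:
                haps[h].substitutions[pos] = alt_base
            gt = HOM_ALT if len(target_haps) == len(carriers) == 2 else (
                HET if len(target_haps) == 1 and len(carriers) == 2 else HOM_ALT
            )
            # a single intact copy carrying the alt behaves as homozygous-alt
            variants.append(Variant(
                locus.contig.name, pos, ref_base, alt_base,
                quality=60.0, depth=100,
                genotypes={spec.strain_id: gt},
                alt_fractions={spec.strain_id: {HET: 0.5, HOM_ALT: 1.0}[gt]},
            ))

    realization = StrainRealization(
        strain_id=spec.strain_id,
        haplotypes=(haps[0], haps[1]),
        copy_number=copy_number,
        variants=variants,
        deleted_spans=(deleted_spans[0], deleted_spans[1]),
    )
    truth.strains[spec.strain_id] = realization
    return realization


def cohort_truth_vcf(locus: ParalogueLocus,
                     realizations: Sequence[StrainRealization]) -> list[Variant]:
    """Merge per-strain truth variants into cohort records (one per site)."""
    by_site: dict[tuple[int, str, str], Variant] = {}
    for sr in realizations:
        for v in sr.variants:
            key = (v.pos, v.ref, v.alt)
            if key not in by_site:
                by_site[key] = Variant(v.contig, v.pos, v.ref, v.alt,
                                       v.quality, v.depth, {}, {})
            merged = by_site[key]
            merged.genotypes.update(v.genotypes)
            merged.alt_fractions.update(v.alt_fractions)
    for v in by_site.values():
        for sr in realizations:
            v.genotypes.setdefault(sr.strain_id, HOM_REF)
            v.alt_fractions.setdefault(sr.strain_id, 0.0)
    return sorted(by_site.values(), key=lambda v: v.pos)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _allowed_starts(kept: list[tuple[int, int]], masked: list[tuple[int, int]],
                    read_len: int) -> list[tuple[int, int]]:
    ivs = _subtract(kept, masked)
    return [(s, e - read_len) for s, e in ivs if e - s >= read_len]


def simulate_read_placements(
    realization: StrainRealization,
    locus: ParalogueLocus,
    coverage: float,
    read_len: int = 100,
    insert_mean: int = 350,
    insert_sd: int = 50,
    error_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    emit_fastq: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str, str]] | None]:
    """Place paired reads uniformly over unmasked retained sequence.

    ``coverage`` is per haplotype.  The placement table records the true
    source interval in the reference contig frame (deleted segments yield
    no placements).  When ``emit_fastq`` is true, read sequences (with
    uniform substitution errors) are returned as (name, seq, qual) tuples
    for external-aligner workflows.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    contig = locus.contig
    rows: list[tuple[str, str, int, int, int]] = []
    fastq: list[tuple[str, str, str]] = [] if emit_fastq else None

    for h, hap in enumerate(realization.haplotypes):
        starts_iv = _allowed_starts(hap.kept, contig.masked, read_len)
        if not starts_iv:
            continue
        lens = np.array([e - s + 1 for s, e in starts_iv], dtype=float)
        total_allowed = float(lens.sum())
        hap_len = sum(e - s for s, e in
                      _subtract(hap.kept, contig.masked))
        n_pairs = int(round(coverage * hap_len / (2 * read_len)))
        if n_pairs == 0:
            continue
        iv_idx = rng.choice(len(starts_iv), size=n_pairs,
                            p=lens / total_allowed)
        offs = rng.random(n_pairs)
        isize = np.clip(
            rng.normal(insert_mean, insert_sd, size=n_pairs),
            2 * read_len, None,
        ).astype(int)
        hap_seq = hap.sequence(contig.residues) if emit_fastq else None
        # reference->haplotype offset per kept interval, for FASTQ extraction
        ref2hap = []
        acc = 0
        for s, e in hap.kept:
            ref2hap.append((s, e, acc - s))
            acc += e - s

        def hap_pos(ref_pos: int) -> int | None:
            for s, e, d in ref2hap:
                if s <= ref_pos < e:
                    return ref_pos + d
            return None

        for k in range(n_pairs):
            s_iv, e_iv = starts_iv[iv_idx[k]]
            start1 = s_iv + int(offs[k] * (e_iv - s_iv + 1))
            name = f"{realization.strain_id}_h{h}_{k}"
            rows.append((f"{name}/1", contig.name, start1,
                         start1 + read_len, h))
            start2 = start1 + isize[k] - read_len
            # the mate must stay inside the same retained interval
            mate_ok = any(s <= start2 and start2 + read_len <= e
                          for s, e in hap.kept)
            if mate_ok:
                rows.append((f"{name}/2", contig.name, start2,
                             start2 + read_len, h))
            if emit_fastq:
                hp = hap_pos(start1)
                if hp is not None:
                    seq = hap_seq[hp:hp + read_len]
                    fastq.append((f"{name}/1", _add_errors(seq, error_rate, rng),
                                  "I" * read_len))
                if mate_ok:
                    hp2 = hap_pos(start2)
                    if hp2 is not None:
                        seq2 = revcomp(hap_seq[hp2:hp2 + read_len])
                        fastq.append((f"{name}/2",
                                      _add_errors(seq2, error_rate, rng),
                                      "I" * read_len))

    table = pd.DataFrame(
        rows, columns=["read_id", "contig", "start", "end", "haplotype"]
    )
    return table, fastq


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Amplicon simulation
# ---------------------------------------------------------------------------

def simulate_amplicon_reads(
    amplicons: dict[str, str],
    proportions: dict[str, float] | Sequence[float],
    n_reads: int,
    error_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Multinomial mixture of per-gene amplicon reads.

    Returns (reads, realized_counts): the realized per-gene source counts
    are the exact truth the assignment stage is scored against.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    gene_ids = list(amplicons)
    if not isinstance(proportions, dict):
        proportions = dict(zip(gene_ids, proportions))
    p = np.array([proportions.get(g, 0.0) for g in gene_ids], dtype=float)
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if n_reads == 0:
        return [], {g: 0 for g in gene_ids}
    p = p / p.sum()
    counts = rng.multinomial(n_reads, p)
    reads: list[tuple[str, str, str]] = []
    i = 0
    for g, c in zip(gene_ids, counts):
        for _ in range(c):
            seq = _add_errors(amplicons[g], error_rate, rng)
            # read name carries the true source gene for recovery tests
            reads.append((f"amp_{i}_src_{g}", seq, "I" * len(seq)))
            i += 1
    # deterministic shuffle so reads are not grouped by source
    order = rng.permutation(len(reads))
    reads = [reads[j] for j in order]
    return reads, dict(zip(gene_ids, (int(c) for c in counts)))


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Sequence-evolution helpers (divergence / polymorphism for MK analyses)
# ---------------------------------------------------------------------------

def evolve_cds(cds: str, rate: float, rng: np.random.Generator,
               nonsyn_scale: float = 1.0) -> str:
    """Neutral-style CDS evolution: per site, a candidate substitution is
    proposed and accepted with probability ``rate`` (times
    ``nonsyn_scale`` when the change is nonsynonymous).  Stop codons are
    never created or destroyed."""
    seq = list(cds)
    u = rng.random(len(seq))
    for i in range(len(seq)):
        c0 = (i // 3) * 3
        codon = "".join(seq[c0:c0 + 3])
        if codon in STOP_CODONS:
            continue
        choices = [b for b in _BASES if b != seq[i]]
        b = choices[rng.integers(3)]
        trial = codon[: i - c0] + b + codon[i - c0 + 1:]
        if trial in STOP_CODONS:
            continue
        nonsyn = GENETIC_CODE[trial] != GENETIC_CODE[codon]
        accept_p = min(1.0, rate * (nonsyn_scale if nonsyn else 1.0))
        if u[i] < accept_p:
            seq[i] = b
    return "".join(seq)


def add_nonsynonymous_divergence(cds: str, n_substitutions: int,
                                 rng: np.random.Generator) -> str:
    """Apply exactly ``n_substitutions`` nonsynonymous substitutions at
    random sites (never creating stops) — used to simulate adaptive
    excess of amino-acid divergence on one gene."""
    seq = list(cds)
    done = 0
    while done < n_substitutions:
        i = int(rng.integers(len(seq)))
        c0 = (i // 3) * 3
        codon = "".join(seq[c0:c0 + 3])
        if codon in STOP_CODONS:
            continue
        b = _BASES[rng.integers(4)]
        if b == seq[i]:
            continue
        trial = codon[: i - c0] + b + codon[i - c0 + 1:]
        if trial in STOP_CODONS or GENETIC_CODE[trial] == GENETIC_CODE[codon]:
            continue
        seq[i] = b
        done += 1
    return "".join(seq)


def sample_polymorphism(cds: str, n_haplotypes: int, n_sites: int,
                        rng: np.random.Generator) -> list[str]:
    """Haplotype sample with ``n_sites`` segregating SNVs at random
    positions and uniform derived-allele counts; stops never created."""
    haps = [list(cds) for _ in range(n_haplotypes)]
    positions = rng.choice(len(cds), size=min(n_sites, len(cds)),
                           replace=False)
    for pos in positions:
        c0 = (pos // 3) * 3
        codon = cds[c0:c0 + 3]
        if codon in STOP_CODONS:
            continue
        options = []
        for b in _BASES:
            if b == cds[pos]:
                continue
            trial = codon[: pos - c0] + b + codon[pos - c0 + 1:]
            if trial not in STOP_CODONS:
                options.append(b)
        if not options:
            continue
        alt = options[rng.integers(len(options))]
        count = 1 + rng.integers(n_haplotypes - 1) if n_haplotypes > 1 else 1
        carriers = rng.choice(n_haplotypes, size=count, replace=False)
        for h in carriers:
            haps[h][pos] = alt
    return ["".join(h) for h in haps]


# ---------------------------------------------------------------------------
# PRT template panel
# ---------------------------------------------------------------------------

_IUPAC_CONCRETE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "K": "G", "Y": "C", "M": "A", "R": "A", "W": "A", "S": "C",
    "B": "C", "D": "A", "H": "A", "V": "A", "N": "A",
}


def make_prt_panel(
    forward: str,
    reverse: str,
    product_sizes: dict[str, int],
    non_targets: Sequence[str] = (),
    n_mismatches: int = 5,
    pad: int = 200,
    seed: int = 0,
) -> dict[str, str]:
    """Engineer per-gene templates for a PRT assay.

    Target genes get exact primer sites separated so that the product has
    the requested size; ``non_targets`` get the forward site corrupted
    with ``n_mismatches`` substitutions, emulating paralogues the assay
    must not amplify.
    """
    from .prt_insilico import IUPAC

    rng = np.random.default_rng(seed)
    forward = forward.upper()
    fwd_site = "".join(_IUPAC_CONCRETE[c] for c in forward)
    rev_site_plus = revcomp("".join(_IUPAC_CONCRETE[c] for c in reverse.upper()))
    templates: dict[str, str] = {}
    for gid, size in product_sizes.items():
        spacer_len = size - len(fwd_site) - len(rev_site_plus)
        if spacer_len < 0:
            raise ValueError(f"product size {size} shorter than the primers")
        fsite = fwd_site
        if gid in non_targets:
            fsite = list(fwd_site)
            # only positions where the degenerate code leaves a base that
            # cannot match are eligible for an engineered mismatch
            eligible = [i for i, c in enumerate(forward) if len(IUPAC[c]) < 4]
            pos = rng.choice(eligible,
                             size=min(n_mismatches, len(eligible)),
                             replace=False)
            for i in pos:
                outside = sorted(set("ACGT") - IUPAC[forward[i]])
                fsite[i] = outside[rng.integers(len(outside))]
            fsite = "".join(fsite)
        templates[gid] = (
            _random_dna(pad, rng) + fsite + _random_dna(spacer_len, rng)
            + rev_site_plus + _random_dna(pad, rng)
        )
    return templates
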