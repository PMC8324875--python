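"""Variant filtering and codon-level consequence annotation.

Filtering applies the calling thresholds used for the study data (site
quality >= 30, depth >= 15) plus an explicit allele-balance rule that
formalises the visual check of alternate-allele read fractions (~0.5 for
heterozygotes, ~1 for homozygotes).  Annotation reconstructs the
reference codon from the gene model, substitutes the alternate base
(strand-aware), and classifies the change as synonymous / missense /
stop_gain / stop_loss; premature stops are additionally reported with the
length of the truncated peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .locus_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    ParalogueLocus,
    SampleSet,
    Variant,
    contig_to_codon,
    extract_cds,
    peptide_length,
    revcomp,
    translate_cds,
)

__all__ = [
    "FilterPolicy",
    "AnnotatedVariant",
    "filter_variants",
    "annotate",
    "annotate_all",
    "truncated_peptide_length",
    "population_frequencies",
    "table1_style",
]


@dataclass
class FilterPolicy:
    min_quality: float = 30.0
    min_depth: int = 15
    het_fraction: tuple[float, float] = (0.3, 0.7)
    hom_alt_min_fraction: float = 0.9

    def __post_init__(self) -> None:
        lo, hi = self.het_fraction
        if not (0 <= lo < hi <= 1) or not (0 <= self.hom_alt_min_fraction <= 1):
            raise ValueError("allele-fraction bounds must be ordered in [0, 1]")


@dataclass
class AnnotatedVariant:
    variant: Variant
    gene_id: str | None
    consequence: str  # synonymous | missense | stop_gain | stop_loss | non_coding
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    truncated_length: int | None = None  # for stop_gain only


def filter_variants(
    variants: list[Variant], policy: FilterPolicy | None = None
) -> tuple[list[Variant], list[tuple[Variant, str]]]:
    """Split variants into (passed, rejected-with-reason).

    A variant passes iff quality >= min_quality, depth >= min_depth, and
    every non-missing genotype's alternate-read fraction (when reported)
    is consistent with its genotype class.  The filter is monotone in
    both thresholds.
    """
    if policy is None:
        policy = FilterPolicy()
    passed, rejected = [], []
    lo, hi = policy.het_fraction
    for v in variants:
        if v.quality < policy.min_quality:
            rejected.append((v, "low_quality"))
            continue
        if v.depth < policy.min_depth:
            rejected.append((v, "low_depth"))
            continue
        bad = None
        for sample, gt in v.genotypes.items():
            if gt is MISSING or sample not in v.alt_fractions:
                continue
            f = v.alt_fractions[sample]
            if gt == HET and not (lo <= f <= hi):
                bad = f"allele_balance:{sample}"
            elif gt == HOM_ALT and f < policy.hom_alt_min_fraction:
                bad = f"allele_balance:{sample}"
            elif gt == HOM_REF and f > 1 - policy.hom_alt_min_fraction:
                bad = f"allele_balance:{sample}"
            if bad:
                break
        if bad:
            rejected.append((v, bad))
        else:
            passed.append(v)
    return passed, rejected


def annotate(variant: Variant, locus: ParalogueLocus) -> AnnotatedVariant:
    """Codon-level consequence of an SNV against the locus gene models.

    The reference codon is rebuilt from the spliced CDS; the alternate
    base is substituted at the mapped offset with strand-aware
    complementation.  A position in no CDS yields ``non_coding``.
    """
    if not variant.is_snv:
        raise ValueError("only SNVs are annotated; indels are unsupported")
    for gene_id, gene in locus.genes.items():
        hit = contig_to_codon(locus, gene_id, variant.pos)
        if hit is None:
            continue
        codon_index, offset = hit
        cds = extract_cds(locus, gene_id)
        c0 = (codon_index - 1) * 3
        ref_codon = cds[c0:c0 + 3]
        alt_base = (variant.alt if gene.strand == "+" else revcomp(variant.alt))
        expected_ref = (variant.ref if gene.strand == "+"
                        else revcomp(variant.ref))
        if ref_codon[offset] != expected_ref:
            raise ValueError(
                f"variant ref allele {variant.ref!r} at {variant.pos} does "
                f"not match reference codon {ref_codon} of {gene_id}"
            )
        alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
        ref_aa, alt_aa = translate_cds(ref_codon), translate_cds(alt_codon)
        if ref_aa == alt_aa:
            cons = "synonymous"
        elif alt_aa == "*":
            cons = "stop_gain"
        elif ref_aa == "*":
            cons = "stop_loss"
        else:
            cons = "missense"
        trunc = None
        if cons == "stop_gain":
            alt_cds = cds[:c0] + alt_codon + cds[c0 + 3:]
            trunc = truncated_peptide_length(alt_cds)
        return AnnotatedVariant(variant, gene_id, cons, codon_index,
                                ref_codon, alt_codon, ref_aa, alt_aa, trunc)
    return AnnotatedVariant(variant, None, "non_coding")


def annotate_all(variants: list[Variant],
                 locus: ParalogueLocus) -> list[AnnotatedVariant]:
    return [annotate(v, locus) for v in variants]


def truncated_peptide_length(cds_with_variant: str) -> int:
    """Number of residues translated before the first in-frame stop."""
    return peptide_length(translate_cds(cds_with_variant))


def population_frequencies(
    annotated: list[AnnotatedVariant],
    samples: SampleSet,
    deleted_genes: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-population allele-frequency table (one row per variant x
    population).

    Wild populations get AF = alt alleles / (2 x genotyped diploids);
    inbred strains are listed as carriers (strains homozygous for the
    alternate allele), with no frequency.  Samples whose copy of the gene
    is deleted (``deleted_genes``: sample -> deleted gene set) are
    reported as not assessable and excluded from denominators.
    """
    deleted_genes = deleted_genes or {}
    rows = []
    wild_pops = sorted({s.population for s in samples
                        if s.sample_class == "wild"})
    for av in annotated:
        v = av.variant
        base = {
            "pos": v.pos,
            "gene": av.gene_id,
            "consequence": av.consequence,
            "codon_index": av.codon_index,
            "ref_codon": av.ref_codon,
            "alt_codon": av.alt_codon,
            "ref_aa": av.ref_aa,
            "alt_aa": av.alt_aa,
        }
        not_assessable = {
            s.sample_id for s in samples
            if av.gene_id and av.gene_id in deleted_genes.get(s.sample_id, set())
        }
        for pop in wild_pops:
            alt = total = 0
            for s in samples:
                if s.population != pop or s.sample_class != "wild":
                    continue
                if s.sample_id in not_assessable:
                    continue
                gt = v.genotypes.get(s.sample_id, MISSING)
                if gt is MISSING:
                    continue
                alt += gt
                total += 2
            if total:
                rows.append(base | {
                    "population": pop,
                    "allele_frequency": alt / total,
                    "carriers": "",
                })
        carriers = [
            s.sample_id for s in samples
            if s.sample_class == "inbred-strain"
            and s.sample_id not in not_assessable
            and v.genotypes.get(s.sample_id, MISSING) == HOM_ALT
        ]
        if carriers:
            rows.append(base | {
                "population": "(Inbred strains)",
                "allele_frequency": float("nan"),
                "carriers": ", ".join(carriers),
            })
        if not_assessable:
            rows.append(base | {
                "population": "(Not assessable: gene deleted)",
                "allele_frequency": float("nan"),
                "carriers": ", ".join(sorted(not_assessable)),
            })
    return pd.DataFrame(rows)


def table1_style(freq_table: pd.DataFrame) -> pd.DataFrame:
    """Rearranged frequency table mirroring the published variant-table
    layout: location, amino-acid change, gene, codons, population, AF."""
    if freq_table.empty:
        return freq_table
    out = freq_table.copy()
    out["amino_acid_change"] = (
        out["ref_aa"].fillna("") + out["codon_index"].astype("Int64").astype(str)
        + out["alt_aa"].fillna("")
    )
    out["location"] = out["pos"] + 1
    cols = ["location", "amino_acid_change", "gene", "ref_codon", "alt_codon",
            "population", "allele_frequency", "carriers", "consequence"]
    return out[cols]
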