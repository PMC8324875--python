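"""Helpers for deposited reference records (GenBank / CDS FASTA).

The published analyses anchor the locus to deposited records: the
129S7-derived ~603 kb contig carrying the six-gene family (HM370554) and
the human/rat orthologue mRNAs (AB036706.1, AY065973.1, XM_017598901).
These utilities extract annotated CDS features from a GenBank flat file
or take a CDS FASTA directly, translate, and report peptide lengths, so
deposited records can be compared against the locus data model.
Downloading is left to ``scripts/fetch_accessions.py`` (requires network
access to NCBI).
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .locus_io import peptide_length, translate_cds

__all__ = [
    "cds_from_fasta",
    "cds_from_genbank",
    "protein_from_cds",
    "protein_lengths",
]


def cds_from_fasta(path: str | Path) -> dict[str, str]:
    """All records of a CDS FASTA, upcased, keyed by record id."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def cds_from_genbank(path: str | Path, gene: str | None = None) -> dict[str, str]:
    """Spliced CDS sequences of annotated CDS features in a GenBank file.

    Keys are the feature's gene (or locus_tag / protein_id) qualifier;
    ``gene`` restricts to one gene name (case-insensitive).
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            name = (feat.qualifiers.get("gene")
                    or feat.qualifiers.get("locus_tag")
                    or feat.qualifiers.get("protein_id")
                    or [f"{rec.id}_CDS"])[0]
            if gene is not None and name.lower() != gene.lower():
                continue
            seq = str(feat.extract(rec.seq)).upper()
            key = name
            i = 2
            while key in out:
                key = f"{name}_{i}"
                i += 1
            out[key] = seq
    return out


def protein_from_cds(cds: str) -> str:
    """Translated peptide up to (excluding) the first stop codon."""
    prot = translate_cds(cds)
    return prot[:peptide_length(prot)]


def protein_lengths(cds_by_id: dict[str, str]) -> dict[str, int]:
    return {name: len(protein_from_cds(cds)) for name, cds in cds_by_id.items()}
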