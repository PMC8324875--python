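"""McDonald-Kreitman tests across orthologues and paralogues.

The MK test contrasts the ratio of nonsynonymous to synonymous variation
segregating *within* a species (polymorphism, Pn/Ps) with the same ratio
for differences *fixed* against a comparator sequence (divergence,
Dn/Ds).  Under neutrality the two ratios are equal; an excess of
nonsynonymous divergence signals adaptive fixation.

Differences between codons are counted by Nei-Gojobori pathway
averaging: for a codon pair differing at d positions, every order of the
d single-base steps is a pathway; the synonymous / nonsynonymous step
counts are averaged over all pathways that avoid stop codons (if every
pathway passes through a stop, all are included instead), so
nonsyn + syn always equals the nucleotide Hamming distance.

Significance comes from a two-sided Fisher exact test computed by exact
integer hypergeometric enumeration, with Benjamini-Hochberg FDR applied
across the whole comparison matrix as one family.  The neutrality index
NI = (Pn/Ps) / (Dn/Ds) is reported alongside (NI < 1: excess
nonsynonymous fixation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .locus_io import (
    GENETIC_CODE,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    STOP_CODONS,
    Variant,
)

__all__ = [
    "MKTable",
    "MKResult",
    "CodonAlignment",
    "reconstruct_haplotypes",
    "count_pathway_differences",
    "tabulate_mk",
    "fisher_exact",
    "neutrality_index",
    "benjamini_hochberg",
    "mk_matrix",
]


@dataclass
class MKTable:
    """Divergence / polymorphism counts: fractional (pathway-averaged)
    and the rounded integer table handed to the exact test."""

    dn: float = 0.0
    ds: float = 0.0
    pn: float = 0.0
    ps: float = 0.0

    def rounded(self) -> tuple[int, int, int, int]:
        """Round half-up to integers for the exact test."""
        return tuple(int(np.floor(x + 0.5)) for x in
                     (self.dn, self.ds, self.pn, self.ps))


@dataclass
class MKResult:
    focal: str
    comparator: str
    table: MKTable
    p_value: float
    neutrality_index: float | None
    significant: bool = False


# ---------------------------------------------------------------------------
# Haplotype reconstruction
# ---------------------------------------------------------------------------

def reconstruct_haplotypes(
    reference_cds: str,
    variants: Sequence[tuple[int, str, str, dict[str, int | None]]],
    sample_ids: Sequence[str],
) -> dict[str, tuple[str, str]]:
    """Per-sample diploid CDS haplotypes from CDS-frame variants.

    ``variants`` rows are (cds_offset, ref_base, alt_base, genotypes).
    Hom-alt substitutes both haplotypes; het yields one haplotype with
    the alternate.  Unphased double-hets are paired by alternating the
    haplotype receiving the alternate allele in site order — MK counting
    is per-column and phase-free, so this choice cannot change the table.
    A sample with a missing genotype at any site is excluded entirely
    (column-level exclusion is not needed for the pooled counts).
    """
    haps: dict[str, tuple[list[str], list[str]]] = {
        s: (list(reference_cds), list(reference_cds)) for s in sample_ids
    }
    het_parity: dict[str, int] = {s: 0 for s in sample_ids}
    dropped: set[str] = set()
    for off, ref, alt, genotypes in sorted(variants, key=lambda r: r[0]):
        if reference_cds[off] != ref:
            raise ValueError(
                f"variant ref base {ref!r} at CDS offset {off} does not "
                f"match reference {reference_cds[off]!r}"
            )
        for s in sample_ids:
            gt = genotypes.get(s, MISSING)
            if gt is MISSING:
                dropped.add(s)
            elif gt == HOM_ALT:
                haps[s][0][off] = alt
                haps[s][1][off] = alt
            elif gt == HET:
                haps[s][het_parity[s] % 2][off] = alt
                het_parity[s] += 1
    return {
        s: ("".join(h[0]), "".join(h[1]))
        for s, h in haps.items() if s not in dropped
    }


# ---------------------------------------------------------------------------
# Nei-Gojobori pathway counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def count_pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two non-stop codons,
    averaged over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    is blocked, all are included.  The two components always sum to the
    Hamming distance.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or any(b not in "ACGT" for b in c):
            raise ValueError(f"codon {c!r} is a stop or not plain DNA")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    paths = []
    for order in itertools.permutations(diff):
        cur = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        ns = sum(1 for a, b in steps if GENETIC_CODE[a] != GENETIC_CODE[b])
        paths.append((blocked, ns, len(steps) - ns))

    usable = [p for p in paths if not p[0]] or paths
    nonsyn = sum(p[1] for p in usable) / len(usable)
    syn = sum(p[2] for p in usable) / len(usable)
    return nonsyn, syn


# ---------------------------------------------------------------------------
# MK tabulation
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Focal within-species CDS haplotypes vs one comparator CDS.

    On construction, codon columns containing a stop codon or a non-ACGT
    base in any sequence are dropped; all sequences must share one codon
    length.
    """

    focal: list[str]
    comparator: str
    comparator_name: str = ""
    retained_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        seqs = self.focal + [self.comparator]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1 or next(iter(lengths)) % 3 != 0:
            raise ValueError("sequences must share a codon-multiple length")
        n_codons = len(self.comparator) // 3
        self.retained_columns = []
        for c in range(n_codons):
            codons = [s[3 * c: 3 * c + 3] for s in seqs]
            if any(cd in STOP_CODONS or set(cd) - set("ACGT") for cd in codons):
                continue
            self.retained_columns.append(c)

    def column(self, c: int) -> tuple[list[str], str]:
        return ([s[3 * c: 3 * c + 3] for s in self.focal],
                self.comparator[3 * c: 3 * c + 3])


def _top_two(codons: list[str]) -> tuple[str, str]:
    """The two most frequent codons (count desc, then lexicographic)."""
    counts: dict[str, int] = {}
    for cd in codons:
        counts[cd] = counts.get(cd, 0) + 1
    ranked = sorted(counts, key=lambda cd: (-counts[cd], cd))
    return ranked[0], ranked[1]


def consensus_codon(codons: list[str]) -> str:
    counts: dict[str, int] = {}
    for cd in codons:
        counts[cd] = counts.get(cd, 0) + 1
    return sorted(counts, key=lambda cd: (-counts[cd], cd))[0]


def tabulate_mk(alignment: CodonAlignment) -> MKTable:
    """Pn/Ps from segregating columns, Dn/Ds from fixed differences.

    Per retained column: >1 distinct focal codon -> polymorphic, counted
    between the two most frequent focal codons; monomorphic and different
    from the comparator -> fixed.  A column that is both polymorphic and
    divergent contributes polymorphism only (no divergence is counted
    from a segregating column).
    """
    table = MKTable()
    for c in alignment.retained_columns:
        focal, comp = alignment.column(c)
        if len(set(focal)) > 1:
            a, b = _top_two(focal)
            ns, s = count_pathway_differences(a, b)
            table.pn += ns
            table.ps += s
        elif focal[0] != comp:
            ns, s = count_pathway_differences(focal[0], comp)
            table.dn += ns
            table.ds += s
    return table


# ---------------------------------------------------------------------------
# Fisher's exact test (exact integer hypergeometric enumeration)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _hypergeom_numerators(n: int, r1: int, c1: int) -> tuple[tuple[int, ...], int, int]:
    """All table probabilities for fixed margins, as exact integers.

    Returns (numerators over the support of a, a_min, denominator index
    is C(n, c1)); P(a) = C(r1, a) * C(n - r1, c1 - a) / C(n, c1).
    """
    a_min = max(0, c1 - (n - r1))
    a_max = min(r1, c1)
    nums = tuple(comb(r1, a) * comb(n - r1, c1 - a)
                 for a in range(a_min, a_max + 1))
    return nums, a_min, a_max


def fisher_exact(table: tuple[int, int, int, int] | MKTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table (dn, ds, pn, ps).

    p is the sum of hypergeometric probabilities, over tables with the
    observed margins, that are no more probable than the observed table.
    Probabilities are compared as exact integers, so ties are exact.
    Degenerate margins give p = 1.
    """
    if isinstance(table, MKTable):
        table = table.rounded()
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    nums, a_min, _ = _hypergeom_numerators(n, r1, c1)
    obs = nums[a - a_min]
    total = sum(x for x in nums if x <= obs)
    denom = comb(n, c1)
    return min(1.0, total / denom)


def neutrality_index(table: MKTable | tuple[int, int, int, int]) -> float | None:
    """NI = (Pn/Ps) / (Dn/Ds); None when Ps = 0 or Dn = 0."""
    if isinstance(table, MKTable):
        dn, ds, pn, ps = table.dn, table.ds, table.pn, table.ps
    else:
        dn, ds, pn, ps = table
    if ps == 0 or dn == 0:
        return None
    return (pn / ps) / (dn / ds) if ds != 0 else None


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.10) -> list[bool]:
    """BH step-up significance flags for one family of tests."""
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return []
    reject, *_ = multipletests(list(p_values), alpha=q, method="fdr_bh")
    return list(reject)


def mk_matrix(
    focal: dict[str, list[str]],
    comparators: dict[str, str],
    fdr_q: float = 0.10,
) -> list[MKResult]:
    """One MK test per (focal gene, comparator), excluding self-pairs.

    ``focal`` maps gene -> pooled within-species CDS haplotypes;
    ``comparators`` maps name -> CDS (a comparator given as a list of
    sequences is collapsed to its per-column majority consensus).  BH is
    applied across the whole matrix as one family at ``fdr_q``.
    """
    results: list[MKResult] = []
    for comp_name, comp_seq in comparators.items():
        if not isinstance(comp_seq, str):
            comp_seq = "".join(
                consensus_codon([s[3 * c: 3 * c + 3] for s in comp_seq])
                for c in range(len(comp_seq[0]) // 3)
            )
        for gene, haplotypes in focal.items():
            if comp_name == gene:
                continue
            aln = CodonAlignment(list(haplotypes), comp_seq, comp_name)
            table = tabulate_mk(aln)
            p = fisher_exact(table)
            results.append(MKResult(gene, comp_name, table, p,
                                    neutrality_index(table)))
    flags = benjamini_hochberg([r.p_value for r in results], q=fdr_q)
    for r, f in zip(results, flags):
        r.significant = f
    return results


def mk_matrix_table(results: list[MKResult]) -> pd.DataFrame:
    """P-value matrix (rows: comparators, columns: focal genes) with
    significance marked by an asterisk, mirroring the published layout."""
    focal = sorted({r.focal for r in results})
    comps = list(dict.fromkeys(r.comparator for r in results))
    df = pd.DataFrame("-", index=comps, columns=focal)
    for r in results:
        mark = "*" if r.significant else ""
        df.loc[r.comparator, r.focal] = f"{r.p_value:.3g}{mark}"
    return df


def mk_detail_table(results: list[MKResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        dn, ds, pn, ps = r.table.rounded()
        rows.append({
            "focal": r.focal, "comparator": r.comparator,
            "Dn": r.table.dn, "Ds": r.table.ds,
            "Pn": r.table.pn, "Ps": r.table.ps,
            "Dn_int": dn, "Ds_int": ds, "Pn_int": pn, "Ps_int": ps,
            "p_value": r.p_value,
            "NI": r.neutrality_index,
            "significant": r.significant,
        })
    return pd.DataFrame(rows)
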