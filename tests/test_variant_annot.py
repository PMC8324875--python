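import numpy as np
import pytest

from paraloc.locus_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    ContigSequence,
    GeneModel,
    ParalogueLocus,
    Sample,
    SampleSet,
    Variant,
    codon_to_contig,
    extract_cds,
    revcomp,
    translate_cds,
)
from paraloc.variant_annot import (
    FilterPolicy,
    annotate,
    filter_variants,
    population_frequencies,
    truncated_peptide_length,
)


def _v(quality=40.0, depth=20, genotypes=None, fractions=None):
    return Variant("c", 10, "A", "G", quality, depth,
                   genotypes or {}, fractions or {})


class TestFilter:
    def test_quality_threshold(self):
        passed, rejected = filter_variants([_v(quality=29)])
        assert passed == [] and rejected[0][1] == "low_quality"

    def test_depth_threshold(self):
        passed, rejected = filter_variants([_v(quality=40, depth=14)])
        assert passed == [] and rejected[0][1] == "low_depth"

    def test_balanced_het_passes(self):
        passed, _ = filter_variants([_v(genotypes={"s": HET},
                                        fractions={"s": 0.5})])
        assert len(passed) == 1

    def test_skewed_het_rejected(self):
        _, rejected = filter_variants([_v(genotypes={"s": HET},
                                          fractions={"s": 0.9})])
        assert rejected[0][1].startswith("allele_balance")

    def test_hom_alt_fraction(self):
        passed, _ = filter_variants([_v(genotypes={"s": HOM_ALT},
                                        fractions={"s": 0.97})])
        assert len(passed) == 1
        _, rejected = filter_variants([_v(genotypes={"s": HOM_ALT},
                                          fractions={"s": 0.7})])
        assert rejected

    def test_monotone_in_thresholds(self, rng):
        variants = [
            _v(quality=float(q), depth=int(d))
            for q, d in zip(rng.uniform(0, 60, 200), rng.integers(1, 40, 200))
        ]
        results = {}
        for minq in (10, 20, 30, 40):
            for mind in (5, 15, 25):
                policy = FilterPolicy(min_quality=minq, min_depth=mind)
                passed, _ = filter_variants(variants, policy)
                results[(minq, mind)] = {id(v) for v in passed}
        for (q1, d1), ids1 in results.items():
            for (q2, d2), ids2 in results.items():
                if q2 >= q1 and d2 >= d1:
                    assert ids2 <= ids1


def _locus_with_cds(cds, strand="+"):
    """Single gene occupying [10, 10+len) on the requested strand."""
    body = cds if strand == "+" else revcomp(cds)
    residues = "A" * 10 + body + "C" * 10
    return ParalogueLocus(ContigSequence("c", residues),
                          {"g": GeneModel("g", strand, [(10, 10 + len(cds))])})


class TestAnnotate:
    CDS = "ATGTGTTACTAGAAATAA"  # M C Y * K *

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("codon_idx,offset,alt_cds_base,expect", [
        (2, 2, "A", ("stop_gain", "C", "*")),    # TGT -> TGA
        (3, 1, "T", ("missense", "Y", "F")),     # TAC -> TTC
        (4, 0, "C", ("stop_loss", "*", "Q")),    # TAG -> CAG
        (5, 2, "G", ("synonymous", "K", "K")),   # AAA -> AAG
    ])
    def test_consequences_both_strands(self, strand, codon_idx, offset,
                                       alt_cds_base, expect):
        locus = _locus_with_cds(self.CDS, strand)
        pos = codon_to_contig(locus, "g", codon_idx, offset)
        ref = locus.contig.residues[pos]
        alt = alt_cds_base if strand == "+" else revcomp(alt_cds_base)
        av = annotate(Variant("c", pos, ref, alt, 60, 30), locus)
        assert (av.consequence, av.ref_aa, av.alt_aa) == expect
        assert av.gene_id == "g" and av.codon_index == codon_idx

    def test_non_coding(self):
        locus = _locus_with_cds(self.CDS)
        av = annotate(Variant("c", 2, "A", "G", 60, 30), locus)
        assert av.consequence == "non_coding" and av.gene_id is None

    def test_ref_mismatch_raises(self):
        locus = _locus_with_cds(self.CDS)
        pos = codon_to_contig(locus, "g", 2, 0)
        with pytest.raises(ValueError, match="does not match"):
            annotate(Variant("c", pos, "G", "A", 60, 30), locus)

    def test_indel_rejected(self):
        locus = _locus_with_cds(self.CDS)
        with pytest.raises(ValueError, match="SNV"):
            annotate(Variant("c", 12, "A", "AT", 60, 30), locus)

    def test_stop_gain_truncation_recorded(self):
        locus = _locus_with_cds(self.CDS)
        pos = codon_to_contig(locus, "g", 2, 2)
        av = annotate(Variant("c", pos, locus.contig.residues[pos], "A",
                              60, 30), locus)
        assert av.truncated_length == 1  # only Met precedes the new stop


class TestAnnotationOracle:
    """Applying the variant to the full CDS and translating must reproduce
    exactly the single-residue change the annotation reports."""

    def test_random_variants_both_strands(self, small_family, rng):
        locus, truth = small_family
        gene_ids = list(locus.genes)
        checked = 0
        while checked < 1000:
            gid = gene_ids[rng.integers(len(gene_ids))]
            gene = locus.gene(gid)
            cds = extract_cds(locus, gid)
            n_codons = len(cds) // 3
            codon_idx = int(rng.integers(1, n_codons + 1))
            offset = int(rng.integers(3))
            pos = codon_to_contig(locus, gid, codon_idx, offset)
            ref = locus.contig.residues[pos]
            alt = "ACGT"[rng.integers(4)]
            if alt == ref:
                continue
            av = annotate(Variant("c", pos, ref, alt, 60, 30), locus)
            # independent oracle: substitute in the CDS, translate whole
            cds_base = alt if gene.strand == "+" else revcomp(alt)
            cds_off = (codon_idx - 1) * 3 + offset
            alt_cds = cds[:cds_off] + cds_base + cds[cds_off + 1:]
            p_ref, p_alt = translate_cds(cds), translate_cds(alt_cds)
            diffs = [i for i, (a, b) in enumerate(zip(p_ref, p_alt), start=1)
                     if a != b]
            if av.consequence == "synonymous":
                assert diffs == []
            else:
                assert diffs == [codon_idx]
                assert p_alt[codon_idx - 1] == av.alt_aa
                assert p_ref[codon_idx - 1] == av.ref_aa
            checked += 1


class TestTruncation:
    def test_premature_stop_at_codon_143(self):
        # 313-codon open reading frame + terminal stop; stop pushed into
        # codon 143 leaves 142 translated residues
        cds = "ATG" + "GCT" * 312 + "TAA"
        mutated = cds[:142 * 3] + "TAG" + cds[143 * 3:]
        assert truncated_peptide_length(mutated) == 142

    def test_full_length_without_internal_stop(self):
        cds = "ATG" + "GCT" * 312 + "TAA"
        assert truncated_peptide_length(cds) == 313

    def test_stop_at_first_codon(self):
        assert truncated_peptide_length("TAAGCTTAA") == 0


class TestPopulationFrequencies:
    def _annotated(self, genotypes):
        locus = _locus_with_cds(TestAnnotate.CDS)
        pos = codon_to_contig(locus, "g", 3, 1)
        v = Variant("c", pos, locus.contig.residues[pos], "T", 60, 30,
                    genotypes)
        return [annotate(v, locus)]

    def test_wild_allele_frequency(self):
        samples = SampleSet([Sample(f"w{i}", "siteA", "wild") for i in range(4)])
        annotated = self._annotated(
            {"w0": HET, "w1": HET, "w2": HOM_ALT, "w3": HOM_REF})
        table = population_frequencies(annotated, samples)
        row = table[table["population"] == "siteA"].iloc[0]
        assert row["allele_frequency"] == pytest.approx(0.5)

    def test_all_hom_ref_zero(self):
        samples = SampleSet([Sample(f"w{i}", "siteA", "wild") for i in range(3)])
        table = population_frequencies(
            self._annotated({f"w{i}": HOM_REF for i in range(3)}), samples)
        assert table.iloc[0]["allele_frequency"] == 0.0

    def test_inbred_strains_listed_as_carriers(self):
        samples = SampleSet([
            Sample("FVB", "lab", "inbred-strain"),
            Sample("WSB", "lab", "inbred-strain"),
            Sample("C3H", "lab", "inbred-strain"),
        ])
        table = population_frequencies(
            self._annotated({"FVB": HOM_ALT, "WSB": HOM_ALT, "C3H": HOM_REF}),
            samples)
        row = table[table["population"] == "(Inbred strains)"].iloc[0]
        assert row["carriers"] == "FVB, WSB"
        assert np.isnan(row["allele_frequency"])

    def test_deleted_gene_not_assessable(self):
        samples = SampleSet([
            Sample("w0", "siteA", "wild"), Sample("w1", "siteA", "wild"),
        ])
        table = population_frequencies(
            self._annotated({"w0": HOM_ALT, "w1": HOM_REF}), samples,
            deleted_genes={"w1": {"g"}})
        row = table[table["population"] == "siteA"].iloc[0]
        # w1 excluded from the denominator entirely
        assert row["allele_frequency"] == pytest.approx(1.0)
        assert (table["population"] == "(Not assessable: gene deleted)").any()


class TestStopGainRecovery:
    def test_injected_stop_gains_all_recovered(self, family):
        from paraloc.synthetic_locus import (
            InjectedVariant, StrainSpec, cohort_truth_vcf, realize_strain,
        )
        from paraloc.variant_annot import annotate_all

        locus, truth = family
        specs = []
        n_injected = 0
        for gid in ("gene1", "gene4"):
            cds = truth.gene_cds[gid]
            idx = next(i // 3 + 1 for i in range(3, len(cds) - 3, 3)
                       if cds[i:i + 3] == "TGT")
            specs.append(StrainSpec(
                f"s_{gid}", injected_variants=[
                    InjectedVariant(gid, idx, "TGA", copies=2)]))
            n_injected += 1
        srs = [realize_strain(locus, truth, s) for s in specs]
        merged = cohort_truth_vcf(locus, srs)
        annotated = annotate_all(merged, locus)
        stops = [a for a in annotated if a.consequence == "stop_gain"]
        assert len(stops) == n_injected
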