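from itertools import combinations

import numpy as np
import pytest

from paraloc.locus_io import HET, HOM_ALT, STOP_CODONS, extract_cds, translate_cds
from paraloc.synthetic_locus import (
    FamilyConfig,
    InjectedVariant,
    StrainSpec,
    add_nonsynonymous_divergence,
    cohort_truth_vcf,
    evolve_cds,
    generate_family,
    realize_strain,
    sample_polymorphism,
    simulate_amplicon_reads,
    simulate_read_placements,
)


class TestGenerateFamily:
    def test_deterministic_for_fixed_seed(self):
        cfg = FamilyConfig(n_genes=3, intron_len=200, intergenic_len=2000,
                           seed=9)
        (l1, t1), (l2, t2) = generate_family(cfg), generate_family(cfg)
        assert l1.contig.residues == l2.contig.residues
        assert t1.gene_cds == t2.gene_cds
        assert l1.contig.masked == l2.contig.masked

    def test_pairwise_identity_near_target(self, family):
        _, truth = family
        cds = list(truth.gene_cds.values())
        for a, b in combinations(cds, 2):
            ident = sum(x == y for x, y in zip(a, b)) / len(a)
            assert 0.86 <= ident <= 0.94

    def test_single_gene_locus(self):
        locus, truth = generate_family(
            FamilyConfig(n_genes=1, intron_len=200, intergenic_len=2000,
                         seed=3))
        assert locus.gene_ids == ["gene1"]
        assert len(truth.gene_cds) == 1

    def test_genes_translate_full_length(self, family):
        locus, truth = family
        for gid, cds in truth.gene_cds.items():
            prot = translate_cds(cds)
            assert prot[-1] == "*" and "*" not in prot[:-1]
            assert extract_cds(locus, gid) == cds

    def test_identity_target_unreachable(self):
        with pytest.raises(ValueError):
            FamilyConfig(pairwise_identity=1.0)

    def test_mask_intervals_inside_intergenic(self, family):
        locus, _ = family
        spans = [g.span for g in locus.genes.values()]
        for ms, me in locus.contig.masked:
            for gs, ge in spans:
                assert me <= gs or ms >= ge


class TestRealizeStrain:
    def test_c57_like_pattern(self, family):
        locus, truth = family
        run = [["gene2", "gene3", "gene4", "gene5", "gene6"]]
        sr = realize_strain(locus, truth,
                            StrainSpec("c57", (list(run), list(run))))
        assert [sr.copy_number[g] for g in locus.gene_ids] == [2, 0, 0, 0, 0, 0]

    def test_het_deletion_pattern(self, family):
        locus, truth = family
        sr = realize_strain(locus, truth,
                            StrainSpec("wild", ([["gene2", "gene3"]], [])))
        assert [sr.copy_number[g] for g in locus.gene_ids] == [2, 1, 1, 2, 2, 2]

    def test_copy_number_is_two_minus_deleting_haplotypes(self, family):
        locus, truth = family
        sr = realize_strain(
            locus, truth,
            StrainSpec("mix", ([["gene2"], ["gene5"]], [["gene5"]])))
        assert sr.copy_number == {"gene1": 2, "gene2": 1, "gene3": 2,
                                  "gene4": 2, "gene5": 0, "gene6": 2}

    def test_non_contiguous_run_rejected(self, family):
        locus, truth = family
        with pytest.raises(ValueError, match="contiguous"):
            realize_strain(locus, truth,
                           StrainSpec("bad", ([["gene2", "gene5"]], [])))

    def test_stop_gain_injection_in_truth_vcf(self, family):
        locus, truth = family
        # find a gene-5 codon whose reference is TGT and push it to TGA
        cds = truth.gene_cds["gene5"]
        codon_idx = next(i // 3 + 1 for i in range(0, len(cds) - 3, 3)
                         if cds[i:i + 3] == "TGT")
        sr = realize_strain(
            locus, truth,
            StrainSpec("stopper", ([], []),
                       [InjectedVariant("gene5", codon_idx, "TGA", copies=2)]))
        assert len(sr.variants) == 1
        v = sr.variants[0]
        assert v.genotypes["stopper"] == HOM_ALT
        # the substitution realises TGA at that codon on both haplotypes
        from paraloc.locus_io import codon_to_contig

        pos = codon_to_contig(locus, "gene5", codon_idx, 2)
        assert v.pos == pos

    def test_variant_in_doubly_deleted_gene_rejected(self, family):
        locus, truth = family
        run = [["gene2"]]
        with pytest.raises(ValueError, match="deleted"):
            realize_strain(
                locus, truth,
                StrainSpec("bad", (list(run), list(run)),
                           [InjectedVariant("gene2", 10, "AAA")]))

    def test_population_frequency_matches_spec_exactly(self, family):
        locus, truth = family
        cds = truth.gene_cds["gene1"]
        idx = next(i // 3 + 1 for i in range(3, len(cds) - 3, 3)
                   if cds[i:i + 3] == "AAA")
        specs = [
            StrainSpec("w1", injected_variants=[InjectedVariant("gene1", idx, "AGA", 1)]),
            StrainSpec("w2", injected_variants=[InjectedVariant("gene1", idx, "AGA", 2)]),
            StrainSpec("w3"),
            StrainSpec("w4"),
        ]
        srs = [realize_strain(locus, truth, s) for s in specs]
        merged = cohort_truth_vcf(locus, srs)
        assert len(merged) == 1
        gts = merged[0].genotypes
        af = sum(gts[s] for s in ("w1", "w2", "w3", "w4")) / 8
        assert af == 3 / 8  # 1 het + 1 hom-alt among 4 diploids


class TestReadPlacements:
    def test_total_placed_bases_close_to_coverage(self, rng):
        cfg = FamilyConfig(n_genes=1, intron_len=200,
                           intergenic_len=48_000, masked_fraction=0.0, seed=4)
        locus, truth = generate_family(cfg)
        sr = realize_strain(locus, truth, StrainSpec("s"))
        table, _ = simulate_read_placements(sr, locus, coverage=10,
                                            read_len=100, rng=rng)
        placed = (table["end"] - table["start"]).sum()
        # diploid: two haplotypes each at 10x
        expected = 2 * 10 * len(locus.contig)
        assert abs(placed - expected) / expected < 0.05

    def test_fully_masked_genome_places_nothing(self, rng):
        locus, truth = generate_family(
            FamilyConfig(n_genes=1, intron_len=200, intergenic_len=2000,
                         masked_fraction=0.0, seed=4))
        locus.contig.masked = [(0, len(locus.contig))]
        sr = realize_strain(locus, truth, StrainSpec("s"))
        table, _ = simulate_read_placements(sr, locus, coverage=5, rng=rng)
        assert len(table) == 0

    def test_fixed_seed_reproducible(self, family):
        locus, truth = family
        sr = realize_strain(locus, truth, StrainSpec("s_repr"))
        t1, _ = simulate_read_placements(sr, locus, coverage=2, seed=77)
        t2, _ = simulate_read_placements(sr, locus, coverage=2, seed=77)
        assert t1.equals(t2)

    def test_no_placements_in_deleted_segments(self, family):
        locus, truth = family
        run = [["gene2", "gene3", "gene4", "gene5", "gene6"]]
        sr = realize_strain(locus, truth, StrainSpec("del", (run, run)))
        table, _ = simulate_read_placements(sr, locus, coverage=4, seed=5)
        (ds, de), = sr.deleted_spans[0]
        inside = table[(table["start"] >= ds) & (table["start"] < de)]
        assert len(inside) == 0

    def test_invalid_coverage(self, family):
        locus, truth = family
        sr = realize_strain(locus, truth, StrainSpec("s_cov"))
        with pytest.raises(ValueError):
            simulate_read_placements(sr, locus, coverage=0)

    def test_fastq_reads_match_reference(self, rng):
        locus, truth = generate_family(
            FamilyConfig(n_genes=1, intron_len=200, intergenic_len=5000,
                         masked_fraction=0.0, seed=4))
        sr = realize_strain(locus, truth, StrainSpec("s"))
        table, fastq = simulate_read_placements(
            sr, locus, coverage=2, rng=rng, emit_fastq=True, error_rate=0.0)
        from paraloc.locus_io import revcomp

        by_name = {name: seq for name, seq, _ in fastq}
        checked = 0
        for _, row in table.head(50).iterrows():
            seq = by_name.get(row["read_id"])
            if seq is None:
                continue
            ref = locus.contig.residues[row["start"]:row["end"]]
            assert seq in (ref, revcomp(ref))
            checked += 1
        assert checked > 10


class TestAmpliconSimulation:
    def test_empty_mixture(self, family):
        _, truth = family
        reads, counts = simulate_amplicon_reads(truth.amplicons,
                                                {"gene1": 1.0}, 0, seed=1)
        assert reads == [] and sum(counts.values()) == 0

    def test_single_source(self, family):
        _, truth = family
        reads, counts = simulate_amplicon_reads(
            truth.amplicons, {"gene3": 1.0}, 500, seed=1)
        assert counts["gene3"] == 500
        assert all(seq == truth.amplicons["gene3"] for _, seq, _ in reads)

    def test_multinomial_counts_sum(self, family):
        _, truth = family
        _, counts = simulate_amplicon_reads(
            truth.amplicons, {"gene6": 0.999, "gene2": 0.001}, 10_000, seed=1)
        assert sum(counts.values()) == 10_000
        assert counts["gene6"] > 9900


class TestEvolutionHelpers:
    def test_evolve_preserves_frame_and_stops(self, rng):
        from paraloc.synthetic_locus import _random_orf

        anc = _random_orf(100, rng)
        der = evolve_cds(anc, 0.1, rng)
        assert len(der) == len(anc)
        prot = translate_cds(der)
        assert "*" not in prot[:-1] and prot[-1] == "*"

    def test_add_nonsynonymous_divergence_counts(self, rng):
        from paraloc.synthetic_locus import _random_orf

        anc = _random_orf(200, rng)
        der = add_nonsynonymous_divergence(anc, 50, rng)
        diffs = sum(a != b for a, b in zip(anc, der))
        assert 0 < diffs <= 50  # same-site hits can overwrite
        assert "*" not in translate_cds(der)[:-1]

    def test_polymorphism_site_count(self, rng):
        from paraloc.synthetic_locus import _random_orf

        anc = _random_orf(200, rng)
        haps = sample_polymorphism(anc, 10, 30, rng)
        assert len(haps) == 10
        seg = sum(len({h[i] for h in haps}) > 1 for i in range(len(anc)))
        assert 0 < seg <= 30
        for h in haps:
            assert "*" not in translate_cds(h)[:-1]
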