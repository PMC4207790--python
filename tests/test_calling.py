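import numpy as np
import pytest
from Bio.Seq import Seq

from adaptmut import calling, genomes
from adaptmut.calling import (
    CallerThresholds,
    MutationCall,
    call_indels,
    call_snps,
    classify_mutation,
    detect_mixed_colony,
    strain_qc,
)
from conftest import make_counts


class TestThresholds:
    def test_fraction_ordering_enforced(self):
        with pytest.raises(ValueError):
            CallerThresholds(
                min_alt_fraction_strain=0.5, max_alt_fraction_ancestor=0.6
            )

    def test_min_depth_domain(self):
        with pytest.raises(ValueError, match="min_depth"):
            CallerThresholds(min_depth=-1)


class TestStrainQC:
    @staticmethod
    def _track(depths, strain="s"):
        return genomes.CoverageTrack(
            strain_id=strain,
            depth={c: np.asarray(d) for c, d in depths.items()},
        )

    def test_uniform_coverage_included(self):
        report = strain_qc(self._track({"chrI": np.full(1000, 10)}))
        assert report.fraction_covered_ge_min_depth == 1.0
        assert report.included

    def test_threshold_boundary_excluded(self):
        d = np.zeros(1000, dtype=int)
        d[:750] = 10
        report = strain_qc(self._track({"chrI": d}))
        assert report.fraction_covered_ge_min_depth == 0.75
        assert not report.included

    def test_mito_excluded_from_fraction(self):
        report = strain_qc(
            self._track({"chrI": np.full(100, 10), "chrM": np.zeros(100, int)}),
            mito_chrom="chrM",
        )
        assert report.fraction_covered_ge_min_depth == 1.0

    def test_all_mito_rejected(self):
        with pytest.raises(ValueError, match="nuclear"):
            strain_qc(self._track({"chrM": np.full(100, 10)}), mito_chrom="chrM")

    def test_39_strains_with_11_degraded_gives_28_included(self, ref):
        reports = []
        for i in range(39):
            degraded = i >= 28
            track = genomes.simulate_coverage(
                ref,
                f"s{i}",
                mean_depth=30,
                seed=100 + i,
                dropout_fraction=0.5 if degraded else 0.0,
            )
            reports.append(strain_qc(track))
        assert sum(r.included for r in reports) == 28


class TestCallSnps:
    def test_self_comparison_is_empty(self, std_counts, thresholds):
        tables, _ = std_counts
        anc = tables["ancestor"]
        assert call_snps(anc, anc, thresholds) == []

    def test_planted_truth_sensitivity_and_fdr(
        self, std_counts, std_planted, thresholds
    ):
        tables, _ = std_counts
        calls = call_snps(tables["ancestor"], tables["s1"], thresholds)
        truth = {(m.chrom, m.pos, m.alt_allele) for m in std_planted}
        called = {(c.chrom, c.pos, c.alt_allele) for c in calls}
        assert truth <= called, "missed planted SNPs"
        assert called == truth, "false positives on clean sites"

    def test_ancestral_variant_not_called(self):
        # ancestor already carries the alternative base at 50%
        anc = make_counts(
            {"chrI": [[15, 15, 0, 0, 0, 0], [30, 0, 0, 0, 0, 0]]}, "anc"
        )
        strain = make_counts(
            {"chrI": [[0, 30, 0, 0, 0, 0], [30, 0, 0, 0, 0, 0]]}, "s"
        )
        assert call_snps(anc, strain) == []

    def test_missing_ancestor_chromosome_skipped_and_logged(self, caplog):
        anc = make_counts({"chrI": [[30, 0, 0, 0, 0, 0]]}, "anc")
        strain = make_counts(
            {"chrI": [[30, 0, 0, 0, 0, 0]], "chrII": [[0, 30, 0, 0, 0, 0]]}, "s"
        )
        with caplog.at_level("INFO", logger="adaptmut.calling"):
            assert call_snps(anc, strain) == []
        assert "lacked ancestor coverage" in caplog.text

    def test_low_depth_is_no_call(self):
        anc = make_counts({"chrI": [[4, 0, 0, 0, 0, 0]]}, "anc")
        strain = make_counts({"chrI": [[0, 30, 0, 0, 0, 0]]}, "s")
        assert call_snps(anc, strain) == []

    def test_symmetric_null(self, std_counts, thresholds):
        tables, _ = std_counts
        anc, clean = tables["ancestor"], tables["clean"]
        assert call_snps(anc, clean, thresholds) == []
        assert call_snps(clean, anc, thresholds) == []

    def test_lowering_strain_threshold_never_removes_calls(self, std_counts):
        tables, _ = std_counts
        strict = CallerThresholds(min_alt_fraction_strain=0.9)
        loose = CallerThresholds(min_alt_fraction_strain=0.6)
        strict_calls = {
            (c.chrom, c.pos)
            for c in call_snps(tables["ancestor"], tables["s1"], strict)
        }
        loose_calls = {
            (c.chrom, c.pos)
            for c in call_snps(tables["ancestor"], tables["s1"], loose)
        }
        assert strict_calls <= loose_calls


@pytest.fixture(scope="module")
def indel_fixture(ref):
    planted = genomes.plant_mutations(
        ref,
        [("s1", "frameshift"), ("s1", "inframe_indel")],
        seed=11,
    )
    tables, _ = genomes.simulate_counts(
        ref, planted, ["ancestor", "s1"], mean_depth=30,
        error_rate=0.005, seed=12,
    )
    return planted, tables


class TestCallIndels:
    def test_planted_deletions_recovered_with_length(self, ref, indel_fixture, thresholds):
        planted, tables = indel_fixture
        calls = call_indels(tables["ancestor"], tables["s1"], ref, thresholds)
        assert {(c.chrom, c.pos, len(c.ref_allele)) for c in calls} == {
            (m.chrom, m.pos, len(m.ref_allele)) for m in planted
        }
        classified = [classify_mutation(c, ref) for c in calls]
        assert sorted(c.functional_class for c in classified) == [
            "frameshift",
            "inframe_indel",
        ]

    def test_no_planted_indels_no_calls(self, ref, thresholds):
        tables, _ = genomes.simulate_counts(
            ref, [], ["ancestor", "s"], mean_depth=30, error_rate=0.01, seed=13
        )
        assert call_indels(tables["ancestor"], tables["s"], ref, thresholds) == []

    def test_homopolymer_deletion_filtered_and_logged(self, caplog):
        seq = "GCGT" * 5 + "AAAAAAAA" + "CGTC" * 5
        ref = genomes.SyntheticReference(chromosomes={"chrI": seq}, genes=())
        L = len(seq)
        anc_arr = np.zeros((L, 6), dtype=np.int64)
        anc_arr[:, 0] = 30  # base identity irrelevant here
        st_arr = anc_arr.copy()
        st_arr[23, 5] = 30  # deletion evidence inside the A-homopolymer
        anc = genomes.NucleotideCountTable("anc", {"chrI": anc_arr})
        st = genomes.NucleotideCountTable("s", {"chrI": st_arr})
        with caplog.at_level("INFO", logger="adaptmut.calling"):
            calls = call_indels(anc, st, ref)
        assert calls == []
        assert "low-complexity" in caplog.text


class TestClassify:
    @staticmethod
    def _gene_ref(codon_overrides: dict[int, str], n_codons=400, strand="+"):
        """Reference with a single gene of known codons starting at pos 11."""
        rng = np.random.default_rng(0)
        filler = ["GCT"] * n_codons  # Ala codons
        for idx, codon in codon_overrides.items():
            filler[idx - 1] = codon
        cds = "".join(filler)
        gene_seq = cds if strand == "+" else str(Seq(cds).reverse_complement())
        pad5 = "".join("ACGT"[i] for i in rng.integers(0, 4, 10))
        pad3 = "".join("ACGT"[i] for i in rng.integers(0, 4, 10))
        chrom_seq = pad5 + gene_seq + pad3
        gene = genomes.Gene("g1", "chrI", 11, 10 + len(gene_seq), strand)
        return genomes.SyntheticReference(
            chromosomes={"chrI": chrom_seq}, genes=(gene,)
        )

    def _snp_call(self, ref, cds_offset, ref_base, alt_base):
        gene = ref.genes[0]
        pos = gene.start + cds_offset - 1
        return MutationCall("s", "chrI", pos, ref_base, alt_base, "snp", 1.0)

    def test_nonsense_at_codon_392(self):
        # CDS offset 1174 (codon 392, first base): CAA -> TAA is Gln -> stop
        ref = self._gene_ref({392: "CAA"})
        call = classify_mutation(self._snp_call(ref, 1174, "C", "T"), ref)
        assert call.functional_class == "nonsense"
        assert call.protein_pos == 392
        assert call.aa_change == ("Q", "*")

    def test_missense_at_codon_153(self):
        # CDS offset 457 (codon 153, first base): CGG -> GGG is Arg -> Gly
        ref = self._gene_ref({153: "CGG"})
        call = classify_mutation(self._snp_call(ref, 457, "C", "G"), ref)
        assert call.functional_class == "missense"
        assert call.protein_pos == 153
        assert call.aa_change == ("R", "G")

    def test_codon_index_at_offset_893(self):
        # CDS offset 893 (codon 298, middle base): GGT -> GAT is Gly -> Asp
        ref = self._gene_ref({298: "GGT"})
        call = classify_mutation(self._snp_call(ref, 893, "G", "A"), ref)
        assert call.protein_pos == 298
        assert call.functional_class == "missense"
        assert call.aa_change == ("G", "D")

    def test_minus_strand_codon_arithmetic(self):
        ref = self._gene_ref({10: "CAA"}, strand="-")
        gene = ref.genes[0]
        # CDS offset 28 = first base of codon 10; genome pos counts from end
        pos = gene.end - 28 + 1
        genome_ref = str(Seq("C").complement())
        call = classify_mutation(
            MutationCall("s", "chrI", pos, genome_ref, "A", "snp", 1.0), ref
        )
        # genome A on the minus strand is CDS T: CAA -> TAA
        assert call.functional_class == "nonsense"
        assert call.protein_pos == 10

    def test_inframe_deletion_rule(self):
        ref = self._gene_ref({})
        gene = ref.genes[0]
        pos = gene.start + 30
        dele = MutationCall(
            "s", "chrI", pos,
            ref.chromosomes["chrI"][pos - 1 : pos + 2], "", "del", 1.0,
        )
        assert classify_mutation(dele, ref).functional_class == "inframe_indel"

    def test_gene_boundary_overlap_flagged_for_review(self):
        ref = self._gene_ref({})
        gene = ref.genes[0]
        spanning = MutationCall(
            "s", "chrI", gene.start - 2,
            ref.chromosomes["chrI"][gene.start - 3 : gene.start + 1],
            "", "del", 1.0,
        )
        out = classify_mutation(spanning, ref)
        assert out.needs_review
        assert out.functional_class is None

    def test_intergenic_snp(self):
        ref = self._gene_ref({})
        call = classify_mutation(
            MutationCall("s", "chrI", 3, ref.chromosomes["chrI"][2], "A", "snp", 1.0),
            ref,
        )
        assert call.functional_class == "intergenic"

    def test_oracle_full_cds_translation_agreement(self, ref):
        # brute-force oracle: translate the entire mutant CDS and diff the
        # proteins, independently of the caller's codon arithmetic
        rng = np.random.default_rng(77)
        genes = list(ref.genes)
        n_checked = 0
        while n_checked < 1000:
            gene = genes[rng.integers(len(genes))]
            pos = int(rng.integers(gene.start, gene.end + 1))
            ref_base = ref.chromosomes[gene.chrom][pos - 1]
            alt = "ACGT"[rng.integers(0, 4)]
            if alt == ref_base:
                continue
            call = classify_mutation(
                MutationCall("s", gene.chrom, pos, ref_base, alt, "snp", 1.0), ref
            )
            # oracle
            seq = ref.chromosomes[gene.chrom]
            mut_seq = seq[: pos - 1] + alt + seq[pos:]
            wt_cds = seq[gene.start - 1 : gene.end]
            mut_cds = mut_seq[gene.start - 1 : gene.end]
            if gene.strand == "-":
                wt_cds = str(Seq(wt_cds).reverse_complement())
                mut_cds = str(Seq(mut_cds).reverse_complement())
            wt_prot = str(Seq(wt_cds).translate())
            mut_prot = str(Seq(mut_cds).translate())
            if wt_prot == mut_prot:
                expected = "synonymous"
            else:
                i = next(
                    k for k, (a, b) in enumerate(zip(wt_prot, mut_prot)) if a != b
                )
                expected = "nonsense" if mut_prot[i] == "*" else "missense"
            assert call.functional_class == expected, (gene, pos, ref_base, alt)
            n_checked += 1


class TestMixedColony:
    def test_threshold_inclusive_at_quarter(self):
        flagged, sites = detect_mixed_colony([(100, 0.25)])
        assert flagged and sites == [100]

    def test_just_below_threshold_not_flagged(self):
        flagged, sites = detect_mixed_colony([(100, 0.24)])
        assert not flagged and sites == []

    def test_two_subclones_at_fifty_fifty(self):
        flagged, sites = detect_mixed_colony([(100, 0.5), (200, 0.5)])
        assert flagged and sites == [100, 200]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            detect_mixed_colony([(1, 1.5)])
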