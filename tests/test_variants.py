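import numpy as np
import pytest

from ataxmap.intervals import GenomeInterval
from ataxmap.variants import (
    AnnotationError,
    OutOfCdsError,
    TranscriptModel,
    VariantRecord,
    annotate_variant,
    candidate_report,
    cds_sequence,
    classify_location,
    control_carrier_index,
    genomic_to_cds,
    private_hom_filter,
    protein_change,
    read_gff3,
    read_vcf,
    restrict_to_intervals,
)


def plus_tx(chrom="chr1"):
    # two exons, CDS 101..112 split 101-106 / 109-114 is 12 bases
    return TranscriptModel(
        gene_id="G1",
        transcript_id="G1.t1",
        chrom=chrom,
        strand="+",
        exons=[(95, 106), (109, 120)],
        cds_start=101,
        cds_end=114,
    )


def minus_tx(chrom="chr1"):
    return TranscriptModel(
        gene_id="G2",
        transcript_id="G2.t1",
        chrom=chrom,
        strand="-",
        exons=[(201, 206), (210, 215)],
        cds_start=201,
        cds_end=215,
    )


class TestVariantRecord:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord("chr1", 5, "A", "A")

    def test_key_and_is_snv(self):
        v = VariantRecord("chr1", 5, "A", "T")
        assert v.key == ("chr1", 5, "A", "T")
        assert v.is_snv
        assert not VariantRecord("chr1", 5, "AT", "A").is_snv


class TestPrivateHomFilter:
    def _case(self, gt):
        return [VariantRecord("chr1", 100, "C", "A", {"case": gt})]

    def test_keeps_only_hom_alt(self):
        index = {("chr1", 100, "C", "A"): (0, 0)}
        assert private_hom_filter(self._case(2), index) != []
        assert private_hom_filter(self._case(1), index) == []
        assert private_hom_filter(self._case(0), index) == []
        assert private_hom_filter(self._case(-1), index) == []

    def test_control_carrier_excludes(self):
        index = {("chr1", 100, "C", "A"): (1, 0)}
        assert private_hom_filter(self._case(2), index) == []

    def test_missing_controls_flagged_not_excluded(self):
        index = {("chr1", 100, "C", "A"): (0, 7)}
        out = private_hom_filter(self._case(2), index)
        assert out[0].flags == ["controls_missing:7"]

    def test_site_absent_from_controls_flagged(self):
        out = private_hom_filter(self._case(2), {})
        assert out[0].flags == ["not_in_controls"]

    def test_multi_sample_requires_case_name(self):
        v = VariantRecord("chr1", 1, "C", "A", {"a": 2, "b": 0})
        with pytest.raises(ValueError):
            private_hom_filter([v], {})
        assert private_hom_filter([v], {}, case_sample="a") != []
        assert private_hom_filter([v], {}, case_sample="b") == []

    def test_restrict_to_intervals_closed_bounds(self):
        vs = [VariantRecord("chr1", p, "C", "A") for p in (9, 10, 20, 21)]
        out = restrict_to_intervals(vs, [GenomeInterval("chr1", 10, 20)])
        assert [v.pos for v in out] == [10, 20]


class TestTranscriptModel:
    def test_validation(self):
        with pytest.raises(AnnotationError, match="strand"):
            TranscriptModel("g", "t", "chr1", "*", [(1, 9)], 1, 9)
        with pytest.raises(AnnotationError, match="overlap"):
            TranscriptModel("g", "t", "chr1", "+", [(1, 10), (5, 20)], 1, 9)
        with pytest.raises(AnnotationError, match="divisible"):
            TranscriptModel("g", "t", "chr1", "+", [(1, 10)], 1, 8)
        with pytest.raises(AnnotationError, match="outside exons"):
            TranscriptModel("g", "t", "chr1", "+", [(10, 20)], 5, 13)

    def test_cds_round_trip_plus(self):
        t = plus_tx()
        for k in range(1, t.cds_length + 1):
            assert t.genomic_to_cds(t.cds_to_genomic(k)) == k

    def test_cds_round_trip_minus(self):
        t = minus_tx()
        assert t.cds_length == 12
        for k in range(1, 13):
            assert t.genomic_to_cds(t.cds_to_genomic(k)) == k
        # coding position 1 is the genomic 3'-most CDS base on minus strand
        assert t.cds_to_genomic(1) == 215
        assert t.cds_to_genomic(12) == 201

    def test_exon_resplitting_invariance(self):
        whole = TranscriptModel("g", "t", "chr1", "+", [(1, 12)], 1, 12)
        split = TranscriptModel("g", "t", "chr1", "+", [(1, 7), (8, 12)], 1, 12)
        for k in range(1, 13):
            assert whole.cds_to_genomic(k) == split.cds_to_genomic(k)

    def test_out_of_cds(self):
        t = plus_tx()
        with pytest.raises(OutOfCdsError):
            t.genomic_to_cds(96)  # exonic but 5' UTR
        with pytest.raises(OutOfCdsError):
            t.cds_to_genomic(0)

    def test_intron_skipped_in_cds_numbering(self):
        t = plus_tx()
        assert t.genomic_to_cds(106) == 6
        assert t.genomic_to_cds(109) == 7


class TestStrandConversion:
    def test_minus_strand_complements_alleles(self):
        v = VariantRecord("chr1", 203, "C", "A")
        cds_pos, ref, alt = genomic_to_cds(v, minus_tx())
        assert (ref, alt) == ("G", "T")
        # 6 bases of the 3' exon (215..210) precede 206..203 in coding order
        assert cds_pos == 10

    def test_plus_strand_keeps_alleles(self):
        v = VariantRecord("chr1", 103, "C", "A")
        cds_pos, ref, alt = genomic_to_cds(v, plus_tx())
        assert (cds_pos, ref, alt) == (3, "C", "A")

    def test_non_snv_rejected(self):
        with pytest.raises(AnnotationError):
            genomic_to_cds(VariantRecord("chr1", 103, "CT", "C"), plus_tx())


class TestProteinChange:
    def test_codon_arithmetic(self):
        # GGT GCA -> position 5 is codon 2, offset 2
        cc = protein_change(5, "C", "T", "GGTGCA")
        assert cc.codon_index == 2
        assert (cc.ref_aa, cc.alt_aa) == ("A", "V")
        assert cc.klass == "missense"
        assert cc.c_notation == "c.5C>T"
        assert cc.p_notation == "p.Ala2Val"

    def test_synonymous(self):
        cc = protein_change(6, "T", "C", "GGTGCT")  # GCT -> GCC, both Ala
        assert cc.klass == "synonymous"
        assert cc.p_notation == "p.Ala2Ala"

    def test_nonsense_uses_ter(self):
        cc = protein_change(6, "G", "A", "GGTTGG")  # TGG Trp -> TGA stop
        assert cc.klass == "nonsense"
        assert cc.p_notation == "p.Trp2Ter"

    def test_reference_mismatch_raises(self):
        with pytest.raises(AnnotationError, match="mismatch"):
            protein_change(1, "A", "T", "GGT")

    def test_length_and_bounds_validation(self):
        with pytest.raises(AnnotationError):
            protein_change(1, "G", "T", "GGTA")
        with pytest.raises(OutOfCdsError):
            protein_change(7, "G", "T", "GGTGCA")


class TestClassifyAndReport:
    def _transcripts(self):
        return [plus_tx(), minus_tx()]

    def test_location_classes(self):
        ts = self._transcripts()
        assert classify_location(VariantRecord("chr1", 103, "C", "A"), ts)[0] == "exonic"
        assert classify_location(VariantRecord("chr1", 107, "C", "A"), ts)[0] == "intronic"
        assert classify_location(VariantRecord("chr1", 150, "C", "A"), ts)[0] == "intergenic"

    def test_funnel_counts_sum_to_total(self):
        rng = np.random.default_rng(17)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 300))}
        ts = self._transcripts()
        variants = []
        for pos in rng.choice(np.arange(1, 290), size=40, replace=False):
            ref = genome["chr1"][pos - 1]
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
            variants.append(VariantRecord("chr1", int(pos), ref, alt))
        table, counts = candidate_report(variants, ts, genome)
        assert sum(counts.values()) == len(variants)
        assert (table["location"].value_counts().reindex(counts).fillna(0).astype(int).to_dict()
                == counts)
        assert table["pos"].is_monotonic_increasing

    def test_utr_exonic_is_unsupported(self):
        calls = annotate_variant(VariantRecord("chr1", 96, "C", "A"), [plus_tx()], None)
        assert calls[0].klass == "unsupported"

    def test_indel_exonic_is_unsupported(self):
        calls = annotate_variant(
            VariantRecord("chr1", 103, "CT", "C"), [plus_tx()], None
        )
        assert calls[0].klass == "unsupported"


class TestVcfIO:
    def _write_vcf(self, path, body, samples=("s1", "s2")):
        head = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        path.write_text(head + body)

    def test_read_vcf_codes(self, tmp_path):
        p = tmp_path / "x.vcf"
        self._write_vcf(
            p,
            "chr1\t10\t.\tC\tA\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            "chr1\t20\t.\tG\tT\t.\tPASS\t.\tGT\t1/1\t./.\n",
        )
        vs = read_vcf(p)
        assert vs[0].genotypes == {"s1": 0, "s2": 1}
        assert vs[1].genotypes == {"s1": 2, "s2": -1}

    def test_multiallelic_decomposition(self, tmp_path):
        p = tmp_path / "x.vcf"
        self._write_vcf(p, "chr1\t10\t.\tC\tA,T\t.\tPASS\t.\tGT\t1/2\t2/2\n")
        vs = read_vcf(p)
        assert [(v.alt, v.genotypes) for v in vs] == [
            ("A", {"s1": 1, "s2": 0}),
            ("T", {"s1": 1, "s2": 2}),
        ]

    def test_control_carrier_index(self, tmp_path):
        p = tmp_path / "x.vcf"
        self._write_vcf(
            p,
            "chr1\t10\t.\tC\tA\t.\tPASS\t.\tGT\t0/1\t./.\n"
            "chr1\t20\t.\tG\tT\t.\tPASS\t.\tGT\t0/0\t0/0\n",
        )
        index = control_carrier_index(p)
        assert index[("chr1", 10, "C", "A")] == (1, 1)
        assert index[("chr1", 20, "G", "T")] == (0, 0)


class TestGff3:
    def test_round_trip_via_simulator_writer(self, tmp_path, small_dataset):
        from ataxmap.simulate import _write_gff3

        path = tmp_path / "genes.gff3"
        _write_gff3(path, small_dataset.transcripts)
        back = read_gff3(path)
        want = {
            (t.gene_id, t.transcript_id, t.chrom, t.strand, tuple(t.exons), t.cds_start, t.cds_end)
            for t in small_dataset.transcripts
        }
        got = {
            (t.gene_id, t.transcript_id, t.chrom, t.strand, tuple(t.exons), t.cds_start, t.cds_end)
            for t in back
        }
        assert got == want
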