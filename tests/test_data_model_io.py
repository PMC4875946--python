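import logging

import pytest

from domseln import data_model_io as io


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGeneModel:
    def test_intervals_sorted_on_construction(self):
        m = io.GeneModel("g", "t", "chr1", "+", ((301, 306), (201, 206)))
        assert m.cds_intervals == ((201, 206), (301, 306))

    def test_rejects_length_not_multiple_of_three(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            io.GeneModel("g", "t", "chr1", "+", ((101, 110),))

    def test_rejects_overlapping_intervals(self):
        with pytest.raises(ValueError, match="overlap"):
            io.GeneModel("g", "t", "chr1", "+", ((1, 9), (5, 13)))

    def test_phase_adjusts_coding_length(self):
        m = io.GeneModel("g", "t", "chr1", "+", ((101, 110),), phase_of_first_cds=1)
        assert m.coding_length == 9


class TestReadGeneModels:
    def test_single_exon_plus_strand(self, tmp_path):
        gff = _write(
            tmp_path,
            "a.gff3",
            "##gff-version 3\n"
            "chr1\tx\tCDS\t101\t109\t.\t+\t0\t"
            "ID=c1;Parent=transcript:t1;gene_id=g1;transcript_id=t1\n",
        )
        (model,) = io.read_gene_models(gff)
        assert model.cds_intervals == ((101, 109),)
        assert model.total_span == 9
        assert model.strand == "+"

    def test_two_cds_minus_strand_sorted_and_spliced(self, tmp_path):
        # 12-nt toy: 201-206 = AAATTT, 301-306 = GGGCCC; read 301..306 first
        # (transcription order on -), reverse-complemented by hand below
        gff = _write(
            tmp_path,
            "b.gff3",
            "##gff-version 3\n"
            "chr1\tx\tCDS\t301\t306\t.\t-\t0\tParent=t1;gene_id=g1;transcript_id=t1\n"
            "chr1\tx\tCDS\t201\t206\t.\t-\t0\tParent=t1;gene_id=g1;transcript_id=t1\n",
        )
        (model,) = io.read_gene_models(gff)
        assert model.cds_intervals == ((201, 206), (301, 306))
        contig = ["A"] * 400
        contig[200:206] = "AAATTT"
        contig[300:306] = "GGGCCC"
        cds = io.extract_cds({"chr1": "".join(contig)}, model)
        assert cds.nt_seq == "GGGCCCAAATTT"  # revcomp of AAATTTGGGCCC
        assert cds.genomic_map[0] == ("chr1", 306)
        assert cds.genomic_map[-1] == ("chr1", 201)

    def test_bad_length_skipped_and_logged(self, tmp_path, caplog):
        gff = _write(
            tmp_path,
            "c.gff3",
            "##gff-version 3\n"
            "chr1\tx\tCDS\t1\t10\t.\t+\t0\tParent=t1;gene_id=g1;transcript_id=t1\n",
        )
        with caplog.at_level(logging.WARNING):
            models = io.read_gene_models(gff)
        assert models == []
        assert "t1" in caplog.text

    def test_gene_model_round_trip(self, tmp_path):
        originals = [
            io.GeneModel("g1", "t1", "chr1", "+", ((10, 21),)),
            io.GeneModel("g2", "t2", "chr2", "-", ((5, 10), (31, 36)), 0),
        ]
        path = tmp_path / "rt.gff3"
        io.write_gene_models(originals, path)
        read_back = sorted(io.read_gene_models(path), key=lambda m: m.gene_id)
        assert read_back == originals


class TestExtractCds:
    GENOME = {"chr1": "ATGAAATAG"}

    def test_plus_strand_identity(self):
        m = io.GeneModel("g", "t", "chr1", "+", ((1, 9),))
        cds = io.extract_cds(self.GENOME, m)
        assert cds.nt_seq == "ATGAAATAG"
        assert cds.aa_len == 2  # Met-Lys + terminal stop
        assert cds.has_terminal_stop
        assert cds.protein_seq == "MK"

    def test_minus_strand_is_reverse_complement(self):
        m = io.GeneModel("g", "t", "chr1", "-", ((1, 9),))
        cds = io.extract_cds(self.GENOME, m)
        assert cds.nt_seq == "CTATTTCAT"

    def test_minus_strand_matches_revcomp_of_plus(self):
        genome = {"chr1": "ATGGCTTGCAAATTTGGGTAG"}
        plus = io.extract_cds(genome, io.GeneModel("g", "t", "chr1", "+", ((1, 21),)))
        minus = io.extract_cds(genome, io.GeneModel("g", "t", "chr1", "-", ((1, 21),)))
        assert minus.nt_seq == io.reverse_complement(plus.nt_seq)

    def test_internal_stop_raises(self):
        genome = {"chr1": "ATGTAAAAATGA"}  # TAA at codon 2 of 4
        m = io.GeneModel("g", "t", "chr1", "+", ((1, 12),))
        with pytest.raises(io.InternalStopError, match="codon 2"):
            io.extract_cds(genome, m)

    def test_out_of_bounds_interval(self):
        m = io.GeneModel("g", "t", "chr1", "+", ((1, 12),))
        with pytest.raises(ValueError, match="exceeds contig"):
            io.extract_cds(self.GENOME, m)

    def test_missing_chromosome(self):
        m = io.GeneModel("g", "t", "chrX", "+", ((1, 9),))
        with pytest.raises(KeyError):
            io.extract_cds(self.GENOME, m)


class TestBuildPartition:
    def test_no_hits_single_unassigned(self):
        part = io.build_partition([], "p", 100)
        assert len(part.segments) == 1
        seg = part.segments[0]
        assert (seg.aa_start, seg.aa_end, seg.label) == (1, 100, io.UNASSIGNED)

    def test_overlapping_hits_merge(self):
        hits = [
            io.DomainHit("p", "PF1", 10, 40, 1e-5),
            io.DomainHit("p", "PF2", 30, 60, 1e-5),
        ]
        part = io.build_partition(hits, "p", 100)
        labels = [(s.aa_start, s.aa_end, s.label) for s in part.segments]
        assert labels == [
            (1, 9, io.UNASSIGNED),
            (10, 60, io.DOMAIN),
            (61, 100, io.UNASSIGNED),
        ]
        # cross-check by per-position enumeration
        for pos in range(1, 101):
            expected = io.DOMAIN if 10 <= pos <= 60 else io.UNASSIGNED
            assert part.region_of(pos) == expected

    def test_full_length_hit(self):
        part = io.build_partition([io.DomainHit("p", "PF1", 1, 100, 0.0)], "p", 100)
        assert [s.label for s in part.segments] == [io.DOMAIN]

    def test_hit_beyond_protein_raises(self):
        with pytest.raises(ValueError, match="PF1"):
            io.build_partition([io.DomainHit("p", "PF1", 90, 120, 0.0)], "p", 100)

    def test_partition_tiles_and_alternates(self, small_proteome):
        for part in small_proteome.partitions.values():
            assert sum(s.length for s in part.segments) == part.aa_len
            for a, b in zip(part.segments, part.segments[1:]):
                assert a.label != b.label


class TestVariants:
    VCF_HEADER = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="x">\n'
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="x">\n'
        "##contig=<ID=chr1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )

    def test_aaf_maf_from_ac_an(self, tmp_path):
        vcf = _write(
            tmp_path, "a.vcf", self.VCF_HEADER + "chr1\t5\t.\tA\tG\t.\t.\tAC=3;AN=2184\n"
        )
        (v,) = io.read_variants(vcf)
        assert v.aaf == pytest.approx(3 / 2184)
        assert v.maf == pytest.approx(3 / 2184)

    def test_major_alt_folds_maf(self, tmp_path):
        vcf = _write(
            tmp_path, "b.vcf", self.VCF_HEADER + "chr1\t5\t.\tA\tG\t.\t.\tAC=2000;AN=2184\n"
        )
        (v,) = io.read_variants(vcf)
        assert v.aaf == pytest.approx(2000 / 2184)
        assert v.maf == pytest.approx(184 / 2184)

    def test_indel_skipped(self, tmp_path):
        vcf = _write(
            tmp_path,
            "c.vcf",
            self.VCF_HEADER + "chr1\t5\t.\tAT\tA\t.\t.\tAC=3;AN=100\n",
        )
        assert io.read_variants(vcf) == []

    def test_multiallelic_split(self, tmp_path):
        vcf = _write(
            tmp_path,
            "d.vcf",
            self.VCF_HEADER + "chr1\t5\t.\tA\tG,T\t.\t.\tAC=3,7;AN=100\n",
        )
        variants = io.read_variants(vcf)
        assert [(v.alt, v.alt_count) for v in variants] == [("G", 3), ("T", 7)]

    def test_genotype_fallback(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "chr1\t5\t.\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
        )
        (v,) = io.read_variants(_write(tmp_path, "e.vcf", text))
        assert (v.allele_number, v.alt_count) == (4, 3)

    def test_variant_round_trip(self, tmp_path):
        originals = [
            io.Variant("chr1", 10, "A", "G", 2184, 3),
            io.Variant("chr1", 22, "C", "T", 2184, 2000),
            io.Variant("chr2", 5, "G", "A", 100, 50),
        ]
        path = tmp_path / "rt.vcf"
        io.write_variants(originals, path)
        read_back = io.read_variants(path)
        assert sorted(read_back, key=lambda v: (v.chrom, v.pos)) == originals

    def test_invariants(self):
        with pytest.raises(ValueError, match="ref equals alt"):
            io.Variant("chr1", 1, "A", "A", 10, 1)
        with pytest.raises(ValueError, match="alt_count"):
            io.Variant("chr1", 1, "A", "G", 10, 11)


class TestDomainHitsIO:
    def test_round_trip(self, tmp_path):
        hits = [
            io.DomainHit("p1", "PF00001", 3, 40, 1e-6),
            io.DomainHit("p2", "PF00002", 1, 10, 1e-4),
        ]
        path = tmp_path / "d.tsv"
        io.write_domain_hits(hits, path)
        assert io.read_domain_hits(path) == hits

    def test_evalue_filter_applied_at_read(self, tmp_path):
        hits = [
            io.DomainHit("p1", "PF00001", 3, 40, 1e-6),
            io.DomainHit("p2", "PF00002", 1, 10, 0.5),
        ]
        path = tmp_path / "d.tsv"
        io.write_domain_hits(hits, path)
        assert io.read_domain_hits(path) == [hits[0]]
        assert io.read_domain_hits(path, e_value_threshold=1.0) == hits

    def test_missing_column_raises(self, tmp_path):
        path = _write(tmp_path, "bad.tsv", "protein_id\tali_start\np1\t3\n")
        with pytest.raises(io.ParseError, match="missing columns"):
            io.read_domain_hits(path)


class TestFastaIO:
    def test_round_trip_preserves_case(self, tmp_path):
        seqs = {"chr1": "ACGTacgtNN", "chr2": "TTTT"}
        path = tmp_path / "g.fa"
        io.write_fasta(seqs, path)
        assert io.read_fasta(path) == seqs
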