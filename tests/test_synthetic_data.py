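import numpy as np
import pytest

from domseln import data_model_io as io
from domseln import selection_dfe as dfe
from domseln import sites_density as sdns
from domseln import synthetic_data as sd
from domseln import variant_classify as vc


class TestSimConfig:
    def test_rejects_infeasible_domain_fraction(self):
        with pytest.raises(ValueError, match="domain_fraction"):
            sd.SimConfig(domain_fraction=1.5)

    def test_rejects_zero_acceptance(self):
        with pytest.raises(ValueError, match="accept_nonsyn_domain"):
            sd.SimConfig(accept_nonsyn_domain=0.0)

    def test_rejects_tiny_sample(self):
        with pytest.raises(ValueError, match="sample_size"):
            sd.SimConfig(sample_size=1)


class TestGenerateProteome:
    def test_minimal_single_gene(self, tmp_path):
        cfg = sd.SimConfig(
            n_genes=1, aa_len_range=(10, 10), domain_fraction=0.0,
            minus_strand_fraction=0.0, two_exon_fraction=0.0, seed=0,
        )
        p = sd.generate_proteome(cfg)
        (model,) = p.gene_models
        cds = p.coding[model.gene_id]
        assert len(cds.nt_seq) == 33  # 10 codons + terminal stop
        assert cds.aa_len == 10
        assert cds.protein_seq.startswith("M")
        assert p.domain_hits == []

    def test_orfs_have_no_internal_stops(self, small_proteome):
        for cds in small_proteome.coding.values():
            assert "*" not in cds.protein_seq
            assert cds.has_terminal_stop

    def test_domain_fraction_realized(self):
        cfg = sd.SimConfig(n_genes=200, domain_fraction=0.44, seed=2)
        p = sd.generate_proteome(cfg)
        assert sd.realized_domain_fraction(p) == pytest.approx(0.44, abs=0.05)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = sd.SimConfig(n_genes=15, seed=9)
        for sub in ("a", "b"):
            p = sd.generate_proteome(cfg)
            variants, _ = sd.simulate_variants(p, cfg)
            anc, _ = sd.simulate_ancestor(p, cfg, {(v.chrom, v.pos) for v in variants})
            sd.write_bundle(p, variants, anc, tmp_path / sub)
        for name in ("genome.fa", "genes.gff3", "domains.tsv", "variants.vcf", "ancestral.fa"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_emitted_files_parse_back(self, tmp_path, small_proteome):
        paths = small_proteome.write(tmp_path)
        models = io.read_gene_models(paths["gene_models"])
        assert len(models) == len(small_proteome.gene_models)
        genome = io.read_fasta(paths["genome"])
        for m in models:
            cds = io.extract_cds(genome, m)
            assert cds.nt_seq == small_proteome.coding[m.gene_id].nt_seq


class TestSimulateVariants:
    def test_zero_theta_empty(self, small_proteome):
        cfg = sd.SimConfig(n_genes=40, theta=0.0, seed=11)
        variants, truth = sd.simulate_variants(small_proteome, cfg)
        assert variants == []
        assert truth.records.empty

    def test_truth_labels_match_classifier(self, small_proteome, small_variants, small_classified):
        _, truth = small_variants
        classified, _ = small_classified
        t = truth.records.sort_values(["chrom", "pos"]).reset_index(drop=True)
        c = (
            vc.classified_variants_frame(classified)
            .sort_values(["chrom", "pos"])
            .reset_index(drop=True)
        )
        assert len(t) == len(c)
        for col in ("effect", "region", "maf_class", "gene_id", "cds_pos"):
            assert (t[col].values == c[col].values).all(), col

    def test_all_maf_classes_populated(self, small_variants):
        _, truth = small_variants
        assert set(truth.records["maf_class"]) == {vc.RARE, vc.LOW, vc.COMMON}

    def test_neutral_nonsyn_syn_ratio_matches_site_ratio(self):
        cfg = sd.SimConfig(n_genes=120, theta=0.05, seed=21)
        p = sd.generate_proteome(cfg)
        variants, truth = sd.simulate_variants(p, cfg)
        sites = sdns.total_site_counts(list(p.coding.values()), p.partitions)
        site_ratio = (
            sites.nonsyn(io.DOMAIN) + sites.nonsyn(io.UNASSIGNED)
        ) / (sites.syn(io.DOMAIN) + sites.syn(io.UNASSIGNED))
        counts = truth.records["effect"].value_counts()
        snp_ratio = counts["nonsynonymous"] / counts["synonymous"]
        assert snp_ratio == pytest.approx(site_ratio, rel=0.1)

    def test_thinning_reduces_domain_nonsyn(self):
        cfg = sd.SimConfig(
            n_genes=120, theta=0.05, accept_nonsyn_domain=0.5, seed=22
        )
        p = sd.generate_proteome(cfg)
        _, truth = sd.simulate_variants(p, cfg)
        t = truth.records
        dom = t[(t.region == io.DOMAIN)]
        un = t[(t.region == io.UNASSIGNED)]
        ratio_dom = (dom.effect == "nonsynonymous").sum() / (dom.effect == "synonymous").sum()
        ratio_un = (un.effect == "nonsynonymous").sum() / (un.effect == "synonymous").sum()
        assert ratio_dom < 0.75 * ratio_un


class TestSimulateAncestor:
    def test_zero_rate_identity(self, small_proteome):
        cfg = sd.SimConfig(
            n_genes=40, divergence_rate=0.0, ancestral_mask_fraction=0.0, seed=11
        )
        anc, truth = sd.simulate_ancestor(small_proteome, cfg)
        assert anc == small_proteome.genome
        assert truth.records.empty

    def test_divergence_count_poisson_mean(self):
        cfg = sd.SimConfig(n_genes=150, divergence_rate=0.02, seed=31)
        p = sd.generate_proteome(cfg)
        _, truth = sd.simulate_ancestor(p, cfg)
        L = sum(3 * c.aa_len for c in p.coding.values())
        expected = cfg.divergence_rate * L
        assert abs(len(truth.records) - expected) < 3 * np.sqrt(expected)

    def test_avoids_polymorphic_sites(self, small_proteome, small_sim_config, small_variants):
        variants, _ = small_variants
        poly = {(v.chrom, v.pos) for v in variants}
        _, truth = sd.simulate_ancestor(small_proteome, small_sim_config, poly)
        emitted = set(zip(truth.records["chrom"], truth.records["pos"]))
        assert emitted.isdisjoint(poly)

    def test_fully_masked_yields_no_divergence_calls(self, small_proteome):
        cfg = sd.SimConfig(
            n_genes=40, divergence_rate=0.02, ancestral_mask_fraction=1.0, seed=11
        )
        anc, _ = sd.simulate_ancestor(small_proteome, cfg)
        for model in small_proteome.gene_models:
            anc_cds = io.extract_cds(anc, model, allow_internal_stop=True)
            recs = vc.call_fixed_divergence(
                small_proteome.coding[model.gene_id], anc_cds.nt_seq, set()
            )
            assert recs == []

    def test_truth_agrees_with_divergence_caller(self, small_proteome, small_sim_config):
        anc, truth = sd.simulate_ancestor(small_proteome, small_sim_config)
        called = []
        for model in small_proteome.gene_models:
            anc_cds = io.extract_cds(anc, model, allow_internal_stop=True)
            called.extend(
                vc.call_fixed_divergence(
                    small_proteome.coding[model.gene_id], anc_cds.nt_seq, set(),
                    small_proteome.partitions[model.gene_id],
                )
            )
        t = truth.records
        unmasked = t[~t["masked"]].sort_values(["gene_id", "cds_pos"]).reset_index(drop=True)
        c = (
            vc.divergence_frame(called)
            .sort_values(["gene_id", "cds_pos"])
            .reset_index(drop=True)
        )
        assert len(unmasked) == len(c)
        for col in ("effect", "region", "ancestral_base", "derived_base"):
            assert (unmasked[col].values == c[col].values).all(), col


class TestSimulateSfsPair:
    def test_neutral_class_means(self):
        pair = sd.simulate_sfs_pair(
            1.0, 0.0, 1000.0, 1000.0, None, n=10, seed=0, folded=False
        )
        for i in (1, 2):
            mean = 1000.0 / i
            assert abs(pair.neutral_counts[i - 1] - mean) < 5 * np.sqrt(mean)
            assert abs(pair.selected_counts[i - 1] - mean) < 5 * np.sqrt(mean)

    def test_same_seed_identical(self):
        a = sd.simulate_sfs_pair(0.3, 50.0, 500.0, 500.0, None, n=12, seed=7)
        b = sd.simulate_sfs_pair(0.3, 50.0, 500.0, 500.0, None, n=12, seed=7)
        assert np.array_equal(a.neutral_counts, b.neutral_counts)
        assert np.array_equal(a.selected_counts, b.selected_counts)

    def test_distortions_scale_means(self):
        r = np.full(5, 3.0)
        r[0] = 1.0
        pair = sd.simulate_sfs_pair(1.0, 0.0, 4000.0, 4000.0, r, n=10, seed=3)
        # doubleton class mean is r_2 * theta * (1/2 + 1/8)
        mean = 3.0 * 4000.0 * (1 / 2 + 1 / 8)
        assert abs(pair.neutral_counts[1] - mean) < 5 * np.sqrt(mean)

    def test_selection_depletes_common_classes(self):
        pair = sd.simulate_sfs_pair(
            0.3, 200.0, 5000.0, 5000.0, None, n=20, seed=9
        )
        sel_common = pair.selected_counts[-3:].sum()
        neu_common = pair.neutral_counts[-3:].sum()
        assert sel_common < neu_common

    def test_small_n_raises(self):
        with pytest.raises(ValueError, match="n must be"):
            sd.simulate_sfs_pair(0.3, 1.0, 1.0, 1.0, None, n=3)


class TestNeutralDos:
    def test_dos_near_zero_under_neutrality(self):
        # aggregate counts over replicates, |DoS| < 3 delta-method SEs
        dn = ds_ = pn = ps = 0
        for seed in range(5):
            cfg = sd.SimConfig(n_genes=80, theta=0.04, divergence_rate=0.01, seed=seed)
            p = sd.generate_proteome(cfg)
            variants, truth = sd.simulate_variants(p, cfg)
            _, div_truth = sd.simulate_ancestor(
                p, cfg, {(v.chrom, v.pos) for v in variants}
            )
            t, d = truth.records, div_truth.records
            pn += (t.effect == "nonsynonymous").sum()
            ps += (t.effect == "synonymous").sum()
            dn += (d.effect == "nonsynonymous").sum()
            ds_ += (d.effect == "synonymous").sum()
        value = dfe.dos(dn, ds_, pn, ps)
        se = dfe.dos_standard_error(dn, ds_, pn, ps)
        assert abs(value) < 3 * se
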