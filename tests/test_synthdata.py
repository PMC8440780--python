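"""Synthetic-data generator: geometry, determinism and distributional checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatialrisk import io
from spatialrisk.qc import MISSING, hwe_exact
from spatialrisk.synthdata import (
    SimConfig,
    generate_cohort,
    generate_contacts,
    generate_eqtl_table,
    generate_reference,
    simulate_all,
)


class TestReference:
    def test_fragments_tile_contiguously(self, small_reference):
        for chrom in small_reference.fragments.chromosomes():
            frags = [f for f in small_reference.fragments.fragments if f.chrom == chrom]
            frags.sort(key=lambda f: f.start)
            assert frags[0].start == 0
            for a, b in zip(frags, frags[1:]):
                assert a.end == b.start  # contiguous, half-open, non-overlapping
            assert [f.index for f in frags] == list(range(len(frags)))

    def test_tiling_arithmetic(self):
        cfg = SimConfig(n_snps=5, n_genes=2, fragment_length=1000, seed=0, n_chromosomes=1)
        ref = generate_reference(cfg)
        frags = ref.fragments.fragments
        length = ref.chrom_lengths["chr1"]
        assert len(frags) == length // 1000
        assert frags[0].start == 0 and frags[-1].end == length

    def test_every_snp_inside_exactly_one_fragment(self, small_reference):
        for snp in small_reference.snps:
            hits = [
                f
                for f in small_reference.fragments.fragments
                if f.chrom == snp.chrom and f.start <= snp.pos < f.end
            ]
            assert len(hits) == 1

    def test_gene_spans_cover_both_sides_of_intragenic_rule(self, small_reference):
        # interval-intersection oracle for fragments overlapped by each gene
        def span(gene):
            return sum(
                1
                for f in small_reference.fragments.fragments
                if f.chrom == gene.chrom and f.start < gene.end and f.end > gene.start
            )

        spans = {span(g) for g in small_reference.genes}
        assert any(s < 3 for s in spans) and any(s >= 3 for s in spans)
        assert spans == set(SimConfig().gene_fragment_spans) | spans

    def test_deterministic_given_seed(self, tmp_path, small_config):
        a = generate_reference(small_config)
        b = generate_reference(small_config)
        for ref, name in ((a, "a"), (b, "b")):
            io.write_fragments_bed(ref.fragments, tmp_path / f"f_{name}.bed")
            io.write_genes_bed(ref.genes, tmp_path / f"g_{name}.bed")
        assert (tmp_path / "f_a.bed").read_bytes() == (tmp_path / "f_b.bed").read_bytes()
        assert (tmp_path / "g_a.bed").read_bytes() == (tmp_path / "g_b.bed").read_bytes()

    def test_impossible_geometry_rejected(self):
        # a gene spanning more fragments than the chromosome holds
        cfg = SimConfig(n_snps=10, n_genes=1, fragment_length=1000, seed=0,
                        chrom_length=3000, gene_fragment_spans=(8,),
                        n_planted_features=1)
        with pytest.raises(ValueError):
            generate_reference(cfg)


class TestContacts:
    def test_required_configurations_present(self, small_config, small_reference, small_contacts):
        fmap = small_reference.fragments
        snp_frags = {
            (f.chrom, f.index)
            for f in (fmap.locate(s.chrom, s.pos) for s in small_reference.snps)
        }
        has_self = any(c.is_self for c in small_contacts)
        has_adjacent = any(
            c.a.chrom == c.b.chrom and abs(c.a.index - c.b.index) == 1
            for c in small_contacts
        )
        has_trans = any(c.a.chrom != c.b.chrom for c in small_contacts)
        has_distal_cis = any(
            c.a.chrom == c.b.chrom and abs(c.a.index - c.b.index) >= 2
            for c in small_contacts
        )
        assert has_self and has_adjacent and has_trans and has_distal_cis
        assert any((c.a.chrom, c.a.index) in snp_frags or (c.b.chrom, c.b.index) in snp_frags
                   for c in small_contacts)

    def test_unordered_pairs_unique(self, small_contacts):
        seen = set()
        for c in small_contacts:
            ka, kb = (c.a.chrom, c.a.index), (c.b.chrom, c.b.index)
            key = (min(ka, kb), max(ka, kb))
            assert key not in seen
            seen.add(key)

    def test_planted_pairs_have_contacts(self, small_reference, small_contacts):
        fmap = small_reference.fragments
        keys = {
            (min(ka, kb), max(ka, kb))
            for c in small_contacts
            for ka, kb in [((c.a.chrom, c.a.index), (c.b.chrom, c.b.index))]
        }
        genes = {g.id: g for g in small_reference.genes}
        snps = {s.id: s for s in small_reference.snps}
        for snp_id, gene_id in small_reference.planted_pairs:
            s, g = snps[snp_id], genes[gene_id]
            fs = fmap.locate(s.chrom, s.pos)
            gene_keys = {
                (f.chrom, f.index) for f in fmap.overlapping(g.chrom, g.start, g.end)
            }
            ks = (fs.chrom, fs.index)
            assert any((min(ks, kg), max(ks, kg)) in keys for kg in gene_keys)

    def test_total_count_near_poisson_expectation(self):
        cfg = SimConfig(n_snps=100, n_genes=10, contact_density=2.0, seed=42,
                        n_cases=10, n_controls=10)
        ref = generate_reference(cfg)
        contacts = generate_contacts(ref, cfg)
        lam = 200.0
        lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
        # a handful of constructed contacts sit on top of the Poisson draw,
        # and dedup can only reduce the count
        n_constructed = len(ref.planted_pairs) + 4
        assert lo - n_constructed <= len(contacts) <= hi + n_constructed


class TestEqtlTable:
    def test_null_pvalues_uniform(self):
        cfg = SimConfig(n_snps=400, n_genes=60, n_tissues=8, seed=3,
                        eqtl_snp_fraction=1.0, planted_effect_total=0.0,
                        n_planted_features=1, n_cases=10, n_controls=10)
        table = generate_eqtl_table(generate_reference(cfg), cfg)
        null = table[table["pval"] > cfg.planted_pval]["pval"]
        assert len(null) > 500
        assert stats.kstest(null, "uniform").pvalue > 0.01

    def test_planted_rows_survive_bh_among_few_nulls(self, small_reference, small_config, small_eqtls):
        planted = small_eqtls[small_eqtls["pval"] <= small_config.planted_pval]
        assert len(planted) == len(small_reference.planted_features)
        pvec = list(planted["pval"]) + [0.3, 0.5, 0.7, 0.9, 0.95]
        # brute-force BH step-up
        order = np.argsort(pvec)
        m = len(pvec)
        q = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            prev = min(prev, m * pvec[i] / (rank_pos + 1))
            q[i] = prev
        assert all(q[: len(planted)] < 0.05)

    def test_zero_tissues_gives_header_only(self):
        cfg = SimConfig(n_snps=10, n_genes=4, n_tissues=0, seed=0,
                        planted_effect_total=0.0, n_cases=10, n_controls=10)
        table = generate_eqtl_table(generate_reference(cfg), cfg)
        assert list(table.columns) == ["snp_id", "gene_id", "tissue", "nes", "pval"]
        assert table.empty


class TestCohort:
    def test_allele_frequency_matches_maf(self):
        cfg = SimConfig(n_cases=5000, n_controls=5000, n_snps=8, n_genes=4,
                        maf_range=(0.3, 0.3), seed=9, missing_rate=0.0,
                        planted_effect_total=0.0)
        ref = generate_reference(cfg)
        # force every MAF to exactly 0.3 (planted SNPs are re-drawn)
        for sid in ref.snp_maf:
            ref.snp_maf[sid] = 0.3
        cohort = generate_cohort(ref, generate_eqtl_table(ref, cfg), cfg)
        freq = cohort.genotypes.alt_freq()
        assert np.all(np.abs(freq - 0.3) < 0.015)

    def test_null_cohort_has_no_case_control_separation(self):
        cfg = SimConfig(n_cases=1000, n_controls=1000, n_snps=40, n_genes=10,
                        planted_effect_total=0.0, seed=21, missing_rate=0.0)
        ref = generate_reference(cfg)
        cohort = generate_cohort(ref, generate_eqtl_table(ref, cfg), cfg)
        y = cohort.label_array()
        n_ok = 0
        for j in range(cohort.genotypes.n_snps):
            col = cohort.genotypes.dosage[:, j]
            p = stats.mannwhitneyu(col[y == 1], col[y == 0]).pvalue
            n_ok += p > 0.01
        assert n_ok >= 0.95 * cohort.genotypes.n_snps

    def test_arm_sizes_and_labels(self, small_config):
        _, _, _, cohort = simulate_all(small_config)
        labels = list(cohort.labels.values())
        assert labels.count("case") == small_config.n_cases
        assert labels.count("control") == small_config.n_controls

    def test_planted_truth_structure(self, small_config):
        _, _, _, cohort = simulate_all(small_config)
        truth = cohort.truth
        mass = sum(truth.tissue_effect_mass.values())
        assert mass == pytest.approx(small_config.planted_effect_total)
        assert truth.tissue_effect_mass[small_config.planted_tissue] == pytest.approx(
            small_config.planted_effect_total
        )
        assert all(v == 0 for t, v in truth.tissue_effect_mass.items()
                   if t != small_config.planted_tissue)

    def test_missingness_only_on_non_core_snps(self, small_config):
        cfg = SimConfig(**{**small_config.__dict__, "missing_rate": 0.2, "core_fraction": 0.5})
        ref = generate_reference(cfg)
        cohort = generate_cohort(ref, generate_eqtl_table(ref, cfg), cfg)
        planted_snps = {s for s, _ in ref.planted_pairs}
        miss = (cohort.genotypes.dosage == MISSING).mean(axis=0)
        idx = {s: j for j, s in enumerate(cohort.genotypes.snp_ids)}
        assert all(miss[idx[s]] == 0.0 for s in planted_snps)
        assert miss.max() > 0  # some SNPs do carry missingness

    def test_same_seed_identical_vcf_bytes(self, tmp_path, small_config):
        for name in ("a", "b"):
            _, _, _, cohort = simulate_all(small_config)
            io.write_vcf(cohort.genotypes, tmp_path / f"{name}.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_genotypes_in_hwe(self):
        cfg = SimConfig(n_cases=500, n_controls=500, n_snps=200, n_genes=10,
                        planted_effect_total=0.0, seed=5, missing_rate=0.0)
        ref = generate_reference(cfg)
        cohort = generate_cohort(ref, generate_eqtl_table(ref, cfg), cfg)
        n_pass = 0
        for j in range(cohort.genotypes.n_snps):
            col = cohort.genotypes.dosage[:, j]
            p = hwe_exact(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
            n_pass += p > 1e-6
        assert n_pass >= 0.99 * cohort.genotypes.n_snps

    def test_negative_effect_total_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(planted_effect_total=-1.0)
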