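"""Spatial eQTL calling: fragment assignment, pairing rules, FDR, cis/trans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialrisk.spatial import (
    Contact,
    Fragment,
    FragmentMap,
    Gene,
    Snp,
    UnmappedSnpError,
    assign_snp_fragment,
    bh_adjust,
    call_spatial_eqtls,
    classify_cis_trans,
    find_spatial_pairs,
    gene_fragment_span,
)


def tile(chrom: str, n: int, size: int = 100) -> list[Fragment]:
    return [Fragment(chrom, i * size, (i + 1) * size, i) for i in range(n)]


@pytest.fixture
def fmap() -> FragmentMap:
    return FragmentMap(tile("chr1", 10) + tile("chr2", 10))


class TestAssignSnpFragment:
    @pytest.mark.parametrize(
        "pos,expected_index",
        [(150, 1), (100, 1), (0, 0), (299, 2)],  # containment + half-open boundary
    )
    def test_containment(self, fmap, pos, expected_index):
        frag = assign_snp_fragment(Snp("rs1", "chr1", pos), fmap)
        assert frag.index == expected_index

    def test_position_outside_map_raises(self, fmap):
        with pytest.raises(UnmappedSnpError, match="rs1"):
            assign_snp_fragment(Snp("rs1", "chr1", 10**9), fmap)


class TestFindSpatialPairs:
    def make(self, fmap, snp_pos, gene_span, contacts, gene_chrom="chr1"):
        snp = Snp("rs1", "chr1", snp_pos)
        gene = Gene("G1", "G1", gene_chrom, *gene_span)
        contact_objs = [
            Contact(fmap.locate(c1, p1), fmap.locate(c2, p2), frozenset({src}))
            for (c1, p1, c2, p2, src) in contacts
        ]
        return find_spatial_pairs([snp], [gene], fmap, contact_objs)

    def test_distal_contact_emits_pair(self, fmap):
        pairs = self.make(fmap, 50, (500, 580), [("chr1", 50, "chr1", 550, "libA")])
        assert [(p.snp_id, p.gene_id) for p in pairs] == [("rs1", "G1")]
        assert pairs[0].supporting_sources == frozenset({"libA"})

    def test_adjacent_only_contact_is_ignored(self, fmap):
        pairs = self.make(fmap, 50, (100, 180), [("chr1", 50, "chr1", 150, "libA")])
        assert pairs == []

    def test_self_contact_is_ignored(self, fmap):
        pairs = self.make(fmap, 50, (10, 90), [("chr1", 50, "chr1", 60, "libA")])
        assert pairs == []

    def test_trans_contact_emits_pair(self, fmap):
        pairs = self.make(
            fmap, 50, (0, 80), [("chr1", 50, "chr2", 50, "libB")], gene_chrom="chr2"
        )
        assert len(pairs) == 1

    def test_intragenic_two_fragment_gene_excluded(self, fmap):
        # SNP inside a gene spanning 2 fragments; even a distal contact back
        # into the gene cannot rescue it
        pairs = self.make(fmap, 250, (220, 380), [("chr1", 250, "chr1", 350, "libA")])
        assert pairs == []

    def test_intragenic_wide_gene_with_distal_contact_included(self, fmap):
        # same SNP, gene widened to 4 fragments, contact to its far fragment
        pairs = self.make(fmap, 250, (220, 580), [("chr1", 250, "chr1", 550, "libA")])
        assert len(pairs) == 1
        assert pairs[0].intragenic

    def test_sources_unioned_across_libraries(self, fmap):
        pairs = self.make(
            fmap, 50, (500, 580),
            [("chr1", 50, "chr1", 550, "libA"), ("chr1", 50, "chr1", 550, "libB")],
        )
        assert pairs[0].supporting_sources == frozenset({"libA", "libB"})

    def test_gene_fragment_span_oracle(self, fmap):
        gene = Gene("G1", "G1", "chr1", 220, 580)
        assert [f.index for f in gene_fragment_span(gene, fmap)] == [2, 3, 4, 5]


class TestBhAdjust:
    def brute_force(self, pvals):
        """Literal step-up: q_(i) = min_{j>=i} m p_(j)/j, clipped at 1."""
        p = np.asarray(pvals, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        for pos, i in enumerate(order):
            candidates = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
            q[i] = min(1.0, min(candidates))
        return q

    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("pvals,expected", [([0.049], [0.049]), ([1, 1, 1], [1, 1, 1])])
    def test_edge_cases(self, pvals, expected):
        assert np.allclose(bh_adjust(pvals), expected)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 51))
            assert np.allclose(bh_adjust(p), self.brute_force(p))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_properties(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)  # q >= p
        assert np.all((0 <= q) & (q <= 1))
        # order preservation: sorting by p sorts q
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestClassifyCisTrans:
    @pytest.mark.parametrize(
        "snp_chrom,pos,gene_chrom,tss,expected",
        [
            ("chr1", 0, "chr1", 1_000_000, "cis"),  # exactly 1 Mb, inclusive
            ("chr1", 0, "chr1", 1_000_001, "trans"),
            ("chr1", 0, "chr2", 10, "trans"),
            ("chr1", 500, "chr1", 400, "cis"),
        ],
    )
    def test_boundaries(self, snp_chrom, pos, gene_chrom, tss, expected):
        snp = Snp("rs1", snp_chrom, pos)
        gene = Gene("G1", "G1", gene_chrom, tss, tss + 100, strand="+")
        assert classify_cis_trans(snp, gene) == expected

    def test_tss_is_strand_aware(self):
        minus = Gene("G1", "G1", "chr1", 100, 200, strand="-")
        assert minus.tss == 199
        plus = Gene("G2", "G2", "chr1", 100, 200, strand="+")
        assert plus.tss == 100


class TestCallSpatialEqtls:
    def setup_scene(self):
        fmap = FragmentMap(tile("chr1", 10) + tile("chr2", 10))
        snps = [Snp("rs1", "chr1", 50)]
        genes = [Gene("G1", "G1", "chr2", 500, 580), Gene("G2", "G2", "chr1", 700, 780)]
        contacts = [
            Contact(fmap.locate("chr1", 50), fmap.locate("chr2", 550), frozenset({"lib"})),
        ]
        pairs = find_spatial_pairs(snps, genes, fmap, contacts)
        return fmap, snps, genes, pairs

    def table(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "gene_id", "tissue", "nes", "pval"])

    def test_bh_within_spatial_rows(self):
        _, snps, genes, pairs = self.setup_scene()
        tbl = self.table(
            [
                ("rs1", "G1", "t1", 0.5, 1e-6),
                ("rs1", "G1", "t2", 0.4, 1e-6),
                ("rs1", "G1", "t3", 0.1, 0.9),
            ]
        )
        records, report = call_spatial_eqtls(pairs, tbl, snps, genes)
        assert len(records) == 2
        assert {r.tissue for r in records} == {"t1", "t2"}
        assert all(r.regime == "trans" for r in records)
        assert report.n_spatial_rows == 3

    def test_non_spatial_row_excluded_regardless_of_p(self):
        _, snps, genes, pairs = self.setup_scene()
        tbl = self.table([("rs1", "G2", "t1", 0.5, 1e-10)])  # G2 not a spatial pair
        records, _ = call_spatial_eqtls(pairs, tbl, snps, genes)
        assert records == []

    def test_empty_pairs_empty_output(self):
        _, snps, genes, _ = self.setup_scene()
        tbl = self.table([("rs1", "G1", "t1", 0.5, 1e-10)])
        records, _ = call_spatial_eqtls([], tbl, snps, genes)
        assert records == []

    def test_unknown_ids_skipped_with_warning(self):
        _, snps, genes, pairs = self.setup_scene()
        tbl = self.table(
            [("rs1", "G1", "t1", 0.5, 1e-6), ("rs_unknown", "G1", "t1", 0.5, 1e-9)]
        )
        with pytest.warns(UserWarning, match="unknown"):
            records, report = call_spatial_eqtls(pairs, tbl, snps, genes)
        assert report.n_unknown_skipped == 1
        assert len(records) == 1

    def test_output_invariant_to_row_order(self):
        _, snps, genes, pairs = self.setup_scene()
        rows = [
            ("rs1", "G1", "t1", 0.5, 1e-6),
            ("rs1", "G1", "t2", 0.4, 2e-6),
            ("rs1", "G1", "t3", 0.1, 0.04),
        ]
        a, _ = call_spatial_eqtls(pairs, self.table(rows), snps, genes)
        b, _ = call_spatial_eqtls(pairs, self.table(rows[::-1]), snps, genes)
        assert [(r.snp_id, r.gene_id, r.tissue, r.qval) for r in a] == [
            (r.snp_id, r.gene_id, r.tissue, r.qval) for r in b
        ]

    def test_gating_monotonic_in_contact_set(self, small_config, small_reference,
                                             small_contacts, small_eqtls):
        ref = small_reference
        full_pairs = find_spatial_pairs(ref.snps, ref.genes, ref.fragments, small_contacts)
        full, _ = call_spatial_eqtls(full_pairs, small_eqtls, ref.snps, ref.genes)
        shrunk_pairs = find_spatial_pairs(
            ref.snps, ref.genes, ref.fragments, small_contacts[::2]
        )
        shrunk, _ = call_spatial_eqtls(shrunk_pairs, small_eqtls, ref.snps, ref.genes)
        full_keys = {(r.snp_id, r.gene_id, r.tissue) for r in full}
        shrunk_keys = {(r.snp_id, r.gene_id, r.tissue) for r in shrunk}
        assert shrunk_keys <= full_keys

    def test_gene_may_be_cis_and_trans_for_different_snps(self):
        fmap = FragmentMap(tile("chr1", 10) + tile("chr2", 10))
        snps = [Snp("rs_cis", "chr1", 50), Snp("rs_trans", "chr2", 50)]
        gene = Gene("G1", "G1", "chr1", 700, 780)
        contacts = [
            Contact(fmap.locate("chr1", 50), fmap.locate("chr1", 750), frozenset({"l"})),
            Contact(fmap.locate("chr2", 50), fmap.locate("chr1", 750), frozenset({"l"})),
        ]
        pairs = find_spatial_pairs(snps, [gene], fmap, contacts)
        tbl = pd.DataFrame(
            [("rs_cis", "G1", "t1", 0.5, 1e-6), ("rs_trans", "G1", "t1", 0.5, 1e-6)],
            columns=["snp_id", "gene_id", "tissue", "nes", "pval"],
        )
        records, _ = call_spatial_eqtls(pairs, tbl, snps, [gene])
        regimes = {r.snp_id: r.regime for r in records}
        assert regimes == {"rs_cis": "cis", "rs_trans": "trans"}
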