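"""Spatial eQTL calling through chromatin-contact fragment pairing.

A SNP and a gene form a *spatial pair* when the restriction fragment
carrying the SNP is observed in physical contact (Hi-C) with a fragment
overlapping the gene.  Contacts between a fragment and itself or its
immediate neighbours are uninformative — ligation of contiguous restriction
sites cannot be distinguished from an undigested site — so same-chromosome
contacts require a fragment-index separation of at least two.  A SNP lying
inside its target gene is only testable when the gene is long enough to be
covered by at least three restriction fragments, otherwise every contact to
the gene is a self/adjacent contact.

Spatial pairs are then intersected with a precomputed tissue-specific eQTL
association table; the surviving associations are corrected for multiple
testing with the Benjamini–Hochberg step-up procedure and classified
cis/trans by linear distance to the gene TSS.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Fragment",
    "Snp",
    "Gene",
    "Contact",
    "SpatialPair",
    "EqtlRecord",
    "FragmentMap",
    "UnmappedSnpError",
    "assign_snp_fragment",
    "gene_fragment_span",
    "find_spatial_pairs",
    "bh_adjust",
    "classify_cis_trans",
    "call_spatial_eqtls",
]

#: maximum SNP–TSS distance (bp) for a same-chromosome pair to count as cis
CIS_WINDOW = 1_000_000

#: minimum |fragment index difference| for an informative same-chromosome contact
MIN_FRAGMENT_SEPARATION = 2

#: minimum number of restriction fragments a gene must overlap for an
#: intragenic SNP-gene pair to be testable
MIN_INTRAGENIC_FRAGMENTS = 3


class UnmappedSnpError(ValueError):
    """Raised when a SNP position falls outside every restriction fragment."""


@dataclass(frozen=True)
class Fragment:
    """Restriction fragment: 0-based half-open interval with an ordinal index."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.chrom}:{self.start}-{self.end}: start >= end")


@dataclass(frozen=True)
class Snp:
    id: str
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "G"


@dataclass(frozen=True)
class Gene:
    """Gene interval; ``tss`` is the strand-aware transcription start site."""

    id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Contact:
    """Unordered fragment-fragment contact from one or more Hi-C libraries."""

    a: Fragment
    b: Fragment
    sources: frozenset[str] = frozenset({"hic"})

    @property
    def is_self(self) -> bool:
        return self.a.chrom == self.b.chrom and self.a.index == self.b.index


@dataclass(frozen=True)
class SpatialPair:
    snp_id: str
    gene_id: str
    supporting_sources: frozenset[str]
    intragenic: bool = False


@dataclass
class EqtlRecord:
    """One significant SNP-gene-tissue association surviving spatial + FDR filters."""

    snp_id: str
    gene_id: str
    tissue: str
    nes: float
    pval: float
    qval: float
    regime: str  # "cis" | "trans"


class FragmentMap:
    """Per-chromosome tiling of restriction fragments with O(log n) lookup."""

    def __init__(self, fragments: list[Fragment]):
        self._by_chrom: dict[str, list[Fragment]] = {}
        for frag in sorted(fragments, key=lambda f: (f.chrom, f.start)):
            self._by_chrom.setdefault(frag.chrom, []).append(frag)
        self._starts = {c: [f.start for f in fs] for c, fs in self._by_chrom.items()}

    @property
    def fragments(self) -> list[Fragment]:
        return [f for fs in self._by_chrom.values() for f in fs]

    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def locate(self, chrom: str, pos: int) -> Fragment | None:
        frags = self._by_chrom.get(chrom)
        if not frags:
            return None
        i = bisect_right(self._starts[chrom], pos) - 1
        if i < 0:
            return None
        frag = frags[i]
        return frag if frag.start <= pos < frag.end else None

    def overlapping(self, chrom: str, start: int, end: int) -> list[Fragment]:
        """Fragments intersecting the half-open interval [start, end)."""
        frags = self._by_chrom.get(chrom)
        if not frags:
            return []
        i = max(bisect_right(self._starts[chrom], start) - 1, 0)
        out = []
        for frag in frags[i:]:
            if frag.start >= end:
                break
            if frag.end > start:
                out.append(frag)
        return out


def assign_snp_fragment(snp: Snp, fragments: FragmentMap) -> Fragment:
    """Return the unique restriction fragment containing the SNP position."""
    frag = fragments.locate(snp.chrom, snp.pos)
    if frag is None:
        raise UnmappedSnpError(
            f"SNP {snp.id} at {snp.chrom}:{snp.pos} falls outside every fragment"
        )
    return frag


def gene_fragment_span(gene: Gene, fragments: FragmentMap) -> list[Fragment]:
    """Restriction fragments overlapping the gene body."""
    return fragments.overlapping(gene.chrom, gene.start, gene.end)


def _informative(f_snp: Fragment, f_gene: Fragment) -> bool:
    """Contact is informative unless self or immediately adjacent on one chromosome."""
    if f_snp.chrom != f_gene.chrom:
        return True
    return abs(f_gene.index - f_snp.index) >= MIN_FRAGMENT_SEPARATION


def find_spatial_pairs(
    snps: list[Snp],
    genes: list[Gene],
    fragments: FragmentMap,
    contacts: list[Contact],
) -> list[SpatialPair]:
    """Pair SNPs with genes through informative fragment-fragment contacts.

    A pair (snp, gene) is emitted when some contact links the SNP fragment to
    a fragment overlapping the gene, the contact is informative (different
    chromosomes, or fragment indices at least two apart), and — if the SNP
    lies inside the gene — the gene overlaps at least three fragments.
    Supporting Hi-C library labels are unioned over all contributing contacts.
    """
    # adjacency: fragment key -> {partner fragment key: source labels}
    neighbours: dict[tuple[str, int], dict[tuple[str, int], set[str]]] = {}
    frag_lookup: dict[tuple[str, int], Fragment] = {}
    for c in contacts:
        ka, kb = (c.a.chrom, c.a.index), (c.b.chrom, c.b.index)
        frag_lookup[ka], frag_lookup[kb] = c.a, c.b
        for k1, k2 in ((ka, kb), (kb, ka)):
            neighbours.setdefault(k1, {}).setdefault(k2, set()).update(c.sources)

    gene_frags = {g.id: gene_fragment_span(g, fragments) for g in genes}

    pairs: dict[tuple[str, str], SpatialPair] = {}
    for snp in snps:
        f_snp = assign_snp_fragment(snp, fragments)
        contacted = neighbours.get((f_snp.chrom, f_snp.index), {})
        if not contacted:
            continue
        for gene in genes:
            span = gene_frags[gene.id]
            intragenic = gene.contains(snp.chrom, snp.pos)
            if intragenic and len(span) < MIN_INTRAGENIC_FRAGMENTS:
                continue
            sources: set[str] = set()
            for f_gene in span:
                libs = contacted.get((f_gene.chrom, f_gene.index))
                if libs and _informative(f_snp, f_gene):
                    sources.update(libs)
            if sources:
                key = (snp.id, gene.id)
                if key in pairs:
                    sources |= pairs[key].supporting_sources
                pairs[key] = SpatialPair(snp.id, gene.id, frozenset(sources), intragenic)
    return [pairs[k] for k in sorted(pairs)]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, clipped at 1;
    ties share a q and input order is preserved.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def classify_cis_trans(snp: Snp, gene: Gene) -> str:
    """cis iff same chromosome and |pos - tss| <= 1 Mb (inclusive); else trans."""
    if snp.chrom == gene.chrom and abs(snp.pos - gene.tss) <= CIS_WINDOW:
        return "cis"
    return "trans"


@dataclass
class SpatialEqtlReport:
    """Counts at each filter stage of a spatial eQTL run."""

    n_eqtl_rows: int = 0
    n_unknown_skipped: int = 0
    n_spatial_rows: int = 0
    n_significant: int = 0
    pairs: int = 0
    notes: list[str] = field(default_factory=list)


def call_spatial_eqtls(
    pairs: list[SpatialPair],
    eqtl_table: pd.DataFrame,
    snps: list[Snp],
    genes: list[Gene],
    alpha: float = 0.05,
    per_tissue_fdr: bool = False,
) -> tuple[list[EqtlRecord], SpatialEqtlReport]:
    """Filter an eQTL table to spatially supported associations at FDR < alpha.

    The table needs columns ``snp_id, gene_id, tissue, nes, pval``.  Rows whose
    (snp, gene) is not a spatial pair are discarded regardless of p-value; BH
    correction is applied jointly across every retained row (pooled over
    tissues) unless ``per_tissue_fdr``.  Rows referencing unknown SNPs or
    genes are skipped and counted in the report.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    report = SpatialEqtlReport(n_eqtl_rows=len(eqtl_table), pairs=len(pairs))
    snp_by_id = {s.id: s for s in snps}
    gene_by_id = {g.id: g for g in genes}
    pair_keys = {(p.snp_id, p.gene_id) for p in pairs}

    known = eqtl_table["snp_id"].isin(snp_by_id) & eqtl_table["gene_id"].isin(gene_by_id)
    report.n_unknown_skipped = int((~known).sum())
    if report.n_unknown_skipped:
        warnings.warn(
            f"skipped {report.n_unknown_skipped} eQTL rows referencing unknown SNPs/genes",
            stacklevel=2,
        )
    df = eqtl_table.loc[known]
    spatial = df[[(r.snp_id, r.gene_id) in pair_keys for r in df.itertuples()]].copy()
    # canonical order so the output is invariant to input row order
    spatial = spatial.sort_values(["snp_id", "gene_id", "tissue"], kind="mergesort")
    report.n_spatial_rows = len(spatial)
    if spatial.empty:
        return [], report

    if per_tissue_fdr:
        spatial["qval"] = spatial.groupby("tissue")["pval"].transform(bh_adjust)
    else:
        spatial["qval"] = bh_adjust(spatial["pval"].to_numpy())

    records = [
        EqtlRecord(
            snp_id=row.snp_id,
            gene_id=row.gene_id,
            tissue=row.tissue,
            nes=float(row.nes),
            pval=float(row.pval),
            qval=float(row.qval),
            regime=classify_cis_trans(snp_by_id[row.snp_id], gene_by_id[row.gene_id]),
        )
        for row in spatial.itertuples()
        if row.qval < alpha
    ]
    report.n_significant = len(records)
    return records, report
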