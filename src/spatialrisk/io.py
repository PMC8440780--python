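"""Readers and writers for the pipeline's on-disk formats.

Conventions: internal coordinates are 0-based half-open; BED/BEDPE are
written 0-based half-open and VCF 1-based, per the respective format
specifications.  All writers are deterministic (fixed column order, fixed
float formatting) so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .qc import MISSING, GenotypeMatrix
from .spatial import Contact, Fragment, FragmentMap, Gene, Snp

EQTL_COLUMNS = ["snp_id", "gene_id", "tissue", "nes", "pval"]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_fragments_bed(fragments: FragmentMap, path) -> None:
    with open(path, "w") as fh:
        for frag in sorted(fragments.fragments, key=lambda f: (f.chrom, f.start)):
            name = f"frag_{frag.chrom}_{frag.index}"
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t{name}\t0\t+\n")


def read_fragments_bed(path) -> FragmentMap:
    frags: list[Fragment] = []
    counters: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            rows.append((chrom, int(start), int(end)))
    for chrom, start, end in sorted(rows):
        idx = counters.get(chrom, 0)
        counters[chrom] = idx + 1
        frags.append(Fragment(chrom, start, end, idx))
    return FragmentMap(frags)


def write_genes_bed(genes: list[Gene], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.id)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n")


def read_genes_bed(path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            genes.append(Gene(id=name, name=name, chrom=chrom, start=start, end=end, strand=strand))
    return genes


def write_contacts_bedpe(contacts: list[Contact], path) -> None:
    rows = []
    for c in contacts:
        a, b = c.a, c.b
        if (b.chrom, b.start) < (a.chrom, a.start):
            a, b = b, a
        rows.append(
            (a.chrom, a.start, a.end, b.chrom, b.start, b.end, ",".join(sorted(c.sources)))
        )
    with open(path, "w") as fh:
        for r in sorted(rows):
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_contacts_bedpe(path, fragments: FragmentMap) -> list[Contact]:
    """Map BEDPE anchor midpoints back onto the restriction-fragment grid."""
    merged: dict[tuple, set[str]] = {}
    frag_of: dict[tuple, Fragment] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            c1, s1, e1, c2, s2, e2 = parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4]), int(parts[5])
            sources = set(parts[6].split(",")) if len(parts) > 6 and parts[6] else {"hic"}
            fa = fragments.locate(c1, (s1 + e1) // 2)
            fb = fragments.locate(c2, (s2 + e2) // 2)
            if fa is None or fb is None:
                continue
            ka, kb = (fa.chrom, fa.index), (fb.chrom, fb.index)
            key = (min(ka, kb), max(ka, kb))
            frag_of[ka], frag_of[kb] = fa, fb
            merged.setdefault(key, set()).update(sources)
    return [
        Contact(frag_of[ka], frag_of[kb], frozenset(srcs))
        for (ka, kb), srcs in sorted(merged.items())
    ]


def write_snp_table(snps: list[Snp], path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tref\talt\n")
        for s in sorted(snps, key=lambda s: (s.chrom, s.pos, s.id)):
            fh.write(f"{s.id}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\n")


def read_snp_table(path) -> list[Snp]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        Snp(id=r.snp_id, chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt)
        for r in df.itertuples()
    ]


def write_eqtl_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=EQTL_COLUMNS, float_format="%.6g")


def read_eqtl_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, status in labels.items():
            fh.write(f"{sid}\t{status}\n")


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"], df["status"]))


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal bi-allelic VCFv4.2 (GT only, 1-based POS)."""
    meta = matrix.snp_meta or {}
    chroms = meta.get("chrom", ["chr1"] * matrix.n_snps)
    pos0 = meta.get("pos", list(range(matrix.n_snps)))
    ref = matrix.ref or ["A"] * matrix.n_snps
    alt = matrix.alt or ["G"] * matrix.n_snps
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(set(chroms)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        order = sorted(range(matrix.n_snps), key=lambda j: (chroms[j], pos0[j]))
        for j in order:
            gts = "\t".join(_GT_STRINGS[int(d)] for d in matrix.dosage[:, j])
            fh.write(
                f"{chroms[j]}\t{pos0[j] + 1}\t{matrix.snp_ids[j]}\t{ref[j]}\t{alt[j]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Load a bi-allelic VCF into a dosage matrix (alt-allele counts)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, pos0, refs, alts, cols = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"variant {var.ID} is not bi-allelic")
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        pos0.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        col = np.full(gt.shape, MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        cols.append(col)
    vcf.close()
    dosage = (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=samples,
        snp_ids=snp_ids,
        dosage=dosage,
        ref=refs,
        alt=alts,
        snp_meta={"chrom": chroms, "pos": pos0},
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
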