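"""Weighted genotype x eQTL feature matrix.

Each individual is represented by tissue-resolved burden features: for
every significant (SNP, gene, tissue) eQTL the feature value is the
individual's alt-allele dosage at the SNP multiplied by the eQTL's
normalized effect size (NES); candidate SNPs with no eQTL contribute their
bare dosage under the pseudo-tissue label "SNPs".  Only SNPs with complete
dosage data across the cohort enter the matrix.

Columns are deterministically ordered (sorted by key), and no per-column
standardisation is applied by default, so the regulariser of the
downstream logistic model sees NES-scaled features; ``standardize=True``
enables z-scoring for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .qc import MISSING, GenotypeMatrix
from .spatial import EqtlRecord

__all__ = ["FeatureKey", "FeatureMatrix", "build_feature_matrix", "drop_feature"]

#: pseudo-tissue grouping bare-dosage features of SNPs without eQTLs
SNP_PSEUDO_TISSUE = "SNPs"


@dataclass(frozen=True, order=True)
class FeatureKey:
    """Identity of one matrix column: an eQTL effect or a bare SNP dosage."""

    kind: str  # "eqtl" | "snp"
    snp_id: str
    gene_id: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("eqtl", "snp"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "eqtl" and not (self.gene_id and self.tissue):
            raise ValueError("eqtl features need gene_id and tissue")

    @property
    def group_tissue(self) -> str:
        """Tissue label used for contribution grouping."""
        return self.tissue if self.kind == "eqtl" else SNP_PSEUDO_TISSUE

    def __str__(self) -> str:
        if self.kind == "snp":
            return self.snp_id
        return f"{self.snp_id}|{self.gene_id}|{self.tissue}"

    @classmethod
    def parse(cls, text: str) -> "FeatureKey":
        parts = text.split("|")
        if len(parts) == 1:
            return cls(kind="snp", snp_id=parts[0])
        if len(parts) == 3:
            return cls(kind="eqtl", snp_id=parts[0], gene_id=parts[1], tissue=parts[2])
        raise ValueError(f"malformed feature key {text!r}")


@dataclass
class FeatureMatrix:
    """Individuals x features with case/control labels; no missing values."""

    sample_ids: list[str]
    keys: list[FeatureKey]
    values: np.ndarray  # float, (n_samples, n_features)
    labels: np.ndarray  # int, 1 = case, 0 = control

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.sample_ids), len(self.keys)):
            raise ValueError("value shape does not match sample/key lists")
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return len(self.keys)

    def tissues(self) -> list[str]:
        return sorted({k.group_tissue for k in self.keys})

    def column(self, key: FeatureKey) -> np.ndarray:
        return self.values[:, self.keys.index(key)]

    def restrict(self, keys: list[FeatureKey]) -> "FeatureMatrix":
        idx = [self.keys.index(k) for k in keys]
        return FeatureMatrix(self.sample_ids, list(keys), self.values[:, idx], self.labels)

    def to_tsv(self, path, sidecar_json=None) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tstatus\t" + "\t".join(str(k) for k in self.keys) + "\n")
            for i, sid in enumerate(self.sample_ids):
                status = "case" if self.labels[i] == 1 else "control"
                row = "\t".join(f"{v:.10g}" for v in self.values[i])
                fh.write(f"{sid}\t{status}\t{row}\n")
        if sidecar_json is not None:
            mapping = {
                str(k): {
                    "kind": k.kind,
                    "snp_id": k.snp_id,
                    "gene_id": k.gene_id,
                    "tissue": k.group_tissue,
                }
                for k in self.keys
            }
            with open(sidecar_json, "w") as fh:
                json.dump(mapping, fh, indent=2, sort_keys=True)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            keys = [FeatureKey.parse(h) for h in header[2:]]
            sample_ids, labels, rows = [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                sample_ids.append(parts[0])
                labels.append(1 if parts[1] == "case" else 0)
                rows.append([float(x) for x in parts[2:]])
        return cls(sample_ids, keys, np.array(rows, dtype=float), np.array(labels))


def build_feature_matrix(
    genotypes: GenotypeMatrix,
    eqtls: list[EqtlRecord],
    snp_ids: list[str],
    labels: dict[str, str],
    standardize: bool = False,
) -> FeatureMatrix:
    """Assemble the weighted dosage matrix from QC'd genotypes and eQTL calls.

    SNPs with any missing dosage across the cohort are dropped.  Each
    retained SNP with one or more eQTL records contributes one column per
    (SNP, gene, tissue) valued dosage x NES; each retained SNP without
    eQTLs contributes a single unweighted dosage column.
    """
    candidate = [s for s in snp_ids if s in set(genotypes.snp_ids)]
    col_of = {s: j for j, s in enumerate(genotypes.snp_ids)}
    complete = [
        s for s in candidate if not np.any(genotypes.dosage[:, col_of[s]] == MISSING)
    ]
    if not complete:
        raise ValueError("no candidate SNP has complete dosage data across the cohort")
    complete_set = set(complete)

    by_key: dict[FeatureKey, float] = {}
    for rec in eqtls:
        if rec.snp_id not in complete_set:
            continue
        key = FeatureKey(kind="eqtl", snp_id=rec.snp_id, gene_id=rec.gene_id, tissue=rec.tissue)
        if key in by_key:
            raise ValueError(f"duplicate eQTL feature {key}")
        by_key[key] = rec.nes

    eqtl_snps = {k.snp_id for k in by_key}
    for s in complete:
        if s not in eqtl_snps:
            by_key[FeatureKey(kind="snp", snp_id=s)] = 1.0

    keys = sorted(by_key)
    dosage = genotypes.dosage.astype(float)
    values = np.column_stack([dosage[:, col_of[k.snp_id]] * by_key[k] for k in keys])
    if standardize:
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=0)) / sd

    y = np.array([1 if labels[s] == "case" else 0 for s in genotypes.sample_ids])
    return FeatureMatrix(list(genotypes.sample_ids), keys, values, y)


def drop_feature(matrix: FeatureMatrix, key: FeatureKey) -> FeatureMatrix:
    """Matrix without the single named column; errors if the key is absent."""
    if key not in matrix.keys:
        raise KeyError(f"feature {key} not present in matrix")
    keep = [k for k in matrix.keys if k != key]
    idx = [matrix.keys.index(k) for k in keep]
    return FeatureMatrix(matrix.sample_ids, keep, matrix.values[:, idx], matrix.labels)
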