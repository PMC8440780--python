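"""Genotype quality control on a case/control dosage matrix.

Implements the standard PLINK-style cohort filters on bi-allelic dosages:

* per-sample method-of-moments inbreeding coefficient F (homozygosity
  outliers removed outside [-0.04, 0.025]);
* pairwise method-of-moments identity-by-descent, removing one member of
  every pair with PI_HAT > 0.08;
* per-SNP exact Hardy–Weinberg equilibrium test (p < 1e-6 removed),
  minor-allele-frequency (< 1%) and missingness (> 5%) filters;
* per-sample missingness (> 5%).

Sample filters run before SNP filters, and SNP statistics are recomputed on
the retained samples.  Every removal in the report cites exactly one rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GenotypeMatrix",
    "QcThresholds",
    "QcReport",
    "inbreeding_f",
    "pi_hat",
    "pi_hat_matrix",
    "hwe_exact",
    "apply_qc",
]

MISSING = -1  # sentinel dosage


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele dosage matrix (0/1/2, -1 = missing)."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray  # int8, shape (n_samples, n_snps)
    ref: list[str] | None = None
    alt: list[str] | None = None
    snp_meta: dict | None = None  # e.g. chrom/pos per SNP, passed through

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0/1/2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def observed(self) -> np.ndarray:
        return self.dosage != MISSING

    def alt_freq(self) -> np.ndarray:
        """Cohort alt-allele frequency per SNP over non-missing genotypes."""
        obs = self.observed()
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeMatrix":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        km = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        meta = None
        if self.snp_meta is not None:
            meta = {k: [v for v, keep in zip(vals, km) if keep] for k, vals in self.snp_meta.items()}
        return GenotypeMatrix(
            sample_ids=[s for s, keep in zip(self.sample_ids, sm) if keep],
            snp_ids=[s for s, keep in zip(self.snp_ids, km) if keep],
            dosage=self.dosage[np.ix_(sm, km)],
            ref=None if self.ref is None else [r for r, keep in zip(self.ref, km) if keep],
            alt=None if self.alt is None else [a for a, keep in zip(self.alt, km) if keep],
            snp_meta=meta,
        )


@dataclass
class QcThresholds:
    f_low: float = -0.04
    f_high: float = 0.025
    pihat: float = 0.08
    hwe_p: float = 1e-6
    maf: float = 0.01
    snp_missing: float = 0.05
    sample_missing: float = 0.05
    # method-of-moments F and IBD are meaningful only on genome-wide marker
    # sets: with m SNPs the null sampling noise of F is ~1/sqrt(m) and that
    # of PI_HAT several times larger, so below these marker counts the
    # homozygosity and relatedness filters would mostly flag noise and are
    # skipped (recorded in the report notes)
    f_min_snps: int = 10_000
    pihat_min_snps: int = 10_000


@dataclass
class QcReport:
    f_by_sample: dict[str, float] = field(default_factory=dict)
    pihat_flagged: list[tuple[str, str, float]] = field(default_factory=list)
    hwe_p_by_snp: dict[str, float] = field(default_factory=dict)
    maf_by_snp: dict[str, float] = field(default_factory=dict)
    missing_by_snp: dict[str, float] = field(default_factory=dict)
    removed_samples: dict[str, str] = field(default_factory=dict)  # id -> rule
    removed_snps: dict[str, str] = field(default_factory=dict)  # id -> rule
    # hooks for filters that need external resources (reference panels, sex
    # chromosomes) and are therefore not computed here
    ancestry_outliers: list[str] = field(default_factory=list)
    sex_check_failures: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_samples": self.removed_samples,
            "removed_snps": self.removed_snps,
            "f_by_sample": self.f_by_sample,
            "pihat_flagged": [list(t) for t in self.pihat_flagged],
            "hwe_p_by_snp": self.hwe_p_by_snp,
            "maf_by_snp": self.maf_by_snp,
            "missing_by_snp": self.missing_by_snp,
        }


def inbreeding_f(matrix: GenotypeMatrix, sample: str) -> float:
    """Method-of-moments inbreeding coefficient for one sample.

    F = (O_hom - E_hom) / (N - E_hom), with E_hom summed over the sample's
    non-missing polymorphic SNPs using the finite-sample-corrected expected
    heterozygosity 2 p q n/(n-1) at cohort alt frequency p and non-missing
    allele count n.  Returns NaN when N == E_hom (degenerate).
    """
    i = matrix.sample_ids.index(sample)
    row = matrix.dosage[i]
    obs_all = matrix.observed()
    p = matrix.alt_freq()
    n_alleles = 2 * obs_all.sum(axis=0)
    usable = (row != MISSING) & (p > 0) & (p < 1) & (n_alleles > 2)
    if not usable.any():
        raise ValueError(f"sample {sample}: no usable polymorphic SNPs for F")
    n = n_alleles[usable].astype(float)
    pj = p[usable]
    e_het = 2.0 * pj * (1.0 - pj) * n / (n - 1.0)
    e_hom = float(np.sum(1.0 - e_het))
    n_snps = int(usable.sum())
    o_hom = int(np.sum(row[usable] != 1))
    denom = n_snps - e_hom
    if abs(denom) < 1e-12:
        return float("nan")
    return (o_hom - e_hom) / denom


def _ibs_expectations(p: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP P(IBS = s | IBD = z) under HWE at alt frequency p."""
    q = 1.0 - p
    e0_ibd0 = 2.0 * p**2 * q**2
    e1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e2_ibd0 = 1.0 - e0_ibd0 - e1_ibd0
    e1_ibd1 = 2.0 * p * q
    e2_ibd1 = 1.0 - e1_ibd1
    return e0_ibd0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1


def _pi_hat_from_counts(n0, n1, n2, s0, s1_0, s2_0, s1_1, s2_1, m):
    """Method-of-moments IBD estimate from IBS counts and expectation sums."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(s0 > 0, n0 / np.where(s0 > 0, s0, 1.0), 0.0)
        p1 = np.where(s1_1 > 0, (n1 - p0 * s1_0) / np.where(s1_1 > 0, s1_1, 1.0), 0.0)
        p2 = (n2 - p0 * s2_0 - p1 * s2_1) / np.maximum(m, 1)
    p0, p1, p2 = (np.clip(x, 0.0, 1.0) for x in (p0, p1, p2))
    total = p0 + p1 + p2
    total = np.where(total > 0, total, 1.0)
    p1, p2 = p1 / total, p2 / total
    return p2 + 0.5 * p1


def pi_hat(
    matrix: GenotypeMatrix, sample_a: str, sample_b: str, min_overlap: int = 50
) -> float:
    """Estimated proportion of the genome shared IBD between two samples."""
    ia, ib = matrix.sample_ids.index(sample_a), matrix.sample_ids.index(sample_b)
    ga, gb = matrix.dosage[ia], matrix.dosage[ib]
    p = matrix.alt_freq()
    both = (ga != MISSING) & (gb != MISSING) & (p > 0) & (p < 1)
    m = int(both.sum())
    if m < min_overlap:
        raise ValueError(
            f"pair ({sample_a}, {sample_b}): only {m} informative SNPs (< {min_overlap})"
        )
    diff = np.abs(ga[both].astype(int) - gb[both].astype(int))
    n0 = int(np.sum(diff == 2))
    n2 = int(np.sum(diff == 0))
    n1 = m - n0 - n2
    e0_0, e1_0, e2_0, e1_1, e2_1 = _ibs_expectations(p[both])
    return float(
        _pi_hat_from_counts(
            n0, n1, n2, e0_0.sum(), e1_0.sum(), e2_0.sum(), e1_1.sum(), e2_1.sum(), m
        )
    )


def pi_hat_matrix(matrix: GenotypeMatrix, min_overlap: int = 50) -> np.ndarray:
    """All-pairs PI_HAT, vectorised via IBS-class indicator products.

    Entries for pairs with fewer than ``min_overlap`` jointly observed
    informative SNPs are NaN.  The result is symmetric with NaN diagonal.
    """
    p = matrix.alt_freq()
    informative = (p > 0) & (p < 1)
    d = matrix.dosage[:, informative].astype(np.float32)
    obs = (d != MISSING).astype(np.float32)
    d = np.where(d == MISSING, 0.0, d)

    ind = [((d == g) * obs).astype(np.float32) for g in (0.0, 1.0, 2.0)]
    m = obs @ obs.T
    # IBS2: same genotype in both; IBS0: opposite homozygotes
    n2 = sum(a @ a.T for a in ind)
    n0 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    n1 = m - n0 - n2

    e0_0, e1_0, e2_0, e1_1, e2_1 = _ibs_expectations(p[informative].astype(np.float32))
    s0 = obs @ (obs * e0_0).T
    s1_0 = obs @ (obs * e1_0).T
    s2_0 = obs @ (obs * e2_0).T
    s1_1 = obs @ (obs * e1_1).T
    s2_1 = obs @ (obs * e2_1).T

    out = _pi_hat_from_counts(n0, n1, n2, s0, s1_0, s2_0, s1_1, s2_1, m)
    out = np.asarray(out, dtype=float)
    out[m < min_overlap] = np.nan
    np.fill_diagonal(out, np.nan)
    return out


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts h compatible with them, the probabilities of tables no more likely
    than the observed one.  Monomorphic SNPs return 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("empty genotype table")
    n_alt = n_ab + 2 * n_bb
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    h_obs = n_ab
    h_min = n_alt % 2
    h_max = min(n_alt, 2 * n - n_alt)
    hs = np.arange(h_min, h_max + 1, 2)
    # log P(h) up to a common constant: 2^h * n! / (naa! h! nbb!)
    nbb = (n_alt - hs) // 2
    naa = n - nbb - hs
    logp = hs * np.log(2.0) - gammaln(naa + 1) - gammaln(hs + 1) - gammaln(nbb + 1)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[(h_obs - h_min) // 2]
    # tolerance guards against ties lost to floating point
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def apply_qc(
    matrix: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full sample-then-SNP filter cascade.

    Sample rules fire in order missingness -> F -> PI_HAT; each removed
    sample cites the first rule it violated.  SNP statistics (missingness,
    MAF, HWE) are recomputed on the retained samples.  Raises if every
    sample is removed.
    """
    th = thresholds or QcThresholds()
    report = QcReport()
    n_samples = matrix.n_samples

    obs = matrix.observed()
    sample_miss = 1.0 - obs.mean(axis=1)
    keep_sample = np.ones(n_samples, dtype=bool)
    for i, sid in enumerate(matrix.sample_ids):
        if sample_miss[i] > th.sample_missing:
            keep_sample[i] = False
            report.removed_samples[sid] = "sample_missingness"

    freq0 = matrix.alt_freq()
    n_informative = int(np.sum((freq0 > 0) & (freq0 < 1)))

    if n_informative >= th.f_min_snps:
        for i, sid in enumerate(matrix.sample_ids):
            if not keep_sample[i]:
                continue
            try:
                f = inbreeding_f(matrix, sid)
            except ValueError:
                continue
            report.f_by_sample[sid] = f
            if np.isnan(f):
                continue  # undefined F: excluded from this filter
            if not (th.f_low <= f <= th.f_high):
                keep_sample[i] = False
                report.removed_samples[sid] = "inbreeding_f"
    else:
        report.notes.append(
            f"homozygosity filter skipped: {n_informative} informative SNPs "
            f"< f_min_snps={th.f_min_snps}"
        )

    # relatedness on samples still standing
    standing = np.flatnonzero(keep_sample)
    if standing.size >= 2 and n_informative >= th.pihat_min_snps:
        sub = matrix.subset(sample_mask=keep_sample)
        ph = pi_hat_matrix(sub)
        miss = 1.0 - sub.observed().mean(axis=1)
        flagged = np.argwhere(np.triu(ph > th.pihat, k=1))
        for a, b in flagged:
            report.pihat_flagged.append((sub.sample_ids[a], sub.sample_ids[b], float(ph[a, b])))
        # greedy removal: higher missingness first, ties by lexicographic id
        for a, b in flagged:
            ia, ib = standing[a], standing[b]
            if not (keep_sample[ia] and keep_sample[ib]):
                continue
            if (miss[a], sub.sample_ids[a]) >= (miss[b], sub.sample_ids[b]):
                drop = ia
            else:
                drop = ib
            keep_sample[drop] = False
            report.removed_samples[matrix.sample_ids[drop]] = "pi_hat"
    elif standing.size >= 2:
        report.notes.append(
            f"relatedness filter skipped: {n_informative} informative SNPs "
            f"< pihat_min_snps={th.pihat_min_snps}"
        )

    if not keep_sample.any():
        raise RuntimeError(f"QC removed every sample; report: {report.to_dict()}")

    trimmed = matrix.subset(sample_mask=keep_sample)

    # SNP filters on recomputed frequencies
    obs = trimmed.observed()
    snp_miss = 1.0 - obs.mean(axis=0)
    freq = trimmed.alt_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep_snp = np.ones(trimmed.n_snps, dtype=bool)
    for j, sid in enumerate(trimmed.snp_ids):
        report.missing_by_snp[sid] = float(snp_miss[j])
        report.maf_by_snp[sid] = float(maf[j]) if np.isfinite(maf[j]) else 0.0
        if snp_miss[j] > th.snp_missing:
            keep_snp[j] = False
            report.removed_snps[sid] = "missingness"
            continue
        if not np.isfinite(maf[j]) or maf[j] < th.maf:
            keep_snp[j] = False
            report.removed_snps[sid] = "maf"
            continue
        col = trimmed.dosage[:, j]
        col = col[col != MISSING]
        p_hwe = hwe_exact(int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2)))
        report.hwe_p_by_snp[sid] = p_hwe
        if p_hwe < th.hwe_p:
            keep_snp[j] = False
            report.removed_snps[sid] = "hwe"

    return trimmed.subset(snp_mask=keep_snp), report
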