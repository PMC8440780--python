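"""Synthetic cohorts with a planted tissue-specific regulatory risk signal.

Every input the pipeline consumes is generated here: a restriction-fragment
tiling of a small diploid genome, gene annotations spanning a configurable
number of fragments, Hi-C style fragment-fragment contacts, a GTEx-style
tissue-specific eQTL association table, and case/control genotypes drawn
from Hardy–Weinberg equilibrium whose disease labels follow a logistic
model over eQTL-weighted dosages.

The disease architecture is *planted*: a small set of (SNP, gene, tissue)
eQTL features, all in one designated tissue, carry the entire log-odds
mass, split evenly.  On the dosage scale each planted feature contributes
``b_f = planted_effect_total / n_planted_features`` (random sign) to the
linear predictor, so the latent-liability standard deviation — and with it
the achievable AUC — is controlled by ``planted_effect_total`` alone.  The
true feature-scale coefficients (what a regression on dosage x NES features
should recover) are ``b_f / nes_f`` and are recorded in :class:`SimTruth`
for parameter-recovery tests.

Deliberately absent from the generative model: linkage disequilibrium,
population structure, imputation noise and Hi-C read-level noise — SNPs are
unlinked and genotypes exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import MISSING, GenotypeMatrix
from .spatial import Contact, Fragment, FragmentMap, Gene, Snp

__all__ = [
    "SimConfig",
    "SimTruth",
    "Reference",
    "Cohort",
    "generate_reference",
    "generate_contacts",
    "generate_eqtl_table",
    "generate_cohort",
    "simulate_all",
]

_LIBRARIES = ("GM12878", "IMR90", "primary_tissue")


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults emulate a reduced WTCCC-like case/control cohort: ~2,000
    genotyped individuals, a few hundred candidate SNPs, tissue-specific
    eQTL effects with a single disease-relevant tissue.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.1, 0.45)
    n_tissues: int = 10
    n_genes: int = 60
    planted_tissue: str = "tissue_0"
    planted_effect_total: float = 3.0
    baseline_logit: float = 0.0
    fragment_length: int = 1000
    contact_density: float = 2.0
    missing_rate: float = 0.02
    seed: int = 0
    # secondary knobs
    n_chromosomes: int = 2
    # explicit per-chromosome length in bp; None = sized automatically to
    # hold the requested genes and SNPs
    chrom_length: int | None = None
    n_planted_features: int = 3
    gene_fragment_spans: tuple[int, ...] = (2, 4)
    nes_sd: float = 0.5
    planted_pval: float = 1e-8
    eqtl_snp_fraction: float = 0.6
    max_tissues_per_pair: int = 3
    core_fraction: float = 0.8
    intragenic_snp_fraction: float = 0.25
    # fraction of null eQTL rows that are eQTL-significant (tiny p) while
    # carrying no disease effect — real expression QTLs need not be risk
    # QTLs; raising this populates the feature matrix with many tissues
    null_significant_fraction: float = 0.0
    # optional multi-tissue planting: ((tissue, share_of_total_effect), ...);
    # each listed tissue receives n_planted_features features carrying
    # share * planted_effect_total. None = everything on planted_tissue.
    planted_tissue_shares: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_snps", "n_genes",
                     "fragment_length", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_tissues < 0:
            raise ValueError("n_tissues must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high < 0.5")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.planted_effect_total < 0:
            raise ValueError("planted_effect_total must be non-negative")
        if self.n_tissues > 0 and self.planted_tissue not in self.tissues:
            raise ValueError(f"planted_tissue {self.planted_tissue!r} not in tissue set")
        for tissue, share in self.planted_allocation:
            if self.n_tissues > 0 and tissue not in self.tissues:
                raise ValueError(f"planted tissue {tissue!r} not in tissue set")
            if share < 0:
                raise ValueError("planted tissue shares must be non-negative")
        if len(self.planted_allocation) * self.n_planted_features > self.n_snps:
            raise ValueError("more planted features than SNPs")
        if not 0 <= self.null_significant_fraction <= 1:
            raise ValueError("null_significant_fraction must lie in [0, 1]")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue_{i}" for i in range(self.n_tissues)]

    @property
    def planted_allocation(self) -> tuple[tuple[str, float], ...]:
        if self.planted_tissue_shares is not None:
            return self.planted_tissue_shares
        return ((self.planted_tissue, 1.0),)


@dataclass
class SimTruth:
    """Ground truth of the planted architecture, for recovery tests."""

    # feature key string "snp|gene|tissue" -> coefficient on the weighted
    # (dosage x NES) feature scale; zero for every unplanted feature
    coefficients: dict[str, float]
    # same keys -> per-allele (dosage-scale) log-odds effect b_f = coef * nes
    dosage_effects: dict[str, float]
    # per-tissue sum of |dosage-scale effect|
    tissue_effect_mass: dict[str, float]
    prevalence: float
    baseline_logit: float

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "dosage_effects": self.dosage_effects,
            "tissue_effect_mass": self.tissue_effect_mass,
            "prevalence": self.prevalence,
            "baseline_logit": self.baseline_logit,
        }


@dataclass
class Reference:
    fragments: FragmentMap
    genes: list[Gene]
    snps: list[Snp]
    snp_maf: dict[str, float]
    planted_features: list[tuple[str, str, str]]  # (snp_id, gene_id, tissue)
    chrom_lengths: dict[str, int]

    @property
    def planted_pairs(self) -> list[tuple[str, str]]:
        return [(s, g) for s, g, _ in self.planted_features]


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    labels: dict[str, str]  # sample_id -> "case" | "control"
    truth: SimTruth

    def label_array(self) -> np.ndarray:
        return np.array([1 if self.labels[s] == "case" else 0 for s in self.genotypes.sample_ids])


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stage)))


def generate_reference(config: SimConfig) -> Reference:
    """Fragment tiling, gene annotation, SNP placement and planted pairs.

    Fragments tile each chromosome contiguously (0-based half-open).  Genes
    are laid out left to right with one-fragment gaps; spans cycle through
    ``gene_fragment_spans`` so both short (< 3 fragments) and long (>= 3)
    genes always exist.  A configurable fraction of SNPs is placed inside
    gene bodies, the rest in intergenic fragments.  Planted (SNP, gene)
    pairs link an intergenic SNP to a gene on another chromosome (or a
    distal one when only one chromosome is requested).
    """
    rng = _stage_rng(config, 0)
    spans = list(config.gene_fragment_spans)
    max_span = max(spans)
    genes_per_chrom = -(-config.n_genes // config.n_chromosomes)
    snps_per_chrom = -(-config.n_snps // config.n_chromosomes)
    if config.chrom_length is not None:
        frags_per_chrom = config.chrom_length // config.fragment_length
        if frags_per_chrom < 1:
            raise ValueError("chromosome shorter than one fragment")
    else:
        frags_per_chrom = max(20, genes_per_chrom * (max_span + 1) + snps_per_chrom + 5)
    chrom_lengths = {
        f"chr{i + 1}": frags_per_chrom * config.fragment_length
        for i in range(config.n_chromosomes)
    }
    if max_span * config.fragment_length > min(chrom_lengths.values()):
        raise ValueError("gene span exceeds chromosome length")

    fragments = [
        Fragment(chrom, i * config.fragment_length, (i + 1) * config.fragment_length, i)
        for chrom in chrom_lengths
        for i in range(frags_per_chrom)
    ]
    fmap = FragmentMap(fragments)

    genes: list[Gene] = []
    cursors = {c: 0 for c in chrom_lengths}
    chrom_names = list(chrom_lengths)
    for g in range(config.n_genes):
        chrom = chrom_names[g % config.n_chromosomes]
        span = spans[(g // config.n_chromosomes) % len(spans)]
        first = cursors[chrom]
        if first + span > frags_per_chrom:
            raise ValueError("ran out of fragments while placing genes")
        cursors[chrom] = first + span + 1
        fl = config.fragment_length
        start = first * fl + fl // 2
        end = (first + span - 1) * fl + fl // 2 + (fl // 4 if span == 1 else 0)
        strand = "+" if rng.uniform() < 0.5 else "-"
        gid = f"GENE{g:04d}"
        genes.append(Gene(id=gid, name=gid, chrom=chrom, start=start, end=end, strand=strand))

    snps: list[Snp] = []
    snp_maf: dict[str, float] = {}
    bases = np.array(list("ACGT"))
    for s in range(config.n_snps):
        sid = f"rs{100000 + s}"
        if genes and rng.uniform() < config.intragenic_snp_fraction:
            gene = genes[int(rng.integers(len(genes)))]
            pos = int(rng.integers(gene.start, gene.end))
            chrom = gene.chrom
        else:
            chrom = chrom_names[int(rng.integers(config.n_chromosomes))]
            pos = int(rng.integers(0, chrom_lengths[chrom]))
        ref, alt = rng.choice(bases, size=2, replace=False)
        snps.append(Snp(id=sid, chrom=chrom, pos=pos, ref=str(ref), alt=str(alt)))
        snp_maf[sid] = float(rng.uniform(*config.maf_range))

    # planted pairs: intergenic SNPs paired with genes guaranteed to pass the
    # adjacency and intragenic spatial rules; common alleles so the planted
    # dosage variance is healthy
    intergenic = [
        s for s in snps if not any(g.contains(s.chrom, s.pos) for g in genes)
    ]
    n_planted = len(config.planted_allocation) * config.n_planted_features
    if len(intergenic) < n_planted:
        intergenic = snps  # degenerate tiny configs
    chosen = rng.choice(len(intergenic), size=n_planted, replace=False)
    lo, hi = config.maf_range
    planted_features: list[tuple[str, str, str]] = []
    for slot, idx in enumerate(chosen):
        tissue = config.planted_allocation[slot // config.n_planted_features][0]
        snp = intergenic[int(idx)]
        snp_maf[snp.id] = float(rng.uniform((lo + hi) / 2, hi))
        candidates = [
            g
            for g in genes
            if g.chrom != snp.chrom
            or abs(fmap.locate(g.chrom, g.start).index - fmap.locate(snp.chrom, snp.pos).index) >= 2
        ]
        gene = candidates[int(rng.integers(len(candidates)))]
        planted_features.append((snp.id, gene.id, tissue))

    return Reference(
        fragments=fmap,
        genes=genes,
        snps=snps,
        snp_maf=snp_maf,
        planted_features=planted_features,
        chrom_lengths=chrom_lengths,
    )


def generate_contacts(reference: Reference, config: SimConfig) -> list[Contact]:
    """Hi-C style contact set over the fragment grid.

    Per SNP a Poisson(``contact_density``) number of random partner
    fragments is drawn.  On top of that the set guarantees, by
    construction: a contact for every planted (SNP, gene) pair, plus — for
    the first SNP — a distal same-chromosome gene contact, a
    different-chromosome gene contact, an adjacent-fragment contact and a
    self contact, so every spatial-rule configuration is represented.
    Unordered duplicates are merged, unioning their library labels.
    """
    rng = _stage_rng(config, 1)
    fmap = reference.fragments
    all_frags = fmap.fragments
    merged: dict[tuple, set[str]] = {}
    frag_of = {(f.chrom, f.index): f for f in all_frags}

    def add(fa: Fragment, fb: Fragment, source: str) -> None:
        ka, kb = (fa.chrom, fa.index), (fb.chrom, fb.index)
        key = (min(ka, kb), max(ka, kb))
        merged.setdefault(key, set()).add(source)

    # random component
    for snp in reference.snps:
        fs = fmap.locate(snp.chrom, snp.pos)
        k = rng.poisson(config.contact_density)
        for _ in range(k):
            fb = all_frags[int(rng.integers(len(all_frags)))]
            add(fs, fb, str(rng.choice(_LIBRARIES)))

    # guaranteed planted-pair contacts
    for snp_id, gene_id in reference.planted_pairs:
        snp = next(s for s in reference.snps if s.id == snp_id)
        gene = next(g for g in reference.genes if g.id == gene_id)
        fs = fmap.locate(snp.chrom, snp.pos)
        gene_frags = fmap.overlapping(gene.chrom, gene.start, gene.end)
        informative = [
            f
            for f in gene_frags
            if f.chrom != fs.chrom or abs(f.index - fs.index) >= 2
        ]
        add(fs, informative[0], "planted")

    # representative geometric configurations, anchored at the first SNP
    snp0 = reference.snps[0]
    f0 = fmap.locate(snp0.chrom, snp0.pos)
    same = [g for g in reference.genes if g.chrom == snp0.chrom]
    other = [g for g in reference.genes if g.chrom != snp0.chrom]
    distal = [
        f
        for g in same
        for f in fmap.overlapping(g.chrom, g.start, g.end)
        if abs(f.index - f0.index) >= 2
    ]
    if distal:
        add(f0, distal[0], "construct")
    if other:
        g = other[0]
        add(f0, fmap.overlapping(g.chrom, g.start, g.end)[0], "construct")
    chrom_frags = [f for f in all_frags if f.chrom == f0.chrom]
    adjacent = [f for f in chrom_frags if abs(f.index - f0.index) == 1]
    if adjacent:
        add(f0, adjacent[0], "construct")
    add(f0, f0, "construct")  # self contact, flagged by Contact.is_self

    return [
        Contact(frag_of[ka], frag_of[kb], frozenset(srcs))
        for (ka, kb), srcs in sorted(merged.items())
    ]


def generate_eqtl_table(reference: Reference, config: SimConfig) -> pd.DataFrame:
    """GTEx-style association table: one row per (SNP, gene, tissue).

    Planted rows sit in the planted tissue with p = ``planted_pval`` and a
    normalized effect size resampled from Normal(0, nes_sd) until
    |NES| >= 0.2 (a vanishing NES would make the planted feature invisible
    on the weighted-dosage scale).  Null rows pair random SNPs with random
    genes and tissues, NES ~ Normal(0, nes_sd), p ~ Uniform(0, 1).
    """
    rng = _stage_rng(config, 2)
    if config.n_tissues == 0:
        return pd.DataFrame(columns=["snp_id", "gene_id", "tissue", "nes", "pval"])
    snp_ids = {s.id for s in reference.snps}
    gene_ids = {g.id for g in reference.genes}
    rows = []
    for snp_id, gene_id, tissue in reference.planted_features:
        if snp_id not in snp_ids or gene_id not in gene_ids:
            raise ValueError(f"planted feature ({snp_id}, {gene_id}) references unknown ids")
        nes = 0.0
        while abs(nes) < 0.2:
            nes = float(rng.normal(0.0, config.nes_sd))
        rows.append((snp_id, gene_id, tissue, nes, config.planted_pval))

    planted_keys = {(s, g) for s, g in reference.planted_pairs}
    tissues = config.tissues
    for snp in reference.snps:
        if rng.uniform() > config.eqtl_snp_fraction:
            continue
        n_genes = int(rng.integers(1, 3))
        for _ in range(n_genes):
            gene = reference.genes[int(rng.integers(len(reference.genes)))]
            if (snp.id, gene.id) in planted_keys:
                continue
            n_t = int(rng.integers(1, config.max_tissues_per_pair + 1))
            for tissue in rng.choice(tissues, size=min(n_t, len(tissues)), replace=False):
                if rng.uniform() < config.null_significant_fraction:
                    pval = float(rng.uniform(0.0, config.planted_pval))
                else:
                    pval = float(rng.uniform())
                rows.append(
                    (
                        snp.id,
                        gene.id,
                        str(tissue),
                        float(rng.normal(0.0, config.nes_sd)),
                        pval,
                    )
                )
    df = pd.DataFrame(rows, columns=["snp_id", "gene_id", "tissue", "nes", "pval"])
    return df.drop_duplicates(subset=["snp_id", "gene_id", "tissue"], keep="first").reset_index(
        drop=True
    )


def _feature_key(snp_id: str, gene_id: str, tissue: str) -> str:
    return f"{snp_id}|{gene_id}|{tissue}"


def generate_cohort(
    reference: Reference, eqtl_table: pd.DataFrame, config: SimConfig
) -> Cohort:
    """Case/control genotypes under HWE with logistic labels.

    Individuals are drawn one batch at a time — genotype per SNP is
    Binomial(2, MAF), the case label Bernoulli(sigmoid(baseline +
    sum_f b_f * dosage_f)) — and accepted into the case or control arm
    until both quotas are met, which preserves the generative model while
    hitting the requested arm sizes exactly.  Missing genotypes are then
    injected at ``missing_rate`` into non-core SNPs only; planted SNPs and
    a ``core_fraction`` of the rest stay complete, exercising the
    complete-SNPs-only rule downstream without emptying the matrix.
    """
    rng = _stage_rng(config, 3)
    snps = reference.snps
    mafs = np.array([reference.snp_maf[s.id] for s in snps])
    snp_index = {s.id: j for j, s in enumerate(snps)}

    # planted effects: per tissue, equal |b| split of that tissue's share,
    # random signs
    planted_set = set(reference.planted_features)
    nes_of = {
        (r.snp_id, r.gene_id, r.tissue): float(r.nes) for r in eqtl_table.itertuples()
    } if len(eqtl_table) else {}
    shares = dict(config.planted_allocation)
    per_tissue_counts: dict[str, int] = {}
    for _, _, tissue in reference.planted_features:
        per_tissue_counts[tissue] = per_tissue_counts.get(tissue, 0) + 1
    coefficients: dict[str, float] = {}
    dosage_effects: dict[str, float] = {}
    b_vec = np.zeros(len(snps))
    if config.planted_effect_total > 0:
        for snp_id, gene_id, tissue in reference.planted_features:
            nes = nes_of.get((snp_id, gene_id, tissue))
            if nes is None:
                continue  # tissue-less configs
            b_mag = (
                config.planted_effect_total
                * shares.get(tissue, 0.0)
                / per_tissue_counts[tissue]
            )
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            b = sign * b_mag
            key = _feature_key(snp_id, gene_id, tissue)
            dosage_effects[key] = b
            coefficients[key] = b / nes
            b_vec[snp_index[snp_id]] += b
    tissue_mass = {t: 0.0 for t in config.tissues}
    for key, b in dosage_effects.items():
        tissue_mass[key.split("|")[2]] += abs(b)

    n_total = config.n_cases + config.n_controls
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    batch = max(256, n_total)
    attempts = 0
    n_case_draws = 0
    n_draws = 0
    while len(case_rows) < config.n_cases or len(control_rows) < config.n_controls:
        attempts += 1
        if attempts > 200:
            raise RuntimeError("label rejection sampling failed to fill arm quotas")
        geno = rng.binomial(2, mafs, size=(batch, len(snps))).astype(np.int8)
        logit = config.baseline_logit + geno @ b_vec
        is_case = rng.uniform(size=batch) < 1.0 / (1.0 + np.exp(-logit))
        n_draws += batch
        n_case_draws += int(is_case.sum())
        for i in range(batch):
            if is_case[i] and len(case_rows) < config.n_cases:
                case_rows.append(geno[i])
            elif not is_case[i] and len(control_rows) < config.n_controls:
                control_rows.append(geno[i])

    dosage = np.vstack(case_rows + control_rows)
    sample_ids = [f"S{i:06d}" for i in range(n_total)]
    labels = {
        sid: ("case" if i < config.n_cases else "control")
        for i, sid in enumerate(sample_ids)
    }

    # missingness on non-core SNPs only
    planted_snp_idx = {snp_index[s] for s, _ in reference.planted_pairs}
    non_planted = [j for j in range(len(snps)) if j not in planted_snp_idx]
    n_core_extra = int(round(config.core_fraction * len(non_planted)))
    core_extra = set(
        int(j) for j in rng.choice(non_planted, size=n_core_extra, replace=False)
    ) if non_planted else set()
    core = planted_snp_idx | core_extra
    if config.missing_rate > 0:
        for j in range(len(snps)):
            if j in core:
                continue
            mask = rng.uniform(size=n_total) < config.missing_rate
            dosage[mask, j] = MISSING

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=[s.id for s in snps],
        dosage=dosage,
        ref=[s.ref for s in snps],
        alt=[s.alt for s in snps],
        snp_meta={"chrom": [s.chrom for s in snps], "pos": [s.pos for s in snps]},
    )
    truth = SimTruth(
        coefficients=coefficients,
        dosage_effects=dosage_effects,
        tissue_effect_mass=tissue_mass,
        prevalence=n_case_draws / n_draws,
        baseline_logit=config.baseline_logit,
    )
    return Cohort(genotypes=matrix, labels=labels, truth=truth)


def simulate_all(config: SimConfig):
    """Convenience wrapper running every generator stage in order."""
    reference = generate_reference(config)
    contacts = generate_contacts(reference, config)
    eqtls = generate_eqtl_table(reference, config)
    cohort = generate_cohort(reference, eqtls, config)
    return reference, contacts, eqtls, cohort
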