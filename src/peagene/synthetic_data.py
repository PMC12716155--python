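"""Genotype-phenotype simulator with known ground truth.

Emulates a targeted-gene SNP panel in pea: ~100 accessions, ~55 genes over
seven chromosomes (storage proteins and starch-pathway enzymes), thousands
of biallelic SNPs in gene bodies and flanking windows, missing calls,
Balding-Nichols-style subpopulation structure, additive gene effects on
protein and starch content, and seed-morphology traits linked to starch via
a latent-threshold model. Every draw flows from ``SimulationConfig.seed``,
so a fixed configuration reproduces bit-identical datasets and files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import trait_stats
from .trait_stats import TraitTable
from .variant_io import (
    FLANKING,
    GeneMap,
    GenotypeMatrix,
    STARCH_ENZYME,
    STORAGE_PROTEIN,
    VariantRecord,
    read_vcf,
)

PROTEIN = "protein_pct"
STARCH = "starch_pct"

# gene-name pools in the field's vocabulary; extras get numbered fallbacks
_STORAGE_NAMES = [
    "legumin_A", "legumin_B", "legumin_A-like_1", "legumin_A-like_3",
    "legumin_A2-like", "legumin_B-like", "legumin_J_2",
    "provicilin", "provicilin-like_1", "provicilin-like_2",
    "provicilin-like_3", "provicilin-like_4", "provicilin-like_5",
    "vicilin-like_1", "vicilin-like_2", "vicilin_chain_C",
    "convicilin_1", "convicilin_2", "conglutin_alpha2-like",
    "albumin-1_A", "albumin-1_A_like", "albumin-1_C", "albumin-1_D",
    "albumin-1_D-like", "albumin-1_E", "albumin-1-like_1",
    "albumin-1-like_2", "albumin-2", "albumin-2-like_4",
]
_STARCH_NAMES = [
    "SBEI", "SBEII", "SSII", "GBSSIa", "GBSSIb", "ISA1", "ISA2", "ISA3",
    "SuSy1", "SuSy2", "SuSy3", "AGPase_S2", "PGMP", "PGDH", "Rb",
    "alpha-amylase", "beta-amylase",
]

_MATERIAL_TYPES = (["cultivar"] * 44 + ["landrace"] * 20
                   + ["breeding_line"] * 19 + ["genebank_accession"] * 17)
_CONTINENTS = (["Europe"] * 66 + ["North_America"] * 9 + ["Asia"] * 8
               + ["Eurasia"] * 6 + ["South_America"] * 2 + ["Oceania"] * 2
               + ["Africa"] * 1 + ["unknown"] * 6)


class ConfigurationError(ValueError):
    pass


@dataclass
class MorphologyLink:
    """Latent-threshold link between binary wrinkling and starch content.

    ``target_r`` is the point-biserial correlation the generator aims for;
    ``wrinkled_fraction`` the marginal frequency of the wrinkled level. The
    maximal attainable |r| for a thresholded Gaussian latent is
    phi(z_q)/sqrt(q(1-q)) (0.798 at a median split), so targets requiring a
    latent correlation above 1 raise a configuration error.
    """

    target_r: float = -0.71
    wrinkled_fraction: float = 0.5
    shape_wrinkle_corr: float = 0.75
    size_shape_corr: float = 0.65
    color_starch_corr: float = 0.45
    pattern_color_corr: float = 0.85
    shape_multicat: bool = False


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror the emulated study: 100 accessions, per-chromosome gene
    counts (14, 2, 12, 3, 14, 12, 1), ancestral minor-allele frequencies up
    to 0.495 with some mass below the 0.05 filter bound, a few percent
    missing calls, and protein/starch intercepts of 25.54 / 40.09 (% dry
    weight). ``gene_effects`` maps trait -> {gene_id: additive effect in
    trait % per minor-allele dosage unit}, shared across a gene's markers
    (each of a gene's m markers carries effect/m).
    """

    n_accessions: int = 100
    chrom_gene_counts: tuple[int, ...] = (14, 2, 12, 3, 14, 12, 1)
    storage_protein_fraction: float = 34 / 55
    snps_per_gene: tuple[float, float] = (100.0, 2.0)  # (mean, dispersion); dispersion<=0 -> exact
    snps_per_gene_overrides: dict[str, int] = field(default_factory=dict)
    flank_snps_mean: float = 24.0
    maf_range: tuple[float, float] = (0.05, 0.495)
    maf_widen_low: float = 0.5  # ancestral support starts at maf_range[0]*this
    rare_fraction: float = 0.7  # markers drawn from below maf_range[0]
    missing_rate: float = 0.03
    n_subpops: int = 3
    fst_like: float = 0.12
    gene_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    trait_intercepts: dict[str, float] = field(
        default_factory=lambda: {PROTEIN: 25.54, STARCH: 40.09}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {PROTEIN: 2.0, STARCH: 3.0}
    )
    subpop_trait_shift: dict[str, list[float]] | None = None
    morphology_link: MorphologyLink = field(default_factory=MorphologyLink)
    n_indels: int = 0
    gene_length_bp: tuple[int, int] = (2000, 5000)
    gene_gap_bp: tuple[int, int] = (20000, 80000)
    flank_bp: int = 1000
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return int(sum(self.chrom_gene_counts))

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} not within (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError(f"missing_rate {self.missing_rate} not in [0, 1)")
        if any(c < 0 for c in self.chrom_gene_counts) or self.n_genes < 1:
            raise ConfigurationError(f"invalid chrom_gene_counts {self.chrom_gene_counts}")
        if len(self.chrom_gene_counts) != 7:
            raise ConfigurationError("chrom_gene_counts must cover 7 chromosomes")
        if not (0 < self.fst_like < 1):
            raise ConfigurationError(f"fst_like {self.fst_like} not in (0, 1)")
        for t, sd in self.noise_sd.items():
            if sd <= 0:
                raise ConfigurationError(f"noise_sd for {t} must be > 0")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    gene_map: GeneMap
    traits: TraitTable
    truth: dict[str, dict[str, float]]  # trait -> gene -> effect
    subpop_labels: pd.Series
    indels: pd.DataFrame
    indel_dosage: np.ndarray
    config: SimulationConfig


def _rngs(config: SimulationConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


# ---------------------------------------------------------------------------
# Gene map


def simulate_gene_map(config: SimulationConfig) -> GeneMap:
    """Place genes on 7 chromosomes with non-overlapping intervals.

    Category labels are permuted over genes so each chromosome mixes
    storage-protein and starch-enzyme genes; gene names come from the
    field's vocabulary with numbered fallbacks.
    """
    config.validate()
    rng = _rngs(config, 6)[0]
    n_genes = config.n_genes
    n_storage = int(round(config.storage_protein_fraction * n_genes))
    categories = np.array(
        [STORAGE_PROTEIN] * n_storage + [STARCH_ENZYME] * (n_genes - n_storage)
    )
    rng.shuffle(categories)
    names_storage = list(_STORAGE_NAMES) + [
        f"storage_protein_{i}" for i in range(len(_STORAGE_NAMES), n_genes)
    ]
    names_starch = list(_STARCH_NAMES) + [
        f"starch_enzyme_{i}" for i in range(len(_STARCH_NAMES), n_genes)
    ]
    rows = []
    it_storage = iter(names_storage)
    it_starch = iter(names_starch)
    gidx = 0
    for chrom_i, count in enumerate(config.chrom_gene_counts, start=1):
        pos = int(rng.integers(50_000, 150_000))
        for _ in range(count):
            length = int(rng.integers(*config.gene_length_bp))
            cat = categories[gidx]
            name = next(it_storage) if cat == STORAGE_PROTEIN else next(it_starch)
            rows.append(
                {
                    "chrom": f"chr{chrom_i}",
                    "start": pos,
                    "end": pos + length,
                    "gene_id": name,
                    "category": cat,
                    "flank_bp": config.flank_bp,
                }
            )
            pos += length + int(rng.integers(*config.gene_gap_bp))
            gidx += 1
    return GeneMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Genotypes


def _draw_marker_count(rng, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return max(1, int(round(mean)))
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return max(1, int(rng.poisson(lam)))


def simulate_genotypes(gene_map: GeneMap, config: SimulationConfig) -> GenotypeMatrix:
    """Draw a biallelic SNP panel with subpopulation structure.

    Per marker, an ancestral minor-allele frequency is drawn from a
    rare-skewed two-component support: with probability ``rare_fraction``
    uniformly below ``maf_range[0]`` (down to ``maf_range[0] *
    maf_widen_low``), else uniformly on ``maf_range``. Sequencing panels are
    dominated by rare variants, and this is what gives the MAF filter
    realistic attrition. Each subpopulation's frequency follows a
    Balding-Nichols beta with
    mean p and variance fst_like * p * (1-p); accession genotypes are
    binomial(2, p_subpop); missing calls are MCAR at ``missing_rate``.

    The returned matrix carries the pre-missingness dosages and subpopulation
    labels as private attributes for phenotype generation.
    """
    config.validate()
    if len(gene_map) == 0:
        raise ConfigurationError("gene map is empty")
    rng = _rngs(config, 6)[1]
    n = config.n_accessions
    lo, hi = config.maf_range
    widened_lo = max(1e-4, lo * config.maf_widen_low)

    # balanced subpopulation assignment, then shuffled
    base = np.repeat(np.arange(config.n_subpops), int(np.ceil(n / config.n_subpops)))[:n]
    subpop = rng.permutation(base)

    records: list[VariantRecord] = []
    freqs: list[float] = []
    bases = np.array(list("ACGT"))
    # markers of causal genes are drawn from the common band: an effect on a
    # marker destined to fail the MAF filter would be invisible by construction
    causal_genes = {g for eff in config.gene_effects.values() for g in eff}
    for row in gene_map.table.itertuples(index=False):
        n_body = _draw_marker_count(rng, *config.snps_per_gene)
        if row.gene_id in config.snps_per_gene_overrides:
            n_body = max(1, int(config.snps_per_gene_overrides[row.gene_id]))
        n_flank = int(rng.poisson(config.flank_snps_mean))
        body_pool = np.arange(row.start + 1, row.end + 1)
        n_body = min(n_body, len(body_pool))
        body_pos = np.sort(rng.choice(body_pool, size=n_body, replace=False))
        flank_pool = np.concatenate(
            [
                np.arange(max(1, row.start - row.flank_bp + 1), row.start + 1),
                np.arange(row.end + 1, row.end + row.flank_bp + 1),
            ]
        )
        n_flank = min(n_flank, len(flank_pool))
        flank_pos = np.sort(rng.choice(flank_pool, size=n_flank, replace=False))
        for pos_arr, category in ((body_pos, str(row.category)), (flank_pos, FLANKING)):
            for pos in pos_arr:
                ref, alt = rng.choice(bases, size=2, replace=False)
                causal_body = row.gene_id in causal_genes and category != FLANKING
                if not causal_body and rng.random() < config.rare_fraction:
                    p_minor = float(rng.uniform(widened_lo, lo))
                else:
                    p_minor = float(rng.uniform(lo, hi))
                p_alt = p_minor if rng.random() < 0.5 else 1.0 - p_minor
                if category == FLANKING:
                    eff = "MODIFIER"
                else:
                    eff = str(
                        rng.choice(
                            ["MODIFIER", "LOW", "MODERATE", "HIGH"],
                            p=[0.70, 0.20, 0.095, 0.005],
                        )
                    )
                rec = VariantRecord(
                    chrom=str(row.chrom), pos=int(pos), ref=str(ref), alt=str(alt),
                    effect_class=eff, gene_id=str(row.gene_id),
                    region_category=category,
                )
                records.append(rec)
                freqs.append(p_alt)

    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    records = [records[i] for i in order]
    p_alt = np.array(freqs)[order]

    F = config.fst_like
    m = len(records)
    if F > 1e-9:
        a = p_alt * (1 - F) / F
        b = (1 - p_alt) * (1 - F) / F
        sub_freq = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, m))
    else:
        sub_freq = np.tile(p_alt, (config.n_subpops, 1))
    true_dosage = rng.binomial(2, sub_freq[subpop, :]).astype(float)
    # causal effects act on minor-allele counts (the coding the scan uses);
    # "minor" is decided by the realized sample frequency, as in the analysis
    realized_p = true_dosage.mean(axis=0) / 2.0
    minor_dosage = np.where(realized_p <= 0.5, true_dosage, 2.0 - true_dosage)
    dosage = true_dosage.copy()
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    ids = [f"PS{i + 1:03d}" for i in range(n)]
    gm = GenotypeMatrix(ids, records, dosage)
    gm._true_dosage = minor_dosage  # type: ignore[attr-defined]
    gm._subpop = pd.Series(subpop, index=ids, name="subpop")  # type: ignore[attr-defined]
    return gm


# ---------------------------------------------------------------------------
# Phenotypes


def _underlying_dosage(genotypes: GenotypeMatrix) -> np.ndarray:
    true = getattr(genotypes, "_true_dosage", None)
    if true is not None:
        return true
    d = genotypes.dosage.copy()
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(np.nan_to_num(col_mean), inds[1])
    return d


def simulate_phenotypes(
    genotypes: GenotypeMatrix, gene_map: GeneMap, config: SimulationConfig
) -> TraitTable:
    """Additive trait values from the causal-gene truth.

    trait = intercept + sum over causal genes of (effect / m_g) * minor-allele
    dosage at each of the gene's m_g body markers + subpopulation shift +
    N(0, noise_sd^2). Flanking-window markers carry no effect. Pleiotropy
    arises from genes shared between the two traits' effect maps.
    """
    config.validate()
    rng = _rngs(config, 6)[2]
    known = set(gene_map.gene_ids)
    for trait, effects in config.gene_effects.items():
        missing = set(effects) - known
        if missing:
            raise ConfigurationError(
                f"causal genes absent from map for {trait}: {sorted(missing)}"
            )
    d = _underlying_dosage(genotypes)
    gene_of = np.array(
        [m.gene_id if m.region_category != FLANKING else None
         for m in genotypes.markers],
        dtype=object,
    )
    subpop = getattr(genotypes, "_subpop", None)

    data = pd.DataFrame(index=pd.Index(genotypes.accession_ids, name="accession_id"))
    types: dict[str, str] = {}
    for trait in (PROTEIN, STARCH):
        y = np.full(genotypes.n_accessions, config.trait_intercepts.get(trait, 0.0))
        for gene, effect in config.gene_effects.get(trait, {}).items():
            cols = np.flatnonzero(gene_of == gene)
            if len(cols) == 0:
                continue  # gene exists in map but carries no markers
            contrib = d[:, cols].sum(axis=1)
            # center so the intercept stays the population trait mean
            y = y + (effect / len(cols)) * (contrib - contrib.mean())
        shifts = (config.subpop_trait_shift or {}).get(trait)
        if shifts is not None:
            if subpop is None:
                raise ConfigurationError(
                    "subpop_trait_shift requested but the genotype matrix "
                    "carries no subpopulation labels (was it subset or "
                    "recoded before phenotype simulation?)"
                )
            y = y + np.asarray(shifts)[subpop.to_numpy()]
        y = y + rng.normal(0.0, config.noise_sd[trait], size=len(y))
        data[trait] = y
        types[trait] = trait_stats.CONTINUOUS

    mat_rng = rng
    data["material_type"] = mat_rng.choice(_MATERIAL_TYPES, size=len(data))
    data["continent"] = mat_rng.choice(_CONTINENTS, size=len(data))
    types["material_type"] = trait_stats.MULTICAT
    types["continent"] = trait_stats.MULTICAT
    return TraitTable(data, types)


def max_attainable_biserial(wrinkled_fraction: float) -> float:
    """Largest |point-biserial| a Gaussian latent threshold can induce."""
    q = wrinkled_fraction
    z = norm.ppf(1 - q)
    return float(norm.pdf(z) / np.sqrt(q * (1 - q)))


def simulate_morphology(traits: TraitTable, config: SimulationConfig) -> TraitTable:
    """Seed morphology from latent variables tied to starch content.

    Wrinkling is a threshold on rho * z(starch) + sqrt(1-rho^2) * noise with
    rho chosen analytically so the realized point-biserial matches
    ``morphology_link.target_r`` (biserial attenuation factor
    phi(z_q)/sqrt(q(1-q))). Shape, size, color and pattern follow with the
    configured cross-correlations.
    """
    link = config.morphology_link
    rng = _rngs(config, 6)[3]
    if STARCH not in traits.data.columns:
        raise ConfigurationError("starch trait required before morphology simulation")
    factor = max_attainable_biserial(link.wrinkled_fraction)
    if abs(link.target_r) >= 1:
        raise ConfigurationError(f"target point-biserial {link.target_r} unattainable")
    rho = link.target_r / factor
    if abs(rho) > 1:
        raise ConfigurationError(
            f"target r={link.target_r} needs latent correlation {rho:.3f} "
            f"(max attainable |r| at wrinkled_fraction={link.wrinkled_fraction} "
            f"is {factor:.3f})"
        )
    z = traits.data[STARCH].to_numpy(dtype=float)
    z = (z - z.mean()) / z.std()
    n = len(z)
    latent = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)
    thresh = np.quantile(latent, 1 - link.wrinkled_fraction)
    wrinkled = latent > thresh

    shape_latent = (
        link.shape_wrinkle_corr * latent
        + np.sqrt(max(0.0, 1 - link.shape_wrinkle_corr**2)) * rng.normal(size=n)
    )
    size = 45.0 + 8.0 * link.size_shape_corr * shape_latent + 8.0 * np.sqrt(
        max(0.0, 1 - link.size_shape_corr**2)
    ) * rng.normal(size=n)
    color_latent = link.color_starch_corr * (-z) + np.sqrt(
        max(0.0, 1 - link.color_starch_corr**2)
    ) * rng.normal(size=n)
    color = pd.cut(
        pd.Series(color_latent), bins=[-np.inf] + list(np.quantile(color_latent, [1 / 3, 2 / 3])) + [np.inf],
        labels=["green", "yellow", "brown"],
    ).astype(str)
    pattern_latent = (
        link.pattern_color_corr * color_latent
        + np.sqrt(max(0.0, 1 - link.pattern_color_corr**2)) * rng.normal(size=n)
    )
    patterned = pattern_latent > np.quantile(pattern_latent, 0.6)

    data = traits.data.copy()
    types = dict(traits.types)
    data["seed_wrinkling"] = np.where(wrinkled, "wrinkled", "smooth")
    types["seed_wrinkling"] = trait_stats.BINARY
    if link.shape_multicat:
        shape = pd.cut(
            pd.Series(shape_latent),
            bins=[-np.inf] + list(np.quantile(shape_latent, [1 / 3, 2 / 3])) + [np.inf],
            labels=["round", "oval", "non_round"],
        ).astype(str)
        data["seed_shape"] = shape.to_numpy()
        types["seed_shape"] = trait_stats.MULTICAT
    else:
        data["seed_shape"] = np.where(
            shape_latent > np.median(shape_latent), "non_round", "round"
        )
        types["seed_shape"] = trait_stats.BINARY
    data["seed_size"] = size
    types["seed_size"] = trait_stats.CONTINUOUS
    data["seed_color"] = color.to_numpy()
    types["seed_color"] = trait_stats.MULTICAT
    data["seed_pattern"] = np.where(patterned, "patterned", "uniform")
    types["seed_pattern"] = trait_stats.BINARY
    return TraitTable(data, types)


# ---------------------------------------------------------------------------
# Full simulation and serialization


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: map, genotypes, phenotypes, morphology, InDels."""
    config.validate()
    gene_map = simulate_gene_map(config)
    genotypes = simulate_genotypes(gene_map, config)
    traits = simulate_phenotypes(genotypes, gene_map, config)
    traits = simulate_morphology(traits, config)
    rng = _rngs(config, 6)[4]
    indel_rows = []
    if config.n_indels > 0:
        gm = gene_map.table
        for _ in range(config.n_indels):
            row = gm.iloc[int(rng.integers(len(gm)))]
            pos = int(rng.integers(row["start"] + 1, row["end"] + 1))
            ref_base = str(rng.choice(list("ACGT")))
            ins = str(rng.choice(list("ACGT")))
            if rng.random() < 0.5:
                ref, alt = ref_base, ref_base + ins
            else:
                ref, alt = ref_base + ins, ref_base
            indel_rows.append({"chrom": row["chrom"], "pos": pos, "ref": ref, "alt": alt})
    indels = pd.DataFrame(indel_rows, columns=["chrom", "pos", "ref", "alt"])
    if len(indels):
        indels = indels.sort_values(["chrom", "pos"]).reset_index(drop=True)
        indel_dosage = rng.binomial(2, 0.2, size=(genotypes.n_accessions, len(indels))).astype(float)
    else:
        indel_dosage = np.empty((genotypes.n_accessions, 0))
    return SimulatedDataset(
        genotypes=genotypes,
        gene_map=gene_map,
        traits=traits,
        truth={t: dict(e) for t, e in config.gene_effects.items()},
        subpop_labels=getattr(genotypes, "_subpop"),
        indels=indels,
        indel_dosage=indel_dosage,
        config=config,
    )


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
_ANN_TERM = {
    "HIGH": "stop_gained",
    "MODERATE": "missense_variant",
    "LOW": "synonymous_variant",
    "MODIFIER": "intron_variant",
}


def write_dataset(ds: SimulatedDataset, out_dir, with_ann: bool = True) -> dict[str, Path]:
    """Emit VCF v4.3, BED-like gene map, trait CSV, type sidecar and truth JSON.

    Output is byte-deterministic for a fixed dataset; SNP and InDel records
    are interleaved in coordinate order.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "gene_map": out / "gene_map.bed",
        "traits": out / "traits.csv",
        "trait_types": out / "trait_types.json",
        "truth": out / "truth.json",
    }

    gm = ds.genotypes
    chroms = sorted(
        {m.chrom for m in gm.markers}
        | set(ds.indels["chrom"].astype(str))
        | set(ds.gene_map.table["chrom"].astype(str))
    )
    entries: list[tuple[str, int, int, str]] = []  # (chrom, pos, tiebreak, line)
    for j, m in enumerate(gm.markers):
        info = "."
        if with_ann:
            info = f"ANN={m.alt}|{_ANN_TERM[m.effect_class]}|{m.effect_class}|{m.gene_id}"
        gts = "\t".join(
            _GT.get(d, "./.") if np.isfinite(d) else "./." for d in gm.dosage[:, j]
        )
        line = (
            f"{m.chrom}\t{m.pos}\t{m.marker_id}\t{m.ref}\t{m.alt}\t.\tPASS\t{info}\tGT\t{gts}"
        )
        entries.append((m.chrom, m.pos, 0, line))
    for i, row in enumerate(ds.indels.itertuples(index=False)):
        gts = "\t".join(
            _GT.get(d, "./.") if np.isfinite(d) else "./."
            for d in ds.indel_dosage[:, i]
        )
        mid = f"{row.chrom}_{row.pos}_{row.ref}_{row.alt}"
        line = f"{row.chrom}\t{row.pos}\t{mid}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}"
        entries.append((str(row.chrom), int(row.pos), 1, line))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        fh.write('##source=peagene-synthetic\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description='
            '"Functional annotations: Allele|Annotation|Impact|Gene">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accession_ids)
            + "\n"
        )
        for _, _, _, line in entries:
            fh.write(line + "\n")

    ds.gene_map.to_bed(paths["gene_map"])
    ds.traits.data.to_csv(paths["traits"], float_format="%.10g", lineterminator="\n")
    with open(paths["trait_types"], "w") as fh:
        json.dump(ds.traits.types, fh, indent=1, sort_keys=True)
    truth_payload = {
        "gene_effects": ds.truth,
        "subpop_labels": {k: int(v) for k, v in ds.subpop_labels.items()},
        "seed": ds.config.seed,
        "config": dataclasses.asdict(ds.config),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True, default=list)
    return paths


def read_dataset(out_dir) -> tuple[GenotypeMatrix, GeneMap, TraitTable, dict]:
    """Round-trip reader for :func:`write_dataset` output."""
    out = Path(out_dir)
    matrix, _, _ = read_vcf(out / "genotypes.vcf")
    gene_map = GeneMap.from_bed(out / "gene_map.bed")
    data = pd.read_csv(out / "traits.csv", index_col="accession_id")
    with open(out / "trait_types.json") as fh:
        types = json.load(fh)
    with open(out / "truth.json") as fh:
        truth = json.load(fh)
    return matrix, gene_map, TraitTable(data, types), truth
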