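"""Reading, encoding, filtering and summarizing SNP data against a gene map.

The analysis consumes a VCF (v4.3) of targeted-gene sequencing variants, keeps
biallelic SNPs as a dosage matrix (accessions x markers), filters on minor
allele frequency and missingness, recodes dosages so 2 always counts minor
alleles, and assigns each marker to a gene body, a flanking region, or leaves
it unassigned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

#: SnpEff impact keywords, most severe first.
EFFECT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
UNANNOTATED = "UNANNOTATED"

STORAGE_PROTEIN = "storage_protein"
STARCH_ENZYME = "starch_enzyme"
FLANKING = "flanking"


class VcfParseError(ValueError):
    """Malformed VCF content; carries an approximate record index."""


@dataclass
class VariantRecord:
    """One biallelic SNP marker with its derived annotations.

    ``maf`` and ``missing_frac`` are filled by :func:`compute_maf`;
    ``gene_id``/``region_category`` by :func:`assign_snps_to_genes`.
    """

    chrom: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    marker_id: str = ""
    effect_class: str = UNANNOTATED
    maf: float = np.nan
    missing_frac: float = np.nan
    gene_id: str | None = None
    region_category: str | None = None
    flipped: bool = False  # set by recode_major_minor

    def __post_init__(self) -> None:
        if not self.marker_id:
            self.marker_id = f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    @property
    def is_snp(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref != self.alt
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )


@dataclass
class GenotypeMatrix:
    """Accessions x markers dosage table in {0, 1, 2, NaN=missing}.

    Dosage semantics after :func:`recode_major_minor`: 0 = homozygous major,
    1 = heterozygous, 2 = homozygous minor. Straight from the VCF the dosage
    counts ALT alleles, which may or may not be the minor allele.
    """

    accession_ids: list[str]
    markers: list[VariantRecord]
    dosage: np.ndarray  # float array, shape (n_accessions, n_markers)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.accession_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.accession_ids)} accessions x {len(self.markers)} markers"
            )

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            accession_ids=list(self.accession_ids),
            markers=[self.markers[i] for i in keep],
            dosage=self.dosage[:, keep].copy(),
        )

    def subset_accessions(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            accession_ids=[self.accession_ids[i] for i in keep],
            markers=list(self.markers),
            dosage=self.dosage[keep, :].copy(),
        )


@dataclass
class GeneMap:
    """Targeted-gene intervals (BED-like, 0-based half-open) with categories."""

    table: pd.DataFrame  # columns: chrom, start, end, gene_id, category, flank_bp

    REQUIRED = ("chrom", "start", "end", "gene_id", "category", "flank_bp")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"gene map missing columns: {missing}")
        if self.table["gene_id"].duplicated().any():
            dup = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene_ids in map: {sorted(set(dup))}")
        if (self.table["end"] < self.table["start"]).any():
            raise ValueError("gene map contains negative-length intervals")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def category_of(self, gene_id: str) -> str:
        row = self.table.loc[self.table["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return str(row["category"].iloc[0])

    @classmethod
    def from_bed(cls, path) -> "GeneMap":
        tbl = pd.read_csv(
            path,
            sep="\t",
            comment=None,
            names=list(cls.REQUIRED),
            header=None,
            skiprows=lambda i: i == 0,  # header line starts with '#'
            dtype={"chrom": str, "gene_id": str, "category": str},
        )
        return cls(tbl)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(self.REQUIRED) + "\n")
            for row in self.table.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}"
                    f"\t{row.category}\t{row.flank_bp}\n"
                )


# ---------------------------------------------------------------------------
# VCF input


def parse_effect_class(ann_field: str | None) -> str:
    """Map a SnpEff-style ANN INFO subfield to a single impact class.

    Multiple annotations collapse to the most severe
    (HIGH > MODERATE > LOW > MODIFIER); a missing or unrecognized field
    yields UNANNOTATED.
    """
    if ann_field is None or ann_field == "":
        return UNANNOTATED
    found: list[str] = []
    for entry in str(ann_field).split(","):
        tokens = entry.split("|")
        hit = next((t for t in tokens if t in EFFECT_CLASSES), None)
        if hit is not None:
            found.append(hit)
    if not found:
        warnings.warn(f"unrecognized ANN impact in {ann_field!r}; treating as {UNANNOTATED}")
        return UNANNOTATED
    return min(found, key=EFFECT_CLASSES.index)


def read_vcf(path) -> tuple[GenotypeMatrix, list[VariantRecord], pd.DataFrame]:
    """Read a VCF into a biallelic-SNP dosage matrix.

    Multi-allelic records are split per ALT allele; any allele that is not a
    single-base substitution is routed to the InDel tally and excluded from
    the matrix. GT ``./.`` (or any half-missing call) becomes NaN.

    Returns ``(matrix, snp_records, indel_table)`` where ``indel_table`` has
    columns chrom/pos/ref/alt, one row per non-SNP allele.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    indels: list[tuple[str, int, str, str]] = []

    for rec_idx, variant in enumerate(vcf):
        try:
            alts = variant.ALT or []
            genos = variant.genotypes  # [[a0, a1, phased], ...]
            ann = variant.INFO.get("ANN")
        except Exception as exc:
            raise VcfParseError(f"malformed VCF record #{rec_idx + 1}: {exc}") from exc
        for alt_idx, alt in enumerate(alts, start=1):
            rec = VariantRecord(
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                ref=str(variant.REF),
                alt=str(alt),
            )
            if not rec.is_snp:
                indels.append((rec.chrom, rec.pos, rec.ref, rec.alt))
                continue
            rec.effect_class = parse_effect_class(ann)
            col = np.full(len(samples), np.nan)
            for s, g in enumerate(genos):
                a = g[:-1]  # drop phasing flag
                if any(int(x) < 0 for x in a):
                    continue  # missing
                col[s] = sum(int(x) == alt_idx for x in a)
            records.append(rec)
            columns.append(col)

    dosage = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    matrix = GenotypeMatrix(samples, records, dosage)
    indel_table = pd.DataFrame(indels, columns=["chrom", "pos", "ref", "alt"])
    return matrix, records, indel_table


# ---------------------------------------------------------------------------
# Frequencies, filtering, recoding


def compute_maf(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker minor allele frequency and missing fraction.

    maf = min(p, 1-p) with p the ALT-allele frequency over non-missing calls.
    A marker with zero non-missing calls gets maf = NaN (flagged via
    missing_frac = 1). Results are also written onto the marker records.
    """
    d = matrix.dosage
    n_nonmiss = np.sum(~np.isnan(d), axis=0)
    missing_frac = np.sum(np.isnan(d), axis=0) / max(matrix.n_accessions, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.nansum(d, axis=0) / (2.0 * n_nonmiss)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    maf[n_nonmiss == 0] = np.nan
    for j, m in enumerate(matrix.markers):
        m.maf = float(maf[j]) if np.isfinite(maf[j]) else np.nan
        m.missing_frac = float(missing_frac[j])
    return maf, missing_frac


def alt_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    d = matrix.dosage
    n_nonmiss = np.sum(~np.isnan(d), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.nansum(d, axis=0) / (2.0 * n_nonmiss)


def filter_markers(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.20,
) -> GenotypeMatrix:
    """Retain markers with maf > maf_min and missing_frac < max_missing.

    Both inequalities are strict ("greater than 5%", "less than 20%").
    Markers with undefined MAF (all calls missing) are always dropped.
    """
    maf, miss = compute_maf(matrix)
    with np.errstate(invalid="ignore"):
        keep = (maf > maf_min) & (miss < max_missing)
    keep &= np.isfinite(maf)
    if not keep.any():
        warnings.warn("marker filter retained zero markers")
    return matrix.subset_markers(keep)


def filter_accessions(matrix: GenotypeMatrix, max_missing: float = 0.20) -> GenotypeMatrix:
    """Optional companion filter: drop accessions with >= max_missing missing calls."""
    if matrix.n_markers == 0:
        return matrix
    miss = np.mean(np.isnan(matrix.dosage), axis=1)
    return matrix.subset_accessions(miss < max_missing)


def recode_major_minor(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Flip dosages (d -> 2-d) wherever the ALT allele is the major allele.

    After recoding, dosage 2 always counts minor alleles. An exact 0.5
    frequency is left unflipped (REF treated as major), which is
    deterministic and order-independent.
    """
    p_alt = alt_frequency(matrix)
    flip = p_alt > 0.5  # strict: ties keep REF as major
    out = matrix.subset_markers(np.ones(matrix.n_markers, dtype=bool))
    out.dosage[:, flip] = 2.0 - out.dosage[:, flip]
    out.markers = [
        replace(m, flipped=bool(f)) if f != m.flipped else m
        for m, f in zip(out.markers, flip)
    ]
    compute_maf(out)
    return out


# ---------------------------------------------------------------------------
# Gene assignment


def assign_snps_to_genes(
    variants: list[VariantRecord], gene_map: GeneMap
) -> list[VariantRecord]:
    """Assign each variant to a gene body, a flanking region, or neither.

    Gene intervals are BED-like 0-based half-open; a 1-based VCF position
    ``pos`` lies in the body iff ``start < pos <= end``. A variant outside
    all bodies but within ``flank_bp`` of exactly one gene is assigned to
    that gene with category ``flanking``; within several flanks it stays
    unassigned (ambiguous). Body overlap ties break by smallest interval,
    then lexicographic gene_id. Mutates and returns ``variants``.
    """
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g for c, g in gene_map.table.groupby("chrom")
    }
    for v in variants:
        genes = by_chrom.get(str(v.chrom))
        v.gene_id = None
        v.region_category = None
        if genes is None:
            continue
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        flank = genes["flank_bp"].to_numpy()
        in_body = (start < v.pos) & (v.pos <= end)
        if in_body.any():
            idx = np.flatnonzero(in_body)
            lengths = end[idx] - start[idx]
            ids = genes["gene_id"].to_numpy()[idx]
            order = sorted(range(len(idx)), key=lambda i: (lengths[i], ids[i]))
            chosen = idx[order[0]]
            v.gene_id = str(genes["gene_id"].iloc[chosen])
            v.region_category = str(genes["category"].iloc[chosen])
            continue
        in_flank = (start - flank < v.pos) & (v.pos <= end + flank)
        if in_flank.sum() == 1:
            chosen = int(np.flatnonzero(in_flank)[0])
            v.gene_id = str(genes["gene_id"].iloc[chosen])
            v.region_category = FLANKING
    return variants


# ---------------------------------------------------------------------------
# Summaries


def summarize(
    matrix: GenotypeMatrix,
    all_variants: list[VariantRecord] | None = None,
    indel_table: pd.DataFrame | None = None,
    maf_bins: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Summary tables for the retained marker panel.

    Produces per-chromosome variant/retained-SNP counts, per-gene SNP counts,
    per-category counts, effect-class x chromosome counts, and a MAF
    histogram restricted to HIGH+MODERATE markers.

    ``all_variants``/``indel_table`` feed the "total genetic variants"
    column; when omitted, totals cover only the retained matrix.
    """
    markers = matrix.markers
    retained = pd.DataFrame(
        {
            "chrom": [m.chrom for m in markers],
            "gene_id": [m.gene_id for m in markers],
            "category": [
                m.region_category if m.region_category is not None else "unassigned"
                for m in markers
            ],
            "effect_class": [m.effect_class for m in markers],
            "maf": [m.maf for m in markers],
        }
    )

    total_by_chrom: dict[str, int] = {}
    source = all_variants if all_variants is not None else markers
    for v in source:
        total_by_chrom[v.chrom] = total_by_chrom.get(v.chrom, 0) + 1
    if indel_table is not None and len(indel_table):
        for c, n in indel_table.groupby("chrom").size().items():
            total_by_chrom[str(c)] = total_by_chrom.get(str(c), 0) + int(n)

    chroms = sorted(set(total_by_chrom) | set(retained["chrom"]))
    per_chromosome = pd.DataFrame(
        {
            "chrom": chroms,
            "total_variants": [total_by_chrom.get(c, 0) for c in chroms],
            "selected_snps": [
                int((retained["chrom"] == c).sum()) for c in chroms
            ],
        }
    )

    per_gene = (
        retained.dropna(subset=["gene_id"])
        .groupby("gene_id")
        .size()
        .rename("n_snps")
        .reset_index()
        .sort_values(["n_snps", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )

    per_category = (
        retained.groupby("category").size().rename("n_snps").reset_index()
    )

    effect_by_chrom = (
        retained.groupby(["effect_class", "chrom"])
        .size()
        .rename("n_snps")
        .reset_index()
    )

    if maf_bins is None:
        maf_bins = np.arange(0.0, 0.55, 0.05)
    hm = retained.loc[retained["effect_class"].isin(["HIGH", "MODERATE"]), "maf"]
    counts, edges = np.histogram(hm.dropna().to_numpy(), bins=maf_bins)
    maf_hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "n_snps": counts}
    )

    return {
        "per_chromosome": per_chromosome,
        "per_gene": per_gene,
        "per_category": per_category,
        "effect_by_chrom": effect_by_chrom,
        "maf_hist_high_moderate": maf_hist,
    }
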