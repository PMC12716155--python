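"""End-to-end orchestration of the analysis stages.

simulate? -> read VCF -> filter -> recode -> assign to genes -> summaries ->
PCA (all + per-category subsets) -> IBS/NJ tree -> per-SNP scans for protein
and starch -> significance selection -> gene-effect aggregation ->
pleiotropy overlap -> PC-score Ward clustering aligned with traits ->
mixed-type trait correlation matrix -> manifest + human-readable report.

All randomness flows from the config seed; a failed stage aborts with the
stage name and leaves that stage's outputs with a ``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, gene_effect, popstruct, synthetic_data, trait_stats, variant_io
from .synthetic_data import PROTEIN, STARCH, MorphologyLink, SimulationConfig
from .trait_stats import TraitTable
from .variant_io import GeneMap, GenotypeMatrix

log = logging.getLogger(__name__)

_TUPLE_FIELDS = {"chrom_gene_counts", "snps_per_gene", "maf_range",
                 "gene_length_bp", "gene_gap_bp"}


class PipelineError(RuntimeError):
    pass


def sim_config_from_dict(d: dict, seed: int | None = None) -> SimulationConfig:
    d = dict(d)
    if "morphology_link" in d and isinstance(d["morphology_link"], dict):
        d["morphology_link"] = MorphologyLink(**d["morphology_link"])
    for k in _TUPLE_FIELDS & set(d):
        d[k] = tuple(d[k])
    if seed is not None:
        d["seed"] = seed
    return SimulationConfig(**d)


@dataclass
class PipelineConfig:
    """Validated run configuration (YAML-backed)."""

    out_dir: str = "peagene_run"
    seed: int = 0
    simulate: dict | None = None
    vcf: str | None = None
    gene_map: str | None = None
    traits: str | None = None
    trait_types: str | None = None
    maf_min: float = 0.05
    max_missing: float = 0.20
    per_accession_missing: float | None = None
    pca_components: int = 10
    scan_alpha: float = 0.05
    pc_covariates: int = 2
    include_flanking: bool = True
    bh_correction: bool = False
    cluster_n_pcs: int = 2
    cluster_k: int = 2
    log_level: str = "INFO"

    def validate(self) -> None:
        have_paths = all(x is not None for x in (self.vcf, self.gene_map, self.traits))
        if (self.simulate is not None) == have_paths:
            raise PipelineError(
                "config must provide exactly one of: a simulate block, or "
                "vcf + gene_map + traits input paths"
            )
        if not (0 <= self.maf_min < 0.5):
            raise PipelineError(f"maf_min {self.maf_min} out of range")
        if not (0 < self.max_missing <= 1):
            raise PipelineError(f"max_missing {self.max_missing} out of range")
        if not (0 < self.scan_alpha <= 1):
            raise PipelineError(f"scan_alpha {self.scan_alpha} out of range")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _StageWriter:
    """Write stage outputs to .partial files, renamed on stage success."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.pending: list[tuple[Path, Path]] = []

    def path(self, name: str) -> Path:
        final = self.out_dir / name
        tmp = self.out_dir / (name + ".partial")
        self.pending.append((tmp, final))
        return tmp

    def commit(self) -> list[Path]:
        finals = []
        for tmp, final in self.pending:
            if tmp.exists():
                tmp.replace(final)
                finals.append(final)
        self.pending.clear()
        return finals


def save_matrix(matrix: GenotypeMatrix, dosage_path: Path, markers_path: Path) -> None:
    pd.DataFrame(
        matrix.dosage, index=pd.Index(matrix.accession_ids, name="accession_id"),
        columns=matrix.marker_ids,
    ).to_csv(dosage_path, float_format="%.10g", lineterminator="\n")
    pd.DataFrame(
        [
            {
                "marker_id": m.marker_id, "chrom": m.chrom, "pos": m.pos,
                "ref": m.ref, "alt": m.alt, "effect_class": m.effect_class,
                "maf": m.maf, "missing_frac": m.missing_frac,
                "gene_id": m.gene_id, "region_category": m.region_category,
                "flipped": m.flipped,
            }
            for m in matrix.markers
        ]
    ).to_csv(markers_path, index=False, float_format="%.10g", lineterminator="\n")


def load_matrix(dosage_path, markers_path) -> GenotypeMatrix:
    dosage = pd.read_csv(dosage_path, index_col="accession_id")
    meta = pd.read_csv(markers_path)
    markers = [
        variant_io.VariantRecord(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            marker_id=str(r.marker_id), effect_class=str(r.effect_class),
            maf=float(r.maf), missing_frac=float(r.missing_frac),
            gene_id=None if pd.isna(r.gene_id) else str(r.gene_id),
            region_category=None if pd.isna(r.region_category) else str(r.region_category),
            flipped=bool(r.flipped),
        )
        for r in meta.itertuples(index=False)
    ]
    return GenotypeMatrix(
        [str(a) for a in dosage.index], markers, dosage.to_numpy(dtype=float)
    )


def run(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json)."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "stage_counts": {},
        "files": {},
        "timestamps": {"started": time.strftime("%Y-%m-%dT%H:%M:%S")},
    }
    emitted: list[Path] = []
    stage = "init"
    try:
        # ------------------------------------------------------------ inputs
        stage = "simulate" if config.simulate is not None else "load-inputs"
        if config.simulate is not None:
            sim_cfg = sim_config_from_dict(config.simulate, seed=config.seed)
            ds = synthetic_data.simulate(sim_cfg)
            sim_paths = synthetic_data.write_dataset(ds, out / "sim")
            vcf_path, map_path, traits_path = (
                sim_paths["vcf"], sim_paths["gene_map"], sim_paths["traits"])
            types_path = sim_paths["trait_types"]
            emitted.extend(sim_paths.values())
        else:
            vcf_path, map_path, traits_path = (
                Path(config.vcf), Path(config.gene_map), Path(config.traits))
            types_path = Path(config.trait_types) if config.trait_types else None

        stage = "read"
        matrix, variants, indels = variant_io.read_vcf(vcf_path)
        gene_map = GeneMap.from_bed(map_path)
        tdata = pd.read_csv(traits_path, index_col=0)
        tdata.index = tdata.index.astype(str)
        if types_path is not None:
            with open(types_path) as f:
                ttypes = json.load(f)
        else:
            ttypes = {
                c: (trait_stats.CONTINUOUS
                    if pd.api.types.is_numeric_dtype(tdata[c])
                    else (trait_stats.BINARY if tdata[c].nunique() == 2
                          else trait_stats.MULTICAT))
                for c in tdata.columns
            }
        traits = TraitTable(tdata, ttypes)
        manifest["stage_counts"]["read"] = {
            "accessions": matrix.n_accessions,
            "snps": matrix.n_markers,
            "indels": int(len(indels)),
        }

        # ------------------------------------------------------------ filter
        stage = "filter"
        w = _StageWriter(out)
        variant_io.assign_snps_to_genes(matrix.markers, gene_map)
        filtered = variant_io.filter_markers(matrix, config.maf_min, config.max_missing)
        if config.per_accession_missing is not None:
            filtered = variant_io.filter_accessions(filtered, config.per_accession_missing)
        filtered = variant_io.recode_major_minor(filtered)
        save_matrix(filtered, w.path("filtered_dosage.csv"), w.path("markers.csv"))
        summaries = variant_io.summarize(filtered, variants, indels)
        for name, df in summaries.items():
            df.to_csv(w.path(f"summary_{name}.csv"), index=False,
                      float_format="%.10g", lineterminator="\n")
        emitted.extend(w.commit())
        manifest["stage_counts"]["filter"] = {
            "retained_snps": filtered.n_markers,
            "accessions": filtered.n_accessions,
        }

        # ------------------------------------------------------------ pca
        stage = "pca"
        w = _StageWriter(out)
        pcas: dict[str, popstruct.PCAResult] = {}
        subsets = {
            "all": np.ones(filtered.n_markers, dtype=bool),
            variant_io.STORAGE_PROTEIN: np.array(
                [m.region_category == variant_io.STORAGE_PROTEIN for m in filtered.markers]),
            variant_io.STARCH_ENZYME: np.array(
                [m.region_category == variant_io.STARCH_ENZYME for m in filtered.markers]),
        }
        for label, mask in subsets.items():
            if mask.sum() < 2:
                log.warning("PCA subset %s has <2 markers; skipped", label)
                continue
            sub = filtered.subset_markers(mask)
            centered, _ = popstruct.impute_and_center(sub)
            pca = popstruct.run_pca(
                centered, config.pca_components, sub.accession_ids, label)
            pcas[label] = pca
            pca.scores.to_csv(w.path(f"pc_scores_{label}.csv"),
                              float_format="%.10g", lineterminator="\n")
            pd.DataFrame({
                "component": [f"PC{k+1}" for k in range(pca.n_components)],
                "explained_fraction": pca.explained_fraction,
            }).to_csv(w.path(f"pc_explained_{label}.csv"), index=False,
                      float_format="%.10g", lineterminator="\n")
        emitted.extend(w.commit())
        manifest["stage_counts"]["pca"] = {
            label: int(m.sum()) for label, m in subsets.items()}

        # ------------------------------------------------------------ tree
        stage = "tree"
        w = _StageWriter(out)
        dm = popstruct.ibs_distance(filtered)
        tree = popstruct.neighbor_joining(dm)
        with open(w.path("nj_tree.nwk"), "w") as f:
            f.write(str(tree).strip() + "\n")
        emitted.extend(w.commit())

        # ------------------------------------------------------------ scan
        stage = "scan"
        w = _StageWriter(out)
        pca_all = pcas["all"]
        sig: dict[str, list] = {}
        tallies = {}
        for trait in (PROTEIN, STARCH):
            if trait not in traits.data.columns:
                log.warning("trait %s absent; scan skipped", trait)
                continue
            results = gene_effect.scan_trait(
                filtered, traits.data, trait, pca_all, config.pc_covariates)
            gene_effect.association_frame(results).to_csv(
                w.path(f"association_{trait}.csv"), index=False,
                float_format="%.10g", lineterminator="\n")
            sel = gene_effect.select_significant(
                results, config.scan_alpha, config.bh_correction)
            sig[trait] = sel
            summaries_g = gene_effect.aggregate_gene_effects(
                sel, include_flanking=config.include_flanking)
            gene_effect.gene_effect_frame(summaries_g).to_csv(
                w.path(f"gene_effects_{trait}.csv"), index=False,
                float_format="%.10g", lineterminator="\n")
            tallies[trait] = gene_effect.annotate_effect_classes(sel)
            manifest["stage_counts"][f"scan_{trait}"] = {
                "markers_tested": len(results), "significant": len(sel)}
        if tallies:
            pd.DataFrame(tallies).rename_axis("effect_class").to_csv(
                w.path("effect_class_tally.csv"), lineterminator="\n")
        if len(sig) == 2:
            overlap = gene_effect.pleiotropy_overlap(sig[PROTEIN], sig[STARCH])
            with open(w.path("pleiotropy.json"), "w") as f:
                json.dump({
                    "n_shared_snps": overlap.n_shared_snps,
                    "n_shared_genes": overlap.n_shared_genes,
                    "shared_snp_ids": overlap.shared_snp_ids,
                    "shared_gene_ids": overlap.shared_gene_ids,
                }, f, indent=1)
            manifest["stage_counts"]["pleiotropy"] = {
                "shared_snps": overlap.n_shared_snps,
                "shared_genes": overlap.n_shared_genes}
        emitted.extend(w.commit())

        # ------------------------------------------------------------ cluster
        stage = "cluster"
        w = _StageWriter(out)
        dend = popstruct.hier_cluster_pcs(pca_all, config.cluster_n_pcs)
        with open(w.path("pc_dendrogram.nwk"), "w") as f:
            f.write(dend.to_newick() + "\n")
        labels = dend.cut(config.cluster_k)
        labels.to_csv(w.path("cluster_labels.csv"), lineterminator="\n")
        for trait in (STARCH, PROTEIN, "seed_wrinkling", "seed_pattern"):
            if trait in traits.data.columns:
                rep = popstruct.align_clusters_with_trait(labels, traits.data, trait)
                rep.to_csv(w.path(f"alignment_{trait}.csv"), index=False,
                           float_format="%.10g", lineterminator="\n")
        emitted.extend(w.commit())

        # ------------------------------------------------------------ correlate
        stage = "correlate"
        w = _StageWriter(out)
        order = [PROTEIN, STARCH, "seed_shape", "seed_wrinkling",
                 "seed_size", "seed_color", "seed_pattern"]
        cols = [c for c in order if c in traits.analyzed_columns]
        if len(cols) >= 2:
            cm = trait_stats.correlation_matrix(traits, cols)
            cm.coef.to_csv(w.path("corr_coef.csv"), float_format="%.10g",
                           lineterminator="\n")
            cm.p.to_csv(w.path("corr_p.csv"), float_format="%.10g",
                        lineterminator="\n")
            cm.method.to_csv(w.path("corr_method.csv"), lineterminator="\n")
            cm.stars.to_csv(w.path("corr_stars.csv"), lineterminator="\n")
        for group_col in ("material_type", "continent"):
            if group_col in traits.data.columns:
                trait_stats.descriptives_by_group(traits, group_col).to_csv(
                    w.path(f"descriptives_{group_col}.csv"), index=False,
                    float_format="%.10g", lineterminator="\n")
        emitted.extend(w.commit())

    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()

    manifest["timestamps"]["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    for p in sorted(set(emitted)):
        if p.exists():
            manifest["files"][str(p.relative_to(out))] = {"sha256": _sha256(p)}
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    report(out)
    return manifest


def report(run_dir) -> Path:
    """Assemble a human-readable summary from emitted stage files."""
    run_dir = Path(run_dir)
    lines: list[str] = ["peagene run report", "=" * 40, ""]

    def section(title: str, filename: str, fmt=None) -> None:
        path = run_dir / filename
        lines.append(title)
        lines.append("-" * len(title))
        if not path.exists():
            lines.append(f"[missing: {filename} — section skipped]\n")
            return
        if filename.endswith(".json"):
            lines.append(path.read_text().strip())
        else:
            try:
                df = pd.read_csv(path)
            except pd.errors.EmptyDataError:
                df = pd.DataFrame()
            if fmt is not None and len(df):
                df = fmt(df)
            lines.append(df.to_string(index=False) if len(df.columns) else "[no rows]")
        lines.append("")

    section("Variants and selected SNPs per chromosome", "summary_per_chromosome.csv")
    section("SNPs per gene", "summary_per_gene.csv")
    section("SNPs per region category", "summary_per_category.csv")
    section("Effect classes by chromosome", "summary_effect_by_chrom.csv")
    section("Explained variance (all SNPs)", "pc_explained_all.csv")
    for trait in (PROTEIN, STARCH):
        section(
            f"Gene effects on {trait} (sorted by significant SNP count)",
            f"gene_effects_{trait}.csv",
        )
    section("Significant-SNP effect-class tally", "effect_class_tally.csv")
    section("Pleiotropy overlap", "pleiotropy.json")
    section("Trait correlation matrix", "corr_coef.csv")
    section("Significance codes", "corr_stars.csv")
    for trait in (STARCH, "seed_wrinkling"):
        section(f"Cluster alignment: {trait}", f"alignment_{trait}.csv")

    out = run_dir / "report.txt"
    out.write_text("\n".join(lines))
    return out
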