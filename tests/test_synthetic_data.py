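"""Generator contracts: gene maps, genotype frequencies, phenotype truth,
morphology linkage, and lossless serialization."""

import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from peagene import synthetic_data as sd
from peagene import trait_stats as ts
from peagene import variant_io as vio
from peagene import gene_effect as ge
from peagene import popstruct as ps
from peagene.trait_stats import TraitTable


def cfg(**kw):
    base = dict(chrom_gene_counts=(1, 1, 1, 1, 1, 1, 1), seed=1)
    base.update(kw)
    return sd.SimulationConfig(**base)


class TestGeneMap:
    def test_study_counts(self):
        m = sd.simulate_gene_map(cfg(chrom_gene_counts=(14, 2, 12, 3, 14, 12, 1)))
        assert len(m) == 58
        assert m.table["chrom"].nunique() == 7
        counts = m.table.groupby("chrom").size()
        assert counts["chr1"] == 14 and counts["chr7"] == 1

    def test_single_gene(self):
        m = sd.simulate_gene_map(cfg(chrom_gene_counts=(1, 0, 0, 0, 0, 0, 0)))
        assert len(m) == 1
        assert m.table.iloc[0]["chrom"] == "chr1"

    def test_non_overlapping_intervals(self):
        m = sd.simulate_gene_map(cfg(chrom_gene_counts=(5, 5, 5, 5, 5, 5, 5)))
        for _, sub in m.table.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    def test_deterministic_under_seed(self):
        c = cfg(chrom_gene_counts=(5, 5, 5, 5, 5, 5, 5), seed=3)
        m1 = sd.simulate_gene_map(c)
        m2 = sd.simulate_gene_map(c)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_both_categories_present(self):
        m = sd.simulate_gene_map(cfg(chrom_gene_counts=(14, 2, 12, 3, 14, 12, 1)))
        cats = set(m.table["category"])
        assert cats == {vio.STORAGE_PROTEIN, vio.STARCH_ENZYME}

    def test_invalid_counts_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_gene_map(cfg(chrom_gene_counts=(1, 1)))


class TestGenotypes:
    def test_no_missing_when_rate_zero(self):
        c = cfg(missing_rate=0.0, snps_per_gene=(5, 0.0), n_accessions=20)
        g = sd.simulate_genotypes(sd.simulate_gene_map(c), c)
        assert not np.isnan(g.dosage).any()

    def test_fst_limit_no_divergence(self):
        c = cfg(fst_like=1e-6, n_subpops=3, n_accessions=300,
                snps_per_gene=(100, 0.0), flank_snps_mean=0.0, missing_rate=0.0)
        g = sd.simulate_genotypes(sd.simulate_gene_map(c), c)
        sub = g._subpop.to_numpy()
        freqs = np.stack([
            g.dosage[sub == s].mean(axis=0) / 2 for s in range(3)
        ])
        # between-subpop variance of allele frequency ~ binomial sampling only
        assert freqs.var(axis=0).mean() < 0.005

    def test_mean_maf_matches_target(self):
        c = cfg(
            chrom_gene_counts=(15, 15, 15, 15, 15, 15, 10),
            snps_per_gene=(100, 0.0), flank_snps_mean=0.0,
            maf_range=(0.3, 0.3), maf_widen_low=1.0,
            missing_rate=0.0, n_accessions=200, fst_like=0.001, seed=5,
        )
        g = sd.simulate_genotypes(sd.simulate_gene_map(c), c)
        maf, _ = vio.compute_maf(g)
        assert g.n_markers == 10_000
        assert abs(maf.mean() - 0.3) < 0.01

    def test_every_marker_assigned(self):
        c = cfg(snps_per_gene=(10, 1.0), flank_snps_mean=3)
        g = sd.simulate_genotypes(sd.simulate_gene_map(c), c)
        assert all(m.gene_id is not None for m in g.markers)
        cats = {m.region_category for m in g.markers}
        assert cats <= {vio.STORAGE_PROTEIN, vio.STARCH_ENZYME, vio.FLANKING}


class TestPhenotypes:
    def test_zero_effects_constant(self):
        c = cfg(noise_sd={sd.PROTEIN: 1e-9, sd.STARCH: 1e-9},
                snps_per_gene=(3, 0.0), n_accessions=30)
        gm = sd.simulate_gene_map(c)
        g = sd.simulate_genotypes(gm, c)
        t = sd.simulate_phenotypes(g, gm, c)
        assert t.data[sd.PROTEIN].std() < 1e-6
        assert t.data[sd.PROTEIN].mean() == pytest.approx(25.54, abs=1e-6)

    def test_single_marker_dosage_contrast(self):
        c = cfg(chrom_gene_counts=(1, 0, 0, 0, 0, 0, 0), snps_per_gene=(1, 0.0),
                flank_snps_mean=0.0, missing_rate=0.0, n_accessions=200,
                noise_sd={sd.PROTEIN: 1e-9, sd.STARCH: 1e-9},
                maf_range=(0.4, 0.495))
        gm = sd.simulate_gene_map(c)
        g = sd.simulate_genotypes(gm, c)
        b = 2.5
        c2 = dataclasses.replace(c, gene_effects={sd.PROTEIN: {gm.gene_ids[0]: b}})
        t = sd.simulate_phenotypes(g, gm, c2)
        d = vio.recode_major_minor(g).dosage[:, 0]  # effect acts on minor dosage
        y = t.data[sd.PROTEIN].to_numpy()
        assert y[d == 2].mean() - y[d == 0].mean() == pytest.approx(2 * b, abs=1e-6)

    def test_unknown_causal_gene_rejected(self):
        c = cfg(gene_effects={sd.PROTEIN: {"not_a_gene": 1.0}})
        gm = sd.simulate_gene_map(c)
        g = sd.simulate_genotypes(gm, c)
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_phenotypes(g, gm, c)

    def test_stage1_recovers_effect_within_3se(self):
        c = cfg(chrom_gene_counts=(2, 1, 1, 1, 1, 1, 1), snps_per_gene=(1, 0.0),
                flank_snps_mean=0.0, missing_rate=0.0, n_accessions=500,
                noise_sd={sd.PROTEIN: 2.0, sd.STARCH: 2.0}, fst_like=0.05,
                seed=17)
        gm = sd.simulate_gene_map(c)
        g = sd.simulate_genotypes(gm, c)
        causal = gm.gene_ids[0]
        c2 = dataclasses.replace(c, gene_effects={sd.PROTEIN: {causal: 3.0}})
        t = sd.simulate_phenotypes(g, gm, c2)
        g = vio.recode_major_minor(g)  # scan on minor-allele coding
        centered, _ = ps.impute_and_center(g)
        pca = ps.run_pca(centered, 2, g.accession_ids)
        res = ge.scan_trait(g, t.data, sd.PROTEIN, pca)
        hit = next(r for r in res
                   if next(m for m in g.markers
                           if m.marker_id == r.marker_id).gene_id == causal)
        assert abs(hit.beta_hat - 3.0) < 3 * hit.se


class TestMorphology:
    def _traits(self, n, seed=0):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame({sd.STARCH: rng.normal(40, 4, n)},
                            index=[f"A{i}" for i in range(n)])
        return TraitTable(data, {sd.STARCH: ts.CONTINUOUS})

    def _realized_r(self, traits):
        r, _ = ts.point_biserial(
            traits.data["seed_wrinkling"], traits.data[sd.STARCH],
            name="seed_wrinkling")
        return r

    def test_zero_target(self):
        c = cfg(morphology_link=sd.MorphologyLink(target_r=0.0))
        out = sd.simulate_morphology(self._traits(1000), c)
        assert abs(self._realized_r(out)) < 0.1

    def test_paper_target_within_band(self):
        c = cfg(morphology_link=sd.MorphologyLink(target_r=-0.71), seed=2)
        out = sd.simulate_morphology(self._traits(2000, seed=2), c)
        assert -0.76 <= self._realized_r(out) <= -0.66

    def test_deterministic_latent_attains_split_maximum(self):
        # target at the attainability bound -> rho = -1, latent = -z exactly
        q = 0.5
        bound = -sd.max_attainable_biserial(q)
        c = cfg(morphology_link=sd.MorphologyLink(target_r=bound,
                                                  wrinkled_fraction=q))
        traits = self._traits(1500, seed=9)
        out = sd.simulate_morphology(traits, c)
        y = out.data[sd.STARCH].to_numpy()
        b = (out.data["seed_wrinkling"] == "wrinkled").to_numpy().astype(float)
        p1 = b.mean()
        closed_form = (y[b == 1].mean() - y[b == 0].mean()) * np.sqrt(
            p1 * (1 - p1)) / y.std()
        assert self._realized_r(out) == pytest.approx(closed_form, rel=1e-10)
        # and it is the most negative value any 0/1 assignment of this size
        # can achieve: the wrinkled set is exactly the lowest-starch half
        assert set(np.flatnonzero(b)) == set(np.argsort(y)[: int(b.sum())])

    def test_unattainable_target_rejected(self):
        c = cfg(morphology_link=sd.MorphologyLink(target_r=-0.9,
                                                  wrinkled_fraction=0.2))
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_morphology(self._traits(100), c)

    def test_all_columns_typed(self):
        c = cfg()
        out = sd.simulate_morphology(self._traits(200), c)
        for col in ("seed_wrinkling", "seed_shape", "seed_size",
                    "seed_color", "seed_pattern"):
            assert col in out.data.columns
            assert col in out.types


class TestSerialization:
    def test_roundtrip_dosage_and_classes(self, small_dataset, tmp_path):
        paths = sd.write_dataset(small_dataset, tmp_path / "ds")
        matrix, gene_map, traits, truth = sd.read_dataset(tmp_path / "ds")
        g = small_dataset.genotypes
        np.testing.assert_array_equal(
            np.nan_to_num(matrix.dosage, nan=-9), np.nan_to_num(g.dosage, nan=-9))
        assert [m.pos for m in matrix.markers] == [m.pos for m in g.markers]
        assert [m.effect_class for m in matrix.markers] == [
            m.effect_class for m in g.markers]
        assert truth["gene_effects"] == small_dataset.truth
        pd.testing.assert_frame_equal(
            traits.data, small_dataset.traits.data, check_exact=False)

    def test_indels_counted_not_in_matrix(self, small_dataset, tmp_path):
        sd.write_dataset(small_dataset, tmp_path / "ds")
        matrix, _, indels = vio.read_vcf(tmp_path / "ds" / "genotypes.vcf")
        assert len(indels) == len(small_dataset.indels)
        assert matrix.n_markers == small_dataset.genotypes.n_markers

    def test_byte_identical_across_runs(self, tmp_path):
        c = cfg(snps_per_gene=(8, 1.0), n_indels=5, n_accessions=25, seed=77,
                gene_effects={})
        for d in ("x", "y"):
            sd.write_dataset(sd.simulate(c), tmp_path / d)
        for name in ("genotypes.vcf", "gene_map.bed", "traits.csv",
                     "trait_types.json", "truth.json"):
            assert filecmp.cmp(tmp_path / "x" / name, tmp_path / "y" / name,
                               shallow=False), name

    def test_empty_marker_vcf_valid(self, tmp_path):
        c = cfg(n_accessions=4)
        gm = sd.simulate_gene_map(c)
        empty = vio.GenotypeMatrix(
            ["PS001", "PS002", "PS003", "PS004"], [], np.empty((4, 0)))
        empty._subpop = pd.Series([0, 0, 0, 0], index=empty.accession_ids)
        ds = sd.SimulatedDataset(
            genotypes=empty, gene_map=gm,
            traits=TraitTable(
                pd.DataFrame({sd.PROTEIN: [25.0] * 4},
                             index=pd.Index(empty.accession_ids,
                                            name="accession_id")),
                {sd.PROTEIN: ts.CONTINUOUS}),
            truth={}, subpop_labels=empty._subpop,
            indels=pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
            indel_dosage=np.empty((4, 0)), config=c,
        )
        sd.write_dataset(ds, tmp_path / "empty")
        matrix, _, indels = vio.read_vcf(tmp_path / "empty" / "genotypes.vcf")
        assert matrix.n_markers == 0
        assert len(indels) == 0


class TestScaleRoundTrip:
    def test_study_scale_counts_match(self, tmp_path):
        """At study scale (~7.7k SNPs, ~1.1k InDels over 100 accessions),
        the VCF reader recovers exactly the write-side totals."""
        c = sd.SimulationConfig(seed=4, n_indels=1131)
        ds = sd.simulate(c)
        sd.write_dataset(ds, tmp_path / "big")
        matrix, _, indels = vio.read_vcf(tmp_path / "big" / "genotypes.vcf")
        assert matrix.n_markers == ds.genotypes.n_markers
        assert len(indels) == 1131
        assert 5000 < matrix.n_markers < 11000
        filtered = vio.filter_markers(matrix)
        assert 1500 < filtered.n_markers < matrix.n_markers
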