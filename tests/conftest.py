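import numpy as np
import pytest

from peagene import synthetic_data as sd
from peagene.variant_io import GenotypeMatrix, VariantRecord


def make_matrix(dosage, accession_ids=None, chrom="chr1"):
    """GenotypeMatrix from a plain dosage array (NaN = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = accession_ids or [f"A{i}" for i in range(n)]
    markers = [
        VariantRecord(chrom=chrom, pos=100 * (j + 1), ref="A", alt="T",
                      marker_id=f"m{j}")
        for j in range(m)
    ]
    return GenotypeMatrix(ids, markers, dosage)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest structured dataset with causal genes, reused across tests."""
    cfg = sd.SimulationConfig(
        n_accessions=80,
        chrom_gene_counts=(3, 1, 2, 1, 3, 2, 1),
        snps_per_gene=(15, 2.0),
        flank_snps_mean=4,
        n_indels=25,
        fst_like=0.12,
        n_subpops=2,
        seed=20_001,
    )
    gm = sd.simulate_gene_map(cfg)
    causal_p = gm.gene_ids[0]
    causal_s = gm.gene_ids[1]
    import dataclasses

    cfg = dataclasses.replace(
        cfg,
        gene_effects={
            sd.PROTEIN: {causal_p: 4.0},
            sd.STARCH: {causal_s: 4.0, causal_p: -3.0},
        },
        snps_per_gene_overrides={causal_p: 2, causal_s: 2},
    )
    return sd.simulate(cfg)
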