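"""Two-stage gene-to-phenotype regression.

Stage 1 fits, separately per SNP, the linear model

    y_i = mu + beta * g_i + gamma1 * PC1_i + gamma2 * PC2_i + eps_i

with g the 0/1/2 minor-allele dosage and PC1/PC2 population-structure
covariates; eps ~ N(0, sigma^2). Markers with two-sided p < alpha (raw 0.05
by default, no multiple-testing correction) are mapped to their genes, and
stage 2 aggregates per gene with inverse-variance weights w_j = 1/SE_j^2:

    E_g  = sum(w_j beta_j) / sum(w_j)
    SD_g = sqrt( sum(w_j (beta_j - E_g)^2) / sum(w_j) )

SD_g is the weighted root-mean-square deviation; a gene backed by a single
significant SNP reports SD_g = 0 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popstruct import PCAResult
from .variant_io import GenotypeMatrix

log = logging.getLogger(__name__)

#: cap on inverse-variance weights when SE -> 0 (perfect fits)
DEFAULT_W_MAX = 1e12


class MonomorphicMarkerError(ValueError):
    """Dosage constant over complete cases; slope not identifiable."""


class RankDeficientError(ValueError):
    """Design matrix collinear; fit skipped."""


@dataclass
class AssociationResult:
    marker_id: str
    trait: str
    beta_hat: float
    se: float
    t_stat: float
    p_value: float
    n_used: int
    gene_id: str | None = None
    region_category: str | None = None
    effect_class: str = "UNANNOTATED"


@dataclass
class GeneEffectSummary:
    gene_id: str
    trait: str
    n_sig_snps: int
    Eg: float
    SDg: float


@dataclass
class PleiotropySummary:
    shared_snp_ids: list[str]
    shared_gene_ids: list[str]

    @property
    def n_shared_snps(self) -> int:
        return len(self.shared_snp_ids)

    @property
    def n_shared_genes(self) -> int:
        return len(self.shared_gene_ids)


def fit_snp_model(
    y: np.ndarray,
    g: np.ndarray,
    pc1: np.ndarray | None = None,
    pc2: np.ndarray | None = None,
    marker_id: str = "",
    trait: str = "",
) -> AssociationResult:
    """OLS of y on [1, g, PC1, PC2] over complete cases.

    Complete cases are rows where both y and g are non-missing (covariates
    are assumed complete). The dosage coefficient, its standard error from
    the design inverse, the t statistic, and a two-sided p-value on
    n_used - p degrees of freedom are returned.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    cols = [np.ones_like(y), g]
    if pc1 is not None:
        cols.append(np.asarray(pc1, dtype=float))
    if pc2 is not None:
        cols.append(np.asarray(pc2, dtype=float))
    X = np.column_stack(cols)
    ok = np.isfinite(y) & np.isfinite(g)
    y, X = y[ok], X[ok]
    n, p = X.shape
    if n < max(6, p + 1):
        raise ValueError(f"only {n} complete cases; need at least {max(6, p + 1)}")
    if np.ptp(X[:, 1]) == 0:
        raise MonomorphicMarkerError(marker_id or "marker constant over complete cases")
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise RankDeficientError(marker_id or "collinear design")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - p
    s2 = float(resid @ resid) / df
    se = float(np.sqrt(max(s2, 0.0) * XtX_inv[1, 1]))
    b = float(beta[1])
    if se == 0.0:
        t = np.inf if b != 0 else 0.0
        pval = 0.0 if b != 0 else 1.0
    else:
        t = b / se
        pval = float(2.0 * stats.t.sf(abs(t), df))
    pval = min(max(pval, np.finfo(float).tiny), 1.0)
    return AssociationResult(
        marker_id=marker_id, trait=trait, beta_hat=b, se=se,
        t_stat=float(t), p_value=pval, n_used=int(n),
    )


def scan_trait(
    matrix: GenotypeMatrix,
    traits: pd.DataFrame,
    trait_name: str,
    pca: PCAResult | None = None,
    n_pc_covariates: int = 2,
) -> list[AssociationResult]:
    """Stage-1 scan: one model fit per marker, in marker order.

    Monomorphic or rank-deficient markers are skipped with a log entry.
    ``pca=None`` (or ``n_pc_covariates=0``) fits the model without
    structure covariates.
    """
    if trait_name not in traits.columns:
        raise KeyError(f"trait {trait_name!r} not in trait table")
    y = traits.loc[matrix.accession_ids, trait_name].to_numpy(dtype=float)
    pcs: list[np.ndarray | None] = [None, None]
    if pca is not None and n_pc_covariates > 0:
        sc = pca.scores.loc[matrix.accession_ids]
        for k in range(min(n_pc_covariates, pca.n_components, 2)):
            pcs[k] = sc.iloc[:, k].to_numpy()
    results: list[AssociationResult] = []
    for j, marker in enumerate(matrix.markers):
        try:
            res = fit_snp_model(
                y, matrix.dosage[:, j], pcs[0], pcs[1],
                marker_id=marker.marker_id, trait=trait_name,
            )
        except (MonomorphicMarkerError, RankDeficientError, ValueError) as exc:
            log.info("skipping marker %s: %s", marker.marker_id, exc)
            continue
        res.gene_id = marker.gene_id
        res.region_category = marker.region_category
        res.effect_class = marker.effect_class
        results.append(res)
    return results


def select_significant(
    results: list[AssociationResult],
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[AssociationResult]:
    """Keep results with p < alpha (strict).

    By default p-values are raw, matching the analysis this package mirrors;
    ``bh_correction=True`` applies Benjamini-Hochberg and selects on the
    adjusted values instead.
    """
    if not results:
        return []
    p = np.array([r.p_value for r in results])
    if bh_correction:
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, p[i] * m / (rank_idx + 1))
            adj[i] = prev
        p = adj
    return [r for r, pv in zip(results, p) if pv < alpha]


def aggregate_gene_effects(
    sig: list[AssociationResult],
    w_max: float = DEFAULT_W_MAX,
    include_flanking: bool = True,
) -> list[GeneEffectSummary]:
    """Stage 2: inverse-variance-weighted gene effects from significant SNPs.

    SNPs without a gene assignment are ignored; flanking-region SNPs inherit
    their assigned gene unless ``include_flanking=False``. Weights are
    1/SE^2, capped at ``w_max`` (a perfect-fit SE of 0 would otherwise
    swamp the gene).
    """
    buckets: dict[tuple[str, str], list[AssociationResult]] = {}
    for r in sig:
        if r.gene_id is None:
            continue
        if not include_flanking and r.region_category == "flanking":
            continue
        buckets.setdefault((r.gene_id, r.trait), []).append(r)
    out: list[GeneEffectSummary] = []
    for (gene, trait), rs in sorted(buckets.items()):
        b = np.array([r.beta_hat for r in rs])
        se = np.array([r.se for r in rs])
        with np.errstate(divide="ignore"):
            w = np.where(se > 0, 1.0 / se**2, np.inf)
        if np.any(w > w_max):
            log.warning("gene %s/%s: capping %d weight(s) at w_max=%g",
                        gene, trait, int((w > w_max).sum()), w_max)
            w = np.minimum(w, w_max)
        Eg = float(np.sum(w * b) / np.sum(w))
        if len(rs) == 1:
            SDg = 0.0
        else:
            SDg = float(np.sqrt(np.sum(w * (b - Eg) ** 2) / np.sum(w)))
        out.append(GeneEffectSummary(gene, trait, len(rs), Eg, SDg))
    return out


def pleiotropy_overlap(
    sig_a: list[AssociationResult], sig_b: list[AssociationResult]
) -> PleiotropySummary:
    """SNPs significant for both traits, and the genes they map to."""
    ids_a = {r.marker_id for r in sig_a}
    gene_of = {r.marker_id: r.gene_id for r in sig_a + sig_b}
    shared = sorted(ids_a & {r.marker_id for r in sig_b})
    genes = sorted({gene_of[m] for m in shared if gene_of[m] is not None})
    return PleiotropySummary(shared, genes)


def annotate_effect_classes(sig: list[AssociationResult]) -> pd.Series:
    """Tally of significant markers per predicted-impact class."""
    order = ["HIGH", "MODERATE", "LOW", "MODIFIER", "UNANNOTATED"]
    counts = pd.Series(0, index=order, name="n_snps")
    for r in sig:
        key = r.effect_class if r.effect_class in counts.index else "UNANNOTATED"
        counts[key] += 1
    return counts


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Per-SNP association table in the exported CSV shape."""
    return pd.DataFrame(
        [
            {
                "marker_id": r.marker_id, "trait": r.trait,
                "beta_hat": r.beta_hat, "se": r.se, "t_stat": r.t_stat,
                "p_value": r.p_value, "n_used": r.n_used,
                "gene_id": r.gene_id, "region_category": r.region_category,
                "effect_class": r.effect_class,
            }
            for r in results
        ]
    )


def gene_effect_frame(summaries: list[GeneEffectSummary]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id, "trait": s.trait,
                "n_sig_snps": s.n_sig_snps, "Eg": s.Eg, "SDg": s.SDg,
            }
            for s in summaries
        ]
    )
    if len(df):
        df = df.sort_values(
            ["trait", "n_sig_snps", "gene_id"], ascending=[True, False, True]
        ).reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=["gene_id", "trait", "n_sig_snps", "Eg", "SDg"])
    return df
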