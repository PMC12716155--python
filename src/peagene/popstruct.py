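"""Population-structure computations on the dosage matrix.

PCA on mean-imputed, centered dosages; identity-by-state distances; a
neighbor-joining tree of accessions; Ward clustering of PC scores; and
alignment of cluster memberships with phenotypes (the dendrogram-vs-trait
comparison used to relate marker profiles to protein and starch content).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from skbio import DistanceMatrix, TreeNode

from .variant_io import GenotypeMatrix


@dataclass
class PCAResult:
    scores: pd.DataFrame        # accessions x PC1..PCk
    explained_fraction: np.ndarray
    marker_subset_label: str = "all"

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class Dendrogram:
    """Rooted agglomerative merge sequence over accessions (scipy linkage)."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> pd.Series:
        if k > len(self.labels):
            raise ValueError(f"k={k} exceeds {len(self.labels)} accessions")
        memb = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(memb, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Rooted Newick with merge heights converted to branch lengths."""
        root = sch.to_tree(self.linkage)

        def walk2(node):
            if node.is_leaf():
                return self.labels[node.id], 0.0
            l_str, l_h = walk2(node.left)
            r_str, r_h = walk2(node.right)
            return (
                f"({l_str}:{node.dist - l_h:.10g},{r_str}:{node.dist - r_h:.10g})",
                node.dist,
            )

        s, _ = walk2(root)
        return s + ";"


def impute_and_center(matrix: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Mean-impute missing dosages per marker, then mean-center columns.

    Markers with all calls missing are dropped with a warning; monomorphic
    markers become zero columns (retained). Returns the numeric matrix and
    the ids of the retained markers.
    """
    d = matrix.dosage.copy()
    n_nonmiss = np.sum(~np.isnan(d), axis=0)
    keep = n_nonmiss > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} all-missing markers before PCA")
    d = d[:, keep]
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(col_mean, inds[1])
    d -= d.mean(axis=0)
    ids = [m for m, k in zip(matrix.marker_ids, keep) if k]
    return d, ids


def run_pca(
    centered: np.ndarray,
    n_components: int = 10,
    accession_ids: list[str] | None = None,
    marker_subset_label: str = "all",
) -> PCAResult:
    """PCA by SVD of the centered matrix.

    explained_fraction_k = sigma_k^2 / sum(sigma^2). Sign convention: the
    largest-|loading| entry of each right singular vector is made positive,
    so score files are reproducible across SVD implementations.
    """
    X = np.asarray(centered, dtype=float)
    n, p = X.shape
    rank = min(n, p)
    if n_components > rank:
        warnings.warn(f"n_components={n_components} > rank bound {rank}; truncating")
        n_components = rank
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U[:, :n_components] * s[:n_components]
    total = float(np.sum(s**2))
    frac = (s[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    idx = accession_ids if accession_ids is not None else list(range(n))
    df = pd.DataFrame(
        scores, index=idx, columns=[f"PC{k+1}" for k in range(n_components)]
    )
    return PCAResult(df, frac, marker_subset_label)


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean identity-by-state over pairwise non-missing markers.

    IBS similarity per marker pair is 1 - |d_i - d_j| / 2 (1 for identical
    genotypes, 0 for opposite homozygotes). A pair of accessions sharing no
    non-missing marker is a hard error.
    """
    d = matrix.dosage
    n = matrix.n_accessions
    miss = np.isnan(d)
    dz = np.where(miss, 0.0, d)
    ok = (~miss).astype(float)
    # sum over shared markers of |di - dj| via |a-b| = a + b - 2*min; do it blockwise
    dist = np.zeros((n, n))
    shared = ok @ ok.T
    for i in range(n):
        diff = np.abs(dz[i] - dz)          # (n, m); garbage where either missing
        both = ok[i] * ok                  # (n, m)
        num = np.sum(diff * both, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i] = num / (2.0 * shared[i])
    if np.any(shared + np.eye(n) * 1 == 0) or np.any(~np.isfinite(dist)):
        bad = np.argwhere(~np.isfinite(dist))
        i, j = bad[0]
        raise ValueError(
            f"accessions {matrix.accession_ids[i]!r} and "
            f"{matrix.accession_ids[j]!r} share zero non-missing markers"
        )
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # kill float asymmetry
    return DistanceMatrix(dist, ids=[str(a) for a in matrix.accession_ids])


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Branch lengths use the standard formulas; a negative length is clamped
    to zero with the deficit transferred to the sister branch, which keeps
    the Newick output valid and total path lengths intact. The returned
    tree is unrooted (trifurcating root node).
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)
    D = dm.data.astype(float).copy()
    if np.any(D < 0):
        raise ValueError("distance matrix has negative entries")
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]

    def _join(ci: TreeNode, cj: TreeNode, li: float, lj: float) -> TreeNode:
        # clamp-and-transfer for negative branch lengths
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ci.length = float(max(li, 0.0))
        cj.length = float(max(lj, 0.0))
        return TreeNode(children=[ci, cj])

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        new = _join(nodes[i], nodes[j], li, lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D = np.delete(np.delete(D, (i, j), axis=0), (i, j), axis=1)
        dnew = np.delete(dnew, (i, j))
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = dnew
        D[:-1, -1] = dnew
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [new]

    # resolve the final three nodes with the three-point formulas
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    lengths = [la, lb, lc]
    # clamp-and-transfer pairwise: move any deficit to the largest sibling
    for k in range(3):
        if lengths[k] < 0:
            big = int(np.argmax(lengths))
            lengths[big] += lengths[k]
            lengths[k] = 0.0
    for node, ln in zip(nodes, lengths):
        node.length = float(max(ln, 0.0))
    return TreeNode(children=nodes)


def hier_cluster_pcs(pca: PCAResult, n_pcs: int = 2) -> Dendrogram:
    """Ward-linkage agglomeration on Euclidean distances over PC scores.

    Mirrors the dendrograms built from the first two PCs of the SNP matrix
    and later aligned with protein/starch values.
    """
    if n_pcs > pca.n_components:
        raise ValueError(f"n_pcs={n_pcs} > available components {pca.n_components}")
    X = pca.scores.iloc[:, :n_pcs].to_numpy()
    Z = sch.linkage(X, method="ward")
    return Dendrogram(Z, [str(i) for i in pca.scores.index])


def align_clusters_with_trait(
    labels: pd.Series, traits: pd.DataFrame, trait_name: str
) -> pd.DataFrame:
    """Per-cluster summary of one trait, flagging the extreme cluster.

    Continuous traits report n/mean/min/max; binary (two-level) traits
    additionally report the count and fraction of the higher-coded level.
    The cluster whose mean is farthest from the grand mean is flagged
    ``extreme``.
    """
    if trait_name not in traits.columns:
        raise KeyError(f"trait {trait_name!r} not in trait table")
    df = traits.loc[labels.index]
    y = df[trait_name]
    levels = pd.unique(y.dropna())
    binary = len(levels) == 2
    if binary and not pd.api.types.is_numeric_dtype(y):
        coding = {lv: i for i, lv in enumerate(sorted(map(str, levels)))}
        y = y.map(lambda v: coding.get(str(v), np.nan))
    rows = []
    for c, idx in labels.groupby(labels).groups.items():
        yc = y.loc[idx].dropna()
        row = {
            "cluster": c,
            "n": int(len(yc)),
            "mean": float(yc.mean()) if len(yc) else np.nan,
            "min": float(yc.min()) if len(yc) else np.nan,
            "max": float(yc.max()) if len(yc) else np.nan,
        }
        if binary:
            row["n_positive"] = int((yc == 1).sum())
            row["frac_positive"] = row["n_positive"] / len(yc) if len(yc) else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    grand = float(y.dropna().mean())
    dev = (out["mean"] - grand).abs()
    out["extreme"] = dev == dev.max()
    return out
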