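"""Mixed-type trait correlation matrix and group descriptives.

Dispatch per unordered type pair:

* continuous-continuous: Pearson r (t-transform p, n-2 df)
* continuous-binary: point-biserial r (Pearson on 0/1 coding)
* continuous-multicat: sqrt(eta-squared) from one-way ANOVA (F-test p)
* categorical-categorical: Cramér's V (uncorrected chi-square p)

The method and significance code of each cell are reported alongside the
coefficient, since the coefficients are not mutually comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONTINUOUS = "continuous"
BINARY = "binary"
MULTICAT = "multicat"

#: which level codes as 1 for the binary traits this package generates;
#: other binary columns default to the lexicographically larger level.
POSITIVE_LEVELS = {
    "seed_wrinkling": "wrinkled",
    "seed_pattern": "patterned",
    "seed_shape": "non_round",
}


@dataclass
class TraitTable:
    """Per-accession phenotypes with a declared type for each analyzed column."""

    data: pd.DataFrame  # indexed by accession_id
    types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = {t for t in self.types.values()} - {CONTINUOUS, BINARY, MULTICAT}
        if unknown:
            raise ValueError(f"unknown declared types: {unknown}")

    def declared(self, col: str) -> str:
        if col not in self.types:
            raise KeyError(f"no declared type for column {col!r}")
        return self.types[col]

    @property
    def analyzed_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in self.types]


@dataclass
class CorrMatrix:
    coef: pd.DataFrame
    p: pd.DataFrame
    method: pd.DataFrame
    stars: pd.DataFrame


def _complete(x: pd.Series, y: pd.Series) -> tuple[pd.Series, pd.Series]:
    ok = x.notna() & y.notna()
    return x[ok], y[ok]


def encode_binary(b: pd.Series, name: str | None = None) -> tuple[np.ndarray, dict]:
    """0/1-encode a two-level variable; the mapping is returned because the
    sign of a point-biserial coefficient depends on it."""
    levels = sorted(map(str, pd.unique(b.dropna().astype(str))))
    if len(levels) != 2:
        raise ValueError(f"binary column has {len(levels)} levels: {levels}")
    pos = POSITIVE_LEVELS.get(name or (b.name or ""), levels[1])
    if pos not in levels:
        pos = levels[1]
    coding = {lv: (1.0 if lv == pos else 0.0) for lv in levels}
    return b.astype(str).map(coding).to_numpy(dtype=float), coding


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided t-test p, pairwise-complete."""
    x, y = _complete(pd.Series(x).reset_index(drop=True), pd.Series(y).reset_index(drop=True))
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x.to_numpy(dtype=float), y.to_numpy(dtype=float))
    return float(r), float(p)


def point_biserial(b, y, name: str | None = None) -> tuple[float, float]:
    """Point-biserial correlation: Pearson on the 0/1-encoded binary."""
    b = pd.Series(b).reset_index(drop=True)
    y = pd.Series(y).reset_index(drop=True)
    b, y = _complete(b, y)
    enc, _ = encode_binary(b, name)
    return pearson(enc, y.to_numpy(dtype=float))


def anova_eta2(groups, y) -> tuple[float, float, float, float]:
    """One-way ANOVA effect size: returns (eta2, sqrt(eta2), F, p).

    eta2 = SS_between / SS_total; F on (k-1, n-k) df.
    """
    g = pd.Series(groups).reset_index(drop=True).astype(str)
    y = pd.Series(y).reset_index(drop=True).astype(float)
    g, y = _complete(g, y)
    levels = pd.unique(g)
    k, n = len(levels), len(y)
    if k < 2:
        raise ValueError("need at least 2 groups")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("all observations identical; eta-squared undefined")
    ss_between = 0.0
    for lv in levels:
        yl = y[g == lv]
        ss_between += len(yl) * float((yl.mean() - grand) ** 2)
    eta2 = ss_between / ss_total
    df1, df2 = k - 1, n - k
    if df2 <= 0:
        raise ValueError("no within-group degrees of freedom")
    ss_within = ss_total - ss_between
    if ss_within <= 0:
        F, p = np.inf, 0.0
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p = float(stats.f.sf(F, df1, df2))
    return float(eta2), float(np.sqrt(eta2)), float(F), float(p)


def cramers_v(a, b) -> tuple[float, float, float]:
    """Cramér's V with uncorrected chi-square: returns (V, chi2, p)."""
    a = pd.Series(a).reset_index(drop=True).astype(str)
    b = pd.Series(b).reset_index(drop=True).astype(str)
    a, b = _complete(a, b)
    table = pd.crosstab(a, b)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (single row or column)")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    n = int(table.to_numpy().sum())
    denom = n * (min(table.shape) - 1)
    V = float(np.sqrt(chi2 / denom)) if denom > 0 else np.nan
    return V, float(chi2), float(p)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def correlation_matrix(traits: TraitTable, columns: list[str] | None = None) -> CorrMatrix:
    """Mixed-type correlation matrix over the declared trait columns."""
    cols = columns if columns is not None else traits.analyzed_columns
    for c in cols:
        traits.declared(c)  # raises on undeclared columns
    k = len(cols)
    coef = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    meth = pd.DataFrame([["self"] * k for _ in range(k)], index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = cols[i], cols[j]
            ta, tb = traits.declared(a), traits.declared(b)
            xa, xb = traits.data[a], traits.data[b]
            try:
                r, p, method = _pair_stat(xa, ta, a, xb, tb, b)
            except ValueError:
                r, p, method = np.nan, np.nan, "undefined"
            coef.iloc[i, j] = coef.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
            meth.iloc[i, j] = meth.iloc[j, i] = method
    stars = pmat.map(lambda p: _stars(p) if np.isfinite(p) else "NA")
    np.fill_diagonal(stars.values, "")
    return CorrMatrix(coef, pmat, meth, stars)


def _pair_stat(xa, ta, name_a, xb, tb, name_b) -> tuple[float, float, str]:
    pair = frozenset((ta, tb))
    if pair == {CONTINUOUS}:
        r, p = pearson(xa, xb)
        return r, p, "pearson"
    if pair == {CONTINUOUS, BINARY}:
        if ta == BINARY:
            r, p = point_biserial(xa, xb, name_a)
        else:
            r, p = point_biserial(xb, xa, name_b)
        return r, p, "point_biserial"
    if pair == {CONTINUOUS, MULTICAT}:
        g, y = (xa, xb) if ta == MULTICAT else (xb, xa)
        _, root_eta, _, p = anova_eta2(g, y)
        return root_eta, p, "sqrt_eta2"
    # both categorical (binary and/or multicat)
    V, _, p = cramers_v(xa, xb)
    return V, p, "cramers_v"


def descriptives_by_group(
    traits: TraitTable, group_col: str, value_cols: list[str] | None = None
) -> pd.DataFrame:
    """Per-group n/mean/min/max/SD for continuous traits.

    Group levels present in the declared categories but absent from the data
    are not invented; empty groups that do occur report n=0 and NaN stats.
    """
    if value_cols is None:
        value_cols = [c for c in traits.analyzed_columns if traits.declared(c) == CONTINUOUS]
    rows = []
    grouped = traits.data.groupby(traits.data[group_col].astype(str), dropna=False)
    for gname, sub in grouped:
        for col in value_cols:
            y = sub[col].dropna().astype(float)
            rows.append(
                {
                    "group": gname,
                    "trait": col,
                    "n": int(len(y)),
                    "mean": float(y.mean()) if len(y) else np.nan,
                    "min": float(y.min()) if len(y) else np.nan,
                    "max": float(y.max()) if len(y) else np.nan,
                    "sd": float(y.std(ddof=1)) if len(y) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
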