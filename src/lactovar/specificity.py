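"""Tissue-specificity t-statistics from a many-tissue expression compendium.

Expression is log2-transformed and Z-scored within each tissue, then each
gene is regressed on a +1/-1 target-tissue indicator (plus intercept and
optional covariates) by ordinary least squares; the indicator's t-statistic
measures how specific the gene is to the target tissue.  Samples whose
tissue category is related to the target (e.g., other mammary tissues when
testing lactating mammary) are excluded before fitting.  Specific genes are
the top fraction (default 10%) by t-statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TStatResult",
    "preprocess",
    "tissue_tstat",
    "top_fraction",
    "tstat_correlation",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-sample metadata.

    ``values`` index = gene IDs, columns = sample IDs; ``sample_meta`` is
    indexed by sample ID with at least ``tissue`` and ``category`` columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene IDs")
        if not set(self.values.columns) <= set(self.sample_meta.index):
            raise ValueError("every sample needs metadata")
        self.sample_meta = self.sample_meta.loc[self.values.columns]


def preprocess(
    expr: ExpressionMatrix, pseudo: float = 1e-3, center: str = "global"
) -> ExpressionMatrix:
    """log2(value + pseudo), then per-gene Z-score standardization.

    ``center="global"`` (default) standardizes each gene over all retained
    samples, preserving the between-tissue mean differences the specificity
    t-statistic measures.  ``center="tissue"`` standardizes each gene within
    each tissue instead; note that this removes between-tissue contrasts and
    is only useful for dispersion diagnostics.  Tissues with a single sample
    have no within-tissue dispersion and are excluded with a warning; genes
    with zero dispersion scale to zero (the zero-SD guard) rather than NaN.
    """
    if center not in ("global", "tissue"):
        raise ValueError("center must be 'global' or 'tissue'")
    if (expr.values.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    logged = np.log2(expr.values + pseudo)
    keep_cols = []
    for tissue, meta in expr.sample_meta.groupby("tissue"):
        cols = meta.index.tolist()
        if len(cols) < 2:
            warnings.warn(f"tissue {tissue!r} has one sample; excluded")
            continue
        keep_cols.extend(cols)
    keep_cols = [c for c in expr.values.columns if c in set(keep_cols)]
    logged = logged[keep_cols]
    if center == "global":
        mu = logged.mean(axis=1)
        sd = logged.std(axis=1, ddof=1)
        logged = logged.sub(mu, axis=0).div(sd.replace(0.0, np.inf), axis=0)
    else:
        for tissue, meta in expr.sample_meta.loc[keep_cols].groupby("tissue"):
            cols = meta.index.tolist()
            block = logged[cols]
            mu = block.mean(axis=1)
            sd = block.std(axis=1, ddof=1)
            logged[cols] = block.sub(mu, axis=0).div(sd.replace(0.0, np.inf), axis=0)
    return ExpressionMatrix(logged, expr.sample_meta.loc[keep_cols])


@dataclass
class TStatResult:
    table: pd.DataFrame  # gene, t, b, eligible
    target_tissue: str
    n_target: int
    n_background: int

    @property
    def t(self) -> pd.Series:
        return self.table.set_index("gene")["t"]


def _covariate_design(meta: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """One-hot factors (single-sample levels merged) and numeric columns."""
    blocks = []
    for cov in covariates:
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            v = col.to_numpy(dtype=float)
            if np.std(v) > 0:
                blocks.append((v - v.mean())[:, None])
        else:
            col = col.astype(str)
            counts = col.value_counts()
            col = col.where(col.map(counts) > 1, "other")
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            if dummies.size:
                blocks.append(dummies)
    return np.hstack(blocks) if blocks else np.empty((len(meta), 0))


def tissue_tstat(
    expr: ExpressionMatrix,
    target_tissue: str,
    excluded_categories: set[str] | None = None,
    covariates: list[str] | None = None,
) -> TStatResult:
    """Per-gene OLS t-statistic for the +1/-1 target-tissue indicator.

    Samples from excluded categories are dropped unless they belong to the
    target tissue itself.  Collinear covariate columns are removed with a
    warning.  Genes without residual variance get an infinite-t sentinel;
    genes without any variance in the used samples get t = 0 and are marked
    ineligible for the top fraction.
    """
    excluded_categories = excluded_categories or set()
    meta = expr.sample_meta
    is_target = (meta["tissue"] == target_tissue).to_numpy()
    drop = meta["category"].isin(excluded_categories).to_numpy() & ~is_target
    use = ~drop
    meta = meta.loc[use]
    is_target = is_target[use]
    if is_target.sum() < 2 or (~is_target).sum() < 2:
        raise ValueError("need >= 2 target and >= 2 background samples")

    Y = expr.values.iloc[:, np.flatnonzero(use)].to_numpy(dtype=float)
    indicator = np.where(is_target, 1.0, -1.0)
    cols = [indicator[:, None], np.ones((len(meta), 1))]
    if covariates:
        cols.append(_covariate_design(meta, covariates))
    X = np.hstack(cols)
    # drop collinear covariate columns (never the indicator or intercept)
    rank = np.linalg.matrix_rank(X)
    while rank < X.shape[1] and X.shape[1] > 2:
        dropped = False
        for j in range(X.shape[1] - 1, 1, -1):
            X_try = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(X_try) == rank:
                warnings.warn("collinear covariate column dropped")
                X = X_try
                dropped = True
                break
        if not dropped:
            break
        rank = np.linalg.matrix_rank(X)

    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    B = XtX_inv @ X.T @ Y.T  # p x genes
    resid = Y.T - X @ B
    df = n - p
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / max(df, 1)
    se_b = np.sqrt(np.maximum(sigma2 * XtX_inv[0, 0], 0.0))
    b = B[0]

    gene_var = Y.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / se_b
    zero_resid = (se_b == 0) & (gene_var > 0)
    t[zero_resid] = np.sign(b[zero_resid]) * np.inf
    no_var = gene_var == 0
    t[no_var] = 0.0
    table = pd.DataFrame(
        {
            "gene": expr.values.index,
            "t": t,
            "b": b,
            "eligible": ~no_var,
        }
    )
    return TStatResult(table, target_tissue, int(is_target.sum()), int((~is_target).sum()))


def top_fraction(result: TStatResult, fraction: float = 0.10) -> set[str]:
    """Genes in the top ``fraction`` by t-statistic; ties at the cutoff included."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    tab = result.table[result.table["eligible"]]
    if tab.empty:
        raise ValueError("no eligible genes")
    k = int(np.ceil(fraction * len(tab)))
    cutoff = np.sort(tab["t"].to_numpy())[::-1][k - 1]
    return set(tab.loc[tab["t"] >= cutoff, "gene"])


def tstat_correlation(res_a: TStatResult, res_b: TStatResult) -> float:
    """Pearson correlation of t-statistics over the shared gene universe."""
    shared = res_a.t.index.intersection(res_b.t.index)
    a = res_a.t.loc[shared].to_numpy()
    b = res_b.t.loc[shared].to_numpy()
    finite = np.isfinite(a) & np.isfinite(b)
    if finite.sum() < 3:
        raise ValueError("need >= 3 shared genes with finite t-statistics")
    return float(np.corrcoef(a[finite], b[finite])[0, 1])
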