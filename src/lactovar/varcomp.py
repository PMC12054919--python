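"""Multi-GRM restricted maximum likelihood (GREML) variance partitioning.

Fits y = 1*mu + sum_f g_f + eps with Var(g_f) = G_f * sigma2_f by
average-information REML with an EM fallback, reports per-component variance
proportions h2_f = sigma2_f / sigma2_P, and computes per-variant enrichment
odds ratios (h2_f / h2_all) / (n_f / n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .grm import GRM, FunctionalClassMap, GenotypeMatrix, compute_grm

__all__ = [
    "PhenotypeTable",
    "VarCompFit",
    "EnrichmentResult",
    "fit_reml",
    "partition_two",
    "partition_multi",
    "per_chromosome_partition",
    "enrichment",
    "enrichment_value",
]


@dataclass
class PhenotypeTable:
    """Deregressed-PTA phenotypes: animal_id, dpta, reliability."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal_id", "dpta", "reliability"}
        if not required <= set(self.df.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        if self.df["animal_id"].duplicated().any():
            raise ValueError("duplicate animal IDs")
        rel = self.df["reliability"].to_numpy(dtype=float)
        if ((rel <= 0) | (rel > 1)).any():
            raise ValueError("reliabilities must lie in (0, 1]")

    @property
    def y(self) -> np.ndarray:
        return self.df["dpta"].to_numpy(dtype=float)

    @property
    def reliability(self) -> np.ndarray:
        return self.df["reliability"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class VarCompFit:
    """REML solution: named genetic variances, residual, SEs, likelihood."""

    components: dict[str, float]
    residual: float
    se: dict[str, float] = field(default_factory=dict)
    prop_se: dict[str, float] = field(default_factory=dict)
    loglik: float = np.nan
    converged: bool = False
    n_iter: int = 0

    @property
    def sigma_p(self) -> float:
        return sum(self.components.values()) + self.residual

    @property
    def proportions(self) -> dict[str, float]:
        sp = self.sigma_p
        return {k: v / sp for k, v in self.components.items()}

    @property
    def h2_all(self) -> float:
        return sum(self.proportions.values())

    def report(self) -> pd.DataFrame:
        rows = [
            {
                "component": k,
                "sigma2": v,
                "h2_f": self.proportions[k],
                "se": self.se.get(k, np.nan),
            }
            for k, v in self.components.items()
        ]
        rows.append(
            {
                "component": "residual",
                "sigma2": self.residual,
                "h2_f": self.residual / self.sigma_p,
                "se": self.se.get("residual", np.nan),
            }
        )
        return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    class_name: str
    h2_f: float
    h2_all: float
    n_f: int
    n: int
    enrichment: float
    defined: bool = True


def _as_y(y) -> np.ndarray:
    if isinstance(y, PhenotypeTable):
        return y.y
    return np.asarray(y, dtype=float)


def _reml_parts(sigma, all_mats, yv, X):
    """Restricted log-likelihood, score vector and AI matrix at ``sigma``."""
    n = len(yv)
    k = len(all_mats)
    V = sum(s * G for s, G in zip(sigma, all_mats))
    c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_V = 2.0 * np.log(np.diag(c)).sum()
    Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    u = (Vinv @ X)[:, 0]
    s_xx = float(X[:, 0] @ u)
    Py = Vinv @ yv - u * (u @ yv) / s_xx
    ypy = float(yv @ Py)
    loglik = -0.5 * (logdet_V + np.log(s_xx) + ypy)
    t = [G @ Py for G in all_mats]
    tr_PG = np.array(
        [np.sum(Vinv * G) - float(u @ (G @ u)) / s_xx for G in all_mats]
    )
    quad = np.array([float(Py @ ti) for ti in t])
    score = -0.5 * (tr_PG - quad)
    Pt = [Vinv @ ti - u * (u @ ti) / s_xx for ti in t]
    AI = 0.5 * np.array(
        [[float(t[i] @ Pt[j]) for j in range(k)] for i in range(k)]
    )
    return loglik, score, AI, quad, tr_PG


def fit_reml(
    y,
    grms: list[GRM] | list[np.ndarray],
    names: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    reliability_weights: np.ndarray | None = None,
) -> VarCompFit:
    """Average-information REML for one or more genomic relationship matrices.

    The model has a single fixed mean.  Updates use the AI matrix; when an AI
    step would take a component negative, that component falls back to one EM
    re-step and is pinned at a small non-negative floor if the EM step is
    still negative.  Setting ``reliability_weights`` (per-animal reliability
    r_i) replaces the residual covariance by diag(1/r_i) * sigma2_e.
    """
    yv = _as_y(y)
    n = len(yv)
    mats = [g.matrix if isinstance(g, GRM) else np.asarray(g, float) for g in grms]
    if not mats:
        raise ValueError("need at least one GRM")
    for G in mats:
        if G.shape != (n, n):
            raise ValueError("all GRMs must match the phenotype length")
    if names is None:
        names = [f"g{i + 1}" for i in range(len(mats))] if len(mats) > 1 else ["genetic"]
    R = (
        np.eye(n)
        if reliability_weights is None
        else np.diag(1.0 / np.asarray(reliability_weights, float))
    )
    all_mats = mats + [R]
    k = len(all_mats)

    var_y = yv.var(ddof=1)
    if var_y <= 0:
        raise ValueError("phenotype variance is zero")
    floor = 1e-8 * var_y
    sigma = np.full(k, var_y / k)
    X = np.ones((n, 1))

    loglik = -np.inf
    converged = False
    it = 0
    AI = np.eye(k)
    n_ai = min(max_iter, 50)
    for it in range(1, n_ai + 1):
        try:
            new_loglik, score, AI, quad, tr_PG = _reml_parts(
                sigma, all_mats, yv, X
            )
        except linalg.LinAlgError as exc:
            raise ValueError("phenotype covariance matrix is singular") from exc

        em = sigma + sigma**2 * (quad - tr_PG) / n
        if it == 1:
            new = em  # EM warm-up step
        else:
            try:
                delta = linalg.solve(AI, score, assume_a="sym")
            except linalg.LinAlgError:
                delta = linalg.lstsq(AI, score)[0]
            new = sigma + delta
            bad = new < 0
            if bad.any():
                new[bad] = em[bad]  # one EM re-step before the bound bites
        new = np.maximum(new, floor)

        change = np.max(np.abs(new - sigma)) / max(var_y, 1e-12)
        ll_change = abs(new_loglik - loglik)
        sigma = new
        prev_ll, loglik = loglik, new_loglik
        # convergence is monitored on the restricted likelihood (the usual
        # REML criterion); a stalled parameter vector also counts
        if it > 1 and (ll_change < tol * (1.0 + abs(prev_ll)) or change < tol):
            converged = True
            break

    if not converged:
        # AI/EM can crawl when a component sits near its boundary; polish
        # with a quasi-Newton bounded maximization of the exact restricted
        # likelihood, using the analytic score as gradient
        from scipy import optimize

        def negll_grad(s):
            ll, sc, *_ = _reml_parts(np.asarray(s), all_mats, yv, X)
            return -ll, -sc

        res = optimize.minimize(
            negll_grad,
            sigma,
            jac=True,
            method="L-BFGS-B",
            bounds=[(floor, None)] * k,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
        )
        sigma = np.asarray(res.x)
        loglik, score, AI, _, _ = _reml_parts(sigma, all_mats, yv, X)
        # KKT check: interior components need a small gradient, boundary
        # components a non-positive one
        at_bound = sigma <= floor * (1 + 1e-6)
        scale = max(abs(loglik), 1.0)
        converged = bool(
            np.all(np.abs(score[~at_bound]) < 1e-3 * scale)
            and np.all(score[at_bound] < 1e-3 * scale)
        )
        it = n_ai + int(res.nit)
    if not converged:
        warnings.warn("REML did not converge within max_iter", RuntimeWarning)

    try:
        ai_inv = linalg.inv(AI)
        se = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
    except linalg.LinAlgError:
        ai_inv = np.full((k, k), np.nan)
        se = np.full(k, np.nan)

    # delta-method SEs of the variance proportions h_i = sigma_i / sigma_P
    sigma_p = sigma.sum()
    prop_se = np.empty(k)
    for i in range(k):
        grad = np.full(k, -sigma[i] / sigma_p**2)
        grad[i] += 1.0 / sigma_p
        prop_se[i] = np.sqrt(max(float(grad @ ai_inv @ grad), 0.0))

    comps = {names[i]: float(sigma[i]) for i in range(k - 1)}
    ses = {names[i]: float(se[i]) for i in range(k - 1)}
    ses["residual"] = float(se[-1])
    pses = {names[i]: float(prop_se[i]) for i in range(k - 1)}
    pses["residual"] = float(prop_se[-1])
    return VarCompFit(
        components=comps,
        residual=float(sigma[-1]),
        se=ses,
        prop_se=pses,
        loglik=float(loglik),
        converged=converged,
        n_iter=it,
    )


def partition_two(
    y, geno: GenotypeMatrix, classmap: FunctionalClassMap, class_name: str, **kw
) -> VarCompFit:
    """Fit one functional class against the complementary background (N=2)."""
    mask = classmap.mask(geno, class_name)
    if not mask.any():
        raise ValueError(f"class {class_name!r} is empty on this panel")
    if mask.all():
        raise ValueError(f"class {class_name!r} covers every variant; no background")
    g_class = compute_grm(geno.take_variants(mask))
    g_rest = compute_grm(geno.take_variants(~mask))
    return fit_reml(y, [g_class, g_rest], names=[class_name, "other"], **kw)


def partition_multi(
    y,
    geno: GenotypeMatrix,
    classmap: FunctionalClassMap,
    class_names: list[str] | None = None,
    overlap_policy: list[str] | None = None,
    **kw,
) -> VarCompFit:
    """Joint fit with one GRM per functional class plus the ``other`` class.

    Variants belonging to several classes are assigned to the first class in
    ``overlap_policy`` (default: the given class order) that contains them.
    """
    class_names = class_names or list(classmap.classes)
    if len(class_names) < 2:
        raise ValueError("need at least two classes for a multi-class fit")
    priority = overlap_policy or class_names
    ids = geno.variants["id"].to_numpy()
    assigned = np.array(["other"] * len(ids), dtype=object)
    for name in reversed(priority):
        members = classmap.classes[name]
        assigned[np.isin(ids, list(members))] = name

    grms, names = [], []
    for name in class_names + ["other"]:
        mask = assigned == name
        if not mask.any():
            warnings.warn(f"class {name!r} empty after overlap resolution; dropped")
            continue
        grms.append(compute_grm(geno.take_variants(mask)))
        names.append(name)
    return fit_reml(y, grms, names=names, **kw)


def per_chromosome_partition(y, geno: GenotypeMatrix, chrom_lengths=None, **kw):
    """One GRM per chromosome fitted jointly, plus length-vs-proportion OLS.

    Returns (fit, per-chromosome DataFrame, regression dict with slope,
    adjusted R2 and p-value).
    """
    import statsmodels.api as sm

    chroms = geno.variants["chrom"].unique().tolist()
    if len(chroms) < 2:
        raise ValueError("per-chromosome partition needs >= 2 chromosomes")
    grms, names, lengths, counts = [], [], [], []
    for c in chroms:
        mask = (geno.variants["chrom"] == c).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"chromosome {c} has < 2 variants; dropped")
            continue
        grms.append(compute_grm(geno.take_variants(mask)))
        names.append(str(c))
        pos = geno.variants.loc[mask, "pos"]
        if chrom_lengths is not None:
            lengths.append(float(chrom_lengths[c]))
        else:
            lengths.append(float(pos.max() - pos.min() + 1))
        counts.append(int(mask.sum()))
    fit = fit_reml(y, grms, names=names, **kw)

    props = [fit.proportions[n] for n in names]
    table = pd.DataFrame(
        {"chrom": names, "n_variants": counts, "length": lengths, "proportion": props}
    )
    ols = sm.OLS(table["proportion"], sm.add_constant(table["length"])).fit()
    regression = {
        "slope": float(ols.params.iloc[1]),
        "adj_r2": float(ols.rsquared_adj),
        "p_value": float(ols.pvalues.iloc[1]),
    }
    return fit, table, regression


def enrichment_value(h2_f: float, h2_all: float, n_f: int, n: int) -> float:
    """Per-variant enrichment odds ratio (h2_f / h2_all) / (n_f / n)."""
    return (h2_f / h2_all) / (n_f / n)


def enrichment(
    fit: VarCompFit,
    counts: dict[str, int],
    n_total: int | None = None,
    include_other: bool = True,
) -> list[EnrichmentResult]:
    """Enrichment of every fitted class given per-class variant counts.

    ``h2_all`` is the sum of all fitted class proportions.  Classes with an
    undefined ratio (no variants, or zero total genetic proportion) are
    returned flagged rather than dropped.
    """
    props = fit.proportions
    h2_all = fit.h2_all
    n = n_total if n_total is not None else sum(counts.get(k, 0) for k in props)
    out = []
    for name, h2_f in props.items():
        if not include_other and name == "other":
            continue
        n_f = counts.get(name, 0)
        if n_f == 0 or h2_all == 0:
            out.append(EnrichmentResult(name, h2_f, h2_all, n_f, n, np.nan, False))
        else:
            out.append(
                EnrichmentResult(
                    name, h2_f, h2_all, n_f, n, enrichment_value(h2_f, h2_all, n_f, n)
                )
            )
    return out
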