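"""Genomic prediction: GBLUP, MultiBLUP, BayesR and BayesRC.

GBLUP/MultiBLUP solve the mixed-model equations with one or two genomic
relationship matrices; validation animals' genomic values come from the
reference-validation relationship block, never their phenotypes.  BayesR
places SNP effects in a four-component normal mixture N(0, gamma_k *
sigma2_beta) with gamma = (0, 0.01, 0.1, 1) and mixing proportions pi
sampled from a Dirichlet; BayesRC gives variants inside and outside the
functional annotation independent mixing proportions.  Prediction accuracy
is reported as the squared Pearson correlation between genomic values and
validation deregressed PTAs, in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import linalg

from .grm import GRM
from .syndata import MIXTURE_GAMMA

__all__ = [
    "MixturePrior",
    "PredictionFit",
    "ReliabilityReport",
    "deregress",
    "center_genotypes",
    "solve_gblup",
    "solve_multiblup",
    "snp_blup",
    "gibbs_bayesr",
    "gibbs_bayesrc",
    "reliability",
    "compare_models",
    "split_reference_validation",
]


@dataclass
class MixturePrior:
    """Four-component mixture prior on SNP effects."""

    gamma: tuple[float, ...] = MIXTURE_GAMMA
    pi: tuple[float, ...] = (0.7, 0.15, 0.1, 0.05)
    pi_by_class: dict[str, tuple[float, ...]] | None = None
    dirichlet_alpha: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    fix_pi: bool = False

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if g[0] != 0.0 or (np.diff(g) <= 0).any():
            raise ValueError("gamma must be ascending with gamma[0] = 0")
        for p in [self.pi] + list((self.pi_by_class or {}).values()):
            arr = np.asarray(p, dtype=float)
            if arr.shape != g.shape or (arr < 0).any() or abs(arr.sum() - 1) > 1e-9:
                raise ValueError("each pi must be a simplex point over the components")


@dataclass
class PredictionFit:
    model: str
    gebv: np.ndarray
    mu: float = 0.0
    sigma2: dict[str, float] = field(default_factory=dict)
    beta_mean: np.ndarray | None = None
    pi_mean: np.ndarray | None = None
    inclusion: np.ndarray | None = None
    mcmc: dict | None = None


def deregress(pta, reliability):
    """Deregressed PTA: the PTA divided by its squared reliability."""
    rel = np.asarray(reliability, dtype=float)
    if (rel <= 0).any() if rel.ndim else rel <= 0:
        raise ValueError("reliability must be positive")
    return np.asarray(pta, dtype=float) / rel**2


def center_genotypes(dosages: np.ndarray) -> np.ndarray:
    """Column-centred dosage matrix W used by the marker-effect models."""
    X = np.asarray(dosages, dtype=float)
    return X - X.mean(axis=0)


def _gls_mean(V_chol, y):
    one = np.ones_like(y)
    Vi_y = linalg.cho_solve(V_chol, y, check_finite=False)
    Vi_1 = linalg.cho_solve(V_chol, one, check_finite=False)
    return float(one @ Vi_y) / float(one @ Vi_1), Vi_1


def _chol_with_ridge(V):
    try:
        return linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        warnings.warn("singular covariance; ridge of 1e-8 added")
        return linalg.cho_factor(
            V + 1e-8 * np.eye(len(V)), lower=True, check_finite=False
        )


def solve_gblup(
    y,
    grm: GRM | np.ndarray,
    sigma2_g: float,
    sigma2_e: float,
    reference_idx=None,
) -> PredictionFit:
    """BLUP of genomic values from a single GRM.

    Only reference animals' phenotypes enter the equations; every animal's
    genomic value follows from its genomic relationship to the reference.
    """
    G = grm.matrix if isinstance(grm, GRM) else np.asarray(grm, float)
    y = np.asarray(y, dtype=float)
    n_all = G.shape[0]
    r = np.arange(n_all) if reference_idx is None else np.asarray(reference_idx)
    yr = y[r] if len(y) == n_all else y
    if sigma2_g <= 0:
        return PredictionFit("GBLUP", np.zeros(n_all), float(yr.mean()),
                             {"genetic": sigma2_g, "residual": sigma2_e})
    V = sigma2_g * G[np.ix_(r, r)] + sigma2_e * np.eye(len(r))
    ch = _chol_with_ridge(V)
    mu, _ = _gls_mean(ch, yr)
    alpha = linalg.cho_solve(ch, yr - mu, check_finite=False)
    gebv = sigma2_g * (G[:, r] @ alpha)
    return PredictionFit(
        "GBLUP", gebv, mu, {"genetic": sigma2_g, "residual": sigma2_e}
    )


def solve_multiblup(
    y,
    grm_functional: GRM | np.ndarray,
    grm_rest: GRM | np.ndarray,
    sigma2_f: float,
    sigma2_r: float,
    sigma2_e: float,
    reference_idx=None,
) -> PredictionFit:
    """Two-component BLUP: functional-class and remaining-marker effects.

    Total genomic value is the sum of the two component BLUPs.  Variance
    components are typically estimated first with ``varcomp.fit_reml``.
    """
    Gf = grm_functional.matrix if isinstance(grm_functional, GRM) else np.asarray(grm_functional, float)
    Gr = grm_rest.matrix if isinstance(grm_rest, GRM) else np.asarray(grm_rest, float)
    y = np.asarray(y, dtype=float)
    n_all = Gf.shape[0]
    r = np.arange(n_all) if reference_idx is None else np.asarray(reference_idx)
    yr = y[r] if len(y) == n_all else y
    V = (
        sigma2_f * Gf[np.ix_(r, r)]
        + sigma2_r * Gr[np.ix_(r, r)]
        + sigma2_e * np.eye(len(r))
    )
    ch = _chol_with_ridge(V)
    mu, _ = _gls_mean(ch, yr)
    alpha = linalg.cho_solve(ch, yr - mu, check_finite=False)
    g_f = sigma2_f * (Gf[:, r] @ alpha)
    g_r = sigma2_r * (Gr[:, r] @ alpha)
    return PredictionFit(
        "MultiBLUP",
        g_f + g_r,
        mu,
        {"functional": sigma2_f, "rest": sigma2_r, "residual": sigma2_e},
    )


def snp_blup(
    y, W: np.ndarray, sigma2_beta: float, sigma2_e: float, reference_idx=None
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge (SNP-BLUP) solution; returns (effects, genomic values).

    Equivalent to GBLUP when the GRM is built from the same centred
    genotypes with sigma2_g = sigma2_beta * 2*sum p(1-p).
    """
    n_all = W.shape[0]
    r = np.arange(n_all) if reference_idx is None else np.asarray(reference_idx)
    Wr = W[r]
    y = np.asarray(y, dtype=float)
    yr = y[r] if len(y) == n_all else y
    lam = sigma2_e / sigma2_beta
    m = W.shape[1]
    yc = yr - yr.mean()
    beta = linalg.solve(Wr.T @ Wr + lam * np.eye(m), Wr.T @ yc, assume_a="pos")
    return beta, W @ beta


@numba.njit(cache=False)
def _gibbs_kernel(
    y, Wt, css, gamma, pi0, alpha, class_idx, n_classes,
    n_iter, burn_in, seed, update_pi, nu, s_e0, s_b0,
):  # pragma: no cover - exercised through the wrappers
    np.random.seed(seed)
    m, n = Wt.shape
    k = gamma.shape[0]
    beta = np.zeros(m)
    comp = np.zeros(m, dtype=np.int64)
    pi = pi0.copy()
    mu = y.mean()
    r = y - mu
    sigma_e = np.var(y) * 0.5
    sigma_b = s_b0

    beta_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    pi_sum = np.zeros((n_classes, k))
    se_sum = 0.0
    sb_sum = 0.0
    mu_sum = 0.0
    se_trace = np.zeros(n_iter)
    n_keep = 0
    logp = np.zeros(k)

    for it in range(n_iter):
        # intercept
        r += mu
        mu = r.mean() + np.random.normal() * np.sqrt(sigma_e / n)
        r -= mu
        # SNP effects and components
        ssq = 0.0
        n_nonzero = 0
        counts = np.zeros((n_classes, k))
        for j in range(m):
            w = Wt[j]
            if beta[j] != 0.0:
                for i in range(n):
                    r[i] += w[i] * beta[j]
            rhs = 0.0
            for i in range(n):
                rhs += w[i] * r[i]
            cj = css[j]
            cls = class_idx[j]
            maxlog = -1e300
            for kk in range(k):
                if pi[cls, kk] <= 0.0:
                    logp[kk] = -1e300
                    continue
                if gamma[kk] == 0.0:
                    logp[kk] = np.log(pi[cls, kk])
                else:
                    v = gamma[kk] * sigma_b
                    lhs = cj + sigma_e / v
                    logp[kk] = (
                        np.log(pi[cls, kk])
                        - 0.5 * np.log(v * cj / sigma_e + 1.0)
                        + 0.5 * rhs * rhs / (sigma_e * lhs)
                    )
                if logp[kk] > maxlog:
                    maxlog = logp[kk]
            tot = 0.0
            for kk in range(k):
                logp[kk] = np.exp(logp[kk] - maxlog)
                tot += logp[kk]
            u = np.random.random() * tot
            acc = 0.0
            kj = k - 1
            for kk in range(k):
                acc += logp[kk]
                if u <= acc:
                    kj = kk
                    break
            comp[j] = kj
            counts[cls, kj] += 1.0
            if gamma[kj] == 0.0:
                beta[j] = 0.0
            else:
                v = gamma[kj] * sigma_b
                lhs = cj + sigma_e / v
                bj = rhs / lhs + np.random.normal() * np.sqrt(sigma_e / lhs)
                beta[j] = bj
                ssq += bj * bj / gamma[kj]
                n_nonzero += 1
                for i in range(n):
                    r[i] -= w[i] * bj
        # scales: scaled-inverse-chi-square updates
        sigma_b = (ssq + nu * s_b0) / np.random.chisquare(nu + n_nonzero)
        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        sigma_e = (sse + nu * s_e0) / np.random.chisquare(nu + n)
        # mixing proportions
        if update_pi:
            for cls in range(n_classes):
                tot = 0.0
                for kk in range(k):
                    g = np.random.gamma(alpha[kk] + counts[cls, kk], 1.0)
                    pi[cls, kk] = g
                    tot += g
                for kk in range(k):
                    pi[cls, kk] /= tot
        se_trace[it] = sigma_e
        if it >= burn_in:
            n_keep += 1
            mu_sum += mu
            se_sum += sigma_e
            sb_sum += sigma_b
            for j in range(m):
                beta_sum[j] += beta[j]
                if comp[j] > 0:
                    incl_sum[j] += 1.0
            for cls in range(n_classes):
                for kk in range(k):
                    pi_sum[cls, kk] += pi[cls, kk]

    return (
        beta_sum / n_keep,
        incl_sum / n_keep,
        pi_sum / n_keep,
        mu_sum / n_keep,
        se_sum / n_keep,
        sb_sum / n_keep,
        se_trace,
    )


def _run_gibbs(model, y, W, prior, class_idx, n_classes, n_iter, burn_in, seed,
               reference_idx):
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    W = np.asarray(W, dtype=float)
    y = np.asarray(y, dtype=float)
    n_all = W.shape[0]
    r = np.arange(n_all) if reference_idx is None else np.asarray(reference_idx)
    yr = y[r] if len(y) == n_all else y
    Wr = np.ascontiguousarray(W[r].T)  # SNP-major for the kernel
    css = (Wr**2).sum(axis=1)
    css = np.maximum(css, 1e-12)
    gamma = np.asarray(prior.gamma, dtype=float)
    k = len(gamma)

    pi0 = np.empty((n_classes, k))
    if n_classes == 1:
        pi0[0] = prior.pi
    else:
        by_class = prior.pi_by_class or {}
        pi0[0] = by_class.get("functional", prior.pi)
        pi0[1] = by_class.get("rest", prior.pi)

    var_y = yr.var()
    # prior scales: residual at half the phenotypic variance, marker scale
    # sized so the average nonzero component tags the other half
    mean_c = float(css.mean()) * len(yr) / max(len(yr), 1)
    expected_gamma = float((gamma * np.asarray(prior.pi)).sum())
    s_b0 = 0.5 * var_y / max(
        css.shape[0] * expected_gamma * mean_c / len(yr), 1e-12
    )
    s_e0 = 0.5 * var_y
    nu = 4.0

    out = _gibbs_kernel(
        yr, Wr, css, gamma, pi0,
        np.asarray(prior.dirichlet_alpha, dtype=float),
        np.asarray(class_idx, dtype=np.int64), n_classes,
        int(n_iter), int(burn_in), int(seed) % (2**31),
        not prior.fix_pi, nu, s_e0, s_b0,
    )
    beta_mean, incl, pi_mean, mu, se, sb, se_trace = out
    if not np.isfinite(beta_mean).all():
        raise FloatingPointError("non-finite state in the Gibbs chain")
    gebv = W @ beta_mean
    return PredictionFit(
        model,
        gebv,
        float(mu),
        {"residual": float(se), "beta_scale": float(sb)},
        beta_mean=beta_mean,
        pi_mean=pi_mean,
        inclusion=incl,
        mcmc={
            "n_iter": int(n_iter),
            "burn_in": int(burn_in),
            "seed": int(seed),
            "sigma2_e_trace": se_trace,
        },
    )


def gibbs_bayesr(
    y, W, prior: MixturePrior | None = None,
    n_iter: int = 25000, burn_in: int = 5000, seed: int = 0,
    reference_idx=None,
) -> PredictionFit:
    """Single-site Gibbs sampler for the BayesR mixture model."""
    prior = prior or MixturePrior()
    class_idx = np.zeros(np.asarray(W).shape[1], dtype=np.int64)
    return _run_gibbs(
        "BayesR", y, W, prior, class_idx, 1, n_iter, burn_in, seed, reference_idx
    )


def gibbs_bayesrc(
    y, W, functional_mask, prior: MixturePrior | None = None,
    n_iter: int = 25000, burn_in: int = 5000, seed: int = 0,
    reference_idx=None,
) -> PredictionFit:
    """BayesRC: class-specific mixture proportions inside/outside the
    functional annotation.  An empty class falls back to plain BayesR."""
    prior = prior or MixturePrior()
    mask = np.asarray(functional_mask, dtype=bool)
    if mask.all() or not mask.any():
        warnings.warn("degenerate functional class; falling back to BayesR")
        fit = gibbs_bayesr(y, W, prior, n_iter, burn_in, seed, reference_idx)
        return PredictionFit("BayesRC", fit.gebv, fit.mu, fit.sigma2,
                             fit.beta_mean, fit.pi_mean, fit.inclusion, fit.mcmc)
    class_idx = np.where(mask, 0, 1).astype(np.int64)
    return _run_gibbs(
        "BayesRC", y, W, prior, class_idx, 2, n_iter, burn_in, seed, reference_idx
    )


def reliability(gebv, dpta_validation, mean_validation_reliability=None) -> float:
    """Validation reliability: squared Pearson correlation, in percent.

    Optionally divides by the mean reliability of the validation records, a
    variant sometimes used to correct for noise in the validation phenotypes;
    off unless ``mean_validation_reliability`` is given.
    """
    g = np.asarray(gebv, dtype=float)
    d = np.asarray(dpta_validation, dtype=float)
    if len(g) < 10:
        raise ValueError("need >= 10 validation animals")
    if g.std() == 0 or d.std() == 0:
        warnings.warn("zero-variance predictions; reliability set to 0")
        return 0.0
    r = np.corrcoef(g, d)[0, 1]
    out = float(r**2 * 100.0)
    if mean_validation_reliability is not None:
        if not 0.0 < mean_validation_reliability <= 1.0:
            raise ValueError("mean validation reliability must lie in (0, 1]")
        out /= mean_validation_reliability
    return out


@dataclass
class ReliabilityReport:
    """Per-trait reliabilities of a model against a baseline, in percent."""

    table: pd.DataFrame  # rows: baseline, model, increase; columns: traits
    baseline_name: str
    model_name: str

    @property
    def increases(self) -> pd.Series:
        return self.table.loc["increase"]

    @property
    def mean_increase(self) -> float:
        return float(self.table.loc["increase"].mean())

    def rendered(self) -> pd.DataFrame:
        return self.table.round(2)


def compare_models(
    model_values: dict[str, float],
    baseline_values: dict[str, float],
    model_name: str = "model",
    baseline_name: str = "baseline",
) -> ReliabilityReport:
    """Per-trait reliability increases (model minus baseline), unrounded.

    Differences are computed before any rounding; ``rendered()`` displays at
    two decimals as reliability tables conventionally do.
    """
    if set(model_values) != set(baseline_values):
        raise ValueError("trait sets differ between model and baseline")
    traits = list(baseline_values)
    table = pd.DataFrame(
        {
            t: [
                baseline_values[t],
                model_values[t],
                model_values[t] - baseline_values[t],
            ]
            for t in traits
        },
        index=[baseline_name, model_name, "increase"],
    )
    return ReliabilityReport(table, baseline_name, model_name)


def split_reference_validation(animal_ids, birth_years, cutoff: int):
    """Reference = born before the cutoff year; validation = at/after."""
    ids = np.asarray(animal_ids)
    years = np.asarray(birth_years)
    if len(ids) != len(years):
        raise ValueError("every animal needs a birth year")
    val = years >= cutoff
    if not val.any() or val.all():
        raise ValueError("reference or validation side is empty")
    return np.flatnonzero(~val), np.flatnonzero(val)
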