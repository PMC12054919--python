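"""miRNA target anti-correlation testing and candidate prioritization.

For each miRNA, Pearson correlations against every mRNA are computed; an
mRNA is "negative" when r < 0 with correlation p <= 0.05.  A 2x2 table over
all mRNAs (negative vs not, predicted target vs not) is tested with a
one-sided Fisher exact test for enrichment of negatives among targets.  A
miRNA is a candidate when its Fisher p < 0.05 AND the variance proportion
captured by its target class exceeds 0.1 (both strict, matching the
published thresholds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MirnaPriorityRecord",
    "correlate_targets",
    "negative_flags",
    "fisher_enrichment",
    "prioritize",
    "de_overlap_test",
]

CORR_P_MAX = 0.05  # inclusive, per the stated rule
FISHER_P_MAX = 0.05  # strict
H2_TARGET_MIN = 0.1  # strict


@dataclass
class MirnaPriorityRecord:
    mirna_id: str
    a: int  # negative and target
    b: int  # negative, not target
    c: int  # not negative, target
    d: int  # neither
    fisher_p: float
    target_class_h2: float = np.nan
    candidate: bool = False


def correlate_targets(
    mirna_expr: pd.DataFrame, mrna_expr: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for every (miRNA, mRNA) pair.

    Both matrices are features x samples over matched sample columns; p uses
    the t approximation with n - 2 df.  Zero-variance series give NaN and a
    warning; such pairs are excluded downstream.
    """
    samples = mirna_expr.columns.intersection(mrna_expr.columns)
    if len(samples) < 3:
        raise ValueError("need >= 3 matched samples")
    A = mirna_expr[samples].to_numpy(dtype=float)
    B = mrna_expr[samples].to_numpy(dtype=float)
    n = len(samples)
    A_c = A - A.mean(axis=1, keepdims=True)
    B_c = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A_c**2).sum(axis=1))
    sb = np.sqrt((B_c**2).sum(axis=1))
    if (sa == 0).any() or (sb == 0).any():
        warnings.warn("zero-variance series; their correlations are NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (A_c @ B_c.T) / np.outer(sa, sb)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    idx, cols = mirna_expr.index, mrna_expr.index
    return (
        pd.DataFrame(r, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
    )


def negative_flags(r: pd.Series, p: pd.Series) -> pd.Series:
    """Anti-correlated mRNAs for one miRNA: r < 0 and p <= 0.05."""
    return (r < 0) & (p <= CORR_P_MAX) & r.notna()


def fisher_enrichment(neg_flags, target_flags, alternative: str = "greater"):
    """One-sided Fisher exact test for negatives enriched among targets.

    Returns ((a, b, c, d), odds_ratio, p) with a = negative & target,
    b = negative & non-target, c = non-negative & target, d = the rest.
    """
    neg = np.asarray(neg_flags, dtype=bool)
    tgt = np.asarray(target_flags, dtype=bool)
    if neg.shape != tgt.shape or neg.size == 0:
        raise ValueError("flags must be a nonempty shared mRNA universe")
    a = int(np.sum(neg & tgt))
    b = int(np.sum(neg & ~tgt))
    c = int(np.sum(~neg & tgt))
    d = int(np.sum(~neg & ~tgt))
    odds, p = stats.fisher_exact([[a, c], [b, d]], alternative=alternative)
    return (a, b, c, d), float(odds), float(p)


def prioritize(
    records: list[MirnaPriorityRecord],
    target_class_h2: dict[str, float] | None = None,
    fisher_p_max: float = FISHER_P_MAX,
    h2_min: float = H2_TARGET_MIN,
) -> set[str]:
    """Candidate miRNAs: Fisher p < 0.05 AND target-class h2 > 0.1 (strict).

    ``target_class_h2`` can supply or override the variance proportion that
    the miRNA's target class captures; miRNAs without one are skipped with a
    warning.
    """
    candidates = set()
    for rec in records:
        h2 = (
            target_class_h2.get(rec.mirna_id, rec.target_class_h2)
            if target_class_h2
            else rec.target_class_h2
        )
        if np.isnan(h2):
            warnings.warn(f"{rec.mirna_id}: no target-class h2; skipped")
            rec.candidate = False
            continue
        rec.target_class_h2 = h2
        rec.candidate = (rec.fisher_p < fisher_p_max) and (h2 > h2_min)
        if rec.candidate:
            candidates.add(rec.mirna_id)
    return candidates


def de_overlap_test(candidate_set: set, de_set: set, universe: set):
    """Chi-square association between candidacy and differential expression.

    Returns (statistic, p, method): Yates-corrected chi-square on the 2x2
    membership cross-tabulation, replaced by a two-sided Fisher exact test
    when any expected cell count falls below 1.
    """
    if not candidate_set:
        raise ValueError("candidate set is empty")
    if not (candidate_set <= universe and de_set <= universe):
        raise ValueError("sets must be subsets of the universe")
    members = sorted(universe)
    cand = np.array([m in candidate_set for m in members])
    de = np.array([m in de_set for m in members])
    table = np.array(
        [
            [np.sum(cand & de), np.sum(cand & ~de)],
            [np.sum(~cand & de), np.sum(~cand & ~de)],
        ]
    )
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 1).any():
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return float("nan"), float(p), "fisher_exact"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p), "chi2_yates"
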