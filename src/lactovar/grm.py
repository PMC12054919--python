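"""Genotype QC, genomic relationship matrices, and variant-class bookkeeping.

The genomic relationship matrix (GRM) follows VanRaden's first method:
``G = Z Z' / (2 * sum_j p_j (1 - p_j))`` where ``Z`` holds dosages centred by
twice the observed alternate-allele frequency.  Functional classes are named
variant subsets defined either by genomic intervals (with per-class flanking
windows) or by explicit variant-ID lists; the designated ``other`` class is
always the complement of the union of the functional classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "FunctionalClassMap",
    "qc_filter",
    "compute_grm",
    "build_class_map",
    "ld_prune",
    "merge_panels",
]

MISSING = -1  # sentinel for missing dosage in integer storage


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    ``dosages`` is an (n, m) float array with values in {0, 1, 2} and NaN for
    missing calls.  ``variants`` is a DataFrame with columns
    (chrom, pos, id, ref, alt); positions are 0-based and strictly increasing
    within each chromosome.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = np.asarray(self.samples)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape does not match samples/variants")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per variant (missing ignored)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.samples,
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index], self.variants, self.samples[index]
        )

    def imputed(self) -> np.ndarray:
        """Dosages with missing values replaced by the variant mean."""
        X = self.dosages.copy()
        if np.isnan(X).any():
            mu = 2.0 * self.allele_freq()
            idx = np.where(np.isnan(X))
            X[idx] = mu[idx[1]]
        return X


@dataclass
class GRM:
    """Realized genomic relationship matrix for a set of individuals."""

    matrix: np.ndarray
    sample_ids: np.ndarray
    n_variants_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square over the sample set")


@dataclass
class FunctionalClassMap:
    """Named variant subsets plus the complementary ``other`` class."""

    classes: dict[str, set] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)
    universe: set = field(default_factory=set)
    other_name: str = "other"

    def other(self) -> set:
        union = set()
        for ids in self.classes.values():
            union |= ids
        return self.universe - union

    def mask(self, geno: GenotypeMatrix, name: str) -> np.ndarray:
        ids = self.other() if name == self.other_name else self.classes[name]
        return geno.variants["id"].isin(ids).to_numpy()

    def counts(self) -> dict[str, int]:
        out = {k: len(v) for k, v in self.classes.items()}
        out[self.other_name] = len(self.other())
        return out


def _hwe_chisq_p(dosages: np.ndarray) -> np.ndarray:
    """1-df chi-square Hardy-Weinberg p per variant from genotype counts."""
    d = dosages
    n0 = np.nansum(d == 0, axis=0).astype(float)
    n1 = np.nansum(d == 1, axis=0).astype(float)
    n2 = np.nansum(d == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    p = np.where(n > 0, (2 * n2 + n1) / (2 * np.maximum(n, 1)), 0.0)
    q = 1.0 - p
    e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
    chi2 = np.zeros_like(n)
    for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
        chi2 += term
    # monomorphic variants have a degenerate test; report p = 1
    mono = (p <= 0) | (p >= 1)
    pval = stats.chi2.sf(chi2, df=1)
    pval[mono] = 1.0
    return pval


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    callrate_min: float = 0.90,
    hwe_p_min: float = 1e-6,
) -> GenotypeMatrix:
    """Standard genotype quality control.

    Filter order: sample call rate, variant call rate, minor allele
    frequency, Hardy-Weinberg (1-df chi-square).  Thresholds are inclusive:
    a variant at MAF exactly ``maf_min`` or HWE p exactly ``hwe_p_min`` is
    retained.
    """
    ok = ~np.isnan(geno.dosages)
    sample_cr = ok.mean(axis=1)
    g = geno.take_samples(sample_cr >= callrate_min)
    if g.n_individuals == 0:
        raise ValueError("no samples pass the call-rate filter")
    ok = ~np.isnan(g.dosages)
    keep = ok.mean(axis=0) >= callrate_min
    g = g.take_variants(keep)
    if g.n_variants:
        g = g.take_variants(g.maf() >= maf_min)
    if g.n_variants:
        g = g.take_variants(_hwe_chisq_p(g.dosages) >= hwe_p_min)
    if g.n_variants == 0:
        raise ValueError("no variants pass QC")
    return g


def compute_grm(geno: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM with observed allele frequencies.

    Monomorphic variants contribute nothing to either the numerator or the
    normalizing denominator.  Missing dosages are mean-imputed first.
    """
    if geno.n_individuals < 2:
        raise ValueError("GRM needs at least two individuals")
    X = geno.imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all variants are monomorphic")
    Xp = X[:, poly]
    pp = p[poly]
    Z = Xp - 2.0 * pp
    denom = 2.0 * np.sum(pp * (1.0 - pp))
    G = (Z @ Z.T) / denom
    return GRM(G, geno.samples, int(poly.sum()))


def build_class_map(
    geno: GenotypeMatrix,
    interval_sets: dict[str, pd.DataFrame] | None = None,
    flank_bp: dict[str, int] | int | None = None,
    explicit_sets: dict[str, set] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> FunctionalClassMap:
    """Map variants to named functional classes.

    ``interval_sets`` maps class name to a BED-like frame with columns
    (chrom, start, end) in 0-based half-open coordinates.  A variant belongs
    to the class iff its position lies in [start - flank, end + flank),
    clipped at chromosome bounds.  ``explicit_sets`` supplies classes as
    literal variant-ID sets.
    """
    interval_sets = interval_sets or {}
    explicit_sets = explicit_sets or {}
    if not isinstance(flank_bp, dict):
        flank_bp = {name: (flank_bp or 0) for name in interval_sets}

    known_chroms = set(geno.variants["chrom"].unique())
    out = FunctionalClassMap(universe=set(geno.variants["id"]))
    var_by_chrom = {
        c: sub for c, sub in geno.variants.groupby("chrom", sort=False)
    }
    for name, bed in interval_sets.items():
        flank = int(flank_bp.get(name, 0))
        ids: set = set()
        for _, row in bed.iterrows():
            chrom = row["chrom"]
            if chrom not in known_chroms:
                raise ValueError(f"unknown chromosome {chrom!r} in intervals for {name!r}")
            lo = max(0, int(row["start"]) - flank)
            hi = int(row["end"]) + flank
            if chrom_lengths and chrom in chrom_lengths:
                hi = min(hi, int(chrom_lengths[chrom]))
            sub = var_by_chrom[chrom]
            hit = sub[(sub["pos"] >= lo) & (sub["pos"] < hi)]
            ids.update(hit["id"])
        out.classes[name] = ids
        out.provenance[name] = ("intervals", flank)
    for name, ids in explicit_sets.items():
        missing = set(ids) - out.universe
        if missing:
            raise ValueError(
                f"class {name!r} references {len(missing)} unknown variant IDs"
            )
        out.classes[name] = set(ids)
        out.provenance[name] = ("explicit", None)
    return out


def ld_prune(
    geno: GenotypeMatrix,
    r2_max: float = 0.9,
    window_bp: int = 1_000_000,
    step: int = 1,
) -> GenotypeMatrix:
    """Greedy keep-first LD pruning within a sliding physical window.

    Scanning left to right within each chromosome, a variant is dropped when
    its squared dosage correlation with any already-kept variant closer than
    ``window_bp`` exceeds ``r2_max`` (the earlier variant of the pair wins).
    ``step`` is the variant stride of the scan; the default 1 examines every
    variant and is the only deterministic order-stable choice.
    """
    if step != 1:
        raise NotImplementedError("only step=1 scanning is supported")
    thresh = min(r2_max, 1.0 - 1e-12)
    X = geno.imputed()
    sd = X.std(axis=0)
    keep_global: list[int] = []
    for chrom, sub in geno.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        kept: list[int] = []  # positions into idx
        for j in range(len(idx)):
            drop = False
            xj = X[:, idx[j]]
            if sd[idx[j]] > 0:
                for i in reversed(kept):
                    if pos[j] - pos[i] > window_bp:
                        break
                    if sd[idx[i]] == 0:
                        continue
                    r = np.corrcoef(xj, X[:, idx[i]])[0, 1]
                    if r * r > thresh:
                        drop = True
                        break
            if not drop:
                kept.append(j)
        keep_global.extend(idx[kept])
    keep_global.sort()
    return geno.take_variants(np.array(keep_global, dtype=int))


def merge_panels(base: GenotypeMatrix, extra: GenotypeMatrix) -> GenotypeMatrix:
    """Union of two panels over the same samples, keyed by (chrom, pos, alleles).

    Duplicated variants keep the ``base`` copy.  Output sorted by (chrom, pos).
    """
    if list(base.samples) != list(extra.samples):
        raise ValueError("panels must cover the same samples, in the same order")

    def keys(g: GenotypeMatrix):
        v = g.variants
        return list(zip(v["chrom"], v["pos"], v["ref"], v["alt"]))

    base_keys = set(keys(base))
    extra_new = [i for i, k in enumerate(keys(extra)) if k not in base_keys]
    dosages = np.hstack([base.dosages, extra.dosages[:, extra_new]])
    variants = pd.concat(
        [base.variants, extra.variants.iloc[extra_new]], ignore_index=True
    )
    order = variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    return GenotypeMatrix(dosages[:, order], variants.iloc[order], base.samples)
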