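"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study data: biallelic
genotypes at a stated MAF spectrum, SNP effects from a four-component normal
mixture with class-specific mixing proportions, deregressed-PTA-like
phenotypes at a target heritability with per-animal reliabilities, expression
panels with planted tissue-specific genes, miRNA/mRNA pairs with planted
anti-correlated targets, and sequencing reads with planted A-to-G editing.
Everything is bit-reproducible given a seed, and every quantity a downstream
stage estimates is recoverable from the returned truth records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import FunctionalClassMap, GenotypeMatrix

#: Variance multipliers of the four-component effect-size mixture: a point
#: mass at zero plus normals at 1%, 10% and 100% of the base effect variance.
MIXTURE_GAMMA = (0.0, 0.01, 0.1, 1.0)

__all__ = [
    "MIXTURE_GAMMA",
    "ClassSpec",
    "SimConfig",
    "TruthRecord",
    "sim_genotypes",
    "sim_class_map",
    "sim_effects_and_phenotypes",
    "sim_expression_panel",
    "sim_mirna_system",
    "sim_edited_reads",
    "sim_birth_years",
]


@dataclass
class ClassSpec:
    """One functional class: its share of variants and mixture proportions."""

    name: str
    fraction: float
    pi: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("class fraction must lie in [0, 1]")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("mixture proportions must be a 4-simplex point")


@dataclass
class SimConfig:
    n_individuals: int
    n_variants: int
    n_chromosomes: int = 2
    chrom_lengths: tuple[int, ...] | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    class_specs: list[ClassSpec] = field(default_factory=list)
    h2_target: float = 0.6
    reliability_range: tuple[float, float] = (0.8, 0.99)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2 or self.n_variants < 1:
            raise ValueError("need >= 2 individuals and >= 1 variant")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.chrom_lengths is None:
            self.chrom_lengths = tuple([1_000_000] * self.n_chromosomes)
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths length must equal n_chromosomes")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError("h2_target must lie in (0, 1)")
        if sum(s.fraction for s in self.class_specs if s.name != "other") > 1.0 + 1e-9:
            raise ValueError("class fractions sum above 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort, for recovery tests."""

    true_effects: np.ndarray
    true_component: np.ndarray  # mixture component index per variant (0..3)
    true_class_of_effect: np.ndarray  # class label per variant
    true_genetic_values: np.ndarray
    true_h2_realized: float
    sigma_e2: float
    true_editing_levels: dict | None = None
    true_specific_genes: dict | None = None
    true_targets: set | None = None


def sim_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Biallelic dosages Binomial(2, p) with p uniform over ``maf_range``.

    Variants are assigned to chromosomes with probability proportional to
    chromosome length and receive distinct, ascending positions.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_variants
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)

    lengths = np.asarray(config.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = np.sort(rng.choice(config.n_chromosomes, size=m, p=probs))
    names = config.chrom_names()
    chroms, positions = [], []
    for c in range(config.n_chromosomes):
        k = int((chrom_idx == c).sum())
        if k == 0:
            continue
        pos = np.sort(rng.choice(int(lengths[c]), size=k, replace=False))
        chroms.extend([names[c]] * k)
        positions.extend(pos.tolist())
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "id": [f"v{i}" for i in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    samples = np.array([f"animal{i}" for i in range(n)])
    return GenotypeMatrix(dosages, variants, samples)


def sim_class_map(geno: GenotypeMatrix, config: SimConfig) -> FunctionalClassMap:
    """Assign each class its stated fraction of variants, disjointly at random."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = geno.variants["id"].to_numpy()
    perm = rng.permutation(len(ids))
    out = FunctionalClassMap(universe=set(ids))
    start = 0
    for spec in config.class_specs:
        if spec.name == "other":
            continue
        k = int(round(spec.fraction * len(ids)))
        out.classes[spec.name] = set(ids[perm[start : start + k]])
        out.provenance[spec.name] = ("simulated", spec.fraction)
        start += k
    return out


def sim_effects_and_phenotypes(
    geno: GenotypeMatrix, classes: FunctionalClassMap, config: SimConfig
):
    """Draw mixture effects per class, then phenotypes at the target h².

    Effect of variant j is N(0, gamma_k) with component k drawn from its
    class's mixing proportions; gamma = (0, 0.01, 0.1, 1).  Genetic values
    g = Z beta (Z centred dosages) are rescaled so that var(g) equals
    h2_target and the empirical noise variance equals 1 - h2_target, which
    pins the realized heritability at the target.  The reported phenotype is
    a deregressed-PTA stand-in: g plus noise whose per-animal variance scales
    as 1/reliability.
    """
    from .varcomp import PhenotypeTable

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    pi_by_class = {s.name: np.asarray(s.pi, dtype=float) for s in config.class_specs}
    default_pi = pi_by_class.get("other", np.array([1.0, 0.0, 0.0, 0.0]))

    ids = geno.variants["id"].to_numpy()
    class_of = np.array(["other"] * len(ids), dtype=object)
    for name, members in classes.classes.items():
        class_of[np.isin(ids, list(members))] = name

    gamma = np.asarray(MIXTURE_GAMMA)
    component = np.empty(len(ids), dtype=int)
    for name in np.unique(class_of):
        pi = pi_by_class.get(name, default_pi)
        sel = class_of == name
        component[sel] = rng.choice(4, size=int(sel.sum()), p=pi)
    beta = rng.standard_normal(len(ids)) * np.sqrt(gamma[component])

    X = geno.imputed()
    Z = X - X.mean(axis=0)
    g = Z @ beta
    h2 = config.h2_target
    sd_g = g.std()
    if sd_g > 0:
        scale = np.sqrt(h2) / sd_g
        g = g * scale
        beta = beta * scale
        realized_sigma_e2 = 1.0 - h2
    else:
        realized_sigma_e2 = 1.0

    n = config.n_individuals
    rel = rng.uniform(*config.reliability_range, size=n)
    e = rng.standard_normal(n) / np.sqrt(rel)
    e = e - e.mean()
    if e.std() > 0:
        e = e * (np.sqrt(realized_sigma_e2) / e.std())
    y = g + e
    var_y = y.var()
    h2_real = float(g.var() / var_y) if var_y > 0 else 0.0

    truth = TruthRecord(
        true_effects=beta,
        true_component=component,
        true_class_of_effect=class_of,
        true_genetic_values=g,
        true_h2_realized=h2_real,
        sigma_e2=realized_sigma_e2,
    )
    table = PhenotypeTable(
        pd.DataFrame(
            {"animal_id": geno.samples, "dpta": y, "reliability": rel}
        )
    )
    return truth, table


def sim_expression_panel(
    n_genes: int,
    tissue_layout: dict[str, int],
    n_specific_per_tissue: int,
    effect_size: float,
    seed: int = 0,
    categories: dict[str, str] | None = None,
):
    """Expression panel with planted tissue-specific genes.

    Baseline log2 expression is N(0, 1); each tissue's planted specific genes
    get a +``effect_size`` mean shift in that tissue's samples.  Values are
    returned on the raw (FPKM-like) scale ``2**log2``.  Returns the panel and
    the truth map tissue -> planted gene IDs.
    """
    from .specificity import ExpressionMatrix

    if n_specific_per_tissue * len(tissue_layout) > n_genes:
        raise ValueError("more planted specific genes than genes")
    for tissue, k in tissue_layout.items():
        if k < 2:
            raise ValueError(f"tissue {tissue!r} needs >= 2 samples")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i}" for i in range(n_genes)]
    tissues = list(tissue_layout)
    categories = categories or {t: t for t in tissues}

    sample_tissue, sample_ids = [], []
    for t in tissues:
        for j in range(tissue_layout[t]):
            sample_tissue.append(t)
            sample_ids.append(f"{t}_s{j}")
    n_samples = len(sample_ids)
    log2 = rng.standard_normal((n_genes, n_samples))

    truth: dict[str, list[str]] = {}
    next_gene = 0
    tissue_arr = np.array(sample_tissue)
    for t in tissues:
        planted = list(range(next_gene, next_gene + n_specific_per_tissue))
        next_gene += n_specific_per_tissue
        log2[np.ix_(planted, np.flatnonzero(tissue_arr == t))] += effect_size
        truth[t] = [genes[i] for i in planted]

    values = pd.DataFrame(2.0**log2, index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "sample": sample_ids,
            "tissue": sample_tissue,
            "category": [categories[t] for t in sample_tissue],
            "project": rng.choice(["projA", "projB"], size=n_samples),
            "breed": rng.choice(["holstein", "jersey"], size=n_samples),
            "sex": rng.choice(["F", "M"], size=n_samples),
            "age": rng.uniform(1.0, 8.0, size=n_samples),
        }
    ).set_index("sample")
    return ExpressionMatrix(values, meta), truth


def sim_mirna_system(
    n_mirna: int,
    n_mrna: int,
    targets_per_mirna: int,
    frac_true_regulators: float,
    corr_strength: float,
    n_samples: int,
    seed: int = 0,
    frac_targets_regulated: float = 0.8,
):
    """miRNA/mRNA expression with planted anti-correlated target links.

    For each true-regulator miRNA, ``frac_targets_regulated`` of its listed
    targets are generated with correlation ~ -corr_strength to the miRNA;
    everything else is independent noise.  Returns (mirna_expr, mrna_expr,
    target_list, truth-regulator set).
    """
    if targets_per_mirna > n_mrna:
        raise ValueError("targets_per_mirna exceeds n_mrna")
    if not 0.0 <= corr_strength < 1.0:
        raise ValueError("corr_strength must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mirs = [f"mir{i}" for i in range(n_mirna)]
    mrnas = [f"mrna{i}" for i in range(n_mrna)]
    samples = [f"s{i}" for i in range(n_samples)]

    mirna_expr = pd.DataFrame(
        rng.standard_normal((n_mirna, n_samples)), index=mirs, columns=samples
    )
    mrna_expr = pd.DataFrame(
        rng.standard_normal((n_mrna, n_samples)), index=mrnas, columns=samples
    )

    n_reg = int(round(frac_true_regulators * n_mirna))
    regulators = set(rng.choice(mirs, size=n_reg, replace=False).tolist())

    # regulated mRNAs are disjoint across regulators so truth stays clean
    n_regulated = int(round(frac_targets_regulated * targets_per_mirna))
    pool = list(rng.permutation(mrnas))
    pairs = []
    for mir in mirs:
        if mir in regulators and n_regulated > 0:
            own = [pool.pop() for _ in range(min(n_regulated, len(pool)))]
            x = mirna_expr.loc[mir].to_numpy()
            for t in own:
                z = rng.standard_normal(n_samples)
                mrna_expr.loc[t] = -corr_strength * x + np.sqrt(
                    1.0 - corr_strength**2
                ) * z
            rest_pool = [m for m in mrnas if m not in own]
            rest = rng.choice(
                rest_pool, size=targets_per_mirna - len(own), replace=False
            ).tolist()
            targets = own + rest
        else:
            targets = rng.choice(mrnas, size=targets_per_mirna, replace=False).tolist()
        pairs.extend((mir, t) for t in targets)

    target_list = pd.DataFrame(pairs, columns=["mirna_id", "mrna_id"])
    return mirna_expr, mrna_expr, target_list, regulators


def sim_edited_reads(
    ref_length: int,
    n_sites: int,
    levels,
    depth: int,
    read_length: int,
    error_rate: float,
    seed: int = 0,
    sites_per_cluster: int = 4,
    cluster_span: int = 80,
    mapped_mismatch_max: int = 3,
):
    """Reads tiling a random reference with planted A-to-G editing.

    Sites are placed at A positions of the reference, grouped into clusters
    of ``sites_per_cluster`` sites spanning at most ``cluster_span`` bp.  At a
    planted site, each overlapping read carries G with probability equal to
    the site's editing level; independent per-base sequencing errors occur at
    ``error_rate``.  A read is flagged mapped when it differs from the
    reference at no more than ``mapped_mismatch_max`` positions, emulating
    the strict initial alignment whose rejects feed the hyper-editing search.

    Returns (reference string, read DataFrame, truth DataFrame of planted
    site positions and levels).
    """
    levels = np.atleast_1d(np.asarray(levels, dtype=float))
    if ((levels < 0) | (levels > 1)).any():
        raise ValueError("editing levels must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=ref_length, p=[0.35, 0.15, 0.15, 0.35])
    a_pos = np.flatnonzero(ref == "A")

    n_clusters = max(1, int(np.ceil(n_sites / sites_per_cluster)))
    gap = ref_length // (n_clusters + 1)
    site_pos: list[int] = []
    for c in range(n_clusters):
        lo = (c + 1) * gap - cluster_span // 2
        hi = lo + cluster_span
        window = a_pos[(a_pos >= lo) & (a_pos < hi)]
        want = min(sites_per_cluster, n_sites - len(site_pos))
        if len(window) < want:
            raise ValueError("not enough A positions to place editing sites")
        site_pos.extend(
            np.sort(rng.choice(window, size=want, replace=False)).tolist()
        )
    site_pos_arr = np.array(sorted(site_pos))
    site_levels = levels[np.arange(len(site_pos_arr)) % len(levels)]
    level_at = dict(zip(site_pos_arr.tolist(), site_levels.tolist()))

    n_reads = int(np.ceil(depth * ref_length / read_length))
    starts = rng.integers(0, max(1, ref_length - read_length + 1), size=n_reads)
    records = []
    for i, s in enumerate(sorted(starts.tolist())):
        seq = ref[s : s + read_length].copy()
        for p in site_pos_arr[(site_pos_arr >= s) & (site_pos_arr < s + read_length)]:
            if rng.random() < level_at[int(p)]:
                seq[p - s] = "G"
        if error_rate > 0:
            err = rng.random(read_length) < error_rate
            for j in np.flatnonzero(err):
                seq[j] = rng.choice(bases[bases != seq[j]])
        quals = rng.integers(30, 41, size=read_length)
        n_mismatch = int((seq != ref[s : s + read_length]).sum())
        records.append(
            {
                "read_id": f"read{i}",
                "chrom": "ref",
                "pos": int(s),
                "seq": "".join(seq),
                "qual": "".join(chr(q + 33) for q in quals),
                "mapped": n_mismatch <= mapped_mismatch_max,
            }
        )
    reads = pd.DataFrame(records)
    truth = pd.DataFrame({"pos": site_pos_arr, "level": site_levels})
    return "".join(ref), reads, truth


def sim_birth_years(
    n: int, validation_frac: float = 0.17, cutoff_year: int = 2010, seed: int = 0
) -> np.ndarray:
    """Birth years putting ~``validation_frac`` of animals at/after the cutoff."""
    rng = np.random.default_rng(seed)
    recent = rng.random(n) < validation_frac
    years = np.where(recent, cutoff_year, rng.integers(2000, cutoff_year, size=n))
    return years.astype(int)
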