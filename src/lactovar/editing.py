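"""Hyper-editing-style A-to-I RNA editing detection on read fixtures.

Reads rejected by a strict initial alignment are A->G collapsed ("hyper-edit
transform") and realigned to the equally collapsed reference, so genuinely
hyper-edited reads place with few mismatches.  Candidate reads are then
screened on the original sequences: enough A->G mismatches (>= 5% of the
read length, or >= 3 for reads <= 60 bp), A->G dominating all mismatches
(> 80%), adequate base quality, and low-complexity filters.  Editing levels
combine the mapped pileup with the recovered reads:

    level = (mapped G + unmapped G) / (mapped depth + unmapped G)

Sites within 100 bp chain into clusters.  The library is unstranded, so
T->C sites are collapsed onto the A->G channel.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EditingCluster",
    "hyper_edit_transform",
    "realign_transformed",
    "classify_candidate_read",
    "editing_level",
    "collapse_strand",
    "call_clusters",
    "cluster_summary",
    "detect_sites",
    "compare_stages",
]

_DNA = set("ACGTN")


def hyper_edit_transform(seq: str) -> str:
    """Collapse the A/G distinction: every A becomes G (idempotent)."""
    if set(seq) - _DNA:
        raise ValueError("sequence contains non-DNA characters")
    return seq.replace("A", "G")


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def realign_transformed(
    reads: list[str],
    reference: str,
    max_mismatch: int,
    seed_len: int = 20,
) -> list[int | None]:
    """Best ungapped placement of each A->G-collapsed read on the collapsed
    reference.

    An exact seed lookup proposes candidate offsets; reads without a seed hit
    fall back to a full Hamming scan.  Ties break leftmost; reads whose best
    placement exceeds ``max_mismatch`` mismatches are reported as None.
    """
    ref_t = _seq_array(hyper_edit_transform(reference))
    L = len(ref_t)
    index: dict[bytes, list[int]] = {}
    step = max(1, seed_len // 2)
    for i in range(0, L - seed_len + 1, 1):
        index.setdefault(ref_t[i : i + seed_len].tobytes(), []).append(i)

    placements: list[int | None] = []
    for read in reads:
        rt = _seq_array(hyper_edit_transform(read))
        rl = len(rt)
        if rl > L:
            placements.append(None)
            continue
        candidates: set[int] = set()
        for off in range(0, max(1, rl - seed_len + 1), step):
            hits = index.get(rt[off : off + seed_len].tobytes(), [])
            candidates.update(h - off for h in hits if 0 <= h - off <= L - rl)
        if candidates:
            best_pos, best_mm = None, max_mismatch + 1
            for pos in sorted(candidates):
                mm = int(np.count_nonzero(ref_t[pos : pos + rl] != rt))
                if mm < best_mm:
                    best_pos, best_mm = pos, mm
            if best_mm <= max_mismatch:
                placements.append(best_pos)
                continue
        # fall back to an exhaustive scan
        windows = np.lib.stride_tricks.sliding_window_view(ref_t, rl)
        mms = np.count_nonzero(windows != rt, axis=1)
        pos = int(np.argmin(mms))  # argmin returns the leftmost minimum
        placements.append(pos if mms[pos] <= max_mismatch else None)
    return placements


def _has_simple_repeat(seq: str, max_repeats: int = 10) -> bool:
    """Mono- or di-nucleotide motif repeated more than ``max_repeats`` times."""
    for motif_len in (1, 2):
        pattern = re.compile(r"(.{%d})\1{%d,}" % (motif_len, max_repeats))
        if pattern.search(seq):
            return True
    return False


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def classify_candidate_read(
    read_seq: str,
    ref_window: str,
    quals: np.ndarray | None = None,
    min_mean_phred: float = 25.0,
    max_n_frac: float = 0.10,
    edit_frac_min: float = 0.8,
    max_simple_repeats: int = 10,
    max_homopolymer: int = 20,
):
    """Screen a placed candidate read; returns (pass, mismatch profile).

    The profile lists (offset, ref_base, read_base).  A->G and T->C
    mismatches count as the editing channel; the read passes when the
    editing count reaches 5% of the read length (>= 3 for reads <= 60 bp),
    exceeds ``edit_frac_min`` of all mismatches, and the quality/complexity
    filters hold.
    """
    if len(read_seq) != len(ref_window):
        raise ValueError("read and reference window lengths differ")
    rl = len(read_seq)
    profile = [
        (i, r, s)
        for i, (r, s) in enumerate(zip(ref_window, read_seq))
        if r != s and s != "N" and r != "N"
    ]
    edit = [m for m in profile if (m[1], m[2]) in (("A", "G"), ("T", "C"))]
    n_edit, n_total = len(edit), len(profile)
    threshold = 3 if rl <= 60 else ceil(0.05 * rl)
    ok = n_edit >= threshold
    ok = ok and n_total > 0 and (n_edit / n_total) > edit_frac_min
    if quals is not None and len(quals):
        ok = ok and float(np.mean(quals)) > min_mean_phred
    ok = ok and (read_seq.count("N") / rl) <= max_n_frac
    ok = ok and not _has_simple_repeat(read_seq, max_simple_repeats)
    ok = ok and _max_homopolymer(read_seq) <= max_homopolymer
    return ok, profile


def editing_level(mapped_g: int, unmapped_g: int, mapped_depth: int) -> float:
    """(mapped G + unmapped G) / (mapped depth + unmapped G); 0 when empty."""
    if min(mapped_g, unmapped_g, mapped_depth) < 0:
        raise ValueError("counts must be nonnegative")
    if mapped_g > mapped_depth:
        raise ValueError("mapped G cannot exceed mapped depth")
    denom = mapped_depth + unmapped_g
    return (mapped_g + unmapped_g) / denom if denom else 0.0


def collapse_strand(sites: pd.DataFrame) -> pd.DataFrame:
    """Relabel T->C sites as A->G (unstranded library), merging duplicates."""
    if sites.empty:
        return sites
    out = sites.copy()
    tc = (out["ref_base"] == "T") & (out["alt_base"] == "C")
    out.loc[tc, ["ref_base", "alt_base"]] = ["A", "G"]
    out["type"] = out["ref_base"] + "-to-" + out["alt_base"]
    count_cols = [c for c in ("mapped_G", "unmapped_G", "mapped_depth") if c in out]
    grouped = out.groupby(["chrom", "pos", "ref_base", "alt_base", "type"], as_index=False)[
        count_cols
    ].sum()
    if count_cols:
        grouped["level"] = [
            editing_level(r.get("mapped_G", 0), r.get("unmapped_G", 0), r.get("mapped_depth", 0))
            for r in grouped.to_dict("records")
        ]
    return grouped.sort_values(["chrom", "pos"]).reset_index(drop=True)


@dataclass
class EditingCluster:
    chrom: str
    start: int
    end: int  # position of the last member site
    n_sites: int
    site_pos: list[int]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_clusters(sites: pd.DataFrame, max_gap: int = 100) -> list[EditingCluster]:
    """Single-linkage chaining of same-chromosome sites with gap <= max_gap."""
    if sites.empty:
        return []
    s = sites[["chrom", "pos"]].drop_duplicates()
    if not s.equals(s.sort_values(["chrom", "pos"])):
        warnings.warn("sites were not sorted; sorting internally")
        s = s.sort_values(["chrom", "pos"])
    clusters: list[EditingCluster] = []
    for chrom, sub in s.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > max_gap:
                members = pos[start:i].tolist()
                clusters.append(
                    EditingCluster(chrom, int(members[0]), int(members[-1]), len(members), members)
                )
                start = i
    return clusters


def cluster_summary(clusters: list[EditingCluster]) -> dict:
    if not clusters:
        return {"n_clusters": 0, "mean_length": 0.0, "mean_sites": 0.0}
    return {
        "n_clusters": len(clusters),
        "mean_length": float(np.mean([c.length for c in clusters])),
        "mean_sites": float(np.mean([c.n_sites for c in clusters])),
    }


def detect_sites(
    reads: pd.DataFrame,
    reference: str,
    chrom: str = "ref",
    max_mismatch_frac: float = 0.10,
    min_support: int = 1,
    **classify_kw,
) -> pd.DataFrame:
    """Full per-sample editing pipeline on a read fixture.

    ``reads`` has columns (read_id, pos, seq, qual, mapped).  Unmapped reads
    go through the hyper-editing transform, realignment, and the candidate
    screen; A->G (and T->C) mismatch positions of passing reads become
    candidate sites.  Mapped reads supply the pileup depth and mapped-G
    counts, and levels follow the combined-count formula.  Sites supported
    by fewer than ``min_support`` recovered reads are discarded.
    """
    unmapped = reads[~reads["mapped"]]
    site_counts: dict[tuple[int, str, str], int] = {}
    placements = realign_transformed(
        unmapped["seq"].tolist(),
        reference,
        max_mismatch=max(1, int(max_mismatch_frac * unmapped["seq"].str.len().max()))
        if len(unmapped)
        else 1,
    )
    for (_, row), pos in zip(unmapped.iterrows(), placements):
        if pos is None:
            continue
        window = reference[pos : pos + len(row["seq"])]
        quals = np.array([ord(c) - 33 for c in row["qual"]]) if row.get("qual") else None
        ok, profile = classify_candidate_read(row["seq"], window, quals, **classify_kw)
        if not ok:
            continue
        for off, ref_b, read_b in profile:
            if (ref_b, read_b) in (("A", "G"), ("T", "C")):
                key = (pos + off, ref_b, read_b)
                site_counts[key] = site_counts.get(key, 0) + 1

    records = []
    mapped = reads[reads["mapped"]]
    m_pos = mapped["pos"].to_numpy() if len(mapped) else np.empty(0, int)
    m_seq = mapped["seq"].tolist()
    for (site, ref_b, read_b), support in sorted(site_counts.items()):
        if support < min_support:
            continue
        mapped_depth = 0
        mapped_g = 0
        for rp, seq in zip(m_pos, m_seq):
            if rp <= site < rp + len(seq):
                mapped_depth += 1
                if seq[site - rp] == read_b:
                    mapped_g += 1
        records.append(
            {
                "chrom": chrom,
                "pos": int(site),
                "ref_base": ref_b,
                "alt_base": read_b,
                "mapped_G": mapped_g,
                "unmapped_G": support,
                "mapped_depth": mapped_depth,
                "level": editing_level(mapped_g, support, mapped_depth),
                "type": f"{ref_b}-to-{read_b}",
            }
        )
    sites = pd.DataFrame(
        records,
        columns=[
            "chrom", "pos", "ref_base", "alt_base",
            "mapped_G", "unmapped_G", "mapped_depth", "level", "type",
        ],
    )
    return collapse_strand(sites)


def compare_stages(
    site_tables: dict[str, pd.DataFrame],
    group_labels: dict[str, str],
    alpha: float = 0.05,
) -> dict:
    """Stage comparison of per-sample editing-site tables.

    A site is stage-qualified when present in every sample of that stage;
    specific = qualified in exactly one stage, common = qualified in both.
    Common sites are tested for differential levels with a Wilcoxon rank-sum
    test, Benjamini-Hochberg adjusted at ``alpha``.
    """
    from statsmodels.stats.multitest import multipletests

    groups = sorted(set(group_labels.values()))
    if len(groups) != 2:
        raise ValueError("exactly two stages required")
    by_group = {
        g: [s for s, lab in group_labels.items() if lab == g] for g in groups
    }
    for g, members in by_group.items():
        if len(members) < 2:
            raise ValueError(f"stage {g!r} needs >= 2 samples")

    presence: dict[str, dict[tuple, float]] = {}
    for sample, tab in site_tables.items():
        presence[sample] = {
            (r["chrom"], r["pos"]): r["level"] for _, r in tab.iterrows()
        }
    qualified = {
        g: set.intersection(*(set(presence[s]) for s in by_group[g]))
        for g in groups
    }
    specific = {
        g: qualified[g] - qualified[other]
        for g, other in ((groups[0], groups[1]), (groups[1], groups[0]))
    }
    common = qualified[groups[0]] & qualified[groups[1]]

    differential = set()
    pvals, keys = [], []
    for site in sorted(common):
        a = [presence[s][site] for s in by_group[groups[0]]]
        b = [presence[s][site] for s in by_group[groups[1]]]
        try:
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        except ValueError:  # identical values
            p = 1.0
        pvals.append(p)
        keys.append(site)
    if pvals:
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        differential = {k for k, r in zip(keys, reject) if r}
    return {
        "stage_specific": specific,
        "common": common,
        "differential": differential,
    }
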