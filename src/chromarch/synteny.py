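"""Loop-synteny conservation testing across two genomes.

Tests whether the genes flanking loop regions in species A are more
syntenically conserved in species B than genes flanking length-matched
background regions.  For each region, the two ends are mapped to their
closest overlapping genes (the synteny anchors); the per-region conservation
count is the number of orthogroups shared between the inter-anchor gene sets
of the two species.  Global fractions are compared with a chi-squared
goodness-of-fit test against background-derived probabilities, and the
per-region count distributions with a one-sided Wilcoxon rank-sum test with
continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chisquare, mannwhitneyu

__all__ = [
    "OrthologyMap",
    "RegionPairSet",
    "sample_background_regions",
    "map_region_to_flanking_genes",
    "synteny_conservation_test",
]


@dataclass
class OrthologyMap:
    """Gene-to-orthogroup assignments for two species (one-to-many allowed)."""

    a_to_og: dict[str, set[str]]
    b_to_og: dict[str, set[str]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologyMap":
        """Build from a table with ``gene_a``, ``gene_b``, ``orthogroup``."""
        a_to_og: dict[str, set[str]] = {}
        b_to_og: dict[str, set[str]] = {}
        for row in df.itertuples():
            a_to_og.setdefault(row.gene_a, set()).add(row.orthogroup)
            b_to_og.setdefault(row.gene_b, set()).add(row.orthogroup)
        return cls(a_to_og=a_to_og, b_to_og=b_to_og)


@dataclass
class RegionPairSet:
    """Mapped foreground/background regions ready for the conservation test."""

    foreground: pd.DataFrame
    background: pd.DataFrame
    n_unmappable_fg: int = 0
    n_unmappable_bg: int = 0


def sample_background_regions(
    chrom_lengths: dict[str, int],
    foreground: pd.DataFrame,
    multiplier: int = 3,
    seed: int | np.random.Generator = 0,
    max_tries_per_region: int = 1_000,
) -> pd.DataFrame:
    """Length-matched random background regions avoiding the foreground.

    Each background region's length is drawn with replacement from the
    foreground length multiset; placement is uniform over the genome and
    rejected when the candidate overlaps any foreground region or runs off a
    chromosome end.  ``multiplier`` times as many regions as the foreground
    are produced; placement failure after bounded retries raises with
    diagnostics.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = (foreground.end - foreground.start).to_numpy(int)
    if lengths.size == 0:
        raise ValueError("empty foreground")
    n_bg = multiplier * lengths.size
    chroms = list(chrom_lengths)
    sizes = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    fg_by_chrom = {
        c: sub[["start", "end"]].to_numpy(int)
        for c, sub in foreground.groupby("chrom")
    }
    rows = []
    for k in range(n_bg):
        L = int(lengths[rng.integers(lengths.size)])
        placed = False
        for _ in range(max_tries_per_region):
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            limit = chrom_lengths[chrom] - L
            if limit <= 0:
                continue
            s = int(rng.integers(limit))
            e = s + L
            ivals = fg_by_chrom.get(chrom)
            if ivals is not None and np.any((ivals[:, 0] < e) & (ivals[:, 1] > s)):
                continue
            rows.append((chrom, s, e))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place background region {k} (length {L}) after "
                f"{max_tries_per_region} tries; genome too crowded"
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _closest_gene(genes_start: np.ndarray, genes_end: np.ndarray,
                  point: int) -> int:
    """Index of the gene overlapping ``point``, else nearest by distance.

    Ties break to the smaller start coordinate.
    """
    inside = np.flatnonzero((genes_start <= point) & (point < genes_end))
    if inside.size:
        return int(inside[np.argmin(genes_start[inside])])
    d_left = np.where(point >= genes_end, point - genes_end + 1, np.inf)
    d_right = np.where(point < genes_start, genes_start - point, np.inf)
    dist = np.minimum(d_left, d_right)
    best = np.flatnonzero(dist == dist.min())
    return int(best[np.argmin(genes_start[best])])


def map_region_to_flanking_genes(
    regions: pd.DataFrame,
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    orthology: OrthologyMap | pd.DataFrame,
) -> pd.DataFrame:
    """Assign each region its two flanking anchor genes and B counterparts.

    Each region end gets the closest overlapping gene (overlap first, then
    nearest, ties to the smaller start).  Regions whose anchors share one
    gene are flagged ``degenerate``; regions whose anchor genes lack
    orthologs are flagged ``unmappable`` and excluded from testing.
    """
    if isinstance(orthology, pd.DataFrame):
        orthology = OrthologyMap.from_frame(orthology)
    rows = []
    for chrom, sub in regions.groupby("chrom", sort=False):
        g = genes_a[genes_a.chrom == chrom].sort_values("start")
        if g.empty:
            for r in sub.itertuples():
                rows.append((chrom, r.start, r.end, None, None, False, True))
            continue
        gs = g.start.to_numpy(int)
        ge = g.end.to_numpy(int)
        gids = g.gene_id.to_numpy()
        for r in sub.itertuples():
            i_left = _closest_gene(gs, ge, int(r.start))
            i_right = _closest_gene(gs, ge, int(r.end) - 1)
            left, right = gids[i_left], gids[i_right]
            degenerate = left == right
            has_orth = (left in orthology.a_to_og
                        and right in orthology.a_to_og)
            rows.append((chrom, r.start, r.end, left, right, degenerate,
                         not has_orth))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "gene_left", "gene_right", "degenerate",
        "unmappable"])


def _inter_anchor_orthogroups(
    gene_lo: str, gene_hi: str,
    order: dict[str, int], ordered_ids: np.ndarray,
    gene_to_og: dict[str, set[str]],
) -> set[str]:
    """Orthogroups of the genes between (and including) two anchors."""
    i, j = order[gene_lo], order[gene_hi]
    if i > j:
        i, j = j, i
    ogs: set[str] = set()
    for gid in ordered_ids[i:j + 1]:
        ogs |= gene_to_og.get(gid, set())
    return ogs


def _region_counts(
    mapped: pd.DataFrame,
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    orthology: OrthologyMap,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region (shared, candidate) ortholog counts.

    candidate = orthogroups spanned between the anchors in species A;
    shared = those also present between the anchor counterparts in species B.
    Each orthogroup counts at most once per region.
    """
    order_a: dict[str, int] = {}
    ids_a_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in genes_a.groupby("chrom"):
        s = sub.sort_values("start")
        ids = s.gene_id.to_numpy()
        ids_a_by_chrom[chrom] = ids
        for i, gid in enumerate(ids):
            order_a[gid] = i
    order_b: dict[str, int] = {}
    ids_b_by_chrom: dict[str, np.ndarray] = {}
    chrom_b_of: dict[str, str] = {}
    for chrom, sub in genes_b.groupby("chrom"):
        s = sub.sort_values("start")
        ids = s.gene_id.to_numpy()
        ids_b_by_chrom[chrom] = ids
        for i, gid in enumerate(ids):
            order_b[gid] = i
            chrom_b_of[gid] = chrom
    # counterpart in B of an A gene: any B gene sharing an orthogroup; index it
    og_to_b: dict[str, list[str]] = {}
    for gid, ogs in orthology.b_to_og.items():
        for og in ogs:
            og_to_b.setdefault(og, []).append(gid)

    shared_counts, candidate_counts = [], []
    for r in mapped.itertuples():
        if r.unmappable:
            continue
        ogs_a = _inter_anchor_orthogroups(
            r.gene_left, r.gene_right, order_a, ids_a_by_chrom[r.chrom],
            orthology.a_to_og)
        # B counterparts of the two anchors (first listed counterpart each)
        b_left = _counterpart(r.gene_left, orthology, og_to_b)
        b_right = _counterpart(r.gene_right, orthology, og_to_b)
        if b_left is None or b_right is None:
            continue
        cb_l, cb_r = chrom_b_of[b_left], chrom_b_of[b_right]
        if cb_l != cb_r:
            ogs_b = orthology.b_to_og.get(b_left, set()) | orthology.b_to_og.get(
                b_right, set())
        else:
            ogs_b = _inter_anchor_orthogroups(
                b_left, b_right, order_b, ids_b_by_chrom[cb_l],
                orthology.b_to_og)
        shared_counts.append(len(ogs_a & ogs_b))
        candidate_counts.append(len(ogs_a))
    return np.asarray(shared_counts), np.asarray(candidate_counts)


def _counterpart(gene_a: str, orthology: OrthologyMap,
                 og_to_b: dict[str, list[str]]) -> str | None:
    for og in sorted(orthology.a_to_og.get(gene_a, ())):
        cands = og_to_b.get(og)
        if cands:
            return sorted(cands)[0]
    return None


def synteny_conservation_test(
    fg_mapped: pd.DataFrame,
    bg_mapped: pd.DataFrame,
    genes_a: pd.DataFrame,
    genes_b: pd.DataFrame,
    orthology: OrthologyMap | pd.DataFrame,
    min_regions: int = 5,
) -> dict:
    """Foreground-vs-background synteny conservation statistics.

    Returns global shared-ortholog fractions, the chi-squared goodness-of-fit
    p-value of the foreground counts against background-derived
    probabilities, and the one-sided (foreground > background) Wilcoxon
    rank-sum p-value with continuity correction on the per-region counts.
    Degenerate inputs (zero variance) yield NA p-values.
    """
    if isinstance(orthology, pd.DataFrame):
        orthology = OrthologyMap.from_frame(orthology)
    fg_shared, fg_cand = _region_counts(fg_mapped, genes_a, genes_b, orthology)
    bg_shared, bg_cand = _region_counts(bg_mapped, genes_a, genes_b, orthology)
    if fg_shared.size < min_regions or bg_shared.size < min_regions:
        raise ValueError(
            f"need at least {min_regions} testable regions per set "
            f"(got {fg_shared.size} foreground, {bg_shared.size} background)")
    fg_tot, fg_n = int(fg_shared.sum()), int(fg_cand.sum())
    bg_tot, bg_n = int(bg_shared.sum()), int(bg_cand.sum())
    fg_frac = fg_tot / fg_n if fg_n else np.nan
    bg_frac = bg_tot / bg_n if bg_n else np.nan

    chi2_p = np.nan
    chi2_stat = np.nan
    if fg_n > 0 and 0.0 < bg_frac < 1.0:
        expected = np.array([bg_frac, 1.0 - bg_frac]) * fg_n
        stat = chisquare([fg_tot, fg_n - fg_tot], f_exp=expected)
        chi2_stat, chi2_p = float(stat.statistic), float(stat.pvalue)

    wilcox_p = np.nan
    wilcox_stat = np.nan
    if np.ptp(np.concatenate([fg_shared, bg_shared])) > 0:
        res = mannwhitneyu(fg_shared, bg_shared, alternative="greater",
                           use_continuity=True, method="asymptotic")
        wilcox_stat, wilcox_p = float(res.statistic), float(res.pvalue)

    return {
        "n_foreground": int(fg_shared.size),
        "n_background": int(bg_shared.size),
        "foreground_fraction": float(fg_frac),
        "background_fraction": float(bg_frac),
        "foreground_mean_shared": float(fg_shared.mean()),
        "background_mean_shared": float(bg_shared.mean()),
        "chi2_statistic": chi2_stat,
        "chi2_p": chi2_p,
        "wilcoxon_statistic": wilcox_stat,
        "wilcoxon_p": wilcox_p,
    }
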