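"""Chromatin-loop calling, APA scoring, anchor and gene-group annotation.

Loops are focal O/E enrichments between two anchors.  The caller here is a
transparent ring-background focal-peak detector; externally called loops can
be imported as BEDPE and flow through the same APA scoring and annotation.
Anchors are classified as promoter (P), enhancer (E) or undefined (U) from
quantile-normalised H3K4me3/me2/me1 coverage; promoter hubs are connected
components of the promoter-promoter loop graph; genes split into GP1
(active, looped), GP2 (active, unlooped) and GP3 (silent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from scipy.stats import poisson
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "LoopSet",
    "AnchorAnnotation",
    "PromoterHub",
    "call_loops",
    "apa",
    "filter_apa_outliers",
    "classify_anchors",
    "promoter_hubs",
    "classify_genes_gp",
    "gene_group_apa",
    "loop_statistics",
    "quantile_normalize_columns",
]


@dataclass
class LoopSet:
    """Anchor-pair intervals with enrichment and APA scores (one chromosome)."""

    chrom: str
    bin_size: int
    table: pd.DataFrame  # bin1, bin2, enrichment, count [, apa]
    anchor_width: int = 2  # bins
    aggregate_apa: float | None = None

    def __len__(self) -> int:
        return len(self.table)

    def anchor_intervals(self) -> pd.DataFrame:
        """BEDPE-style bp intervals, anchors expanded to ``anchor_width`` bins."""
        half = self.anchor_width // 2
        bs = self.bin_size
        t = self.table
        return pd.DataFrame({
            "chrom1": self.chrom,
            "start1": np.maximum(t.bin1 - half, 0) * bs,
            "end1": (t.bin1 - half + self.anchor_width) * bs,
            "chrom2": self.chrom,
            "start2": np.maximum(t.bin2 - half, 0) * bs,
            "end2": (t.bin2 - half + self.anchor_width) * bs,
        })

    def unique_anchors(self) -> pd.DataFrame:
        """Deduplicated anchor bins with the loops each participates in."""
        bins = np.concatenate([self.table.bin1.to_numpy(), self.table.bin2.to_numpy()])
        uniq = np.unique(bins)
        return pd.DataFrame({"chrom": self.chrom, "bin": uniq})


@dataclass
class AnchorAnnotation:
    """P/E/U classes and normalised mark coverage per unique anchor."""

    anchors: pd.DataFrame  # chrom, bin, cpm_* columns, class
    window: int
    loop_classes: pd.Series  # per-loop 'P-P', 'P-E', 'E-E', 'U'
    category_counts: pd.Series


@dataclass
class PromoterHub:
    anchors: list[int]  # anchor bins
    genes: list[str]
    span: int  # bp

    @property
    def n_promoters(self) -> int:
        return len(self.anchors)


def call_loops(
    oe: np.ndarray,
    counts: np.ndarray,
    chrom: str = "chr",
    bin_size: int = 1,
    min_dist: int = 2,
    max_dist: int | None = None,
    fold_threshold: float = 2.0,
    min_count: int = 5,
    ring_radius: int = 5,
    anchor_width: int = 2,
    pixel_alpha: float | None = 1e-6,
) -> LoopSet:
    """Focal-peak loop calling with a local ring background.

    A pixel is a candidate when its O/E exceeds ``fold_threshold`` times the
    mean of the surrounding ring (a ``(2r+1)`` square minus the central 3x3)
    and its raw count reaches ``min_count``; with ``pixel_alpha`` set
    (default) the raw count must additionally be Poisson-significant against
    the ring's mean raw count, which suppresses chance O/E spikes in the
    sparse long-distance band.  8-connected candidates merge; the peak
    (max O/E) pixel of each component is reported.  Distances are in bins.
    """
    n = oe.shape[0]
    if min_dist < 2:
        raise ValueError("min_dist must be at least 2 bins")
    max_dist = max_dist if max_dist is not None else n
    idx = np.arange(n)
    dist = idx[None, :] - idx[:, None]
    band = (dist >= min_dist) & (dist <= max_dist)
    if not band.any():
        raise ValueError("empty O/E band between min_dist and max_dist")

    fin = np.isfinite(oe)
    vals = np.where(fin, oe, 0.0)
    r = ring_radius
    big = _box_sum(vals, r), _box_sum(fin.astype(float), r)
    small = _box_sum(vals, 1), _box_sum(fin.astype(float), 1)
    ring_sum = big[0] - small[0]
    ring_cnt = big[1] - small[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        ring_mean = np.where(ring_cnt > 0, ring_sum / ring_cnt, np.nan)
    cand = band & fin & np.isfinite(ring_mean)
    cand &= oe >= fold_threshold * np.where(ring_mean > 0, ring_mean, np.inf)
    cand &= counts >= min_count
    if pixel_alpha is not None:
        big_c = _box_sum(counts.astype(float), r)
        small_c = _box_sum(counts.astype(float), 1)
        ring_lam = np.where(ring_cnt > 0, (big_c - small_c) / np.maximum(ring_cnt, 1), 0.0)
        with np.errstate(invalid="ignore"):
            sig = poisson.sf(counts - 1, np.maximum(ring_lam, 1e-12)) < pixel_alpha
        cand &= sig

    labels, n_comp = cc_label(cand, structure=np.ones((3, 3), dtype=int))
    rows = []
    for comp in range(1, n_comp + 1):
        ii, jj = np.nonzero(labels == comp)
        k = np.argmax(oe[ii, jj])
        b1, b2 = int(ii[k]), int(jj[k])
        with np.errstate(invalid="ignore"):
            enr = float(oe[b1, b2] / ring_mean[b1, b2])
        rows.append((min(b1, b2), max(b1, b2), enr, float(counts[b1, b2])))
    table = pd.DataFrame(rows, columns=["bin1", "bin2", "enrichment", "count"])
    table = table.sort_values(["bin1", "bin2"], kind="stable").reset_index(drop=True)
    return LoopSet(chrom=chrom, bin_size=bin_size, table=table,
                   anchor_width=anchor_width)


def _box_sum(mat: np.ndarray, r: int) -> np.ndarray:
    """Sum over the (2r+1)x(2r+1) neighbourhood of each pixel."""
    n = mat.shape[0]
    S = np.zeros((n + 1, n + 1))
    S[1:, 1:] = mat.cumsum(0).cumsum(1)
    out = np.empty_like(mat, dtype=float)
    i = np.arange(n)
    lo = np.clip(i - r, 0, n)
    hi = np.clip(i + r + 1, 0, n)
    out = (S[np.ix_(hi, hi)] - S[np.ix_(lo, hi)] - S[np.ix_(hi, lo)]
           + S[np.ix_(lo, lo)])
    return out


def apa(
    oe: np.ndarray,
    loops: LoopSet,
    half_window: int = 10,
) -> LoopSet:
    """Aggregate peak analysis of a loop set on the O/E map.

    Each loop contributes the ``(2h+1)`` square of O/E centred on its pixel;
    APA = mean of the central 3x3 over the mean of the lower-left corner
    quadrant (``h/2 x h/2``), the short-distance background.  The aggregate
    APA applies the same ratio to the element-wise mean submatrix.  Loops too
    close to the matrix edge or diagonal are skipped (count reported via
    ``loops.table['apa']`` NaN).
    """
    h = half_window
    n = oe.shape[0]
    q = max(1, h // 2)
    per_loop = np.full(len(loops), np.nan)
    acc = np.zeros((2 * h + 1, 2 * h + 1))
    cnt = np.zeros_like(acc)
    used = 0
    for k, row in enumerate(loops.table.itertuples()):
        b1, b2 = int(row.bin1), int(row.bin2)
        if b1 - h < 0 or b2 + h >= n or (b2 - b1) <= 2 * h:
            continue
        sub = oe[b1 - h:b1 + h + 1, b2 - h:b2 + h + 1]
        per_loop[k] = _apa_ratio(sub, h, q)
        fin = np.isfinite(sub)
        acc[fin] += sub[fin]
        cnt[fin] += 1
        used += 1
    if used == 0:
        raise ValueError("all loops skipped: too close to edge or diagonal")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_map = np.where(cnt > 0, acc / cnt, np.nan)
    loops.table = loops.table.assign(apa=per_loop)
    loops.aggregate_apa = _apa_ratio(mean_map, h, q)
    return loops


def _apa_ratio(sub: np.ndarray, h: int, q: int) -> float:
    centre = np.nanmean(sub[h - 1:h + 2, h - 1:h + 2])
    corner = np.nanmean(sub[-q:, :q])  # lower-left: shorter-distance background
    if not np.isfinite(corner) or corner == 0:
        return np.nan
    return float(centre / corner)


def filter_apa_outliers(loops: LoopSet, z_max: float = 3.0) -> tuple[LoopSet, pd.DataFrame]:
    """Remove loops whose log-APA is an outlier of the set's distribution.

    Loops with ``|z| > z_max`` on log APA are dropped (both tails — very
    high-intensity signals typically mark rearrangement or assembly
    artefacts).  Returns the filtered set and the removed rows.
    """
    if len(loops) < 10:
        raise ValueError("need at least 10 loops to estimate the APA distribution")
    if "apa" not in loops.table:
        raise ValueError("run apa() before filtering")
    log_apa = np.log(loops.table["apa"].to_numpy(float))
    ok = np.isfinite(log_apa)
    mu, sd = log_apa[ok].mean(), log_apa[ok].std()
    if sd == 0:
        z = np.zeros_like(log_apa)
    else:
        z = (log_apa - mu) / sd
    keep = ~ok | (np.abs(z) <= z_max)
    removed = loops.table[~keep]
    filtered = LoopSet(
        chrom=loops.chrom, bin_size=loops.bin_size,
        table=loops.table[keep].reset_index(drop=True),
        anchor_width=loops.anchor_width, aggregate_apa=loops.aggregate_apa,
    )
    return filtered, removed


def quantile_normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalisation across columns (mean-of-sorted reference,
    mid-rank ties)."""
    arr = df.to_numpy(float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        ranks = pd.Series(arr[:, j]).rank(method="average").to_numpy() - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        frac = ranks - lo
        out[:, j] = ref[lo] * (1 - frac) + ref[np.minimum(hi, n - 1)] * frac
    return pd.DataFrame(out, columns=df.columns, index=df.index)


def _window_cpm(track: np.ndarray, track_bin: int, centre_bp: np.ndarray,
                window: int) -> np.ndarray:
    total = track.sum()
    half = window // 2
    out = np.empty(centre_bp.size)
    csum = np.concatenate([[0.0], np.cumsum(track)])
    nt = track.size
    lo = np.clip((centre_bp - half) // track_bin, 0, nt)
    hi = np.clip(-(-(centre_bp + half) // track_bin), 0, nt)
    out = csum[hi] - csum[lo]
    return out / total * 1e6 if total > 0 else out


def classify_anchors(
    loops: LoopSet,
    tracks: dict[str, dict[str, np.ndarray]],
    track_bin: int,
    window: int = 2_000,
    activity_quantile: float | None = None,
    enhancer_mark: str = "h3k4me1",
) -> AnchorAnnotation:
    """Assign promoter/enhancer/undefined identity to loop anchors.

    CPM coverage of H3K4me3 and the configured enhancer mark (H3K4me1 or
    H3K4me2) is computed in a ``window`` around each anchor centre together
    with genome-wide tiling windows and quantile-normalised across marks.
    The per-mark activity threshold is the Li cross-entropy threshold of the
    pooled window-coverage distribution (it falls in the gap between the
    background bulk and signal-bearing windows); pass ``activity_quantile``
    to use a plain genome-wide coverage quantile instead.  Classes: P when
    H3K4me3 is active and >= the enhancer mark, E when the enhancer mark is
    active without H3K4me3, U otherwise.
    """
    marks = ("h3k4me3", enhancer_mark)
    for mk in marks:
        if loops.chrom not in tracks[mk]:
            raise ValueError(f"track {mk} missing chromosome {loops.chrom}")
    anchors = loops.unique_anchors()
    centre = (anchors["bin"].to_numpy() * loops.bin_size
              + loops.bin_size // 2)
    # genome-wide tiling windows give the activity threshold a reference
    nt = tracks[marks[0]][loops.chrom].size
    tiles = np.arange(window // 2, nt * track_bin - window // 2, window)
    cov = {}
    for mk in marks:
        tr = tracks[mk][loops.chrom]
        cov[mk] = np.concatenate([
            _window_cpm(tr, track_bin, centre, window),
            _window_cpm(tr, track_bin, tiles, window),
        ])
    qn = quantile_normalize_columns(pd.DataFrame(cov))
    if activity_quantile is not None:
        thr = {
            mk: np.quantile(qn[mk].to_numpy()[len(centre):], activity_quantile)
            for mk in marks
        }
    else:
        from .insulation import li_threshold
        thr = {mk: li_threshold(qn[mk].to_numpy()) for mk in marks}
    me3 = qn["h3k4me3"].to_numpy()[:len(centre)]
    me1 = qn[enhancer_mark].to_numpy()[:len(centre)]
    classes = np.full(len(centre), "U", dtype="U1")
    classes[(me3 >= thr["h3k4me3"]) & (me3 >= me1)] = "P"
    classes[(me1 >= thr[enhancer_mark]) & (me3 < thr["h3k4me3"])] = "E"
    anchors = anchors.assign(
        cpm_h3k4me3=me3, **{f"cpm_{enhancer_mark}": me1}, **{"class": classes})

    by_bin = dict(zip(anchors["bin"], classes))
    loop_cls = []
    for row in loops.table.itertuples():
        c1, c2 = by_bin[row.bin1], by_bin[row.bin2]
        if "U" in (c1, c2):
            loop_cls.append("U")
        else:
            loop_cls.append("-".join(sorted((c1, c2), reverse=True)))  # P before E
    loop_classes = pd.Series(loop_cls, index=loops.table.index)
    return AnchorAnnotation(
        anchors=anchors, window=window, loop_classes=loop_classes,
        category_counts=loop_classes.value_counts(),
    )


def promoter_hubs(
    loops: LoopSet,
    annotation: AnchorAnnotation,
    genes: pd.DataFrame | None = None,
) -> list[PromoterHub]:
    """Connected components of the promoter-promoter loop graph (>= 2 promoters).

    Nodes are P-classified anchors; edges are P-P loops.  Member genes are
    the nearest TSS per promoter anchor when a gene table is given.
    """
    p_anchors = annotation.anchors.loc[
        annotation.anchors["class"] == "P", "bin"].to_numpy()
    index = {b: i for i, b in enumerate(p_anchors)}
    pp = loops.table[annotation.loop_classes == "P-P"]
    if len(index) == 0 or pp.empty:
        return []
    src = [index[b] for b in pp.bin1]
    dst = [index[b] for b in pp.bin2]
    n = len(index)
    graph = coo_matrix((np.ones(len(src)), (src, dst)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    hubs: list[PromoterHub] = []
    tss = None
    if genes is not None and len(genes):
        sub = genes[genes.chrom == loops.chrom]
        tss = (sub["tss"].to_numpy(float), sub["gene_id"].to_numpy())
    for comp in range(n_comp):
        members = p_anchors[labels == comp]
        if members.size < 2:
            continue
        member_genes = []
        if tss is not None and tss[0].size:
            for b in members:
                centre = b * loops.bin_size + loops.bin_size // 2
                member_genes.append(tss[1][np.argmin(np.abs(tss[0] - centre))])
            member_genes = sorted(set(member_genes))
        hubs.append(PromoterHub(
            anchors=sorted(int(b) for b in members),
            genes=member_genes,
            span=int((members.max() - members.min() + 1) * loops.bin_size),
        ))
    hubs.sort(key=lambda h: h.anchors[0])
    return hubs


def classify_genes_gp(
    genes: pd.DataFrame,
    atac_peaks: pd.DataFrame,
    k4me3_peaks: pd.DataFrame,
    loops: LoopSet,
    tss_window: int = 1_000,
) -> pd.DataFrame:
    """GP1/GP2/GP3 gene groups from peak and loop evidence at the TSS.

    GP1: ATAC and H3K4me3 peaks at the TSS and the TSS overlaps a loop
    anchor.  GP2: peaks but no loop (a single mark gives GP2 with
    ``partial=True``).  GP3: no peaks.  Flags are evaluated within
    ``+-tss_window`` bp of the TSS.
    """
    rows = []
    anchors = loops.anchor_intervals()
    a_starts = np.concatenate([anchors.start1.to_numpy(float),
                               anchors.start2.to_numpy(float)])
    a_ends = np.concatenate([anchors.end1.to_numpy(float),
                             anchors.end2.to_numpy(float)])
    for g in genes.itertuples():
        if not np.isfinite(g.tss):
            continue
        lo, hi = g.tss - tss_window, g.tss + tss_window
        has_atac = _any_overlap(atac_peaks, g.chrom, lo, hi)
        has_me3 = _any_overlap(k4me3_peaks, g.chrom, lo, hi)
        in_loop = bool(g.chrom == loops.chrom
                       and ((a_starts < hi) & (a_ends > lo)).any())
        if has_atac and has_me3:
            group = "GP1" if in_loop else "GP2"
            partial = False
        elif has_atac or has_me3:
            group = "GP2"
            partial = True
        else:
            group = "GP3"
            partial = False
        rows.append((g.gene_id, g.chrom, g.tss, has_atac, has_me3, in_loop,
                     group, partial))
    return pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "tss", "atac_peak", "h3k4me3_peak",
        "loop_anchor", "group", "partial"])


def gene_group_apa(
    oe: np.ndarray,
    gp_table: pd.DataFrame,
    bin_size: int,
    chrom: str,
    half_window: int = 10,
    max_pairs: int = 500,
) -> dict[str, float]:
    """Aggregate APA of promoter-promoter pairs within each gene group.

    For every group (GP1/GP2/GP3), consecutive same-group TSS bins are paired
    and scored with :func:`apa`; looped GP1 promoters pile up enriched
    (>1) while GP2/GP3 pairs sit at background (~1).  Groups whose pairs all
    fall too close to the diagonal or matrix edge return NaN.
    """
    out: dict[str, float] = {}
    sub = gp_table[gp_table.chrom == chrom]
    for group, rows in sub.groupby("group"):
        bins = np.sort((rows.tss.to_numpy(float) // bin_size).astype(int))
        pairs = [(int(a), int(b)) for a, b in zip(bins, bins[1:])
                 if b - a > 2 * half_window][:max_pairs]
        if not pairs:
            out[group] = np.nan
            continue
        pseudo = LoopSet(chrom=chrom, bin_size=bin_size, table=pd.DataFrame({
            "bin1": [p[0] for p in pairs], "bin2": [p[1] for p in pairs],
            "enrichment": 1.0, "count": 0.0}))
        try:
            apa(oe, pseudo, half_window=half_window)
            out[group] = float(pseudo.aggregate_apa)
        except ValueError:
            out[group] = np.nan
    return out


def _any_overlap(peaks: pd.DataFrame, chrom: str, lo: float, hi: float) -> bool:
    if peaks is None or not len(peaks):
        return False
    sub = peaks[peaks.chrom == chrom]
    return bool(((sub.start.to_numpy(float) < hi)
                 & (sub.end.to_numpy(float) > lo)).any())


def loop_statistics(
    loops: LoopSet,
    annotation: AnchorAnnotation,
    genes: pd.DataFrame | None = None,
    exons: pd.DataFrame | None = None,
) -> dict:
    """Summary statistics of an annotated loop set.

    Median loop span (bp); histogram of enhancer partners per promoter over
    P-E loops; genomic context of E anchors (exonic > intronic > intergenic
    by interval-overlap precedence) when gene/exon tables are given.
    """
    spans = (loops.table.bin2 - loops.table.bin1).to_numpy() * loops.bin_size
    out: dict = {
        "n_loops": len(loops),
        "median_span": float(np.median(spans)) if len(loops) else np.nan,
        "category_counts": annotation.category_counts.to_dict(),
    }
    by_bin = dict(zip(annotation.anchors["bin"], annotation.anchors["class"]))
    partners: dict[int, set[int]] = {}
    for row in loops.table.itertuples():
        c1, c2 = by_bin[row.bin1], by_bin[row.bin2]
        if {c1, c2} == {"P", "E"}:
            p = row.bin1 if c1 == "P" else row.bin2
            e = row.bin2 if c1 == "P" else row.bin1
            partners.setdefault(p, set()).add(e)
    hist: dict[int, int] = {}
    for p, es in partners.items():
        hist[len(es)] = hist.get(len(es), 0) + 1
    out["enhancers_per_promoter"] = dict(sorted(hist.items()))

    if genes is not None:
        e_bins = annotation.anchors.loc[
            annotation.anchors["class"] == "E", "bin"].to_numpy()
        contexts = []
        gsub = genes[genes.chrom == loops.chrom]
        esub = exons[exons.chrom == loops.chrom] if exons is not None else None
        for b in e_bins:
            lo = b * loops.bin_size
            hi = lo + loops.bin_size
            if esub is not None and len(esub) and (
                    (esub.start.to_numpy(float) < hi)
                    & (esub.end.to_numpy(float) > lo)).any():
                contexts.append("exonic")
            elif len(gsub) and ((gsub.start.to_numpy(float) < hi)
                                & (gsub.end.to_numpy(float) > lo)).any():
                contexts.append("intronic")
            else:
                contexts.append("intergenic")
        out["enhancer_context"] = pd.Series(contexts).value_counts().to_dict()
    return out
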