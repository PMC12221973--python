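"""Diamond insulation profiles, boundary calling and classification.

The insulation score of a bin is the log2 ratio of the mean balanced signal
in a diamond window crossing that bin to the chromosome-wide mean of such
diamonds; local minima of the score are insulation boundaries.  Boundary
strength is the topographic prominence of the minimum, split into strong and
weak classes at the Li minimum cross-entropy threshold of the strength
distribution.  Boundaries are then classified hierarchically against loop
anchors, TSSs, accessible regions and compartment limits, and inter-boundary
domains are averaged into rescaled pile-ups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .matrix import ContactMatrix, coarsen_counts, ice_balance

__all__ = [
    "InsulationProfile",
    "BoundarySet",
    "insulation_profile",
    "scan_parameters",
    "call_boundaries",
    "li_threshold",
    "classify_boundaries",
    "rescaled_pileup",
]

BOUNDARY_CLASSES = ("loop-anchor", "TSS", "accessible", "compartment-limit",
                    "unassigned")


@dataclass
class InsulationProfile:
    chrom: str
    bin_size: int
    window: int  # bp
    scores: np.ndarray  # log2, NaN where undefined


@dataclass
class BoundarySet:
    """Called insulation boundaries for one chromosome."""

    chrom: str
    bin_size: int
    bins: np.ndarray  # boundary bin indices
    strength: np.ndarray  # prominence of the insulation minimum
    strong: np.ndarray  # bool, strength >= Li threshold
    li_threshold: float
    classes: np.ndarray | None = None  # one of BOUNDARY_CLASSES

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.chrom,
            "start": self.bins * self.bin_size,
            "end": (self.bins + 1) * self.bin_size,
            "bin": self.bins,
            "strength": self.strength,
            "strong": self.strong,
        })
        if self.classes is not None:
            df["class"] = self.classes
        return df


def insulation_profile(m: ContactMatrix, window: int) -> InsulationProfile:
    """Per-bin diamond insulation score at one window size.

    ``score(i) = log2(mean diamond [i-w, i) x (i, i+w] / mean over bins)``;
    NaN where less than half of the diamond lies in valid bins or within
    ``w`` bins of the chromosome edge.
    """
    if window % m.bin_size != 0:
        raise ValueError("window must be a multiple of the bin size")
    w = window // m.bin_size
    n = m.n_bins
    if window >= (n * m.bin_size) / 2:
        raise ValueError("window must be smaller than half the chromosome")
    bal = m.balanced
    filled = np.nan_to_num(bal, nan=0.0)
    ok = np.isfinite(bal).astype(float)
    # summed-area tables for O(1) diamond sums
    S = np.zeros((n + 1, n + 1))
    C = np.zeros((n + 1, n + 1))
    S[1:, 1:] = filled.cumsum(0).cumsum(1)
    C[1:, 1:] = ok.cumsum(0).cumsum(1)

    def block(tab, r0, r1, c0, c1):
        return tab[r1, c1] - tab[r0, c1] - tab[r1, c0] + tab[r0, c0]

    means = np.full(n, np.nan)
    for i in range(w, n - w):
        r0, r1 = i - w, i
        c0, c1 = i + 1, i + w + 1
        cnt = block(C, r0, r1, c0, c1)
        if cnt >= 0.5 * w * w:
            means[i] = block(S, r0, r1, c0, c1) / cnt
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom_mean = np.nanmean(means)
        scores = np.log2(means / chrom_mean)
    return InsulationProfile(chrom=m.chrom, bin_size=m.bin_size, window=window,
                             scores=scores)


def _minima_with_prominence(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local minima of the score and their topographic prominence."""
    x = -scores
    filler = np.nanmin(x) - 1.0 if np.isfinite(x).any() else 0.0
    xf = np.where(np.isfinite(x), x, filler)
    peaks, props = find_peaks(xf, prominence=0.0)
    keep = np.isfinite(scores[peaks])
    return peaks[keep], props["prominences"][keep]


def li_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Li minimum cross-entropy threshold of a value distribution.

    The histogram threshold minimising the Li-Lee cross-entropy between the
    data and its two-level (below/above) reconstruction, found by exhaustive
    search over histogram bin edges.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least two distinct values")
    shift = 0.0
    if x.min() <= 0:  # objective needs positive support
        shift = -x.min() + np.ptp(x) * 1e-3
        x = x + shift
    hist, edges = np.histogram(x, bins=n_bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * centres)
    total_w, total_wx = cw[-1], cwx[-1]
    best_t, best_obj = centres[0], np.inf
    for k in range(1, n_bins):
        w0, w1 = cw[k - 1], total_w - cw[k - 1]
        if w0 == 0 or w1 == 0:
            continue
        m0 = cwx[k - 1] / w0
        m1 = (total_wx - cwx[k - 1]) / w1
        if m0 <= 0 or m1 <= 0:
            continue
        obj = -(cwx[k - 1] * np.log(m0) + (total_wx - cwx[k - 1]) * np.log(m1))
        if obj < best_obj:
            best_obj, best_t = obj, edges[k]
    return float(best_t - shift)


def call_boundaries(
    profile: InsulationProfile | list[InsulationProfile],
    unmappable: list[tuple[int, int]] | None = None,
    strength_threshold: float | None = None,
    mask_margin: int = 2,
) -> BoundarySet:
    """Boundaries as prominence-graded local minima of the insulation score.

    When two profiles (the two optimal windows) are given, a minimum must
    appear in both within one bin; the position and strength from the first
    (smaller-window) profile are reported.  Minima within ``mask_margin``
    bins of an unmappable interval are removed.  The strong/weak split uses
    the Li threshold of the strength distribution unless an explicit
    ``strength_threshold`` is passed.
    """
    profiles = profile if isinstance(profile, list) else [profile]
    p0 = profiles[0]
    if np.isfinite(p0.scores).sum() < 10:
        raise ValueError("fewer than 10 finite insulation scores")
    bins, strength = _minima_with_prominence(p0.scores)
    for other in profiles[1:]:
        ob, _ = _minima_with_prominence(other.scores)
        if ob.size:
            near = np.min(np.abs(bins[:, None] - ob[None, :]), axis=1) <= 1
        else:
            near = np.zeros(bins.size, dtype=bool)
        bins, strength = bins[near], strength[near]
    if unmappable:
        bad = np.zeros(bins.size, dtype=bool)
        for s, e in unmappable:
            lo = s // p0.bin_size - mask_margin
            hi = -(-e // p0.bin_size) + mask_margin
            bad |= (bins >= lo) & (bins < hi)
        bins, strength = bins[~bad], strength[~bad]
    if strength_threshold is None:
        if strength.size >= 2 and np.ptp(strength) > 0:
            thr = li_threshold(strength)
        else:
            thr = 0.0
    else:
        thr = strength_threshold
    return BoundarySet(
        chrom=p0.chrom, bin_size=p0.bin_size, bins=bins, strength=strength,
        strong=strength >= thr, li_threshold=thr,
    )


def scan_parameters(
    counts: np.ndarray,
    base_bin: int,
    chrom: str,
    resolutions: list[int],
    window_multipliers: tuple[int, ...] = (5, 10, 25),
    criterion: str = "prominence",
) -> tuple[int, int, int, pd.DataFrame]:
    """Choose the (resolution, window, window) grid point with the strongest
    partitioning.

    For every resolution (a multiple of ``base_bin``) the raw counts are
    coarsened, re-balanced, and the insulation profile computed at each
    window multiplier.  The score of a grid point is the mean boundary
    prominence (``criterion='prominence'``, default) or the mean absolute
    insulation score (``criterion='absolute'``).  Returns the best
    resolution, its two best windows (ascending) and the full grid report.
    Ties break to the smallest resolution, then smallest windows.
    """
    if len(resolutions) < 2:
        raise ValueError("need at least 2 resolutions to scan")
    rows = []
    for res in sorted(resolutions):
        k = res // base_bin
        if k < 1 or res % base_bin:
            raise ValueError(f"resolution {res} is not a multiple of {base_bin}")
        coarse = coarsen_counts(counts, k)
        m = ContactMatrix(chrom, res, coarse)
        try:
            ice_balance(m)
        except (ValueError, RuntimeError):
            continue
        for mult in window_multipliers:
            window = mult * res
            try:
                prof = insulation_profile(m, window)
                bins, strength = _minima_with_prominence(prof.scores)
            except ValueError:
                continue
            if criterion == "prominence":
                score = float(strength.mean()) if strength.size else np.nan
            else:
                score = float(np.nanmean(np.abs(prof.scores)))
            rows.append((res, window, mult, bins.size, score))
    report = pd.DataFrame(
        rows, columns=["resolution", "window", "multiplier", "n_boundaries", "score"]
    )
    usable = report.dropna(subset=["score"])
    usable = usable[usable["n_boundaries"] > 0]
    if usable.empty:
        raise ValueError("no boundaries found anywhere on the scan grid")
    per_res = usable.groupby("resolution")["score"].mean()
    best_res = int(per_res.sort_index().idxmax())
    at_res = usable[usable.resolution == best_res].sort_values(
        ["score", "window"], ascending=[False, True], kind="stable")
    windows = sorted(at_res["window"].head(2).tolist())
    if len(windows) == 1:
        windows.append(windows[0])
    return best_res, int(windows[0]), int(windows[1]), report


def classify_boundaries(
    b: BoundarySet,
    loops: pd.DataFrame | None,
    tss: pd.DataFrame | None,
    accessible: pd.DataFrame | None,
    limits: pd.DataFrame | None,
    tolerance: int = 1,
) -> BoundarySet:
    """Hierarchical boundary classification by strict feature precedence.

    loop-anchor > TSS (of genes not at loop anchors) > accessible >
    compartment-limit > unassigned.  A feature matches when its interval
    comes within ``tolerance`` bins of the boundary bin.  Input tables use
    bp coordinates (``chrom``/``start``/``end``; loops in BEDPE layout with
    both anchors; limits with a ``bin`` column).
    """
    bs = b.bin_size
    tol_bp = tolerance * bs
    classes = np.full(b.bins.size, "unassigned", dtype="U17")
    b_start = b.bins * bs
    b_end = b_start + bs

    def hits(starts, ends):
        if starts.size == 0:
            return np.zeros(b.bins.size, dtype=bool)
        s = starts[None, :] - tol_bp
        e = ends[None, :] + tol_bp
        return ((b_start[:, None] < e) & (b_end[:, None] > s)).any(axis=1)

    anchor_tables = []
    loop_gene_mask = None
    if loops is not None and len(loops):
        _check_chrom(loops, b.chrom, "loops")
        sub = loops[(loops.chrom1 == b.chrom) | (loops.chrom2 == b.chrom)]
        a_starts = np.concatenate([
            sub.loc[sub.chrom1 == b.chrom, "start1"].to_numpy(float),
            sub.loc[sub.chrom2 == b.chrom, "start2"].to_numpy(float)])
        a_ends = np.concatenate([
            sub.loc[sub.chrom1 == b.chrom, "end1"].to_numpy(float),
            sub.loc[sub.chrom2 == b.chrom, "end2"].to_numpy(float)])
        anchor_tables = [a_starts, a_ends]
        la = hits(a_starts, a_ends)
        classes[la] = "loop-anchor"
    if tss is not None and len(tss):
        _check_chrom(tss, b.chrom, "tss")
        sub = tss[tss.chrom == b.chrom]
        pos = sub["tss"].to_numpy(float) if "tss" in sub else sub["start"].to_numpy(float)
        # genes whose TSS sits at a loop anchor do not count for the TSS class
        if anchor_tables:
            a_starts, a_ends = anchor_tables
            in_loop = ((pos[:, None] >= a_starts[None, :] - tol_bp)
                       & (pos[:, None] < a_ends[None, :] + tol_bp)).any(axis=1)
            pos = pos[~in_loop]
        t = hits(pos, pos + 1)
        classes[t & (classes == "unassigned")] = "TSS"
    if accessible is not None and len(accessible):
        _check_chrom(accessible, b.chrom, "accessible")
        sub = accessible[accessible.chrom == b.chrom]
        a = hits(sub.start.to_numpy(float), sub.end.to_numpy(float))
        classes[a & (classes == "unassigned")] = "accessible"
    if limits is not None and len(limits):
        sub = limits[limits.chrom == b.chrom]
        pos = sub["bin"].to_numpy(float) * bs
        c = hits(pos, pos + 1)
        classes[c & (classes == "unassigned")] = "compartment-limit"
    b.classes = classes
    return b


def _check_chrom(df: pd.DataFrame, chrom: str, name: str) -> None:
    cols = [c for c in ("chrom", "chrom1", "chrom2") if c in df.columns]
    seen = set()
    for c in cols:
        seen.update(df[c].unique())
    if seen and chrom not in seen:
        raise ValueError(
            f"{name}: chromosome {chrom!r} absent; found {sorted(seen)!r}"
        )


def _resample_1d(length: int, grid: int) -> np.ndarray:
    """Area-weighted resampling matrix mapping ``length`` cells to ``grid``."""
    R = np.zeros((grid, length))
    scale = length / grid
    for g in range(grid):
        lo, hi = g * scale, (g + 1) * scale
        for cell in range(int(np.floor(lo)), min(length, int(np.ceil(hi)))):
            overlap = min(hi, cell + 1) - max(lo, cell)
            if overlap > 0:
                R[g, cell] = overlap
    return R


def rescaled_pileup(
    oe: np.ndarray,
    b: BoundarySet,
    max_span: int = 100_000,
    grid: int = 30,
) -> tuple[np.ndarray, int]:
    """Average rescaled O/E map of inter-boundary domains with flanks.

    Domains are the intervals between consecutive strong boundaries no
    further apart than ``max_span``.  Each domain submatrix, extended by one
    domain length on each side, is area-resampled onto a ``3*grid`` square
    (the central third is the domain) and averaged element-wise.  Returns
    ``(pileup, n_domains)``.
    """
    strong = np.sort(b.bins[b.strong])
    n = oe.shape[0]
    spans = []
    for s, e in zip(strong, strong[1:]):
        if (e - s) * b.bin_size <= max_span and e - s >= 2:
            spans.append((int(s), int(e)))
    if not spans:
        raise ValueError(f"no inter-boundary domains within {max_span} bp")
    G = 3 * grid
    acc = np.zeros((G, G))
    cnt = np.zeros((G, G))
    used = 0
    for s, e in spans:
        L = e - s
        lo, hi = s - L, e + L
        if lo < 0 or hi > n:
            continue
        sub = oe[lo:hi, lo:hi]
        R = _resample_1d(hi - lo, G)
        fin = np.isfinite(sub)
        vals = np.where(fin, sub, 0.0)
        num = R @ vals @ R.T
        den = R @ fin.astype(float) @ R.T
        with np.errstate(invalid="ignore", divide="ignore"):
            res = np.where(den > 0, num / den, np.nan)
        ok = np.isfinite(res)
        acc[ok] += res[ok]
        cnt[ok] += 1
        used += 1
    if used == 0:
        raise ValueError("all qualifying domains fell off the matrix edge")
    with np.errstate(invalid="ignore", divide="ignore"):
        pileup = np.where(cnt > 0, acc / cnt, np.nan)
    return pileup, used
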