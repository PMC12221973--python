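"""Contact-matrix normalisation and comparison.

Holds the per-chromosome :class:`ContactMatrix` container and the standard
Hi-C/Micro-C matrix operations: iterative-correction (ICE) balancing,
distance-decay expected profiles, observed-over-expected transformation and
the stratum-adjusted correlation coefficient (SCC) for map reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

__all__ = [
    "ContactMatrix",
    "DecayProfile",
    "MatrixComparison",
    "ice_balance",
    "resolution_for_bin_count",
    "coarsen_counts",
    "expected_by_distance",
    "diagonal_means",
    "smooth_diagonal_means",
    "observed_over_expected",
    "scc",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact map for one chromosome.

    ``counts`` is the dense raw matrix; ``weights`` the multiplicative ICE
    bias correction per bin (NaN for invalid bins); ``valid`` marks bins that
    survived the coverage filter.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    weights: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if self.valid is None:
            self.valid = self.counts.sum(axis=0) > 0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def bins(self) -> pd.DataFrame:
        starts = np.arange(self.n_bins) * self.bin_size
        return pd.DataFrame({
            "chrom": self.chrom, "start": starts, "end": starts + self.bin_size,
        })

    @property
    def balanced(self) -> np.ndarray:
        """Bias-corrected matrix; invalid bins are NaN."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; run ice_balance first")
        w = self.weights
        return self.counts * w[:, None] * w[None, :]


@dataclass
class DecayProfile:
    """Mean balanced contact frequency as a function of genomic distance."""

    distances: np.ndarray
    frequency: np.ndarray
    per_chrom: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class MatrixComparison:
    scc: float
    per_chrom: dict[str, float]
    resolution: int


def resolution_for_bin_count(genome_length: int, target_bins: int,
                             base_bin: int) -> int:
    """Resolution (bp) giving roughly ``target_bins`` genome-wide.

    Analysis resolutions are specified as target genome-wide bin counts
    (e.g. 5,000 / 10,000 / 20,000 / 50,000 bins) so that species with very
    different genome sizes are analysed at comparable granularity; the
    result is rounded to the nearest multiple of the base bin size (minimum
    one base bin).
    """
    if target_bins <= 0 or base_bin <= 0:
        raise ValueError("target_bins and base_bin must be positive")
    raw = genome_length / target_bins
    return max(base_bin, int(round(raw / base_bin)) * base_bin)


def coarsen_counts(counts: np.ndarray, factor: int) -> np.ndarray:
    """Aggregate a count matrix into ``factor``-times-larger bins."""
    if factor == 1:
        return counts
    n = counts.shape[0]
    nk = -(-n // factor)
    pad = nk * factor - n
    padded = np.pad(counts, ((0, pad), (0, pad)))
    return padded.reshape(nk, factor, nk, factor).sum(axis=(1, 3))


def ice_balance(
    m: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-9,
    coverage_fraction: float = 0.02,
) -> ContactMatrix:
    """Iterative-correction balancing to equalise bin marginals.

    Bins whose raw marginal is below ``coverage_fraction`` of the median
    non-zero marginal are flagged invalid and excluded.  On convergence every
    valid bin's marginal of the balanced matrix equals the number of valid
    bins (mean balanced value 1), with coefficient of variation below ``tol``.
    Weights are stored on the returned matrix (same object, updated in place).
    """
    counts = m.counts
    marg = counts.sum(axis=0)
    nonzero = marg[marg > 0]
    if nonzero.size < 2:
        raise ValueError("fewer than 2 bins with signal; cannot balance")
    valid = marg >= coverage_fraction * np.median(nonzero)
    if valid.sum() < 2:
        raise ValueError("fewer than 2 valid bins after coverage filter")

    sub = counts[np.ix_(valid, valid)]
    bias = np.ones(sub.shape[0])
    converged = False
    for it in range(1, max_iter + 1):
        s = (sub * bias[None, :]).sum(axis=1) * bias
        s_mean = s.mean()
        if s_mean == 0:
            raise ValueError("all-zero marginals during balancing")
        s /= s_mean
        cv = s.std() / s.mean()
        bias /= np.sqrt(np.where(s > 0, s, 1.0))
        if cv < tol:
            converged = True
            break
    if not converged:
        s = (sub * bias[None, :]).sum(axis=1) * bias
        resid = s.std() / s.mean()
        raise RuntimeError(
            f"ICE did not converge in {max_iter} iterations "
            f"(marginal CV residual {resid:.3e})"
        )
    # scale weights so valid-bin marginals of the balanced matrix equal 1
    bal = sub * bias[:, None] * bias[None, :]
    scale = np.sqrt(bal.sum(axis=0).mean())
    bias /= scale if scale > 0 else 1.0

    weights = np.full(m.n_bins, np.nan)
    weights[valid] = bias
    m.weights = weights
    m.valid = valid
    return m


def diagonal_means(m: ContactMatrix) -> np.ndarray:
    """Mean balanced value of each diagonal over valid-bin pairs.

    Distances with no valid pair are NaN.  This is the exact per-distance
    expected used by :func:`observed_over_expected`.
    """
    bal = m.balanced
    n = m.n_bins
    out = np.full(n, np.nan)
    vmask = np.outer(m.valid, m.valid)
    for d in range(n):
        vals = np.diagonal(bal, offset=d)
        ok = np.diagonal(vmask, offset=d)
        if ok.any():
            out[d] = vals[ok].mean()
    return out


def expected_by_distance(
    matrices: dict[str, ContactMatrix] | ContactMatrix,
    min_dist: int = 1_000,
    max_dist: int = 100_000_000,
    ratio: float = 1.12,
) -> DecayProfile:
    """Distance-decay curve on a log-spaced grid, averaged across chromosomes.

    Per-chromosome curves are computed on a shared geometric grid (step
    ``ratio``) spanning ``min_dist`` to ``max_dist`` clipped to chromosome
    length, then averaged with equal chromosome weight.
    """
    if isinstance(matrices, ContactMatrix):
        matrices = {matrices.chrom: matrices}
    n_steps = int(np.ceil(np.log(max_dist / min_dist) / np.log(ratio)))
    edges = min_dist * ratio ** np.arange(n_steps + 1)
    centres = np.sqrt(edges[:-1] * edges[1:])
    per_chrom: dict[str, np.ndarray] = {}
    for chrom, m in matrices.items():
        dmeans = diagonal_means(m)
        dists_bp = np.arange(m.n_bins) * m.bin_size
        curve = np.full(centres.size, np.nan)
        which = np.searchsorted(edges, dists_bp, side="right") - 1
        for k in range(centres.size):
            sel = (which == k) & np.isfinite(dmeans)
            if sel.any():
                curve[k] = dmeans[sel].mean()
        per_chrom[chrom] = curve
    stacked = np.vstack(list(per_chrom.values()))
    fin = np.isfinite(stacked)
    tot = np.where(fin, stacked, 0.0).sum(axis=0)
    cnt = fin.sum(axis=0)
    avg = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return DecayProfile(distances=centres, frequency=avg, per_chrom=per_chrom)


def smooth_diagonal_means(dmeans: np.ndarray, frac: float = 0.25) -> np.ndarray:
    """Smooth per-diagonal means over a geometric distance window.

    Each distance d is replaced by the pair-count-weighted average of the
    means at distances within ``d*(1 +- frac)``.  Smoothing suppresses both
    sampling noise and the aliasing of planted segmental structure into the
    distance curve; it is the right expected for saddle and pile-up
    analyses, whereas the raw per-diagonal means give the exactly-unit
    diagonal normalisation.
    """
    n = dmeans.size
    out = np.full(n, np.nan)
    out[0] = dmeans[0]
    counts = (n - np.arange(n)).astype(float)
    for i in range(1, n):
        lo = max(1, int(np.floor(i * (1 - frac))))
        hi = min(n, int(np.ceil(i * (1 + frac))) + 1)
        vals = dmeans[lo:hi]
        ok = np.isfinite(vals)
        if ok.any():
            out[i] = np.average(vals[ok], weights=counts[lo:hi][ok])
    return out


def observed_over_expected(m: ContactMatrix, smooth: bool = False,
                           smooth_frac: float = 0.25) -> np.ndarray:
    """O/E matrix: balanced counts over per-diagonal expected means.

    With ``smooth=False`` (default) the expected is the exact per-diagonal
    mean, so every retained diagonal of the result has mean exactly 1 over
    valid pairs.  With ``smooth=True`` the expected is smoothed over a
    geometric distance window first (see :func:`smooth_diagonal_means`),
    which compartment and pile-up analyses should prefer.  Pixels involving
    invalid bins, or at distances with zero expected, are NaN.
    """
    bal = m.balanced
    n = m.n_bins
    dmeans = diagonal_means(m)
    if smooth:
        dmeans = smooth_diagonal_means(dmeans, frac=smooth_frac)
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    exp = dmeans[dist]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp > 0, bal / exp, np.nan)
    invalid = ~m.valid
    oe[invalid, :] = np.nan
    oe[:, invalid] = np.nan
    return oe


def _smooth(mat: np.ndarray, span: int) -> np.ndarray:
    if span <= 1:
        return mat
    filled = np.nan_to_num(mat, nan=0.0)
    mask = np.isfinite(mat).astype(float)
    num = uniform_filter(filled, size=span, mode="constant")
    den = uniform_filter(mask, size=span, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    out[~np.isfinite(mat)] = np.nan
    return out


def scc(
    a: dict[str, ContactMatrix] | ContactMatrix,
    b: dict[str, ContactMatrix] | ContactMatrix,
    max_dist: int = 5_000_000,
    smooth_span: int = 3,
) -> MatrixComparison:
    """Stratum-adjusted correlation coefficient between two maps.

    Both maps are 2D mean-filter smoothed, then Pearson correlations are
    computed per diagonal (stratum) up to ``max_dist`` and combined as a
    weighted mean with weights ``N_d * sqrt(var_a var_d)`` (variance-
    stabilised stratum weighting).  Per-chromosome SCCs are averaged.
    Strata with fewer than 3 valid pairs, or zero variance in either map,
    are skipped.
    """
    if isinstance(a, ContactMatrix):
        a = {a.chrom: a}
    if isinstance(b, ContactMatrix):
        b = {b.chrom: b}
    if set(a) != set(b):
        raise ValueError("chromosome sets differ")
    per_chrom: dict[str, float] = {}
    resolution = next(iter(a.values())).bin_size
    for chrom in a:
        ma, mb = a[chrom], b[chrom]
        if ma.n_bins != mb.n_bins or ma.bin_size != mb.bin_size:
            raise ValueError(f"binning differs on {chrom}")
        xa = _smooth(ma.balanced, smooth_span)
        xb = _smooth(mb.balanced, smooth_span)
        dmax = min(ma.n_bins - 1, max_dist // ma.bin_size)
        num = 0.0
        den = 0.0
        for d in range(1, dmax + 1):
            va = np.diagonal(xa, offset=d)
            vb = np.diagonal(xb, offset=d)
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < 3:
                continue
            va, vb = va[ok], vb[ok]
            sa, sb = va.std(), vb.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            w = ok.sum() * sa * sb
            num += w * r
            den += w
        if den == 0:
            continue
        per_chrom[chrom] = num / den
    if not per_chrom:
        raise ValueError("no usable strata in any chromosome")
    return MatrixComparison(
        scc=float(np.mean(list(per_chrom.values()))),
        per_chrom=per_chrom,
        resolution=resolution,
    )
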